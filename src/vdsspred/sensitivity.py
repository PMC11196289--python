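"""logP sensitivity sweeps and fold-error / AFE / AAFE evaluation.

The sweep walks a drug across a logP grid (default 0.5-unit steps,
endpoints inclusive) and records each method's VDss together with the
logP-sensitive intermediates (fut/fup ratio, adipose Kp, muscle Kp).  The
evaluation computes fold errors of predictions against observed VDss and
aggregates them as the average fold error (AFE, geometric-mean bias) and
absolute average fold error (AAFE, geometric-mean precision), grouped by
logP source, by drug, or combined.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import intermediates as im
from .datamodel import (
    DrugRecord,
    MethodConstants,
    METHOD_NAMES,
    PredictionResult,
    TissueComposition,
    load_drug_table,
    load_tissue_table,
)
from .methods import MethodInput, predict

__all__ = [
    "SweepSpec",
    "ErrorSummary",
    "logp_grid",
    "sweep",
    "fold_error",
    "afe",
    "aafe",
    "evaluate",
    "summaries_frame",
    "text_table",
]

GROUPINGS = ("by_source", "by_drug", "combined")


@dataclass(frozen=True)
class SweepSpec:
    """A logP sweep request for one drug.

    ``drug`` may be a DrugRecord or the name of a packaged fixture drug.
    """

    drug: DrugRecord | str
    methods: Sequence[str] = METHOD_NAMES
    logp_min: float = 2.0
    logp_max: float = 7.0
    step: float = 0.5

    def __post_init__(self):
        if not self.logp_min <= self.logp_max:
            raise ValueError("logp_min must not exceed logp_max")
        if not self.step > 0:
            raise ValueError("step must be positive")
        unknown = set(self.methods) - set(METHOD_NAMES)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")


def logp_grid(logp_min: float, logp_max: float, step: float) -> list[float]:
    """Inclusive grid built by integer stepping (no float accumulation)."""
    n = int(math.floor((logp_max - logp_min) / step + 1e-9))
    points = [logp_min + i * step for i in range(n + 1)]
    if points[-1] < logp_max - 1e-9:
        points.append(logp_max)
    return points


def _resolve_drug(drug: DrugRecord | str) -> DrugRecord:
    if isinstance(drug, DrugRecord):
        return drug
    for record in load_drug_table():
        if record.name == drug:
            return record
    raise KeyError(f"unknown drug {drug!r} (not in the packaged table)")


def sweep(
    spec: SweepSpec,
    tissues: Sequence[TissueComposition] | None = None,
    constants: MethodConstants | None = None,
    **options,
) -> pd.DataFrame:
    """Run every requested method across the logP grid.

    Returns a tidy frame with one row per (logp, method) carrying the VDss
    in litres plus the sweep intermediates ``fut_over_fup``, ``kp_adipose``
    and ``kp_muscle`` (tissue-composition Kp = Kpu * fup).  A method
    failure at a grid point is recorded as a flagged row (``ok=False`` with
    the message in ``error``), never a crash.
    """
    drug = _resolve_drug(spec.drug)
    tissues = load_tissue_table() if tissues is None else tissues
    constants = MethodConstants() if constants is None else constants
    adipose = next((t for t in tissues if t.tissue == "adipose"), None)
    muscle = next((t for t in tissues if t.tissue == "muscle"), None)
    rows = []
    for logp in logp_grid(spec.logp_min, spec.logp_max, spec.step):
        f_i = im.fraction_ionized(drug.pka, 7.4, drug.ionization_class)
        fut = im.fut_lombardo(logp, f_i, drug.fup)
        shared = {
            "fut_over_fup": fut / drug.fup,
            "kp_adipose": (
                im.kpu_rodgers_rowland(logp, drug, adipose, constants.rodgers_rowland)
                * drug.fup
                if adipose is not None
                else float("nan")
            ),
            "kp_muscle": (
                im.kpu_rodgers_rowland(logp, drug, muscle, constants.rodgers_rowland)
                * drug.fup
                if muscle is not None
                else float("nan")
            ),
        }
        for method in spec.methods:
            row = {"drug": drug.name, "method": method, "logp": logp, **shared}
            try:
                result = predict(
                    drug, method, logp=logp, tissues=tissues,
                    constants=constants, **options,
                )
                row.update(vdss_L=result.vdss, ok=True, error="")
            except Exception as exc:  # noqa: BLE001 - flagged row by contract
                row.update(vdss_L=float("nan"), ok=False, error=str(exc))
            rows.append(row)
    columns = [
        "drug", "method", "logp", "vdss_L", "ok", "error",
        "fut_over_fup", "kp_adipose", "kp_muscle",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# error metrics


def fold_error(predicted: float, observed: float) -> float:
    """Ratio predicted/observed; both must be positive."""
    if not (predicted > 0 and observed > 0):
        raise ValueError(
            f"fold error needs positive inputs, got {predicted!r}/{observed!r}"
        )
    return predicted / observed


def afe(folds: Iterable[float]) -> float:
    """Average fold error: 10**(mean of log10 fold errors) — bias."""
    folds = [float(f) for f in folds]
    if not folds:
        raise ValueError("afe of an empty list")
    if any(f <= 0 for f in folds):
        raise ValueError("fold errors must be positive")
    return 10.0 ** (sum(math.log10(f) for f in folds) / len(folds))


def aafe(folds: Iterable[float]) -> float:
    """Absolute average fold error: 10**(mean |log10 fold|) — precision."""
    folds = [float(f) for f in folds]
    if not folds:
        raise ValueError("aafe of an empty list")
    if any(f <= 0 for f in folds):
        raise ValueError("fold errors must be positive")
    return 10.0 ** (sum(abs(math.log10(f)) for f in folds) / len(folds))


@dataclass(frozen=True)
class ErrorSummary:
    """AFE/AAFE over one group of fold errors.

    ``folds`` holds (drug, logp_source, method, fold_error) tuples; ``key``
    names the group (a logP source, a drug, or "all").
    """

    grouping: str
    key: str
    method: str
    folds: tuple[tuple[str, str, str, float], ...]
    afe: float
    aafe: float


def _summarise(grouping, key, method, folds) -> ErrorSummary:
    values = [f[3] for f in folds]
    return ErrorSummary(
        grouping=grouping,
        key=key,
        method=method,
        folds=tuple(folds),
        afe=afe(values),
        aafe=aafe(values),
    )


def evaluate(
    predictions: Sequence[PredictionResult],
    observed: Mapping[str, float],
    grouping: str = "by_source",
) -> list[ErrorSummary]:
    """Fold errors of predictions vs observed VDss, aggregated per group.

    ``grouping`` is ``by_source`` (one summary per logP source x method),
    ``by_drug`` (per drug x method) or ``combined`` (all drugs and sources
    per method).  Every prediction's drug must have an observed value.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    folds = []
    for pred in predictions:
        if pred.drug not in observed:
            raise KeyError(f"no observed VDss for {pred.drug!r}")
        folds.append(
            (
                pred.drug,
                pred.logp_source,
                pred.method,
                fold_error(pred.vdss, observed[pred.drug]),
            )
        )
    keyfun = {
        "by_source": lambda f: f[1],
        "by_drug": lambda f: f[0],
        "combined": lambda f: "all",
    }[grouping]
    groups: dict[tuple[str, str], list] = {}
    for f in folds:
        groups.setdefault((keyfun(f), f[2]), []).append(f)
    return [
        _summarise(grouping, key, method, group)
        for (key, method), group in sorted(groups.items())
    ]


def summaries_frame(summaries: Sequence[ErrorSummary]) -> pd.DataFrame:
    """Tidy frame of AFE/AAFE summaries (full precision)."""
    return pd.DataFrame(
        [
            {
                "grouping": s.grouping,
                "key": s.key,
                "method": s.method,
                "n": len(s.folds),
                "afe": s.afe,
                "aafe": s.aafe,
            }
            for s in summaries
        ]
    )


def text_table(summaries: Sequence[ErrorSummary]) -> str:
    """Human-readable AFE/AAFE table (two decimals), methods as columns."""
    frame = summaries_frame(summaries)
    lines = []
    methods = [m for m in METHOD_NAMES if m in set(frame["method"])]
    header = f"{'group':<14}" + "".join(f"{m:>16}" for m in methods)
    sub = f"{'':<14}" + "".join(f"{'AFE':>8}{'AAFE':>8}" for _ in methods)
    lines += [header, sub]
    for key in dict.fromkeys(frame["key"]):
        cells = [f"{key:<14}"]
        sub_frame = frame[frame["key"] == key].set_index("method")
        for m in methods:
            if m in sub_frame.index:
                cells.append(
                    f"{sub_frame.loc[m, 'afe']:>8.2f}{sub_frame.loc[m, 'aafe']:>8.2f}"
                )
            else:
                cells.append(f"{'-':>8}{'-':>8}")
        lines.append("".join(cells))
    return "\n".join(lines) + "\n"
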