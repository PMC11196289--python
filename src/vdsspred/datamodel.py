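"""Domain types, packaged parameter tables, and validated loaders.

The package ships three parameter tables:

* a four-drug physicochemical table (logP by source, pKa, fraction unbound
  in plasma, blood-to-plasma ratio, H-bond counts) together with the
  observed human steady-state volume of distribution from IV studies;
* a 13-tissue composition table (residual-blood-adjusted fractional
  volumes of neutral lipid, neutral phospholipid, extra- and intracellular
  water, tissue-to-plasma albumin and lipoprotein ratios, and absolute
  tissue volumes for a 70-kg human);
* the method constants used by the six prediction models.

User-supplied drug tables (CSV or JSON) are validated against the same
invariants as the packaged data; every validation failure names the field.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "LOGP_SOURCES",
    "METHOD_NAMES",
    "ValidationError",
    "IonizationClass",
    "DrugRecord",
    "TissueComposition",
    "OieTozerConstants",
    "RodgersRowlandConstants",
    "KorzekwaNagarConstants",
    "TcmNewConstants",
    "MethodConstants",
    "PredictionResult",
    "load_drug_table",
    "write_drug_table",
    "load_tissue_table",
    "load_method_constants",
    "load_kn_regression_constants",
    "total_tissue_volume",
]

#: Sources of octanol:water logP values recognised in drug tables.
LOGP_SOURCES = ("admet", "literature", "hplc")

#: The six prediction methods, in canonical reporting order.
METHOD_NAMES = (
    "oie_tozer",
    "rr_tissue",
    "rr_muscle",
    "adjusted_fup",
    "korzekwa_nagar",
    "tcm_new",
)

_DRUG_CSV_COLUMNS = [
    "name", "ionization_class", "pKa", "fup", "bpr",
    "logp_admet", "logp_literature", "logp_hplc",
    "hbd", "hba", "n_so", "n_no2", "dipole", "observed_vdss_L",
]

# The fixed tolerance on the fractional-composition sum: residual-blood
# adjusted tissue compositions can slightly exceed unity (adipose does).
_COMPOSITION_SUM_TOL = 1e-2


class ValidationError(ValueError):
    """A record failed validation; ``field`` names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


class IonizationClass(str, Enum):
    NEUTRAL = "neutral"
    WEAK_BASE = "weak_base"


def _is_missing(value: Any) -> bool:
    if value is None:
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class DrugRecord:
    """One drug's physicochemical parameters and observed human VDss.

    ``logp_by_source`` maps any of ``admet``, ``literature``, ``hplc`` to a
    log10 octanol:water partition coefficient; at least one source must be
    present.  ``pka`` is the basic pKa and is required for weak bases.
    ``observed_vdss`` is in litres for a 70-kg human and may be absent
    (synthetic drugs have no clinical truth).  Hydrogen-bond counts,
    SO/NO2 counts and the dipole moment (Debye) are only needed by the
    microsomal-partitioning (Korzekwa-Nagar) method and may be absent.
    """

    name: str
    ionization_class: IonizationClass
    fup: float
    bpr: float
    logp_by_source: Mapping[str, float]
    pka: float | None = None
    hbd: int | None = None
    hba: int | None = None
    n_so: int | None = None
    n_no2: int | None = None
    dipole: float | None = None
    observed_vdss: float | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "ionization_class", IonizationClass(self.ionization_class)
        )
        if not self.name:
            raise ValidationError("name", "must be non-empty")
        if not (0.0 < self.fup <= 1.0):
            raise ValidationError("fup", f"must be in (0, 1], got {self.fup!r}")
        if not self.bpr > 0:
            raise ValidationError("bpr", f"must be positive, got {self.bpr!r}")
        logp = {
            k: float(v) for k, v in dict(self.logp_by_source).items()
            if not _is_missing(v)
        }
        unknown = set(logp) - set(LOGP_SOURCES)
        if unknown:
            raise ValidationError(
                "logp_by_source", f"unknown logP source(s): {sorted(unknown)}"
            )
        if not logp:
            raise ValidationError("logp_by_source", "at least one logP source required")
        object.__setattr__(self, "logp_by_source", logp)
        if self.ionization_class is IonizationClass.WEAK_BASE:
            if _is_missing(self.pka):
                raise ValidationError("pKa", "required for weak bases")
        elif not _is_missing(self.pka):
            raise ValidationError("pKa", "must be absent for neutral drugs")
        if self.observed_vdss is not None and not self.observed_vdss > 0:
            raise ValidationError("observed_vdss_L", "must be positive when present")
        for fld in ("hbd", "hba", "n_so", "n_no2"):
            v = getattr(self, fld)
            if v is not None and (int(v) != v or v < 0):
                raise ValidationError(fld, "must be a non-negative integer")

    def logp(self, source: str) -> float:
        try:
            return self.logp_by_source[source]
        except KeyError:
            raise KeyError(f"{self.name}: no {source!r} logP value") from None


@dataclass(frozen=True)
class TissueComposition:
    """One tissue row: absolute volume (L, 70-kg human), fractional
    composition, and tissue-to-plasma binding-protein ratios."""

    tissue: str
    volume: float
    f_nl: float
    f_np: float
    f_ew: float
    f_iw: float
    albumin_ratio: float
    lipoprotein_ratio: float

    def __post_init__(self):
        if not self.volume > 0:
            raise ValidationError("volume", f"must be positive, got {self.volume!r}")
        for fld in ("f_nl", "f_np", "f_ew", "f_iw", "albumin_ratio", "lipoprotein_ratio"):
            v = getattr(self, fld)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(fld, f"must be in [0, 1], got {v!r}")
        total = self.f_nl + self.f_np + self.f_ew + self.f_iw
        if total > 1.0 + _COMPOSITION_SUM_TOL:
            raise ValidationError(
                "f_nl", f"fractional volumes sum to {total:.4f} > 1"
            )


@dataclass(frozen=True)
class OieTozerConstants:
    v_p: float = 0.0436       # plasma volume, L/kg
    v_e: float = 0.151        # extracellular fluid (excl. plasma), L/kg
    r_ei: float = 1.4         # extracellular:plasma binding-protein ratio
    v_r: float = 0.38         # remainder volume, L/kg


@dataclass(frozen=True)
class RodgersRowlandConstants:
    v_plasma: float = 3.5     # plasma volume, L (70-kg human)
    ph_iw: float = 7.22       # intracellular water pH
    ph_p: float = 7.4         # plasma pH
    f_nl_plasma: float = 0.0023
    f_np_plasma: float = 0.0013


@dataclass(frozen=True)
class KorzekwaNagarConstants:
    v_p: float = 0.043        # plasma volume, L/kg
    v_t: float = 0.557        # tissue volume, L/kg
    r1_neutral: float = 0.116
    a: float = 20.0
    b: float = 0.76
    #: fum regression constants (const1..3, a1, a2, b2, b3, c2, d1, e, f);
    #: ``None`` makes the method unavailable, not a load-time error.
    fum_regression: Mapping[str, float] | None = None


@dataclass(frozen=True)
class TcmNewConstants:
    iw_wb: float = 0.48       # whole-body intracellular water, L/kg
    ew_wb: float = 0.22       # whole-body extracellular water, L/kg
    nl_wb: float = 0.149      # whole-body neutral-lipid equivalent, L/kg
    nlp_blood: float = 0.00075
    iw_blood: float = 0.29
    ew_blood: float = 0.53
    nl_blood: float = 0.004
    v_plasma: float = 0.04    # plasma volume, L/kg


@dataclass(frozen=True)
class MethodConstants:
    """All method constants plus shared physiological defaults."""

    body_weight: float = 70.0
    hematocrit: float = 0.45
    # plasma (neutral lipid + phospholipid) / plasma water volume ratio
    vlipid_over_vwater: float = (0.0023 + 0.0013) / 0.945
    oie_tozer: OieTozerConstants = field(default_factory=OieTozerConstants)
    rodgers_rowland: RodgersRowlandConstants = field(
        default_factory=RodgersRowlandConstants
    )
    korzekwa_nagar: KorzekwaNagarConstants = field(
        default_factory=KorzekwaNagarConstants
    )
    tcm_new: TcmNewConstants = field(default_factory=TcmNewConstants)

    def __post_init__(self):
        if not self.body_weight > 0:
            raise ValidationError("body_weight", "must be positive")
        if not (0.0 < self.hematocrit < 1.0):
            raise ValidationError("hematocrit", "must be in (0, 1)")


@dataclass(frozen=True)
class PredictionResult:
    """A single VDss prediction: method x drug x logP with intermediates.

    ``intermediates`` holds exactly the symbols the method defines (e.g.
    ``fut`` for Oie-Tozer, the per-tissue ``kpu`` map for the tissue-level
    methods, ``fup_adj`` for the adjusted-fup method, ``fum`` for the
    microsomal method).
    """

    drug: str
    method: str
    logp_used: float
    logp_source: str
    vdss: float
    intermediates: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if not self.vdss > 0:
            raise ValidationError("vdss", f"must be positive, got {self.vdss!r}")

    def as_row(self) -> dict[str, Any]:
        """Flatten to a serialisable row (nested maps become JSON)."""
        row: dict[str, Any] = {
            "drug": self.drug,
            "method": self.method,
            "logp_source": self.logp_source,
            "logp": self.logp_used,
            "vdss_L": self.vdss,
        }
        for key, value in self.intermediates.items():
            row[key] = json.dumps(value) if isinstance(value, dict) else value
        return row


# ---------------------------------------------------------------------------
# loaders


def _data_path(name: str):
    return resources.files("vdsspred").joinpath("data", name)


def _record_from_mapping(raw: Mapping[str, Any]) -> DrugRecord:
    for col in ("name", "ionization_class", "fup", "bpr"):
        if col not in raw or _is_missing(raw[col]):
            raise ValidationError(col, "missing required column/value")
    logp = {}
    for source in LOGP_SOURCES:
        v = raw.get(f"logp_{source}")
        if not _is_missing(v):
            logp[source] = float(v)
    def opt(col, cast=float):
        v = raw.get(col)
        return None if _is_missing(v) else cast(v)
    return DrugRecord(
        name=str(raw["name"]),
        ionization_class=IonizationClass(str(raw["ionization_class"])),
        pka=opt("pKa"),
        fup=float(raw["fup"]),
        bpr=float(raw["bpr"]),
        logp_by_source=logp,
        hbd=opt("hbd", int),
        hba=opt("hba", int),
        n_so=opt("n_so", int),
        n_no2=opt("n_no2", int),
        dipole=opt("dipole"),
        observed_vdss=opt("observed_vdss_L"),
    )


def load_drug_table(source: str | Path | None = None) -> list[DrugRecord]:
    """Load a drug table from CSV/JSON, or the packaged four-drug fixture.

    The packaged table contains griseofulvin, itraconazole, posaconazole
    and isavuconazole with their published physicochemical parameters and
    observed human VDss values.
    """
    if source is None:
        with resources.as_file(_data_path("drugs.csv")) as p:
            frame = pd.read_csv(p)
    else:
        path = Path(source)
        if path.suffix.lower() == ".json":
            rows = json.loads(path.read_text())
            if not isinstance(rows, list):
                raise ValidationError("table", "JSON drug table must be a list")
            return [_record_from_mapping(r) for r in rows]
        frame = pd.read_csv(path)
    missing = {"name", "ionization_class", "fup", "bpr"} - set(frame.columns)
    if missing:
        raise ValidationError(sorted(missing)[0], "missing column")
    return [_record_from_mapping(row) for row in frame.to_dict("records")]


def write_drug_table(records: Iterable[DrugRecord], path: str | Path) -> None:
    """Write records to CSV or JSON (by extension); round-trips exactly."""
    path = Path(path)
    rows = []
    for r in records:
        row: dict[str, Any] = {
            "name": r.name,
            "ionization_class": r.ionization_class.value,
            "pKa": r.pka,
            "fup": r.fup,
            "bpr": r.bpr,
        }
        for source in LOGP_SOURCES:
            row[f"logp_{source}"] = r.logp_by_source.get(source)
        row.update(
            hbd=r.hbd, hba=r.hba, n_so=r.n_so, n_no2=r.n_no2,
            dipole=r.dipole, observed_vdss_L=r.observed_vdss,
        )
        rows.append(row)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows, columns=_DRUG_CSV_COLUMNS).to_csv(path, index=False)


def load_tissue_table(source: str | Path | None = None) -> list[TissueComposition]:
    """Load the 13-tissue composition table (or a user override CSV)."""
    if source is None:
        with resources.as_file(_data_path("tissues.csv")) as p:
            frame = pd.read_csv(p)
    else:
        frame = pd.read_csv(source)
    tissues = []
    for row in frame.to_dict("records"):
        tissues.append(
            TissueComposition(
                tissue=str(row["tissue"]),
                volume=float(row["volume_L"]),
                f_nl=float(row["f_nl"]),
                f_np=float(row["f_np"]),
                f_ew=float(row["f_ew"]),
                f_iw=float(row["f_iw"]),
                albumin_ratio=float(row["albumin_ratio"]),
                lipoprotein_ratio=float(row["lipoprotein_ratio"]),
            )
        )
    return tissues


def total_tissue_volume(tissues: Sequence[TissueComposition]) -> float:
    return sum(t.volume for t in tissues)


def load_kn_regression_constants(
    source: str | Path | None = None,
) -> Mapping[str, float] | None:
    """Load fum regression constants from YAML; ``None`` if unset.

    The packaged default file carries nulls (the published regression
    constants live in an external supplement); the microsomal-partitioning
    method is then unavailable until the user fills the file in.
    """
    if source is None:
        with resources.as_file(_data_path("kn_constants.yaml")) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(source).read_text())
    if raw is None:
        return None
    constants = raw.get("fum_regression_constants", raw)
    if constants is None:
        return None
    required = {"const1", "const2", "const3", "a1", "a2", "b2", "b3", "c2", "d1", "e", "f"}
    if any(constants.get(k) is None for k in required):
        return None
    extra = set(constants) - required
    if extra:
        raise ValidationError("fum_regression_constants",
                              f"unknown key(s): {sorted(extra)}")
    return {k: float(constants[k]) for k in required}


def _constants_from_mapping(raw: Mapping[str, Any]) -> MethodConstants:
    known = {"body_weight_kg", "hematocrit", "vlipid_over_vwater",
             "oie_tozer", "rodgers_rowland", "korzekwa_nagar", "tcm_new"}
    extra = set(raw) - known
    if extra:
        raise ValidationError("constants", f"unknown key(s): {sorted(extra)}")

    def build(cls, key, **overrides):
        section = dict(raw.get(key) or {})
        section.update(overrides)
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - allowed
        if unknown:
            raise ValidationError(key, f"unknown key(s): {sorted(unknown)}")
        return cls(**section)

    kn_section = dict(raw.get("korzekwa_nagar") or {})
    fum = kn_section.pop("fum_regression_constants", None)
    if fum is not None:
        fum = {k: float(v) for k, v in fum.items()}
    kn = KorzekwaNagarConstants(fum_regression=fum, **kn_section)

    kwargs: dict[str, Any] = {"korzekwa_nagar": kn}
    if "body_weight_kg" in raw:
        kwargs["body_weight"] = float(raw["body_weight_kg"])
    if "hematocrit" in raw:
        kwargs["hematocrit"] = float(raw["hematocrit"])
    if "vlipid_over_vwater" in raw:
        kwargs["vlipid_over_vwater"] = float(raw["vlipid_over_vwater"])
    kwargs["oie_tozer"] = build(OieTozerConstants, "oie_tozer")
    kwargs["rodgers_rowland"] = build(RodgersRowlandConstants, "rodgers_rowland")
    kwargs["tcm_new"] = build(TcmNewConstants, "tcm_new")
    return MethodConstants(**kwargs)


def load_method_constants(source: str | Path | None = None) -> MethodConstants:
    """Load method constants from YAML (packaged defaults if no path)."""
    if source is None:
        with resources.as_file(_data_path("method_constants.yaml")) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(source).read_text())
    return _constants_from_mapping(raw or {})
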