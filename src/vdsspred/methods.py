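"""The six steady-state volume of distribution prediction methods.

Each method consumes one drug record, one chosen logP value and the shared
method constants, and returns a :class:`~vdsspred.datamodel.PredictionResult`
whose ``intermediates`` carry exactly the quantities that method defines
(fut; per-tissue Kpu/Kp maps; adjusted fup; fum; oil:buffer logP).  All
methods are pure and deterministic; per-kg formulations are scaled by the
configured body weight (70 kg by default).

The six methods:

``oie_tozer``
    Physiological four-space model driven by the tissue fraction unbound
    regression.
``rr_tissue``
    Tissue-composition Kpu summed over 13 tissues (unbound volume of
    distribution, converted with VDss = Vuss * fup).
``rr_muscle``
    Same Kpu equation but the muscle coefficient applied to the whole
    66.87 L tissue volume.
``adjusted_fup``
    Perfusion-limited sum of tissue Kp values where Kp = Kpu * fup_adj and
    fup_adj corrects fup for plasma lipid partitioning; blood cells enter
    through the erythrocyte:plasma ratio.
``korzekwa_nagar``
    Microsomal-partitioning surrogate: fum from the L*KL regression
    (requires regression constants and molecular descriptors).
``tcm_new``
    Blood:plasma-ratio tissue-composition model; the only method that does
    not use fup.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

from . import intermediates as im
from .datamodel import (
    DrugRecord,
    IonizationClass,
    MethodConstants,
    PredictionResult,
    TissueComposition,
    load_method_constants,
    load_tissue_table,
    total_tissue_volume,
)

__all__ = [
    "MethodInput",
    "vdss_oie_tozer",
    "vdss_rr_tissue_specific",
    "vdss_rr_muscle_only",
    "vdss_adjusted_fup",
    "vdss_korzekwa_nagar",
    "vdss_tcm_new",
    "predict",
]


@dataclass(frozen=True)
class MethodInput:
    """One prediction request: drug, chosen logP, and options.

    ``options`` may carry ``adipose_partition`` ("octanol", the default, or
    "oil" to use the vegetable-oil partition coefficient for adipose),
    ``hematocrit`` and ``vlipid_over_vwater`` overrides, and
    ``logp_source`` (a label recorded in the result).
    """

    drug: DrugRecord
    logp: float
    body_weight: float = 70.0
    options: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        import math

        if not math.isfinite(self.logp):
            raise ValueError(f"logp must be finite, got {self.logp!r}")
        if not self.body_weight > 0:
            raise ValueError("body_weight must be positive")
        unknown = set(self.options) - {
            "adipose_partition", "hematocrit", "vlipid_over_vwater", "logp_source",
        }
        if unknown:
            raise ValueError(f"unknown option(s): {sorted(unknown)}")

    @property
    def logp_source(self) -> str:
        return self.options.get("logp_source", "sweep")


def _result(inp: MethodInput, method: str, vdss: float, **intermediates):
    return PredictionResult(
        drug=inp.drug.name,
        method=method,
        logp_used=inp.logp,
        logp_source=inp.logp_source,
        vdss=vdss,
        intermediates=intermediates,
    )


def vdss_oie_tozer(
    inp: MethodInput, constants: MethodConstants = MethodConstants()
) -> PredictionResult:
    """Physiological model: VDss/kg = V_p + fup V_e + R_e/i V_p (1 - fup)
    + V_r fup/fut, with fut from the tissue-binding regression."""
    c = constants.oie_tozer
    drug = inp.drug
    f_i = im.fraction_ionized(drug.pka, 7.4, drug.ionization_class)
    fut = im.fut_lombardo(inp.logp, f_i, drug.fup)
    per_kg = (
        c.v_p
        + drug.fup * c.v_e
        + c.r_ei * c.v_p * (1.0 - drug.fup)
        + c.v_r * drug.fup / fut
    )
    return _result(inp, "oie_tozer", per_kg * inp.body_weight, fut=fut, f_i74=f_i)


def _kpu_map(
    inp: MethodInput,
    tissues: Sequence[TissueComposition],
    constants: MethodConstants,
) -> dict[str, float]:
    """Per-tissue Kpu; adipose optionally uses the vegetable-oil partition."""
    adipose_mode = inp.options.get("adipose_partition", "octanol")
    if adipose_mode not in ("octanol", "oil"):
        raise ValueError(f"adipose_partition must be 'octanol' or 'oil', got {adipose_mode!r}")
    kpu = {}
    for tissue in tissues:
        override = None
        if adipose_mode == "oil" and tissue.tissue == "adipose":
            override = 10.0 ** im.logp_oil_from_octanol(inp.logp)
        kpu[tissue.tissue] = im.kpu_rodgers_rowland(
            inp.logp, inp.drug, tissue, constants.rodgers_rowland, override
        )
    return kpu


def vdss_rr_tissue_specific(
    inp: MethodInput,
    tissues: Sequence[TissueComposition] | None = None,
    constants: MethodConstants = MethodConstants(),
) -> PredictionResult:
    """Tissue-composition model over 13 tissues:
    Vuss = V_p/fup + sum(V_i Kpu_i), VDss = Vuss fup."""
    tissues = load_tissue_table() if tissues is None else tissues
    kpu = _kpu_map(inp, tissues, constants)
    vuss = constants.rodgers_rowland.v_plasma / inp.drug.fup + sum(
        t.volume * kpu[t.tissue] for t in tissues
    )
    return _result(inp, "rr_tissue", vuss * inp.drug.fup, vuss=vuss, kpu=kpu)


def vdss_rr_muscle_only(
    inp: MethodInput,
    tissues: Sequence[TissueComposition] | None = None,
    constants: MethodConstants = MethodConstants(),
) -> PredictionResult:
    """Muscle Kpu applied to the total tissue volume:
    Vuss = V_p/fup + (sum V_i) Kpu_muscle, VDss = Vuss fup."""
    tissues = load_tissue_table() if tissues is None else tissues
    muscle = next((t for t in tissues if t.tissue == "muscle"), None)
    if muscle is None:
        raise ValueError("tissue table has no 'muscle' row")
    kpu_muscle = im.kpu_rodgers_rowland(
        inp.logp, inp.drug, muscle, constants.rodgers_rowland
    )
    vuss = (
        constants.rodgers_rowland.v_plasma / inp.drug.fup
        + total_tissue_volume(tissues) * kpu_muscle
    )
    return _result(
        inp, "rr_muscle", vuss * inp.drug.fup, vuss=vuss, kpu={"muscle": kpu_muscle}
    )


def vdss_adjusted_fup(
    inp: MethodInput,
    tissues: Sequence[TissueComposition] | None = None,
    constants: MethodConstants = MethodConstants(),
) -> PredictionResult:
    """Perfusion-limited sum with lipid-corrected fup:
    VDss = V_p + V_e E:P + sum(V_t Kp_t), Kp = Kpu * fup_adj.

    The erythrocyte volume is derived from the plasma volume and the
    hematocrit; tissue extraction ratios are taken as zero.
    """
    tissues = load_tissue_table() if tissues is None else tissues
    drug = inp.drug
    hct = float(inp.options.get("hematocrit", constants.hematocrit))
    ratio = float(
        inp.options.get("vlipid_over_vwater", constants.vlipid_over_vwater)
    )
    logd = im.log_d(inp.logp, drug, 7.4)
    fup_adj = im.fup_adjusted(drug.fup, logd, ratio)
    ep = im.erythrocyte_plasma_ratio(drug.bpr, hct)
    kpu = _kpu_map(inp, tissues, constants)
    kp = {name: value * fup_adj for name, value in kpu.items()}
    v_plasma = constants.rodgers_rowland.v_plasma
    v_ery = hct / (1.0 - hct) * v_plasma
    vdss = v_plasma + v_ery * ep + sum(t.volume * kp[t.tissue] for t in tissues)
    return _result(
        inp, "adjusted_fup", vdss, fup_adj=fup_adj, logd74=logd, ep_ratio=ep, kp=kp
    )


def vdss_korzekwa_nagar(
    inp: MethodInput, constants: MethodConstants = MethodConstants()
) -> PredictionResult:
    """Microsomal-partitioning model: VDss/kg = V_p + V_t fup
    + V_t R_1 (1 - fup) + fup (a (1 - fum)/fum + b).

    Requires the fum regression constants and the molecular descriptors
    (H-bond counts, SO/NO2 counts, dipole).  The underlying regression was
    developed excluding drugs with fup < 0.005, so such inputs warn.
    """
    c = constants.korzekwa_nagar
    if c.fum_regression is None:
        raise ValueError(
            "Korzekwa-Nagar unavailable: fum regression constants not configured"
        )
    drug = inp.drug
    if drug.fup < 0.005:
        warnings.warn(
            f"{drug.name}: fup={drug.fup} is below the 0.005 applicability "
            "bound of the microsomal-partitioning model",
            RuntimeWarning,
            stacklevel=2,
        )
    log_lkl = im.log_lkl_korzekwa(inp.logp, drug, c.fum_regression)
    lkl = 10.0 ** log_lkl
    fum = im.fum_from_lkl(lkl)
    per_kg = (
        c.v_p
        + c.v_t * drug.fup
        + c.v_t * c.r1_neutral * (1.0 - drug.fup)
        + drug.fup * (c.a * (1.0 - fum) / fum + c.b)
    )
    return _result(
        inp, "korzekwa_nagar", per_kg * inp.body_weight, fum=fum, log_lkl=log_lkl
    )


def vdss_tcm_new(
    inp: MethodInput, constants: MethodConstants = MethodConstants()
) -> PredictionResult:
    """Blood:plasma-ratio tissue-composition model:
    VDss/kg = BPR * (IW_WB + EW_WB + 10**logP_oil (NL_WB + NLP/5))
    / (IW_bl + EW_bl + 10**logP (NL_bl + NLP)) + V_plasma."""
    c = constants.tcm_new
    drug = inp.drug
    logp_oil = im.logp_oil_from_octanol(inp.logp)
    numerator = c.iw_wb + c.ew_wb + 10.0 ** logp_oil * (c.nl_wb + c.nlp_blood / 5.0)
    denominator = c.iw_blood + c.ew_blood + 10.0 ** inp.logp * (
        c.nl_blood + c.nlp_blood
    )
    per_kg = drug.bpr * numerator / denominator + c.v_plasma
    return _result(inp, "tcm_new", per_kg * inp.body_weight, logp_oil=logp_oil)


_DISPATCH = {
    "oie_tozer": lambda inp, tissues, constants: vdss_oie_tozer(inp, constants),
    "rr_tissue": vdss_rr_tissue_specific,
    "rr_muscle": vdss_rr_muscle_only,
    "adjusted_fup": vdss_adjusted_fup,
    "korzekwa_nagar": lambda inp, tissues, constants: vdss_korzekwa_nagar(
        inp, constants
    ),
    "tcm_new": lambda inp, tissues, constants: vdss_tcm_new(inp, constants),
}


def predict(
    drug: DrugRecord,
    method: str,
    logp: float | None = None,
    logp_source: str | None = None,
    tissues: Sequence[TissueComposition] | None = None,
    constants: MethodConstants | None = None,
    **options: Any,
) -> PredictionResult:
    """Single dispatch entry point.

    Give either an explicit ``logp`` or a ``logp_source`` naming one of the
    drug's recorded logP values.  Extra keyword options (e.g.
    ``adipose_partition="oil"``) are forwarded to the method.
    """
    if method not in _DISPATCH:
        raise ValueError(
            f"unknown method {method!r}; valid methods: {sorted(_DISPATCH)}"
        )
    if (logp is None) == (logp_source is None):
        raise ValueError("give exactly one of logp / logp_source")
    if logp is None:
        logp = drug.logp(logp_source)
        options = {**options, "logp_source": logp_source}
    constants = load_method_constants() if constants is None else constants
    inp = MethodInput(
        drug=drug, logp=logp, body_weight=constants.body_weight, options=options
    )
    if method in ("rr_tissue", "rr_muscle", "adjusted_fup") and tissues is None:
        tissues = load_tissue_table()
    return _DISPATCH[method](inp, tissues, constants)
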