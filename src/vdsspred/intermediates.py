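"""Ionization math and per-method intermediate quantities.

Everything here is a pure scalar function of drug parameters and tissue
composition: fraction ionized (Henderson-Hasselbalch), the X/Y ionization
terms of the tissue-composition partition equation, logD, the tissue
fraction-unbound regression, the unbound tissue:plasma-water partition
coefficient Kpu, the lipid-corrected ("adjusted") plasma fraction unbound,
the erythrocyte:plasma ratio, the microsomal-binding L*KL regression and
its conversion to fraction unbound in microsomes, and the vegetable-oil
logP mapping.

Extreme logP values can push the tissue fraction unbound above 1 or the
adjusted fup into deep underflow; both emit warnings rather than errors so
that sensitivity sweeps can traverse the full grid.
"""
from __future__ import annotations

import math
import warnings
from typing import Mapping

from .datamodel import (
    DrugRecord,
    IonizationClass,
    RodgersRowlandConstants,
    TissueComposition,
    ValidationError,
)

__all__ = [
    "fraction_ionized",
    "xy_terms",
    "log_d",
    "fut_lombardo",
    "kpu_rodgers_rowland",
    "fup_adjusted",
    "erythrocyte_plasma_ratio",
    "log_lkl_korzekwa",
    "fum_from_lkl",
    "logp_oil_from_octanol",
]

_KN_KEYS = ("const1", "const2", "const3", "a1", "a2", "b2", "b3", "c2", "d1", "e", "f")


def fraction_ionized(
    pka: float | None,
    ph: float,
    ionization_class: IonizationClass | str = IonizationClass.WEAK_BASE,
) -> float:
    """Fraction of a monoprotic weak base ionized at ``ph``.

    Neutral drugs return exactly 0.  For a weak base the
    Henderson-Hasselbalch equation gives ``1 / (1 + 10**(ph - pka))``.
    """
    if not (0.0 <= ph <= 14.0):
        raise ValueError(f"pH must be in [0, 14], got {ph!r}")
    if IonizationClass(ionization_class) is IonizationClass.NEUTRAL:
        return 0.0
    if pka is None:
        raise ValidationError("pKa", "required for weak bases")
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def xy_terms(
    drug: DrugRecord,
    constants: RodgersRowlandConstants = RodgersRowlandConstants(),
) -> tuple[float, float]:
    """Ionization terms of the Kpu equation.

    Neutral drugs: X = Y = 1.  Weak bases: X = 1 + 10**(pKa - pH_IW) and
    Y = 1 + 10**(pKa - pH_P), with intracellular pH 7.22 and plasma pH 7.4
    by default.
    """
    if drug.ionization_class is IonizationClass.NEUTRAL:
        return 1.0, 1.0
    x = 1.0 + 10.0 ** (drug.pka - constants.ph_iw)
    y = 1.0 + 10.0 ** (drug.pka - constants.ph_p)
    return x, y


def log_d(logp: float, drug: DrugRecord, ph: float = 7.4) -> float:
    """Distribution coefficient at ``ph`` via the monoprotic-base correction.

    Neutral drugs: logD = logP.  Weak bases:
    ``logD = logP - log10(1 + 10**(pKa - ph))``.
    """
    if drug.ionization_class is IonizationClass.NEUTRAL:
        return logp
    return logp - math.log10(1.0 + 10.0 ** (drug.pka - ph))


def fut_lombardo(logp: float, f_i74: float, fup: float) -> float:
    """Tissue fraction unbound from the logP / ionization / fup regression:
    ``log(fut) = 0.0080 - 0.2294 logP - 0.9311 f_i(7.4) + 0.8885 log(fup)``.

    Warns (does not raise) when the regression extrapolates above 1.
    """
    if not fup > 0:
        raise ValueError(f"fup must be positive, got {fup!r}")
    log_fut = 0.0080 - 0.2294 * logp - 0.9311 * f_i74 + 0.8885 * math.log10(fup)
    fut = 10.0 ** log_fut
    if fut > 1.0:
        warnings.warn(
            f"fut regression extrapolates above 1 (fut={fut:.4g}); "
            "interpreting as weak tissue binding",
            RuntimeWarning,
            stacklevel=2,
        )
    return fut


def kpu_rodgers_rowland(
    logp: float,
    drug: DrugRecord,
    tissue: TissueComposition,
    constants: RodgersRowlandConstants = RodgersRowlandConstants(),
    partition_override: float | None = None,
) -> float:
    """Unbound tissue:plasma-water partition coefficient for a neutral or
    weakly basic drug from tissue composition.

    ``Kpu = X f_IW / Y + f_EW + [P f_NL + (0.3 P + 0.7) f_NP] / Y
    + [(1/fup - 1 - (P f_NL,P + (0.3 P + 0.7) f_NP,P)) R]`` where
    P = 10**logP (or ``partition_override``, e.g. a vegetable-oil:water
    partition coefficient for adipose) and R is the tissue:plasma
    lipoprotein ratio for neutral drugs or the albumin ratio for weak
    bases.  The protein term can be negative for highly lipophilic drugs;
    a non-positive total is a physically inconsistent input and raises.
    """
    if not drug.fup > 0:
        raise ValueError("fup must be positive")
    p = 10.0 ** logp if partition_override is None else partition_override
    x, y = xy_terms(drug, constants)
    if drug.ionization_class is IonizationClass.NEUTRAL:
        r = tissue.lipoprotein_ratio
    else:
        r = tissue.albumin_ratio
    water = x * tissue.f_iw / y + tissue.f_ew
    lipid = (p * tissue.f_nl + (0.3 * p + 0.7) * tissue.f_np) / y
    protein = (
        1.0 / drug.fup
        - 1.0
        - (p * constants.f_nl_plasma + (0.3 * p + 0.7) * constants.f_np_plasma)
    ) * r
    kpu = water + lipid + protein
    if not kpu > 0:
        raise ValueError(
            f"non-positive Kpu ({kpu:.4g}) for {drug.name}/{tissue.tissue}: "
            "physically inconsistent inputs"
        )
    return kpu


def fup_adjusted(fup: float, logd74: float, vlipid_over_vwater: float) -> float:
    """Lipid-binding-corrected plasma fraction unbound:
    ``1 / (10**logD(7.4) (V_lipid/V_water) + 1 + (1 - fup)/fup)``.

    Always <= fup and strictly decreasing in logD.
    """
    if not (0.0 < fup <= 1.0):
        raise ValueError(f"fup must be in (0, 1], got {fup!r}")
    denom = 10.0 ** logd74 * vlipid_over_vwater + 1.0 + (1.0 - fup) / fup
    adj = 1.0 / denom
    if adj < 1e-12:
        warnings.warn(
            f"adjusted fup underflows ({adj:.3g}) at logD={logd74:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return adj


def erythrocyte_plasma_ratio(bpr: float, hematocrit: float = 0.45) -> float:
    """Erythrocyte:plasma concentration ratio from the blood:plasma ratio:
    ``E:P = (BPR - (1 - Hct)) / Hct``, clipped at 0 with a warning."""
    if not (0.0 < hematocrit < 1.0):
        raise ValueError(f"hematocrit must be in (0, 1), got {hematocrit!r}")
    ep = (bpr - (1.0 - hematocrit)) / hematocrit
    if ep < 0.0:
        warnings.warn(
            f"negative erythrocyte:plasma ratio ({ep:.4g}) clipped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return ep


def log_lkl_korzekwa(
    logp: float,
    drug: DrugRecord,
    constants: Mapping[str, float],
    pka_acidic: float | None = None,
) -> float:
    """log10 of the microsomal lipid-binding product L*KL.

    Three species terms (neutral, cation, anion) are summed as powers of
    ten; the cation term carries a ``pKa,b - 7.4`` shift and the anion
    term a ``pKa,a - 7.4`` shift, and the total is corrected by
    ``-log10(1 + 10**(pKa,b - 7.4)) - log10(1 + 10**(7.4 - pKa,a))``.
    A species whose group is absent contributes zero to the sum and a zero
    correction (absent basic pKa -> -inf, absent acidic pKa -> +inf).
    """
    if constants is None:
        raise ValueError("fum regression constants unavailable")
    missing = [k for k in _KN_KEYS if k not in constants]
    if missing:
        raise ValueError(f"fum regression constants missing: {missing}")
    for fld in ("hbd", "hba", "n_so", "n_no2", "dipole"):
        if getattr(drug, fld) is None:
            raise ValidationError(fld, f"required by the microsomal model ({drug.name})")
    c = constants
    acc, don = drug.hba, drug.hbd
    so, no2 = drug.n_so, drug.n_no2
    group = c["e"] * so + c["f"] * no2
    pka_b = drug.pka if drug.ionization_class is IonizationClass.WEAK_BASE else None

    total = 10.0 ** (c["const1"] + c["a1"] * logp + c["d1"] * drug.dipole + group)
    correction = 0.0
    if pka_b is not None:
        total += 10.0 ** (
            c["const2"] + c["a2"] * logp + c["b2"] * acc + c["c2"] * don
            + group + pka_b - 7.4
        )
        correction -= math.log10(1.0 + 10.0 ** (pka_b - 7.4))
    if pka_acidic is not None:
        total += 10.0 ** (c["const3"] + c["b3"] * acc + group + pka_acidic - 7.4)
        correction -= math.log10(1.0 + 10.0 ** (7.4 - pka_acidic))
    return math.log10(total) + correction


def fum_from_lkl(lkl: float) -> float:
    """Fraction unbound in microsomes from ``(1 - fum)/fum = L*KL``."""
    if lkl < 0:
        raise ValueError(f"L*KL must be non-negative, got {lkl!r}")
    return 1.0 / (1.0 + lkl)


def logp_oil_from_octanol(logp_oct: float) -> float:
    """Vegetable-oil:buffer logP from octanol:buffer logP:
    ``1.099 logP - 1.31``."""
    return 1.099 * logp_oct - 1.31
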