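"""Seeded generators for synthetic drug records and IV bolus profiles.

The drug generator spans the lipophilic-drug regime the package targets:
logP 2-7, weak bases with pKa 3-5 (neutral with probability 0.25), fup
log-uniform over 0.002-0.2, blood:plasma ratio 0.6-0.8, plus the molecular
descriptors the microsomal-partitioning method needs.  Three logP values
are drawn per drug and assigned rank-ordered to the in-silico, literature
and chromatographic sources, mirroring the ordering seen in practice.

The profile generator samples 1-3 compartment micro constants (or takes
them explicitly), evaluates the closed-form bolus solution on a sampling
schedule, applies multiplicative log-normal noise, and returns the
generating parameters including the analytic steady-state volume so that
recovery can be checked.  Identical seeds give identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datamodel import DrugRecord, IonizationClass, load_kn_regression_constants
from .pkanalysis import ConcProfile, conc_bolus, vss_from_micro

__all__ = [
    "DrugGenSpec",
    "ProfileGenSpec",
    "generate_drugs",
    "generate_profile",
    "synthetic_kn_constants",
    "DEFAULT_SCHEDULE",
]

#: Sampling schedule (h) covering distribution and elimination phases.
DEFAULT_SCHEDULE = (
    0.083, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0, 36.0, 48.0, 72.0,
)


@dataclass(frozen=True)
class DrugGenSpec:
    """Ranges for synthetic drug records (defaults span the study regime)."""

    n: int
    seed: int
    logp_range: tuple[float, float] = (2.0, 7.0)
    pka_range: tuple[float, float] = (3.0, 5.0)
    neutral_probability: float = 0.25
    fup_range: tuple[float, float] = (0.002, 0.2)  # log-uniform
    bpr_range: tuple[float, float] = (0.6, 0.8)
    hbd_range: tuple[int, int] = (0, 5)
    hba_range: tuple[int, int] = (2, 12)
    n_so_range: tuple[int, int] = (0, 2)
    n_no2_range: tuple[int, int] = (0, 2)
    dipole_range: tuple[float, float] = (1.0, 15.0)

    def __post_init__(self):
        if not self.n > 0:
            raise ValueError("n must be positive")
        for name in ("logp_range", "pka_range", "fup_range", "bpr_range",
                     "dipole_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name}: low bound exceeds high bound")
        if not (0.0 <= self.neutral_probability <= 1.0):
            raise ValueError("neutral_probability must be in [0, 1]")
        if not (0 < self.fup_range[0] and self.fup_range[1] <= 1):
            raise ValueError("fup_range must lie in (0, 1]")


def generate_drugs(spec: DrugGenSpec) -> list[DrugRecord]:
    """Draw ``spec.n`` valid drug records; bit-reproducible under the seed."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n):
        logps = np.sort(rng.uniform(*spec.logp_range, size=3))
        neutral = rng.random() < spec.neutral_probability
        pka = None if neutral else float(rng.uniform(*spec.pka_range))
        lo, hi = spec.fup_range
        fup = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        records.append(
            DrugRecord(
                name=f"syn{i:04d}",
                ionization_class=(
                    IonizationClass.NEUTRAL if neutral else IonizationClass.WEAK_BASE
                ),
                pka=pka,
                fup=fup,
                bpr=float(rng.uniform(*spec.bpr_range)),
                logp_by_source={
                    "admet": float(logps[0]),
                    "literature": float(logps[1]),
                    "hplc": float(logps[2]),
                },
                hbd=int(rng.integers(spec.hbd_range[0], spec.hbd_range[1] + 1)),
                hba=int(rng.integers(spec.hba_range[0], spec.hba_range[1] + 1)),
                n_so=int(rng.integers(spec.n_so_range[0], spec.n_so_range[1] + 1)),
                n_no2=int(rng.integers(spec.n_no2_range[0], spec.n_no2_range[1] + 1)),
                dipole=float(rng.uniform(*spec.dipole_range)),
                observed_vdss=None,
            )
        )
    return records


@dataclass(frozen=True)
class ProfileGenSpec:
    """Spec for a simulated IV bolus profile.

    Give explicit micro ``params`` (v1 in L, rate constants in 1/h) or let
    them be sampled from the ranges.  ``noise_cv`` is the coefficient of
    variation of multiplicative log-normal noise (0 = exact curve).
    """

    n_compartments: int = 2
    seed: int = 0
    dose: float = 100.0  # mg
    schedule: Sequence[float] = DEFAULT_SCHEDULE
    noise_cv: float = 0.0
    params: Mapping[str, float] | None = None
    v1_range: tuple[float, float] = (10.0, 60.0)
    k10_range: tuple[float, float] = (0.05, 0.4)
    k_inter_range: tuple[float, float] = (0.05, 1.0)

    def __post_init__(self):
        if self.n_compartments not in (1, 2, 3):
            raise ValueError("n_compartments must be 1, 2 or 3")
        if not self.noise_cv >= 0:
            raise ValueError("noise_cv must be non-negative")
        if len(self.schedule) < 2 or any(
            b <= a for a, b in zip(self.schedule, self.schedule[1:])
        ):
            raise ValueError("schedule must be strictly increasing with >= 2 points")


def _sample_params(spec: ProfileGenSpec, rng) -> dict[str, float]:
    params = {
        "v1": float(rng.uniform(*spec.v1_range)),
        "k10": float(rng.uniform(*spec.k10_range)),
    }
    for i in range(2, spec.n_compartments + 1):
        params[f"k1{i}"] = float(rng.uniform(*spec.k_inter_range))
        # return rate slower than distribution keeps phases distinguishable
        params[f"k{i}1"] = float(rng.uniform(*spec.k_inter_range)) / i
    return params


def generate_profile(spec: ProfileGenSpec) -> tuple[ConcProfile, dict[str, float]]:
    """Simulate one profile; returns it with the generating parameters.

    The returned dict carries the micro constants plus ``vss`` (the
    analytic steady-state volume, L) and ``n_compartments``.
    """
    rng = np.random.default_rng(spec.seed)
    params = dict(spec.params) if spec.params is not None else _sample_params(spec, rng)
    expected = set(_expected_names(spec.n_compartments))
    if set(params) != expected:
        raise ValueError(f"params must be exactly {sorted(expected)}")
    clean = conc_bolus(spec.schedule, params, spec.dose)
    if spec.noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + spec.noise_cv**2))
        noise = np.exp(rng.normal(0.0, sigma, size=len(clean)) - sigma**2 / 2.0)
        concs = clean * noise
    else:
        concs = clean
    profile = ConcProfile(
        times=tuple(spec.schedule),
        concentrations=tuple(float(c) for c in concs),
        dose=spec.dose,
    )
    truth = dict(params)
    truth["vss"] = vss_from_micro(params)
    truth["n_compartments"] = spec.n_compartments
    return profile, truth


def _expected_names(n: int) -> tuple[str, ...]:
    names = ["v1", "k10"]
    for i in range(2, n + 1):
        names += [f"k1{i}", f"k{i}1"]
    return tuple(names)


def synthetic_kn_constants() -> Mapping[str, float]:
    """The shipped SYNTHETIC microsomal-regression constants.

    Plausible signs and magnitudes for exercising the Korzekwa-Nagar
    pipeline in tests and examples; not the published regression.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("vdsspred").joinpath("data", "kn_constants_synthetic.yaml")
    ) as path:
        constants = load_kn_regression_constants(path)
    assert constants is not None
    return constants
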