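"""Non-compartmental and compartmental analysis of IV bolus profiles.

NCA computes AUC/AUMC by the linear-up/log-down trapezoid with log-linear
extrapolation to infinity, then CL = dose/AUC, MRT = AUMC/AUC and
VDss = MRT * CL.  The compartmental route fits mammillary 1-3 compartment
bolus models by weighted least squares (1/yhat^2 weighting, i.e. constant
relative error), with deterministic initialisation from curve stripping,
and selects among fits by the Akaike information criterion.

AIC convention: ``m * ln(WSS/m) + 2p`` with WSS the weighted sum of squared
residuals, m the number of observations and p = 2n fitted parameters.
Only AIC differences matter for model selection.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .datamodel import ValidationError

__all__ = [
    "ConcProfile",
    "NcaResult",
    "CompartmentalFit",
    "FitError",
    "nca_vdss",
    "fit_compartments",
    "select_model",
    "conc_bolus",
    "vss_from_micro",
]


class FitError(RuntimeError):
    """Compartmental fit failed to converge; message carries diagnostics."""


@dataclass(frozen=True)
class ConcProfile:
    """An IV-bolus concentration-time profile.

    ``times`` in hours (strictly increasing, non-negative), concentrations
    in mg/L (positive), dose in mg.
    """

    times: tuple[float, ...]
    concentrations: tuple[float, ...]
    dose: float
    route: str = "iv_bolus"

    def __post_init__(self):
        times = tuple(float(t) for t in self.times)
        concs = tuple(float(c) for c in self.concentrations)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", concs)
        if len(times) != len(concs):
            raise ValidationError("times", "times and concentrations differ in length")
        if len(times) < 2:
            raise ValidationError("times", "need at least two samples")
        if times[0] < 0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("times", "must be strictly increasing and >= 0")
        if any(c <= 0 for c in concs):
            raise ValidationError("concentrations", "must all be positive")
        if not self.dose > 0:
            raise ValidationError("dose", "must be positive")
        if self.route != "iv_bolus":
            raise ValidationError("route", f"only iv_bolus supported, got {self.route!r}")


class NcaResult(NamedTuple):
    auc: float      # mg*h/L, extrapolated to infinity
    aumc: float     # mg*h^2/L
    mrt: float      # h
    cl: float       # L/h
    vdss: float     # L
    lambda_z: float  # 1/h terminal rate constant


def _terminal_slope(times, concs, n_terminal: int) -> float:
    t = np.asarray(times[-n_terminal:], dtype=float)
    logc = np.log(np.asarray(concs[-n_terminal:], dtype=float))
    slope, _ = np.polyfit(t, logc, 1)
    lambda_z = -slope
    if not lambda_z > 0:
        raise ValueError(
            "terminal phase is not monotonically declining; "
            "log-linear extrapolation undefined"
        )
    return float(lambda_z)


def nca_vdss(profile: ConcProfile, n_terminal: int = 3) -> NcaResult:
    """Model-free VDss from moments of an IV-bolus profile.

    The first sample is back-extrapolated log-linearly to t=0 when the
    profile does not start at zero; the terminal rate constant comes from
    a log-linear regression through the last ``n_terminal`` points.
    """
    if len(profile.times) < 4:
        raise ValidationError("times", "NCA needs at least four samples")
    if n_terminal < 2 or n_terminal > len(profile.times):
        raise ValueError("n_terminal must be in [2, n_samples]")
    times = list(profile.times)
    concs = list(profile.concentrations)
    if times[0] > 0:
        # log-linear back-extrapolation from the first two samples
        if concs[1] < concs[0]:
            k = math.log(concs[0] / concs[1]) / (times[1] - times[0])
            c0 = concs[0] * math.exp(k * times[0])
        else:
            c0 = concs[0]
        times.insert(0, 0.0)
        concs.insert(0, c0)
    auc = aumc = 0.0
    for (t1, c1), (t2, c2) in zip(zip(times, concs), zip(times[1:], concs[1:])):
        dt = t2 - t1
        if c2 < c1:
            ratio = math.log(c1 / c2)
            auc += dt * (c1 - c2) / ratio
            aumc += dt * (t1 * c1 - t2 * c2) / ratio + dt * dt * (c1 - c2) / ratio**2
        else:
            auc += dt * (c1 + c2) / 2.0
            aumc += dt * (t1 * c1 + t2 * c2) / 2.0
    lambda_z = _terminal_slope(profile.times, profile.concentrations, n_terminal)
    clast, tlast = concs[-1], times[-1]
    auc += clast / lambda_z
    aumc += clast * tlast / lambda_z + clast / lambda_z**2
    cl = profile.dose / auc
    mrt = aumc / auc
    return NcaResult(auc=auc, aumc=aumc, mrt=mrt, cl=cl, vdss=mrt * cl,
                     lambda_z=lambda_z)


# ---------------------------------------------------------------------------
# compartmental models


def _rate_matrix(params: dict[str, float], n: int) -> np.ndarray:
    k = np.zeros((n, n))
    k[0, 0] = -params["k10"]
    for i in range(2, n + 1):
        k1i, ki1 = params[f"k1{i}"], params[f"k{i}1"]
        k[0, 0] -= k1i
        k[i - 1, 0] = k1i
        k[0, i - 1] = ki1
        k[i - 1, i - 1] = -ki1
    return k


def conc_bolus(times, params: dict[str, float], dose: float) -> np.ndarray:
    """Central-compartment concentration of a mammillary bolus model.

    ``params`` holds ``v1`` (L) and micro rate constants ``k10``, ``k12``,
    ``k21``, ``k13``, ``k31`` (1/h) as applicable.
    """
    n = 1 + sum(1 for key in ("k12", "k13") if key in params)
    times = np.asarray(times, dtype=float)
    if n == 1:
        central = dose * np.exp(-params["k10"] * times)
    else:
        k = _rate_matrix(params, n)
        lam, vec = np.linalg.eig(k)
        coeff = np.linalg.solve(vec, np.eye(n)[:, 0] * dose)
        central = (vec[0, :] * coeff) @ np.exp(np.outer(lam, times))
        central = np.real(central)
    return central / params["v1"]


def vss_from_micro(params: dict[str, float]) -> float:
    """Analytic steady-state volume: V1 (1 + k12/k21 + k13/k31)."""
    vss = params["v1"]
    for i in (2, 3):
        if f"k1{i}" in params:
            vss += params["v1"] * params[f"k1{i}"] / params[f"k{i}1"]
    return vss


@dataclass(frozen=True)
class CompartmentalFit:
    """A fitted 1-3 compartment bolus model.

    ``volumes`` are (central, peripheral...) in litres with peripheral
    volumes V1*k1i/ki1; ``vdss`` is their sum.
    """

    n_compartments: int
    volumes: tuple[float, ...]
    rate_constants: dict[str, float]
    aic: float
    vdss: float
    wss: float
    n_obs: int

    def __post_init__(self):
        if any(v <= 0 for v in self.volumes):
            raise ValidationError("volumes", "must all be positive")
        if any(v <= 0 for v in self.rate_constants.values()):
            raise ValidationError("rate_constants", "must all be positive")


_PARAM_NAMES = {
    1: ("v1", "k10"),
    2: ("v1", "k10", "k12", "k21"),
    3: ("v1", "k10", "k12", "k21", "k13", "k31"),
}


def _strip_exponentials(times, concs, n: int):
    """Peel log-linear phases slow-to-fast; returns (A, lambda) fast-first."""
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    terms = []
    residual = concs.copy()
    mask = np.ones_like(times, dtype=bool)
    for phase in range(n):
        idx = np.where(mask & (residual > 0))[0]
        if len(idx) < 2:
            break
        take = idx[-max(3, len(idx) // (n - phase)):] if phase < n - 1 else idx
        slope, intercept = np.polyfit(times[take], np.log(residual[take]), 1)
        lam = max(-slope, 1e-6)
        amp = math.exp(intercept)
        terms.append((amp, lam))
        residual = residual - amp * np.exp(-lam * times)
        mask = mask & (times < times[take[0]])
    while len(terms) < n:  # degenerate data: split the slowest phase
        amp, lam = terms[-1]
        terms.append((amp * 0.5, lam * 5.0))
    return sorted(terms, key=lambda t: -t[1])  # fast phase first


def _macro_to_micro(macro, dose, n: int) -> dict[str, float]:
    amps = np.array([a for a, _ in macro])
    lams = np.array([l for _, l in macro])
    c0 = amps.sum()
    v1 = dose / c0
    if n == 1:
        return {"v1": v1, "k10": float(lams[0])}
    if n == 2:
        k21 = float((amps[0] * lams[1] + amps[1] * lams[0]) / c0)
        k10 = float(lams[0] * lams[1] / k21)
        k12 = float(lams.sum() - k21 - k10)
        params = {"v1": v1, "k10": k10, "k12": k12, "k21": k21}
    else:
        # numerator polynomial s^2 + beta s + gamma of the transfer function
        r = []
        for i in range(3):
            others = [j for j in range(3) if j != i]
            r.append(
                amps[i] / c0 * (lams[others[0]] - lams[i]) * (lams[others[1]] - lams[i])
            )
        mat = np.array([[-lams[0], 1.0], [-lams[1], 1.0]])
        rhs = np.array([r[0] - lams[0] ** 2, r[1] - lams[1] ** 2])
        beta, gamma = np.linalg.solve(mat, rhs)
        disc = max(beta**2 - 4 * gamma, 0.0)
        k21 = (beta + math.sqrt(disc)) / 2.0
        k31 = (beta - math.sqrt(disc)) / 2.0
        k10 = float(np.prod(lams)) / (k21 * k31)
        d = lams.sum() - k10 - k21 - k31
        e = (
            lams[0] * lams[1] + lams[0] * lams[2] + lams[1] * lams[2]
            - k21 * k31 - k10 * (k21 + k31)
        )
        # k12 + k13 = d ; k31 k12 + k21 k13 = e
        k12 = (e - k21 * d) / (k31 - k21) if abs(k31 - k21) > 1e-12 else d / 2
        k13 = d - k12
        params = {"v1": v1, "k10": k10, "k12": k12, "k21": k21, "k13": k13, "k31": k31}
    # guard against unphysical stripping artefacts
    return {key: (value if value > 0 else 1e-3) for key, value in params.items()}


def fit_compartments(profile: ConcProfile, n: int) -> CompartmentalFit:
    """Fit an n-compartment bolus model by 1/yhat^2-weighted least squares.

    Initialisation is deterministic: curve stripping provides macro
    exponentials that are converted exactly to micro constants, plus fixed
    perturbed restarts; the best weighted sum of squares wins.
    """
    if n not in (1, 2, 3):
        raise ValueError("n must be 1, 2 or 3")
    m = len(profile.times)
    if m < 4 * n:
        raise ValidationError("times", f"{n}-compartment fit needs >= {4 * n} samples")
    names = _PARAM_NAMES[n]
    times = np.asarray(profile.times)
    concs = np.asarray(profile.concentrations)

    def residuals(theta):
        params = dict(zip(names, np.exp(theta)))
        pred = conc_bolus(times, params, profile.dose)
        pred = np.maximum(pred, 1e-300)
        return (concs - pred) / pred

    macro = _strip_exponentials(times, concs, n)
    base = _macro_to_micro(macro, profile.dose, n)
    starts = [np.log([base[name] for name in names])]
    for factor in (0.5, 2.0):
        starts.append(starts[0] + math.log(factor))
    best = None
    diagnostics = []
    for theta0 in starts:
        try:
            sol = least_squares(residuals, theta0, method="lm", max_nfev=2000)
        except Exception as exc:  # singular model at a start point
            diagnostics.append(str(exc))
            continue
        if not np.all(np.isfinite(sol.x)):
            diagnostics.append("non-finite solution")
            continue
        wss = float(2.0 * sol.cost)
        if best is None or wss < best[0]:
            best = (wss, sol)
    if best is None:
        raise FitError(
            f"{n}-compartment fit did not converge from any start: {diagnostics}"
        )
    wss, sol = best
    params = dict(zip(names, (float(v) for v in np.exp(sol.x))))
    volumes = [params["v1"]]
    for i in (2, 3):
        if f"k1{i}" in params:
            volumes.append(params["v1"] * params[f"k1{i}"] / params[f"k{i}1"])
    p = len(names)
    aic = m * math.log(max(wss, 1e-300) / m) + 2 * p
    return CompartmentalFit(
        n_compartments=n,
        volumes=tuple(volumes),
        rate_constants={key: value for key, value in params.items() if key != "v1"},
        aic=aic,
        vdss=sum(volumes),
        wss=wss,
        n_obs=m,
    )


def select_model(fits: Sequence[CompartmentalFit]) -> CompartmentalFit:
    """Minimum-AIC fit; ties broken toward fewer compartments."""
    if not fits:
        raise ValueError("select_model of an empty list")
    return min(fits, key=lambda f: (f.aic, f.n_compartments))
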