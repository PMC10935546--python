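"""Fitting of the auxiliary binding, mobility and partitioning assays.

Covers the measurements that bracket the stability model: NMR
chemical-shift-perturbation (CSP) titrations under fast exchange, direct
and competition fluorescence binding, biexponential FRAP recovery, and
fluorescence partition free energies.  All nonlinear fits go through
lmfit with analytic forward models; parameter uncertainties come from a
seeded residual-resampling bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import lmfit

from .stability_core import R_KJ

__all__ = [
    "TitrationCurve",
    "BindingFit",
    "CompetitionFit",
    "CspRecord",
    "FrapTrace",
    "FrapFit",
    "PartitionMeasurement",
    "csp",
    "fit_binding_curve",
    "random_coil_deviation",
    "select_significant",
    "fit_competition",
    "ki_from_ic50",
    "fit_frap",
    "partition_energy",
]

CSP_NITROGEN_WEIGHT = 0.15


@dataclass(frozen=True)
class TitrationCurve:
    """Observable vs ligand (or competitor) concentration."""

    x: tuple[float, ...]  # mM
    y: tuple[float, ...]
    A_conc: float  # receptor/dye concentration, mM
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y) or len(self.x) < 3:
            raise ValueError("need matched x/y with at least 3 points")
        xs = np.asarray(self.x)
        if np.any(xs < 0) or np.any(np.diff(xs) <= 0):
            raise ValueError("x must be nonnegative and strictly increasing")


@dataclass(frozen=True)
class BindingFit:
    Kd: float  # mM
    amplitude: float
    offset: float
    err: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise ValueError("Kd must be positive")


@dataclass(frozen=True)
class CompetitionFit:
    IC50: float  # mM
    n: float
    F0: float
    dF: float
    Ki: float | None = None
    err: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.IC50 <= 0 or self.n <= 0:
            raise ValueError("IC50 and Hill coefficient must be positive")


@dataclass(frozen=True)
class CspRecord:
    """Per-residue chemical-shift perturbation record."""

    residue: int  # 1-based
    dH: float  # ppm
    dN: float  # ppm
    csp: float  # ppm
    dRC: float | None = None


@dataclass(frozen=True)
class FrapTrace:
    """Normalized FRAP recovery trace (pre-bleach mean = 1)."""

    t: tuple[float, ...]  # s
    recovery: tuple[float, ...]
    bleach_time: float = 0.0

    def post_bleach(self) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(self.t)
        r = np.asarray(self.recovery)
        mask = t >= self.bleach_time
        return t[mask] - self.bleach_time, r[mask]


@dataclass(frozen=True)
class FrapFit:
    Rtot: float
    A1: float  # fast amplitude
    A2: float  # slow amplitude
    r1: float  # fast rate, s^-1
    r2: float  # slow rate, s^-1

    def __post_init__(self) -> None:
        if not self.r1 >= self.r2 > 0:
            raise ValueError("rates must satisfy r1 >= r2 > 0")
        if self.A1 < 0 or self.A2 < 0:
            raise ValueError("amplitudes must be nonnegative")

    @property
    def fast_fraction(self) -> float:
        return self.A1 / (self.A1 + self.A2)

    @property
    def slow_fraction(self) -> float:
        return self.A2 / (self.A1 + self.A2)


@dataclass(frozen=True)
class PartitionMeasurement:
    """Background-corrected in/out fluorescence intensities."""

    I_in: float
    I_out: float
    bg_in: float = 0.0
    bg_out: float = 0.0
    T: float = 295.15

    def __post_init__(self) -> None:
        if self.I_in <= self.bg_in or self.I_out <= self.bg_out:
            raise ValueError("signal must exceed background in both phases")

    @property
    def Kp(self) -> float:
        return (self.I_in - self.bg_in) / (self.I_out - self.bg_out)


def csp(dH: float, dN: float, alpha_w: float = CSP_NITROGEN_WEIGHT) -> float:
    """Weighted 1H/15N chemical-shift perturbation: sqrt(dH^2 + (a*dN)^2)."""
    return math.hypot(dH, alpha_w * dN)


def _quadratic_bound(B: np.ndarray, Kd: float, A: float) -> np.ndarray:
    """Bound fraction of the receptor for total ligand B (fast exchange)."""
    s = Kd + A + B
    return (s - np.sqrt(s * s - 4.0 * A * B)) / (2.0 * A)


def _bootstrap_ci(model_fn, x, y, best, param_names, seed, reps, ci=0.95):
    rng = np.random.default_rng(seed)
    fitted = model_fn(x, *best)
    resid = y - fitted
    draws = []
    for _ in range(reps):
        y_star = fitted + rng.choice(resid, size=resid.size, replace=True)
        try:
            draws.append(_refit(model_fn, x, y_star, best))
        except Exception:
            continue
    if not draws:
        return {}
    arr = np.array(draws)
    lo, hi = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    return {
        name: (float(np.percentile(arr[:, j], lo)),
               float(np.percentile(arr[:, j], hi)))
        for j, name in enumerate(param_names)
    }


def _refit(model_fn, x, y, p0):
    from scipy.optimize import least_squares

    res = least_squares(lambda p: model_fn(x, *p) - y, p0, max_nfev=200)
    return res.x


def fit_binding_curve(
    curve: TitrationCurve,
    bootstrap_reps: int = 0,
    seed: int = 0,
) -> BindingFit:
    """Fit a direct binding titration with the exact two-state quadratic.

    S = offset + amplitude * bound_fraction(B; Kd, A), where A is the
    fixed receptor (or dye) concentration and B the titrated ligand.
    At B = 0 the model equals the offset; as B -> inf it approaches
    offset + amplitude.
    """
    x = np.asarray(curve.x)
    y = np.asarray(curve.y)
    A = curve.A_conc

    def forward(B, Kd, amplitude, offset):
        return offset + amplitude * _quadratic_bound(B, Kd, A)

    model = lmfit.Model(forward, independent_vars=["B"])
    span = y[-1] - y[0]
    params = model.make_params(
        Kd=dict(value=max(np.median(x), 1e-6), min=1e-9),
        amplitude=dict(value=span if span != 0 else 1.0),
        offset=dict(value=float(y[0])),
    )
    result = model.fit(y, params, B=x)
    if not result.success:
        raise RuntimeError(f"binding fit did not converge: {result.message}")
    best = (result.params["Kd"].value, result.params["amplitude"].value,
            result.params["offset"].value)
    err = {}
    if bootstrap_reps:
        err = _bootstrap_ci(
            lambda B, Kd, amp, off: off + amp * _quadratic_bound(B, Kd, A),
            x, y, np.array(best), ("Kd", "amplitude", "offset"),
            seed, bootstrap_reps,
        )
    return BindingFit(Kd=best[0], amplitude=best[1], offset=best[2], err=err)


def random_coil_deviation(
    Href: float, H0: float, H30: float,
    Nref: float, N0: float, N30: float,
    alpha_w: float = CSP_NITROGEN_WEIGHT,
) -> float:
    """Shift of a residue toward its random-coil position upon titration.

    1/2*(|Href-H0| - |Href-H30| + a*(|Nref-N0| - |Nref-N30|)); positive
    values mean the titration moved the resonance toward the random-coil
    reference.
    """
    return 0.5 * (
        abs(Href - H0) - abs(Href - H30)
        + alpha_w * (abs(Nref - N0) - abs(Nref - N30))
    )


def select_significant(
    csps: Sequence[CspRecord], threshold: float = 0.02
) -> list[CspRecord]:
    """Records with CSP strictly above threshold (default one line width)."""
    return [rec for rec in csps if rec.csp > threshold]


def fit_competition(
    curve: TitrationCurve,
    bootstrap_reps: int = 0,
    seed: int = 0,
    hill_max: float = 4.0,
) -> CompetitionFit:
    """Fit a competition titration F = F0 + dF*(1 + C/IC50)^(-n)."""
    x = np.asarray(curve.x)
    y = np.asarray(curve.y)

    def forward(C, IC50, n, F0, dF):
        return F0 + dF * (1.0 + C / IC50) ** (-n)

    model = lmfit.Model(forward, independent_vars=["C"])
    positive_x = x[x > 0]
    params = model.make_params(
        IC50=dict(value=float(np.median(positive_x)), min=1e-9),
        n=dict(value=1.0, min=1e-3, max=hill_max),
        F0=dict(value=float(y[-1])),
        dF=dict(value=float(y[0] - y[-1])),
    )
    result = model.fit(y, params, C=x)
    if not result.success:
        raise RuntimeError(f"competition fit did not converge: {result.message}")
    p = result.params
    best = (p["IC50"].value, p["n"].value, p["F0"].value, p["dF"].value)
    err = {}
    if bootstrap_reps:
        err = _bootstrap_ci(
            lambda C, IC50, n, F0, dF: F0 + dF * (1.0 + C / IC50) ** (-n),
            x, y, np.array(best), ("IC50", "n", "F0", "dF"), seed, bootstrap_reps,
        )
    return CompetitionFit(IC50=best[0], n=best[1], F0=best[2], dF=best[3], err=err)


def ki_from_ic50(IC50: float, B: float, Kd_dye: float) -> float:
    """Cheng-Prusoff conversion: Ki = IC50 / (1 + B/Kd_dye)."""
    if Kd_dye <= 0:
        raise ValueError("probe Kd must be positive")
    return IC50 / (1.0 + B / Kd_dye)


def fit_frap(trace: FrapTrace) -> FrapFit:
    """Fit a biexponential recovery R(t) = Rtot - A1*e^(-r1 t) - A2*e^(-r2 t).

    Only post-bleach points are fit; fast/slow ordering (r1 >= r2) is
    enforced by swapping after the fit.
    """
    t, r = trace.post_bleach()
    if t.size < 6:
        raise ValueError(f"need at least 6 post-bleach points, got {t.size}")

    def forward(x, Rtot, A1, A2, r1, r2):
        return Rtot - A1 * np.exp(-r1 * x) - A2 * np.exp(-r2 * x)

    model = lmfit.Model(forward, independent_vars=["x"])
    depth = max(float(r[-1] - r[0]), 1e-3)
    t_span = float(t[-1] - t[0]) or 1.0
    params = model.make_params(
        Rtot=dict(value=float(r[-1]), min=0.0),
        A1=dict(value=0.6 * depth, min=0.0),
        A2=dict(value=0.4 * depth, min=0.0),
        r1=dict(value=10.0 / t_span, min=1e-6),
        r2=dict(value=1.0 / t_span, min=1e-6),
    )
    result = model.fit(r, params, x=t)
    if not result.success:
        raise RuntimeError(f"FRAP fit did not converge: {result.message}")
    p = result.params
    a1, a2 = p["A1"].value, p["A2"].value
    r1, r2 = p["r1"].value, p["r2"].value
    if r1 < r2:  # keep the fast component first
        a1, a2, r1, r2 = a2, a1, r2, r1
    return FrapFit(Rtot=p["Rtot"].value, A1=a1, A2=a2, r1=r1, r2=r2)


def partition_energy(m: PartitionMeasurement) -> float:
    """Partition free energy dG_part = R*T*ln(Kp) in kJ mol^-1.

    Kp is the background-corrected in/out intensity ratio; positive values
    mean enrichment inside condensates.  Use T = 310.15 K for in-cell
    measurements.
    """
    return R_KJ * m.T * math.log(m.Kp)
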