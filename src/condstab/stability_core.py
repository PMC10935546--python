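"""Condensate stability: polymerization free energy and the sticker model.

Measured side
-------------
An isodesmic self-assembly (polymerization) scheme links the total protein
concentration ``ctot`` and the dilute-phase concentration ``c1`` to a mean
association constant,

    ctot = c1 / (1 - c1*Ka)^2    <=>    Ka = 1/c1 - 1/sqrt(c1*ctot),

and the condensate stability is ``dG_sat = R*T*ln(Ka * c0)`` with standard
state c0 = 1 M.  Larger dG_sat means more stable condensates; in the limit
ctot >> c1 it converges to -R*T*ln(csat/c0).

Model side
----------
A stickers-and-spacers pair-counting free energy with four interaction
types (FG/RG cation-pi attraction, p/p and n/n repulsion, p/n attraction):

    dG_sat = x_FG*x_RG*(dG0_FGRG - s_FGRG)
           + 1/2*x_p*(x_p - 1)*(dG0_pp + s_pp)
           + 1/2*x_n*(x_n - 1)*(dG0_nn + s_nn)
           + x_p*x_n*(dG0_pn - s_pn)

where the screening energies ``s`` reduce attractions and soften
repulsions, and the charge counts x_p, x_n are the pH-titrated,
ion-binding-adjusted effective counts (fractional values are used directly
in the pair counts, a mean-field continuous extension).

With screening and binding off and x_p fixed, the model is exactly a
parabola in the net charge Q = x_p - x_n, which yields closed forms for
the most stable charge, acid count and pH; those analytic optima are
implemented here alongside the full prediction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .ion_binding import BindingModel, adjusted_charge_counts, competitive_occupancy
from .sequence_features import IonizableCounts, PkaTable, StickerCounts, titrated_counts
from .solution_model import (
    CONSTANTS,
    SolutionCondition,
    ionic_strength,
    screening_constant,
)

__all__ = [
    "R_KJ",
    "StabilityMeasurement",
    "FloryHugginsState",
    "InteractionParameters",
    "AnalyticSummary",
    "ka_from_concentrations",
    "dilute_from_ka",
    "dgsat_from_concentrations",
    "flory_huggins_dg",
    "flory_huggins_ddg",
    "predict_dgsat",
    "parabola_coefficients",
    "charge_optimum",
    "interaction_ratio_estimates",
    "composition_optimum",
    "optimal_pH",
    "effective_sticker_counts",
]

R_KJ = CONSTANTS.R / 1000.0  # kJ mol^-1 K^-1

#: Cation charges for the salts used in the study design.
CATION_CHARGES: Mapping[str, int] = {
    "Na": 1, "K": 1, "Gu": 1, "Mg": 2, "Ca": 2, "Y": 3,
}


@dataclass(frozen=True)
class StabilityMeasurement:
    """One (ctot, c1) observation under a solution condition."""

    sample_id: str
    seq_id: str
    ctot: float  # uM
    c1: float  # uM
    condition: SolutionCondition

    def __post_init__(self) -> None:
        if not 0 < self.c1 <= self.ctot:
            raise ValueError(
                f"sample {self.sample_id!r}: require 0 < c1 <= ctot "
                f"(got c1={self.c1}, ctot={self.ctot})"
            )

    @property
    def Ka(self) -> float:
        """Association constant in M^-1 (0 when no condensate formed)."""
        return ka_from_concentrations(self.c1, self.ctot)

    @property
    def dG_sat(self) -> float:
        return dgsat_from_concentrations(self.c1, self.ctot, self.condition.T)


@dataclass(frozen=True)
class FloryHugginsState:
    """A condensed phase in two-state Flory-Huggins theory."""

    chi: float
    phi1b: float
    N1: int
    V0: float  # dm^3 mol^-1

    def __post_init__(self) -> None:
        if not 0 < self.phi1b < 1:
            raise ValueError("condensed-phase volume fraction must be in (0, 1)")
        if self.N1 < 1:
            raise ValueError("chain length must be >= 1")
        if self.V0 <= 0:
            raise ValueError("molar segment volume must be positive")


@dataclass(frozen=True)
class InteractionParameters:
    """The 15 fitted model parameters.

    Four zero-salt pair free energies (kJ mol^-1; attractions positive
    because dG_sat is positive for stable condensates, repulsions
    negative), four screening distances (m), a shared relative dielectric,
    and one Kd (mM) per cation.
    """

    dG0_FGRG: float
    dG0_pp: float
    dG0_nn: float
    dG0_pn: float
    r0_FGRG: float
    r0_pp: float
    r0_nn: float
    r0_pn: float
    eps_r: float
    kd_by_ion: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dG0_FGRG < 0 or self.dG0_pn < 0:
            raise ValueError("attraction free energies must be >= 0")
        if self.dG0_pp > 0 or self.dG0_nn > 0:
            raise ValueError("repulsion free energies must be <= 0")
        if not 1 < self.eps_r <= 100:
            raise ValueError("relative dielectric must lie in (1, 100]")
        for r0 in (self.r0_FGRG, self.r0_pp, self.r0_nn, self.r0_pn):
            if r0 < 0:
                raise ValueError("screening distances must be >= 0")
        for name, kd in self.kd_by_ion.items():
            if not 0 < kd <= 1000:
                raise ValueError(f"Kd for {name!r} must lie in (0, 1000] mM")

    def binding_model(self) -> BindingModel:
        return BindingModel(
            kd_by_ion=dict(self.kd_by_ion),
            z_by_ion={k: CATION_CHARGES[k] for k in self.kd_by_ion},
        )


@dataclass(frozen=True)
class AnalyticSummary:
    """Derived analytic quantities for a parabola/optimum analysis."""

    Q: float | None = None
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    Q_opt: float | None = None
    xn_opt: float | None = None
    pH_opt: float | None = None
    A: float | None = None
    B: float | None = None
    C: float | None = None
    D: float | None = None
    classification: str | None = None


# ---------------------------------------------------------------------------
# polymerization model
# ---------------------------------------------------------------------------

def ka_from_concentrations(c1: float, ctot: float) -> float:
    """Association constant (M^-1) from dilute and total concentrations (uM).

    Inverts the isodesmic series ctot = c1/(1 - c1*Ka)^2:
    ``Ka = 1/c1 - 1/sqrt(c1*ctot)``.  Returns 0 when c1 == ctot (no
    condensate; a warning is emitted).
    """
    if c1 <= 0:
        raise ValueError("c1 must be positive")
    if c1 > ctot:
        raise ValueError(f"c1 ({c1}) exceeds ctot ({ctot})")
    c1_M = c1 * 1e-6
    ctot_M = ctot * 1e-6
    if c1 == ctot:
        warnings.warn("c1 == ctot: no condensate, Ka = 0", stacklevel=2)
        return 0.0
    return 1.0 / c1_M - 1.0 / math.sqrt(c1_M * ctot_M)


def dilute_from_ka(Ka: float, ctot: float) -> float:
    """Dilute-phase concentration (uM) from Ka (M^-1) and ctot (uM).

    Exact inverse of :func:`ka_from_concentrations`:
    ``c1 = 1/Ka + (1 - sqrt(1 + 4*Ka*ctot)) / (2*ctot*Ka^2)``, evaluated
    in the algebraically equivalent cancellation-free form
    ``c1 = (1/Ka) * u / (u + 2)`` with ``u = 4*Ka*ctot / (1 + sqrt(1 +
    4*Ka*ctot))``, which stays accurate down to Ka -> 0 (c1 -> ctot).
    """
    if Ka < 0:
        raise ValueError("Ka must be >= 0")
    if Ka == 0.0:
        return ctot
    ctot_M = ctot * 1e-6
    x = Ka * ctot_M
    u = 4.0 * x / (1.0 + math.sqrt(1.0 + 4.0 * x))
    c1_M = u / ((u + 2.0) * Ka)
    return c1_M * 1e6


def dgsat_from_concentrations(c1: float, ctot: float, T: float = 295.15) -> float:
    """Condensate stability dG_sat = R*T*ln(Ka*c0) in kJ mol^-1 (c0 = 1 M)."""
    Ka = ka_from_concentrations(c1, ctot)
    if Ka == 0.0:
        raise ValueError("Ka = 0 (c1 == ctot): dG_sat undefined")
    return R_KJ * T * math.log(Ka)


# ---------------------------------------------------------------------------
# Flory-Huggins comparison forms
# ---------------------------------------------------------------------------

def flory_huggins_dg(state: FloryHugginsState, T: float = 295.15) -> float:
    """-R*T*ln(csat) predicted by two-state Flory-Huggins theory (kJ mol^-1).

    dG_FH = R*T*(chi*phi*N*(2 - phi) - ln(phi/(N*V0)) - phi*(N - 1)).
    """
    s = state
    return R_KJ * T * (
        s.chi * s.phi1b * s.N1 * (2.0 - s.phi1b)
        - math.log(s.phi1b / (s.N1 * s.V0))
        - s.phi1b * (s.N1 - 1)
    )


def flory_huggins_ddg(
    state_a: FloryHugginsState, state_b: FloryHugginsState, T: float = 295.15
) -> float:
    """Stability difference between two conditions (kJ mol^-1).

    For equal condensed-phase volume fractions this reduces to
    ``2*(chi_a - chi_b)*R*T*phi*N``; in general it is the difference of
    the two full evaluations.
    """
    if state_a.N1 != state_b.N1:
        raise ValueError("chain lengths must match for a stability comparison")
    if state_a.phi1b == state_b.phi1b and state_a.V0 == state_b.V0:
        return (
            2.0 * (state_a.chi - state_b.chi) * R_KJ * T
            * state_a.phi1b * state_a.N1
        )
    return flory_huggins_dg(state_a, T) - flory_huggins_dg(state_b, T)


# ---------------------------------------------------------------------------
# stickers-and-spacers prediction
# ---------------------------------------------------------------------------

def effective_sticker_counts(
    base: StickerCounts,
    counts: IonizableCounts,
    cond: SolutionCondition,
    params: InteractionParameters,
    binding: bool = True,
    pka: PkaTable | None = None,
) -> StickerCounts:
    """pH-titrated (simple Asp/Glu + Arg/Lys) and ion-adjusted counts."""
    pka = pka or PkaTable()
    x_n_prime, _ = titrated_counts(counts, cond.pH, pka, groups=("Asp", "Glu"))
    _, x_p_prime = titrated_counts(counts, cond.pH, pka, groups=("Arg", "Lys"))
    if not binding:
        return replace(base, x_p=x_p_prime, x_n=x_n_prime,
                       charge_inverted_past_zero=False)
    occ = competitive_occupancy(cond.ions, params.binding_model())
    return adjusted_charge_counts(
        x_n_prime, x_p_prime, occ, params.binding_model(),
        x_FG=base.x_FG, x_RG=base.x_RG,
    )


def _pair_energy(
    stickers: StickerCounts,
    params: InteractionParameters,
    s_fg: float, s_pp: float, s_nn: float, s_pn: float,
) -> float:
    x_fg, x_rg = stickers.x_FG, stickers.x_RG
    x_p, x_n = stickers.x_p, stickers.x_n
    return (
        x_fg * x_rg * (params.dG0_FGRG - s_fg)
        + 0.5 * x_p * (x_p - 1.0) * (params.dG0_pp + s_pp)
        + 0.5 * x_n * (x_n - 1.0) * (params.dG0_nn + s_nn)
        + x_p * x_n * (params.dG0_pn - s_pn)
    )


def predict_dgsat(
    stickers: StickerCounts,
    cond: SolutionCondition,
    params: InteractionParameters,
    screening: bool = True,
) -> float:
    """Model dG_sat (kJ mol^-1) for given sticker counts and condition.

    ``stickers`` must already reflect the condition's pH (and, if ion
    binding is being modelled, its ion composition) — see
    :func:`effective_sticker_counts`.  With ``screening=False`` all
    screening energies are zero and the bare pair free energies apply.
    """
    if not screening:
        return _pair_energy(stickers, params, 0.0, 0.0, 0.0, 0.0)
    I_mM = ionic_strength(cond)
    s = [
        screening_constant(1, 1, params.eps_r, I_mM, r0, cond.T)
        for r0 in (params.r0_FGRG, params.r0_pp, params.r0_nn, params.r0_pn)
    ]
    return _pair_energy(stickers, params, *s)


# ---------------------------------------------------------------------------
# analytic structure: parabola in Q and optima
# ---------------------------------------------------------------------------

def parabola_coefficients(
    x_FG: int, x_RG: int, x_p: float, params: InteractionParameters
) -> tuple[float, float, float]:
    """Zero-salt parabola dG_sat = alpha + beta*Q + gamma*Q^2 at fixed x_p.

    Obtained by substituting x_n = x_p - Q into the pair-counting model:
    gamma = dG_nn/2, beta = -x_p*dG_pn + (1 - 2*x_p)*dG_nn/2, and alpha
    collects the Q-independent terms.
    """
    g_fg, g_pp, g_nn, g_pn = (
        params.dG0_FGRG, params.dG0_pp, params.dG0_nn, params.dG0_pn,
    )
    alpha = (
        x_FG * x_RG * g_fg
        + 0.5 * x_p * (x_p - 1.0) * g_pp
        + x_p**2 * g_pn
        + 0.5 * (x_p**2 - x_p) * g_nn
    )
    beta = -x_p * g_pn + 0.5 * (1.0 - 2.0 * x_p) * g_nn
    gamma = 0.5 * g_nn
    return alpha, beta, gamma


def charge_optimum(x_p: float, ratio_pn_nn: float) -> tuple[float, float]:
    """Most stable net charge and acid count at fixed x_p.

    Q_opt = x_p*(1 + dG_pn/dG_nn) - 1/2 and x_n_opt = x_p - Q_opt
    = 1/2 - x_p*(dG_pn/dG_nn).  Since the attraction and the repulsion
    have opposite signs, the ratio is negative and Q_opt < x_p.
    """
    if not math.isfinite(ratio_pn_nn):
        raise ValueError("interaction ratio must be finite")
    q_opt = x_p * (1.0 + ratio_pn_nn) - 0.5
    xn_opt = 0.5 - x_p * ratio_pn_nn
    return q_opt, xn_opt


def interaction_ratio_estimates(
    mode: Literal["from_qopt", "from_phopt"],
    x_p: float,
    Q_opt: float | None = None,
    pKa: float | None = None,
    pH_opt: float | None = None,
    x_n0: float | None = None,
) -> float:
    """Estimate dG_pn/dG_nn from an observed stability optimum.

    ``from_qopt`` rearranges the optimal-charge relation:
    ratio = (Q_opt + 1/2)/x_p - 1.  ``from_phopt`` uses the optimal-pH
    condition with a single acid pKa:
    ratio = (1/x_p)*(1/2 - x_n0/(10^(pKa - pH_opt) + 1)), which reduces to
    (1 - x_n0)/(2*x_p) when the optimum sits at the pKa.
    """
    if x_p <= 0:
        raise ValueError("x_p must be positive")
    if mode == "from_qopt":
        if Q_opt is None:
            raise ValueError("from_qopt mode requires Q_opt")
        return (Q_opt + 0.5) / x_p - 1.0
    if mode == "from_phopt":
        if pKa is None or pH_opt is None or x_n0 is None:
            raise ValueError("from_phopt mode requires pKa, pH_opt and x_n0")
        return (0.5 - x_n0 / (10.0 ** (pKa - pH_opt) + 1.0)) / x_p
    raise ValueError(f"unknown mode {mode!r}")


def composition_optimum(
    A: float, B: float, C: float, x_FG: float
) -> tuple[float, float, float, str]:
    """Jointly optimal charge composition from the free-energy ratios.

    With A = dG_FGRG/dG_pn, B = |dG_pp|/dG_pn, C = |dG_nn|/dG_pn and the
    cation-pi donors counted within the positive stickers (x_RG tied to
    x_p), stationarity of

        f(x_p, x_n) = A*x_FG*x_p - B*x_p*(x_p-1)/2 - C*x_n*(x_n-1)/2
                      + x_p*x_n

    gives   x_p_opt = C*(1 + B + 2*A*x_FG) / (2*(B*C - 1))
            x_n_opt = (B*(C + 1) + 2*A*x_FG) / (2*(B*C - 1))
            Q_opt   = (C - B + 2*A*x_FG*(C - 1)) / (2*(B*C - 1)).

    The stationary point is a maximum iff the discriminant D = B*C - 1 is
    positive (repulsions dominating the cross attraction); otherwise it is
    a saddle and no interior maximum exists.
    """
    if B < 0 or C < 0:
        raise ValueError("B and C are magnitude ratios and must be >= 0")
    D = B * C - 1.0
    if D == 0.0:
        raise ValueError("degenerate ratios: B*C = 1, no unique stationary point")
    xp_opt = C * (1.0 + B + 2.0 * A * x_FG) / (2.0 * D)
    xn_opt = (B * (C + 1.0) + 2.0 * A * x_FG) / (2.0 * D)
    q_opt = xp_opt - xn_opt
    classification = "max" if D > 0 else "saddle"
    return xp_opt, xn_opt, q_opt, classification


def composition_objective(
    x_p: float, x_n: float, A: float, B: float, C: float, x_FG: float
) -> float:
    """dG_sat/dG_pn as a function of composition (for numeric cross-checks)."""
    return (
        A * x_FG * x_p
        - 0.5 * B * x_p * (x_p - 1.0)
        - 0.5 * C * x_n * (x_n - 1.0)
        + x_p * x_n
    )


def optimal_pH(
    base: StickerCounts,
    counts: IonizableCounts,
    params: InteractionParameters,
    pH_grid: Sequence[float] | None = None,
    cond_template: SolutionCondition | None = None,
    screening: bool = False,
    binding: bool = False,
    pka: PkaTable | None = None,
) -> float:
    """pH at which the predicted dG_sat is maximal.

    Numeric argmax over a grid (default 2-9) with golden-section
    refinement around the best grid point.  Non-unimodal profiles return
    the global maximum with a warning.
    """
    pka = pka or PkaTable()
    grid = np.asarray(pH_grid if pH_grid is not None else np.linspace(2.0, 9.0, 141))
    template = cond_template or SolutionCondition(pH=7.0)

    def value(pH: float) -> float:
        cond = replace(template, pH=float(pH))
        stickers = effective_sticker_counts(
            base, counts, cond, params, binding=binding, pka=pka
        )
        return predict_dgsat(stickers, cond, params, screening=screening)

    vals = np.array([value(p) for p in grid])
    best = int(np.argmax(vals))
    # count strict local maxima on the grid to flag non-unimodal profiles
    interior = vals[1:-1]
    n_local = int(np.sum((interior > vals[:-2]) & (interior > vals[2:])))
    if n_local > 1:
        warnings.warn("stability profile is not unimodal in pH; returning "
                      "the global maximum", stacklevel=2)
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if lo == hi:
        return float(grid[best])
    res = minimize_scalar(
        lambda p: -value(p), bounds=(float(lo), float(hi)), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)
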