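"""Cation binding to acidic sidechains, charge inversion, and ELS analysis.

Multivalent cations bind individual Asp/Glu carboxylates non-cooperatively
with modest (tens to hundreds of mM) dissociation constants.  A bound
cation of charge ``z_c`` replaces the sidechain's -1 with a net
``+(z_c - 1)``: monovalent binding merely neutralizes, divalent binding
inverts the site charge from -1 to +1.  Because the protein is at uM and
the ions at mM-M concentrations, site occupancy is computed without ligand
depletion, with all cations competing for the same independent sites.

The electrophoretic light-scattering (ELS) helpers reproduce the
site-count bookkeeping used to translate a mobility-derived change in net
charge into a number of binding sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .sequence_features import StickerCounts
from .solution_model import IonSpecies

__all__ = [
    "BindingModel",
    "OccupancyResult",
    "ElsEstimate",
    "two_state_bound_fraction",
    "competitive_occupancy",
    "adjusted_charge_counts",
    "els_site_count",
    "els_site_summary",
    "mobility_standard_curve",
]


@dataclass(frozen=True)
class BindingModel:
    """Per-cation dissociation constants (mM) and charges."""

    kd_by_ion: Mapping[str, float]
    z_by_ion: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, kd in self.kd_by_ion.items():
            if kd <= 0:
                raise ValueError(f"Kd for {name!r} must be positive")
        for name, z in self.z_by_ion.items():
            if z < 1:
                raise ValueError(f"cation {name!r} must have z >= 1")


@dataclass(frozen=True)
class OccupancyResult:
    """Fraction of acidic sites bound by each cation, and unbound."""

    theta_by_ion: Mapping[str, float]
    U: float

    @property
    def theta_total(self) -> float:
        return sum(self.theta_by_ion.values())


@dataclass(frozen=True)
class ElsEstimate:
    """One ELS-derived binding-site estimate."""

    RT_recep: float  # mM
    LT: float  # mM
    RL: float  # mM
    pct_bound: float  # %
    delta_charge: float
    n_sites: int
    n_sites_raw: float


def two_state_bound_fraction(
    R_T: float, L_T: float, Kd: float
) -> tuple[float, float]:
    """Bound complex concentration and receptor bound fraction.

    Exact two-state binding:
    ``RL = ((R+L+Kd) - sqrt((R+L+Kd)^2 - 4*R*L)) / 2``, evaluated via the
    numerically stable quadratic root (product-over-conjugate form) so the
    dilute-receptor regime R_T << Kd does not lose precision.
    """
    if R_T < 0 or L_T < 0:
        raise ValueError("concentrations must be >= 0")
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    if R_T == 0 or L_T == 0:
        return 0.0, 0.0
    s = R_T + L_T + Kd
    disc = math.sqrt(s * s - 4.0 * R_T * L_T)
    # RL = (s - disc)/2 = 2*R*L/(s + disc): the latter avoids cancellation
    RL = 2.0 * R_T * L_T / (s + disc)
    return RL, RL / R_T


def competitive_occupancy(
    ions: Sequence[IonSpecies], model: BindingModel
) -> OccupancyResult:
    """No-depletion competitive occupancy of independent acidic sites.

    theta_i = (L_i/Kd_i) / (1 + sum_j L_j/Kd_j);  U = 1 / (1 + sum_j ...).
    Anions are ignored.  Every cation present must have a Kd in the model.
    """
    loads: dict[str, float] = {}
    for ion in ions:
        if ion.z < 1 or ion.conc == 0:
            continue
        if ion.name not in model.kd_by_ion:
            raise KeyError(
                f"no dissociation constant for cation {ion.name!r} in binding model"
            )
        loads[ion.name] = (
            loads.get(ion.name, 0.0) + ion.conc / model.kd_by_ion[ion.name]
        )
    denom = 1.0 + sum(loads.values())
    theta = {name: load / denom for name, load in loads.items()}
    return OccupancyResult(theta_by_ion=theta, U=1.0 / denom)


def adjusted_charge_counts(
    x_n_prime: float,
    x_p_prime: float,
    occ: OccupancyResult,
    model: BindingModel,
    x_FG: int = 0,
    x_RG: int = 0,
) -> StickerCounts:
    """Apply cation occupancy and charge inversion to the charge counts.

    Unbound sites keep their -1; a site bound by a cation of charge ``z_c``
    contributes ``+(z_c - 1)``, so the effective negative count is

        x_n = x_n' * U - x_n' * sum_i theta_i * (z_c,i - 1).

    The positive count is unchanged (bound, inverted sites are not added to
    ``x_p`` for pair counting).  ``x_n`` may go negative at high multivalent
    occupancy; this extrapolated regime is flagged on the result.
    """
    inversion = sum(
        theta * (model.z_by_ion[name] - 1)
        for name, theta in occ.theta_by_ion.items()
    )
    x_n = x_n_prime * occ.U - x_n_prime * inversion
    return StickerCounts(
        x_FG=x_FG,
        x_RG=x_RG,
        x_p=x_p_prime,
        x_n=x_n,
        charge_inverted_past_zero=x_n < 0,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def els_site_count(delta_charge: float, pct_bound: float) -> tuple[int, float]:
    """Binding sites implied by a charge change at a given bound percentage.

    ``n = (|delta_charge| / 2) * (100 / pct_bound)``: each bound divalent
    ion changes the site charge by two units, and only ``pct_bound`` % of
    chains carry a bound ion at any instant.  Returns the
    half-away-from-zero rounded count and the raw value.
    """
    if pct_bound <= 0:
        raise ValueError("pct_bound must be positive")
    raw = (abs(delta_charge) / 2.0) * (100.0 / pct_bound)
    return _round_half_away(raw), raw


def els_site_summary(estimates: Sequence[float]) -> tuple[int, int]:
    """Mean and half-range of site-count estimates, rounded to integers."""
    if len(estimates) < 2:
        raise ValueError("need at least two site-count estimates")
    mean = sum(estimates) / len(estimates)
    spread = (max(estimates) - min(estimates)) / 2.0
    return _round_half_away(mean), _round_half_away(spread)


def mobility_standard_curve(
    standards: Sequence[tuple[float, float]], query_mu: float
) -> tuple[float, dict]:
    """Interpolate a net charge from an electrophoretic-mobility standard curve.

    Fits mobility = a * Q + b by ordinary least squares over ``standards``
    (charge, mobility) pairs and inverts it at ``query_mu``.  Returns the
    charge and fit diagnostics (slope, intercept, R^2, n).
    """
    if len(standards) < 2:
        raise ValueError("need at least two standards")
    q = np.asarray([s[0] for s in standards], dtype=float)
    mu = np.asarray([s[1] for s in standards], dtype=float)
    if np.ptp(q) == 0:
        raise ValueError("standards must span at least two distinct charges")
    design = np.column_stack([q, np.ones_like(q)])
    (a, b), res, *_ = np.linalg.lstsq(design, mu, rcond=None)
    if a == 0:
        raise ValueError("degenerate standard curve: zero slope")
    ss_tot = float(np.sum((mu - mu.mean()) ** 2))
    ss_res = float(np.sum((mu - (a * q + b)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    diagnostics = {"slope": float(a), "intercept": float(b), "r_squared": r2,
                   "n_standards": len(standards)}
    return (query_mu - b) / a, diagnostics
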