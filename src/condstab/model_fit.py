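"""Global fitting of the interaction parameters to a dG_sat dataset.

The model is fit in nested stages of increasing complexity:

* ``base``       — 4 zero-salt pair free energies only;
* ``screen``     — + 4 screening distances and the relative dielectric;
* ``bind``       — base + one Kd per cation in the design;
* ``full``       — everything (15 parameters for a six-cation design).

Each stage warm-starts from the previous one and is polished by
basin-hopping around a bounded trust-region least-squares local solver,
with all stochastic steps seeded so a fit is reproducible bit-for-bit.
Nested variants are compared with an F-test on the residual sums of
squares, and parameter uncertainties come from a residual-resampling
bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .sequence_features import IonizableCounts, PkaTable, StickerCounts, titrated_counts
from .solution_model import CONSTANTS, SolutionCondition, ionic_strength
from .stability_core import CATION_CHARGES, InteractionParameters, StabilityMeasurement

__all__ = [
    "SequenceFeatures",
    "Dataset",
    "FitVariant",
    "FitResult",
    "VARIANTS",
    "residuals",
    "fit_model",
    "compare_variants",
    "bootstrap_uncertainty",
]

_KD_UPPER_MM = 1000.0


@dataclass(frozen=True)
class SequenceFeatures:
    """Sticker and ionizable counts for one sequence."""

    stickers: StickerCounts
    ionizable: IonizableCounts


@dataclass(frozen=True)
class Dataset:
    """Measurements plus the per-sequence counts needed to model them."""

    measurements: tuple[StabilityMeasurement, ...]
    sequences: Mapping[str, SequenceFeatures]
    pka: PkaTable = field(default_factory=PkaTable)

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        missing = {
            m.seq_id for m in self.measurements if m.seq_id not in self.sequences
        }
        if missing:
            raise KeyError(f"measurements reference unknown sequences: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.measurements)

    def cations(self) -> tuple[str, ...]:
        """Cation names appearing anywhere in the design, stable order."""
        seen: dict[str, None] = {}
        for m in self.measurements:
            for ion in m.condition.ions:
                if ion.z >= 1:
                    seen.setdefault(ion.name, None)
        return tuple(seen)

    def observed_dgsat(self) -> np.ndarray:
        return np.array([m.dG_sat for m in self.measurements])


@dataclass(frozen=True)
class FitVariant:
    """Which physical effects the fit includes."""

    screening: bool
    binding: bool

    @property
    def name(self) -> str:
        return {
            (False, False): "base",
            (True, False): "screen",
            (False, True): "bind",
            (True, True): "full",
        }[(self.screening, self.binding)]

    def n_params(self, n_cations: int) -> int:
        n = 4
        if self.screening:
            n += 5
        if self.binding:
            n += n_cations
        return n


VARIANTS: Mapping[str, FitVariant] = {
    "base": FitVariant(False, False),
    "screen": FitVariant(True, False),
    "bind": FitVariant(False, True),
    "full": FitVariant(True, True),
}


@dataclass(frozen=True)
class FitResult:
    params: InteractionParameters
    variant: FitVariant
    rss: float
    n_obs: int
    n_params: int
    seed: int
    n_hops: int
    converged: bool

    @property
    def rms(self) -> float:
        return math.sqrt(self.rss / self.n_obs)


# ---------------------------------------------------------------------------
# vectorized forward model
# ---------------------------------------------------------------------------

class _DesignMatrix:
    """Per-measurement arrays precomputed once per dataset.

    Everything that does not depend on the fitted parameters — titrated
    charge counts, motif counts, ionic strength, temperature and the
    cation concentration matrix — is frozen here so a residual evaluation
    is a handful of numpy expressions over the whole design.
    """

    def __init__(self, ds: Dataset, cations: Sequence[str]):
        n = len(ds)
        self.cations = tuple(cations)
        self.z_c = np.array([CATION_CHARGES[c] for c in self.cations], dtype=float)
        self.x_fg = np.empty(n)
        self.x_rg = np.empty(n)
        self.xp = np.empty(n)
        self.xn_prime = np.empty(n)
        self.I_mM = np.empty(n)
        self.T = np.empty(n)
        self.L = np.zeros((n, len(self.cations)))  # mM per cation
        self.y = ds.observed_dgsat()
        for i, m in enumerate(ds.measurements):
            feats = ds.sequences[m.seq_id]
            self.x_fg[i] = feats.stickers.x_FG
            self.x_rg[i] = feats.stickers.x_RG
            xn, _ = titrated_counts(
                feats.ionizable, m.condition.pH, ds.pka, groups=("Asp", "Glu")
            )
            _, xp = titrated_counts(
                feats.ionizable, m.condition.pH, ds.pka, groups=("Arg", "Lys")
            )
            self.xn_prime[i] = xn
            self.xp[i] = xp
            self.I_mM[i] = ionic_strength(m.condition)
            self.T[i] = m.condition.T
            for ion in m.condition.ions:
                if ion.z >= 1:
                    j = self.cations.index(ion.name)
                    self.L[i, j] += ion.conc
        c = CONSTANTS
        # r_d = sqrt(eps_r) * g;  g depends only on T and I
        self.g = np.sqrt(c.eps0 * c.R * self.T / (2e3 * c.F**2 * self.I_mM / 1e3))
        self.k0 = c.F**2 / (c.N_A * 8.0 * math.pi * c.eps0)  # J m / mol

    def predict(self, p: InteractionParameters, variant: FitVariant) -> np.ndarray:
        xn = self.xn_prime
        if variant.binding:
            kd = np.array([p.kd_by_ion[cat] for cat in self.cations])
            load = self.L / kd
            denom = 1.0 + load.sum(axis=1)
            theta = load / denom[:, None]
            xn = self.xn_prime * (1.0 / denom - theta @ (self.z_c - 1.0))
        if variant.screening:
            r_d = math.sqrt(p.eps_r) * self.g
            k = self.k0 / p.eps_r / 1000.0  # kJ m / mol
            s_fg = k / (r_d + p.r0_FGRG)
            s_pp = k / (r_d + p.r0_pp)
            s_nn = k / (r_d + p.r0_nn)
            s_pn = k / (r_d + p.r0_pn)
        else:
            s_fg = s_pp = s_nn = s_pn = 0.0
        return (
            self.x_fg * self.x_rg * (p.dG0_FGRG - s_fg)
            + 0.5 * self.xp * (self.xp - 1.0) * (p.dG0_pp + s_pp)
            + 0.5 * xn * (xn - 1.0) * (p.dG0_nn + s_nn)
            + self.xp * xn * (p.dG0_pn - s_pn)
        )


def residuals(
    ds: Dataset, params: InteractionParameters, variant: FitVariant | str
) -> np.ndarray:
    """Observed minus modelled dG_sat (kJ mol^-1), in measurement order."""
    variant = VARIANTS[variant] if isinstance(variant, str) else variant
    design = _DesignMatrix(ds, ds.cations())
    return design.y - design.predict(params, variant)


# ---------------------------------------------------------------------------
# parameter vector <-> InteractionParameters
# ---------------------------------------------------------------------------

class _ParamSpace:
    """Flat bounded vector representation for one fit variant.

    Screening distances are carried in nm inside the vector (converted to
    m on the way out) so all entries share comparable magnitudes.
    """

    _R0_NM = 1e-9

    def __init__(self, variant: FitVariant, cations: Sequence[str],
                 bounds: Mapping[str, tuple[float, float]] | None = None):
        self.variant = variant
        self.cations = tuple(cations)
        b = {
            "dG0_FGRG": (0.0, 5.0),
            "dG0_pp": (-2.0, 0.0),
            "dG0_nn": (-2.0, 0.0),
            "dG0_pn": (0.0, 2.0),
            "r0": (0.0, 100.0),  # nm
            "eps_r": (2.0, 100.0),
            "kd": (0.5, _KD_UPPER_MM),
        }
        if bounds:
            b.update(bounds)
        self.names = ["dG0_FGRG", "dG0_pp", "dG0_nn", "dG0_pn"]
        lo = [b["dG0_FGRG"][0], b["dG0_pp"][0], b["dG0_nn"][0], b["dG0_pn"][0]]
        hi = [b["dG0_FGRG"][1], b["dG0_pp"][1], b["dG0_nn"][1], b["dG0_pn"][1]]
        if variant.screening:
            for r in ("r0_FGRG", "r0_pp", "r0_nn", "r0_pn"):
                self.names.append(r)
                lo.append(b["r0"][0])
                hi.append(b["r0"][1])
            self.names.append("eps_r")
            lo.append(b["eps_r"][0])
            hi.append(b["eps_r"][1])
        if variant.binding:
            for cat in self.cations:
                self.names.append(f"kd_{cat}")
                lo.append(b["kd"][0])
                hi.append(b["kd"][1])
        self.lo = np.array(lo)
        self.hi = np.array(hi)
        # scale steps to each parameter's range for the hop proposals
        self.scale = 0.25 * (self.hi - self.lo)

    def to_params(self, x: np.ndarray,
                  template: InteractionParameters) -> InteractionParameters:
        d = dict(zip(self.names, x))
        for r in ("r0_FGRG", "r0_pp", "r0_nn", "r0_pn"):
            if r in d:
                d[r] = d[r] * self._R0_NM
        kd = dict(template.kd_by_ion)
        for cat in self.cations:
            key = f"kd_{cat}"
            if key in d:
                kd[cat] = float(d.pop(key))
        fields = {
            "dG0_FGRG": template.dG0_FGRG, "dG0_pp": template.dG0_pp,
            "dG0_nn": template.dG0_nn, "dG0_pn": template.dG0_pn,
            "r0_FGRG": template.r0_FGRG, "r0_pp": template.r0_pp,
            "r0_nn": template.r0_nn, "r0_pn": template.r0_pn,
            "eps_r": template.eps_r,
        }
        fields.update({k: float(v) for k, v in d.items()})
        return InteractionParameters(kd_by_ion=kd, **fields)

    def from_params(self, p: InteractionParameters) -> np.ndarray:
        vals = []
        for name in self.names:
            if name.startswith("kd_"):
                vals.append(p.kd_by_ion.get(name[3:], 100.0))
            elif name.startswith("r0_"):
                vals.append(getattr(p, name) / self._R0_NM)
            else:
                vals.append(getattr(p, name))
        return np.clip(np.array(vals, dtype=float), self.lo, self.hi)


_DEFAULT_START = {
    "dG0_FGRG": 0.3, "dG0_pp": -0.1, "dG0_nn": -0.1, "dG0_pn": 0.1,
    "r0": 5e-9, "eps_r": 50.0, "kd": 200.0,
}


def _start_params(cations: Sequence[str]) -> InteractionParameters:
    s = _DEFAULT_START
    return InteractionParameters(
        dG0_FGRG=s["dG0_FGRG"], dG0_pp=s["dG0_pp"], dG0_nn=s["dG0_nn"],
        dG0_pn=s["dG0_pn"], r0_FGRG=s["r0"], r0_pp=s["r0"], r0_nn=s["r0"],
        r0_pn=s["r0"], eps_r=s["eps_r"],
        kd_by_ion={c: s["kd"] for c in cations},
    )


def fit_model(
    ds: Dataset,
    variant: FitVariant | str,
    seed: int = 0,
    n_hops: int = 50,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    warm_start: InteractionParameters | None = None,
    staged: bool = True,
) -> FitResult:
    """Fit one model variant to a dataset.

    With ``staged=True`` (default) richer variants are warm-started from a
    quick fit of the nested simpler variants, which is how the global
    optimization avoids most local minima; basin-hopping with ``n_hops``
    seeded random restarts around the incumbent then polishes the result.
    Deterministic for fixed ``(seed, n_hops)``.
    """
    variant = VARIANTS[variant] if isinstance(variant, str) else variant
    cations = ds.cations()
    design = _DesignMatrix(ds, cations)
    if warm_start is None and staged and (variant.screening or variant.binding):
        base = fit_model(ds, VARIANTS["base"], seed=seed,
                         n_hops=max(4, n_hops // 4), staged=False)
        warm_start = base.params
        if variant.screening and variant.binding:
            bind = fit_model(ds, VARIANTS["bind"], seed=seed,
                             n_hops=max(4, n_hops // 2),
                             warm_start=warm_start, staged=False)
            screen = fit_model(ds, VARIANTS["screen"], seed=seed,
                               n_hops=max(4, n_hops // 2),
                               warm_start=warm_start, staged=False)
            # merge the two half-model optima into one full-model start
            warm_start = replace(
                bind.params,
                r0_FGRG=screen.params.r0_FGRG, r0_pp=screen.params.r0_pp,
                r0_nn=screen.params.r0_nn, r0_pn=screen.params.r0_pn,
                eps_r=screen.params.eps_r,
            )
    template = warm_start or _start_params(cations)
    space = _ParamSpace(variant, cations, bounds)

    def objective(x: np.ndarray) -> np.ndarray:
        return design.y - design.predict(space.to_params(x, template), variant)

    def local(x0: np.ndarray) -> tuple[np.ndarray, float, bool]:
        res = least_squares(
            objective, np.clip(x0, space.lo, space.hi),
            bounds=(space.lo, space.hi), method="trf", x_scale="jac",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
        )
        return res.x, float(np.sum(res.fun**2)), res.success

    rng = np.random.default_rng(seed)
    x_best, rss_best, ok = local(space.from_params(template))
    converged = ok
    x_inc = x_best
    for _ in range(n_hops):
        proposal = x_inc + rng.normal(0.0, 1.0, size=x_inc.shape) * space.scale
        x_try, rss_try, ok = local(proposal)
        if rss_try < rss_best:
            x_best, rss_best, converged = x_try, rss_try, ok
        # Metropolis-style acceptance of the hop origin (T ~ data scale)
        if rss_try < np.sum((objective(x_inc)) ** 2) or rng.random() < 0.1:
            x_inc = x_try
    return FitResult(
        params=space.to_params(x_best, template),
        variant=variant,
        rss=rss_best,
        n_obs=len(ds),
        n_params=variant.n_params(len(cations)),
        seed=seed,
        n_hops=n_hops,
        converged=converged,
    )


def compare_variants(
    fit_small: FitResult, fit_large: FitResult, n_obs: int | None = None
) -> tuple[float, float]:
    """F-test of a nested model pair: returns (F, p).

    F = ((rss_s - rss_l)/(p_l - p_s)) / (rss_l/(n - p_l)); small p means
    the extra parameters of the larger model are statistically justified.
    """
    small, large = fit_small.variant, fit_large.variant
    nested = (small.screening <= large.screening
              and small.binding <= large.binding)
    if not nested or fit_large.n_params <= fit_small.n_params:
        raise ValueError("variants are not strictly nested")
    if fit_small.rss < fit_large.rss:
        raise ValueError("nesting violated: larger model has larger RSS")
    n = n_obs if n_obs is not None else fit_large.n_obs
    dof_num = fit_large.n_params - fit_small.n_params
    dof_den = n - fit_large.n_params
    if dof_den <= 0:
        raise ValueError("not enough observations for the F-test")
    if fit_large.rss == 0.0:
        return math.inf, 0.0
    F = ((fit_small.rss - fit_large.rss) / dof_num) / (fit_large.rss / dof_den)
    p = float(stats.f.sf(F, dof_num, dof_den))
    return F, p


def bootstrap_uncertainty(
    ds: Dataset,
    best: FitResult,
    reps: int = 100,
    seed: int = 0,
    ci: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap percentile intervals per parameter.

    Resampled residuals are added to the best-fit predictions and each
    replicate is refit locally from the best-fit warm start (no hops).
    Deterministic per seed.
    """
    if reps < 2:
        raise ValueError("need at least two bootstrap replicates")
    cations = ds.cations()
    design = _DesignMatrix(ds, cations)
    space = _ParamSpace(best.variant, cations)
    x_hat = space.from_params(best.params)
    fitted = design.predict(best.params, best.variant)
    resid = design.y - fitted
    rng = np.random.default_rng(seed)
    draws = np.empty((reps, len(x_hat)))
    for r in range(reps):
        y_star = fitted + rng.choice(resid, size=resid.size, replace=True)

        def objective(x: np.ndarray, y=y_star) -> np.ndarray:
            return y - design.predict(space.to_params(x, best.params),
                                      best.variant)

        res = least_squares(objective, x_hat, bounds=(space.lo, space.hi),
                            method="trf", max_nfev=200)
        draws[r] = res.x
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    out = {}
    for j, name in enumerate(space.names):
        out[name] = (float(np.percentile(draws[:, j], lo_q)),
                     float(np.percentile(draws[:, j], hi_q)))
    return out
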