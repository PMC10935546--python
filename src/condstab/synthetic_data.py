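"""Synthetic sequences, stability designs and assay data.

Every input the analysis pipeline consumes can be generated here with a
known ground truth, so each downstream stage has a recovery test that
needs no external data.  The defaults emulate the study conditions the
model was developed for:

* a reference disordered chain with 32 positive residues (26 R, 6 K),
  36 acidic residues (19 D, 17 E), and 14 FG / 14 RG sticker motifs,
  with the acidic residues grouped into 5 local clusters;
* a charge-variant series of 5 sequences produced by trimming acidic
  residues (simple net charges -6 to -1);
* a 71-condition stability design: a pH series (3.2-7.6) on the
  reference chain plus chloride-salt additions of Na+, K+, Gu+, Mg2+,
  Ca2+ and Y3+ on a 150 mM NaCl / 20 mM buffer background for all five
  sequences;
* homoscedastic Gaussian noise of 0.75 kJ/mol on dG_sat (the residual
  scale of the global fit), applied in free-energy space.

All generators are deterministic per seed and attach their ground truth
to the returned objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .assay_fits import CspRecord, FrapFit, FrapTrace, TitrationCurve, csp
from .ion_binding import two_state_bound_fraction
from .model_fit import Dataset, SequenceFeatures
from .sequence_features import (
    IonizableCounts,
    SequenceRecord,
    count_ionizable_groups,
    sticker_counts,
)
from .solution_model import IonSpecies, SolutionCondition, salt_ions
from .stability_core import (
    InteractionParameters,
    R_KJ,
    StabilityMeasurement,
    dilute_from_ka,
    effective_sticker_counts,
    predict_dgsat,
)

__all__ = [
    "SequenceSpec",
    "DesignRow",
    "NoiseSpec",
    "REFERENCE_SEQUENCE_SPEC",
    "CHARGE_SERIES_SPECS",
    "TRUE_PARAMETERS",
    "generate_sequence",
    "charge_series",
    "paper_like_design",
    "generate_dgsat_dataset",
    "generate_titration",
    "generate_frap_trace",
]


@dataclass(frozen=True)
class SequenceSpec:
    """Composition targets for a synthetic disordered chain.

    ``n_fg``/``n_rg`` of the F/R residues are embedded in Gly-adjacent
    sticker motifs; the remaining charged and aromatic residues are placed
    with non-Gly/Ser neighbours so the motif counts round-trip exactly.
    ``n_negative_clusters`` > 0 groups the acidic residues into that many
    contiguous blocks (local negative-charge regions).
    """

    n_res: int
    n_R: int
    n_K: int
    n_D: int
    n_E: int
    n_F: int
    n_Y: int = 0
    n_fg: int = 0
    n_rg: int = 0
    n_negative_clusters: int = 0

    def __post_init__(self) -> None:
        if self.n_fg > self.n_F + self.n_Y:
            raise ValueError("more FG motifs than F/Y residues")
        if self.n_rg > self.n_R:
            raise ValueError("more RG motifs than R residues")
        if min(self.n_R, self.n_K, self.n_D, self.n_E, self.n_F, self.n_Y) < 0:
            raise ValueError("negative composition target")


@dataclass(frozen=True)
class DesignRow:
    """One condition of a stability design."""

    sample_id: str
    seq_id: str
    pH: float
    T: float
    additions: tuple[tuple[str, int, float], ...]  # (cation, z, mM) chloride salts
    ctot: float  # uM

    def condition(
        self, background_na_mm: float = 150.0, buffer_i_mm: float = 20.0
    ) -> SolutionCondition:
        ions: list[IonSpecies] = salt_ions("Na", 1, background_na_mm)
        for name, z, conc in self.additions:
            ions.extend(salt_ions(name, z, conc))
        return SolutionCondition(
            pH=self.pH, T=self.T, ions=tuple(ions),
            extra_ionic_strength=buffer_i_mm,
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Noise amplitudes for the generators."""

    sigma_dg: float = 0.75  # kJ mol^-1, residual scale of the global fit
    sigma_obs: float = 0.0  # per-assay observable noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_dg < 0 or self.sigma_obs < 0:
            raise ValueError("noise amplitudes must be >= 0")


#: Reference chain: 32 positives (26 R / 6 K), 36 acids (19 D / 17 E),
#: 14 FG + 14 RG motifs, acids in 5 clusters.
REFERENCE_SEQUENCE_SPEC = SequenceSpec(
    n_res=236, n_R=26, n_K=6, n_D=19, n_E=17, n_F=14,
    n_fg=14, n_rg=14, n_negative_clusters=5,
)

#: Charge-variant series: acidic residues trimmed from the reference
#: composition, emulating C-terminal truncation of an acidic tail.
CHARGE_SERIES_SPECS: Mapping[str, SequenceSpec] = {
    "N0": SequenceSpec(n_res=238, n_R=26, n_K=6, n_D=20, n_E=18, n_F=14,
                       n_fg=14, n_rg=14, n_negative_clusters=5),
    "N1": REFERENCE_SEQUENCE_SPEC,
    "N2": SequenceSpec(n_res=234, n_R=26, n_K=6, n_D=18, n_E=17, n_F=14,
                       n_fg=14, n_rg=14, n_negative_clusters=5),
    "N3": SequenceSpec(n_res=232, n_R=26, n_K=6, n_D=18, n_E=16, n_F=14,
                       n_fg=14, n_rg=14, n_negative_clusters=5),
    "N4": SequenceSpec(n_res=230, n_R=26, n_K=6, n_D=17, n_E=16, n_F=14,
                       n_fg=14, n_rg=14, n_negative_clusters=5),
}

#: Ground-truth interaction parameters for the forward model.  The
#: dielectric and the cation Kd ladder are the study's fitted values; the
#: zero-salt pair energies and screening distances are chosen so the
#: forward dG_sat spans ~16-32 kJ/mol over the default design with a
#: stability optimum near +13 net charge.
TRUE_PARAMETERS = InteractionParameters(
    dG0_FGRG=1.855,
    dG0_pp=-1.19,
    dG0_nn=-1.16,
    dG0_pn=0.911,
    r0_FGRG=0.40e-9,
    r0_pp=0.80e-9,
    r0_nn=0.85e-9,
    r0_pn=1.18e-9,
    eps_r=47.0,
    kd_by_ion={"Na": 1000.0, "K": 487.0, "Gu": 173.0,
               "Mg": 105.0, "Ca": 73.0, "Y": 5.0},
)

_SEPARATORS = "ANQ"  # never Gly/Ser: cannot create accidental sticker motifs


def generate_sequence(spec: SequenceSpec, seed: int = 0,
                      seq_id: str = "synthetic") -> SequenceRecord:
    """Build a chain whose counts round-trip the spec exactly.

    Sticker motifs are embedded as Gly-X dipeptides; all other F/Y/R are
    flanked by non-Gly/Ser filler so neither motif rule picks them up.
    Token order is a seeded shuffle, so the same seed always yields the
    same sequence.
    """
    rng = np.random.default_rng(seed)
    n_fg_from_f = min(spec.n_fg, spec.n_F)
    n_fg_from_y = spec.n_fg - n_fg_from_f
    tokens = (
        ["GF"] * n_fg_from_f
        + ["GY"] * n_fg_from_y
        + ["GR"] * spec.n_rg
        + ["F"] * (spec.n_F - n_fg_from_f)
        + ["Y"] * (spec.n_Y - n_fg_from_y)
        + ["R"] * (spec.n_R - spec.n_rg)
        + ["K"] * spec.n_K
    )
    acid_tokens = ["D"] * spec.n_D + ["E"] * spec.n_E
    rng.shuffle(tokens)
    rng.shuffle(acid_tokens)

    if spec.n_negative_clusters > 0 and acid_tokens:
        k = min(spec.n_negative_clusters, len(acid_tokens))
        clusters = [list(chunk) for chunk in np.array_split(acid_tokens, k)]
        cluster_tokens = ["".join(c) for c in clusters]
        positions = sorted(
            rng.choice(len(tokens) + 1, size=k, replace=False), reverse=True
        )
        for pos, block in zip(positions, cluster_tokens):
            tokens.insert(int(pos), block)
    else:
        for tok in acid_tokens:
            tokens.insert(int(rng.integers(0, len(tokens) + 1)), tok)

    seps = rng.choice(list(_SEPARATORS), size=len(tokens))
    body = "".join(t + s for t, s in zip(tokens, seps))
    if len(body) > spec.n_res:
        raise ValueError(
            f"composition needs {len(body)} residues but n_res={spec.n_res}"
        )
    pad = "".join(rng.choice(list("ANQST"), size=spec.n_res - len(body)))
    return SequenceRecord(id=seq_id, residues=body + pad,
                          description="synthetic charged IDR")


def charge_series(seed: int = 0) -> dict[str, SequenceRecord]:
    """The five-sequence charge-variant series, deterministic per seed."""
    return {
        name: generate_sequence(spec, seed=seed + i, seq_id=name)
        for i, (name, spec) in enumerate(CHARGE_SERIES_SPECS.items())
    }


_PH_SERIES = (3.2, 3.6, 4.0, 4.4, 4.8, 5.2, 5.6, 6.0, 6.5, 7.0, 7.6)
_SALT_ADDITIONS: tuple[tuple[str, tuple[tuple[str, int, float], ...]], ...] = (
    ("ctrl", ()),
    ("Na10", (("Na", 1, 10.0),)),
    ("Na30", (("Na", 1, 30.0),)),
    ("Na50", (("Na", 1, 50.0),)),
    ("K10", (("K", 1, 10.0),)),
    ("Gu10", (("Gu", 1, 10.0),)),
    ("Ca3.3", (("Ca", 2, 3.3),)),
    ("Ca10", (("Ca", 2, 10.0),)),
    ("Ca30", (("Ca", 2, 30.0),)),
    ("Mg3.3", (("Mg", 2, 3.3),)),
    ("Mg10", (("Mg", 2, 10.0),)),
    ("Y0.5", (("Y", 3, 0.5),)),
)


def paper_like_design(T: float = 295.15) -> list[DesignRow]:
    """The default 71-row design: 11 pH points on the reference chain plus
    12 salt conditions for each of the five charge variants (pH 8)."""
    rows = [
        DesignRow(sample_id=f"N1_pH{ph:g}", seq_id="N1", pH=ph, T=T,
                  additions=(), ctot=120.0)
        for ph in _PH_SERIES
    ]
    for seq_id in CHARGE_SERIES_SPECS:
        for label, adds in _SALT_ADDITIONS:
            rows.append(
                DesignRow(sample_id=f"{seq_id}_{label}", seq_id=seq_id,
                          pH=8.0, T=T, additions=adds, ctot=170.0)
            )
    assert len(rows) == 71
    return rows


def generate_dgsat_dataset(
    seqs: Mapping[str, SequenceRecord] | None = None,
    params: InteractionParameters = TRUE_PARAMETERS,
    design: Sequence[DesignRow] | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[Dataset, dict]:
    """Forward-simulate a stability dataset under the full model.

    Per row the true dG_sat is computed with screening and binding on,
    Gaussian noise of ``noise.sigma_dg`` is added in free-energy space,
    and the dilute-phase concentration is back-computed from the noisy
    value and the row's total concentration.  Returns the dataset and a
    ground-truth sidecar (true parameters, per-row true dG_sat, flags).
    """
    seqs = seqs if seqs is not None else charge_series(seed=noise.seed)
    design = list(design) if design is not None else paper_like_design()
    rng = np.random.default_rng(noise.seed)
    features = {
        sid: SequenceFeatures(
            stickers=sticker_counts(rec),
            ionizable=count_ionizable_groups(rec),
        )
        for sid, rec in seqs.items()
    }
    measurements = []
    truth_rows = []
    for row in design:
        cond = row.condition()
        feats = features[row.seq_id]
        stickers = effective_sticker_counts(
            feats.stickers, feats.ionizable, cond, params, binding=True
        )
        dg_true = predict_dgsat(stickers, cond, params, screening=True)
        dg_noisy = dg_true + rng.normal(0.0, noise.sigma_dg)
        ka = math.exp(dg_noisy / (R_KJ * cond.T))  # M^-1
        c1 = dilute_from_ka(ka, row.ctot)
        no_condensate = c1 >= row.ctot * (1.0 - 1e-12)
        c1 = min(c1, row.ctot)
        truth_rows.append({
            "sample_id": row.sample_id, "dg_true": dg_true,
            "dg_noisy": dg_noisy, "no_condensate": no_condensate,
        })
        if no_condensate:
            continue
        measurements.append(
            StabilityMeasurement(
                sample_id=row.sample_id, seq_id=row.seq_id,
                ctot=row.ctot, c1=c1, condition=cond,
            )
        )
    ds = Dataset(measurements=tuple(measurements), sequences=features)
    truth = {
        "params": params, "sigma_dg": noise.sigma_dg, "seed": noise.seed,
        "rows": truth_rows,
    }
    return ds, truth


# ---------------------------------------------------------------------------
# assay generators
# ---------------------------------------------------------------------------

def _binding_forward(xs: np.ndarray, Kd: float, A: float,
                     amplitude: float, offset: float) -> np.ndarray:
    s = Kd + A + xs
    bound = (s - np.sqrt(s * s - 4.0 * A * xs)) / (2.0 * A)
    return offset + amplitude * bound


def generate_titration(
    model: Literal["binding", "competition", "csp"],
    xs: Sequence[float],
    noise: NoiseSpec = NoiseSpec(),
    *,
    Kd: float = 150.0,
    A_conc: float = 0.02,
    amplitude: float = 0.1,
    offset: float = 0.0,
    IC50: float = 0.2,
    hill_n: float = 1.0,
    F0: float = 1e5,
    dF: float = 9e5,
    seq: SequenceRecord | None = None,
    kd_range: tuple[float, float] = (82.0, 174.0),
    weak_kd: float = 2000.0,
    reference_x: float = 30.0,
):
    """Forward-simulate a titration with ground truth in ``meta``.

    ``binding``      — direct two-state curve (CSP or fluorescence).
    ``competition``  — Hill-type displacement curve.
    ``csp``          — per-residue curves for a sequence: residues inside
    acidic clusters titrate with Kd drawn from ``kd_range`` and amplitudes
    giving CSPs well above the 0.02 ppm significance line at the
    ``reference_x`` point; all others bind weakly (Kd ``weak_kd``) and
    stay below it.  Returns (records at ``reference_x``, curves).
    """
    xs_arr = np.asarray(xs, dtype=float)
    rng = np.random.default_rng(noise.seed)
    if model == "binding":
        y = _binding_forward(xs_arr, Kd, A_conc, amplitude, offset)
        y = y + rng.normal(0.0, noise.sigma_obs, size=y.shape)
        return TitrationCurve(
            x=tuple(xs_arr), y=tuple(y), A_conc=A_conc,
            meta={"model": "binding", "true_Kd": Kd,
                  "true_amplitude": amplitude, "true_offset": offset},
        )
    if model == "competition":
        y = F0 + dF * (1.0 + xs_arr / IC50) ** (-hill_n)
        y = y + rng.normal(0.0, noise.sigma_obs, size=y.shape)
        return TitrationCurve(
            x=tuple(xs_arr), y=tuple(y), A_conc=A_conc,
            meta={"model": "competition", "true_IC50": IC50,
                  "true_n": hill_n, "true_F0": F0, "true_dF": dF},
        )
    if model == "csp":
        if seq is None:
            seq = generate_sequence(REFERENCE_SEQUENCE_SPEC, seed=noise.seed,
                                    seq_id="csp_reference")
        records = []
        curves = {}
        res = seq.residues
        for i, aa in enumerate(res):
            residue = i + 1
            neighbours = res[max(i - 1, 0): i + 2]
            in_cluster = any(a in "DE" for a in neighbours)
            true_kd = (float(rng.uniform(*kd_range)) if in_cluster
                       else float(rng.uniform(weak_kd, 2 * weak_kd)))
            amp_h = (float(rng.uniform(0.08, 0.15)) if in_cluster
                     else float(rng.uniform(0.005, 0.02)))
            amp_n = amp_h * float(rng.uniform(0.5, 2.0)) / CSP_WEIGHT_INV
            bound = _binding_forward(xs_arr, true_kd, A_conc, 1.0, 0.0)
            d_h = amp_h * bound + rng.normal(0, noise.sigma_obs, bound.shape)
            d_n = amp_n * bound + rng.normal(0, noise.sigma_obs, bound.shape)
            csp_vals = np.hypot(d_h, 0.15 * d_n)
            curves[residue] = TitrationCurve(
                x=tuple(xs_arr), y=tuple(csp_vals), A_conc=A_conc,
                meta={"model": "csp", "true_Kd": true_kd,
                      "in_cluster": in_cluster, "residue": residue},
            )
            j = int(np.argmin(np.abs(xs_arr - reference_x)))
            records.append(
                CspRecord(residue=residue, dH=float(d_h[j]), dN=float(d_n[j]),
                          csp=csp(float(d_h[j]), float(d_n[j])))
            )
        return records, curves
    raise ValueError(f"unknown titration model {model!r}")


CSP_WEIGHT_INV = 1.0 / 0.15


def generate_frap_trace(
    params: FrapFit,
    times: Sequence[float],
    noise: NoiseSpec = NoiseSpec(),
    n_prebleach: int = 10,
    prebleach_dt: float = 2.0,
) -> FrapTrace:
    """Simulate a normalized FRAP trace with a pre-bleach plateau at 1.0."""
    rng = np.random.default_rng(noise.seed)
    t_post = np.asarray(times, dtype=float)
    t_pre = -prebleach_dt * np.arange(n_prebleach, 0, -1)
    r_pre = np.ones_like(t_pre)
    r_post = (params.Rtot
              - params.A1 * np.exp(-params.r1 * t_post)
              - params.A2 * np.exp(-params.r2 * t_post))
    t = np.concatenate([t_pre, t_post])
    r = np.concatenate([r_pre, r_post])
    r = r + rng.normal(0.0, noise.sigma_obs, size=r.shape)
    return FrapTrace(t=tuple(t), recovery=tuple(r), bleach_time=0.0)
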