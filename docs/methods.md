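# Methods

This note documents the models implemented in `condstab`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Stability from concentrations

Condensation is treated as isodesmic self-assembly: monomers at dilute
concentration c₁ add to clusters of any size with one mean association
constant Ka, so c_tot = c₁/(1 − c₁Ka)² and

    Ka = 1/c₁ − 1/√(c₁·c_tot),     ΔG_sat = RT ln(Ka·c°),  c° = 1 M.

`dilute_from_ka` inverts this exactly using the cancellation-free form
c₁ = (1/Ka)·u/(u+2), u = 4Ka·c_tot/(1+√(1+4Ka·c_tot)), accurate to
1e−10 relative down to Ka → 0 (verified against a brute-force truncated
series of the cluster sum).  c₁ = c_tot is flagged "no condensate"
(Ka = 0).  Protein concentrations are µM throughout; the default in
vitro temperature is 295.15 K (room temperature), overridable per
measurement.  In the strong-assembly limit c_tot ≫ c₁ the measure
converges to −RT ln(c_sat/c°), the saturation-concentration free energy.
Two-state Flory–Huggins forms (`flory_huggins_dg`/`_ddg`) are provided
for comparison but are not used for fitting, because c_sat empirically
varies with c_tot in this family of systems.

## Charge bookkeeping

Nine ionizable group types are titrated with fixed textbook pKa values
(C-term 3.6, Asp 4.0, Glu 4.5, His 6.4, N-term 7.8, Cys 8.14, Tyr 9.6,
Lys 10.4, Arg 12.5); full-mode net charge is the Henderson–Hasselbalch
positive minus negative charged-site count.  The sticker model itself
uses only the simple counts: x_p from Arg+Lys (effectively constant over
pH 3.2–7.6) and x_n from Asp+Glu, titrated.  pKa values can be
overridden only explicitly (`PkaTable.with_overrides`); no environment-
dependent pKa shifting is attempted — a deliberate simplification that is
reasonable for a disordered chain but wrong near folded interfaces.

Sticker motifs: the default rule counts F/Y (→ x_FG) and R (→ x_RG) with
a Gly on at least one side; a variant counts F and R adjacent to Gly or
Ser.  Both published definitions are implemented because the source
analyses use both; the Gly-bounded rule is the default since it defines
the sticker classes of the fitted model.  A residue may contribute to
several counts (every R is in x_p; a Gly-adjacent R is also in x_RG).

## Ion binding and charge inversion

Each acidic site binds cations independently and competitively with no
ligand depletion (protein µM, ions mM–M):

    θ_i = (L_i/Kd_i) / (1 + Σ_j L_j/Kd_j),    U = 1/(1 + Σ_j L_j/Kd_j).

The effective acid count becomes x_n = x_n′·U − x_n′·Σ θ_i (z_i − 1):
monovalent binding neutralizes, divalent binding inverts (−1 → +1).
Bound, inverted sites are deliberately *not* added to x_p for pair
counting; x_n may go negative at extreme occupancy, which is flagged as
an extrapolation.  The depletion-aware two-state quadratic
(`two_state_bound_fraction`, evaluated by the numerically stable root)
backs the electrophoretic light-scattering worked example, where
n = (|Δcharge|/2)·(100/%bound) sites are inferred from a mobility
standard curve; site counts are rounded half-away-from-zero and
summarized as mean ± half-range.

## Screening

Ionic strength I = ½Σc_i z_i² counts the explicitly listed ions (fully
dissociated, no depletion by binding) plus an optional fixed offset for
buffer ions (+20 mM in the default synthetic design; default 0 for user
conditions, since it is genuinely unclear whether buffer ions should
enter).  The Debye length uses the standard two-cloud form
r_d = √(ε·ε₀·R·T/(2·10³·F²·I)), and the screening energy of a
unit-charge pair is

    s_r = F²/(N_A·8π·ε·ε₀) · 1/(r_d + r₀)

— the electrostatic energy of a mole of charge pairs at separation
2(r_d + r₀), of order 2.5 kJ/mol at 160 mM and ε = 47 with r₀ = 0.
Magnitudes are computed with |z_a z_b| = 1 and applied with fixed signs:
attractions (FG/RG, pn) are reduced, repulsions (pp, nn) softened.  A
tight/loose-complex variant s_s ∝ Δr₀/((r_d+r₀)(r_d+n·r₀)) with its
linear-in-I limit is available but not part of the default model.

## The global fit

The 15 parameters are 4 zero-salt pair energies (signs constrained:
attractions ≥ 0, repulsions ≤ 0), 4 screening distances, a shared ε, and
one Kd per cation (bounded at 1000 mM, where the Na⁺ value pegs).  The
objective is unweighted SSR of ΔG_sat in kJ/mol.  Fitting is staged:
base (4 params) → its optimum warm-starts the +screening and +binding
variants → their optima are merged to start the full model.  Each stage
runs a seeded Metropolis basin-hopping loop (default 50 hops; 10 in the
bundled pipelines, which profiling showed is past the point of
diminishing returns for this problem size) around a bounded
trust-region least-squares polish with Jacobian scaling; screening
distances are carried in nm internally so the vector is well
conditioned.  Everything is deterministic per (seed, n_hops).  Nested
variants are compared by F-test on RSS; uncertainties come from a seeded
residual-resampling bootstrap refit from the best-fit warm start (1000
reps by default).

**Identifiability of ε.**  With a free r₀ *and* a free zero-salt offset
per interaction, the shared dielectric is nearly flat in profile
likelihood over the design's ionic-strength window (0.17–0.26 M): on
noiseless synthetic data, fixing ε anywhere in [30, 99] and re-optimizing
the other 14 parameters changes the RSS by under 1e−3 (kJ/mol)², far
below the residual noise scale.  Replicate fits at the 0.75 kJ/mol noise
level recover the cation Kd ladder well (Ca²⁺ within ±50% in 10/10
replicates) but scatter ε across most of its bounds.  Bootstrap
intervals, which refit locally from the optimum, understate this
uncertainty; treat fitted ε (and the r₀ values individually) as
conditional on the basin, not as independently measured quantities.

## Analytic structure

At fixed x_p with no salt the model is ΔG_sat = α + βQ + γQ² with
γ = ΔG_nn/2 and β = −x_p·ΔG_pn + ½(1−2x_p)ΔG_nn, giving
Q_opt = x_p(1 + ΔG_pn/ΔG_nn) − ½ and x_n_opt = ½ − x_p·ΔG_pn/ΔG_nn; the
pH optimum sits at the acid pKa exactly when ΔG_pn/ΔG_nn = (1−x_n⁰)/(2x_p).
The joint composition optimum uses ratios A = ΔG_FG/RG/ΔG_pn,
B = |ΔG_pp|/ΔG_pn, C = |ΔG_nn|/ΔG_pn with the cation-π donors counted
inside the positive stickers (x_RG tied to x_p); stationarity gives
x_p_opt = C(1+B+2A·x_FG)/(2(BC−1)), x_n_opt = (B(C+1)+2A·x_FG)/(2(BC−1)),
a maximum iff the discriminant D = BC−1 > 0 (repulsions dominating the
cross attraction).  These closed forms are cross-validated against
numeric maximization in the tests.  The closed form for the optimal
stability value itself is not exposed; `optimal_pH` is computed
numerically (grid argmax plus bounded golden-section refinement, with a
warning on non-unimodal profiles).

## Assay fits

CSP = √(δH² + (0.15·δN)²); significance threshold 0.02 ppm, strict.
Direct binding titrations are fit to offset + amplitude × the exact
two-state bound fraction (total-ligand convention); competition curves to
F₀ + ΔF(1 + C/IC50)^(−n) with the Hill coefficient free in (0, 4];
IC50 → Ki by Cheng–Prusoff.  FRAP recovery is biexponential with fast/
slow ordering enforced by swap, fit to post-bleach points only (≥ 6
required).  Partition free energies are RT ln of the background-corrected
in/out intensity ratio (310.15 K for in-cell measurements).  All
nonlinear fits use lmfit with analytic forward models; errors are seeded
residual-resampling bootstrap percentiles.  Fast exchange is assumed
throughout — no lineshape modelling.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical design* of the study: a
reference chain of 236 residues with 32 positives (26 R/6 K), 36 acids
(19 D/17 E) in five clusters and 14 FG/14 RG motifs; a five-member
charge series (simple charges −6 … −1) built by trimming acids; 71
stability conditions (11-point pH series 3.2–7.6 plus 12 salt conditions
× 5 sequences on 150 mM NaCl/20 mM buffer, c_tot 120–170 µM); Gaussian
noise of 0.75 kJ/mol applied homoscedastically in free-energy space (the
residual scale of the global fit), with c₁ back-computed from the noisy
ΔG_sat.  Ground-truth parameters use the study's fitted dielectric
(ε = 47) and cation Kd ladder (Y³⁺ 5, Ca²⁺ 73, Mg²⁺ 105, Gu⁺ 173,
K⁺ 487, Na⁺ 1000 mM); the unpublished pair energies and screening
distances were chosen once so the forward model spans ~16–30 kJ/mol with
a pH optimum at ~4.4, mild monovalent destabilization and strong,
charge-dependent multivalent stabilization.

Not emulated: sequence-patterning effects (charge blockiness beyond
cluster placement, FG/RG positioning), temperature dependence, anion
binding, Hofmeister chemistry, condensed-phase composition, or any
imaging/spectral raw data.  Passing recovery tests therefore demonstrate
correctness of the inference machinery under the model's own
assumptions, not that the model captures every feature of real
condensate data.

## Known limitations

* The shared dielectric is not practically identifiable from the default
  design (see above); only the Kd ladder and the effective (screened)
  pair energies are well determined.
* Mean-field pair counting uses fractional x values in ½x(x−1); this
  continuous extension is an approximation to discrete site statistics.
* Extended Debye–Hückel screening only; no activity-coefficient model
  beyond it, no ion-specific (Hofmeister) corrections, so Gu⁺ behaviour
  is captured only through its fitted Kd.
* The isodesmic model is a thermodynamic barometer, not a phase-diagram
  theory: no binodal computation is attempted.
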