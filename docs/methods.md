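# Methods

## Binding model

The assay couples two independent 1:1 equilibria at a single protein
site: P + L ⇌ PL with dissociation constant Kd* (fluorescent probe) and
P + I ⇌ PI with Kd (inhibitor). No cooperativity, no 2:1 stoichiometry,
no kinetics — equilibrium concentrations only. All internal
concentrations are molar; the reporting layer converts to µM or nM.

For direct titrations the fraction of probe bound FB = [PL]/[L]t is the
smaller root of the quadratic mass balance, evaluated in the
cancellation-stable form 2[P]t/(s + √(s² − 4[P]t[L]t)) with
s = [P]t + [L]t + Kd*. This is exact under probe depletion; no
"[L] ≈ [L]t" approximation is made anywhere.

For competitive titrations FB comes from the exact ternary solution.
fpbind evaluates the trigonometric closed form of the cubic in free
protein and then applies three Newton iterations (clamped to
[0, [P]t]) on the mass balance

    P(1 + [L]t/(Kd* + P) + [I]t/(Kd + P)) = [P]t.

The polish matters: when free protein falls orders of magnitude below
both dissociation constants, the bare closed form loses up to ~4×10⁻⁶ in
FB to floating-point cancellation; after polishing it agrees with an
independent bracketed (Brent) root finder to ≈2×10⁻¹⁶ across a
1000-system log-uniform sweep. Degenerate branches (non-positive
discriminant, non-finite intermediates) are routed to the Brent solver
outright. The Brent oracle itself uses `xtol` at the smallest positive
double and scipy's minimum relative tolerance, because the free-protein
root can sit near 10⁻¹² M — far below brentq's default absolute
tolerance.

The signal map is intensity-weighted anisotropy mixing,
r = (Q·FB·rb + (1−FB)·rf)/(Q·FB + 1−FB). Q defaults to 1 (no quantum
yield change on binding), which reduces to the linear mixture; Q is
configurable because some probes brighten on binding. Plateaus are
constrained to the physical range [0, 0.4] and a valid probe has
rb > rf.

## Fitting

Both fitters minimize unweighted squared residuals on anisotropy with
`scipy.optimize.least_squares` (trust-region reflective, bounded).
Because titrations span decades, Kd is parametrized as log10 Kd with
bounds [10⁻¹², 10⁻¹] M, and a multi-start over 7 log-spaced initial
guesses (spanning the sampled concentration decades, padded one decade
each way) guards against local minima; the winner is the lowest-RSS
start. Standard errors are asymptotic (Jacobian-based Gauss–Newton
covariance scaled by RSS/dof), with the Kd error delta-mapped from log
space; they describe curvature at the optimum, not a resampling
distribution.

Direct fits float (log10 Kd*, rf, rb). Competitive fits float
(log10 Kd, rf, rb) per curve by default — floating the plateaus absorbs
plate/day effects — with an option to fix them from a direct fit.
Replicates follow the mean ± SD table convention: each independent
experiment (its triplicates pooled) is fitted separately, and the
arithmetic mean and sample SD (n−1) of the per-experiment Kds are
reported on the linear scale. One experiment yields an undefined SD,
flagged rather than silently zero.

Two quality flags: a direct curve whose top protein point is below
Kd*/10 — or whose fitted model reaches under 10% probe saturation at the
top of the titration, the degenerate-family equivalent — carries a
plateau warning (Kd* ill-determined, wide SE). A competitive fit whose
model predicts less than 20% displacement of bound probe at the top
inhibitor concentration is flagged "weak binder"; its Kd is at best a
lower bound.

Fold selectivity is the plain ratio Kd(Gal-1)/Kd(Gal-3C) of mean Kds,
optionally rounded to significant figures for reporting; it is computed
before any rounding, so selectivity(a,b)·selectivity(b,a) = 1 exactly.

## Synthetic data

The plate generator emulates a displacement assay campaign: an exact
geometric dilution series (default 10 points, 3-fold, from 100 µM — a
range that brackets µM-to-nM affinities), a replicate structure of
independent experiments each in triplicate (default 3 × 3; the
two-experiment scheme of early screening tables is one parameter away),
and i.i.d. Gaussian noise on anisotropy (default SD 0.002, an
instrument-level figure). Default assay constants are probe Kd* 50 nM,
probe 20 nM, protein 100 nM (= 2·Kd*); these are package conventions for
a well-configured assay, not measured values. Noise streams are derived
per (experiment, replicate) via CRC32 sub-seeds XORed into the design
seed, so enlarging a design never perturbs already-generated wells.

What the generator does *not* emulate: intensity/G-factor corrections,
well-position and edge artifacts, meniscus effects, pipetting error
correlated along the dilution series, or compound-specific optical
interference. Passing recovery tests therefore demonstrates estimator
correctness under the stated noise model, not robustness to every
real-plate pathology.

The trajectory generator draws a hidden bound/unbound state per frame
(Bernoulli with the designed occupancy). Bound frames sit on the
reference pose displaced by a random rigid offset plus per-atom jitter
calibrated so expected RMSD ≈ the designed bound mean (0.8 Å default);
unbound frames are rigidly displaced to ≈ the unbound mean (5 Å).
Dihedrals come from state-specific von Mises clusters (κ = 50 default,
four angles, means 120° apart between states). Frames are i.i.d. —
there is no kinetic correlation structure — so bound-fraction recovery
tests check counting and classification, not autocorrelation handling.

## Pose statistics

RMSD to the reference is computed without refitting, because frames are
assumed receptor-superposed upstream; this makes a 1 Å rigid drift score
exactly 1 Å. Heavy-atom selection and symmetry-equivalent-atom
corrections (e.g. carboxylate oxygen swaps) are the caller's
responsibility; no symmetry correction is applied — a documented
limitation that can inflate RMSD for symmetric groups. Bound-frame
classification uses strict RMSD < threshold (2 Å default). Equally
spaced subsampling is fixed as indices ⌊k·N/n⌋ to make "equally spaced"
deterministic; spacings differ by at most one frame.

dPCA featurizes each angle φ as (sin φ, cos φ) — continuous across the
±180° wrap — and runs ordinary PCA (full SVD) on the pooled features of
all ligands; individual ligands are then projected with the shared means
and loadings so their embeddings are directly comparable. Component
signs are fixed by making each component's largest-magnitude loading
positive. A feature matrix with total variance ≤ 10⁻¹² (numerically
constant input) is rejected as degenerate rather than fitted.

## Pipelines and sizes

`run_affinity_pipeline` fits every curve in a plate CSV (direct curves
first, refining Kd*; then competitive curves against it), assembles
per-compound mean ± SD tables and the selectivity table, and writes
deterministic sorted-key JSON plus a tidy fitted-curve CSV. Runs log the
package version, seed, and a config hash. `run_pose_pipeline` reports
full-series and 30-frame-subsample bound counts and writes the dPCA
embedding CSV (ligand, frame, dPC1, dPC2, RMSD, bound flag).

Test and acceptance problem sizes are chosen for desk-scale turnaround:
recovery sweeps use 200 single-experiment curves, oracle sweeps 1000
systems, trajectory checks 3000–10,000 frames. These sizes give binomial
or median-statistic margins comfortably tighter than the asserted
tolerances (e.g. ±0.02 on a 0.9 bound fraction at n = 10,000).

## Known limitations

- Asymptotic SEs only; no bootstrap or profile-likelihood intervals
  (tables report cross-experiment SD instead).
- No global multi-curve fitting with shared plateaus, no IC50/Cheng–
  Prusoff reporting (Kd is fitted directly), no cooperative or 2:1
  models.
- The weak-binder Kd lower bound is a flag, not a censored-likelihood
  estimate.
- XYZ I/O (via MDAnalysis) keeps 5 decimal places; round-trips are exact
  to 10⁻⁴ Å.
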