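# fpbind

Exact equilibrium analysis for fluorescence-polarization (FP) binding
assays, plus pose-ordering statistics for ligand MD trajectories. The
package covers the quantitative core of a galectin-inhibitor profiling
campaign: determining probe and inhibitor dissociation constants from
plate-format anisotropy titrations, reporting fold selectivity between
galectin-1 and the galectin-3 carbohydrate-recognition domain (Gal-3C),
and classifying how tightly a simulated ligand keeps to its
crystallographic binding pose.

**Who it is for.** Assay scientists fitting FP displacement curves who
want exact (depletion-correct) binding models instead of IC50
approximations, and computational chemists post-processing trajectories
into bound-frame counts and dihedral-PCA embeddings.

## Models

**Direct binding** (protein P titrated into fluorescent probe L): the
fraction of probe bound follows the exact quadratic mass balance

    FB = ([P]t + [L]t + Kd* − sqrt(([P]t + [L]t + Kd*)² − 4[P]t[L]t)) / (2[L]t)

**Competitive binding** (inhibitor I displacing probe at fixed P + L):
FB is the physically meaningful root of the ternary cubic mass balance
(Wang's exact solution for two ligands competing for one receptor site).
fpbind evaluates the trigonometric closed form and polishes it with Newton
steps on the free-protein mass balance, so it agrees with a brute-force
bracketed root finder to machine precision in every concentration regime.

Measured anisotropy is the mixture r = (Q·FB·rb + (1−FB)·rf)/(Q·FB + 1−FB)
with free/bound plateaus rf, rb and intensity ratio Q (default 1). Kd is
fitted as log10 Kd by bounded multi-start least squares; each independent
experiment (triplicates pooled) is fitted separately and reported as
mean ± SD across experiments.

**Pose statistics**: per-frame ligand RMSD to a reference pose (no
refitting — frames arrive receptor-aligned), bound-frame counts at a
strict RMSD < 2 Å, deterministic equally spaced subsampling, and dPCA —
PCA on sine/cosine-transformed dihedral angles, fitted on all ligands
pooled and applied per ligand.

## Worked example

Simulate a competitive plate for a 5.7 nM inhibitor (probe Kd* 50 nM,
protein 100 nM, probe 20 nM; 3 experiments × 3 triplicates, 10-point
3-fold dilution from 100 µM, anisotropy noise SD 0.002) and refit it:

```sh
$ fpbind simulate-compete --true-kd 5.7e-9 --seed 1 --compound 11 \
    --target Gal-3C --out plate.csv
$ fpbind fit-compete --plate plate.csv --probe-kd 50e-9 --units nM --out fit.json
11 / Gal-3C: Kd = 5.67 ± 0.124 nM
$ fpbind selectivity --kd-gal1 2.2e-6 --kd-gal3c 5.7e-9
390
```

The fit recovers 5.67 ± 0.12 nM against the 5.7 nM ground truth — the
mean and SD are computed across the three independently fitted
experiments, the convention used in affinity tables. The selectivity
command reports Kd(Gal-1)/Kd(Gal-3C) rounded to two significant figures:
a 2.2 µM / 5.7 nM pair is 390-fold selective for Gal-3C.

The same operations are available as a library:

```python
from fpbind import (EquilibriumSystem, PlateDesign, simulate_competition_plate,
                    fit_competitive)

design = PlateDesign(seed=1)                      # 3 exp × 3 reps, noise 0.002
system = EquilibriumSystem(protein_total=100e-9, probe_total=20e-9,
                           probe_kd=50e-9, inhibitor_kd=5.7e-9)
curve = simulate_competition_plate(design, system)
result = fit_competitive(curve, probe_kd=50e-9)
print(result.kd_mean)                             # 5.670457612042841e-09
```

`DirectBindingFP`, `CompetitiveBindingFP` and `DihedralPCA` are
scikit-learn estimators (`fit`/`predict`/`transform`, `get_params`), so
they compose with sklearn pipelines and model selection.

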