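# cordbmi

Analysis library for asking whether the **cord-blood plasma metabolome at
birth predicts a child's body-mass-index trajectory through adolescence**,
written for epidemiologists and biostatisticians working with birth-cohort
data (irregular growth visits, LC-MS metabolite panels, request-only cohort
access).  Because such cohort data are rarely redistributable, the package
ships a seeded synthetic-cohort generator with known ground truth, so every
stage of the pipeline is testable end to end.

## What it computes

1. **Growth percentiles (LMS method).**  BMI at age *t* is converted to a
   z-score with the reference's Box-Cox power *L*, median *M* and
   coefficient of variation *S*:
   `z = ((X/M)^L − 1)/(L·S)` (log form at *L* = 0), `BMIPCT = 100·Φ(z)`,
   with *L, M, S* interpolated in age per sex.  Percentiles are defined
   from age 2 years.
2. **Trajectory groups.**  Visits are pooled into time-windows (≥ 30
   children, ≤ 12 months wide), averaged per child, and missing windows
   imputed from the neighboring observed values.  k-means (k = 2) on the
   complete percentile matrix separates overall-high from normal-range
   children; the sign of PC2 splits each cluster by trajectory shape,
   giving **early-OWO**, **late-OWO**, **NW-A**, **NW-B** (the two NW
   subgroups collapse to **NW** for analysis).
3. **Metabolite QC.**  CV > 20% exclusion, half-minimum imputation of
   non-detects, rank-based inverse normal transformation (Blom offset 3/8).
4. **Co-abundance modules.**  Unsigned weighted network `a_ij =
   |cor(x_i,x_j)|^β` (β from the scale-free topology criterion),
   topological-overlap similarity, average-linkage clustering, tree cut
   with minimum module size 15; each module is summarized by an oriented
   unit-variance eigen-metabolite (PC1).
5. **Associations.**  Baseline-category multinomial logistic regression of
   trajectory group on each eigen-score or metabolite (covariates: sex,
   race, preterm birth, maternal smoking, maternal overweight/obesity,
   maternal education), odds ratios per SD with Wald 95% CIs,
   Benjamini–Hochberg FDR per contrast family, sex-interaction likelihood
   ratio tests.
6. **Time-window models.**  Per-window OLS of BMI on exposure with a sex
   interaction and 2-df LRT screening; effects standardized by the
   within-sex window BMI SD; sensitivity variants adjusting for cesarean
   section, breastfeeding, and birthweight (skipped in the first window).

## Worked example

```bash
python examples/03_trajectory_groups.py
```

```
25 windows; min n = 96, max width = 12.0 months

4-level group sizes: {'early-OWO': 372, 'NW-A': 273, 'late-OWO': 220, 'NW-B': 35}
PC1 explains 89.2% of variance, PC2 7.2%
agreement with planted classes: 97.9% (the generator's ground truth)
```

Every emitted window satisfies the participation/width constraints; PC1
(overall percentile level) dominates the trajectory matrix with PC2 adding
the early-versus-late onset contrast; and 97.9% of children land in their
planted 3-level class.  Continuing with `examples/05_module_associations.py`:

```
module associations, early-OWO vs NW (ordered by FDR):
 exposure    or  ci_lo  ci_hi     p     q
    black 1.571  1.338  1.844 0.000 0.000
    green 0.753  0.644  0.880 0.000 0.001
    brown 0.787  0.673  0.919 0.003 0.006
   yellow 0.804  0.688  0.939 0.006 0.010
     blue 0.934  0.802  1.089 0.386 0.540
...
```

The modules passing FDR are exactly the generator's shifted blocks: the
CE-like block (planted +0.25 SD in early-OWO children) shows OR > 1, the
TAG/DAG-like blocks (−0.25 SD) show OR < 1, and the null blocks sit at
OR ≈ 1.  `examples/06_time_windows.py` shows the same signals per
time-window and the birthweight-mediation sensitivity: early-window
standardized effects shrink from 0.069 to 0.047 under birthweight
adjustment while cesarean adjustment leaves them unchanged.

The full pipeline also runs from the shell:

```bash
cordbmi generate --seed 1 --out-dir cohort/
cordbmi run --in-dir cohort/ --out-dir run/
```

writing windows, trajectory groups, module membership/eigen-scores,
association tables, per-window effects and a JSON summary under `run/`.

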