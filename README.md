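# asymmorph

Procrustes-based shape analysis and fluctuating-asymmetry (FA) statistics
for bilaterally symmetric organisms, built for studies that ask whether two
populations differ in *developmental instability* — the inability to buffer
development against random perturbation, which leaves its signature as
small, random left–right differences.

The package grew out of geometric-morphometric work on fossil spatangoid
echinoid tests (landmarks digitised from photogrammetric 3D models, pore
pairs counted per petal), but nothing in it is specific to echinoids: it
applies to any structure with **object symmetry** (a midline running
through the object itself) plus any countable bilateral trait.

## What it computes

**Shape route.** Landmark configurations \(X_i\) are superimposed by
generalized Procrustes analysis: each configuration is centred, rescaled to
unit centroid size \(CS = \sqrt{\sum_l \lVert x_l - \bar{x}\rVert^2}\), and
rotated to a least-squares fit of the sample consensus. Each observation is
then decomposed against its reflected-and-relabeled copy into a
**symmetric** component (the average of the aligned original and mirror)
and an **asymmetric** component (half their difference). A two-factor
mixed-model Procrustes ANOVA partitions the total Procrustes sum of squares
into

| effect            | measures                      | tested against    |
|-------------------|-------------------------------|-------------------|
| Individual        | symmetric individual variation| Individual × Side |
| Side              | directional asymmetry (DA)    | Individual × Side |
| Individual × Side | fluctuating asymmetry (FA)    | Measurement error |
| Measurement error | replicate digitising noise    | —                 |

with degrees of freedom scaled by the symmetric/asymmetric shape-subspace
dimensions (for *k* landmark pairs and *u* median landmarks in 2D,
\(s = a = 2k+u-2\)). PCA of the symmetric and asymmetric components
visualises where in the structure each kind of variation lives, and
Levene's test (Brown–Forsythe, median-centred) compares per-individual
scalar FA scores across populations.

**Meristic route.** For a bilateral count (right *R*, left *L* per
specimen), the pipeline screens signed differences \(d = R - L\) with an
iterated Grubbs outlier test, checks size dependence of \(|d|\) (Spearman),
normality (Shapiro–Wilk, to exclude antisymmetry) and DA (one-sample *t*),
then reports the indices

    FA1  = mean |R − L|            FA4a = 0.798 · √var(R − L)

(0.798 ≈ √(2/π), so both estimate the same quantity under ideal FA, but
FA4a is unbiased by DA). Count–size allometry is compared across
populations by an ANCOVA slope-homogeneity test on \((R+L)/2\) versus body
size, and ordered categorical traits are tabulated as percentages per
population.

**Synthetic data.** `synthetic_data` generates both data types with known
variance components (symmetric individual variation, DA field, FA,
digitising noise; allometric slope, DA shift, count FA), so every estimate
the pipeline produces has a recoverable ground truth.

## Worked example

```python
import asymmorph as am

# a replicated landmark sample on the built-in 21-landmark template
# (9 paired + 3 median landmarks), 33 individuals x 2 digitisations
T, smap, names = am.echinoid_oral_template()
sample = am.simulate_landmarks(am.LandmarkSimParams(n_individuals=33, replicates=2, seed=42))
table = am.procrustes_anova(sample, smap)
print(table.format_text())
```

```
Effect                          SS            MS     df        F           P
----------------------------------------------------------------------------
Individual              2.15129677    3.5383e-03    608     8.44     <0.0001
Side                    0.07017803    3.6936e-03     19     8.81     <0.0001
Individual x Side       0.25492467    4.1928e-04    608    22.52     <0.0001
Measurement error       0.02334812    1.8619e-05   1254
```

Every stratum is significant: individuals differ in symmetric shape, a
consistent DA displacement is present (Side), and the individual-by-side
interaction — the FA signal — stands far above digitising error.
Method-of-moments inversion of the mean squares recovers the generating
variance components (truth here: 9e-4, 1e-4, 9e-6):

```python
am.variance_components(table)
# {'sigma2_me': 9.31e-06, 'sigma2_fa': 1.00e-04, 'sigma2_ind': 8.80e-04}
```

The meristic side of the same study design:

```python
recs = am.simulate_meristic(am.MeristicSimParams(n=35, seed=42))
rep = am.fa_indices(recs)
# FA1=0.97  FA4a=0.88  mean(R-L)=0.69  t_P=0.0008  DA_dominates=False
```

The *t* test detects the injected DA shift, but |mean(R−L)| < FA4a, so
between-sides variation is still dominated by developmental instability —
the comparison that decides whether a trait's asymmetry is usable as an
instability proxy.

A command-line interface mirrors the workflows:

```sh
asymmorph simulate landmarks --n 33 --reps 2 --seed 42 --out data/
asymmorph anova --landmarks data/landmarks.csv --map data/symmetry_map.json
asymmorph simulate counts --n 35 --seed 42 --out data/
asymmorph meristic-fa --counts data/counts.csv --out results/
```

## Layout

- `asymmorph.landmark_io` — MeshLab PickPoints / CSV / TPS landmark readers,
  counts and states CSV, symmetry-map validation
- `asymmorph.procrustes_core` — centroid size, ordinary and generalized
  Procrustes superimposition
- `asymmorph.bilateral_symmetry` — reflection with relabeling, object-symmetry
  decomposition, individual FA scores
- `asymmorph.procrustes_anova` — mixed-model Procrustes ANOVA, variance
  components, Levene's test
- `asymmorph.shape_pca` — covariance PCA of shape coordinates and components
- `asymmorph.meristic_fa` — Grubbs screen, FA1/FA4a pipeline, allometry
  ANCOVA, categorical tabulation
- `asymmorph.synthetic_data` — ground-truth generators and the built-in
  echinoid-oral template
- `asymmorph.pipeline_cli` — end-to-end workflows and the `asymmorph` CLI

See `docs/methods.md` for the statistical model, numerical choices and
known limitations.
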