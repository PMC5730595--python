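# noisetissue

Stochastic gene-expression noise analysis for plant tissues, at the level a
confocal experiment actually produces: tables of nucleus positions, areas and
background-corrected mean grey values from fluorescent reporters.

The package answers four questions about expression variability in a tissue:

1. **How fast do expression levels fluctuate in single cells?** A
   photoconvertible reporter (green KikG irreversibly switched to red KikR by
   a 405 nm pulse) separates old from new protein; the auto-correlation of
   the regrowing green pool between 3 h and 6 h after conversion measures the
   memory of expression. The package simulates the underlying two-stage
   kinetic scheme exactly and provides the closed-form birth–death bound the
   measurement can be compared against.
2. **How much of the variability is intrinsic vs extrinsic?** Two spectrally
   distinct reporters (CFP/YFP) with identical promoters in every cell: the
   correlated part of their per-cell scatter is extrinsic (cell state), the
   uncorrelated part intrinsic (gene-local stochasticity).
3. **Is the extrinsic state coupled between neighbouring cells?** A
   covariance-normalized cross-reporter statistic with a randomization test
   and a distance-tier profile.
4. **Does cell division explain that coupling?** A mother→daughter
   inheritance model quantifies the sibling coupling left by copying
   molecular content, with and without inheriting the kinetic rates.

Because no public dataset of such nucleus tables exists, a first-class
synthetic-data module generates tables with exactly known ground truth
(lognormal extrinsic/intrinsic factors, a spatially correlated extrinsic
field, ploidy-like nuclear areas, duplicate technical measurements), so every
estimator in the package is validated against analytic targets.

## The model and the statistics

Expression follows the linear two-stage scheme
∅ →^{v0} mRNA →^{v1} protein with first-order decay d0 (mRNA) and d1
(protein). Extrinsic noise is a per-cell random translation rate v1 (gamma,
mean ⟨v1⟩, variance Var(v1)), constant over the observation window. The
reference parameter set is v0 = 2.25 h⁻¹, d0 = 1.125 h⁻¹, ⟨v1⟩ = 45 h⁻¹,
Var(v1) = 100 h⁻², d1 = 0.09 h⁻¹ (stationary mean ≈ 1000 molecules).

Key quantities:

- auto-correlation bound: the post-conversion green pool starts at zero, so
  its correlation between t1 and t2 is bounded below by the birth–death
  closed form c0 = e^{−d1(t2−t1)} √((1−e^{−d1 t1})/(1−e^{−d1 t2}));
- dual-reporter decomposition on mean-normalized channels c, y:
  η²_int = ⟨(c−y)²⟩/(2⟨c⟩⟨y⟩), η²_ext = (⟨cy⟩−⟨c⟩⟨y⟩)/(⟨c⟩⟨y⟩),
  reported ×100;
- neighbour coupling: r = Cov(C_i, Y_nn(i)) (both orderings pooled) divided
  by the within-cell covariance Cov(C_i, Y_i), the extrinsic-variance
  estimate, giving a measure in [−1, 1]; significance by joint permutation of
  (C, Y) pairs over positions;
- sibling coupling: the same statistic over daughter pairs that copied their
  mother's mRNA and protein at division.

## Worked example

```
$ python examples/autocorrelation_bound.py
birth-death lower bound c0(6h, 3h) = 0.575
Var(v1) =     0 h^-2:  r(3h, 6h) = 0.692 +- 0.004
Var(v1) =    25 h^-2:  r(3h, 6h) = 0.709 +- 0.004
Var(v1) =   100 h^-2:  r(3h, 6h) = 0.757 +- 0.003
```

The measured auto-correlation always sits above the 0.575 bound and grows
with the extrinsic variance: cell identity dominates the memory of
expression. With Var(v1) = 100 h⁻² the model predicts r in the range
0.6–1 for the 3 h/6 h interval, which is the regime real leaf measurements
fall into.

```
$ python examples/noise_decomposition.py
intrinsic noise  eta2_int =  11.84   (analytic  11.75)
extrinsic noise  eta2_ext =  39.35   (analytic  39.99)
```

On a 2000-cell synthetic tissue the decomposition recovers the generator's
analytic targets within a few percent; extrinsic noise dominates intrinsic,
as in real epidermis.

```
$ python examples/spatial_coupling.py
nearest-neighbour coupling r = 0.322 (generator target 0.34)
randomization test p = 0.0002  (floor = 0.0002)
tier 1: mean =  0.323 ... tier 5: mean =  0.034
```

The other examples (`decay_rate.py`, `inheritance.py`) estimate the reporter
degradation rate from a pulse-chase cohort (0.092 ± 0.002 h⁻¹ against a
generating rate of 0.09 h⁻¹) and the sibling coupling left by division
(≈ 0.16 for state-only inheritance at the calibrated 37.8 h mean division
age; 1.0 when rates are inherited too).

## Command line

Every stage also runs from the shell and writes CSV outputs plus a
reproducibility config and a QC sidecar:

```
noisetissue synth   --seed 1 --out results/synth
noisetissue noise   --input results/synth/tissue.csv --out results/noise
noisetissue spatial --seed 1 --out results/spatial
```

Stages: `synth`, `simulate`, `kik-decay`, `temporal`, `noise`, `spatial`,
`tiers`, `inherit`. Exit codes: 0 ok, 2 schema/usage error, 3 estimation
failure.

## Layout

- `src/noisetissue/model.py` — two-stage SSA, moments, auto-correlation,
  decay estimation
- `src/noisetissue/measurements.py` — table preprocessing and QC
- `src/noisetissue/noise.py` — intrinsic/extrinsic decomposition, group
  comparisons, area quartiles
- `src/noisetissue/spatial.py` — neighbour coupling, randomization test,
  distance tiers
- `src/noisetissue/inheritance.py` — division model and sibling coupling
- `src/noisetissue/synthetic.py` — ground-truth data generators
- `src/noisetissue/{io,config,pipeline,cli}.py` — CSV dialects, run
  configuration, stages, CLI
- `docs/methods.md` — modelling assumptions, estimator conventions, and
  known limitations
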