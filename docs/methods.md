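# Methods

## The expression model

All simulation rests on the linear two-stage scheme: transcription at rate
v0 (mRNA·h⁻¹), mRNA decay at d0·m, translation at v1·m, protein decay at
d1·p. Sample paths are generated with the exact direct-method SSA (numba
kernels in `_kernels.py`); there is no tau-leaping or diffusion
approximation anywhere. Photoconversion is bookkeeping, not chemistry: at
the conversion instant the whole green pool is relabelled red, conserving
total protein. Because the red pool is a pure death process after that, its
sample paths are drawn by sequential binomial thinning between output times
(survival e^{−d1·Δt}), which is distribution-exact at the sampled times and
cheaper than simulating its jumps.

The reference parameter set used throughout defaults and examples is
v0 = 2.25 h⁻¹, d0 = 1.125 h⁻¹, ⟨v1⟩ = 45 h⁻¹, Var(v1) = 100 h⁻²,
d1 = 0.09 h⁻¹: stationary mRNA mean 2, protein mean 1000, protein variance
mean·(1 + v1/(d0+d1)) ≈ 38 000.

**Extrinsic noise.** Cell-to-cell variability is a per-cell translation
rate, constant over the few-hour observation window (quasi-static: the
extrinsic correlation time is assumed long compared with the intrinsic
one). Only its mean and variance are physically constrained; the sampling
law is a gamma distribution matched to them. Gamma was chosen over a
truncated normal because it is supported on the positive axis — no
truncation bias, and at CV ≈ 0.22 the two are nearly indistinguishable.

**Initial conditions.** Stationary states are drawn as: mRNA exactly
Poisson(v0/d0) (the exact stationary marginal of a linear birth–death
process), protein relaxed from its deterministic stationary mean by a
10/d1-hour burn-in of exact simulation (protein is the slowest species; ten
lifetimes leave no measurable memory of the starting point). For the
post-conversion auto-correlation no burn-in is needed at all: green is zero
immediately after conversion and only the mRNA initial state matters, which
is available in closed form. This makes the 10⁵-trajectory ensemble exact
and fast.

## Moment oracles

First moments of the scheme are closed forms (with the t·e^{−dt} branch at
d0 = d1). Second moments satisfy a closed linear five-ODE system
(dVar_m/dt = v0 + d0·μ_m − 2d0·Var_m, etc.), integrated with tight
tolerances (rtol = atol = 1e-10); at t = ∞ the classic stationary forms are
returned directly. These moments are used purely as oracles to validate
the SSA ensembles, never as the analysis itself.

## Auto-correlation and its bound

The non-stationary auto-correlation of the regrowing green pool is
estimated by Monte Carlo: every trajectory draws its own translation rate,
starts from the pre-conversion stationary state, and the Pearson
correlation of green counts between t1 and t2 is taken across trajectories
(standard error (1−r²)/√n). The closed-form lower bound is the
auto-correlation of a constant-rate birth–death process started at zero,
c0(t2, t1) = e^{−d1(t2−t1)} √((1−e^{−d1 t1})/(1−e^{−d1 t2})), with the
continuous limit √(t1/t2) at d1 = 0. At the reference parameters
c0(6, 3) = 0.575, and the Monte-Carlo estimate rises from ≈ 0.69 (no
extrinsic noise) to ≈ 0.76 (Var(v1) = 100 h⁻²). The exact closed form of
the two-stage auto-correlation with extrinsic noise is not implemented;
the Monte-Carlo estimate plus the bound and the moment oracles cover every
use the package makes of it.

## Measurement tables and preprocessing

The input dialect is one row per nucleus/channel/time point/replicate with
8-bit mean grey values and a per-image, per-channel background. Technical
duplicates are averaged first (halving technical variance). Normalization
subtracts the background and divides by the per-image, per-channel mean,
pooling time points of a channel so that within-channel ratios — decay
between 3 h and 6 h — are preserved. Normalization is per image because
the downstream noise calculations are per image; a dataset-wide mean would
mix acquisition conditions. Background-subtracted values ≤ 0 are excluded
and counted, not clamped: clamping would bias the normalization mean.
Images whose two channel distributions differ in a two-sample
Kolmogorov–Smirnov test at α = 0.05 are dropped (a channel skew would
masquerade as intrinsic noise); α is configurable.

## Noise decomposition conventions

On mean-normalized channels the estimators are
η²_int = ⟨(c−y)²⟩/(2⟨c⟩⟨y⟩) and η²_ext = (⟨cy⟩−⟨c⟩⟨y⟩)/(⟨c⟩⟨y⟩), with
1/n moment sums; the total is their sum by construction and is also checked
against the independent formula (⟨(c²+y²)/2⟩−⟨c⟩⟨y⟩)/(⟨c⟩⟨y⟩). Values are
reported ×100 — the squared-CV scale on which tissue-level medians land in
the tens. Small-sample negative extrinsic estimates are reported as
computed. Group summaries are the median and mean of per-image values;
group differences use the Wilcoxon rank-sum test, exact by enumeration for
groups up to 12 without ties and tie-corrected normal otherwise (fully tied
data returns p = 1). Note the per-image estimates of lognormal-type data
are right-skewed, so medians across small images sit a little below the
analytic expectation; at ≥ 500 cells per image the gap is within a few
percent.

Nuclear-area quartiles (a proxy for ploidy via endoreduplication) are
formed at the empirical 25/50/75 percentiles with boundary ties assigned to
the lower bin — hence fully tied areas collapse into the first bin — and
quartiles with fewer than 5 cells reported as missing. Per-quartile
uncertainty comes from a bootstrap over cells (1000 resamples by default).

## Spatial coupling

Nearest neighbours are computed from nucleus centroids by a stable argsort
of the full Euclidean distance matrix: exact, and deterministic under
distance ties (lower cell index first); at the table sizes this analysis
meets (≤ a few thousand nuclei per image) the dense approach is both
simplest and fastest to verify. The coupling statistic pools
Cov(C_i, Y_nn(i)) and Cov(Y_i, C_nn(i)) and divides by the within-cell
covariance Cov(C_i, Y_i): since the covariance between stochastically
identical cells equals the extrinsic variance, the ratio is 1 for identical
neighbours, 0 for independent ones, and is immune to intrinsic-noise
attenuation (unlike a plain Pearson correlation of neighbour scatter).
Both covariances use the same 1/n convention so the normalization cancels.

Significance is a one-sided randomization test for positive coupling: the
(C, Y) pairs are permuted jointly across positions — preserving the
within-cell covariance, breaking only the arrangement — with add-one
smoothing, p = (1+#{r_perm ≥ r_obs})/(1+n_perm). The default 5000
permutations give a floor of 1/5001 ≈ 0.0002. The distance profile
assigns each of a cell's k = 39 nearest neighbours (default) to tier
⌈distance/width⌉ capped at 5, with width = the mean nearest-neighbour
distance (one cell diameter); per-tier means and SDs are over all
(cell, neighbour) pairs. Edge cells keep full neighbour lists (no edge
correction) — a small-image bias source, negligible at ≥ 1000 cells. Note
that with k = 39 on a roughly hexagonal tissue the fifth ring is only
corner-sampled; profile validations that need a well-sampled fifth tier use
a larger k (≈ 85).

## Division inheritance

A mother (two reporters sharing one drawn translation rate, stationary
state by burn-in) copies its exact mRNA and protein counts to both
daughters — content is copied, not binomially partitioned, because the
modelled observable is the concentration-like normalized intensity. The
daughters then evolve independently for a common age drawn from an
exponential division-age law. In `state_only` mode each daughter draws a
fresh translation rate; in `full` mode both keep the mother's rate forever.
Sibling coupling uses the same covariance-normalized cross-reporter
statistic as the spatial analysis.

For state-only inheritance the expected coupling has a closed form: at age
t a daughter retains a fraction e^{−d1 t} of the mother's extrinsic signal,
so with u = E[e^{−2d1 t}] and w = E[(1−e^{−d1 t})²] over the age law,
r = u/(u+w) (the mRNA stage enters only through its stationary mean and
cancels). The mean division age is not fixed by the expression model; the
package default inverts this closed form for the age at which state-only
siblings couple at 0.16, giving 37.8 h at d1 = 0.09 h⁻¹ — a plausible
cell-cycle time for young leaf epidermis — and reports the value used.

A structural property worth stating explicitly: under this estimator,
full-rate inheritance yields r = 1 identically, independent of the age law.
Conditional on the shared mother rate λ, each daughter reporter is
λ/d1 plus independent intrinsic terms, so the sibling cross-covariance and
the within-cell covariance are both Var(λ/d1). Full mode is therefore the
absolute ceiling of the inheritance contribution; any measured neighbour
coupling below 1 requires either rate turnover or dilution by non-sibling
neighbour pairs.

## Synthetic data

`generate_tissue` emulates a dual-reporter tissue snapshot: a jittered
hexagonal grid (default 20 µm spacing, 2 µm jitter); a per-cell lognormal
extrinsic factor shared by both channels (σ = 0.58 default → η²_ext = 40 on
the ×100 scale); independent per-channel lognormal intrinsic factors
(σ = 0.28 → η²_int ≈ 11.4); nuclear areas from a ploidy-class mixture
(2C–16C, area ∝ content^{2/3}); additive Gaussian technical noise per
duplicate (default SD 1 grey unit); signal scale 10 grey units over a
background of 10, validated so the 99.9th percentile stays below the 8-bit
ceiling. Spatial coupling is realized as a Gaussian field with correlation
ρ(d) = a·e^{−d/L} plus a white nugget, factored exactly through a Cholesky
decomposition (exactness over speed; fine to ~5000 cells). The `coupling`
parameter is the target covariance-normalized coupling at one grid spacing;
it is converted to the Gaussian ρ through the lognormal moment formula
r(d) = (e^{ρ(d)σ²}−1)/(e^{σ²}−1), and configurations whose implied field
weight a would exceed 1 are rejected with a message. The generator emits
the drawn latent factors and the analytic η² targets (including the
technical-noise contribution to the intrinsic component); the analytic
targets are exact only for a homogeneous extrinsic σ and are NaN when the
area-dependent extrinsic gain is switched on.

`generate_kik_timecourse` runs each cell's conversion experiment by exact
simulation and maps counts affinely to grey (0.09 grey/molecule over
background 10, putting a stationary pool of ~1000 molecules mid-range of
8 bit), with multiplicative lognormal technical noise (default σ = 0.1) per
duplicate. A non-degrading protein (d1 = 0) has no stationary pool; its
pre-conversion pool is the amount accumulated from zero over 20 mRNA
lifetimes.

What the generator does *not* emulate — and hence what passing tests do not
establish about real microscopy: segmentation errors, spectral bleed-through
between channels, depth-dependent attenuation, bleaching across time
points, cell growth or division during the time course, and non-lognormal
outliers. The generator's role is estimator validation against known
truth, not image realism.

## Problem sizes and numerical choices

Default validation sizes were chosen so each check resolves its question
with comfortable Monte-Carlo margins on a single CPU: 10⁴–10⁵ trajectories
for auto-correlation (SE ≤ 0.005), 2000-cell tissues for noise and spatial
recovery, 10⁴ sibling pairs for inheritance (SE ≈ 0.02), 50 cohorts of 400
nuclei for decay recovery, 1000 syntheses for permutation-test calibration.
Seeds are explicit everywhere; per-stage seeds derive from a master seed
and the stage name (SeedSequence splitting), so pipeline results are
independent of stage execution order, and identical config + seed gives
byte-identical CSV output. Covariance conventions are 1/n throughout the
coupling estimators; correlation on zero-variance input raises rather than
returning NaN; degenerate cases (d0 = d1, d = 0 limits, all-tied groups,
empty tiers, sub-threshold quartiles) take explicit branches.

## Known limitations

- The exact non-stationary two-stage auto-correlation with extrinsic noise
  is available only through Monte Carlo here; the closed-form bound plus
  moment oracles bracket it but do not replace it.
- The division-age law is exponential with a calibrated mean; real division
  ages are narrower than exponential, which would steepen the age decay of
  sibling coupling.
- Edge cells are not corrected for truncated neighbourhoods.
- The tier profile's fifth ring is under-sampled at the default k = 39.
- Normalization is per image and channel; datasets acquired under varying
  settings should not be pooled before normalization.
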