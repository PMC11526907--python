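# Methods

## Diffusion model

Pathology spread is modeled as linear diffusion on the structural
connectome. With `W[i,j]` the projection strength from region `i` to region
`j`, the anterograde Laplacian is `L_a = D_out − Wᵀ` (`D_out` = diagonal of
row sums) and the retrograde Laplacian is `L_r = D_in − W` (`D_in` =
diagonal of column sums). Both are unnormalized strength Laplacians: every
column sums to zero, so `exp(−cLt)` conserves total mass, and the two are
exact transposes of one another under `W ↔ Wᵀ` — both properties are tested.
Normalization (e.g. by region volume) is not applied by default; a
pre-scaling hook on the adjacency is the place to add it.

The propagator is the dense matrix exponential (`scipy.linalg.expm`).
Because `−L` has nonnegative off-diagonal entries, the propagator is
entrywise nonnegative up to round-off; entries are clipped at zero. A
fixed-step RK4 integration of `dx/dt = −cLx` serves as the independent
oracle in tests (agreement to 1e−6 max-abs at step 1e−3).

Observed regional pathology is the log₁₀ of the across-animal mean percent
area occupied, per region and timepoint. The regression

    y(t) = b₀(t) + b_a(t)·log₁₀ x_a(t) + b_r(t)·log₁₀ x_r(t) + ε(t)

is fit by OLS per timepoint over regions with nonzero observed pathology and
both predictors above a floor (default 1e−12). The floor realizes the
masking of effectively unreachable regions before taking logs: no
pseudo-counts, no −∞. Zero observed means are likewise excluded per
timepoint; no imputation anywhere.

The rate constants `(c_a, c_r)` are global across timepoints and minimize
the pooled SSE (equal weight per region×timepoint). Search is a log-spaced
grid over `[1e−3, 1e2]` per month (default 20×20, smaller grids for
resampling loops) followed by Nelder-Mead refinement in log₁₀ rate space
from the best cell; the objective is cheap but potentially multimodal, so
the grid guards against bad basins, and the whole procedure is deterministic
given the configuration. A per-timepoint-rates variant was considered and
rejected: the joint fit is identified by the differing time profiles of the
two predictors, while per-timepoint rates would let the intercept absorb
them. Single-direction modes (`anterograde`, `retrograde`) drop the other
predictor with its weight fixed at zero; `euclidean` mode reuses the same
machinery on a symmetric inverse-distance surrogate network (kernel
configurable: `1/d` default, `exp(−d/d₀)` optional) with a single rate and
predictor.

The propagator does not depend on the seed region — a seed's prediction is a
column of the cached matrix exponential. A shared `PropagatorCache` is what
makes the seed-null and cross-validation loops affordable.

## Validation

*Seed specificity.* Alternate seeds are drawn uniformly without replacement
from all non-seed regions (with replacement available when the connectome is
small), the model fully refit per seed, and per timepoint
`p = (1 + #{r_alt ≥ r_actual}) / (1 + n_alt)` — the add-one convention so p
is never 0; the raw proportion is stored alongside. On pure-noise data this
p is uniform to within KS distance 0.1 (checked by simulation); on planted
data the true seed wins at the timepoints that carry seed signal. Seed
specificity fades at late timepoints as diffusion approaches its quasi-steady
state — expected, and visible in the per-timepoint p values.

*Model comparison.* Cross-validation splits the **regions** (the units of
the regional vector y(t)) into random halves, fits on the training half, and
scores Pearson r of the predictions on the held-out half; 500 iterations by
default. Distributions are compared pairwise per timepoint with a two-sided
Wilcoxon rank-sum test. Mouse-level resampling is not implemented: the
regression consumes across-mouse means, so mouse splits would change the
target vector itself rather than hold out regions. The random split stream
is anchored to the lexicographic order of region labels, so results are
invariant to input file row order (to float round-off in the OLS).

## Vulnerability

Composite vulnerability is the mean residual per region over the 1, 3, 6
and 9 month timepoints; earlier timepoints are excluded because model
performance there is weaker and their residual patterns differ from the
stable late ones (the residual correlation matrix makes this visible, and
the synthetic planted-offset scenario reproduces the pattern). Positive
score = more pathology than connectivity predicts = more vulnerable.
Hemispheric twins of an anatomical region are averaged into one score by
default (residuals are conserved across hemispheres); only defined
residuals contribute — imputing zeros for masked regions would bias scores
toward resilience. Peak-timepoint summaries break ties toward the earliest
timepoint and flag all-zero series as `"none"`.

## Expression QC and association

Segment QC removes a segment when any metric falls strictly below its
threshold — trimmed 80, stitched 80, aligned 75, saturation 50, percent of
genes above LOQ 3 — with the first failing rule (in that order) recorded as
the reason. Gene QC computes a per-segment limit of quantification from
negative probes, `LOQ = geomean × geoSD²` (the multiplier is configurable),
calls a gene detected when its count exceeds the segment LOQ, and removes
genes detected in under 1% of segments. Outlier removal uses one-pass
two-sided Grubbs tests at α = 0.01 with the t-distribution critical value
`G_crit = ((n−1)/√n)·√(t²/(n−2+t²))`, `t` the upper `α/(2n)` quantile at
`n−2` df: *global* across genes on pooled (log₂ geometric-mean) values, and
*local* within a gene across its per-segment log₂ values. The inputs carry
one value per gene per segment, so the local test is necessarily the
across-segment form; probe-level within-segment testing would require probe
data the interface does not carry. An a-priori keep-list can exempt named
genes from QC.

Normalization: per gene, z-score → logistic → min-max to [0, 1] (the
"scaled sigmoid"; center and slope configurable), then the Blom rank
inverse-normal transform `Φ⁻¹((rank − 3/8)/(n + 1/4))` with average ranks
for ties. Both are rank functions, so the sigmoid is order-irrelevant after
the rank transform — it is applied anyway for fidelity to the stated
pipeline, with `skip_sigmoid` as the equivalent fast path (equality is
tested). Association is Pearson r of the transformed gene vector against
the transformed vulnerability, with the exact t-based two-sided p
(vectorized across genes; verified against `scipy.stats.pearsonr`), and
Benjamini-Hochberg FDR across genes. Constant gene vectors are flagged and
excluded from the FDR rather than given fake statistics.

Preranked enrichment is the classic weighted Kolmogorov-Smirnov running sum
(weight 1 on |score|) on the r-ranked gene list. The null is gene-label
permutation — the phenotype is a single regional vector, so phenotype
permutation is unavailable — with one null distribution per distinct set
size. NES divides ES by the mean |null ES| of matching sign; p is the
add-one same-sign exceedance; FDR is the standard preranked convention
(same-sign null NES exceedance rate over observed exceedance rate, clipped
to [0, 1]). On an exact magnitude tie between the positive and negative
running-sum extremes, the positive side wins (documented tie rule, matched
by the brute-force oracle in tests). The kinase filter intersects
significant positively-associated genes (q < 0.05) with a kinase list and a
differential-expression list, ordered by descending r.

## Synthetic data

The generator emulates the study's three inputs with known ground truth.
Connectomes are directed Bernoulli(density) graphs with log-normal weights;
weak repair edges guarantee that the designated seed candidate reaches every
region both along and against edge direction, so all four model variants
are informative. An optional hemispheric variant mirrors the block structure
with weak commissural edges. Pathology is generated from the model equation
at true parameters (defaults `c_a = 0.5`, `c_r = 2.0` per month, retrograde
weight dominant, intercept ramping with time) plus planted per-region
offsets δ, with per-mouse i.i.d. normal noise in log₁₀ space — matching the
model's additive error term — then back-transformed to percent area.
Expression plants genes correlated with the vulnerability profile at a set
population correlation among pure-noise nulls.

The default scenario mirrors the study design: 40 regions, timepoints
{0.1, 0.2, 0.3, 0.5, 1, 3, 6, 9} months, 5 mice per timepoint, noise sd 0.1
(log₁₀), offset sd 0.15, 50 planted genes (true r 0.6) among 1,000 nulls.
All randomness flows through numpy's PCG64 generator; a fixed seed
reproduces identical datasets on any platform.

What the synthetic data does *not* emulate: per-mouse random effects and
unequal section sampling, pathology clearance/saturation dynamics (the
generator is the linear model itself plus noise, so fits to it cannot
reveal model misspecification), spatial autocorrelation of expression, and
probe-level count structure. Passing tests therefore demonstrate that the
estimators recover what the model family can represent — not that the
linear model is the right description of any particular real dataset.

## Problem sizes and determinism

Heavy resampling loops (seed nulls, cross-validation) run with grid-only
optimization (no local refinement) and modest grids — the rate constants
enter the held-out comparisons only through fairly flat objectives, and
grid-only refits keep the null distributions exchangeable with the actual
fit. Calibration simulations use 30-region, 2-timepoint datasets; parameter
recovery uses the full 40-region, 8-timepoint design. The pipeline manifest
records input SHA-256 hashes, the full configuration, the package version
and derived sub-seeds; reruns with the same config are byte-identical (all
floats are written with round-trip precision and JSON keys are sorted).

## Known limitations

- The connectome is treated at whatever parcellation the input provides;
  no volume normalization or voxel-scale modeling.
- Observed pathology is averaged across mice before fitting; mouse-level
  variance does not propagate into fit uncertainty.
- Single-outlier (non-iterative) Grubbs tests can miss masked multiple
  outliers.
- The Euclidean surrogate's kernel choice (inverse distance) is a
  convention; conclusions about the surrogate's inferiority should be
  checked against the exponential kernel where it matters.
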