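# netspread

Network-diffusion modeling of seeded protein pathology spread, residual-based
regional vulnerability, and its association with regional gene expression.

## The problem

When misfolded α-synuclein is seeded at a single brain region (e.g. by
pre-formed fibril injection into the dorsal striatum of a mouse), pathology
spreads over months to hundreds of other regions. A large part of that
spatiotemporal pattern is explained by passive transport along axonal
projections; what is *not* explained — the per-region residual — measures
intrinsic regional vulnerability or resilience, and can be mined against
regional gene expression for candidate molecular drivers.

`netspread` implements that analysis chain as a tested, reusable library and
CLI for researchers working with regional pathology quantifications, a
structural connectome, and a gene×region expression atlas.

## The model

Let `W` be the weighted directed connectome, `W[i,j]` the projection strength
from region `i` to region `j`. Two graph Laplacians are derived:

    L_a = D_out − Wᵀ   (anterograde: mass moves along edge direction)
    L_r = D_in  − W    (retrograde: mass moves against it)

Pathology seeded as a one-hot vector `x₀` diffuses as `x(t) = exp(−c L t) x₀`
with a global rate constant `c` (per month) for each direction. Observed
regional pathology (log₁₀ of the across-animal mean percent area occupied) is
regressed per timepoint on both diffusion predictions:

    y(t) = b₀(t) + b_a(t)·log₁₀ x_a(t) + b_r(t)·log₁₀ x_r(t) + ε(t)

`(c_a, c_r)` are shared across timepoints and chosen to minimize the pooled
sum of squared residuals; `(b₀, b_a, b_r)` are per-timepoint OLS weights.
The model is validated two ways: by refitting with randomly relocated seeds
(seed-specificity null) and by cross-validated comparison against
anterograde-only, retrograde-only, and Euclidean-distance surrogate models.
Residuals `ε(t)`, averaged over the late timepoints (1, 3, 6, 9 months),
define composite regional vulnerability; per-gene Pearson correlations of
normalized expression with vulnerability (sigmoid scaling, rank
inverse-normal transform, BH-FDR) plus preranked gene-set enrichment and a
kinase/differential-expression filter close the chain.

## Worked example

Everything below runs on synthetic data with known ground truth — no
downloads needed:

```python
import numpy as np, netspread as ns

conn = ns.synth_connectome(40, density=0.25, rng_seed=7)
truth = ns.default_truth(conn, delta_sd=0.15, rng_seed=8)   # c_a=0.5, c_r=2.0
pathology = ns.synth_pathology(conn, truth, n_mice=5, noise_sd=0.1, rng_seed=9)
summary = ns.summarize_pathology(pathology, conn)

fit = ns.fit_model(summary, conn, truth.seed_region,
                   config=ns.FitConfig(grid_size=10))
print(f"c_a = {fit.params.c_a:.3f} (true 0.5), c_r = {fit.params.c_r:.3f} (true 2.0)")
print("r(t):", {f"{t:g}": round(fit.fits[t].r, 3) for t in fit.timepoints})

vmap = ns.composite_vulnerability(fit)
delta = np.array([truth.delta[r] for r in vmap.region_ids])
print(f"vulnerability vs planted offsets: "
      f"r = {ns.model_fit_statistic(vmap.score, delta):.3f}")
```

Output:

```
c_a = 0.609 (true 0.5), c_r = 2.566 (true 2.0)
r(t): {'0.1': 0.929, '0.2': 0.848, '0.3': 0.829, '0.5': 0.822, '1': 0.78, '3': 0.775, '6': 0.751, '9': 0.778}
vulnerability vs planted offsets: r = 0.992
```

The fitted rate constants land near the generating values despite
mouse-level log-normal noise, the per-timepoint fit correlations are the
model's train-fit quality, and the composite residual score recovers the
planted per-region vulnerability offsets almost exactly.

The same pipeline runs from the shell:

```sh
netspread simulate --rng 7 -o data/
netspread fit --connectome data/connectome.tsv --pathology data/pathology.csv \
    --seed R000 -o fit.json
netspread run --config pipeline.yaml -o out/     # full 6-stage pipeline
```

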