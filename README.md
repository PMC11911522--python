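# stsisal

Reference-free cell-type deconvolution for spot-based spatial
transcriptomics.

Spot-level platforms (Spatial Transcriptomics, 10x Visium and kin)
measure the summed expression of the several cells captured at each
location.  `stsisal` estimates, for every spot, the proportions of the
cell types mixed there — **without** an annotated single-cell
reference, which is often unavailable or mismatched.  It is aimed at
computational biologists who want per-spot composition, per-type
expression profiles and ranked marker genes directly from a genes × spots
count matrix.

## Method in brief

The data are modeled as a linear mixture `Y = M H` with non-negative
per-type profiles `M ∈ R^{L×K}` and column-stochastic proportions
`H ∈ R^{K×S}` (`1ᵀH = 1ᵀ`).  After scaling each gene to sum one across
spots, every gene becomes a convex combination of the row-normalized
proportion rows: the gene cloud lies in a (K−1)-simplex whose corners
are scaled proportion rows.  The pipeline

1. picks `K` by the small-sample-corrected AIC
   `L·S·ln(SSR_K/(L·S)) + 2p + 2p(p+1)/(L·S−p−1)`, `p = K(L+S)`, over
   seeded constrained factorizations;
2. iteratively selects cell-type-specific genes (coefficient-of-variation
   seed list, alternating-NNLS factorization, standardized one-vs-rest
   contrasts) until the reconstruction RMSE converges, keeping < 1,000
   genes;
3. identifies the simplex corners with SISAL — minimum-volume fitting of
   the inverse mixing matrix, `min −log|det Q| + τ·Σ hinge(QX)`, solved
   by successive linearization with an ADMM (split augmented Lagrangian)
   inner solver;
4. rescales the corners into proportions via the least-squares system
   `αᵀHp = 1ᵀ`, recovers `M` by rowwise non-negative least squares, and
   ranks markers by projected distance to each corner;
5. optionally maps the anonymous types onto a labeled reference panel by
   the mean of Pearson correlation and a naive-Bayes posterior.

Full details, parameter meanings and limitations: `docs/methods.md`.

## Worked example

```python
from stsisal import (make_reference, simulate_spots, stsisal_deconvolve,
                     proportion_metrics)

# a synthetic tissue: 4 cell types, 3 regions x 80 spots, 3,000 genes,
# 30% heterogeneous spots
ref = make_reference(K=4, L=3000, n_markers_per_type=40,
                     marker_fold=12.0, seed=7)
truth = simulate_spots(ref, n_regions=3, spots_per_region=80,
                       het_rate=0.3, seed=7)

result = stsisal_deconvolve(truth.Y, K="auto", seed=7)
print("selected K:", result.K)

report = proportion_metrics(result.H, truth.P_true)
print(f"PCC  {report.pcc:.3f}")
print(f"RMSE {report.rmse:.3f}")
print(f"MAE  {report.mae:.3f}")
print(f"JSD  {report.jsd:.3f}")
```

Output:

```
selected K: 4
PCC  0.977
RMSE 0.064
MAE  0.047
JSD  0.021
```

The AIC scan recovers the simulated number of cell types; the aligned
per-spot proportions correlate at 0.98 with the ground truth, with a
mean absolute proportion error under 5 points.  `result.M` holds the
per-type expression profiles over `result.selected_genes`, and
`result.markers` the 50 genes closest to each simplex corner — the
data-driven marker list for each anonymous type.

The same workflow is available from the shell:

```bash
stsisal simulate --k 4 --l 3000 --spots-per-region 80 --het-rate 0.3 \
        --n-markers 40 --seed 7 --out sim/
stsisal deconvolve --input sim/ --k auto --seed 7 --out run/
stsisal evaluate --est run/H.tsv --truth sim/P_true.tsv
stsisal smoke --seed 7        # end-to-end self-check
```

Every output directory contains a `config.json` that reproduces the run
exactly; a single `--seed` drives all randomness.

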