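# Methods

## The problem and the model

Spot-based spatial transcriptomics measures, at each capture location
("spot" or "pixel"), the summed expression of the handful of cells that
happen to sit there.  Resolving tissue architecture therefore requires
*deconvolution*: estimating, for every spot, the proportions of the cell
types that contribute to it.  `stsisal` does this without any annotated
single-cell reference.

The model is linear mixing.  With `L` genes, `S` spots and `K` cell
types, the observed matrix is

    Y = M H,      M ∈ R^{L×K} ≥ 0,   H ∈ R^{K×S} ≥ 0,   1ᵀH = 1ᵀ,

so every spot's expression is a convex combination of `K` per-type
profiles.  The assumption `K < S ≪ L` makes the problem a simplex
identification task: after scaling every gene to sum one across spots
(`ỹ_i = y_i / Σ_s y_is`), each gene becomes a convex combination of the
*row-normalized* proportion rows `h̃_k = h_k / Σ_s h_ks`.  The gene
cloud thus lives in a (K−1)-dimensional simplex whose corners are scaled
proportion rows, and finding the corners solves the deconvolution.  This
genes-as-points orientation is the only one in which the subsequent
rescaling (below) can produce a column-stochastic `H`.

## Pipeline stages

1. **Preprocessing** (`data`): missing values load as zero; genes are
   kept when their detection fraction (share of spots with a positive
   value) lies strictly between 5% and 100%; optional per-spot
   library-size log-normalization (`log1p` after scaling each spot to a
   fixed total, default 1e4).  Deconvolution itself runs on the
   filtered *non-log* values by default because the mixing model is
   linear in expression; a `use_lognorm` switch is provided.

2. **Number of cell types** (`model_selection`): for each candidate K a
   constrained factorization (below) yields the residual sum of squares
   `SSR_K = ||Y − M̂Ĥ||²_F`, scored by the small-sample-corrected AIC

       AIC(K) = L·S·ln(SSR_K/(L·S)) + 2p + 2p(p+1)/(L·S − p − 1),
       p = K(L+S).

   The selected K is the argmin; the whole curve is reported so a knee
   can be inspected.  Two numerical choices matter here and are the
   package's own:

   * the scan runs on a **depth-normalized, variance-stabilized** copy
     of the matrix.  A column-stochastic `H` cannot represent per-spot
     sequencing depth, and count noise grows with the mean
     (`var ≈ μ + φμ²`), so on unscaled counts the extra components of an
     over-sized model absorb depth and high-expression shot noise and
     the argmin drifts upward.  Spots are scaled to a common total and
     each gene is divided by `sqrt(μ + φμ²)` with a robust global
     `φ = median((var−μ)/μ²)`.  Both are diagonal rescalings and leave
     the mixing rank untouched.  (A log transform would also stabilize
     variance but makes the mixture nonlinear, which adds a spurious
     component of its own.)
   * the scan uses the full filtered gene complement, not a
     high-variance subset: the parameter penalty `2K(L+S)` only
     dominates the noise absorbed by an extra component when the
     gene/spot ratio is large.

3. **Cell-type-specific gene selection** (`features`): an initial list
   of the top coefficient-of-variation genes (sd/mean across spots,
   sample sd, ties by gene id) is refined iteratively: fit the
   factorization, regress every gene on the estimated proportion rows by
   non-negative least squares, score each type by the standardized
   one-vs-rest contrast (own-type coefficient minus the best other type,
   over the per-gene residual scale), keep the top `per_type` genes per
   type, and replace the working list with their union (interleaved
   rank-by-rank, capped at 999 genes).  The loop stops when successive
   reconstruction RMSEs differ by at most `rmse_tol` (default 1e-4).

4. **Inner factorization "deconf"** (`deconf`): alternating exact
   non-negative least squares.  `H` columns are solved with a heavily
   weighted sum-to-one row appended to the design, then clipped at zero
   and renormalized; `M` rows by plain NNLS.  Both updates use a batched
   active-set NNLS (all right-hand sides share one Gram factorization
   per passive-set pattern), verified against the reference
   single-column solver.  Iterations stop at `||Y−MH||_F ≤ tol_a`
   (default `1e-6·||Y||_F`), at 1,000 iterations, or when the residual
   stalls; a step that would increase the residual is discarded, so the
   recorded error trace is non-increasing.  `H` is initialized from
   flat Dirichlet draws under the run seed; `M` from one NNLS pass.
   All-zero proportion rows are re-seeded from Dirichlet noise to
   prevent rank collapse.  Factors are only identified up to a diagonal
   rescaling, so all internal comparisons use the reconstruction `MH`.

5. **Corner identification** (`sisal`): the row-normalized gene cloud is
   centered and projected onto its top K−1 right singular vectors; a
   constant-one coordinate is appended and the simplex is fit on the
   inverse mixing matrix `Q = M⁻¹` by minimizing

       −log|det Q| + τ · Σ hinge(Q X),    hinge(z) = max(−z, 0),

   subject to the barycentric coordinates of every point summing to one.
   The hinge makes the fit robust: a hard minimum-volume fit must
   enclose every point, the soft fit may leave outliers slightly
   outside.  Each outer step linearizes the log-determinant, solves the
   convex subproblem by ADMM (splitting `Z = QX`, hinge prox, rows of
   `Q` decoupled up to one shared equality multiplier), and backtracks
   until the true objective decreases, so the objective trace is
   non-increasing.  Initialization is a deterministic greedy
   farthest-point rule (vertex-component style); the proximal weight
   adapts to the accepted step sizes; vertices are canonically ordered
   by descending first projected coordinate.  Defaults: `τ = 1.0`,
   100 outer iterations, 40 ADMM iterations.  On noiseless data whose
   vertices are present, large `τ` reproduces the hard-constraint
   solution exactly; with the soft default the fitted simplex shrinks by
   O(1/(Nτ)), which is the intended noise robustness, not an error.

6. **Rescaling and outputs** (`pipeline`): SISAL's corners, lifted back
   to spot space, form the pseudo-proportion matrix `Hp` (K×S), equal to
   the row-normalized proportion rows up to one unknown scale per type.
   The least-squares solution of `αᵀHp = 1ᵀ` recovers the inverse
   scales, and `H = diag(α)·Hp` — negatives clipped (the clipped mass is
   reported) and columns renormalized — is the final proportion matrix.
   Per-type profiles `M` come from rowwise NNLS of the selected-gene
   matrix on `H`; marker genes are, per corner, the `G` genes (default
   50) closest to it in the projected space.

7. **Label assignment** (`pipeline.assign_labels`): when a labeled
   reference is available, estimated and reference profiles are depth
   normalized and `log1p` transformed on their shared genes (≥ 20
   required); each pair is scored by the mean of the Pearson correlation
   and a Gaussian naive-Bayes posterior (trained on reference cells, or
   on seeded pseudo-replicates of the mean profiles when only those are
   given).  Assignment is greedy from the global maximum, each reference
   used at most once; estimated types whose best remaining score falls
   below the threshold (default 0.3, deliberately conservative) stay
   "unassigned".  Because the naive-Bayes posterior is normalized over
   reference classes, it is near 1 for *some* class even for a
   nonsense profile; the Pearson half of the composite is what lets
   non-matching profiles fall below threshold.

8. **Evaluation** (`evaluate`): estimated types are matched to true
   types by the assignment maximizing summed per-row Pearson
   correlation; metrics are RMSE, MAE (`Σ|P̂−P|/(S·K)`), mean per-spot
   Jensen–Shannon divergence (natural log, per-spot bound ln 2; base 2
   available), and the Pearson correlation of the flattened aligned
   matrices (per-type correlations are also reported, since the matrix
   granularity is a convention).

## Synthetic data generator

`simulate` emulates how spot data arise from single cells without any
external download.  A synthetic reference gives each of K types a shared
log-normal baseline (median ≈ 0.3 counts per cell per gene, sigma 1.2 —
the sparse droplet regime, chosen so the detection filter is active)
plus `n_markers_per_type` exclusive marker genes elevated
`marker_fold`-fold in the owning type (≥ 3× guaranteed).  Spots are laid
out in regions, each with a distinct dominant type; per spot, the number
of co-occurring types is uniform on {2..min(6, K)}, proportions are flat
Dirichlet with the largest coordinate swapped onto the dominant type,
and a Bernoulli *heterogeneity rate* marks spots drawn without the
dominance constraint.  Expression is the sum of the sampled cells'
negative-binomial counts (per-cell dispersion θ = 2, 5–15 cells per
spot), realized as one Gamma–Poisson draw per (gene, type) with shape
`n_k·θ`; the recorded ground truth is the realized cell-count fraction,
because a spot is a finite sum of cells, not its expected mixture.

What the generator does *not* emulate: global (non-marker) expression
differences between types, spatial autocorrelation beyond region
membership, platform-specific dropout beyond NB sparsity, segmentation
artifacts, and ambient contamination.  Passing tests therefore show the
estimator recovers a linear cell mixture under realistic count noise,
not that it handles every artifact of real tissue.

## Study conditions used by the tests and the acceptance script

The recovery experiments use K_true = 4, 3 regions × 80 spots,
L = 3,000 genes, heterogeneity 0.3 (varied 0–0.6 for the robustness
comparison), with well-separated marker blocks concretized as 40
exclusive markers per type at 12-fold enrichment — the contrast range of
clearly distinct cell types (e.g. neuronal vs glial classes).  With
weaker contrast the corner of a type that is never regionally dominant
becomes unidentifiable from geometry alone; given the true marker genes
the corner identification itself remains accurate, which locates the
limit in the signal, not the solver.

One observed property deserves emphasis: under these conditions
accuracy *improves* as the heterogeneity rate rises.  With dominance
enforced everywhere, a never-dominant type's proportion never exceeds
roughly 0.4, so no spot approaches its simplex corner and the corner is
estimated from far-away data; heterogeneous spots occasionally let that
type dominate, sampling the corner directly.  Heterogeneity hurts
region-level interpretability but helps the geometry.

## Known limitations

* All reported proportions inherit the minimum-volume geometry: when no
  gene is pure for a type, the fitted corner sits inside the true one
  and proportions are compressed toward uniform before rescaling.
* The AIC scan's argmin is knife-edge when the gene/spot ratio is small
  (≲ 4); inspect the reported curve, not only `best_k`.
* `K` much larger than the number of distinct spatial niches (dominant
  regions plus heterogeneous spots) degrades corner sampling; this is a
  property of the data, not the solver.
* Runtime scales with `L'·S` per deconf iteration and with `K!` nowhere;
  ultra-high-resolution data (tens of thousands of spots) violate
  `S ≪ L` and are out of scope.
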