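# Methods

## The model

`stiffnet` treats a microbial co-occurrence network as a structural
framework and its weight matrix as a stiffness matrix. Let
`W ∈ R^{n×n}` be the symmetric weight matrix over `n` taxa (correlation
magnitudes on retained edges, unit diagonal), `A` the 0/1 adjacency,
and let the node attribute `x` be the per-taxon mean relative abundance
measured in two states: `x_a` in the reference cohort (A, e.g. healthy
controls) and `x_b` in the condition cohort (B). The observed
displacement is `d = x_b − x_a`. Five per-taxon parameters follow:

- **force** `f = W d` — the load consistent with the observed
  displacement under stiffness `W`;
- **displacement** `d = W⁻¹ f` — the deformation a known force causes;
  when `W` is singular or has condition number above `1e12`, the
  minimum-norm least-squares solution is used and the profile carries a
  `REGULARIZED` flag (never silent);
- **stiffness scale** `s_i = x_i / Σ_j w_ij y_j` — the diagonal
  rescaling with `diag(s)·W·y = x`; by default `y = x_a` and `x = x_b`,
  i.e. the scale that maps the reference state onto the condition state
  (direction configurable);
- **perturbation matrix** `G_ij = |(dx_i/x_i)/(dx_j/x_j)|` with the
  baseline (cohort A) value in the denominator and a pseudocount
  (default `1e-6`) replacing zero baselines;
- **impact** `I_i = Σ_j A_ij G_ji` — the aggregate response of `i`'s
  neighborhood to perturbing `i`;
- **stability** `S_i = 1 / Σ_j A_ij G_ij` — the inverse response of `i`
  to perturbations of its neighbors. Stability is often described as
  ranging from 0 to 1; we treat that as an empirical observation,
  report raw values, and log a note when `S_i > 1`.

Entries whose denominators vanish (zero relative change, isolated
nodes) are carried as NaN plus an explicit defined-mask and serialized
as `NA`; they are never coerced to zero.

## Network construction

Per-cohort networks are built by estimating a taxon-taxon correlation
matrix and thresholding on absolute value: an edge is kept iff
`|ρ_ij| ≥ min_abs_corr`; its weight is `|ρ_ij|` and its sign is kept
separately for the positive/negative (P/N) analyses. `W` stores
magnitudes with a unit diagonal so that it is usually diagonally
dominant and invertible — a hollow signed correlation matrix is
frequently singular, which would make the displacement solve
meaningless.

Estimators: Spearman (default; robust to compositional skew and
monotone distortions), Pearson, and a compositional log-ratio estimator
in the SparCC family. The compositional estimator infers basis
correlations from the log-ratio variance matrix
`T_ij = Var[log(x_i/x_j)]` under a sparsity assumption, iteratively
excluding the most strongly correlated pair (|ρ| > 0.1, up to
`sparcc_iterations` rounds, default 10) and re-solving the linear
system for basis variances. It is a single point estimate on
pseudocount-adjusted proportions — no Dirichlet resampling layer —
which is adequate for thresholded network construction where only sign
and rough magnitude matter. It is the default choice for
first-order-neighbor graphs.

The edge threshold default is `min_abs_corr = 0.3`. Network topology is
sensitive to this cutoff; it is always explicit in the configuration.
No per-edge permutation/bootstrap significance filtering is applied.

Single-correlation caveat: Pearson correlations between proportions are
distorted by the compositional closure when the taxa involved occupy a
large share of the community; the test suite demonstrates recovery of a
generating correlation for a *rare* pair, where closure is negligible.

## Permutation inference

Cohorts are pooled and the sample→cohort assignment permuted (cohort
sizes preserved). Every permutation rebuilds the reference-cohort
network *and* both attribute vectors, then recomputes the three tested
parameters (s, I, S); force and displacement are computed but not
permutation-tested. Pseudo-P values per taxon:
`P1 = #(R_i < R)/N_valid`, `P2 = #(R_i ≥ R)/N_valid` (ties count toward
P2; undefined null values are dropped from `N_valid`, never zeroed).
P-values of exactly 0 are reported as 0 to match the `N/B` convention;
the `(N+1)/(B+1)` smoothing is not applied by default.

Small `P2` means the real value is unusually *high* → the taxon is
labeled significantly increased; small `P1` → significantly decreased.
Benjamini–Hochberg FDR control (via statsmodels) is applied across taxa
separately within each direction and each parameter; a taxon can never
receive both labels. One published description of this scheme prints
the two FDR conditions identically and tabulates "significantly
increased" under the `R_i < R` column, which inverts the directional
reading; we follow the directional logic stated here and surface the
discrepancy rather than silently resolving it.

Default `n_perm = 1000`, `alpha = 0.05`. Each permutation draws from an
independent child seed of one root seed, so results are reproducible
and independent of execution order.

## Neighborhood analyses

Biomarkers are the significantly increased/decreased taxa (by default
the union over impact and stability; configurable). The FON
(first-order-neighbor) graph is the induced subgraph on biomarkers and
their direct neighbors in one cohort's network. Non-biomarker nodes
adjacent to both biomarker classes are "shared" neighbors (shared takes
precedence); biomarker nodes keep their class role regardless of
adjacency. The P/N table counts edge signs in four between-cluster edge
sets (increased-biomarkers↔their neighbors, increased↔shared,
decreased↔their neighbors, decreased↔shared); biomarker-internal edges
are not counted. A cell with positive edges and no negative edges
serializes as an en-dash ("–"); an empty edge set as `NA`.

"Allies" subgroups are connected components of the biomarker-induced
subgraph restricted to positive edges, of size ≥ 3 by default, ordered
by size then mean |weight|, each flagged when it is a complete positive
clique. The literature does not pin down a module definition; positive
connected components are the most transparent choice and the algorithm
is pluggable.

## Synthetic data generator

Two-cohort compositional abundances from a logistic-normal model:
multivariate normal log-abundances with a block-structured correlation
backbone (unit log-variance by default), exponentiated and renormalized
per sample. Cohort B can carry a planted relationship alteration of a
taxon subset: `sign_flip` negates the mutual correlations of planted
pairs, `decorrelate` zeroes them, `strengthen` raises their magnitude
to ≥ 0.9. Rewired (and any non-PSD backbone) matrices are repaired by
eigenvalue clipping with a logged warning; note that an equicorrelated
block of k taxa cannot be more negative than −1/(k−1), so a sign-flip
of a strong block is necessarily attenuated by the repair (for k = 5,
to about −0.25). Both cohorts share the log-scale mean vector (default:
a linear ramp from 0 to −2, giving realistically uneven abundances), so
a planted signal lives purely in the association structure. Zero
inflation is a post-hoc multiplicative Bernoulli mask (not mechanistic)
that never removes a sample's most abundant taxon, followed by
renormalization.

What the generator does *not* emulate: sequencing-depth variation,
taxon-specific dispersion, phylogenetic structure, and the
zero-generating process of real 16S data. Passing calibration and
recovery tests therefore demonstrates correctness of the inference
machinery under a known model, not performance on real gut-microbiome
data.

## Validation experiments and their problem sizes

Two protocols (in `stiffnet.experiments`) fix the study conditions:

- **Null calibration** — 20 replicates of exchangeable cohorts (40
  taxa, 30+30 samples, backbone blocks of 5 taxa at ρ = 0.7 and 0.4,
  10% zero inflation), default pipeline settings, 500 permutations.
  Pooled pseudo-P2 values should be near-uniform (KS distance < 0.1)
  and the FDR-label rate ≤ 0.07 at alpha 0.05.
- **Planted recovery** — 5 replicates with a single 5-taxon ρ = 0.7
  block sign-flipped in cohort B, marginal means equal, no zero
  inflation, 500 permutations. The edge threshold for this experiment
  is 0.45, near the Spearman critical value at p ≈ 0.01 for 30 samples,
  so that chance edges do not drown the four planted block edges per
  taxon.

A structural finding from the recovery protocol: when marginal means
are held equal, the relative changes `r_i` entering `G` are pure noise,
and `G = |r_i/r_j|` is a heavy-tailed noise ratio. Impact and stability
then differ between the real and permuted analyses only through the
adjacency (a log-scale shift of roughly ln 2), which is small against
the log-scale spread of the `G` sums — so impact and stability have
essentially no post-FDR power against pure relationship alterations.
The stiffness scale, whose denominator `Σ_j w_ij y_j` aggregates stable
mean abundances over weighted neighbors, detects the planted taxa
reliably (recovery ≈ 0.7 at FDR 0.05 with false-positive rate ≤ 0.05
under these conditions). Both recovery channels are reported by the
reproduction script. On real data, where abundance shifts accompany
relationship alterations, impact and stability are informative through
their dependence on the realized relative changes.

## Numerical choices and degenerate inputs

- Zero-variance taxa get zero correlations (flagged via log), not NaN.
- Condition-number cap `1e12` switches the displacement solve to
  minimum-norm least squares with a `REGULARIZED` flag.
- Denominator guards use a `1e-12` tolerance; pseudocount `1e-6` for
  zero baselines and log transforms.
- Sample columns renormalize to proportions on input; all-zero taxa are
  dropped with a warning; fewer than 3 surviving taxa or fewer than 3
  samples per cohort is an error.
- Ties in pseudo-P counting go to `P2` (the `≥` side), matching the
  counting definition.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; end-to-end runs with the same seed are
  byte-identical.

## Known limitations

- The correlation estimator and edge threshold of the original
  formulation are underdetermined; defaults here (Spearman, 0.3) are a
  documented choice, not a reproduction.
- The compositional estimator omits the Dirichlet resampling layer and
  bootstrap p-values of full SparCC implementations.
- BIOM-format input is not supported; abundance tables are TSV/CSV.
- Impact/stability significance has little power for pure covariance
  alterations with matched means (see above) — a property of the
  statistics, not of the implementation.
- P/N ratios are undefined for graphs with no negative edges; the
  sentinel values (`POSITIVE_ONLY`, `NO_EDGES`) propagate to tables as
  "–" and `NA` rather than infinities.
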