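# Methods

## Model

A bulk expression profile is modelled as a non-negative convex combination
of cell-type-specific profiles, m = B f with f on the probability simplex.
The package assumes inputs are already normalised (TPM for RNA-seq,
quantile-normalised intensities for arrays) and comparable across samples;
it performs no normalisation of its own. All computations are on the
linear expression scale — replicate averaging, specificity scoring and
condition numbers alike — because the mixing model itself is linear and
no log transform precedes the scoring.

## Stage 1: marker identification

Replicate columns of each purified cell type are averaged (arithmetic
mean) into the g × k reference X; genes expressed nowhere are dropped
first since they carry no specificity signal and would break the
row-mean normalisation.

**Specificity.** S'_i = (1/k) Σ_j (X_ij/X̄_i·) log2(X_ij/X̄_i·), with the
standard entropy convention 0·log2 0 := 0. This is a relative-entropy-like
divergence of the gene's across-type profile from uniformity: exactly 0
for a flat profile and log2 k for expression exclusive to one type. The
final score S_i = tanh(λ W_i)·S'_i multiplies in an expression weight
W_i = max(X_i·)/median_t max(X_t·); λ (default 0.1) sets how quickly the
tanh saturates, so lowly expressed genes are damped while for highly
expressed genes expression no longer interferes with specificity.

**Null and candidate test.** The null distribution of S is estimated from
`n_background` (default 100) random g × k matrices with entries i.i.d.
Uniform[min X, max X], each scored exactly like the real data (weights
from the random matrix itself, keeping the null self-contained and
exchangeable); all g·n_background scores are pooled. The null centre μ is
the mode of a Gaussian KDE (Silverman bandwidth, 512-point grid) — more
outlier-robust than the mean against the occasional highly specific
random row — and the scale σ is the maximum-likelihood normal scale with
the location fixed at μ. Each gene's one-sided z-test p-value
1 − Φ((S_i−μ)/σ) is BH-adjusted across all genes; adjusted p ≤ 0.01
(default) defines the candidates.

**Seeds and allocation.** π_i = log2[max(X_i·)/(Σ_j X_ij − max(X_i·)) ·
(k−1)] measures exclusivity; when the non-max sum is exactly 0 a
pseudo-expression ε = 1 (TPM-equivalent) replaces it, keeping π finite
and monotone in the maximal expression. Per cell type the candidate
peaking there with the highest π is the seed (π ties break on the
lexicographically smaller gene id). Mutual linearity with seed j is
ρ_ij = r²_ij · (1+e^(−π_i))^(−1) · sgn(r_ij), with r the Pearson
correlation computed across the replicate-level purified samples rather
than the k averaged columns (k points would make the correlation
degenerate for small panels). Genes with zero variance across samples get
ρ = 0. The empirical p-value ranks ρ_ij within the ascending-sorted
co-linearities ρ*_j of all non-candidate genes with the same seed:
P_ij = 1 − (first 1-based index with ρ*_j ≥ ρ_ij + 1)/(n+1); when no
background value reaches ρ_ij the candidate lies beyond the whole null
and P_ij = 0. Candidates are allocated to every type with P ≤ 0.05
(shared markers are expected for related lineages); candidates allocated
nowhere are discarded. The background set is per cell type, not pooled.

## Stage 2: signature and deconvolution

For each k in an inclusive sweep (default 50–200, step 1) the candidate
signature is the union over cell types of each type's top-k markers by
descending π (types with fewer markers contribute their full list; shared
markers enter once — signature rows are genes, duplication would be
meaningless). The candidate minimising the 2-norm condition number
κ = σ_max/σ_min wins; κ ties resolve to the smaller k (smaller signature
preferred), and rank-deficient candidates report κ = ∞ and are discarded.

Each bulk sample is regressed on B's columns with a Huber M-estimator
(tuning constant 1.345, the standard 95%-efficiency default) and no
intercept, since the mixing model has no baseline term. In weighted mode
the fit is iterated with per-gene weights w_g = 1/(B f̂)²_g, capped at
their 0.99 quantile to bound the influence of near-zero predictions,
until the fraction vector changes by less than 1e-4 (max 50 iterations).
Under multiplicative noise — the variance of m_g proportional to its
squared signal, the typical regime for expression data — this is
inverse-variance weighting, and it equalises the leverage of high- and
low-expression signature genes. Negative coefficients are clipped to 0
and the remainder renormalised to sum to 1; a sample whose coefficients
are all non-positive is reported as non-identifiable rather than
silently zeroed. Signature genes missing from the bulk matrix are dropped
with a warning when under 5% of the signature, an error otherwise.

Accuracy metrics flatten all sample × type entries: PCC, RMSD =
sqrt(mean (f−f̂)²) and mAD = mean |f−f̂|. RMSD ≥ mAD is not asserted
anywhere; it does not hold in general.

## Synthetic data generator

The generator emulates a purified-reference experiment with known ground
truth. Every gene has a log-normal baseline (median 100, log-sd 0.7,
mimicking the heavy-tailed spread of TPM values) shared across cell
types; exclusive markers are elevated by a constant fold change (default
10×) in one type, shared markers in two adjacent types; replicates
multiply the mean profile by log-normal noise (default log-sd 0.2). Bulk
samples are convex combinations of the collapsed purified profiles with
symmetric Dirichlet fractions plus multiplicative log-normal noise — the
same construction as benchmark mixture experiments that pool purified RNA
in known proportions — so at zero noise every mixture lies exactly in the
reference's column space. Default problem sizes (2000 genes, 5 types,
4 replicates per type, 60 exclusive markers per type, 10% shared
complement, 100 bulk mixtures at 5% noise) describe a modest blood-panel
experiment and keep a full pipeline run in seconds.

What the generator does *not* emulate: cross-subject variability of the
reference profiles, batch and platform effects between reference and
bulk, genes expressed by cell types absent from the panel, count-level
sampling noise, and markers whose fold change varies by gene. Passing
tests on this generator therefore demonstrate correctness of the
algorithms and their contracts, not performance on heterogeneous real
tissues, where reference mismatch usually dominates the error.

## Numerical and design choices

- All randomness flows through a single injectable seed
  (`numpy.random.default_rng`); fixed-seed runs are byte-reproducible
  end to end.
- Rank deficiency in κ is detected at the SVD tolerance
  σ_max · max(g,k) · eps rather than exact zero.
- BH and seed-selection ties break lexicographically on gene id so output
  ordering never depends on dictionary or sort instability.
- Duplicate gene ids at load keep the highest-mean row; rows with missing
  values are dropped; both are logged.
- The reported "twice-cutoff filtered p-value" variant for highly
  expressed genes mentioned in passing in the field is not implemented;
  its definition is unspecified.

## Limitations

- Estimation is reference-based only; no reference-free mode.
- The weighting scheme's cap quantile (0.99), tolerance (1e-4) and
  iteration limit (50) are fixed defaults declared in `bulkdecon.deconv`;
  the weighting is swappable by fitting with `weighted=False`.
- The empirical p-value resolution is bounded by the background size
  (1/(n+1)); very small marker panels give coarse p-values.
- With many closely correlated cell types the per-type allocation can
  legitimately assign one gene to several types; downstream consumers
  should not assume marker lists are disjoint.
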