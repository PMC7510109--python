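# bulkdecon

Marker-gene identification and cell-type deconvolution of bulk expression
profiles.

A bulk RNA-seq (or microarray) sample is a mixture of cell types, and its
expression profile **m** is well approximated as a convex combination of
the cell types' individual profiles, **m = B f**, where **B** is a
genes × cell-types *signature matrix* of marker genes and **f** the vector
of cell-type fractions.  `bulkdecon` takes a panel of purified
(FACS-sorted) expression profiles — TPM for RNA-seq, quantile-normalised
intensities for arrays — and estimates **f** for bulk samples in two
stages.

**Stage 1 — marker identification.** Replicates are averaged into a
g × k reference X. Each gene gets a specificity score

    S'_i = (1/k) Σ_j (X_ij / X̄_i·) · log2(X_ij / X̄_i·)

(0 for a flat profile, log2 k for a profile exclusive to one type), damped
by a tanh-transformed expression weight, S_i = tanh(λ·W_i)·S'_i with
W_i = max(X_i·)/median_t max(X_t·) and λ = 0.1, so weakly expressed genes
are disfavoured. Significance comes from a one-sided z-test against a
null of scores computed on uniformly random expression matrices (KDE-mode
centre, fixed-location normal scale); genes with BH-adjusted p ≤ 0.01 are
candidates. Each cell type's *seed marker* is the candidate peaking in
that type with the highest π-value, π_i = log2[max(X_i·)/(ΣX_ij −
max(X_i·)) · (k−1)]. Candidates are then allocated to cell types by
*mutual linearity* with the seeds, ρ_ij = r²_ij · logistic(π_i) ·
sgn(r_ij) (r = Pearson correlation across the purified replicates), using
a rank-based empirical p-value against the non-candidate background;
allocation requires p ≤ 0.05, and a gene may serve several related types.

**Stage 2 — signature and deconvolution.** The top-k markers per type
(k swept from 50 to 200, ranked by π) define candidate signature matrices;
the one with the lowest condition number κ = σ_max/σ_min is kept. Each
bulk sample is fitted by robust linear regression (Huber M-estimator, no
intercept), optionally with per-gene weights w_g = 1/(B f̂)²_g iterated to
convergence (w-RLM) to balance gene expression magnitudes; negative
coefficients are clipped to 0 and the rest renormalised to sum to 1.
Accuracy against known fractions is reported as PCC, RMSD and mAD.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/03_deconvolve_mixtures.py` simulates a 5-type purified
panel, identifies markers, builds the signature and deconvolves 100 noisy
mixtures:

```
first sample, true vs estimated fractions:
  true:      {'CT01': 0.0248, 'CT02': 0.0877, 'CT03': 0.315, 'CT04': 0.4952, 'CT05': 0.0773}
  estimated: {'CT01': 0.0255, 'CT02': 0.0875, 'CT03': 0.3188, 'CT04': 0.4907, 'CT05': 0.0775}
PCC  = 0.9999
RMSD = 0.0021
mAD  = 0.0015
```

PCC is the Pearson correlation between all true and estimated fraction
entries; RMSD/mAD are on the fraction scale, so 0.0021 means fractions
are typically off by about 0.2 percentage points at 5% measurement noise.

The same pipeline is available from the shell:

```bash
bulkdecon simulate --outdir run --seed 1
bulkdecon markers run/reference.tsv run/samplesheet.tsv --out run/markers.tsv --seed 1
bulkdecon signature run/markers.tsv run/reference.tsv run/samplesheet.tsv --out run/signature.tsv
bulkdecon deconv run/bulk.tsv run/signature.tsv --out run/fractions.tsv
bulkdecon evaluate run/fractions_true.tsv run/fractions.tsv
```

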