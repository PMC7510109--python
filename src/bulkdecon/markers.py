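"""Stage 1: marker-gene identification across cell types.

The stage has two parts.  First, every gene gets a *specificity score*

    S'_i = (1/k) * sum_j (X_ij / Xbar_i) * log2(X_ij / Xbar_i)

a relative-entropy-like quantity over its expression profile across the k
cell types (0 for a flat profile, log2(k) for a profile exclusive to one
type), damped by a tanh-transformed expression weight

    S_i = tanh(lambda * W_i) * S'_i,   W_i = max(X_i.) / median_t max(X_t.)

so that weakly expressed genes are unlikely to be called markers.
Significance is assessed with a one-sided z-test against a null of
specificity scores computed from uniformly random expression matrices,
whose centre is located by a kernel density estimate and whose scale is a
maximum-likelihood normal fit at that centre; genes with
Benjamini-Hochberg adjusted p <= alpha are candidates.

Second, candidates are *allocated* to cell types by mutual linearity.  For
each cell type the candidate with maximal expression in that type and the
highest pi-value

    pi_i = log2[ max(X_i.) / (sum_j X_ij - max(X_i.)) * (k - 1) ]

is the *seed marker*.  Each candidate's co-linearity with seed j is

    rho_ij = r_ij^2 * logistic(pi_i) * sgn(r_ij)

with r the Pearson correlation across the replicate-level purified
samples.  An empirical (Monte-Carlo style) p-value compares rho_ij against
the co-linearities of all non-candidate genes with the same seed, and a
candidate is allocated to every cell type where that p-value falls at or
below the allocation threshold.  A gene may legitimately be allocated to
several closely related cell types; candidates allocated nowhere are
discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "specificity_raw",
    "gene_weights",
    "specificity_final",
    "background_scores",
    "fit_background",
    "candidate_markers",
    "pi_values",
    "select_seeds",
    "mutual_linearity",
    "empirical_pvalues",
    "allocate",
    "identify_markers",
    "MarkerResult",
]

DEFAULT_LAMBDA = 0.1
DEFAULT_N_BACKGROUND = 100
DEFAULT_ALPHA_CANDIDATE = 0.01
DEFAULT_P_ALLOCATE = 0.05
DEFAULT_EPSILON = 1.0


def specificity_raw(X: pd.DataFrame) -> pd.Series:
    """Raw specificity score S' per gene; 0*log2(0) is taken as 0.

    Zero for a constant row, log2(k) for a row exclusive to one cell type.
    """
    values = np.asarray(X, dtype=float)
    row_mean = values.mean(axis=1)
    if (row_mean == 0).any():
        raise ValueError("all-zero expression rows must be removed before scoring")
    ratio = values / row_mean[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(ratio > 0, ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    s = terms.mean(axis=1)
    return pd.Series(s, index=X.index, name="s_raw")


def gene_weights(X: pd.DataFrame) -> pd.Series:
    """Expression weight W: row maximum over the median of all row maxima."""
    row_max = np.asarray(X, dtype=float).max(axis=1)
    med = np.median(row_max)
    if med == 0:
        raise ValueError("median of row maxima is zero; filter silent genes first")
    return pd.Series(row_max / med, index=X.index, name="weight")


def specificity_final(
    s_raw: pd.Series, weights: pd.Series, lam: float = DEFAULT_LAMBDA
) -> pd.Series:
    """Weighted specificity S = tanh(lambda * W) * S'."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    s = np.tanh(lam * np.asarray(weights, dtype=float)) * np.asarray(s_raw, dtype=float)
    return pd.Series(s, index=s_raw.index, name="s_final")


def _scores_for_matrix(values: np.ndarray, lam: float) -> np.ndarray:
    # S for a raw ndarray; rows that are all-zero cannot occur for draws
    # from Uniform[min, max] with max > 0.
    df = pd.DataFrame(values)
    return specificity_final(specificity_raw(df), gene_weights(df), lam).to_numpy()


def background_scores(
    X: pd.DataFrame,
    n_profiles: int = DEFAULT_N_BACKGROUND,
    seed: int | np.random.Generator | None = None,
    lam: float = DEFAULT_LAMBDA,
) -> np.ndarray:
    """Null specificity scores from uniformly random expression matrices.

    Each of the ``n_profiles`` replicates is a g x k matrix with entries
    i.i.d. Uniform[min(X), max(X)], scored with the same pipeline as the
    real data (weights computed from the random matrix itself); all
    ``n_profiles * g`` scores are pooled.
    """
    if n_profiles < 1:
        raise ValueError("n_profiles must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo = float(np.asarray(X).min())
    hi = float(np.asarray(X).max())
    g, k = X.shape
    if lo == hi:
        return np.zeros(n_profiles * g)
    pooled = [
        _scores_for_matrix(rng.uniform(lo, hi, size=(g, k)), lam)
        for _ in range(n_profiles)
    ]
    return np.concatenate(pooled)


def fit_background(scores: np.ndarray, grid_size: int = 512) -> tuple[float, float]:
    """Fit the null as a normal centred at the KDE mode of the scores.

    The centre ``mu`` is the arg-max of a Gaussian kernel density estimate
    (Silverman bandwidth) of the pooled null scores, which is robust to the
    heavy right tail of occasional highly specific random rows.  The scale
    ``sigma`` is the maximum-likelihood normal scale with the location held
    at ``mu``, i.e. the root mean squared deviation from ``mu``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 30:
        raise ValueError("need at least 30 null scores to fit the background")
    if np.ptp(scores) == 0:
        raise ValueError("degenerate null (zero variance); increase n_profiles")
    kde = stats.gaussian_kde(scores, bw_method="silverman")
    grid = np.linspace(scores.min(), scores.max(), grid_size)
    mu = float(grid[np.argmax(kde(grid))])
    sigma = float(np.sqrt(np.mean((scores - mu) ** 2)))
    return mu, sigma


def candidate_markers(
    s_final: pd.Series,
    mu: float,
    sigma: float,
    alpha: float = DEFAULT_ALPHA_CANDIDATE,
) -> pd.DataFrame:
    """One-sided z-test of each S_i against the null centre, BH-corrected.

    Tests H0: S_i <= mu against H1: S_i > mu with p = 1 - Phi((S_i-mu)/sigma).
    Returns a per-gene frame with ``p_value``, ``p_adjusted`` and a boolean
    ``candidate`` column (adjusted p <= alpha).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = (np.asarray(s_final, dtype=float) - mu) / sigma
    p = stats.norm.sf(z)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"p_value": p, "p_adjusted": p_adj, "candidate": p_adj <= alpha},
        index=s_final.index,
    )


def pi_values(X: pd.DataFrame, epsilon: float = DEFAULT_EPSILON) -> pd.Series:
    """pi-value: log2 ratio of the top cell type to the mean of the rest.

    For a gene expressed strictly exclusively in one type the remaining
    sum is 0; a pseudo-expression ``epsilon`` then replaces it so pi stays
    finite and monotone in the maximal expression.
    """
    if X.shape[1] < 2:
        raise ValueError("pi-values need at least two cell types")
    values = np.asarray(X, dtype=float)
    row_max = values.max(axis=1)
    rest = values.sum(axis=1) - row_max
    rest = np.where(rest == 0, epsilon, rest)
    k = X.shape[1]
    with np.errstate(divide="ignore"):
        pi = np.log2(row_max / rest * (k - 1))
    return pd.Series(pi, index=X.index, name="pi")


def select_seeds(
    candidates: pd.Index | list[str], pi: pd.Series, X: pd.DataFrame
) -> dict[str, str]:
    """Pick one seed marker per cell type.

    For cell type j the seed is the candidate whose arg-max expression
    column is j and whose pi-value is highest among those; pi ties break on
    the lexicographically smaller gene id.
    """
    candidates = pd.Index(candidates)
    home = X.loc[candidates].idxmax(axis=1)
    seeds: dict[str, str] = {}
    for cell_type in X.columns:
        eligible = candidates[home == cell_type]
        if len(eligible) == 0:
            raise ValueError(
                f"no candidate marker peaks in cell type {cell_type!r}; "
                "consider relaxing the candidate alpha"
            )
        sub = pi.loc[eligible]
        best = sub.index[np.lexsort((sub.index.to_numpy(), -sub.to_numpy()))[0]]
        seeds[cell_type] = str(best)
    return seeds


def _row_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of A with every row of B.

    Rows with zero variance get correlation 0 (logged by the caller).
    """
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    a_norm = np.linalg.norm(Ac, axis=1)
    b_norm = np.linalg.norm(Bc, axis=1)
    denom = np.outer(a_norm, b_norm)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (Ac @ Bc.T) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def mutual_linearity(
    expr: pd.DataFrame,
    genes: pd.Index | list[str],
    seeds: dict[str, str],
    pi: pd.Series,
) -> pd.DataFrame:
    """Co-linearity rho of each gene with every cell type's seed marker.

    rho_ij = r_ij^2 * logistic(pi_i) * sgn(r_ij), where r_ij is the
    Pearson correlation between gene i and the seed of type j across the
    replicate-level purified samples (not the averaged profile, which
    would leave only k points).
    """
    if expr.shape[1] < 3:
        raise ValueError("mutual linearity needs at least three purified samples")
    genes = pd.Index(genes)
    cell_types = list(seeds)
    A = expr.loc[genes].to_numpy(dtype=float)
    B = expr.loc[[seeds[ct] for ct in cell_types]].to_numpy(dtype=float)
    n_flat = int((A.std(axis=1) == 0).sum())
    if n_flat:
        logger.warning("%d genes have zero variance across samples; rho set to 0", n_flat)
    r = _row_correlations(A, B)
    damp = 1.0 / (1.0 + np.exp(-pi.loc[genes].to_numpy(dtype=float)))
    rho = r**2 * damp[:, None] * np.sign(r)
    return pd.DataFrame(rho, index=genes, columns=cell_types)


def empirical_pvalues(rho: pd.DataFrame, rho_background: pd.DataFrame) -> pd.DataFrame:
    """Empirical p-value of each candidate rho against the background rhos.

    Per cell type the background co-linearities are sorted ascending and

        P_ij = 1 - (first 1-based index with rho*_j >= rho_ij + 1) / (n + 1)

    When no background value reaches rho_ij the candidate is beyond the
    whole null and P_ij = 0 (the most significant outcome).
    """
    if rho_background.shape[0] == 0:
        raise ValueError("empty background gene set")
    out = np.empty(rho.shape)
    for j, cell_type in enumerate(rho.columns):
        bg = np.sort(rho_background[cell_type].to_numpy(dtype=float))
        n = bg.size
        idx = np.searchsorted(bg, rho[cell_type].to_numpy(dtype=float), side="left")
        p = 1.0 - (idx + 2) / (n + 1)
        out[:, j] = np.where(idx >= n, 0.0, p)
    return pd.DataFrame(out, index=rho.index, columns=rho.columns)


def allocate(P: pd.DataFrame, threshold: float = DEFAULT_P_ALLOCATE) -> dict[str, list[str]]:
    """Allocate each candidate to every cell type with P_ij <= threshold.

    Genes significant for several types are shared markers and appear in
    each of those lists; genes significant nowhere are dropped.
    """
    allocations: dict[str, list[str]] = {}
    for cell_type in P.columns:
        hits = P.index[P[cell_type] <= threshold]
        allocations[str(cell_type)] = [str(g) for g in hits]
    return allocations


@dataclass
class MarkerResult:
    """Full stage-1 output."""

    specificity: pd.DataFrame  # per gene: s_raw, weight, s_final, p_value, p_adjusted, pi
    null_mu: float
    null_sigma: float
    seeds: dict[str, str]
    rho: pd.DataFrame  # candidates x cell types
    p_empirical: pd.DataFrame  # candidates x cell types
    allocations: dict[str, list[str]] = field(default_factory=dict)

    @property
    def markers(self) -> pd.Index:
        """All allocated marker genes (union over cell types)."""
        seen: list[str] = []
        for genes in self.allocations.values():
            seen.extend(genes)
        return pd.Index(sorted(set(seen)))

    def table(self) -> pd.DataFrame:
        """Long-format marker table, one row per (gene, allocated type)."""
        rows = []
        for cell_type in sorted(self.allocations):
            for gene in sorted(self.allocations[cell_type]):
                spec = self.specificity.loc[gene]
                rows.append(
                    {
                        "gene": gene,
                        "cell_type": cell_type,
                        "s_raw": spec["s_raw"],
                        "weight": spec["weight"],
                        "s_final": spec["s_final"],
                        "p_adjusted": spec["p_adjusted"],
                        "pi": spec["pi"],
                        "rho": self.rho.loc[gene, cell_type],
                        "p_empirical": self.p_empirical.loc[gene, cell_type],
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "gene",
                "cell_type",
                "s_raw",
                "weight",
                "s_final",
                "p_adjusted",
                "pi",
                "rho",
                "p_empirical",
            ],
        )


def identify_markers(
    expr: pd.DataFrame,
    X: pd.DataFrame,
    *,
    lam: float = DEFAULT_LAMBDA,
    n_background: int = DEFAULT_N_BACKGROUND,
    alpha_candidate: float = DEFAULT_ALPHA_CANDIDATE,
    p_allocate: float = DEFAULT_P_ALLOCATE,
    epsilon: float = DEFAULT_EPSILON,
    seed: int | np.random.Generator | None = None,
) -> MarkerResult:
    """Run the whole marker-identification stage.

    Parameters
    ----------
    expr
        Replicate-level purified expression (genes x samples), used for the
        mutual-linearity correlations.
    X
        Collapsed reference profile (genes x cell types) on the same gene
        index as ``expr``.
    seed
        Seed (or Generator) for the random background profiles; fixing it
        makes the whole stage deterministic.
    """
    s_raw = specificity_raw(X)
    weights = gene_weights(X)
    s_final = specificity_final(s_raw, weights, lam)
    null = background_scores(X, n_profiles=n_background, seed=seed, lam=lam)
    mu, sigma = fit_background(null)
    tests = candidate_markers(s_final, mu, sigma, alpha_candidate)
    pi = pi_values(X, epsilon)

    specificity = pd.DataFrame(
        {
            "s_raw": s_raw,
            "weight": weights,
            "s_final": s_final,
            "p_value": tests["p_value"],
            "p_adjusted": tests["p_adjusted"],
            "candidate": tests["candidate"],
            "pi": pi,
        }
    )

    candidates = specificity.index[specificity["candidate"]]
    if len(candidates) == 0:
        raise ValueError("no candidate markers at the requested alpha")
    background_genes = specificity.index.difference(candidates)
    seeds = select_seeds(candidates, pi, X)

    rho = mutual_linearity(expr, candidates, seeds, pi)
    rho_bg = mutual_linearity(expr, background_genes, seeds, pi)
    P = empirical_pvalues(rho, rho_bg)
    allocations = allocate(P, p_allocate)

    n_markers = sum(len(v) for v in allocations.values())
    logger.info(
        "stage 1: %d candidates, %d allocations across %d cell types",
        len(candidates),
        n_markers,
        len(allocations),
    )
    return MarkerResult(
        specificity=specificity,
        null_mu=mu,
        null_sigma=sigma,
        seeds=seeds,
        rho=rho,
        p_empirical=P,
        allocations=allocations,
    )
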