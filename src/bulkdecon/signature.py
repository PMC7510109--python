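"""Signature-matrix construction by condition-number minimisation.

The signature matrix B is the genes x cell-types submatrix of the
reference profile restricted to a subset of the allocated markers.  For
each k in an inclusive sweep range, the top-k markers of every cell type
(sorted by descending pi-value) are pooled, deduplicated, and the
condition number kappa(B) = sigma_max / sigma_min of the resulting matrix
is recorded; the candidate with the lowest kappa wins.  A low condition
number means the linear system solved during deconvolution is well
conditioned, so fraction estimates are stable against noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["condition_number", "build_signature", "SignatureMatrix"]

DEFAULT_K_RANGE = (50, 200)


def condition_number(B: pd.DataFrame | np.ndarray) -> float:
    """2-norm condition number: ratio of largest to smallest singular value.

    Returns ``inf`` for a rank-deficient matrix.
    """
    values = np.asarray(B, dtype=float)
    s = np.linalg.svd(values, compute_uv=False)
    tol = s[0] * max(values.shape) * np.finfo(float).eps
    if s[-1] <= tol:
        return float("inf")
    return float(s[0] / s[-1])


@dataclass
class SignatureMatrix:
    """Chosen signature with its sweep diagnostics."""

    values: pd.DataFrame  # genes x cell types
    chosen_k: int
    condition_number: float
    per_k_kappa: dict[int, float]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns


def _ranked_markers(
    allocations: dict[str, list[str]], pi: pd.Series
) -> dict[str, list[str]]:
    """Sort each cell type's markers by descending pi (gene id breaks ties)."""
    ranked = {}
    for cell_type, genes in allocations.items():
        sub = pi.loc[list(genes)]
        order = np.lexsort((sub.index.to_numpy(), -sub.to_numpy()))
        ranked[cell_type] = [str(sub.index[i]) for i in order]
    return ranked


def build_signature(
    allocations: dict[str, list[str]],
    X: pd.DataFrame,
    pi: pd.Series,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
) -> SignatureMatrix:
    """Sweep top-k markers per cell type and keep the best-conditioned B.

    For every k in the inclusive range the candidate gene set is the union
    over cell types of each type's top-k markers by pi-value (a type with
    fewer than k markers contributes its full list; shared markers enter
    once).  Ties in kappa across the sweep resolve to the smaller k.
    """
    lo, hi = int(k_range[0]), int(k_range[1])
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid k range {k_range}")
    empty = [ct for ct, genes in allocations.items() if len(genes) == 0]
    if empty:
        raise ValueError(f"cell types without any marker: {empty}")
    short = {ct: len(g) for ct, g in allocations.items() if len(g) < lo}
    if short:
        logger.info("cell types with fewer than %d markers use their full list: %s", lo, short)

    ranked = _ranked_markers(allocations, pi)
    per_k_kappa: dict[int, float] = {}
    best_k, best_kappa, best_genes = None, np.inf, None
    for k in range(lo, hi + 1):
        genes: list[str] = []
        seen: set[str] = set()
        for cell_type in sorted(ranked):
            for gene in ranked[cell_type][:k]:
                if gene not in seen:
                    seen.add(gene)
                    genes.append(gene)
        kappa = condition_number(X.loc[genes])
        per_k_kappa[k] = kappa
        if kappa < best_kappa:
            best_k, best_kappa, best_genes = k, kappa, genes
    if best_genes is None:
        raise ValueError("every candidate signature was rank deficient")
    B = X.loc[best_genes]
    logger.info("signature: k=%d, %d genes, kappa=%.3f", best_k, len(best_genes), best_kappa)
    return SignatureMatrix(
        values=B,
        chosen_k=int(best_k),
        condition_number=float(best_kappa),
        per_k_kappa=per_k_kappa,
    )
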