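"""Stage 2: cell-type fraction estimation by weighted robust regression.

A bulk profile m is modelled as a convex combination of the cell-type
signature columns, m = B f.  Each bulk sample is fitted independently with
a robust linear model (Huber M-estimator, no intercept) on the signature
genes; optionally a per-gene weighting loop rebalances the contribution of
genes across the expression range (w_g = 1 / (B fhat)_g^2, capped at a
high quantile, iterated to convergence), which is the inverse-variance
weighting when noise is multiplicative.  Negative coefficients are clipped
to zero and the remainder renormalised to sum to one, so every estimated
fraction vector lies on the probability simplex.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["deconvolve", "evaluate", "DeconvMetrics"]

HUBER_T = 1.345
WEIGHT_CAP_QUANTILE = 0.99
WEIGHT_TOL = 1e-4
WEIGHT_MAX_ITER = 50


@dataclass
class DeconvMetrics:
    """Agreement between true and estimated fractions, flattened over all
    sample x cell-type entries."""

    pcc: float
    rmsd: float
    mad: float


def _clip_normalise(coef: np.ndarray) -> np.ndarray:
    coef = np.clip(coef, 0.0, None)
    total = coef.sum()
    if total <= 0:
        raise ValueError("all regression coefficients non-positive; sample not identifiable")
    return coef / total


def _fit_rlm(y: np.ndarray, B: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.RLM(y, B, M=sm.robust.norms.HuberT(t=HUBER_T))
        return np.asarray(model.fit().params, dtype=float)


def _fit_sample(y: np.ndarray, B: np.ndarray, weighted: bool) -> np.ndarray:
    coef = _fit_rlm(y, B)
    f = _clip_normalise(coef)
    if not weighted:
        return f
    for _ in range(WEIGHT_MAX_ITER):
        pred = B @ f
        pred = np.where(pred > 0, pred, np.nan)
        w = 1.0 / pred**2
        w = np.where(np.isnan(w), np.nanmax(w), w)
        w = np.minimum(w, np.nanquantile(w, WEIGHT_CAP_QUANTILE))
        sqrt_w = np.sqrt(w)
        coef = _fit_rlm(y * sqrt_w, B * sqrt_w[:, None])
        f_new = _clip_normalise(coef)
        if np.max(np.abs(f_new - f)) < WEIGHT_TOL:
            return f_new
        f = f_new
    return f


def deconvolve(
    bulk: pd.DataFrame,
    B: pd.DataFrame,
    weighted: bool = True,
) -> pd.DataFrame:
    """Estimate cell-type fractions for every bulk sample.

    Parameters
    ----------
    bulk
        Genes x samples bulk expression; gene ids are intersected with the
        signature's genes (signature genes missing from the bulk are
        dropped with a warning when they are under 5% of the signature,
        otherwise an error is raised).
    B
        Signature matrix, genes x cell types (a
        :class:`~bulkdecon.signature.SignatureMatrix`'s ``values``).
    weighted
        Apply the per-gene weighting loop (w-RLM) instead of the plain
        robust fit.

    Returns
    -------
    pandas.DataFrame
        Samples x cell types; rows are non-negative and sum to one.
    """
    if hasattr(B, "values") and not isinstance(B, pd.DataFrame):  # SignatureMatrix
        B = B.values
    if (np.asarray(bulk) < 0).any():
        raise ValueError("bulk expression must be non-negative")
    common = B.index.intersection(bulk.index)
    missing = B.shape[0] - len(common)
    if missing:
        if missing / B.shape[0] >= 0.05:
            raise ValueError(
                f"{missing}/{B.shape[0]} signature genes absent from the bulk matrix"
            )
        logger.warning("dropping %d signature genes absent from the bulk matrix", missing)
    k = B.shape[1]
    if len(common) < k:
        raise ValueError(f"need at least {k} shared genes, found {len(common)}")
    design = B.loc[common].to_numpy(dtype=float)
    data = bulk.loc[common].to_numpy(dtype=float)

    fractions = np.empty((bulk.shape[1], k))
    for s in range(bulk.shape[1]):
        fractions[s] = _fit_sample(data[:, s], design, weighted)
    return pd.DataFrame(fractions, index=bulk.columns, columns=B.columns)


def evaluate(f_true: pd.DataFrame, f_hat: pd.DataFrame) -> DeconvMetrics:
    """PCC, RMSD and mAD between true and estimated fraction matrices."""
    if list(f_true.index) != list(f_hat.index) or list(f_true.columns) != list(
        f_hat.columns
    ):
        raise ValueError("fraction matrices have mismatching sample or cell-type labels")
    a = f_true.to_numpy(dtype=float).ravel()
    b = f_hat.to_numpy(dtype=float).ravel()
    diff = a - b
    rmsd = float(np.sqrt(np.mean(diff**2)))
    mad = float(np.mean(np.abs(diff)))
    pcc = float(np.corrcoef(a, b)[0, 1])
    return DeconvMetrics(pcc=pcc, rmsd=rmsd, mad=mad)
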