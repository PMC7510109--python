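"""Synthetic purified references and bulk mixtures with known ground truth.

The generator emulates the structure of a FACS-purified reference
experiment: every gene has a log-normal baseline abundance shared across
cell types (mimicking the heavy-tailed spread of TPM values), planted
markers are elevated by a constant fold change in their home cell type
(or in two related cell types for shared markers), and each replicate
sample is the cell type's mean profile perturbed by multiplicative
log-normal noise.  Bulk samples are convex combinations of the purified
profiles with Dirichlet-distributed true fractions, again with
multiplicative log-normal noise, so at zero noise every mixture lies
exactly in the column space of the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "simulate_reference", "simulate_bulk"]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic reference and mixtures.

    Defaults describe a modest blood-panel-sized experiment: 2000 genes,
    five cell types with four purified replicates each, 60 exclusive
    markers per type at 10-fold elevation, plus a 10% complement of
    markers shared between adjacent cell-type pairs, with 20%
    multiplicative noise (log scale) on replicates.
    """

    n_genes: int = 2000
    k_cell_types: int = 5
    markers_per_type: int = 60
    shared_marker_fraction: float = 0.1
    n_replicates_per_type: int = 4
    marker_fold_change: float = 10.0
    noise_sd: float = 0.2
    n_bulk: int = 100
    dirichlet_alpha: float = 1.0
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sd: float = 0.7
    seed: int | None = None

    def validate(self) -> None:
        n_shared = self.n_shared_per_pair * max(self.k_cell_types - 1, 0)
        if self.markers_per_type * self.k_cell_types + n_shared > self.n_genes:
            raise ValueError("more planted markers than genes")
        if self.k_cell_types < 2:
            raise ValueError("need at least two cell types")
        if self.marker_fold_change <= 1:
            raise ValueError("marker fold change must exceed 1")
        for name in ("n_genes", "markers_per_type", "n_replicates_per_type", "n_bulk"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or not 0 <= self.shared_marker_fraction <= 1:
            raise ValueError("invalid noise or shared-marker settings")

    @property
    def n_shared_per_pair(self) -> int:
        return int(round(self.shared_marker_fraction * self.markers_per_type))

    @property
    def cell_types(self) -> list[str]:
        return [f"CT{j + 1:02d}" for j in range(self.k_cell_types)]


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _mean_profiles(cfg: SimulationConfig, rng: np.random.Generator):
    """Noise-free genes x cell-types mean matrix plus the planted truth map."""
    baselines = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    means = np.tile(baselines[:, None], (1, cfg.k_cell_types))
    genes = _gene_ids(cfg.n_genes)
    truth_rows: list[tuple[str, str]] = []

    cursor = 0
    for j in range(cfg.k_cell_types):
        for _ in range(cfg.markers_per_type):
            means[cursor, j] *= cfg.marker_fold_change
            truth_rows.append((genes[cursor], cfg.cell_types[j]))
            cursor += 1
    # shared markers: elevated in two adjacent (hence correlated) cell types
    for j in range(cfg.k_cell_types - 1):
        for _ in range(cfg.n_shared_per_pair):
            means[cursor, j] *= cfg.marker_fold_change
            means[cursor, j + 1] *= cfg.marker_fold_change
            truth_rows.append((genes[cursor], cfg.cell_types[j]))
            truth_rows.append((genes[cursor], cfg.cell_types[j + 1]))
            cursor += 1

    truth = pd.DataFrame(truth_rows, columns=["gene", "cell_type"])
    return pd.DataFrame(means, index=genes, columns=cfg.cell_types), truth


def simulate_reference(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate replicate-level purified profiles with planted markers.

    Returns
    -------
    expr : pandas.DataFrame
        Genes x samples replicate-level expression.
    sheet : pandas.Series
        Sample id -> cell-type label.
    truth : pandas.DataFrame
        Long-format map of planted markers (columns ``gene``,
        ``cell_type``); shared markers appear once per home type.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    means, truth = _mean_profiles(cfg, rng)

    sample_ids, labels, columns = [], [], []
    for j, cell_type in enumerate(cfg.cell_types):
        profile = means.iloc[:, j].to_numpy()
        for r in range(cfg.n_replicates_per_type):
            noise = (
                rng.lognormal(0.0, cfg.noise_sd, cfg.n_genes)
                if cfg.noise_sd > 0
                else np.ones(cfg.n_genes)
            )
            columns.append(profile * noise)
            sample_ids.append(f"{cell_type}_r{r + 1}")
            labels.append(cell_type)
    expr = pd.DataFrame(
        np.column_stack(columns), index=means.index, columns=sample_ids
    )
    sheet = pd.Series(labels, index=sample_ids)
    return expr, sheet, truth


def simulate_bulk(
    X: pd.DataFrame,
    n_bulk: int = 100,
    dirichlet_alpha: float = 1.0,
    noise_sd: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mix reference profiles into bulk samples with known fractions.

    Each sample's true fraction vector is drawn from a symmetric
    Dirichlet(alpha); its expression is ``X @ f`` perturbed entry-wise by
    multiplicative log-normal noise with log-scale standard deviation
    ``noise_sd`` (0.05 corresponds to roughly 5% relative noise).

    Returns the genes x samples bulk matrix and the samples x cell-types
    true fraction matrix.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = X.shape[1]
    fractions = rng.dirichlet(np.full(k, float(dirichlet_alpha)), size=n_bulk)
    mixtures = X.to_numpy(dtype=float) @ fractions.T
    if noise_sd > 0:
        mixtures = mixtures * rng.lognormal(0.0, noise_sd, mixtures.shape)
    sample_ids = [f"bulk{s + 1:03d}" for s in range(n_bulk)]
    bulk = pd.DataFrame(mixtures, index=X.index, columns=sample_ids)
    f_true = pd.DataFrame(fractions, index=sample_ids, columns=X.columns)
    return bulk, f_true
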