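"""Synthetic scRNA-seq count generator with known dispersion and heterogeneity.

The generative cascade is:

1. a "master cell" expression profile ``M_i`` drawn i.i.d. exponential;
2. an optional heterogeneous subpopulation: a fixed-size random subset of
   genes (fraction ``prct``) receives a log2 fold change drawn from
   ``Normal(0, s)``, applied in cells independently classified as
   heterogeneous (uniform(0,1) draw above ``cell_dev_threshold``);
3. Gaussian jitter of the master profile, ``Normal(loc, max(floor, 0.2*loc))``
   truncated at zero, where ``loc`` is ``M_i`` (or ``M_i * 2**log2fc_i`` in a
   heterogeneous cell).  Two modes are supported: ``jitter_mode='gene'`` (the
   default) draws the jitter once per gene, so every gene's cross-cell count
   moments follow the variance model exactly at its own jittered mean;
   ``jitter_mode='cell'`` draws an independent mean per gene and cell, which
   adds the jitter variance on top of the model variance (a 20 % extra CV for
   well-expressed genes) and shifts the whole CV-mean cloud off the model
   curve;
4. counts ``x_ij ~ NB(size, prob)`` with the (size, prob) implied by the
   variance model ``sigma^2 = beta*mu + alpha*mu^2`` at the cell's mean
   (Poisson whenever that variance does not exceed the mean; zero mean gives
   count 0).

Full ground truth (master profile, fold changes, gene and cell masks) is
recorded so detection performance can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .model_core import GEVMParams
from .preprocessing import CountMatrix

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "generate_master",
    "inject_heterogeneity",
    "sample_cell_means",
    "sample_counts",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults are the reference simulation: 15,000 genes, 1,000 cells, unit
    master mean, 10 % of genes altered with log2 fold-change SD 2, and a 10 %
    expected heterogeneous-cell fraction.
    """

    n_genes: int = 15_000
    n_cells: int = 1_000
    master_mean: float = 1.0
    alpha: float = 0.0
    beta: float = 1.0
    prct: float = 0.1
    s: float = 2.0
    cell_dev_threshold: float = 0.9
    jitter_sd_floor: float = 0.2
    jitter_mode: str = "gene"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_mode not in ("gene", "cell"):
            raise ValueError("jitter_mode must be 'gene' or 'cell'")
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("n_genes and n_cells must be >= 1")
        if self.master_mean <= 0:
            raise ValueError("master_mean must be > 0")
        if not 0 <= self.prct <= 1:
            raise ValueError("prct must lie in [0, 1]")
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if not 0 <= self.cell_dev_threshold <= 1:
            raise ValueError("cell_dev_threshold must lie in [0, 1]")
        if self.jitter_sd_floor <= 0:
            raise ValueError("jitter_sd_floor must be > 0")
        GEVMParams(self.alpha, self.beta)  # validates alpha/beta

    @property
    def params(self) -> GEVMParams:
        return GEVMParams(self.alpha, self.beta)


@dataclass
class SimulatedDataset:
    """Counts plus the ground truth they were generated from."""

    counts: CountMatrix
    master: np.ndarray
    log2fc: np.ndarray
    altered_genes: np.ndarray
    het_cells: np.ndarray
    config: SimConfig

    def __post_init__(self) -> None:
        if self.counts.values.shape != (self.config.n_genes, self.config.n_cells):
            raise ValueError("counts dimensions do not match config")
        if np.any(self.log2fc[~self.altered_genes] != 0):
            raise ValueError("log2fc must be zero outside altered_genes")


def generate_master(n_genes: int, master_mean: float, rng: np.random.Generator) -> np.ndarray:
    """Draw the master-cell profile: i.i.d. exponential with the given mean."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if master_mean <= 0:
        raise ValueError("master_mean must be > 0")
    return rng.exponential(master_mean, size=n_genes)


def inject_heterogeneity(
    master: np.ndarray,
    prct: float,
    s: float,
    cell_dev_threshold: float,
    n_cells: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Choose altered genes, their shared log2 fold changes, and heterogeneous cells.

    A fixed-size uniform subset of round(prct * n_genes) genes receives
    ``log2FC ~ Normal(0, s)``; each cell is independently heterogeneous with
    probability ``1 - cell_dev_threshold``.  Returns (log2fc, altered_genes
    mask, het_cells mask).
    """
    n_genes = len(master)
    if not 0 <= prct <= 1:
        raise ValueError("prct must lie in [0, 1]")
    if s < 0:
        raise ValueError("s must be >= 0")
    n_alt = int(round(prct * n_genes))
    altered = np.zeros(n_genes, dtype=bool)
    if n_alt:
        altered[rng.choice(n_genes, size=n_alt, replace=False)] = True
    log2fc = np.zeros(n_genes)
    log2fc[altered] = rng.normal(0.0, s, size=n_alt)
    het_cells = rng.uniform(size=n_cells) > cell_dev_threshold
    return log2fc, altered, het_cells


def sample_cell_means(
    master: np.ndarray,
    log2fc: np.ndarray,
    altered_genes: np.ndarray,
    het_cells: np.ndarray,
    jitter_sd_floor: float,
    rng: np.random.Generator,
    jitter_mode: str = "gene",
) -> np.ndarray:
    """Gaussian cell means derived from the master profile, truncated at zero.

    The Normal location is ``M_i`` (or ``M_i * 2**log2fc_i`` for an altered
    gene in a heterogeneous cell) and the SD is ``max(floor, 0.2 * location)``,
    so the jitter keeps a 20 % CV above the floor regardless of fold change.

    With ``jitter_mode='gene'`` the jitter is drawn once per gene and the
    fold-change multiplier is applied to the jittered baseline, so a gene's
    mean is common to all cells of the same class; with ``jitter_mode='cell'``
    every (gene, cell) entry gets an independent draw.
    """
    if jitter_mode == "gene":
        base = rng.normal(master, np.maximum(jitter_sd_floor, 0.2 * master))
        np.clip(base, 0.0, None, out=base)
        return base[:, None] * np.where(het_cells[None, :], 2.0 ** log2fc[:, None], 1.0)
    if jitter_mode != "cell":
        raise ValueError("jitter_mode must be 'gene' or 'cell'")
    loc = master[:, None] * np.where(het_cells[None, :], 2.0 ** log2fc[:, None], 1.0)
    scale = np.maximum(jitter_sd_floor, 0.2 * loc)
    mu = rng.normal(loc, scale)
    np.clip(mu, 0.0, None, out=mu)
    return mu


def sample_counts(
    mu_matrix: np.ndarray,
    params: GEVMParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """NB counts at each mean under sigma^2 = beta*mu + alpha*mu^2.

    Entries where the model variance does not exceed the mean fall back to
    Poisson; zero means give count 0.  NB (size, prob) follow
    size = mu/(beta-1+alpha*mu), prob = 1/(beta+alpha*mu), which reproduce the
    model mean and variance exactly.
    """
    mu = np.asarray(mu_matrix, dtype=float)
    if np.any(mu < 0):
        raise ValueError("means must be nonnegative")
    var = params.beta * mu + params.alpha * mu**2
    counts = np.zeros(mu.shape, dtype=np.int64)
    pois = (mu > 0) & (var <= mu)
    nb = (mu > 0) & (var > mu)
    if pois.any():
        counts[pois] = rng.poisson(mu[pois])
    if nb.any():
        m = mu[nb]
        size = m / (params.beta - 1.0 + params.alpha * m)
        prob = 1.0 / (params.beta + params.alpha * m)
        counts[nb] = rng.negative_binomial(size, prob)
    return counts


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Compose the full cascade deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    master = generate_master(config.n_genes, config.master_mean, rng)
    log2fc, altered, het = inject_heterogeneity(
        master, config.prct, config.s, config.cell_dev_threshold, config.n_cells, rng
    )
    mu = sample_cell_means(
        master, log2fc, altered, het, config.jitter_sd_floor, rng, config.jitter_mode
    )
    values = sample_counts(mu, config.params, rng)
    width_g = len(str(config.n_genes))
    width_c = len(str(config.n_cells))
    counts = CountMatrix(
        values=values,
        gene_ids=np.array([f"G{i:0{width_g}d}" for i in range(config.n_genes)], dtype=object),
        cell_ids=np.array([f"C{j:0{width_c}d}" for j in range(config.n_cells)], dtype=object),
    )
    return SimulatedDataset(
        counts=counts,
        master=master,
        log2fc=log2fc,
        altered_genes=altered,
        het_cells=het,
        config=config,
    )
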