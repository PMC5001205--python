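"""Statistical calling of variably expressed genes (VEGs) from CV differences.

Under a homogeneous population the CV differences scatter normally around
the fitted baseline.  Because variable genes drag the fitted curve (and the
raw mean of D) upward, the null centre is taken as the mode of a Gaussian
kernel density estimate of D, and the null SD is fitted from the left half
only (values at or below the centre, reflected about it) — the side
uncontaminated by high-variability genes.  Upper-tail normal p-values are
then corrected with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocessing import GeneStats

__all__ = ["NormalNull", "estimate_null", "veg_pvalues", "bh_fdr", "build_veg_table", "call_vegs"]


@dataclass(frozen=True)
class NormalNull:
    """Null distribution of CV differences: Normal(center, sd)."""

    center: float
    sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.center):
            raise ValueError("null center must be finite")
        if not np.isfinite(self.sd) or self.sd <= 0:
            raise ValueError("null sd must be finite and > 0")


def estimate_null(D: np.ndarray, bw_method="silverman", grid_size: int = 512) -> NormalNull:
    """Kernel-density mode and reflected left-half SD of the CV differences.

    The centre is the argmax of a Gaussian KDE evaluated on ``grid_size``
    points spanning [min D, max D] (leftmost mode on ties, with a warning);
    the SD is sqrt(mean((D - center)^2)) over D <= center, i.e. a moment fit
    of the half sample reflected about the centre.
    """
    D = np.asarray(D, dtype=float)
    D = D[np.isfinite(D)]
    if len(D) < 100:
        raise ValueError("need at least 100 CV differences to estimate the null")
    if np.ptp(D) == 0:
        raise ValueError("CV differences are constant; null sd would be 0")
    kde = sps.gaussian_kde(D, bw_method=bw_method)
    grid = np.linspace(D.min(), D.max(), grid_size)
    dens = kde(grid)
    peak = dens.max()
    maxima = np.flatnonzero(np.isclose(dens, peak, rtol=1e-9, atol=0.0))
    if len(maxima) > 1 and np.any(np.diff(maxima) > 1):
        warnings.warn("multimodal CV-difference density; using the leftmost mode", stacklevel=2)
    center = float(grid[maxima[0]])
    left = D[D <= center]
    sd = float(np.sqrt(np.mean((left - center) ** 2)))
    if not sd > 0:
        raise ValueError("null sd is 0; CV differences below the center are degenerate")
    return NormalNull(center=center, sd=sd)


def veg_pvalues(D: np.ndarray, null: NormalNull) -> np.ndarray:
    """Upper-tail normal p-value of each CV difference (decreasing in D)."""
    return sps.norm.sf(np.asarray(D, dtype=float), loc=null.center, scale=null.sd)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")


def build_veg_table(
    stats: GeneStats,
    D: np.ndarray,
    null: NormalNull,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene table: mean, cv, D, p, q (BH FDR) and the VEG flag.

    Genes with undefined D (NaN) get p = q = 1 and are never called.
    """
    D = np.asarray(D, dtype=float)
    p = np.ones(len(D))
    ok = np.isfinite(D)
    p[ok] = veg_pvalues(D[ok], null)
    q = np.ones(len(D))
    q[ok] = bh_fdr(p[ok])
    table = pd.DataFrame(
        {
            "mean": stats.mean,
            "cv": stats.cv,
            "D": D,
            "p": p,
            "q": q,
        },
        index=stats.gene_ids,
    )
    return call_vegs(table, fdr_threshold)


def call_vegs(table: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Flag genes with FDR below the threshold as VEGs."""
    table = table.copy()
    table["is_veg"] = table["q"] < fdr_threshold
    return table
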