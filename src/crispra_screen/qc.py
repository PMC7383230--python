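"""Cell/gene quality filtering, library-size normalization and
highly-variable-gene selection.

Comparisons are strict in the printed direction of the thresholds
("less than", "more than"): boundary cells survive. The screen profile
removes cells with < 4,000 UMIs, < 1,600 detected genes, > 20,000 UMIs,
> 5,000 genes, or > 5% mitochondrial UMIs; genes are kept when detected
in at least 10 cells. Expression values are ln(1 + 10,000 * count /
cell_total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen_data import ScreenMatrix

SCALE_FACTOR = 10_000.0
MITO_PREFIX = "mt-"


@dataclass(frozen=True)
class QCProfile:
    name: str
    min_umis: int
    min_genes: int
    max_umis: int
    max_genes: int
    max_pct_mito: float
    min_cells_per_gene: int = 10

    def __post_init__(self):
        if self.min_umis >= self.max_umis or self.min_genes >= self.max_genes:
            raise ValueError("QC profile min thresholds must be below max thresholds")


SCREEN_PROFILE = QCProfile("screen", min_umis=4_000, min_genes=1_600,
                           max_umis=20_000, max_genes=5_000, max_pct_mito=5.0)
PILOT_PROFILE = QCProfile("pilot", min_umis=15_000, min_genes=4_000,
                          max_umis=40_000, max_genes=6_500, max_pct_mito=5.0)

PROFILES = {p.name: p for p in (SCREEN_PROFILE, PILOT_PROFILE)}


def qc_metrics(matrix: ScreenMatrix, mito_prefix: str = MITO_PREFIX) -> ScreenMatrix:
    """Ensure per-cell QC fields exist; mitochondrial genes are flagged by
    gene-id prefix when no ``is_mito`` column is present."""
    genes = matrix.genes
    if "is_mito" not in genes.columns:
        genes = genes.copy()
        genes["is_mito"] = genes.index.str.lower().str.startswith(mito_prefix)
        matrix = ScreenMatrix(matrix.counts, matrix.cells, genes, matrix.repeats)
    return matrix.with_qc_fields()


def filter_cells(matrix: ScreenMatrix, profile: QCProfile) -> ScreenMatrix:
    """Remove cells violating any profile bound (strict inequalities)."""
    m = qc_metrics(matrix)
    cells = m.cells
    bad = (
        (cells["total_umis"] < profile.min_umis)
        | (cells["n_genes_detected"] < profile.min_genes)
        | (cells["total_umis"] > profile.max_umis)
        | (cells["n_genes_detected"] > profile.max_genes)
        | (cells["pct_mito"] > profile.max_pct_mito)
    )
    if bad.all():
        raise ValueError("no cells survive QC filtering")
    return m.subset_cells(~bad.to_numpy())


def filter_genes(matrix: ScreenMatrix, min_cells: int | None = None,
                 profile: QCProfile | None = None) -> ScreenMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells."""
    if min_cells is None:
        min_cells = profile.min_cells_per_gene if profile is not None else 10
    detected = (matrix.counts > 0).sum(axis=0)
    keep = detected >= min_cells
    if not keep.any():
        raise ValueError("no genes survive filtering")
    return matrix.subset_genes(keep)


def qc_report(before: ScreenMatrix, after: ScreenMatrix, profile: QCProfile) -> dict:
    m = qc_metrics(before)
    cells = m.cells
    return {
        "profile": profile.name,
        "cells_in": int(before.n_cells),
        "cells_out": int(after.n_cells),
        "removed_low_umis": int((cells["total_umis"] < profile.min_umis).sum()),
        "removed_low_genes": int((cells["n_genes_detected"] < profile.min_genes).sum()),
        "removed_high_umis": int((cells["total_umis"] > profile.max_umis).sum()),
        "removed_high_genes": int((cells["n_genes_detected"] > profile.max_genes).sum()),
        "removed_high_mito": int((cells["pct_mito"] > profile.max_pct_mito).sum()),
        "genes_in": int(before.n_genes),
        "genes_out": int(after.n_genes),
    }


@dataclass
class NormalizedMatrix:
    """ln(1 + scale_factor * count / total) expression values."""

    values: np.ndarray  # cells x genes, float32
    cells: pd.DataFrame
    genes: pd.DataFrame
    scale_factor: float = SCALE_FACTOR
    hvg_mask: np.ndarray | None = None

    @property
    def gene_ids(self):
        return self.genes.index

    def hvg_values(self) -> np.ndarray:
        if self.hvg_mask is None:
            raise ValueError("highly variable genes not selected yet")
        return self.values[:, self.hvg_mask]


def normalize_log(matrix: ScreenMatrix, scale_factor: float = SCALE_FACTOR) -> NormalizedMatrix:
    """Library-size-adjusted, log-transformed expression.

    value = ln(1 + count / cell_total * scale_factor). Raises on cells
    with zero total counts (excluded upstream by cell filtering).
    """
    totals = matrix.counts.sum(axis=1).astype(np.float64)
    if (totals == 0).any():
        raise ValueError("cells with zero total counts; run filter_cells first")
    vals = matrix.counts.astype(np.float32) * (scale_factor / totals)[:, None].astype(np.float32)
    np.log1p(vals, out=vals)
    return NormalizedMatrix(vals, matrix.cells.copy(), matrix.genes.copy(), scale_factor)


def select_hvg(norm: NormalizedMatrix, min_mean: float = 0.01, max_mean: float = 5.0,
               min_disp: float = 0.5, n_bins: int = 20) -> np.ndarray:
    """Highly-variable genes by mean and binned-normalized dispersion.

    Works on back-scaled expression (expm1 of the log values):
    dispersion = variance / mean, z-scored within ``n_bins``
    equal-frequency bins of the mean. A gene is flagged when its mean of
    the log values lies in (min_mean, max_mean) and the normalized
    dispersion exceeds ``min_disp``. The mask is stored on ``norm``.
    """
    X = np.expm1(norm.values)  # float32; moments accumulated in float64
    n = X.shape[0]
    s1 = X.sum(axis=0, dtype=np.float64)
    s2 = np.einsum("ij,ij->j", X, X, dtype=np.float64)
    mean = s1 / n
    var = np.maximum(s2 - n * mean ** 2, 0.0) / max(n - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    log_mean = np.log1p(mean)

    df = pd.DataFrame({"mean": mean, "disp": disp})
    pos = df["mean"] > 0
    bins = pd.qcut(df.loc[pos, "mean"], q=n_bins, duplicates="drop")
    z = np.zeros(len(df))
    grouped = df.loc[pos, "disp"].groupby(bins, observed=True)
    mu = grouped.transform("mean")
    sd = grouped.transform("std")
    zpos = (df.loc[pos, "disp"] - mu) / sd.replace(0.0, np.nan)
    z[pos.to_numpy()] = zpos.fillna(0.0).to_numpy()

    mask = (log_mean > min_mean) & (log_mean < max_mean) & (z > min_disp)
    if not mask.any():
        raise ValueError("no highly variable genes at these thresholds")
    norm.hvg_mask = mask
    return mask
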