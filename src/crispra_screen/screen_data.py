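"""In-memory containers for screen count data and simulation ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class ScreenMatrix:
    """Cells x genes UMI counts plus cells x repeat-family counts.

    ``counts`` is a dense non-negative integer array (cells x genes);
    ``cells`` and ``genes`` carry per-cell and per-gene metadata indexed
    like the matrix; ``repeats`` is a cells x repeat-family count frame
    aligned to ``cells``.
    """

    counts: np.ndarray
    cells: pd.DataFrame  # index: barcode; columns incl. total_umis, n_genes_detected, pct_mito
    genes: pd.DataFrame  # index: gene_id; columns incl. is_mito, is_signature
    repeats: pd.DataFrame | None = None

    def __post_init__(self):
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError("counts shape does not match metadata")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.repeats is not None and len(self.repeats) != len(self.cells):
            raise ValueError("repeat counts not aligned to cells")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def with_qc_fields(self, force: bool = False) -> "ScreenMatrix":
        """Compute total_umis, n_genes_detected and pct_mito from counts.
        Existing fields are kept unless ``force`` is set (they stay valid
        under cell subsetting)."""
        have = {"total_umis", "n_genes_detected", "pct_mito"} <= set(self.cells.columns)
        if have and not force:
            return self
        cells = self.cells.copy()
        totals = self.counts.sum(axis=1)
        cells["total_umis"] = totals
        cells["n_genes_detected"] = (self.counts > 0).sum(axis=1)
        mito_mask = self.genes["is_mito"].to_numpy(dtype=bool)
        mito = self.counts[:, mito_mask].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals > 0, 100.0 * mito / totals, 0.0)
        cells["pct_mito"] = pct
        return ScreenMatrix(self.counts, cells, self.genes, self.repeats)

    def subset_cells(self, mask) -> "ScreenMatrix":
        mask = np.asarray(mask)
        rep = self.repeats.loc[mask] if (self.repeats is not None and mask.dtype == bool) else (
            self.repeats.iloc[mask] if self.repeats is not None else None)
        cells = self.cells.loc[mask] if mask.dtype == bool else self.cells.iloc[mask]
        return ScreenMatrix(self.counts[mask], cells, self.genes, rep)

    def subset_genes(self, mask) -> "ScreenMatrix":
        mask = np.asarray(mask)
        genes = self.genes.loc[mask] if mask.dtype == bool else self.genes.iloc[mask]
        return ScreenMatrix(self.counts[:, mask], self.cells, genes, self.repeats)

    def to_anndata(self):
        """Export as an AnnData object (repeat counts in ``.obsm``)."""
        import anndata

        ad = anndata.AnnData(
            X=scipy.sparse.csr_matrix(self.counts),
            obs=self.cells.copy(),
            var=self.genes.copy(),
        )
        if self.repeats is not None:
            ad.obsm["repeats"] = self.repeats.to_numpy()
            ad.uns["repeat_families"] = list(self.repeats.columns)
        return ad

    def write_mtx(self, outdir) -> None:
        """Write counts as MatrixMarket with genes.tsv / barcodes.tsv sidecars."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(outdir / "matrix.mtx"), scipy.sparse.coo_matrix(self.counts))
        self.genes.to_csv(outdir / "genes.tsv", sep="\t")
        self.cells.to_csv(outdir / "barcodes.tsv", sep="\t")
        if self.repeats is not None:
            self.repeats.to_csv(outdir / "repeats.tsv", sep="\t")

    @classmethod
    def read_mtx(cls, outdir) -> "ScreenMatrix":
        outdir = Path(outdir)
        counts = np.asarray(scipy.io.mmread(str(outdir / "matrix.mtx")).todense())
        genes = pd.read_csv(outdir / "genes.tsv", sep="\t", index_col=0)
        cells = pd.read_csv(outdir / "barcodes.tsv", sep="\t", index_col=0)
        repeats = None
        if (outdir / "repeats.tsv").exists():
            repeats = pd.read_csv(outdir / "repeats.tsv", sep="\t", index_col=0)
        for col in ("is_mito", "is_signature"):
            if col in genes.columns:
                genes[col] = genes[col].astype(bool)
        return cls(counts.astype(np.int64), cells, genes, repeats)


@dataclass
class GroundTruth:
    """Planted truth of a simulated screen."""

    true_hit_sgrnas: set
    cell_guides: pd.DataFrame  # index barcode; columns guide_1, guide_2 ("" if none), is_doublet
    cell_state: pd.Series  # bool per barcode: ZGA-like state
    cell_factor_value: pd.Series  # continuous planted intensity per barcode
    signature_genes: list
    per_gene_base_mean: pd.Series  # relative expression mean per gene (sums to 1)
    repeat_molecules: pd.DataFrame | None = None  # planted molecule table, cells x families
    is_low_quality: pd.Series | None = None

    def __post_init__(self):
        if self.cell_guides.index.duplicated().any():
            raise ValueError("duplicate cell barcodes in ground truth")

    @property
    def singlet_guides(self) -> pd.Series:
        """True guide per non-doublet cell."""
        sing = self.cell_guides.loc[~self.cell_guides["is_doublet"]]
        return sing["guide_1"]

    def write_tsv(self, path) -> None:
        out = self.cell_guides.copy()
        out["state"] = self.cell_state
        out["factor_value"] = self.cell_factor_value
        if self.is_low_quality is not None:
            out["is_low_quality"] = self.is_low_quality
        out["is_true_hit"] = out["guide_1"].isin(self.true_hit_sgrnas)
        out.to_csv(path, sep="\t")
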