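"""Per-sgRNA hit calling on the ZGA-like factor, and the pilot-style
expressing-fraction analysis.

For each targeting sgRNA that shows any evidence of activating its own
target gene (mean log2 fold-change vs non-targeting cells > 0), the
factor values Z of its cells are regressed on an intercept plus a binary
targeting indicator against the pooled non-targeting cells. The
indicator coefficient delta equals the difference of group means; the
p-value comes from the Gaussian likelihood-ratio test (chi-square, 1 df).
P-values are Benjamini-Hochberg adjusted over the activation-passing
set, and hits are reported at a 10% FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _rows_per_guide(guides: np.ndarray) -> dict:
    """Row indices per guide id (single pass over the cell labels)."""
    codes, uniq = pd.factorize(guides)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    out = {}
    for i, g in enumerate(uniq):
        lo = np.searchsorted(sorted_codes, i, side="left")
        hi = np.searchsorted(sorted_codes, i, side="right")
        out[g] = order[lo:hi]
    return out


@dataclass
class SignatureFraction:
    group: str
    fraction: float
    n_cells: int
    n_expressing: int


def activation_filter(norm_values: np.ndarray, gene_ids, cell_guides: pd.Series,
                      library, pseudocount: float = 1.0) -> pd.DataFrame:
    """Mean log2 fold-change of each targeting sgRNA's own target gene in
    its cells versus all non-targeting cells.

    ``norm_values`` is the normalized log expression (cells x genes)
    aligned with ``cell_guides`` (per-cell assigned guide). Returns a
    frame indexed by guide id with columns target_gene, n_cells, log2fc,
    passes_activation (log2fc > 0, strict).
    """
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    nt_ids = set(library.nontargeting_ids)
    guides = cell_guides.to_numpy()
    guide_rows = _rows_per_guide(guides)
    nt_rows = np.concatenate([guide_rows.get(g, np.array([], int)) for g in nt_ids]) \
        if nt_ids else np.array([], int)
    rows = []
    targeting = library.guides.loc[library.guides["is_targeting"]]
    for guide_id, target in zip(targeting["guide_id"], targeting["target_gene"]):
        grows = guide_rows.get(guide_id, np.array([], int))
        n = len(grows)
        if target not in gene_pos:
            rows.append((guide_id, target, n, np.nan, False))
            continue
        j = gene_pos[target]
        if n == 0:
            import warnings

            warnings.warn(f"sgRNA {guide_id} has no assigned cells; skipped")
            rows.append((guide_id, target, 0, np.nan, False))
            continue
        m1 = float(norm_values[grows, j].mean())
        m0 = float(norm_values[nt_rows, j].mean())
        lfc = np.log2((m1 + pseudocount) / (m0 + pseudocount))
        rows.append((guide_id, target, n, lfc, bool(lfc > 0)))
    return pd.DataFrame(
        rows, columns=["guide_id", "target_gene", "n_cells", "log2fc", "passes_activation"]
    ).set_index("guide_id")


def regress_factor(z_sgrna: np.ndarray, z_nt: np.ndarray) -> tuple:
    """OLS of factor values on intercept + targeting indicator over the
    union of one sgRNA's cells and the non-targeting pool.

    Returns (delta, pvalue): delta is the indicator coefficient, equal to
    the difference of group means; the p-value is the Gaussian
    likelihood-ratio test of the indicator (chi-square with 1 df).
    """
    z1 = np.asarray(z_sgrna, dtype=float)
    z0 = np.asarray(z_nt, dtype=float)
    if len(z1) < 2 or len(z0) < 2:
        raise ValueError("each group needs at least 2 cells")
    n = len(z1) + len(z0)
    delta = z1.mean() - z0.mean()
    rss1 = ((z1 - z1.mean()) ** 2).sum() + ((z0 - z0.mean()) ** 2).sum()
    zall = np.concatenate([z1, z0])
    rss0 = ((zall - zall.mean()) ** 2).sum()
    if rss1 <= 0:
        pvalue = 0.0 if rss0 > rss1 else 1.0
        return float(delta), pvalue
    lrt = n * np.log(rss0 / rss1)
    pvalue = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    return float(delta), pvalue


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def score_sgrnas(z: pd.Series, cell_guides: pd.Series, library,
                activation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sgRNA effect sizes and LRT p-values of the factor regression.

    ``z``: factor values per cell (aligned with ``cell_guides``). Only
    activation-passing sgRNAs are tested when ``activation`` is given.
    """
    guides = cell_guides.to_numpy()
    guide_rows = _rows_per_guide(guides)
    zvals = z.to_numpy()
    nt_rows = [guide_rows.get(g, np.array([], int)) for g in library.nontargeting_ids]
    z_nt = zvals[np.concatenate(nt_rows)] if nt_rows else np.array([])
    rows = []
    test_set = library.targeting_ids
    if activation is not None:
        test_set = [g for g in test_set
                    if g in activation.index and bool(activation.loc[g, "passes_activation"])]
    target_of = library.guides.set_index("guide_id")["target_gene"].to_dict()
    for guide_id in test_set:
        z1 = zvals[guide_rows.get(guide_id, np.array([], int))]
        if len(z1) < 2:
            continue
        delta, p = regress_factor(z1, z_nt)
        rows.append((guide_id, target_of.get(guide_id, ""), len(z1), delta, p))
    return pd.DataFrame(
        rows, columns=["sgrna_id", "target_gene", "n_cells", "delta", "pvalue"]
    ).set_index("sgrna_id")


def call_hits(results: pd.DataFrame, fdr: float = 0.10) -> pd.DataFrame:
    """BH-adjust the per-sgRNA p-values and flag hits at ``q < fdr``.

    Adds qvalue, is_hit and gene_both_sgrnas_hit columns; sorted by
    qvalue then p-value.
    """
    out = results.copy()
    if out.empty:
        out["qvalue"] = pd.Series(dtype=float)
        out["is_hit"] = pd.Series(dtype=bool)
        out["gene_both_sgrnas_hit"] = pd.Series(dtype=bool)
        return out
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    out["is_hit"] = out["qvalue"] < fdr
    hit_counts = out.loc[out["is_hit"]].groupby("target_gene").size()
    tested_counts = out.groupby("target_gene").size()
    both = (hit_counts.reindex(tested_counts.index, fill_value=0) == tested_counts) & (
        tested_counts > 1
    )
    out["gene_both_sgrnas_hit"] = out["target_gene"].map(both).fillna(False).astype(bool)
    return out.sort_values(["qvalue", "pvalue"])


def signature_fraction(counts: np.ndarray, gene_ids, cell_mask, signature,
                       group: str = "", min_signature_umis: int = 3) -> SignatureFraction:
    """Fraction of cells in a group expressing the signature: summed raw
    UMIs over signature genes >= ``min_signature_umis``."""
    cell_mask = np.asarray(cell_mask)
    if cell_mask.dtype == bool:
        n = int(cell_mask.sum())
    else:
        n = len(cell_mask)
    if n == 0:
        raise ValueError("empty cell group")
    sig_cols = np.isin(np.asarray(gene_ids), list(signature))
    sig_umis = counts[cell_mask][:, sig_cols].sum(axis=1)
    expressing = int((sig_umis >= min_signature_umis).sum())
    return SignatureFraction(group, expressing / n, n, expressing)


def fold_change_of_fractions(treated: SignatureFraction, control: SignatureFraction) -> float:
    """Ratio of expressing-cell fractions (treated / control)."""
    if control.fraction == 0:
        raise ZeroDivisionError("control group has no expressing cells")
    return treated.fraction / control.fraction
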