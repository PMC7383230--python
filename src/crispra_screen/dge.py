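"""Negative-binomial differential expression and the cumulative
signature-rank enrichment statistic.

For one sgRNA versus the non-targeting pool, every gene is tested with a
negative binomial GLM (log link, log library-size offset, variance
mu + phi mu^2). The per-gene dispersion phi is a method-of-moments
estimate on offset-adjusted counts pooled across the two groups (floored
at 1e-8, no empirical-Bayes shrinkage); the likelihood-ratio statistic
compares group-specific versus shared means against chi-square(1).

The enrichment statistic ranks upregulated genes by significance and
counts cumulative signature genes among the top r for r = 1..400; an
empirical background band (mean +/- 1 sd) is built from leave-one-out
comparisons among the non-targeting sgRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

DISPERSION_FLOOR = 1e-8
DEFAULT_TOP_RANK = 400


def _moment_dispersion(y: np.ndarray, s: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pooled within-group method-of-moments dispersion per gene.

    y: cells x genes counts; s: per-cell size factors; labels: binary
    group labels. Uses z = y / s with Var(z) ~= lambda * mean(1/s) +
    phi * lambda^2 within each group.
    """
    phis = np.zeros(y.shape[1])
    weights = np.zeros(y.shape[1])
    for g in np.unique(labels):
        mask = labels == g
        z = y[mask] / s[mask, None]
        lam = z.mean(axis=0)
        v = z.var(axis=0, ddof=1)
        inv_s = float(np.mean(1.0 / s[mask]))
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = (v - lam * inv_s) / lam ** 2
        phi_g = np.where(np.isfinite(phi_g), phi_g, 0.0)
        w = mask.sum() - 1
        phis += w * phi_g
        weights += w
    return np.clip(phis / np.maximum(weights, 1), DISPERSION_FLOOR, None)


def _nb_mle_rate(y: np.ndarray, s: np.ndarray, phi: np.ndarray,
                 max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Per-gene MLE of the rate lambda with mu_i = s_i * lambda and fixed
    dispersion, by Newton iteration on beta = log(lambda). Genes with all
    zero counts get rate 0."""
    tot = y.sum(axis=0)
    ssum = s.sum()
    lam0 = tot / ssum
    zero = lam0 <= 0
    beta = np.log(np.where(zero, 1.0, lam0))
    for _ in range(max_iter):
        mu = s[:, None] * np.exp(beta)[None, :]
        denom = 1.0 + phi[None, :] * mu
        score = ((y - mu) / denom).sum(axis=0)
        info = (mu * (1.0 + phi[None, :] * y) / denom ** 2).sum(axis=0)
        step = score / np.maximum(info, 1e-300)
        step = np.clip(step, -2.0, 2.0)
        beta = beta + np.where(zero, 0.0, step)
        if np.max(np.abs(step)) < tol:
            break
    lam = np.exp(beta)
    lam[zero] = 0.0
    return lam


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood (summed over cells); safe at mu = 0."""
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-300)
    ll = (
        special.gammaln(y + r[None, :])
        - special.gammaln(r[None, :])
        - special.gammaln(y + 1.0)
        + r[None, :] * np.log(r[None, :] / (r[None, :] + mu))
        + y * np.log(mu / (r[None, :] + mu))
    )
    # y = 0 terms with mu -> 0 contribute 0; the clamp above keeps logs finite
    return ll.sum(axis=0)


def nb_glm_lrt(counts: np.ndarray, labels, libsizes) -> pd.DataFrame:
    """NB likelihood-ratio test per gene between two cell groups.

    counts: cells x genes raw UMIs; labels: binary per cell (1 = sgRNA
    group, 0 = control); libsizes: per-cell totals used as offsets.
    Returns log2FC (group 1 over group 0), lrt_statistic and pvalue per
    gene; all-zero genes get p = 1 and log2FC = 0.
    """
    y = np.asarray(counts, dtype=np.float64)
    labels = np.asarray(labels)
    lib = np.asarray(libsizes, dtype=np.float64)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("labels must define exactly two groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError("each group needs at least 2 cells")
    s = lib / lib.mean()

    phi = _moment_dispersion(y, s, labels)
    mask1 = labels == groups[-1]
    mask0 = ~mask1

    lam_null = _nb_mle_rate(y, s, phi)
    lam1 = _nb_mle_rate(y[mask1], s[mask1], phi)
    lam0 = _nb_mle_rate(y[mask0], s[mask0], phi)

    ll_null = _nb_loglik(y, s[:, None] * lam_null[None, :], phi)
    ll_alt = _nb_loglik(y[mask1], s[mask1, None] * lam1[None, :], phi) + _nb_loglik(
        y[mask0], s[mask0, None] * lam0[None, :], phi
    )
    lrt = np.clip(2.0 * (ll_alt - ll_null), 0.0, None)
    pvals = stats.chi2.sf(lrt, df=1)

    pseudo = 1.0 / s.sum()  # one pseudo-molecule over the summed size factors
    log2fc = np.log2((lam1 + pseudo) / (lam0 + pseudo))

    all_zero = y.sum(axis=0) == 0
    pvals = np.where(all_zero, 1.0, pvals)
    lrt = np.where(all_zero, 0.0, lrt)
    log2fc = np.where(all_zero, 0.0, log2fc)
    return pd.DataFrame({"log2fc": log2fc, "lrt_statistic": lrt, "pvalue": pvals})


def rank_upregulated(dge: pd.DataFrame, top_n: int = DEFAULT_TOP_RANK) -> list:
    """Upregulated genes (log2fc > 0) ordered by ascending p-value; ties
    by descending log2fc then lexicographic gene id. Truncated at
    ``top_n``; shorter lists are not padded."""
    up = dge.loc[dge["log2fc"] > 0].copy()
    up["gene"] = up.index.astype(str)
    up = up.sort_values(["pvalue", "log2fc", "gene"], ascending=[True, False, True])
    return up.index[:top_n].tolist()


def cumulative_zga_curve(ranked_genes, signature, max_rank: int = DEFAULT_TOP_RANK) -> np.ndarray:
    """curve[r-1] = number of signature genes among the top r ranked
    genes, for r = 1..min(max_rank, len(ranked))."""
    sig = set(signature)
    flags = np.fromiter((g in sig for g in ranked_genes[:max_rank]), dtype=int,
                        count=min(len(ranked_genes), max_rank))
    return np.cumsum(flags)


@dataclass
class BackgroundBand:
    """Per-rank mean and sd of enrichment curves from control-vs-control
    comparisons."""

    mean: np.ndarray
    sd: np.ndarray

    def upper(self) -> np.ndarray:
        return self.mean + self.sd


def _curve_at(curve: np.ndarray, rank: int) -> float:
    if len(curve) == 0:
        return 0.0
    return float(curve[min(rank, len(curve)) - 1])


def sgrna_enrichment_curve(counts, libsizes, cell_guides, guide_id, nt_ids, signature,
                           gene_ids, max_rank: int = DEFAULT_TOP_RANK,
                           exclude_from_nt=None) -> np.ndarray:
    """Full DGE + ranking + cumulative-curve pipeline for one sgRNA
    against the non-targeting pool."""
    guides = np.asarray(cell_guides)
    nt_set = set(nt_ids) - (set(exclude_from_nt) if exclude_from_nt else set())
    mask1 = guides == guide_id
    mask0 = np.isin(guides, list(nt_set - {guide_id}))
    sel = mask1 | mask0
    dge = nb_glm_lrt(counts[sel], mask1[sel].astype(int), np.asarray(libsizes)[sel])
    dge.index = pd.Index(gene_ids, name="gene_id")
    ranked = rank_upregulated(dge, top_n=max_rank)
    return cumulative_zga_curve(ranked, signature, max_rank=max_rank)


def nt_background(counts, libsizes, cell_guides, nt_ids, signature, gene_ids,
                  max_rank: int = DEFAULT_TOP_RANK) -> BackgroundBand:
    """Leave-one-out background: each non-targeting sgRNA's cells versus
    the union of the remaining non-targeting cells, through the full DGE
    and curve pipeline. Requires >= 3 non-targeting sgRNAs."""
    nt_ids = list(nt_ids)
    if len(nt_ids) < 3:
        raise ValueError("need at least 3 non-targeting sgRNAs for the background")
    curves = []
    for nt in nt_ids:
        curve = sgrna_enrichment_curve(
            counts, libsizes, cell_guides, nt, nt_ids, signature, gene_ids,
            max_rank=max_rank,
        )
        full = np.zeros(max_rank)
        full[: len(curve)] = curve
        if len(curve) and len(curve) < max_rank:
            full[len(curve):] = curve[-1]
        curves.append(full)
    arr = np.vstack(curves)
    return BackgroundBand(mean=arr.mean(axis=0), sd=arr.std(axis=0, ddof=1))


def enrichment_call(curve: np.ndarray, band: BackgroundBand,
                    rank: int = DEFAULT_TOP_RANK) -> bool:
    """True when the sgRNA's curve overlaps the control background at
    ``rank``: curve(rank) <= mean(rank) + 1 sd(rank). Enriched sgRNAs
    return False."""
    c = _curve_at(curve, rank)
    idx = min(rank, len(band.mean)) - 1
    return bool(c <= band.mean[idx] + band.sd[idx])
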