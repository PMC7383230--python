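"""Multi-view latent factor analysis of gene and repeat expression.

`MultiViewFactorModel` fits a deterministic truncated singular-value
decomposition to the column-concatenation of several views (e.g.
highly-variable gene expression and repeat-family expression), after
per-view feature standardisation and per-view rescaling to unit total
variance so no view dominates by dimensionality. Factors play the role
of latent transcriptional programs; the ZGA-like factor is identified
algorithmically from its loadings: hypergeometric enrichment of a
signature gene set among the top absolute gene loadings, plus the
requirement that the designated repeat family (MERVL by default) carries
the top absolute repeat loading.

The fit is deterministic: no random initialisation, and a fixed sign
convention (the largest-magnitude loading of each factor is positive).
Grouping labels (the cell-to-sgRNA assignment) are carried through the
fit and reported descriptively as per-group factor means; they do not
alter the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class ViewMatrix:
    """One view: a cells x features matrix of normalized log expression."""

    name: str
    values: np.ndarray
    feature_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_ids):
            raise ValueError(f"view {self.name}: values shape does not match feature ids")
        if not np.isfinite(self.values).all():
            raise ValueError(f"view {self.name}: non-finite values")


class MultiViewFactorModel(BaseEstimator, TransformerMixin):
    """Truncated multi-view SVD with per-view variance balancing.

    Parameters
    ----------
    n_factors : int, default 5
        Number of latent factors K.
    scale_features : bool, default True
        Standardise each feature to unit variance within its view
        (constant features stay zero).
    balance_views : bool, default True
        Rescale each view to unit total variance so views contribute
        equally regardless of feature count.

    Attributes (after fit)
    ----------
    factors_ : ndarray, cells x K
        Factor values Z; columns are mutually orthogonal.
    loadings_ : dict view name -> DataFrame (features x K)
        Per-view loading matrices W.
    variance_explained_ : DataFrame (views x K)
        Fraction of each view's (preprocessed) variance explained by
        each single factor; entries in [0, 1], row sums <= 1.
    singular_values_ : ndarray, K
    group_means_ : DataFrame or None
        Mean factor values per grouping label when groups were provided.
    """

    def __init__(self, n_factors: int = 5, scale_features: bool = True,
                 balance_views: bool = True):
        self.n_factors = n_factors
        self.scale_features = scale_features
        self.balance_views = balance_views

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y=None, groups=None):
        views = self._as_views(X)
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        n_cells = views[0].values.shape[0]
        if n_cells < 2:
            raise ValueError("need at least 2 cells")
        total_features = sum(v.values.shape[1] for v in views)
        if self.n_factors > min(n_cells, total_features):
            raise ValueError(
                f"n_factors={self.n_factors} exceeds min(cells, features)="
                f"{min(n_cells, total_features)}"
            )
        for v in views[1:]:
            if v.values.shape[0] != n_cells:
                raise ValueError("views are not row-aligned")

        blocks, self._view_slices = [], {}
        self._center, self._scale, self._view_weight = {}, {}, {}
        start = 0
        for v in views:
            Xv, center, scale, weight = self._preprocess(v.values)
            self._center[v.name] = center
            self._scale[v.name] = scale
            self._view_weight[v.name] = weight
            blocks.append(Xv)
            self._view_slices[v.name] = slice(start, start + Xv.shape[1])
            start += Xv.shape[1]
        Xall = np.concatenate(blocks, axis=1)

        # deterministic truncated SVD via the feature-space Gram matrix
        G = Xall.T @ Xall
        evals, evecs = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1][: self.n_factors]
        lam = np.clip(evals[order], 0.0, None)
        V = evecs[:, order]
        # fixed sign convention: the largest-|loading| entry is positive
        for k in range(V.shape[1]):
            j = int(np.argmax(np.abs(V[:, k])))
            if V[j, k] < 0:
                V[:, k] = -V[:, k]
        S = np.sqrt(lam)
        Z = Xall @ V

        self.view_names_ = [v.name for v in views]
        self.feature_ids_ = {v.name: list(v.feature_ids) for v in views}
        self.singular_values_ = S
        self.components_ = V
        self.factors_ = Z
        self.loadings_ = {
            v.name: pd.DataFrame(
                V[self._view_slices[v.name]],
                index=pd.Index(v.feature_ids, name="feature"),
                columns=[f"factor_{k + 1}" for k in range(self.n_factors)],
            )
            for v in views
        }
        ss_view = {v.name: (Xall[:, self._view_slices[v.name]] ** 2).sum() for v in views}
        ve = np.zeros((len(views), self.n_factors))
        for i, v in enumerate(views):
            sl = self._view_slices[v.name]
            ve[i] = lam * (V[sl] ** 2).sum(axis=0) / max(ss_view[v.name], 1e-300)
        self.variance_explained_ = pd.DataFrame(
            ve, index=pd.Index(self.view_names_, name="view"),
            columns=[f"factor_{k + 1}" for k in range(self.n_factors)],
        )
        self.group_means_ = None
        if groups is not None:
            zf = pd.DataFrame(Z, columns=self.variance_explained_.columns)
            zf["group"] = np.asarray(groups)
            self.group_means_ = zf.groupby("group").mean()
        return self

    def _preprocess(self, values: np.ndarray):
        X = np.asarray(values, dtype=np.float64)
        center = X.mean(axis=0)
        X = X - center
        if self.scale_features:
            sd = X.std(axis=0, ddof=0)
            scale = np.where(sd > 0, sd, 1.0)
            X = X / scale
        else:
            scale = np.ones(X.shape[1])
        if self.balance_views:
            total_var = (X ** 2).sum() / X.shape[0]
            weight = 1.0 / np.sqrt(total_var) if total_var > 0 else 1.0
            X = X * weight
        else:
            weight = 1.0
        return X, center, scale, weight

    # -- transforming ----------------------------------------------------

    def transform(self, X):
        views = self._as_views(X)
        blocks = []
        for v in views:
            Xv = (np.asarray(v.values, float) - self._center[v.name]) / self._scale[v.name]
            blocks.append(Xv * self._view_weight[v.name])
        return np.concatenate(blocks, axis=1) @ self.components_

    @staticmethod
    def _as_views(X) -> list:
        if isinstance(X, ViewMatrix):
            return [X]
        views = list(X)
        if not views:
            raise ValueError("no views given")
        if not all(isinstance(v, ViewMatrix) for v in views):
            raise TypeError("expected ViewMatrix instances")
        return views


def fit_factors(views, groups=None, k: int = 5, **kwargs) -> MultiViewFactorModel:
    """Functional wrapper over MultiViewFactorModel."""
    return MultiViewFactorModel(n_factors=k, **kwargs).fit(views, groups=groups)


def rank_loadings(model: MultiViewFactorModel, factor_index: int, view: str,
                  top_n: int = 50) -> pd.DataFrame:
    """Features of one view sorted by absolute loading on one factor
    (descending; ties broken lexicographically by feature id).
    ``factor_index`` is zero-based."""
    load = model.loadings_[view].iloc[:, factor_index]
    df = pd.DataFrame({"loading": load, "abs_loading": load.abs()})
    df = df.sort_index().sort_values("abs_loading", ascending=False, kind="stable")
    return df.head(top_n).drop(columns="abs_loading")


def signature_enrichment_p(top_features, signature, universe_size: int,
                           signature_size: int) -> float:
    """Hypergeometric upper-tail probability of observing at least the
    seen overlap between ``top_features`` and the signature."""
    top = list(top_features)
    overlap = len(set(top) & set(signature))
    return float(stats.hypergeom.sf(overlap - 1, universe_size, signature_size, len(top)))


def identify_zga_factor(model: MultiViewFactorModel, signature, gene_view: str = "genes",
                        repeat_view: str = "repeats", repeat_family: str = "MERVL",
                        top_n: int = 50, p_threshold: float = 0.01, universe=None):
    """Pick the factor whose top gene loadings are enriched for the ZGA
    signature and whose top repeat loading is the designated family.

    ``universe`` is the gene population the hypergeometric enrichment is
    referred to — normally all genes that entered the analysis (e.g. the
    post-QC gene set), of which the fitted gene view is the
    highly-variable subset; it defaults to the view's own features.

    Returns ``(factor_index, p_value)`` with a zero-based index, or
    ``(None, None)`` when no factor qualifies (a valid outcome).
    """
    signature = set(signature)
    gene_ids = model.feature_ids_[gene_view]
    if universe is None:
        universe_ids = set(gene_ids)
    else:
        universe_ids = set(universe) | set(gene_ids)
    universe = len(universe_ids)
    sig_in_universe = len(signature & universe_ids)
    if not signature or sig_in_universe == 0 or sig_in_universe >= universe:
        return None, None
    best = (None, None)
    best_p = np.inf
    for k in range(model.n_factors):
        top = rank_loadings(model, k, gene_view, top_n).index
        p = signature_enrichment_p(top, signature, universe, sig_in_universe)
        if p < best_p:
            best_p = p
            best = (k, p)
    k, p = best
    if k is None or p >= p_threshold:
        return None, None
    if repeat_view in model.loadings_:
        rl = model.loadings_[repeat_view].iloc[:, k].abs()
        if rl.idxmax() != repeat_family:
            return None, None
    return k, p


def variance_explained(model: MultiViewFactorModel) -> pd.DataFrame:
    return model.variance_explained_.copy()
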