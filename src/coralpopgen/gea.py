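"""Redundancy-analysis (RDA) genotype-environment association.

The centered genotype matrix is regressed on sample-level environment
predictors (each sample inherits the retained temperature PCs of its
site); the constrained ordination axes are the principal directions of
the fitted-value matrix.  Per-SNP loadings on the retained axes are
summarized by a Mahalanobis distance, rescaled by a genomic inflation
factor (median D^2 over the chi-square median), converted to upper-tail
chi-square p-values, and corrected by Benjamini-Hochberg.  SNPs with
q < 0.1 are temperature outliers; the 100 lowest-p SNPs form the
"top-100" set used in the enrichment synthesis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .variants import GenotypeMatrix

__all__ = ["RdaModel", "fit_rda", "outlier_scan", "RdaOutlierScanner"]


class RdaOutlierScanner(BaseEstimator):
    """Estimator interface for the RDA outlier scan.

    Parameters
    ----------
    n_axes : int or None
        Retained constrained axes for the Mahalanobis statistic; ``None``
        keeps the axes whose eigenvalue exceeds the broken-stick
        expectation (at least 1, at most the number of predictors).
    q_threshold : float
        Outlier call threshold on the BH q-value.
    top_n : int
        Size of the lowest-p "top" set.

    Attributes
    ----------
    loadings_ : ndarray (sites x k)
        SNP loadings on the constrained axes.
    eigenvalues_ : ndarray
        Constrained eigenvalues, non-increasing.
    constrained_fraction_ : float
        Proportion of total genotype variance explained by the
        environment predictors.
    n_axes_retained_ : int
    table_ : DataFrame
        Per-SNP contig, pos, D2, p, q, is_outlier, is_top100.
    inflation_ : float
        Genomic inflation factor lambda.
    """

    def __init__(self, n_axes: int | None = None, q_threshold: float = 0.1, top_n: int = 100):
        self.n_axes = n_axes
        self.q_threshold = q_threshold
        self.top_n = top_n

    def fit(self, gm: GenotypeMatrix, env_predictors: pd.DataFrame):
        """Fit the constrained ordination and score every SNP.

        ``env_predictors`` is indexed by sample id (one row per sample,
        k predictor columns, full rank).
        """
        x = env_predictors.reindex(gm.sample_ids).to_numpy(dtype=np.float64)
        if np.isnan(x).any():
            raise ValueError("environment predictors missing for some samples")
        n, k = x.shape
        if n < k + 2:
            raise ValueError("need at least n_predictors + 2 samples")
        xs = x - x.mean(axis=0)
        rank = np.linalg.matrix_rank(xs)
        if rank < k:
            corr = np.corrcoef(xs, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            cols = list(env_predictors.columns)
            raise ValueError(
                f"rank-deficient predictors (collinear: {cols[i]!r}, {cols[j]!r})"
            )
        y = gm.dosages.astype(np.float64)
        if (gm.dosages < 0).any():
            raise ValueError("RDA requires no missing genotypes")
        yc = y - y.mean(axis=0)
        qx, _ = np.linalg.qr(xs)
        yhat = qx @ (qx.T @ yc)
        u, s, vt = np.linalg.svd(yhat, full_matrices=False)
        s = s[:k]
        vt = vt[:k]
        self.eigenvalues_ = s**2 / (n - 1)
        self.loadings_ = vt.T  # sites x k
        total_ss = float(np.sum(yc * yc))
        self.constrained_fraction_ = float(np.sum(s**2) / total_ss) if total_ss else 0.0
        self.n_predictors_ = k

        n_axes = self.n_axes if self.n_axes is not None else self._broken_stick_axes()
        if n_axes > k:
            raise ValueError("n_axes exceeds the number of constrained axes")
        self.n_axes_retained_ = n_axes
        self.table_ = self._scan(gm, n_axes)
        return self

    def _broken_stick_axes(self) -> int:
        k = len(self.eigenvalues_)
        props = self.eigenvalues_ / self.eigenvalues_.sum()
        bstick = np.array([np.sum(1.0 / np.arange(i + 1, k + 1)) / k for i in range(k)])
        keep = 0
        for i in range(k):
            if props[i] > bstick[i]:
                keep += 1
            else:
                break
        return min(max(keep, 1), k)

    def _scan(self, gm: GenotypeMatrix, n_axes: int) -> pd.DataFrame:
        z = self.loadings_[:, :n_axes]
        if z.shape[0] <= n_axes:
            raise ValueError("fewer SNPs than retained axes")
        mu = z.mean(axis=0)
        cov = np.cov(z, rowvar=False).reshape(n_axes, n_axes)
        zc = z - mu
        d2 = np.einsum("ij,jk,ik->i", zc, np.linalg.pinv(cov), zc)
        lam = float(np.median(d2) / sps.chi2.ppf(0.5, df=n_axes))
        if lam <= 0 or not np.isfinite(lam):
            lam = 1.0
        self.inflation_ = lam
        p = sps.chi2.sf(d2 / lam, df=n_axes)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        q = multipletests(p, method="fdr_bh")[1]
        tab = pd.DataFrame(
            {
                "contig": gm.contigs,
                "pos": gm.positions,
                "D2": d2,
                "p": p,
                "q": q,
                "is_outlier": q < self.q_threshold,
            }
        )
        order = tab.sort_values(
            ["p", "D2", "contig", "pos"], ascending=[True, False, True, True]
        ).index[: min(self.top_n, len(tab))]
        tab["is_top100"] = False
        tab.loc[order, "is_top100"] = True
        return tab


class RdaModel:
    """Fitted RDA ordination (thin view over a fitted scanner)."""

    def __init__(self, scanner: RdaOutlierScanner):
        self._scanner = scanner
        self.loadings = scanner.loadings_
        self.eigenvalues = scanner.eigenvalues_
        self.constrained_fraction = scanner.constrained_fraction_
        self.n_axes_retained = scanner.n_axes_retained_
        self.gm = scanner._gm

    @property
    def n_predictors(self) -> int:
        return self._scanner.n_predictors_


def fit_rda(gm: GenotypeMatrix, env_predictors: pd.DataFrame, n_axes: int | None = None) -> RdaModel:
    """Fit the constrained ordination; returns a model usable with
    :func:`outlier_scan`."""
    scanner = RdaOutlierScanner(n_axes=n_axes)
    scanner._gm = gm
    scanner.fit(gm, env_predictors)
    return RdaModel(scanner)


def outlier_scan(
    model: RdaModel,
    n_axes: int | None = None,
    q_threshold: float = 0.1,
    top_n: int = 100,
) -> pd.DataFrame:
    """Per-SNP outlier table (contig, pos, D2, p, q, is_outlier, is_top100)."""
    sc = model._scanner
    if n_axes is not None and n_axes != sc.n_axes_retained_:
        if n_axes > len(sc.eigenvalues_):
            raise ValueError("n_axes exceeds the number of constrained axes")
        sc.n_axes_retained_ = n_axes
    sc.q_threshold = q_threshold
    sc.top_n = top_n
    sc.table_ = sc._scan(model.gm, sc.n_axes_retained_)
    return sc.table_


def sample_env_predictors(
    env_scores: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Expand per-site environment PCs to one row per sample."""
    site_of = metadata.set_index("sample_id")["site"]
    out = env_scores.reindex(site_of.to_numpy())
    out.index = site_of.index
    return out


def env_pc_scores(
    env: pd.DataFrame, variance_target: float = 0.80, max_pcs: int = 5
) -> pd.DataFrame:
    """Per-site retained temperature PCs (standardized descriptors)."""
    from sklearn.decomposition import PCA as _SkPCA

    sd = env.std(ddof=0)
    env = env.loc[:, sd > 0]
    z = (env - env.mean()) / env.std(ddof=0)
    n_comp = min(len(env) - 1, z.shape[1])
    model = _SkPCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(z.to_numpy())
    cum = np.cumsum(model.explained_variance_ratio_)
    n_keep = min(max(int(np.searchsorted(cum, variance_target - 1e-12) + 1), 1), max_pcs, n_comp)
    return pd.DataFrame(
        scores[:, :n_keep],
        index=env.index,
        columns=[f"PC{i + 1}" for i in range(n_keep)],
    )
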