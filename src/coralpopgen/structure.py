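"""Genotype PCA and ancestry-coefficient estimation.

Ancestry is modeled as in sparse nonnegative matrix factorization of
one-hot-encoded genotypes: the (samples x 3*sites) genotype-class
indicator matrix Y is approximated by Q @ G where the rows of Q (one per
sample) are admixture coefficients on the K-simplex and G holds per
ancestral population genotype-class frequencies in [0, 1].  The fit
minimizes the ridge-penalized least-squares objective
``0.5 * ||W * (Q G - Y)||^2 + 0.5 * alpha * ||Q||^2`` by alternating
projected-gradient block updates (monotone in the objective); W masks
missing or held-out genotype entries.  The ridge acts on the admixture
coefficients, as in the original sparse-NMF formulation, where it
stabilizes Q when data are limited.  The number of ancestral
populations K is chosen by a masked cross-entropy criterion: a fraction
of genotype entries is hidden during fitting and scored under the
model's predicted genotype-class probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA as _SkPCA

from .variants import GenotypeMatrix

__all__ = [
    "PcaResult",
    "pca",
    "AncestryResult",
    "AncestryModel",
    "estimate_ancestry",
    "choose_K",
    "subcluster",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray  # samples x components
    eigenvalues: np.ndarray  # sample-covariance eigenvalues, non-increasing
    loadings: np.ndarray  # sites x components
    total_variance: float  # total variance of the centered matrix (ddof=1)


def pca(gm: GenotypeMatrix, n_components: int) -> PcaResult:
    """PCA of column-centered, unscaled dosages.

    Requires a complete (no missing data) matrix, i.e. post-filter.
    Deterministic up to component sign.
    """
    if gm.missing_mask().any():
        raise ValueError("PCA requires no missing data (filter first)")
    if n_components > min(gm.n_samples, gm.n_sites):
        raise ValueError("n_components exceeds matrix rank bound")
    x = gm.dosages.astype(np.float64)
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    total = x.var(axis=0, ddof=1).sum()
    return PcaResult(
        scores=scores,
        eigenvalues=model.explained_variance_,
        loadings=model.components_.T,
        total_variance=float(total),
    )


# ---------------------------------------------------------------------------
# Ancestry estimation
# ---------------------------------------------------------------------------

@dataclass
class AncestryResult:
    K: int
    Q: np.ndarray  # samples x K, rows on the simplex
    G: np.ndarray  # K x (3 * sites) genotype-class frequencies in [0, 1]
    objective: float
    cross_entropy: float | None = None
    converged: bool = True

    def hard_assignment(self) -> np.ndarray:
        """Cluster index per sample by largest admixture coefficient."""
        return np.argmax(self.Q, axis=1)


def _one_hot(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(Y, W): genotype-class indicators and observation weights.

    Y is samples x (3 * sites); missing entries have Y = 0 and W = 0
    for the whole genotype-class triple.
    """
    n, L = dosages.shape
    Y = np.zeros((n, 3 * L), dtype=np.float32)
    W = np.zeros((n, 3 * L), dtype=np.float32)
    for v in (0, 1, 2):
        Y[:, v::3] = dosages == v
    obs = (dosages >= 0).astype(np.float32)
    for v in range(3):
        W[:, v::3] = obs
    return Y, W


def _project_rows_to_simplex(q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    k = q.shape[1]
    u = np.sort(q, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1, dtype=q.dtype)
    cond = u - css / ind > 0
    rho = k - 1 - np.argmax(cond[:, ::-1], axis=1)
    lam = css[np.arange(len(q)), rho] / (rho + 1.0)
    return np.maximum(q - lam[:, None], 0.0)


class AncestryModel(BaseEstimator):
    """Simplex-constrained ridge NMF of one-hot genotypes.

    Parameters
    ----------
    K : int
        Number of ancestral populations.
    alpha : float
        Ridge penalty on Q (the sparse-NMF regularization weight).
    n_init : int
        Random restarts; the best objective is kept.
    max_iter, inner_steps, tol
        Outer iterations, projected-gradient steps per block, and the
        relative objective-change stopping tolerance.
    random_state : int
        Seed for restarts.

    Attributes
    ----------
    Q_, G_, objective_, n_iter_, converged_
    """

    def __init__(
        self,
        K: int = 2,
        alpha: float = 10.0,
        n_init: int = 10,
        max_iter: int = 200,
        inner_steps: int = 3,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.K = K
        self.alpha = alpha
        self.n_init = n_init
        self.max_iter = max_iter
        self.inner_steps = inner_steps
        self.tol = tol
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _objective(self, Y, W, Q, G) -> float:
        r = W * (Q @ G - Y)
        return 0.5 * float(np.sum(r * r, dtype=np.float64)) + 0.5 * self.alpha * float(
            np.sum(Q * Q, dtype=np.float64)
        )

    def _fit_once(self, Y, W, rng):
        n, m = Y.shape
        K = self.K
        Q = rng.dirichlet(np.ones(K), size=n).astype(np.float32)
        # seed components from distinct random samples (smoothed one-hot
        # rows) so that ancestral populations start well separated
        anchors = rng.choice(n, size=min(K, n), replace=False)
        G = np.tile(Y.mean(axis=0), (K, 1))
        G[: len(anchors)] = 0.7 * Y[anchors] + 0.3 * Y.mean(axis=0)[None, :]
        G = np.clip(G + rng.normal(0, 0.01, (K, m)), 0.0, 1.0).astype(np.float32)
        obj = self._objective(Y, W, Q, G)
        converged = False
        it = 0
        for it in range(self.max_iter):
            # Q block first: with components seeded from distinct samples,
            # admixture rows differentiate before G is re-estimated
            lip_q = float(np.linalg.norm(G @ G.T, 2)) + self.alpha
            for _ in range(self.inner_steps):
                grad = (W * (Q @ G - Y)) @ G.T + self.alpha * Q
                Q = _project_rows_to_simplex(Q - grad / lip_q)
            # G block: projected gradient with exact Lipschitz step
            lip_g = float(np.linalg.norm(Q.T @ Q, 2)) + 1e-12
            for _ in range(self.inner_steps):
                grad = Q.T @ (W * (Q @ G - Y))
                G = np.clip(G - grad / lip_g, 0.0, 1.0)
            new_obj = self._objective(Y, W, Q, G)
            if obj - new_obj <= self.tol * max(obj, 1.0):
                obj = new_obj
                converged = True
                break
            obj = new_obj
        return Q, G, obj, it + 1, converged

    def fit(self, dosages: np.ndarray, y=None, holdout_mask: np.ndarray | None = None):
        """Fit on a samples x sites dosage matrix ({0,1,2}, -1/NaN missing).

        ``holdout_mask`` (samples x sites, boolean) hides entries from
        the fit; they can then be scored with :meth:`cross_entropy`.
        """
        dosages = np.asarray(dosages)
        if np.issubdtype(dosages.dtype, np.floating):
            d = np.where(np.isnan(dosages), -1, dosages).astype(np.int64)
        else:
            d = dosages.astype(np.int64)
        Y, W = _one_hot(d)
        if holdout_mask is not None:
            hm = np.repeat(holdout_mask, 3).reshape(W.shape)
            W = W * (~hm)
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_init)):
            fit = self._fit_once(Y, W, rng)
            if best is None or fit[2] < best[2]:
                best = fit
        Q, G, obj, n_iter, converged = best
        if not converged:
            warnings.warn("ancestry fit did not converge; best iterate returned")
        self.Q_, self.G_ = Q, G
        self.objective_ = obj
        self.n_iter_ = n_iter
        self.converged_ = converged
        self._Y, self._Wobs = Y, _one_hot(d)[1]
        return self

    def predict_proba(self) -> np.ndarray:
        """Predicted genotype-class probabilities, samples x (3*sites),
        each triple clipped and renormalized."""
        P = self.Q_ @ self.G_
        n, m = P.shape
        P = np.clip(P.reshape(n, m // 3, 3), 1e-9, None)
        P /= P.sum(axis=2, keepdims=True)
        return P.reshape(n, m)

    def cross_entropy(self, mask: np.ndarray) -> float:
        """Mean negative log predicted probability of the true genotype
        class over the masked (sample, site) entries."""
        P = self.predict_proba()
        hm = np.repeat(mask, 3).reshape(P.shape)
        sel = (self._Y > 0) & hm & (self._Wobs > 0)
        if not sel.any():
            raise ValueError("holdout mask covers no observed genotypes")
        return float(-np.mean(np.log(P[sel])))


def estimate_ancestry(
    gm: GenotypeMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    alpha: float = 10.0,
    n_init: int = 10,
    max_iter: int = 200,
) -> AncestryResult:
    """Fit the ancestry model at a fixed K (functional wrapper)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    d = gm.dosages if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    model = AncestryModel(
        K=K, alpha=alpha, n_init=n_init, max_iter=max_iter, random_state=seed
    ).fit(d)
    return AncestryResult(
        K=K, Q=model.Q_, G=model.G_, objective=model.objective_,
        converged=model.converged_,
    )


def choose_K(
    gm: GenotypeMatrix | np.ndarray,
    K_range=range(1, 6),
    holdout_fraction: float = 0.05,
    seed: int = 0,
    n_init: int = 3,
    max_iter: int = 150,
    alpha: float = 10.0,
) -> tuple[int, dict[int, float]]:
    """Select K by the masked cross-entropy criterion.

    Hides ``holdout_fraction`` of genotype entries, fits each candidate
    K on the remainder, and scores the hidden entries; the best K
    minimizes the cross-entropy.  Returns (best K, full curve).
    """
    d = gm.dosages if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    rng = np.random.default_rng(seed)
    mask = rng.random(d.shape) < holdout_fraction
    mask &= np.asarray(d) >= 0
    if mask.sum() < 10:
        raise ValueError("holdout too small to score; increase holdout_fraction")
    curve: dict[int, float] = {}
    for K in K_range:
        model = AncestryModel(
            K=K, alpha=alpha, n_init=n_init, max_iter=max_iter,
            random_state=int(rng.integers(2**31)),
        ).fit(d, holdout_mask=mask)
        curve[K] = model.cross_entropy(mask)
    best = min(curve, key=curve.get)
    return best, curve


def subcluster(
    gm: GenotypeMatrix,
    ancestry: AncestryResult,
    seed: int = 0,
    K_range=range(1, 6),
    min_cluster_size: int = 4,
    **fit_kwargs,
) -> dict[int, AncestryResult]:
    """Second-round ancestry estimation within each first-round cluster.

    Samples are assigned to clusters by their largest admixture
    coefficient; clusters smaller than ``min_cluster_size`` are skipped
    with a warning.
    """
    assign = ancestry.hard_assignment()
    out: dict[int, AncestryResult] = {}
    rng = np.random.default_rng(seed)
    for k in range(ancestry.K):
        members = np.flatnonzero(assign == k)
        if len(members) < min_cluster_size:
            warnings.warn(f"cluster {k} has {len(members)} samples; skipped")
            continue
        sub = gm.take_samples(members)
        k_range = [kk for kk in K_range if kk <= len(members)]
        s = int(rng.integers(2**31))
        best_k, _ = choose_K(sub, K_range=k_range, seed=s, **fit_kwargs)
        out[k] = estimate_ancestry(sub, best_k, seed=s)
    return out
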