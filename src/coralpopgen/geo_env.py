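"""Geographic / environmental distances and Mantel correlation tests.

Isolation by distance and by environment are assessed by correlating
linearized genetic distance FST/(1-FST) against great-circle geographic
distance between islands and Euclidean distance in a reduced
(PCA) temperature-descriptor space, using one-sided Mantel permutation
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "linearize_fst",
    "great_circle_km",
    "env_pca_distance",
    "mantel",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal.

    ``kind`` is one of ``genetic_linearized``, ``geographic_km``,
    ``environment_euclidean``.  Linearized genetic distances may carry
    small negative entries (negative FST estimates); they are retained
    and flagged via ``has_negative``.
    """

    labels: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal not zero")
        if self.has_negative and self.kind != "genetic_linearized":
            raise ValueError(f"negative distances not allowed for kind={self.kind}")

    @property
    def has_negative(self) -> bool:
        return bool((self.values < -1e-12).any())

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reindex(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int


def linearize_fst(fst: pd.DataFrame) -> DistanceMatrix:
    """Elementwise FST/(1-FST); errors on FST = 1 (infinite distance)."""
    vals = fst.to_numpy(dtype=np.float64)
    if np.any(vals >= 1.0):
        raise ValueError("FST of 1 cannot be linearized (infinite distance)")
    out = vals / (1.0 - vals)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(list(fst.index), out, "genetic_linearized")


def great_circle_km(coords: pd.DataFrame) -> DistanceMatrix:
    """Haversine distances (km) from a table with lat / lon columns in
    degrees, indexed by label."""
    lat = coords["lat"].to_numpy(dtype=np.float64)
    lon = coords["lon"].to_numpy(dtype=np.float64)
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude outside [-90, 90]")
    lon = (lon + 180.0) % 360.0 - 180.0
    if np.any(~np.isfinite(lat) | ~np.isfinite(lon)):
        raise ValueError("non-finite coordinates")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(np.sqrt(h), 1.0))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(coords.index), d, "geographic_km")


def island_coordinates(metadata: pd.DataFrame) -> pd.DataFrame:
    """Island coordinate = mean of its site coordinates."""
    return metadata.groupby("island")[["lat", "lon"]].mean()


def env_pca_distance(
    env: pd.DataFrame,
    variance_target: float = 0.80,
    max_pcs: int = 5,
    island_of: pd.Series | None = None,
) -> DistanceMatrix:
    """Euclidean distance on the leading PCs of standardized descriptors.

    Retains the smallest number of PCs reaching ``variance_target``
    cumulative explained variance, capped at ``max_pcs``.  Constant
    descriptor columns are dropped with a warning.  When ``island_of``
    maps site id -> island, site scores are averaged per island first
    and island-level distances are returned.
    """
    if env.isna().any().any():
        raise ValueError("environment table contains missing values")
    if len(env) < 2:
        raise ValueError("need at least 2 sites")
    sd = env.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"constant descriptor columns dropped: {constant}")
        env = env.drop(columns=constant)
        sd = sd.drop(constant)
    z = (env - env.mean()) / sd
    n_comp = min(len(env) - 1, z.shape[1])
    model = _SkPCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(z.to_numpy())
    cum = np.cumsum(model.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_keep = min(max(n_keep, 1), max_pcs, n_comp)
    scores = scores[:, :n_keep]
    frame = pd.DataFrame(scores, index=env.index)
    if island_of is not None:
        frame = frame.groupby(island_of.reindex(frame.index)).mean()
    x = frame.to_numpy()
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix([str(i) for i in frame.index], d, "environment_euclidean")


def mantel(
    x: DistanceMatrix,
    y: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
) -> MantelResult:
    """One-sided ("greater") Mantel permutation test.

    r is the Pearson correlation of the lower triangles; the p-value is
    ``(1 + #{permuted r >= observed}) / (1 + n_perm)`` under
    simultaneous row/column permutations of y.
    """
    if set(x.labels) != set(y.labels):
        raise ValueError("distance matrices have different labels")
    if len(x.labels) < 4:
        raise ValueError("need at least 4 labels for a Mantel test")
    y = y.reindex(x.labels)
    n = len(x.labels)
    iu, ju = np.triu_indices(n, k=1)
    a = x.values[iu, ju]
    ym = y.values
    b = ym[iu, ju]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance distance triangle")

    az = (a - a.mean()) / a.std()
    r_obs = float(np.mean(az * (b - b.mean()) / b.std()))

    if n_perm == 0:
        return MantelResult(r=r_obs, p=1.0, n_perm=0, seed=seed)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    bp = ym[perms[:, iu], perms[:, ju]]  # (n_perm, n_pairs)
    bz = bp - bp.mean(axis=1, keepdims=True)
    denom = bp.std(axis=1)
    r_perm = (bz / denom[:, None] * az[None, :]).mean(axis=1)
    p = (1.0 + np.sum(r_perm >= r_obs)) / (1.0 + n_perm)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, seed=seed)
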