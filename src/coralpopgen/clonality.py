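"""Clone (multilocus lineage) detection from pairwise genetic distances.

Clonal replicates — ramets of the same genet — show near-zero pairwise
genetic distance, well separated from the distances between distinct
genets.  The module computes Prevosti allele-sharing distances, locates
the gap between the clonal mode and the main mode of the distance
histogram, and merges samples below that threshold into multilocus
lineages (MLLs) by single linkage, keeping one ramet per genet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .variants import GenotypeMatrix

__all__ = [
    "pairwise_distance",
    "detect_threshold",
    "assign_mll",
    "ClonalPartition",
    "CloneDetector",
]


def pairwise_distance(gm: GenotypeMatrix) -> np.ndarray:
    """Prevosti allele-sharing distance matrix.

    d(i, j) = mean over co-typed sites of |dosage_i - dosage_j| / 2.
    Symmetric with zero diagonal.  Raises if a pair shares no typed site.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = gm.dosages
    typed = (d >= 0).astype(np.float64)
    # |a-b| over {0,1,2} decomposes into indicator cross-products.
    ind = [(d == v).astype(np.float64) for v in (0, 1, 2)]
    absdiff = (
        ind[0] @ ind[1].T + ind[1] @ ind[0].T
        + ind[1] @ ind[2].T + ind[2] @ ind[1].T
        + 2.0 * (ind[0] @ ind[2].T + ind[2] @ ind[0].T)
    )
    cotyped = typed @ typed.T
    off = ~np.eye(gm.n_samples, dtype=bool)
    if np.any(cotyped[off] == 0):
        raise ValueError("a sample pair shares no co-typed sites")
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = absdiff / (2.0 * cotyped)
    np.fill_diagonal(dist, 0.0)
    return dist


def detect_threshold(d: np.ndarray) -> float:
    """Clonal distance threshold from the gap in the distance histogram.

    A near-zero clonal mode is any pair below 10% of the median pairwise
    distance.  The threshold is the left edge of the first empty
    histogram bin (Freedman-Diaconis widths) after that mode; 0 when no
    clonal mode exists or all distances are equal.
    """
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    v = d[np.triu_indices(n, k=1)]
    if np.allclose(v, v[0]):
        warnings.warn("all pairwise distances equal; no clonal threshold")
        return 0.0
    med = np.median(v)
    clonal = v < 0.1 * med
    if not clonal.any():
        return 0.0
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    width = 2.0 * iqr / len(v) ** (1.0 / 3.0)
    if width <= 0:
        width = (v.max() - v.min()) / 50.0
    edges = np.arange(0.0, v.max() + 2 * width, width)
    counts, _ = np.histogram(v, bins=edges)
    clone_max = v[clonal].max()
    start_bin = int(np.searchsorted(edges, clone_max, side="right") - 1)
    for b in range(start_bin + 1, len(counts)):
        if counts[b] == 0:
            return float(edges[b])
    warnings.warn("no empty histogram bin after clonal mode; using midpoint")
    return float((clone_max + v[~clonal].min()) / 2.0)


@dataclass
class ClonalPartition:
    """Assignment of samples to multilocus lineages.

    ``mll_assignment`` maps sample id -> MLL id; ``representatives`` holds
    one sample (the lexicographically smallest id) per MLL.
    """

    threshold: float
    mll_assignment: dict[str, str]
    representatives: list[str]

    @property
    def n_mll(self) -> int:
        return len(self.representatives)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, m in self.mll_assignment.items():
            out.setdefault(m, []).append(s)
        return {m: sorted(v) for m, v in out.items()}


def assign_mll(d: np.ndarray, threshold: float, sample_ids: list[str]) -> ClonalPartition:
    """Single-linkage MLL assignment: connected components of the graph
    with an edge wherever distance <= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    adj = csr_matrix((d <= threshold).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=False)
    members: dict[int, list[str]] = {}
    for sid, lab in zip(sample_ids, labels):
        members.setdefault(int(lab), []).append(sid)
    reps = {lab: min(v) for lab, v in members.items()}
    order = sorted(reps.values())
    mll_of_rep = {rep: f"MLL{k + 1:03d}" for k, rep in enumerate(order)}
    assignment = {
        sid: mll_of_rep[reps[int(lab)]] for sid, lab in zip(sample_ids, labels)
    }
    return ClonalPartition(
        threshold=float(threshold),
        mll_assignment=assignment,
        representatives=sorted(reps.values()),
    )


class CloneDetector(BaseEstimator):
    """Estimator-style clone caller over a genotype matrix.

    Parameters
    ----------
    threshold : float or None
        Clonal distance cutoff.  ``None`` (default) detects it from the
        distance histogram gap.

    Attributes
    ----------
    threshold_ : float
        The cutoff used.
    partition_ : ClonalPartition
    labels_ : ndarray of str
        Per-sample MLL id, in input sample order.
    representatives_ : list of str
    """

    def __init__(self, threshold: float | None = None):
        self.threshold = threshold

    def fit(self, gm: GenotypeMatrix, y=None) -> "CloneDetector":
        d = pairwise_distance(gm)
        thr = detect_threshold(d) if self.threshold is None else self.threshold
        part = assign_mll(d, thr, gm.sample_ids)
        self.threshold_ = part.threshold
        self.partition_ = part
        self.labels_ = np.array([part.mll_assignment[s] for s in gm.sample_ids])
        self.representatives_ = part.representatives
        return self

    def fit_predict(self, gm: GenotypeMatrix, y=None) -> np.ndarray:
        return self.fit(gm).labels_

    def keep_one_ramet(self, gm: GenotypeMatrix) -> GenotypeMatrix:
        """Subset to one representative sample per MLL."""
        return gm.take_samples(self.representatives_)
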