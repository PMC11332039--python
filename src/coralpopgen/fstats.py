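"""f2 distances and f4 admixture statistics with block-jackknife errors.

Per-site estimators use sample allele frequencies with the standard
finite-sample bias correction: for allele count n (2 x diploids) and
frequency estimate p, E[p_hat(1-p_hat)] corrections of the form
p(1-p)/(n-1) are subtracted per population so that f2 is unbiased.
f4 is computed through its f2 representation

    f4(A,B;C,D) = (f2(A,D) + f2(B,C) - f2(A,C) - f2(B,D)) / 2,

which equals the familiar per-site product (pA-pB)(pC-pD) when the four
groups are distinct (the per-population corrections cancel) and remains
unbiased when labels repeat, so that f4(A,B;A,B) = f2(A,B) and
f4(A,B;C,C) = 0 hold exactly.

Standard errors come from a weighted delete-one-block jackknife over
contiguous blocks of SNPs; |Z| >= 3 is the conventional significance
flag for f4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import GenotypeMatrix

__all__ = ["FStatResult", "f2", "f4"]

Z_SIGNIFICANT = 3.0


@dataclass
class FStatResult:
    statistic: float
    se: float
    z: float
    n_sites: int
    n_blocks: int
    block_size: int
    populations: tuple[str, ...]

    @property
    def significant(self) -> bool:
        return abs(self.z) >= Z_SIGNIFICANT


def _freqs_and_counts(gm: GenotypeMatrix, groups, label):
    members = np.array([i for i, s in enumerate(gm.sample_ids) if groups.get(s) == label])
    if len(members) == 0:
        raise ValueError(f"group {label!r} has no samples")
    d = gm.dosages[members, :]
    typed = d >= 0
    n = 2.0 * typed.sum(axis=0)  # allele count
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(typed, d, 0).sum(axis=0) / np.maximum(n, 1e-300)
    return p, n


def _f2_per_site(pA, nA, pB, nB) -> np.ndarray:
    """Unbiased per-site f2 contributions."""
    return (
        (pA - pB) ** 2
        - pA * (1.0 - pA) / np.maximum(nA - 1.0, 1e-300)
        - pB * (1.0 - pB) / np.maximum(nB - 1.0, 1e-300)
    )


def _block_ids(n_sites: int, block_size: int) -> np.ndarray:
    return np.arange(n_sites) // block_size


def _jackknife(values: np.ndarray, blocks: np.ndarray) -> tuple[float, float, int]:
    """Weighted delete-one-block jackknife mean and SE (Busing et al.)."""
    n = len(values)
    total = values.sum()
    est = total / n
    uniq = np.unique(blocks)
    g = len(uniq)
    if g < 2:
        return est, np.nan, g
    block_sums = np.array([values[blocks == b].sum() for b in uniq])
    block_n = np.array([(blocks == b).sum() for b in uniq], dtype=float)
    loo = (total - block_sums) / (n - block_n)  # delete-one-block estimates
    h = n / block_n
    theta_j = g * est - np.sum((1.0 - block_n / n) * loo)
    tau = h * est - (h - 1.0) * loo
    var = np.mean((tau - theta_j) ** 2 / (h - 1.0))
    return est, float(np.sqrt(var)), g


def _finalize(per_site: np.ndarray, block_size: int, pops) -> FStatResult:
    n = len(per_site)
    if n == 0:
        raise ValueError("no co-typed sites for the requested groups")
    blocks = _block_ids(n, block_size)
    est, se, g = _jackknife(per_site, blocks)
    z = est / se if se and np.isfinite(se) and se > 0 else np.nan
    return FStatResult(
        statistic=float(est), se=float(se), z=float(z), n_sites=n,
        n_blocks=g, block_size=block_size, populations=tuple(pops),
    )


def f2(gm: GenotypeMatrix, groups, A: str, B: str, block_size: int = 500) -> FStatResult:
    """Bias-corrected f2 distance between groups A and B.

    Sites require at least two typed diploids (four alleles) in each
    group.  f2(A, A) is identically zero.
    """
    groups = pd.Series(groups)
    if A == B:
        n = gm.n_sites
        return FStatResult(0.0, 0.0, np.nan, n, 0, block_size, (A, B))
    pA, nA = _freqs_and_counts(gm, groups, A)
    pB, nB = _freqs_and_counts(gm, groups, B)
    ok = (nA >= 4) & (nB >= 4)
    return _finalize(_f2_per_site(pA, nA, pB, nB)[ok], block_size, (A, B))


def f4(
    gm: GenotypeMatrix,
    groups,
    A: str,
    B: str,
    C: str,
    D: str,
    block_size: int = 500,
) -> FStatResult:
    """f4(A,B;C,D) admixture statistic with block-jackknife Z.

    Positive values indicate allele sharing between (A,C) / (B,D)
    relative to (A,D) / (B,C); under the unadmixed tree (A,B),(C,D)
    the expectation is 0.
    """
    groups = pd.Series(groups)
    labels = (A, B, C, D)
    stats = {}
    for lab in set(labels):
        stats[lab] = _freqs_and_counts(gm, groups, lab)
    ok = np.ones(gm.n_sites, dtype=bool)
    for lab in set(labels):
        ok &= stats[lab][1] >= 4

    # aggregate coefficients per unordered pair so that repeated labels
    # cancel exactly (f4(A,B;C,C) is identically zero, not zero in the mean)
    coefs: dict[tuple[str, str], float] = {}
    for X, Y, w in ((A, D, 0.5), (B, C, 0.5), (A, C, -0.5), (B, D, -0.5)):
        if X == Y:
            continue
        key = (X, Y) if X <= Y else (Y, X)
        coefs[key] = coefs.get(key, 0.0) + w
    per_site = np.zeros(gm.n_sites)
    for (X, Y), w in coefs.items():
        if w == 0.0:
            continue
        pX, nX = stats[X]
        pY, nY = stats[Y]
        per_site = per_site + w * _f2_per_site(pX, nX, pY, nY)
    return _finalize(per_site[ok], block_size, labels)
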