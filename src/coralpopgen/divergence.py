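"""Weir-Cockerham FST: per-site components, 500 bp windows, genomic
islands of differentiation (GIDs), and genome-wide pairwise group FST.

The site-level estimator is the two-population Weir & Cockerham (1984)
variance-component decomposition into among-population (a),
among-individual-within-population (b) and within-individual (c)
components, computed from per-population allele frequencies and observed
heterozygosities of diploid genotypes.  Windowed and genome-wide values
aggregate the components as a ratio of sums, sum(a)/sum(a+b+c), the
standard low-bias aggregation for these components.  Negative site
estimates are retained (not clamped).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .variants import GenotypeMatrix

__all__ = [
    "wc_fst_site",
    "window_fst",
    "WindowFstTrack",
    "GidSet",
    "call_gids",
    "pairwise_group_fst",
]


def _group_site_summaries(gm: GenotypeMatrix, members: np.ndarray):
    """Per-site (n, p, h) for one group: diploid count, ALT frequency,
    observed heterozygosity, over non-missing calls."""
    d = gm.dosages[members, :]
    typed = d >= 0
    n = typed.sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(typed, d, 0).sum(axis=0) / np.maximum(2.0 * n, 1e-300)
        h = (d == 1).sum(axis=0) / np.maximum(n, 1e-300)
    return n, p, h


def wc_fst_site(
    gm: GenotypeMatrix,
    groups,
    pair: tuple[str, str],
) -> pd.DataFrame:
    """Per-site Weir-Cockerham components for one population pair.

    Parameters
    ----------
    gm
        Genotype matrix.
    groups
        Mapping / pandas Series from sample id to group label.
    pair
        The two group labels to compare.

    Returns
    -------
    DataFrame with columns ``contig, pos, a, b, c, theta, valid``.  Sites
    where either group has fewer than two typed genotypes are marked
    invalid (components NaN); sites with a+b+c == 0 have theta NaN.
    """
    groups = pd.Series(groups)
    idx = [
        np.array([i for i, s in enumerate(gm.sample_ids) if groups.get(s) == g])
        for g in pair
    ]
    if any(len(i) == 0 for i in idx):
        raise ValueError(f"empty group in pair {pair}")
    n1, p1, h1 = _group_site_summaries(gm, idx[0])
    n2, p2, h2 = _group_site_summaries(gm, idx[1])
    a, b, c, valid = _wc_components(n1, p1, h1, n2, p2, h2)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    return pd.DataFrame(
        {
            "contig": gm.contigs,
            "pos": gm.positions,
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
            "valid": valid,
        }
    )


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Vectorized Weir & Cockerham (1984) a, b, c for r=2 populations."""
    r = 2.0
    valid = (n1 >= 2) & (n2 >= 2)
    n1 = np.maximum(n1, 2.0)  # placeholder for invalid sites, masked below
    n2 = np.maximum(n2, 2.0)
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
    with np.errstate(invalid="ignore", divide="ignore"):
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c, valid


@dataclass
class WindowFstTrack:
    """Non-overlapping 500 bp bins with per-pair and mean-across-pairs FST.

    ``windows`` columns: contig, start, end (0-based half-open),
    ``n_snps``, one ``fst_<A>__<B>`` column per lineage pair, and
    ``mean_fst`` (unweighted mean over pairs).  Windows without SNPs are
    excluded.
    """

    windows: pd.DataFrame
    pair_columns: list[str]
    window_bp: int


def window_fst(
    gm: GenotypeMatrix,
    groups,
    window_bp: int = 500,
    pairs: list[tuple[str, str]] | None = None,
) -> WindowFstTrack:
    """Bin per-site WC components into non-overlapping windows.

    The window value is the ratio of summed components over the SNPs in
    the bin; the among-lineage mean is the unweighted mean of the
    pairwise window values.
    """
    groups = pd.Series(groups)
    if pairs is None:
        labels = sorted(set(groups.loc[groups.index.intersection(gm.sample_ids)]))
        pairs = list(combinations(labels, 2))
    site_tables = {pair: wc_fst_site(gm, groups, pair) for pair in pairs}

    bin_idx = (gm.positions - 1) // window_bp
    keys = pd.DataFrame({"contig": gm.contigs, "bin": bin_idx})
    grouped = keys.groupby(["contig", "bin"], sort=True).indices

    rows = []
    for (ctg, b), site_ix in grouped.items():
        row: dict = {
            "contig": ctg,
            "start": int(b) * window_bp,
            "end": (int(b) + 1) * window_bp,
        }
        vals = []
        n_snps = 0
        for pair, tab in site_tables.items():
            sub = tab.iloc[site_ix]
            ok = sub["valid"].to_numpy()
            n_snps = max(n_snps, int(ok.sum()))
            denom = (sub["a"] + sub["b"] + sub["c"]).to_numpy()[ok].sum()
            num = sub["a"].to_numpy()[ok].sum()
            v = num / denom if ok.any() and denom != 0 else np.nan
            row[f"fst_{pair[0]}__{pair[1]}"] = v
            vals.append(v)
        row["n_snps"] = n_snps
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            row["mean_fst"] = np.nanmean(vals) if len(vals) else np.nan
        if n_snps > 0:
            rows.append(row)
    cols = ["contig", "start", "end", "n_snps"] + [
        f"fst_{a}__{b}" for a, b in pairs
    ] + ["mean_fst"]
    windows = pd.DataFrame(rows, columns=cols)
    return WindowFstTrack(
        windows=windows,
        pair_columns=[f"fst_{a}__{b}" for a, b in pairs],
        window_bp=window_bp,
    )


@dataclass
class GidSet:
    """Genomic islands of differentiation: the top-quantile windows by
    mean among-lineage FST."""

    gid_windows: pd.DataFrame  # subset of the track's windows
    quantile: float

    def contains(self, contig: str, pos: int) -> bool:
        """1-based position membership (windows are 0-based half-open)."""
        w = self.gid_windows
        hit = w[(w["contig"] == contig) & (w["start"] <= pos - 1) & (pos - 1 < w["end"])]
        return len(hit) > 0


def call_gids(track: WindowFstTrack, quantile: float = 0.01) -> GidSet:
    """Top ``ceil(quantile * W)`` windows by mean among-lineage FST.

    Ties at the cut are broken by (contig, start) ascending so that
    exactly the target count is kept.
    """
    w = track.windows[track.windows["n_snps"] >= 1].copy()
    if len(w) == 0:
        raise ValueError("empty window track")
    if len(w) < 100:
        warnings.warn("fewer than 100 windows; GID quantile is coarse")
    n_gid = math.ceil(quantile * len(w))
    w = w.sort_values(
        ["mean_fst", "contig", "start"], ascending=[False, True, True]
    )
    return GidSet(gid_windows=w.head(n_gid).reset_index(drop=True), quantile=quantile)


def pairwise_group_fst(gm: GenotypeMatrix, groups, min_samples: int = 2) -> pd.DataFrame:
    """Genome-wide ratio-of-sums WC FST for every pair of groups.

    Groups with fewer than ``min_samples`` samples are dropped with a
    warning.  Returns a symmetric labeled matrix with zero diagonal.
    """
    groups = pd.Series(groups)
    labels = sorted(set(groups.loc[groups.index.intersection(gm.sample_ids)]))
    sizes = {
        g: sum(1 for s in gm.sample_ids if groups.get(s) == g) for g in labels
    }
    usable = [g for g in labels if sizes[g] >= min_samples]
    dropped = [g for g in labels if g not in usable]
    if dropped:
        warnings.warn(f"groups dropped (<{min_samples} samples): {dropped}")
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable groups")
    mat = pd.DataFrame(0.0, index=usable, columns=usable)
    summaries = {}
    for g in usable:
        members = np.array([i for i, s in enumerate(gm.sample_ids) if groups.get(s) == g])
        summaries[g] = _group_site_summaries(gm, members)
    for g1, g2 in combinations(usable, 2):
        n1, p1, h1 = summaries[g1]
        n2, p2, h2 = summaries[g2]
        a, b, c, valid = _wc_components(n1, p1, h1, n2, p2, h2)
        num = np.nansum(np.where(valid, a, np.nan))
        den = np.nansum(np.where(valid, a + b + c, np.nan))
        theta = num / den if den != 0 else np.nan
        mat.loc[g1, g2] = theta
        mat.loc[g2, g1] = theta
    return mat
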