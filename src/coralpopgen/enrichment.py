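"""Synthesis of temperature outliers, genomic islands, and selection calls.

Joins the per-SNP RDA outlier table, GID window membership, and
divergent-selection calls into the headline enrichment report: what
fraction of SNPs are temperature-associated, how many of the top-100
outliers sit in genomic islands of differentiation, and whether
selection is enriched among them relative to the genome-wide baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .divergence import GidSet

__all__ = ["percent", "snp_in_window", "EnrichmentReport", "build_report"]


def percent(count: int, denominator: int) -> float:
    """100 * count / denominator rounded half-up to 2 decimals."""
    if denominator == 0:
        raise ValueError("zero denominator")
    frac = Decimal(count) * 100 / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def snp_in_window(positions, windows: pd.DataFrame, contigs=None) -> np.ndarray:
    """Membership of 1-based SNP positions in 0-based half-open windows.

    A SNP at position P is inside [s, e) iff s <= P-1 < e.  Windows must
    be sorted and non-overlapping within each contig.
    """
    windows = windows.reset_index(drop=True)
    positions = np.asarray(positions)
    if contigs is None:
        contigs = np.array([""] * len(positions), dtype=object)
        wctg = np.array([""] * len(windows), dtype=object)
    else:
        contigs = np.asarray(contigs, dtype=object)
        wctg = windows["contig"].to_numpy()
    out = np.zeros(len(positions), dtype=bool)
    for ctg in dict.fromkeys(wctg):
        w = windows[wctg == ctg].sort_values("start")
        starts = w["start"].to_numpy()
        ends = w["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping windows on {ctg!r}")
        sel = contigs == ctg
        x = positions[sel] - 1
        k = np.searchsorted(starts, x, side="right") - 1
        ok = (k >= 0) & (x < ends[np.clip(k, 0, len(ends) - 1)])
        out[sel] = ok
    return out


@dataclass
class EnrichmentReport:
    n_snps: int
    n_outliers: int
    outlier_percent: float
    n_top100: int
    n_top100_in_gid: int
    n_top100_selected: int
    n_top100_in_gid_selected: int
    genome_fraction_selected: float
    enrichment_top100_selected: float
    enrichment_top100_in_gid_selected: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])

    def to_text(self) -> str:
        f = self
        ratio1 = "n/a" if np.isnan(f.enrichment_top100_selected) else f"{f.enrichment_top100_selected:.2f}x"
        ratio2 = "n/a" if np.isnan(f.enrichment_top100_in_gid_selected) else f"{f.enrichment_top100_in_gid_selected:.2f}x"
        pct = lambda c, d: f"{percent(c, d):.2f}%" if d else "n/a"
        return (
            "Temperature-outlier / GID / selection enrichment\n"
            "(outlier percent uses the unlinked SNP total as denominator)\n"
            f"  SNPs tested:                 {f.n_snps}\n"
            f"  outliers (q<0.1):            {f.n_outliers} ({f.outlier_percent:.2f}%)\n"
            f"  top outliers considered:     {f.n_top100}\n"
            f"  ... in GIDs:                 {f.n_top100_in_gid} ({pct(f.n_top100_in_gid, f.n_top100)})\n"
            f"  ... under divergent sel.:    {f.n_top100_selected} ({pct(f.n_top100_selected, f.n_top100)})\n"
            f"  ... in GIDs and selected:    {f.n_top100_in_gid_selected}"
            f" ({pct(f.n_top100_in_gid_selected, f.n_top100_in_gid) if f.n_top100_in_gid else 'n/a'} of GID outliers)\n"
            f"  genome under divergent sel.: {100 * f.genome_fraction_selected:.2f}%\n"
            f"  enrichment (top outliers selected vs genome):        {ratio1}\n"
            f"  enrichment (GID outliers selected vs genome):        {ratio2}\n"
        )


def build_report(
    outliers: pd.DataFrame,
    gids: GidSet | pd.DataFrame,
    selected: np.ndarray,
) -> EnrichmentReport:
    """Assemble the enrichment report.

    Parameters
    ----------
    outliers
        Per-SNP RDA table with contig, pos, q, is_outlier, is_top100.
    gids
        GID windows (``GidSet`` or its window frame).
    selected
        Boolean divergent-selection flag per SNP, aligned with
        ``outliers`` rows.
    """
    selected = np.asarray(selected, dtype=bool)
    if len(selected) != len(outliers):
        raise ValueError(
            f"selection flags ({len(selected)}) do not match SNP table ({len(outliers)})"
        )
    windows = gids.gid_windows if isinstance(gids, GidSet) else gids
    in_gid = snp_in_window(
        outliers["pos"].to_numpy(), windows, outliers["contig"].to_numpy()
    )
    top = outliers["is_top100"].to_numpy()
    n = len(outliers)
    n_out = int(outliers["is_outlier"].sum())
    n_top = int(top.sum())
    n_top_gid = int((top & in_gid).sum())
    n_top_sel = int((top & selected).sum())
    n_top_gid_sel = int((top & in_gid & selected).sum())
    genome_frac = float(selected.mean())
    frac_top_sel = n_top_sel / n_top if n_top else np.nan
    frac_gid_sel = n_top_gid_sel / n_top_gid if n_top_gid else np.nan
    return EnrichmentReport(
        n_snps=n,
        n_outliers=n_out,
        outlier_percent=percent(n_out, n),
        n_top100=n_top,
        n_top100_in_gid=n_top_gid,
        n_top100_selected=n_top_sel,
        n_top100_in_gid_selected=n_top_gid_sel,
        genome_fraction_selected=genome_frac,
        enrichment_top100_selected=(
            frac_top_sel / genome_frac if genome_frac > 0 else np.nan
        ),
        enrichment_top100_in_gid_selected=(
            frac_gid_sel / genome_frac if genome_frac > 0 else np.nan
        ),
    )
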