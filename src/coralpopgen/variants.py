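"""Genotype container, VCF input/output, site filters, and LD pruning.

The central object of the pipeline is :class:`GenotypeMatrix`, a dense
samples x sites matrix of diploid alternate-allele dosages over
``{0, 1, 2, MISSING}`` for biallelic SNPs, together with the per-site
coordinates (contig, 1-based position) and site quality scores.

Filtering reproduces a standard short-variant curation chain: keep
biallelic SNPs with minor allele frequency >= 0.05, site quality >= 30
and no missing calls, then discard variants in linkage disequilibrium
(r^2 >= 0.2) within a sliding window of 1000 sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "FilterSpec",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "apply_site_filters",
    "ld_prune",
]


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted as a diploid biallelic GT."""


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with site coordinates.

    Parameters
    ----------
    dosages
        ``(n_samples, n_sites)`` int8 array of ALT-allele counts; ``-1``
        marks a missing call.
    sample_ids
        Ordered sample identifiers (length ``n_samples``).
    contigs
        Per-site contig name (length ``n_sites``).
    positions
        Per-site 1-based position, strictly increasing within a contig.
    qual
        Per-site quality score (float; NaN when absent).
    """

    dosages: np.ndarray
    sample_ids: list[str]
    contigs: np.ndarray
    positions: np.ndarray
    qual: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.contigs = np.asarray(self.contigs, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.qual = np.asarray(self.qual, dtype=np.float64)
        n, s = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if not (len(self.contigs) == len(self.positions) == len(self.qual) == s):
            raise ValueError("site annotation lengths do not match dosage columns")
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, -1}")
        for ctg in np.unique(self.contigs):
            pos = self.positions[self.contigs == ctg]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {ctg}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def dosages_float(self) -> np.ndarray:
        """Dosages as float64 with missing calls as NaN."""
        x = self.dosages.astype(np.float64)
        x[self.dosages == MISSING] = np.nan
        return x

    def allele_frequencies(self) -> np.ndarray:
        """Per-site ALT allele frequency over non-missing calls."""
        x = self.dosages_float()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(x, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.sample_ids),
            self.contigs[idx],
            self.positions[idx],
            self.qual[idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        if len(idx) and isinstance(next(iter(idx)), str):
            order = {s: i for i, s in enumerate(self.sample_ids)}
            idx = [order[s] for s in idx]
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            self.dosages[idx, :],
            [self.sample_ids[i] for i in idx],
            self.contigs,
            self.positions,
            self.qual,
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(),
            list(self.sample_ids),
            self.contigs.copy(),
            self.positions.copy(),
            self.qual.copy(),
        )


@dataclass(frozen=True)
class FilterSpec:
    """Site-filter and LD-pruning thresholds.

    Defaults follow the curation used throughout the pipeline: MAF >= 0.05
    (inclusive), QUAL >= 30, no missing data, and r^2 >= 0.2 pruning in a
    1000-site window.
    """

    min_maf: float = 0.05
    min_qual: float = 30.0
    max_missing_fraction: float = 0.0
    ld_r2_max: float = 0.2
    ld_window_sites: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if not 0.0 <= self.ld_r2_max <= 1.0:
            raise ValueError("ld_r2_max must be in [0, 1]")
        if self.ld_window_sites < 1:
            raise ValueError("ld_window_sites must be >= 1")


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

_GT_TYPE_TO_DOSAGE = {0: 0, 1: 1, 3: 2, 2: MISSING}  # cyvcf2 gt_types codes


def read_vcf(path) -> tuple[GenotypeMatrix, int]:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records and non-SNP records (REF/ALT longer than one
    base) are excluded; their count is returned alongside the matrix.

    Returns
    -------
    (GenotypeMatrix, int)
        The genotype matrix and the number of excluded records.
    """
    from cyvcf2 import VCF

    try:
        reader = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    sample_ids = list(reader.samples)
    rows: list[np.ndarray] = []
    contigs: list[str] = []
    positions: list[int] = []
    quals: list[float] = []
    excluded = 0
    for var in reader:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            excluded += 1
            continue
        try:
            dos = np.array(
                [_GT_TYPE_TO_DOSAGE[int(t)] for t in var.gt_types], dtype=np.int8
            )
        except KeyError as exc:
            raise VcfParseError(
                f"unrecognized genotype at {var.CHROM}:{var.POS}"
            ) from exc
        rows.append(dos)
        contigs.append(var.CHROM)
        positions.append(var.POS)
        quals.append(np.nan if var.QUAL is None else float(var.QUAL))
    if rows:
        dosages = np.stack(rows, axis=1)
    else:
        dosages = np.zeros((len(sample_ids), 0), dtype=np.int8)
    gm = GenotypeMatrix(
        dosages, sample_ids, np.array(contigs, dtype=object),
        np.array(positions, dtype=np.int64), np.array(quals, dtype=np.float64),
    )
    return gm, excluded


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 (REF=A, ALT=T, FILTER=PASS, FORMAT=GT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=coralpopgen\n")
        for ctg in dict.fromkeys(gm.contigs):  # preserve order
            fh.write(f"##contig=<ID={ctg}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_sites):
            q = gm.qual[j]
            qstr = "." if np.isnan(q) else f"{q:.6g}"
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in gm.dosages[:, j])
            fh.write(
                f"{gm.contigs[j]}\t{gm.positions[j]}\t.\tA\tT\t{qstr}\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

def apply_site_filters(gm: GenotypeMatrix, spec: FilterSpec = FilterSpec()) -> GenotypeMatrix:
    """Keep sites with MAF >= min_maf, QUAL >= min_qual and missingness
    <= max_missing_fraction (all boundaries inclusive); site order preserved.
    """
    if gm.n_sites == 0:
        return gm.copy()
    maf = gm.minor_allele_frequencies()
    miss = gm.missing_mask().mean(axis=0)
    with np.errstate(invalid="ignore"):
        keep = (
            (np.nan_to_num(maf, nan=-1.0) >= spec.min_maf)
            & (gm.qual >= spec.min_qual)
            & (miss <= spec.max_missing_fraction)
        )
    if not keep.any():
        warnings.warn("all sites removed by filters; returning empty matrix")
    return gm.take_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _standardize_columns(x: np.ndarray) -> np.ndarray:
    """Column z-scores; monomorphic columns become all-zero (r^2 := 0)."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    z = np.zeros_like(x)
    ok = sd > 0
    z[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return z

def _pairwise_complete_r2(x: np.ndarray, i: int, j: int) -> float:
    both = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
    if both.sum() < 2:
        return 0.0
    a, b = x[both, i], x[both, j]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ld_prune(gm: GenotypeMatrix, spec: FilterSpec = FilterSpec()) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning within each contig.

    A candidate site is discarded when its squared Pearson dosage
    correlation with any of the previous ``ld_window_sites - 1``
    *retained* sites reaches ``ld_r2_max``; otherwise it is retained
    (the earlier site of an offending pair always survives).  Counting
    the window over retained sites makes the pass idempotent.  Missing
    data are handled pairwise-complete; r^2 against a monomorphic site
    is 0.
    """
    keep_global = np.zeros(gm.n_sites, dtype=bool)
    window = spec.ld_window_sites
    thr = spec.ld_r2_max
    x = gm.dosages_float()
    has_missing = np.isnan(x).any()
    n = gm.n_samples
    for ctg in dict.fromkeys(gm.contigs):
        cols = np.flatnonzero(gm.contigs == ctg)
        s = len(cols)
        kept_local: list[int] = []
        if has_missing:
            xc = x[:, cols]
            for j in range(s):
                prior = kept_local[-(window - 1):] if window > 1 else []
                if any(_pairwise_complete_r2(xc, i, j) >= thr for i in prior):
                    continue
                kept_local.append(j)
        else:
            z = _standardize_columns(x[:, cols])
            zkept = np.empty_like(z)  # kept columns, in order
            for j in range(s):
                w0 = max(0, len(kept_local) - (window - 1))
                ctx = zkept[:, w0 : len(kept_local)]
                if ctx.shape[1] and window > 1:
                    r2 = (ctx.T @ z[:, j] / n) ** 2
                    if np.any(r2 >= thr):
                        continue
                zkept[:, len(kept_local)] = z[:, j]
                kept_local.append(j)
        keep_global[cols[kept_local]] = True
    return gm.take_sites(np.flatnonzero(keep_global))
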