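import numpy as np
import pytest

from coralpopgen.variants import (
    MISSING,
    FilterSpec,
    apply_site_filters,
    ld_prune,
    read_vcf,
    write_vcf,
)
from conftest import make_gm


# ---------------------------------------------------------------------------
# VCF round trip
# ---------------------------------------------------------------------------

def test_vcf_round_trip(tmp_path, small_survey):
    _, gm, *_ = small_survey
    path = tmp_path / "survey.vcf"
    write_vcf(gm, path)
    back, excluded = read_vcf(path)
    assert excluded == 0
    assert back.sample_ids == gm.sample_ids
    np.testing.assert_array_equal(back.dosages, gm.dosages)
    np.testing.assert_array_equal(back.positions, gm.positions)
    np.testing.assert_allclose(back.qual, gm.qual, rtol=1e-5)


def test_read_vcf_dosages_and_multiallelic_exclusion(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=c1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
        "c1\t10\t.\tA\tT\t40\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "c1\t20\t.\tA\tT,G\t40\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "c1\t30\t.\tA\tT\t40\tPASS\t.\tGT\t./.\t0/1\t1/1\n"
    )
    gm, excluded = read_vcf(vcf)
    assert excluded == 1
    assert gm.n_sites == 2
    np.testing.assert_array_equal(gm.dosages[:, 0], [0, 1, 2])
    np.testing.assert_array_equal(gm.dosages[:, 1], [MISSING, 1, 2])


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

def test_maf_boundary_inclusive():
    # 10 diploids, ALT count 1/20 -> MAF exactly 0.05: kept
    d = np.zeros((10, 1), dtype=np.int8)
    d[0, 0] = 1
    gm = make_gm(d)
    out = apply_site_filters(gm, FilterSpec())
    assert out.n_sites == 1
    # ALT count 0 -> MAF 0: removed
    gm0 = make_gm(np.zeros((10, 1), dtype=np.int8))
    with pytest.warns(UserWarning):
        assert apply_site_filters(gm0, FilterSpec()).n_sites == 0


def test_qual_boundary():
    d = np.array([[0], [1], [1], [2]], dtype=np.int8)
    kept = apply_site_filters(make_gm(d, qual=[30.0]), FilterSpec())
    removed = apply_site_filters(make_gm(d, qual=[29.9]), FilterSpec())
    assert kept.n_sites == 1
    assert removed.n_sites == 0


def test_missingness_removes_site_at_zero_tolerance():
    d = np.array([[0, 0], [1, 1], [MISSING, 1], [2, 2]], dtype=np.int8)
    out = apply_site_filters(make_gm(d), FilterSpec())
    assert out.n_sites == 1
    assert out.positions[0] == 2


def test_filters_idempotent_and_order_insensitive(small_survey):
    _, gm, *_ = small_survey
    spec = FilterSpec()
    once = apply_site_filters(gm, spec)
    twice = apply_site_filters(once, spec)
    np.testing.assert_array_equal(once.dosages, twice.dosages)
    # independent criteria applied separately, in either order
    maf_only = FilterSpec(min_maf=0.05, min_qual=0.0, max_missing_fraction=1.0)
    qual_only = FilterSpec(min_maf=0.0, min_qual=30.0, max_missing_fraction=1.0)
    ab = apply_site_filters(apply_site_filters(gm, maf_only), qual_only)
    ba = apply_site_filters(apply_site_filters(gm, qual_only), maf_only)
    np.testing.assert_array_equal(ab.positions, ba.positions)
    np.testing.assert_array_equal(ab.positions, once.positions)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def brute_force_prune(gm, r2_max, window):
    """Nested-loop greedy reference: candidate vs the last window-1
    retained sites of its contig."""
    x = gm.dosages.astype(float)
    kept: list[int] = []
    by_contig = {}
    for j in range(gm.n_sites):
        by_contig.setdefault(gm.contigs[j], []).append(j)
    for cols in by_contig.values():
        local_kept = []
        for j in cols:
            drop = False
            for i in local_kept[-(window - 1):] if window > 1 else []:
                a, b = x[:, i], x[:, j]
                if a.std() == 0 or b.std() == 0:
                    r2 = 0.0
                else:
                    r2 = np.corrcoef(a, b)[0, 1] ** 2
                if r2 >= r2_max:
                    drop = True
                    break
            if not drop:
                local_kept.append(j)
        kept.extend(local_kept)
    return sorted(kept)


def test_identical_columns_pruned():
    col = np.array([0, 1, 2, 0, 1, 2], dtype=np.int8)
    gm = make_gm(np.stack([col, col], axis=1))
    out = ld_prune(gm, FilterSpec())
    assert out.n_sites == 1
    assert out.positions[0] == 1  # earlier site kept


def test_uncorrelated_columns_kept():
    # orthogonal dosage patterns: r^2 = 0 exactly
    a = np.array([0, 0, 2, 2, 0, 0, 2, 2], dtype=np.int8)
    b = np.array([0, 2, 0, 2, 2, 0, 2, 0], dtype=np.int8)
    assert abs(np.corrcoef(a, b)[0, 1]) < 1e-12
    gm = make_gm(np.stack([a, b], axis=1))
    assert ld_prune(gm, FilterSpec()).n_sites == 2


@pytest.mark.parametrize("seed,window", [(0, 1000), (1, 50), (2, 7)])
def test_prune_matches_brute_force(seed, window):
    rng = np.random.default_rng(seed)
    n, s = 30, 400
    # correlated blocks: duplicate and jitter columns to create LD
    base = rng.integers(0, 3, (n, s // 4))
    x = np.repeat(base, 4, axis=1)
    flip = rng.random(x.shape) < 0.25
    x = np.where(flip, rng.integers(0, 3, x.shape), x).astype(np.int8)
    contigs = ["c1"] * (s // 2) + ["c2"] * (s - s // 2)
    gm = make_gm(x, contigs=contigs, positions=list(range(1, s // 2 + 1)) * 2)
    spec = FilterSpec(ld_r2_max=0.2, ld_window_sites=window)
    got = ld_prune(gm, spec)
    expected = brute_force_prune(gm, spec.ld_r2_max, spec.ld_window_sites)
    np.testing.assert_array_equal(
        np.sort(np.concatenate([np.flatnonzero(gm.contigs == c)[
            np.isin(gm.positions[gm.contigs == c], got.positions[got.contigs == c])
        ] for c in ("c1", "c2")])),
        expected,
    )
    # idempotence
    again = ld_prune(got, spec)
    np.testing.assert_array_equal(again.dosages, got.dosages)


def test_prune_pairwise_complete_with_missing():
    col = np.array([0, 1, 2, 0, 1, 2, 0, 1], dtype=np.int8)
    col2 = col.copy()
    col2[0] = MISSING  # still near-perfectly correlated on complete pairs
    gm = make_gm(np.stack([col, col2], axis=1))
    assert ld_prune(gm, FilterSpec()).n_sites == 1
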