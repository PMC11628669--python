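"""Genotype container, file round trips, filters, karyotype handling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyorda import (KARYOTYPE_ID, MISSING, append_karyotype,
                      filter_coverage, filter_maf, impute_missing,
                      minor_allele_frequency, read_012, read_vcf,
                      subsample_one_per_cytotype, write_012, write_vcf)
from karyorda.data import GenotypeMatrix

from conftest import make_genotypes, make_samples

# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def _write_vcf_text(tmp_path, body, samples=("A", "B", "C")):
    path = tmp_path / "in.vcf"
    head = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" \
        + "\t".join(samples) + "\n"
    path.write_text(VCF_HEADER + head + body)
    return path


def test_vcf_direct_encoding(tmp_path):
    """0/0, 0/1, 1/1 become 0, 1, 2 when the alt allele is the minor one."""
    path = _write_vcf_text(
        tmp_path, "chr1\t100\tsnp1\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
    g = read_vcf(path)
    assert list(g.values[:, 0]) == [0, 1, 2]
    assert g.locus_map.loc[0, "position"] == 100


def test_vcf_minor_allele_reorientation(tmp_path):
    """A site where the alt allele is the major one gets flipped so counts
    refer to the rarer (ref) allele."""
    body = "chr1\t100\tsnp1\tA\tT\t.\tPASS\t.\tGT\t1/1\t1/1\t1/1\t0/1\t1/1\n"
    path = _write_vcf_text(tmp_path, body, samples=list("ABCDE"))
    g = read_vcf(path)  # alt freq 0.9 -> flip
    assert list(g.values[:, 0]) == [0, 0, 0, 1, 0]


def test_vcf_multiallelic_dropped_and_missing(tmp_path):
    body = (
        "chr1\t100\tsnp1\tA\tT\t.\tPASS\t.\tGT\t0/0\t./.\t1/1\n"
        "chr1\t200\tsnp2\tA\tT,G\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
    )
    g = read_vcf(_write_vcf_text(tmp_path, body))
    assert g.n_loci == 1
    assert g.values[1, 0] == MISSING


def test_vcf_roundtrip_through_writer(tmp_path):
    rng = np.random.default_rng(3)
    vals = rng.integers(0, 3, size=(10, 5)).astype(np.int8)
    vals[rng.random(vals.shape) < 0.2] = MISSING
    # write_vcf emits alt dosage; the reader may flip alt-major columns,
    # so fold both to minor orientation before comparing
    g = make_genotypes(vals)
    write_vcf(g, tmp_path / "rt.vcf")
    g2 = read_vcf(tmp_path / "rt.vcf")
    for j in range(5):
        a, b = vals[:, j], g2.values[:, j]
        same = np.array_equal(a, b)
        called = a != MISSING
        flipped = np.array_equal(np.where(called, 2 - a, MISSING), b)
        assert same or flipped


def test_012_roundtrip_identity(tmp_path):
    """A 10-sample, 5-locus 012 file round-trips to an identical matrix."""
    rng = np.random.default_rng(1)
    vals = rng.integers(0, 3, size=(10, 5)).astype(np.int16)
    vals[rng.random(vals.shape) < 0.3] = MISSING
    g = make_genotypes(vals)
    write_012(g, tmp_path / "m.tsv", tmp_path / "l.tsv")
    g2 = read_012(tmp_path / "m.tsv", tmp_path / "l.tsv")
    assert np.array_equal(g.values, g2.values)
    assert g2.sample_ids == g.sample_ids
    pd.testing.assert_frame_equal(g.locus_map, g2.locus_map)


def test_012_karyotype_column_flag_roundtrips(tmp_path):
    g = make_genotypes([[0, 1], [2, 0], [1, 1]])
    s = make_samples(3, two_n=[70, 72, 74])
    gk = append_karyotype(g, s)
    write_012(gk, tmp_path / "m.tsv", tmp_path / "l.tsv")
    g2 = read_012(tmp_path / "m.tsv", tmp_path / "l.tsv")
    assert g2.karyotype_col == gk.karyotype_col
    assert np.array_equal(g2.values, gk.values)


def test_malformed_and_empty_inputs(tmp_path):
    (tmp_path / "bad.tsv").write_text("sample_id\tL1\n")
    (tmp_path / "loci.tsv").write_text("locus_id\tcontig\tposition\nL1\tc\t1\n")
    with pytest.raises(ValueError, match="zero samples"):
        read_012(tmp_path / "bad.tsv", tmp_path / "loci.tsv")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def test_coverage_filter_keeps_min_called_boundary():
    """A locus called in exactly min_called samples is retained."""
    rng = np.random.default_rng(0)
    vals = rng.integers(0, 3, size=(153, 3)).astype(np.int8)
    vals[100:, 0] = MISSING          # 100 of 153 called -> kept at 100
    vals[:, 1] = MISSING             # fully missing -> dropped
    g = filter_coverage(make_genotypes(vals), min_called=100)
    assert g.locus_ids == ["L1", "L3"]


def test_coverage_filter_matches_brute_force():
    rng = np.random.default_rng(42)
    vals = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
    vals[rng.random(vals.shape) < 0.4] = MISSING
    g = make_genotypes(vals)
    for min_called in (1, 5, 10, 15, 20):
        kept = set(filter_coverage(g, min_called).locus_ids)
        expect = {f"L{j + 1}" for j in range(50)
                  if sum(vals[i, j] != MISSING for i in range(20)) >= min_called}
        assert kept == expect


def test_maf_filter_examples():
    # 10 samples, one het, rest hom-major: MAF 0.05 -> dropped at 0.10
    low = np.zeros((10, 1), dtype=np.int8)
    low[0, 0] = 1
    mono = np.zeros((10, 1), dtype=np.int8)
    common = np.tile([0, 1], 5).reshape(10, 1).astype(np.int8)
    g = make_genotypes(np.hstack([low, mono, common]))
    kept = filter_maf(g, 0.10)
    assert kept.locus_ids == ["L3"]


def test_maf_threshold_sweep_recovers_cutoff():
    """Columns swept over known MAFs: minimum retained MAF == threshold."""
    n = 40
    cols, mafs = [], []
    for k in range(0, 21):  # MAF = k/40 in 0..0.5
        col = np.zeros(n, dtype=np.int8)
        col[:k] = 2
        cols.append(col)
        mafs.append(k / n)
    g = make_genotypes(np.column_stack(cols))
    mafs = np.array(mafs)
    for thr in (0.05, 0.10, 0.25):
        kept = filter_maf(g, thr)
        kept_mafs = mafs[[int(l[1:]) - 1 for l in kept.locus_ids]]
        assert kept_mafs.min() >= thr
        assert np.isclose(kept_mafs.min(), thr)  # boundary column retained
        dropped = sorted(set(g.locus_ids) - set(kept.locus_ids))
        assert all(mafs[int(l[1:]) - 1] < thr for l in dropped)


def test_maf_computed_on_called_genotypes_only():
    col = np.array([1, 1, MISSING, MISSING, MISSING, MISSING, 0, 0, 0, 0],
                   dtype=np.int8).reshape(-1, 1)
    g = make_genotypes(col)
    assert np.isclose(minor_allele_frequency(g)[0], 2 / 12)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_filter_order_stability(seed):
    """Coverage-then-MAF equals MAF-then-coverage (MAF uses called only)."""
    rng = np.random.default_rng(seed)
    vals = rng.integers(0, 3, size=(15, 20)).astype(np.int8)
    vals[rng.random(vals.shape) < 0.3] = MISSING
    g = make_genotypes(vals)
    a = filter_maf(filter_coverage(g, 8), 0.1)
    b = filter_coverage(filter_maf(g, 0.1), 8)
    assert a.locus_ids == b.locus_ids


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def test_impute_mode_and_identity():
    col = np.array([[0], [0], [2], [MISSING]], dtype=np.int8)
    g = impute_missing(make_genotypes(col))
    assert list(g.values[:, 0]) == [0, 0, 2, 0]
    complete = make_genotypes([[0, 1], [2, 1]])
    assert np.array_equal(impute_missing(complete).values, complete.values)


def test_impute_count_matches_missingness():
    rng = np.random.default_rng(9)
    vals = rng.integers(0, 3, size=(30, 40)).astype(np.int8)
    mask = rng.random(vals.shape) < 0.15
    vals[mask] = MISSING
    n_missing = int(mask.sum())
    g = impute_missing(make_genotypes(vals))
    changed = int((g.values != vals).sum())
    assert changed == n_missing
    assert not (g.values == MISSING).any()


def test_impute_all_missing_column_errors():
    vals = np.full((4, 1), MISSING, dtype=np.int8)
    with pytest.raises(ValueError, match="entirely missing"):
        impute_missing(make_genotypes(vals))


# ---------------------------------------------------------------------------
# karyotype pseudo-locus
# ---------------------------------------------------------------------------

def test_append_karyotype_adds_flagged_column():
    g = make_genotypes([[0, 1], [1, 2], [2, 0]])
    s = make_samples(3, two_n=[70, 74, 78])
    gk = append_karyotype(g, s)
    assert gk.n_loci == 3
    assert gk.karyotype_col == 2
    assert list(gk.values[:, 2]) == [70, 74, 78]
    assert gk.locus_ids[-1] == KARYOTYPE_ID


def test_append_karyotype_zero_variance_rejected():
    g = make_genotypes([[0, 1], [1, 2], [2, 0]])
    s = make_samples(3, two_n=[72, 72, 72])
    with pytest.raises(ValueError, match="zero variance"):
        append_karyotype(g, s)


def test_append_karyotype_drops_uncounted_samples():
    g = make_genotypes([[0], [1], [2], [1]])
    s = make_samples(4, two_n=[70, np.nan, 74, 76])
    gk = append_karyotype(g, s)
    assert gk.n_samples == 3
    assert "S2" not in gk.sample_ids


def test_karyotype_exempt_from_filters_and_standardized():
    vals = np.array([[0, 70], [1, 74], [2, 82], [MISSING, 78]], dtype=np.int16)
    g = GenotypeMatrix(vals, pd.DataFrame({
        "locus_id": ["L1", KARYOTYPE_ID], "contig": ["c", "."],
        "position": [100, 0]}), ["S1", "S2", "S3", "S4"], karyotype_col=1)
    kept = filter_maf(filter_coverage(g, 4), 0.4)
    assert kept.locus_ids == [KARYOTYPE_ID]  # L1 fails both, 2n survives
    gi = impute_missing(g)
    Y = gi.analysis_matrix()
    assert np.isclose(Y[:, 1].mean(), 0) and np.isclose(Y[:, 1].std(ddof=1), 1)


# ---------------------------------------------------------------------------
# cytotype subsampling
# ---------------------------------------------------------------------------

def test_subsample_one_per_cytotype_counts():
    pops = ["P1"] * 5 + ["P2"]
    two_n = [72, 72, 72, 74, 74, 80]
    g = make_genotypes(np.zeros((6, 2), dtype=np.int8))
    s = make_samples(6, populations=pops, two_n=two_n)
    sub_g, sub_s = subsample_one_per_cytotype(g, s, seed=0)
    assert sub_g.n_samples == 3  # {72, 74} in P1 + single-sample P2
    assert list(sub_s.table["population"]) == ["P1", "P1", "P2"]


def test_subsample_size_deterministic_membership_varies(study_sim):
    g, s, _, _ = study_sim
    expected = s.table.groupby("population")["two_n"].nunique().sum()
    sizes = set()
    members = set()
    for seed in range(5):
        sub_g, _ = subsample_one_per_cytotype(g, s, seed=seed)
        sizes.add(sub_g.n_samples)
        members.add(tuple(sub_g.sample_ids))
    assert sizes == {expected}
    assert len(members) > 1  # different seeds pick different representatives
    sub_a, _ = subsample_one_per_cytotype(g, s, seed=3)
    sub_b, _ = subsample_one_per_cytotype(g, s, seed=3)
    assert sub_a.sample_ids == sub_b.sample_ids
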