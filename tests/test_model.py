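"""Round-trip and format-edge tests for pooled VCF / truth-table I/O."""

import math

import pytest

from poolfilter.model import (
    CallSet,
    FormatError,
    PoolCounts,
    PoolVariant,
    read_callset,
    read_truthset,
    write_callset,
    write_truthset,
)


def _assert_callsets_equal(a: CallSet, b: CallSet):
    assert a.pool_size_n == b.pool_size_n
    assert a.num_pools == b.num_pools
    assert len(a) == len(b)
    for va, vb in zip(a.variants, b.variants):
        assert va.key == vb.key
        assert va.in_db == vb.in_db
        assert va.counts == vb.counts
        assert math.isclose(va.qual, vb.qual, rel_tol=1e-9, abs_tol=1e-9)


def test_write_read_round_trip_simulated(small_sim, tmp_path):
    _, cs, _ = small_sim
    path = write_callset(cs, tmp_path / "pools.vcf")
    back = read_callset(path)
    _assert_callsets_equal(cs, back)


def test_round_trip_preserves_extreme_quals(tiny_callset, tmp_path):
    # QUAL spans orders of magnitude in pooled callers; full double precision kept
    tiny_callset.variants[0].qual = 1234567.891234
    tiny_callset.variants[1].qual = 20.000000001
    back = read_callset(write_callset(tiny_callset, tmp_path / "q.vcf"))
    _assert_callsets_equal(tiny_callset, back)


def test_written_vcf_is_valid_for_htslib(small_sim, tmp_path):
    pysam = pytest.importorskip("pysam")
    _, cs, _ = small_sim
    path = write_callset(cs, tmp_path / "pools.vcf")
    recs = list(pysam.VariantFile(str(path)))
    assert len(recs) == len(cs)
    for rec, v in zip(recs, cs.variants):
        assert (rec.chrom, rec.pos, rec.ref, rec.alts[0]) == v.key
        assert ("DB" in rec.info) == v.in_db
        ads = [tuple(s["AD"]) for s in rec.samples.values()]
        assert ads == [(c.ref_reads, c.alt_reads) for c in v.counts]
        # htslib stores QUAL in single precision
        assert math.isclose(rec.qual, v.qual, rel_tol=1e-5)


def test_empty_callset_writes_header_only(tmp_path):
    cs = CallSet(pool_size_n=12, variants=[], num_pools=2)
    path = write_callset(cs, tmp_path / "empty.vcf")
    lines = path.read_text().splitlines()
    assert all(l.startswith("#") for l in lines)
    assert len(read_callset(path)) == 0


def test_one_variant_one_data_line(tiny_callset, tmp_path):
    cs = CallSet(pool_size_n=12, variants=tiny_callset.variants[:1], num_pools=2)
    path = write_callset(cs, tmp_path / "one.vcf")
    data = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert len(data) == 1


def _vcf(tmp_path, records, samples=("pool001", "pool002")):
    header = [
        "##fileformat=VCFv4.2",
        "##pool_size_n=12",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    path = tmp_path / "in.vcf"
    path.write_text("\n".join(header + records) + "\n")
    return path


def test_insertion_record_excluded_with_counter(tmp_path):
    path = _vcf(tmp_path, [
        "1\t100\t.\tA\tG\t50\t.\t.\tAD\t10,5\t8,0",
        "1\t200\t.\tA\tAT\t60\t.\t.\tAD\t10,5\t8,0",  # insertion
    ])
    cs = read_callset(path)
    assert len(cs) == 1
    assert cs.metadata["skipped_non_snv"] == 1
    with pytest.raises(FormatError):
        read_callset(path, strict=True)


def test_db_membership_from_id_field_and_sidecar(tmp_path):
    path = _vcf(tmp_path, [
        "1\t100\trs42\tA\tG\t50\t.\t.\tAD\t10,5\t8,0",
        "1\t200\t.\tA\tG\t60\t.\t.\tAD\t10,5\t8,0",
        "1\t300\t.\tA\tG\t70\t.\tDB\tAD\t10,5\t8,0",
    ])
    cs = read_callset(path)
    assert [v.in_db for v in cs.variants] == [True, False, True]
    # explicit membership table overrides the ID/INFO rule
    member = tmp_path / "member.tsv"
    member.write_text("1\t200\tA\tG\n")
    cs2 = read_callset(path, membership=member)
    assert [v.in_db for v in cs2.variants] == [False, True, False]


def test_multiallelic_policies(tmp_path):
    path = _vcf(tmp_path, ["1\t100\t.\tA\tG,T\t50\t.\t.\tAD\t10,5,2\t8,0,1"])
    with pytest.raises(FormatError, match="multiallelic"):
        read_callset(path)
    assert len(read_callset(path, multiallelic="skip")) == 0
    cs = read_callset(path, multiallelic="split")
    assert [v.key for v in cs.variants] == [("1", 100, "A", "G"), ("1", 100, "A", "T")]
    assert cs.variants[0].counts == (PoolCounts(10, 5), PoolCounts(8, 0))
    assert cs.variants[1].counts == (PoolCounts(10, 2), PoolCounts(8, 1))


def test_missing_count_field_names_record(tmp_path):
    path = _vcf(tmp_path, ["1\t100\t.\tA\tG\t50\t.\t.\tGT\t0/1\t0/0"])
    with pytest.raises(FormatError, match="1:100"):
        read_callset(path)


def test_duplicate_variant_key_is_an_error(tmp_path):
    path = _vcf(tmp_path, [
        "1\t100\t.\tA\tG\t50\t.\t.\tAD\t10,5\t8,0",
        "1\t100\t.\tA\tG\t60\t.\t.\tAD\t10,5\t8,0",
    ])
    with pytest.raises(ValueError, match="duplicate"):
        read_callset(path)


def test_truthset_tsv_dedup_and_empty(tmp_path):
    p = tmp_path / "truth.tsv"
    p.write_text("1\t100\tA\tG\n1\t100\tA\tG\n")
    assert len(read_truthset(p)) == 1
    p2 = tmp_path / "empty.tsv"
    p2.write_text("")
    assert len(read_truthset(p2)) == 0
    p3 = tmp_path / "bad.tsv"
    p3.write_text("1\t100\tA\tG\n1\toops\tA\tG\n")
    with pytest.raises(FormatError, match=":2"):
        read_truthset(p3)


def test_truthset_round_trip_via_generator(small_sim, tmp_path):
    _, _, truth = small_sim
    path = write_truthset(truth.truth_set(), tmp_path / "truth.tsv")
    assert read_truthset(path).keys == truth.true_keys()


def test_variant_invariants_enforced():
    with pytest.raises(ValueError):
        PoolVariant("1", 1, "A", "A", 10.0, (PoolCounts(1, 1),))
    with pytest.raises(ValueError):
        PoolVariant("1", 1, "A", "AT", 10.0, (PoolCounts(1, 1),))
    with pytest.raises(ValueError):
        PoolCounts(-1, 0)
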