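"""The KS statistic, the QF/MPF filters, threshold scans and their algebra."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from poolfilter.ksfilter import (
    apply_mpf,
    apply_qf,
    intersect_filters,
    ks_d,
    mpf_grid,
    qf_grid,
    scan_thresholds,
)
from poolfilter.model import CallSet
from poolfilter.stratify import stratify_quals
from conftest import make_variant


# ---------------------------------------------------------------- ks_d

def test_ks_d_reference_cases():
    assert ks_d([1, 2, 3], [1, 2, 3]) == 0.0
    assert ks_d([1, 2, 3], [10, 11, 12]) == 1.0
    # ECDF differences at pooled points {1, 1.5, 2, 3}: 0.5, 0, 0.5, 0
    assert ks_d([1, 2], [1.5, 3]) == 0.5
    with pytest.raises(ValueError):
        ks_d([], [1.0])


def test_ks_d_matches_scipy_on_random_pairs_with_ties(rng):
    for _ in range(300):
        na, nb = rng.integers(2, 200, size=2)
        # integer-valued draws force ties within and across samples
        a = rng.integers(0, 30, size=na).astype(float)
        b = rng.integers(0, 30, size=nb).astype(float)
        expected = stats.ks_2samp(a, b, method="asymp").statistic
        assert ks_d(a, b) == pytest.approx(expected, abs=1e-12)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    a=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=40),
    b=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=40),
)
def test_ks_d_symmetric_and_monotone_invariant(a, b):
    d = ks_d(a, b)
    assert 0.0 <= d <= 1.0
    assert d == ks_d(b, a)
    # a common strictly monotone transform leaves the statistic unchanged
    # (doubling is exact for every float, so distinct values stay distinct)
    fa = [2.0 * x for x in a]
    fb = [2.0 * x for x in b]
    assert ks_d(fa, fb) == pytest.approx(d, abs=1e-12)


# ---------------------------------------------------------------- filters

def test_qf_is_strict_and_below_min_is_identity(tiny_callset):
    out = apply_qf(tiny_callset, 10.0)  # below the minimum QUAL
    assert out.removed_keys == frozenset()
    assert len(out.surviving) == len(tiny_callset)

    quals = {50.0: 100, 74.0: 200, 100.0: 300}
    cs = CallSet(pool_size_n=12, variants=[
        make_variant(pos, q, [(9, 1)]) for q, pos in quals.items()
    ])
    out = apply_qf(cs, 74.0)
    assert [v.qual for v in out.surviving.variants] == [100.0]
    assert len(out.removed_keys) == 2


def test_qf_survivors_shrink_with_threshold(small_sim):
    _, cs, _ = small_sim
    prev = cs.key_set()
    for t in (30, 60, 120, 240):
        surv = apply_qf(cs, t).surviving.key_set()
        assert surv <= prev
        prev = surv


def test_mpf_zero_is_identity(small_sim):
    _, cs, _ = small_sim
    out = apply_mpf(cs, 0.0)
    assert out.removed_keys == frozenset()
    assert out.pool_resets == 0
    assert [v.counts for v in out.surviving.variants] == [v.counts for v in cs.variants]


def test_mpf_partial_and_full_removal():
    cs = CallSet(pool_size_n=12, variants=[
        make_variant(100, 50.0, [(99, 1), (985, 15)]),   # 1.0% and 1.5% -> both reset
        make_variant(200, 60.0, [(99, 1), (97, 3)]),     # 1.0% and 3.0% -> partial
    ])
    out = apply_mpf(cs, 2.6)
    assert out.removed_keys == {("1", 100, "A", "G")}
    (survivor,) = out.surviving.variants
    assert [c.alt_reads for c in survivor.counts] == [0, 3]
    assert survivor.qual == 60.0  # QUAL untouched
    assert out.pool_resets == 3


def test_filters_idempotent(small_sim):
    _, cs, _ = small_sim
    for outcome, reapply in (
        (apply_qf(cs, 80.0), lambda s: apply_qf(s, 80.0)),
        (apply_mpf(cs, 2.6), lambda s: apply_mpf(s, 2.6)),
    ):
        again = reapply(outcome.surviving)
        assert again.surviving.key_set() == outcome.surviving.key_set()
        assert [v.counts for v in again.surviving.variants] == \
               [v.counts for v in outcome.surviving.variants]


def test_filter_counts_conserved(small_sim):
    _, cs, _ = small_sim
    for out in (apply_qf(cs, 80.0), apply_mpf(cs, 2.6)):
        assert len(out.surviving) + len(out.removed_keys) == len(cs)
        assert out.surviving.key_set() | out.removed_keys == cs.key_set()


# ---------------------------------------------------------------- scans

def test_default_grids_match_guideline():
    assert len(qf_grid()) == 181
    assert qf_grid()[0] == 20 and qf_grid()[-1] == 200
    assert len(mpf_grid()) == 51
    assert mpf_grid()[0] == 0.0 and mpf_grid()[-1] == 5.0


@pytest.mark.parametrize("kind", ["qf", "mpf"])
def test_scan_matches_from_scratch_composition(small_sim, kind):
    _, cs, _ = small_sim
    grid = [20.0, 50.0, 90.0, 140.0] if kind == "qf" else [0.0, 1.0, 2.5, 4.0]
    result = scan_thresholds(cs, kind, grid)
    apply_fn = apply_qf if kind == "qf" else apply_mpf
    for t, d, rdb, rnov in result.as_rows():
        outcome = apply_fn(cs, t)
        strat = stratify_quals(outcome.surviving)
        assert d == pytest.approx(ks_d(strat.in_db_quals, strat.novel_quals), abs=1e-12)
        full = stratify_quals(cs)
        assert rdb == full.n_in_db - strat.n_in_db
        assert rnov == full.n_novel - strat.n_novel
    best_from_scan = min(d for d in result.dstat_at if d is not None)
    assert result.best_dstat == best_from_scan
    assert result.best_threshold == min(
        t for t, d in zip(result.grid, result.dstat_at) if d == best_from_scan
    )


def test_scan_tie_break_picks_smallest_threshold():
    # identical in.db and novel QUAL distributions, all above the grid: D = 0 everywhere
    variants = [
        make_variant(100, 500.0, [(0, 10)], in_db=True),
        make_variant(200, 500.0, [(0, 10)], in_db=False),
        make_variant(300, 900.0, [(0, 10)], in_db=True),
        make_variant(400, 900.0, [(0, 10)], in_db=False),
    ]
    cs = CallSet(pool_size_n=12, variants=variants)
    result = scan_thresholds(cs, "qf", [20.0, 50.0, 100.0])
    assert all(d == 0.0 for d in result.dstat_at)
    assert result.best_threshold == 20.0
    assert result.best_dstat == 0.0


def test_scan_degenerate_points_excluded_with_warning():
    variants = [
        make_variant(100, 30.0, [(0, 10)], in_db=True),   # only in.db dies first
        make_variant(200, 500.0, [(0, 10)], in_db=False),
        make_variant(300, 600.0, [(0, 10)], in_db=False),
    ]
    cs = CallSet(pool_size_n=12, variants=variants)
    with pytest.warns(UserWarning, match="excluded"):
        result = scan_thresholds(cs, "qf", [20.0, 100.0])
    assert result.dstat_at[1] is None
    assert result.best_threshold == 20.0


def test_scan_rejects_bad_grids(small_sim):
    _, cs, _ = small_sim
    with pytest.raises(ValueError):
        scan_thresholds(cs, "qf", [])
    with pytest.raises(ValueError):
        scan_thresholds(cs, "qf", [50.0, 50.0])
    with pytest.raises(ValueError):
        scan_thresholds(cs, "nope", [20.0])


# ---------------------------------------------------------------- intersection

def test_intersection_is_set_intersection(small_sim):
    _, cs, _ = small_sim
    qf_out = apply_qf(cs, 90.0)
    mpf_out = apply_mpf(cs, 2.6)
    final = intersect_filters(qf_out, mpf_out)
    fk = final.key_set()
    assert fk == qf_out.surviving.key_set() & mpf_out.surviving.key_set()
    assert len(final) <= min(len(qf_out.surviving), len(mpf_out.surviving))
    # survivors carry MPF-adjusted counts and original QUAL
    mpf_counts = {v.key: v.counts for v in mpf_out.surviving.variants}
    quals = {v.key: v.qual for v in cs.variants}
    for v in final.variants:
        assert v.counts == mpf_counts[v.key]
        assert v.qual == quals[v.key]


def test_intersection_rejects_mismatched_inputs(small_sim, tiny_callset):
    _, cs, _ = small_sim
    with pytest.raises(ValueError, match="different input"):
        intersect_filters(apply_qf(cs, 50.0), apply_mpf(tiny_callset, 1.0))


def test_intersection_with_empty_outcome(tiny_callset):
    qf_out = apply_qf(tiny_callset, 1e9)  # removes everything
    mpf_out = apply_mpf(tiny_callset, 0.0)
    assert len(intersect_filters(qf_out, mpf_out)) == 0
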