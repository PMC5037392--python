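"""Kolmogorov–Smirnov guided variant filters for Pool-seq call sets.

Two complementary filters are tuned with the same objective:

* **QF (quality filter)** — drop a variant from every pool unless its
  caller quality exceeds a threshold (``QUAL > t``).
* **MPF (minimum-percentage filter)** — per pool, reset the ALT read
  count to zero when ALT reads are below ``t``% of the pool's depth; a
  variant zeroed in every pool is dropped entirely.

For each candidate threshold the filter is applied, the surviving QUAL
values are split into database-annotated (in.db) vs novel samples, and
the two-sample Kolmogorov–Smirnov statistic

    D = sup_x | F_in.db(x) - F_novel(x) |

is computed over the pooled sample points.  Because database membership
and caller quality are independent for genuine variants, the threshold
minimising D is the one that best removes the error-driven excess of
low-quality novel calls without distorting the genuine signal.  The two
filters are combined by intersecting their survivor sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Sequence

import numpy as np

from .allele_freq import cohort_af_map
from .model import CallSet, PoolCounts, PoolVariant, VariantKey

__all__ = [
    "ks_d",
    "FilterOutcome",
    "ScanResult",
    "apply_qf",
    "apply_mpf",
    "scan_thresholds",
    "intersect_filters",
    "qf_grid",
    "mpf_grid",
]


def ks_d(sample_a: Sequence[float] | np.ndarray, sample_b: Sequence[float] | np.ndarray) -> float:
    """Two-sample Kolmogorov–Smirnov D statistic.

    The supremum of the absolute ECDF difference, evaluated exactly at the
    pooled sample points (ties handled by right-continuous ECDFs).
    Symmetric in its arguments; D ∈ [0, 1].
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("KS statistic undefined for an empty sample")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


@dataclass
class FilterOutcome:
    """Result of applying one filter to a call set."""

    surviving: CallSet
    removed_keys: frozenset[VariantKey]
    #: number of (variant, pool) cells whose ALT count was reset (MPF only)
    pool_resets: int = 0
    input_keys: frozenset[VariantKey] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        surv = self.surviving.key_set()
        if surv & self.removed_keys:
            raise ValueError("surviving and removed keys overlap")
        if not self.input_keys:
            self.input_keys = surv | self.removed_keys
        elif surv | self.removed_keys != self.input_keys:
            raise ValueError("surviving ∪ removed does not cover the input key set")


def apply_qf(cs: CallSet, qual_threshold: float) -> FilterOutcome:
    """Quality filter: keep variants with ``qual > qual_threshold`` (strict)."""
    if qual_threshold < 0:
        raise ValueError("qual_threshold must be >= 0")
    kept = [v for v in cs.variants if v.qual > qual_threshold]
    removed = frozenset(v.key for v in cs.variants if v.qual <= qual_threshold)
    surviving = CallSet(
        pool_size_n=cs.pool_size_n, variants=kept, num_pools=cs.num_pools,
        metadata=dict(cs.metadata),
    )
    return FilterOutcome(surviving=surviving, removed_keys=removed,
                         input_keys=cs.key_set())


def apply_mpf(cs: CallSet, th_percent: float) -> FilterOutcome:
    """Minimum-percentage filter at ``th_percent``.

    Every (variant, pool) cell with ALT reads strictly below th% of depth
    has its ALT count reset to 0; variants left with no ALT reads in any
    pool are removed entirely.  QUAL values are untouched.
    """
    if not 0 <= th_percent <= 100:
        raise ValueError(f"th_percent must be in [0, 100], got {th_percent}")
    # same strict rational comparison as apply_mpf_to_counts, hoisted out
    frac = Fraction(str(th_percent))
    num, den = frac.numerator, frac.denominator
    kept: list[PoolVariant] = []
    removed: set[VariantKey] = set()
    resets = 0
    for v in cs.variants:
        new_counts = []
        for c in v.counts:
            d = c.ref_reads + c.alt_reads
            if d > 0 and 100 * c.alt_reads * den < num * d:
                nc = PoolCounts(c.ref_reads, 0) if c.alt_reads else c
                resets += c.alt_reads > 0
            else:
                nc = c
            new_counts.append(nc)
        if any(c.alt_reads > 0 for c in new_counts):
            kept.append(replace(v, counts=tuple(new_counts)))
        else:
            removed.add(v.key)
    surviving = CallSet(
        pool_size_n=cs.pool_size_n, variants=kept, num_pools=cs.num_pools,
        metadata=dict(cs.metadata),
    )
    return FilterOutcome(surviving=surviving, removed_keys=frozenset(removed),
                         pool_resets=resets, input_keys=cs.key_set())


@dataclass
class ScanResult:
    """Grid scan of a filter threshold against the KS objective."""

    filter_kind: str
    grid: list[float]
    dstat_at: list[float | None]
    removed_in_db_at: list[int]
    removed_novel_at: list[int]
    best_threshold: float
    best_dstat: float

    def as_rows(self) -> list[tuple]:
        return list(zip(self.grid, self.dstat_at, self.removed_in_db_at,
                        self.removed_novel_at))


def qf_grid(lo: int = 20, hi: int = 200, step: int = 1) -> list[float]:
    """Default quality-threshold grid: 20..200 in steps of 1."""
    return [float(t) for t in range(lo, hi + 1, step)]


def mpf_grid() -> list[float]:
    """Default minimum-percentage grid: 0.0..5.0% in steps of 0.1%.

    Generated as k/10 for integer k to keep grid points exact.
    """
    return [k / 10 for k in range(0, 51)]


def _survivor_matrix_mpf(alt: np.ndarray, depth: np.ndarray, th: float) -> np.ndarray:
    """Boolean per-(variant, pool) mask of cells NOT reset at threshold th."""
    frac = Fraction(str(th))
    # reset iff 100*alt < th*depth, in exact integer arithmetic
    keep_cell = 100 * alt * frac.denominator >= frac.numerator * depth
    return keep_cell


def scan_thresholds(
    cs: CallSet,
    filter_kind: str,
    grid: Sequence[float] | None = None,
    subset: str = "all",
    rarity_cutoff: float = 0.01,
) -> ScanResult:
    """Scan a threshold grid, minimising the KS D between in.db and novel QUALs.

    For each grid value the filter is applied, the surviving variants'
    QUAL values are stratified by database membership (optionally after
    restricting to rare/common variants on unfiltered cohort AF), and the
    two-sample KS D is recorded.  Grid points where either class empties
    are recorded as missing and excluded from the argmin (with a warning).
    Ties are broken toward the smallest threshold — the least aggressive
    filter attaining the minimum D.
    """
    if filter_kind not in ("qf", "mpf"):
        raise ValueError(f"unknown filter kind {filter_kind!r}")
    if subset not in ("all", "rare", "common"):
        raise ValueError(f"unknown subset {subset!r}")
    if grid is None:
        grid = qf_grid() if filter_kind == "qf" else mpf_grid()
    grid = [float(t) for t in grid]
    if not grid:
        raise ValueError("empty threshold grid")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")

    quals = cs.quals()
    in_db = cs.in_db_mask()
    universe = np.ones(len(cs), dtype=bool)
    if subset != "all":
        af_map = cohort_af_map(cs)
        afs = np.array([af_map[k] for k in cs.keys()])
        universe = afs < rarity_cutoff if subset == "rare" else afs >= rarity_cutoff
    n_in_db = int((universe & in_db).sum())
    n_novel = int((universe & ~in_db).sum())
    if n_in_db == 0 or n_novel == 0:
        raise ValueError("call set has an empty in.db or novel class")

    if filter_kind == "mpf":
        ref = cs.ref_matrix()
        alt = cs.alt_matrix()
        depth = ref + alt

    dstats: list[float | None] = []
    rem_db: list[int] = []
    rem_novel: list[int] = []
    for t in grid:
        if filter_kind == "qf":
            alive = quals > t
        else:
            keep_cell = _survivor_matrix_mpf(alt, depth, t)
            alive = ((alt > 0) & keep_cell).any(axis=1)
        a = quals[universe & in_db & alive]
        b = quals[universe & ~in_db & alive]
        rem_db.append(n_in_db - a.size)
        rem_novel.append(n_novel - b.size)
        if a.size == 0 or b.size == 0:
            dstats.append(None)
            continue
        dstats.append(ks_d(a, b))

    defined = [(d, t) for d, t in zip(dstats, grid) if d is not None]
    if not defined:
        raise ValueError("every grid point degenerates: one class always empties")
    if len(defined) < len(grid):
        warnings.warn(
            f"{len(grid) - len(defined)} grid point(s) emptied a class and were "
            "excluded from the argmin",
            stacklevel=2,
        )
    best_dstat = min(d for d, _ in defined)
    best_threshold = next(t for d, t in defined if d == best_dstat)
    return ScanResult(
        filter_kind=filter_kind,
        grid=grid,
        dstat_at=dstats,
        removed_in_db_at=rem_db,
        removed_novel_at=rem_novel,
        best_threshold=best_threshold,
        best_dstat=best_dstat,
    )


def intersect_filters(qf_out: FilterOutcome, mpf_out: FilterOutcome) -> CallSet:
    """Variants surviving both filters, with MPF-adjusted counts and original QUAL.

    Both outcomes must derive from the same input call set; survivors keep
    the MPF outcome's per-pool counts (QF does not alter counts).
    """
    if qf_out.input_keys != mpf_out.input_keys:
        raise ValueError("filter outcomes derive from different input call sets")
    qf_keys = qf_out.surviving.key_set()
    both = [v for v in mpf_out.surviving.variants if v.key in qf_keys]
    return CallSet(
        pool_size_n=mpf_out.surviving.pool_size_n,
        variants=both,
        num_pools=mpf_out.surviving.num_pools,
        metadata=dict(mpf_out.surviving.metadata),
    )
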