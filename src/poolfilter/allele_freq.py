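"""Allele-frequency estimation for pooled sequencing.

The AF of a variant in one pool is the fraction of reads supporting the
alternative allele; the cohort AF ("poolAF") is the unweighted mean of the
per-pool AFs.  In a pool of ``n`` diploids the true per-pool AF is confined
to the lattice {0, 1, ..., 2n}/(2n) — read-level noise blurs calls off this
lattice, which is what the minimum-percentage filter (MPF) exploits: a
pool whose ALT reads fall below a small percentage of its depth most
likely observed sequencing error, so its ALT count is reset to zero.
"""

from __future__ import annotations

import csv
from fractions import Fraction
from pathlib import Path

import numpy as np

from .model import CallSet, PoolCounts, PoolVariant

__all__ = [
    "per_pool_af",
    "cohort_af",
    "apply_mpf_to_counts",
    "af_lattice",
    "classify_rarity",
    "cohort_af_map",
    "write_af_table",
]


def per_pool_af(c: PoolCounts) -> float | None:
    """ALT-read fraction in one pool; ``None`` when the pool has no coverage."""
    d = c.depth()
    if d == 0:
        return None
    return c.alt_reads / d


def cohort_af(v: PoolVariant, *, zero_depth: str = "exclude") -> float:
    """Cohort allele frequency: mean of per-pool ALT-read fractions.

    Parameters
    ----------
    zero_depth
        ``"exclude"`` (default) drops pools with no coverage from the
        mean; ``"zero"`` counts them as AF 0.

    Raises
    ------
    ValueError
        If every pool has zero depth ("no coverage").
    """
    if zero_depth not in ("exclude", "zero"):
        raise ValueError(f"unknown zero_depth policy {zero_depth!r}")
    afs = [per_pool_af(c) for c in v.counts]
    defined = [a for a in afs if a is not None]
    if not defined:
        raise ValueError(f"{v.chrom}:{v.pos}: no coverage in any pool")
    if zero_depth == "zero":
        return sum(defined) / len(afs)
    return sum(defined) / len(defined)


def cohort_af_map(cs: CallSet, *, zero_depth: str = "exclude") -> dict:
    """Variant key -> cohort AF for a whole call set (vectorised)."""
    ref = cs.ref_matrix()
    alt = cs.alt_matrix()
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    covered = (depth > 0).sum(axis=1)
    if np.any(covered == 0):
        bad = np.flatnonzero(covered == 0)[0]
        v = cs.variants[bad]
        raise ValueError(f"{v.chrom}:{v.pos}: no coverage in any pool")
    if zero_depth == "zero":
        means = np.nansum(af, axis=1) / depth.shape[1]
    else:
        means = np.nanmean(af, axis=1)
    return dict(zip(cs.keys(), means.tolist()))


def apply_mpf_to_counts(c: PoolCounts, th_percent: float) -> PoolCounts:
    """Reset a pool's ALT reads to 0 when they are below ``th_percent`` of depth.

    The comparison is strict (< th%) and carried out in exact rational
    arithmetic so grid values such as 2.6 behave identically to their
    decimal meaning: reset iff ``100 * alt < th * depth``.
    """
    if not 0 <= th_percent <= 100:
        raise ValueError(f"th_percent must be in [0, 100], got {th_percent}")
    d = c.depth()
    if d == 0:
        return c
    th = Fraction(str(th_percent))
    if 100 * c.alt_reads * th.denominator < th.numerator * d:
        return PoolCounts(c.ref_reads, 0)
    return c


def af_lattice(n: int) -> np.ndarray:
    """Attainable per-pool allele frequencies for a pool of ``n`` diploids.

    Returns the 2n+1 values k/(2n), k = 0..2n, strictly increasing.  The
    smallest non-zero value, 1/(2n), is the pool's ideal detection limit
    (~0.042 for n = 12).
    """
    if n < 1:
        raise ValueError(f"pool size must be >= 1, got {n}")
    return np.arange(2 * n + 1) / (2 * n)


def classify_rarity(af: float, cutoff: float = 0.01) -> str:
    """Classify a cohort AF as ``"rare"`` (strictly below cutoff) or ``"common"``."""
    if not 0 <= af <= 1:
        raise ValueError(f"AF must be in [0, 1], got {af}")
    return "rare" if af < cutoff else "common"


def write_af_table(cs: CallSet, path: str | Path, *, zero_depth: str = "exclude") -> Path:
    """TSV of per-variant cohort AF and per-pool AFs (empty cell = no coverage)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["chrom", "pos", "ref", "alt", "pool_af"]
            + [f"af_pool{i + 1:03d}" for i in range(cs.num_pools)]
        )
        for v in cs.variants:
            afs = [per_pool_af(c) for c in v.counts]
            writer.writerow(
                [v.chrom, v.pos, v.ref_allele, v.alt_allele,
                 f"{cohort_af(v, zero_depth=zero_depth):.6g}"]
                + ["" if a is None else f"{a:.6g}" for a in afs]
            )
    return path
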