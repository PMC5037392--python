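"""Stratification of call-set quality scores by database membership.

The filtering guideline rests on one observation: whether a variant is
already annotated in a public database (in.db) is independent of the
quality score the caller assigns it, so the QUAL distributions of the
in.db and novel classes should look alike.  An excess of low-QUAL mass in
the novel class betrays sequencing-error calls, and the divergence between
the two empirical distributions is the quantity the filters minimise.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np

from .allele_freq import cohort_af_map
from .model import CallSet

__all__ = ["StratifiedQuals", "stratify_quals", "removal_percent", "round_percent"]


@dataclass(frozen=True)
class StratifiedQuals:
    """QUAL samples of the database-annotated and novel variant classes."""

    in_db_quals: np.ndarray
    novel_quals: np.ndarray

    @property
    def n_in_db(self) -> int:
        return int(self.in_db_quals.size)

    @property
    def n_novel(self) -> int:
        return int(self.novel_quals.size)


def stratify_quals(
    cs: CallSet,
    subset: str = "all",
    rarity_cutoff: float = 0.01,
) -> StratifiedQuals:
    """Split a call set's QUAL values into in.db vs novel samples.

    ``subset`` optionally restricts to ``"rare"`` or ``"common"`` variants
    (cohort AF strictly below / at-or-above ``rarity_cutoff``) before
    partitioning by the ``in_db`` flag.

    Raises
    ------
    ValueError
        If either class is empty after restriction — the KS statistic is
        undefined on a degenerate stratification.
    """
    if subset not in ("all", "rare", "common"):
        raise ValueError(f"unknown subset {subset!r}")
    quals = cs.quals()
    in_db = cs.in_db_mask()
    if subset != "all":
        af_map = cohort_af_map(cs)
        afs = np.array([af_map[k] for k in cs.keys()])
        keep = afs < rarity_cutoff if subset == "rare" else afs >= rarity_cutoff
        quals, in_db = quals[keep], in_db[keep]
    a, b = quals[in_db], quals[~in_db]
    if a.size == 0 or b.size == 0:
        raise ValueError(
            f"degenerate stratification (subset={subset!r}): "
            f"{a.size} in.db vs {b.size} novel variants"
        )
    return StratifiedQuals(in_db_quals=a, novel_quals=b)


def round_percent(value: Fraction | float) -> float:
    """Round a percentage to 2 decimals, half away from zero (report style)."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(str(value))
    return float(dec.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def removal_percent(before: int, after: int) -> float:
    """Percentage of variants a filter removed, to 2 decimals.

    ``before`` and ``after`` are class sizes before and after filtering.
    """
    if before <= 0:
        raise ValueError("before must be > 0")
    if not 0 <= after <= before:
        raise ValueError(f"need 0 <= after <= before, got {after} / {before}")
    return round_percent(Fraction(100 * (before - after), before))
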