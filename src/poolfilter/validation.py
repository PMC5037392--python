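"""Benchmarking pooled call sets against individual-sequencing truth sets.

Individual sequencing of the subjects of one pool gives a truth set:
variants seen there are taken as true.  A pooled call set is then scored
by its true positives (called ∩ truth), false-positive rate, and — after
filtering — the percentage of true positives retained relative to the
unfiltered baseline.  A separate helper summarises allele-frequency
concordance against an external AF source (public databases or array
genotyping of the same subjects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .allele_freq import classify_rarity, cohort_af_map
from .model import CallSet, TruthSet, VariantKey
from .stratify import round_percent

__all__ = [
    "TruthComparison",
    "ConcordanceSummary",
    "truth_metrics",
    "compare_to_truth",
    "stratified_truth_comparison",
    "af_concordance",
]


@dataclass(frozen=True)
class TruthComparison:
    """Variant-presence metrics of a call set against a truth set.

    Percentages are reported to 2 decimals (half-up), table style.
    """

    n_called: int
    n_tp: int
    tp_retained_percent: float
    fpr_percent: float


def truth_metrics(n_called: int, n_tp: int, baseline_tp: int | None = None) -> TruthComparison:
    """Compute FPR and TP-retained percentages from raw counts.

    FPR = 100·(called − TP)/called.  TP retained = 100·TP/baseline_tp when a
    baseline (the unfiltered set's TP count) is given, else 100.
    """
    if n_called <= 0:
        raise ValueError("n_called must be > 0")
    if not 0 <= n_tp <= n_called:
        raise ValueError(f"need 0 <= n_tp <= n_called, got {n_tp} / {n_called}")
    fpr = round_percent(Fraction(100 * (n_called - n_tp), n_called))
    if baseline_tp is None:
        retained = 100.0
    elif baseline_tp <= 0:
        raise ValueError("baseline_tp must be > 0 when given")
    else:
        retained = round_percent(Fraction(100 * n_tp, baseline_tp))
    return TruthComparison(n_called=n_called, n_tp=n_tp,
                           tp_retained_percent=retained, fpr_percent=fpr)


def compare_to_truth(
    called_keys: Iterable[VariantKey],
    truth: TruthSet,
    baseline_tp: int | None = None,
) -> TruthComparison:
    """Score a set of called variant keys against a truth set.

    Matching is by exact (chrom, pos, ref, alt) key.
    """
    called = frozenset(called_keys)
    if not called:
        raise ValueError("empty called set")
    n_tp = len(called & truth.keys)
    return truth_metrics(len(called), n_tp, baseline_tp)


def stratified_truth_comparison(
    cs: CallSet,
    truth: TruthSet,
    rarity_cutoff: float = 0.01,
    *,
    af_source: Mapping[VariantKey, float] | None = None,
    baseline_tp: Mapping[str, int] | None = None,
) -> dict[str, TruthComparison]:
    """Truth comparison overall and split into common/rare strata.

    Stratification uses the cohort AF from ``af_source`` when given —
    pass the *unfiltered* call set's AFs when scoring a filtered set, so
    filtering cannot move a variant between strata — else AFs computed
    from ``cs`` itself.  ``baseline_tp`` optionally maps stratum name to
    the unfiltered TP count for TP-retained percentages.  An empty
    stratum is omitted with a warning.
    """
    afs = dict(af_source) if af_source is not None else cohort_af_map(cs)
    strata: dict[str, list[VariantKey]] = {"all": [], "common": [], "rare": []}
    for key in cs.keys():
        strata["all"].append(key)
        strata[classify_rarity(afs[key], rarity_cutoff)].append(key)
    out: dict[str, TruthComparison] = {}
    for name, keys in strata.items():
        if not keys:
            warnings.warn(f"empty {name!r} stratum omitted", stacklevel=2)
            continue
        base = baseline_tp.get(name) if baseline_tp else None
        out[name] = compare_to_truth(keys, truth, baseline_tp=base)
    return out


@dataclass(frozen=True)
class ConcordanceSummary:
    """Agreement between pooled AF estimates and a reference AF source."""

    r_squared: float
    n_pairs: int
    delta_min: float
    delta_q1: float
    delta_median: float
    delta_mean: float
    delta_q3: float
    delta_max: float


def af_concordance(pairs: Sequence[tuple[float, float]]) -> ConcordanceSummary:
    """Summarise (pool AF, reference AF) pairs.

    ``r_squared`` is the square of the Pearson correlation coefficient;
    delta statistics summarise pool AF − reference AF.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (pool_af, reference_af) pairs")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one coordinate; correlation undefined")
    r = np.corrcoef(x, y)[0, 1]
    delta = x - y
    q1, med, q3 = np.percentile(delta, [25, 50, 75])
    return ConcordanceSummary(
        r_squared=float(r * r),
        n_pairs=int(arr.shape[0]),
        delta_min=float(delta.min()),
        delta_q1=float(q1),
        delta_median=float(med),
        delta_mean=float(delta.mean()),
        delta_q3=float(q3),
        delta_max=float(delta.max()),
    )
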