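"""Domain types and I/O for pooled-sequencing (Pool-seq) variant call sets.

A *pool* is a sequencing library made from the DNA of ``n`` diploid
individuals.  A pooled caller (e.g. CRISP) reports one variant record per
site with a single quality score (QUAL) and, per pool, the read counts
supporting the reference and alternative alleles.  This module defines the
in-memory containers for such call sets and reads/writes them as VCF 4.2
with one sample column per pool carrying allelic depths (``AD``).

QUAL is serialized at full double precision by :func:`write_callset` and
parsed back as a Python float, so a write/read round trip is lossless.
htslib-based readers truncate QUAL to single precision; files written here
remain valid VCF 4.2 for them regardless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "PoolCounts",
    "PoolVariant",
    "CallSet",
    "TruthSet",
    "VariantKey",
    "FormatError",
    "read_callset",
    "write_callset",
    "read_truthset",
    "write_truthset",
    "read_membership",
]

logger = logging.getLogger(__name__)

#: (chrom, pos, ref, alt) — the strand-free identity of an SNV.
VariantKey = tuple[str, int, str, str]

_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True, slots=True)
class PoolCounts:
    """REF/ALT supporting read counts for one variant in one pool."""

    ref_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError(
                f"read counts must be non-negative, got ({self.ref_reads}, {self.alt_reads})"
            )

    def depth(self) -> int:
        """Total reads covering the site in this pool."""
        return self.ref_reads + self.alt_reads


@dataclass(slots=True)
class PoolVariant:
    """A single SNV with its caller quality and per-pool read counts.

    ``in_db`` flags presence in any public variant database (1000Genomes,
    dbSNP, ExAC, ESP) as supplied by the annotation source.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    qual: float
    counts: tuple[PoolCounts, ...]
    in_db: bool = False

    def __post_init__(self) -> None:
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(
                f"{self.chrom}:{self.pos} alleles must be single bases (SNV), "
                f"got {self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.chrom}:{self.pos} REF equals ALT")
        if self.qual < 0:
            raise ValueError(f"{self.chrom}:{self.pos} negative QUAL {self.qual}")
        self.counts = tuple(self.counts)

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class CallSet:
    """An ordered collection of pooled SNV calls for a cohort of pools.

    Parameters
    ----------
    pool_size_n
        Number of diploid individuals per pool (2n chromosomes each).
    variants
        Variant records; every record must carry one :class:`PoolCounts`
        per pool and keys must be unique across the set.
    num_pools
        Declared number of pools; inferred from the first variant when
        omitted.
    """

    pool_size_n: int
    variants: list[PoolVariant]
    num_pools: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pool_size_n < 1:
            raise ValueError("pool_size_n must be >= 1")
        if self.num_pools is None:
            if not self.variants:
                raise ValueError("num_pools required for an empty CallSet")
            self.num_pools = len(self.variants[0].counts)
        if self.num_pools < 1:
            raise ValueError("num_pools must be >= 1")
        seen: set[VariantKey] = set()
        for v in self.variants:
            if len(v.counts) != self.num_pools:
                raise ValueError(
                    f"{v.chrom}:{v.pos} has {len(v.counts)} pools, expected {self.num_pools}"
                )
            if v.key in seen:
                raise ValueError(f"duplicate variant key {v.key}")
            seen.add(v.key)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[PoolVariant]:
        return iter(self.variants)

    def keys(self) -> list[VariantKey]:
        return [v.key for v in self.variants]

    def key_set(self) -> frozenset[VariantKey]:
        return frozenset(v.key for v in self.variants)

    # Dense views used by the vectorised scans; rebuilt on demand.
    def quals(self) -> np.ndarray:
        return np.array([v.qual for v in self.variants], dtype=float)

    def in_db_mask(self) -> np.ndarray:
        return np.array([v.in_db for v in self.variants], dtype=bool)

    def ref_matrix(self) -> np.ndarray:
        """(n_variants, num_pools) REF read counts."""
        return np.array(
            [[c.ref_reads for c in v.counts] for v in self.variants], dtype=np.int64
        ).reshape(len(self.variants), self.num_pools)

    def alt_matrix(self) -> np.ndarray:
        """(n_variants, num_pools) ALT read counts."""
        return np.array(
            [[c.alt_reads for c in v.counts] for v in self.variants], dtype=np.int64
        ).reshape(len(self.variants), self.num_pools)

    def subset(self, keys: Iterable[VariantKey]) -> "CallSet":
        """New CallSet with input order restricted to ``keys``."""
        wanted = set(keys)
        return CallSet(
            pool_size_n=self.pool_size_n,
            variants=[v for v in self.variants if v.key in wanted],
            num_pools=self.num_pools,
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class TruthSet:
    """Variant keys deemed true (e.g. confirmed by individual sequencing)."""

    keys: frozenset[VariantKey]

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.keys


# ---------------------------------------------------------------------------
# VCF I/O (narrow schema: SNVs, per-pool allelic depths)
# ---------------------------------------------------------------------------

_VCF_COLS = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]


def _format_qual(q: float) -> str:
    # repr() is the shortest string that round-trips the double exactly
    return repr(int(q)) if float(q).is_integer() else repr(float(q))


def write_callset(cs: CallSet, vcf_path: str | Path) -> Path:
    """Write a CallSet as VCF 4.2 with one sample column per pool.

    Per-pool counts go into the ``AD`` FORMAT field (REF,ALT depths);
    database membership is recorded as the standard ``DB`` INFO flag.
    The pool size is documented in a ``##pool_size_n`` header line.
    """
    vcf_path = Path(vcf_path)
    samples = [f"pool{i + 1:03d}" for i in range(cs.num_pools)]
    contigs = sorted({v.chrom for v in cs.variants})
    lines = [
        "##fileformat=VCFv4.2",
        "##source=poolfilter",
        f"##pool_size_n={cs.pool_size_n}",
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        '##INFO=<ID=DB,Number=0,Type=Flag,Description="Membership in a public variant database">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the REF and ALT alleles">',
        "\t".join(_VCF_COLS + samples),
    ]
    for v in cs.variants:
        info = "DB" if v.in_db else "."
        fields = [
            v.chrom,
            str(v.pos),
            ".",
            v.ref_allele,
            v.alt_allele,
            _format_qual(v.qual),
            ".",
            info,
            "AD",
        ]
        fields += [f"{c.ref_reads},{c.alt_reads}" for c in v.counts]
        lines.append("\t".join(fields))
    vcf_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return vcf_path


DbRule = Callable[[str, str, Mapping[str, str]], bool]
"""Database-membership rule: (ID, INFO, info-dict) -> bool."""


def _default_db_rule(vid: str, info: str, info_map: Mapping[str, str]) -> bool:
    # standard conventions: a non-missing ID (rsID) or the DB INFO flag
    return vid not in (".", "") or "DB" in info_map


def _parse_info(info: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if info in (".", ""):
        return out
    for item in info.split(";"):
        k, _, val = item.partition("=")
        out[k] = val
    return out


def read_callset(
    vcf_path: str | Path,
    *,
    pool_size_n: int | None = None,
    count_field: str = "AD",
    membership: Iterable[VariantKey] | str | Path | None = None,
    db_rule: DbRule | None = None,
    multiallelic: str = "error",
    strict: bool = False,
) -> CallSet:
    """Read a pooled VCF into a :class:`CallSet`.

    Parameters
    ----------
    pool_size_n
        Individuals per pool; taken from a ``##pool_size_n`` header line
        when present, otherwise required.
    count_field
        Name of the per-sample field holding "REF,ALT" read depths
        (callers differ; allelic-depth style ``AD`` is the default).
    membership
        Optional explicit database-membership source: a set of variant
        keys or a path to a 4-column TSV.  When given it overrides
        ``db_rule``.
    db_rule
        Fallback membership rule on (ID, INFO) — default: ID is not '.'
        or the ``DB`` INFO flag is present.
    multiallelic
        ``"error"`` (default), ``"split"`` into biallelic records, or
        ``"skip"``.
    strict
        When True, non-SNV records raise instead of being skipped.

    Non-SNV records (INDELs, symbolic alleles) are excluded; the count of
    exclusions is available as ``metadata["skipped_non_snv"]``.
    """
    vcf_path = Path(vcf_path)
    if multiallelic not in ("error", "split", "skip"):
        raise ValueError(f"unknown multiallelic policy {multiallelic!r}")
    member_keys: frozenset[VariantKey] | None = None
    if membership is not None:
        if isinstance(membership, (str, Path)):
            member_keys = read_membership(membership)
        else:
            member_keys = frozenset(membership)
    rule = db_rule or _default_db_rule

    variants: list[PoolVariant] = []
    header_n: int | None = None
    n_samples: int | None = None
    skipped = 0
    with open(vcf_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                if line.startswith("##pool_size_n="):
                    header_n = int(line.split("=", 1)[1])
                continue
            if line.startswith("#CHROM"):
                n_samples = len(line.split("\t")) - len(_VCF_COLS)
                continue
            if n_samples is None:
                raise FormatError(f"{vcf_path}:{lineno}: data line before #CHROM header")
            fields = line.split("\t")
            if len(fields) != len(_VCF_COLS) + n_samples:
                raise FormatError(
                    f"{vcf_path}:{lineno}: expected {len(_VCF_COLS) + n_samples} columns, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, vid, ref, alt_s, qual_s, _filt, info, fmt = fields[:9]
            alts = alt_s.split(",")
            if len(alts) > 1:
                if multiallelic == "error":
                    raise FormatError(
                        f"{vcf_path}:{lineno}: multiallelic record {chrom}:{pos_s} "
                        "(set multiallelic='split' or 'skip')"
                    )
                if multiallelic == "skip":
                    skipped += 1
                    continue
            fmt_keys = fmt.split(":")
            try:
                ad_idx = fmt_keys.index(count_field)
            except ValueError:
                raise FormatError(
                    f"{vcf_path}:{lineno}: record {chrom}:{pos_s} lacks per-pool "
                    f"count field {count_field!r} in FORMAT {fmt!r}"
                ) from None
            info_map = _parse_info(info)
            for ai, alt in enumerate(alts, start=1):
                if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                    if strict:
                        raise FormatError(
                            f"{vcf_path}:{lineno}: non-SNV record {chrom}:{pos_s} {ref}>{alt}"
                        )
                    skipped += 1
                    continue
                counts = []
                for si, sample in enumerate(fields[9:]):
                    parts = sample.split(":")
                    ad = parts[ad_idx] if ad_idx < len(parts) else "."
                    if ad in (".", ""):
                        raise FormatError(
                            f"{vcf_path}:{lineno}: record {chrom}:{pos_s} sample "
                            f"{si + 1} missing {count_field} value"
                        )
                    depths = ad.split(",")
                    try:
                        counts.append(
                            PoolCounts(int(depths[0]), int(depths[ai]))
                        )
                    except (IndexError, ValueError) as exc:
                        raise FormatError(
                            f"{vcf_path}:{lineno}: record {chrom}:{pos_s} sample "
                            f"{si + 1}: cannot parse {count_field}={ad!r}"
                        ) from exc
                key = (chrom, int(pos_s), ref, alt)
                if member_keys is not None:
                    in_db = key in member_keys
                else:
                    in_db = rule(vid, info, info_map)
                variants.append(
                    PoolVariant(
                        chrom=chrom,
                        pos=int(pos_s),
                        ref_allele=ref,
                        alt_allele=alt,
                        qual=0.0 if qual_s in (".", "") else float(qual_s),
                        counts=tuple(counts),
                        in_db=in_db,
                    )
                )
    n = pool_size_n if pool_size_n is not None else header_n
    if n is None:
        raise FormatError(
            f"{vcf_path}: pool_size_n not given and no ##pool_size_n header line"
        )
    if skipped:
        logger.info("read_callset(%s): skipped %d non-SNV/multiallelic records", vcf_path, skipped)
    cs = CallSet(pool_size_n=n, variants=variants, num_pools=n_samples)
    cs.metadata["skipped_non_snv"] = skipped
    cs.metadata["source"] = str(vcf_path)
    return cs


# ---------------------------------------------------------------------------
# Truth sets and membership tables
# ---------------------------------------------------------------------------

def _read_key_tsv(path: Path) -> frozenset[VariantKey]:
    keys: set[VariantKey] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated columns")
            chrom, pos_s, ref, alt = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad position {pos_s!r}") from exc
            keys.add((chrom, pos, ref, alt))
    return frozenset(keys)


def _read_key_vcf(path: Path) -> frozenset[VariantKey]:
    keys: set[VariantKey] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos_s, _vid, ref, alt_s = fields[:5]
            for alt in alt_s.split(","):
                keys.add((chrom, int(pos_s), ref, alt))
    return frozenset(keys)


def read_truthset(path: str | Path) -> TruthSet:
    """Read a truth call set from a VCF or a 4-column (chrom, pos, ref, alt) TSV.

    Duplicate lines are deduplicated; an empty file yields an empty set.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        return TruthSet(_read_key_vcf(path))
    return TruthSet(_read_key_tsv(path))


def write_truthset(truth: TruthSet | Iterable[VariantKey], path: str | Path) -> Path:
    """Write variant keys as a sorted 4-column TSV."""
    path = Path(path)
    keys = truth.keys if isinstance(truth, TruthSet) else frozenset(truth)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(keys):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
    return path


def read_membership(path: str | Path) -> frozenset[VariantKey]:
    """Read a database-membership table (same 4-column TSV as truth sets)."""
    return _read_key_tsv(Path(path))
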