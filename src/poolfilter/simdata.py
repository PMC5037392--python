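"""Synthetic pooled-sequencing cohorts with full ground truth.

The generator emulates the statistical structure a Pool-seq filtering
guideline has to cope with:

* **True variants.**  A population allele frequency is drawn from a
  rare-skewed mixture; each pool of ``n`` diploids receives allele copies
  ``k ~ Binomial(2n, p)`` (conditioned on the variant segregating in the
  cohort), so the true per-pool AF sits on the lattice {0..2n}/(2n).
  Read counts then add binomial sampling noise at the pool's depth,
  with a per-base error rate ε perturbing the read-level ALT fraction.
* **Error sites.**  Sites with no variant allele in any individual, whose
  ALT reads arise purely from sequencing error (rate ε·ρ, where ρ is the
  fraction of errors producing the specific ALT base).  At high depth
  these reach a caller's minimum-evidence floor and surface as spurious
  low-AF calls.
* **Caller behaviour.**  A site is emitted only when at least one pool
  holds ``min_alt_reads`` (default 4) ALT reads, mirroring a pooled
  caller's evidence floor.  QUAL is a stand-in score — NOT a
  reimplementation of any caller's quality model: log-normal per class,
  with the true-variant location increasing with cohort AF (callers
  score on supporting evidence, so common variants earn higher QUAL)
  and the error-site location low and narrow.
* **Annotation.**  A true variant is flagged as database-annotated with a
  probability that increases with its cohort AF (common variants are
  almost always known, rare ones often novel); error sites are never
  annotated by default.

Defaults correspond to a targeted resequencing cohort of 83 pools of 12
individuals at ~352× mean depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy import stats

from .model import CallSet, PoolCounts, PoolVariant, TruthSet, VariantKey, write_truthset

__all__ = [
    "SimConfig",
    "SimRecord",
    "SimTruth",
    "simulate_cohort",
    "expected_spurious_rate",
    "write_sim_outputs",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    All probabilities lie in [0, 1]; ``error_rate`` ε must lie in [0, 0.1)
    (0 gives the error-free limit).
    """

    seed: int = 0
    num_pools: int = 83
    pool_size_n: int = 12
    num_true_variants: int = 3000
    num_error_sites: int = 13000
    #: fraction of true variants drawn from the rare AF component
    rare_fraction: float = 0.8
    rare_af_range: tuple[float, float] = (2.5e-4, 0.01)
    common_af_range: tuple[float, float] = (0.01, 0.5)
    mean_depth: float = 352.0
    #: gamma shape of the depth mixture (negative-binomial dispersion)
    depth_shape: float = 10.0
    #: per-base sequencing error rate ε
    error_rate: float = 0.005
    #: fraction ρ of errors producing the specific ALT base
    error_alt_fraction: float = 1 / 3
    # Stand-in caller quality: log-normal per class.  True variants:
    # location = log(qual_true_base) + qual_af_slope * log(AF / qual_af_pivot),
    # i.e. QUAL rises with the evidence behind the call.
    qual_true_base: float = 700.0
    qual_af_slope: float = 0.3
    qual_af_pivot: float = 0.01
    qual_true_log_sd: float = 0.6
    qual_error_log_mean: float = math.log(42.0)
    qual_error_log_sd: float = 0.35
    qual_min: float = 20.0
    # annotation probability rises from p_min (AF→0) to p_max with scale af_scale
    annot_p_min: float = 0.33
    annot_p_max: float = 0.95
    annot_af_scale: float = 0.02
    p_error_annotated: float = 0.0
    #: caller evidence floor: a site needs this many ALT reads in some pool
    min_alt_reads: int = 4
    #: Dirichlet concentration for unequal DNA contribution (None = balanced)
    dna_dirichlet: float | None = None
    chrom: str = "1"
    region_length: int = 5_000_000

    def validate(self) -> None:
        bad: list[str] = []
        if self.num_pools < 1:
            bad.append("num_pools")
        if self.pool_size_n < 1:
            bad.append("pool_size_n")
        if self.num_true_variants < 0 or self.num_error_sites < 0:
            bad.append("num_true_variants/num_error_sites")
        if self.num_true_variants + self.num_error_sites < 1:
            bad.append("no sites requested")
        if not 0 <= self.rare_fraction <= 1:
            bad.append("rare_fraction")
        for name, (lo, hi) in (("rare_af_range", self.rare_af_range),
                               ("common_af_range", self.common_af_range)):
            if not (0 < lo <= hi <= 1):
                bad.append(name)
        if self.mean_depth <= 0 or self.depth_shape <= 0:
            bad.append("mean_depth/depth_shape")
        if not 0 <= self.error_rate < 0.1:
            bad.append("error_rate")
        if not 0 < self.error_alt_fraction <= 1:
            bad.append("error_alt_fraction")
        if self.qual_true_log_sd <= 0 or self.qual_error_log_sd <= 0:
            bad.append("qual log-sd")
        if self.qual_true_base <= 0 or self.qual_af_pivot <= 0 or self.qual_af_slope < 0:
            bad.append("qual_true_base/qual_af_pivot/qual_af_slope")
        if self.qual_min < 0:
            bad.append("qual_min")
        for name, p in (("annot_p_min", self.annot_p_min),
                        ("annot_p_max", self.annot_p_max),
                        ("p_error_annotated", self.p_error_annotated)):
            if not 0 <= p <= 1:
                bad.append(name)
        if self.annot_af_scale <= 0:
            bad.append("annot_af_scale")
        if self.min_alt_reads < 1:
            bad.append("min_alt_reads")
        if self.region_length < self.num_true_variants + self.num_error_sites:
            bad.append("region_length")
        if bad:
            raise ValueError(f"invalid SimConfig fields: {', '.join(bad)}")

    def annot_prob(self, af: float) -> float:
        """P(a true variant with cohort AF ``af`` is database-annotated)."""
        span = self.annot_p_max - self.annot_p_min
        return self.annot_p_min + span * (1.0 - math.exp(-af / self.annot_af_scale))


@dataclass(frozen=True)
class SimRecord:
    """Ground truth for one simulated site."""

    key: VariantKey
    is_true: bool
    true_af: float
    copies: tuple[int, ...]
    in_db: bool
    emitted: bool


@dataclass
class SimTruth:
    """Complete ground truth of a simulated cohort (emitted sites or not)."""

    pool_size_n: int
    num_pools: int
    records: list[SimRecord]

    def __iter__(self) -> Iterator[SimRecord]:
        return iter(self.records)

    def true_keys(self) -> frozenset[VariantKey]:
        return frozenset(r.key for r in self.records if r.is_true)

    def truth_set(self) -> TruthSet:
        return TruthSet(self.true_keys())

    def true_af_map(self) -> dict[VariantKey, float]:
        return {r.key: r.true_af for r in self.records if r.is_true}

    def n_emitted(self, *, true: bool) -> int:
        return sum(1 for r in self.records if r.emitted and r.is_true == true)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#chrom\tpos\tref\talt\tis_true\ttrue_af\tin_db\temitted\tcopies\n")
            for r in self.records:
                chrom, pos, ref, alt = r.key
                fh.write(
                    f"{chrom}\t{pos}\t{ref}\t{alt}\t{int(r.is_true)}\t"
                    f"{r.true_af:.8g}\t{int(r.in_db)}\t{int(r.emitted)}\t"
                    f"{','.join(map(str, r.copies))}\n"
                )
        return path


def _draw_true_afs(cfg: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    """Rare-skewed population AF mixture, log-uniform within each component."""
    is_rare = rng.random(size) < cfg.rare_fraction
    lo_r, hi_r = np.log10(cfg.rare_af_range)
    lo_c, hi_c = np.log10(cfg.common_af_range)
    afs = np.where(
        is_rare,
        10 ** rng.uniform(lo_r, hi_r, size),
        10 ** rng.uniform(lo_c, hi_c, size),
    )
    return afs


def _draw_copies(cfg: SimConfig, rng: np.random.Generator, p: np.ndarray) -> np.ndarray:
    """Per-pool allele copies Binomial(2n, p), conditioned on >=1 copy overall."""
    two_n = 2 * cfg.pool_size_n
    copies = rng.binomial(two_n, p[:, None], size=(p.size, cfg.num_pools))
    # a called variant segregates in the cohort: redraw monomorphic rows
    for _ in range(10_000):
        empty = copies.sum(axis=1) == 0
        if not empty.any():
            break
        copies[empty] = rng.binomial(
            two_n, p[empty, None], size=(int(empty.sum()), cfg.num_pools)
        )
    else:  # pragma: no cover - pathological AF ranges only
        raise RuntimeError("could not condition on segregating variants")
    return copies


def _read_alt_fraction(cfg: SimConfig, f: np.ndarray) -> np.ndarray:
    """True allele fraction -> expected ALT read fraction under error ε."""
    eps, rho = cfg.error_rate, cfg.error_alt_fraction
    return f * (1 - eps) + (1 - f) * eps * rho


def simulate_cohort(cfg: SimConfig) -> tuple[CallSet, SimTruth]:
    """Generate a pooled call set plus its ground truth, deterministically.

    Returns the emitted :class:`CallSet` (sites reaching the caller's
    evidence floor, ordered by position) and a :class:`SimTruth` covering
    every simulated site, emitted or not.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_sites = cfg.num_true_variants + cfg.num_error_sites
    two_n = 2 * cfg.pool_size_n
    n_chrom_total = two_n * cfg.num_pools

    positions = np.sort(rng.choice(cfg.region_length, size=n_sites, replace=False)) + 1
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    is_true = np.zeros(n_sites, dtype=bool)
    is_true[rng.permutation(n_sites)[: cfg.num_true_variants]] = True

    # per-pool true allele copies
    copies = np.zeros((n_sites, cfg.num_pools), dtype=np.int64)
    pop_af = np.zeros(n_sites)
    if cfg.num_true_variants:
        pop_af[is_true] = _draw_true_afs(cfg, rng, cfg.num_true_variants)
        copies[is_true] = _draw_copies(cfg, rng, pop_af[is_true])
    true_af = copies.sum(axis=1) / n_chrom_total  # realised cohort AF

    # sequencing depth per (site, pool): gamma-poisson (negative binomial)
    nb_p = cfg.depth_shape / (cfg.depth_shape + cfg.mean_depth)
    depth = rng.negative_binomial(cfg.depth_shape, nb_p, size=(n_sites, cfg.num_pools))

    if cfg.dna_dirichlet is not None:
        f = _unbalanced_fractions(cfg, rng, copies, is_true)
    else:
        f = copies / two_n
    alt_p = _read_alt_fraction(cfg, f)
    alt = rng.binomial(depth, alt_p)
    ref = depth - alt

    emitted = (alt >= cfg.min_alt_reads).any(axis=1)

    # stand-in caller quality: evidence-scaled log-normal with a floor
    safe_af = np.where(true_af > 0, true_af, cfg.qual_af_pivot)
    mu_true = (
        math.log(cfg.qual_true_base)
        + cfg.qual_af_slope * np.log(safe_af / cfg.qual_af_pivot)
    )
    log_mu = np.where(is_true, mu_true, cfg.qual_error_log_mean)
    log_sd = np.where(is_true, cfg.qual_true_log_sd, cfg.qual_error_log_sd)
    qual = np.maximum(cfg.qual_min, np.exp(rng.normal(log_mu, log_sd)))
    qual = np.round(qual, 3)

    annot_p = np.where(
        is_true,
        np.array([cfg.annot_prob(a) for a in true_af]),
        cfg.p_error_annotated,
    )
    in_db = rng.random(n_sites) < annot_p

    records: list[SimRecord] = []
    variants: list[PoolVariant] = []
    for i in range(n_sites):
        key = (cfg.chrom, int(positions[i]), str(_BASES[ref_idx[i]]), str(_BASES[alt_idx[i]]))
        records.append(
            SimRecord(
                key=key,
                is_true=bool(is_true[i]),
                true_af=float(true_af[i]),
                copies=tuple(int(k) for k in copies[i]),
                in_db=bool(in_db[i]),
                emitted=bool(emitted[i]),
            )
        )
        if emitted[i]:
            variants.append(
                PoolVariant(
                    chrom=key[0],
                    pos=key[1],
                    ref_allele=key[2],
                    alt_allele=key[3],
                    qual=float(qual[i]),
                    counts=tuple(
                        PoolCounts(int(ref[i, j]), int(alt[i, j]))
                        for j in range(cfg.num_pools)
                    ),
                    in_db=bool(in_db[i]),
                )
            )
    cs = CallSet(
        pool_size_n=cfg.pool_size_n,
        variants=variants,
        num_pools=cfg.num_pools,
        metadata={"simulated": True, "seed": cfg.seed},
    )
    truth = SimTruth(pool_size_n=cfg.pool_size_n, num_pools=cfg.num_pools, records=records)
    return cs, truth


def _unbalanced_fractions(
    cfg: SimConfig,
    rng: np.random.Generator,
    copies: np.ndarray,
    is_true: np.ndarray,
) -> np.ndarray:
    """Effective ALT fraction under unequal per-individual DNA contribution.

    Individuals within a pool contribute Dirichlet-distributed DNA weights;
    each variant's copies are spread over individuals uniformly (at most 2
    per diploid), and the effective read-level fraction is the weighted
    genotype mean instead of copies/(2n).
    """
    n_sites, num_pools = copies.shape
    n = cfg.pool_size_n
    weights = rng.dirichlet(np.full(n, cfg.dna_dirichlet), size=num_pools)
    f = np.zeros((n_sites, num_pools))
    for i in np.flatnonzero(is_true):
        for j in range(num_pools):
            k = copies[i, j]
            if k == 0:
                continue
            genotypes = np.zeros(n, dtype=np.int64)
            # distribute k allele copies over n diploids, capacity 2 each
            slots = rng.permutation(np.repeat(np.arange(n), 2))[:k]
            np.add.at(genotypes, slots, 1)
            f[i, j] = float(np.dot(weights[j], genotypes / 2.0))
    return f


def expected_spurious_rate(cfg: SimConfig) -> float:
    """Analytic probability that an error site reaches the caller's floor.

    An error site is emitted when ALT reads ≥ ``min_alt_reads`` in at
    least one pool, ALT reads being Binomial(d, ε·ρ) at random depth d.
    The per-pool miss probability E_d[BinomCDF(min_alt−1; d, ε·ρ)] is
    computed by enumeration over the negative-binomial depth distribution.
    """
    cfg.validate()
    p_err = cfg.error_rate * cfg.error_alt_fraction
    if p_err == 0:
        return 0.0
    nb_p = cfg.depth_shape / (cfg.depth_shape + cfg.mean_depth)
    d_max = int(stats.nbinom.ppf(1 - 1e-12, cfg.depth_shape, nb_p))
    d = np.arange(d_max + 1)
    pmf = stats.nbinom.pmf(d, cfg.depth_shape, nb_p)
    miss_given_d = stats.binom.cdf(cfg.min_alt_reads - 1, d, p_err)
    miss = float(np.dot(pmf, miss_given_d)) + float(1 - pmf.sum())  # tail ≈ 0
    miss = min(1.0, miss)
    return 1.0 - miss ** cfg.num_pools


def write_sim_outputs(cs: CallSet, truth: SimTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write pools VCF, membership TSV and truth TSV for a simulated cohort."""
    from .model import write_callset  # local import to avoid cycle at module load

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": write_callset(cs, out_dir / "pools.vcf"),
        "membership": write_truthset(
            frozenset(v.key for v in cs.variants if v.in_db), out_dir / "membership.tsv"
        ),
        "truth": write_truthset(truth.truth_set(), out_dir / "truth.tsv"),
        "sim_truth": truth.write(out_dir / "sim_truth.tsv"),
    }
    return paths
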