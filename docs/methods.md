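# Methods

## The filtering problem

A pooled library of *n* diploids can only carry allele frequencies on
the lattice {0, 1, …, 2n}/(2n); for the default *n* = 12 the smallest
real per-pool AF is 1/24 ≈ 0.042. A pooled caller that accepts a small
absolute number of supporting reads (CRISP-style floor of 4) will, at
depths of several hundred ×, also emit sites whose ALT reads are pure
sequencing error — these cluster at per-pool AFs far below the lattice
minimum and at low caller quality. Distinguishing them from genuine
rare variants (cohort AF < 0.01, strict) is the entire problem: in a
typical targeted Pool-seq cohort the large majority of calls are rare,
and false positives concentrate exactly there.

## The KS-guided threshold choice

Variants are partitioned by presence in any public database (in.db vs
novel). The guideline's premise: database membership and caller quality
are conditionally independent for *genuine* variants, so the two QUAL
distributions should be similar; an excess of low-QUAL mass in the
novel class measures error contamination. For each candidate threshold
*t* of a filter, the filter is applied, the surviving QUALs are
stratified, and the two-sample Kolmogorov–Smirnov statistic

    D(t) = sup_x | F_in.db(x; t) − F_novel(x; t) |

is evaluated exactly at the pooled sample points (right-continuous
ECDFs, ties allowed). The selected cut-off is the grid argmin of D;
ties break toward the smallest threshold, i.e. the least aggressive
filter. Grid points at which either class empties are recorded as
missing and excluded from the argmin with a warning. The statistic is
implemented natively (sorted searchsorted ECDF evaluation); an
established reference implementation is used in the tests as an
independent oracle, never as the implementation.

Default grids follow the guideline: QUAL thresholds 20–200 in steps of
1 (181 evaluations, strict `QUAL > t`), MPF thresholds 0–5% in steps of
0.1% (51 evaluations, generated as k/10 to keep grid values exact).
The MPF comparison "ALT reads < t% of depth" is done in exact rational
arithmetic (`100·alt·den < num·depth`) so decimal grid points such as
2.6 behave as written, with no float boundary artifacts.

Only the D statistic is used for selection; no p-value enters the
procedure (a p-value would conflate distributional similarity with
sample size, which the scan deliberately varies).

## Filters and their combination

* **QF** removes a variant from every pool when `QUAL ≤ t`.
* **MPF** acts per (variant, pool) cell: ALT counts strictly below *t*%
  of the cell's depth are reset to 0 (the literal "reset to 0" rule —
  the pool then contributes AF 0 to the cohort mean through its
  unchanged depth); a variant with no remaining ALT reads anywhere is
  removed. QUAL is a variant-level score and is left untouched, also
  for partially reset variants entering later KS samples.
* Both filters are idempotent, and survivors shrink monotonically in
  the threshold.
* The combined call set is the key-set intersection of the two
  survivor sets, carrying the MPF-adjusted counts and original QUAL.
  The two scans are one-dimensional and independent; no joint (QF, MPF)
  optimisation is attempted.

## Allele frequencies

Per-pool AF = ALT reads / (REF + ALT reads); undefined at zero depth.
Cohort AF = unweighted mean of the defined per-pool AFs. Pools with no
coverage are excluded from the mean by default (configurable to count
as zero): the unweighted-mean definition does not address missing
coverage, and excluding avoids biasing AF downward at poorly covered
sites. Rarity is classified on cohort AF with a strict cutoff
(default 0.01).

## Validation metrics

Against a truth set of (chrom, pos, ref, alt) keys from individual
sequencing: TP = |called ∩ truth|, FPR = 100·(called − TP)/called,
TP retained = 100·TP_after/TP_before. Percentages are reported to two
decimals, rounded half away from zero, computed through exact rational
arithmetic so printed-table reproduction is bit-stable. Rarity strata
for before/after comparisons use the *unfiltered* cohort AFs for both
rows, so filtering cannot move a variant between strata. Matching is
exact-key; no positional fuzziness (same reference build assumed).

AF concordance against an external source reports R² (the squared
Pearson correlation) and min/quartiles/median/mean/max of the paired
AF differences.

## The synthetic cohort generator

No suitable pooled cohort with per-pool counts and individual-level
truth is publicly available, so the package ships a generator whose
defaults describe the study conditions the guideline targets: 83 pools
of 12 diploids, negative-binomial depth with mean 352× (gamma shape 10,
giving a realistic ~32% coefficient of variation), per-base error rate
ε = 0.005 with ρ = 1/3 of errors producing the specific ALT base, and a
caller evidence floor of 4 ALT reads in at least one pool.

* **True variants** (default 3000): population AF from a rare-skewed
  mixture — 80% log-uniform on [2.5·10⁻⁴, 0.01], 20% log-uniform on
  [0.01, 0.5] — so that, as in targeted cohort data, roughly 80% of
  calls are rare. Pool allele copies are Binomial(2n, p), redrawn until
  the variant segregates in the cohort (a called variant has at least
  one carrier). Read counts are Binomial(d, f(1−ε) + (1−f)ε·ρ) with
  f = copies/(2n).
* **Error sites** (default 13000): zero copies everywhere; ALT reads
  Binomial(d, ε·ρ). Under the defaults ~31% of error sites reach the
  evidence floor, yielding an unfiltered cohort FPR near 57% —
  the high-FPR regime the guideline is designed for. The emission
  probability has a closed form (`expected_spurious_rate`): 1 − m^P
  with m = E_d[BinomCDF(floor−1; d, ε·ρ)], the expectation enumerated
  over the depth distribution; the Monte-Carlo emission rate is checked
  against it in the tests.
* **QUAL** is a stand-in score, *not* a reimplementation of any
  caller's quality model. True variants draw log-normal QUAL with
  location log(700) + 0.3·log(AF/0.01) — quality rises with the
  evidence behind a call, so common variants score far higher than
  rare ones — and scale 0.6. Error sites draw log-normal(log 42, 0.35):
  a low, narrow band, reflecting that spurious calls rest on a handful
  of reads and concentrate below QUAL ≈ 100. All QUALs are floored at
  20 and rounded to 3 decimals. The narrow error band matters
  structurally: it makes D(t) fall steeply while errors are being
  removed and then turn upward once they are exhausted, giving the scan
  an interior optimum, which is the regime the guideline assumes.
* **Annotation**: a true variant is database-annotated with probability
  0.33 + 0.62·(1 − exp(−AF/0.02)) — increasing in AF from ~1/3 for the
  rarest variants to 0.95 for common ones, matching the observation
  that most common variants are already catalogued while most rare
  variants are novel. Error sites are never annotated by default
  (configurable).
* Unequal per-individual DNA contribution can be switched on
  (Dirichlet weights within each pool) but is off by default, matching
  a protocol that balances DNA per genome.
* Determinism: all draws flow through one seeded NumPy generator in a
  fixed order; the same seed reproduces the cohort byte-for-byte
  through the VCF writer.

What the generator does *not* model: read-level artifacts (mapping
error, strand bias, base-quality structure), INDELs, linkage between
sites, caller-specific quality semantics, and annotation errors in the
databases themselves. Passing the recovery tests therefore shows that
the procedure behaves as designed under its own assumptions — errors
concentrated at low AF and low QUAL, annotation independent of quality
given the class — not that any particular real data set will yield the
same thresholds.

## Problem sizes and test design

The test suite exercises most properties on a down-scaled cohort
(20 pools, 2000 sites) and runs the full-size default cohort for the
headline recovery property: over five seeded cohorts, the complete
pipeline (both scans → apply → intersect → truth comparison) must cut
the FPR at least five-fold while retaining at least 90% of true
variants (medians across seeds), with the selected QUAL threshold lying
between the error-class and true-class QUAL medians. Five full cohorts
keep that check under half a minute while leaving headroom for the
stochastic spread between seeds.

## I/O choices

Call sets are read and written as VCF 4.2 with one sample column per
pool, per-pool counts in an allelic-depth (`AD`) FORMAT field (the
field name is configurable, since pooled callers differ), database
membership as the standard `DB` INFO flag or a non-missing ID on write,
and the pool size recorded in a `##pool_size_n` header line. The
reader's default membership rule (non-'.' ID or `DB` flag) can be
overridden by an explicit membership table. QUAL is serialized at full
double precision and parsed back losslessly; htslib-based readers
truncate QUAL to single precision, which is why the narrow-schema I/O
is implemented natively (files remain valid VCF 4.2 for any reader —
validity is cross-checked against an htslib parser in the tests).
Multiallelic records are rejected by default and can be split into
biallelic records or skipped; non-SNV records are excluded with a
counter (or an error in strict mode). Truth sets and membership tables
are 4-column TSVs (or VCFs for truth), deduplicated on read.

## Known limitations

* The KS objective's flat region beyond the error-exhaustion point
  means the selected QF threshold has seed-to-seed spread; the
  tie-break toward smaller thresholds mitigates but does not remove
  this.
* The in.db/novel scan defaults to all variants (`subset="all"`);
  restricting to rare variants is supported but changes the D scale.
* Cohort AF is the unweighted pool mean; no correction for unequal
  pool depths or unequal DNA contribution is applied at estimation
  time.
* INDELs are out of scope throughout.
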