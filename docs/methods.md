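# Methods

## Scope and model

`ctdnamon` implements the analytical core of serial ctDNA monitoring during
neoadjuvant chemotherapy (NACT) for gastric cancer: duplex-barcode molecule
grooming, a panel-of-normals background-error model, tissue-informed and
naive positivity calling, longitudinal response metrics, and survival
stratification. All stages operate on an abstract targeted panel — 1-based,
fully closed integer coordinates 1..`panel_positions` with single-base
alleles and per-position gene labels — because nothing in the method depends
on genomic sequence context beyond the substitution class. Wet-lab steps,
read alignment, functional annotation and copy-number segmentation are out
of scope; copy-number state is a pure ratio threshold (loss ≤ 0.65,
gain ≥ 1.50, boundaries inclusive) applied to externally supplied
tumor/normal depth ratios per unit.

## Molecule grooming

Reads sharing (position, barcode pair, strand) form a strand-family. The
molecule key canonicalizes the pair by sorting its two tags, so the
plus-strand pair (a, b) and the minus-strand pair (b, a) identify one
double-stranded source molecule; the canonicalization is an involution by
construction. Family consensus is the read-weighted majority allele, subject
to an agreement threshold: unanimity for families of ≤ 3 reads, ≥ 80%
otherwise (both configurable). When both strand-families of a molecule
survive, their consensus alleles must agree or the molecule is rejected as a
single-strand artifact. Simplex molecules (one strand observed) are
retained, flagged, and count toward position totals and — by default —
toward allele support; a `duplex_only` policy restricts support to
duplex-confirmed molecules while keeping simplex molecules in the totals,
since the positivity thresholds are defined on distinct supporting molecules
and total molecules, not on duplex status. A single read is a valid
molecule: the evidential burden sits in the positivity thresholds, not the
groomer. Malformed records are dropped and counted, never fatal. Ties
between equally supported alleles resolve to the first allele in sort order,
a deterministic choice that only matters for degenerate families.

## Background error model and the noise rule

Healthy-donor pileups (default 30 donors) pool into a per-(position,
substitution) database: pooled background allele fraction = Σ support /
Σ total over donors covering the position, plus the maximum per-donor
support. A candidate with `support` of `total` molecules is **signal** only
if both
P(X ≥ support | total, pooled background) < α under the exact binomial tail
(α = 0.01, per candidate, no multiplicity correction), and
support > the normals' maximum support. The phrase "not significantly
higher" in the source protocol names no test; the exact binomial tail plus
strict max-exceedance is this package's documented instantiation, chosen
because it handles the single-digit molecule counts involved without
approximation and mirrors the dual allele-fraction / supporting-reads
phrasing. Keys never observed in any donor have background 0 and maximum
support 0, so for them the rule reduces to "any support at all" and the
burden passes to the positivity thresholds. The joint criterion is
conservative: its realized per-site false-call rate sits well below α
(asserted ≤ 0.02 at α = 0.01 over ≥ 10⁴ null site-tests).

## Calling chain

Candidates are non-reference alleles at VAF ≥ 0.1% (inclusive). Indel allele
pairs are reduced to minimal left-aligned representation before
set-membership against tissue variants. The white-blood-cell control flags
candidates with WBC allele fraction > 0.25% or WBC support > 1
(package defaults; the source protocol states only that the buffy coat is
used for germline/CHIP filtering), labeling fraction > 35% as germline and
the rest as clonal hematopoiesis; candidates at WBC-uncovered positions are
kept and annotated. Positivity: support ≥ 3 (tissue-informed) or ≥ 6
(naive), total ≥ 100, all thresholds inclusive. "Total reads ≥ 100" is
interpreted as consensus molecules, consistent with the grooming's purpose
of making molecules the unit of evidence. A sample is positive iff ≥ 1 PASS
somatic variant. Tissue-informed calling dominates naive calling by
construction (its support threshold is strictly lower at equal total).

## Longitudinal metrics

Negative samples carry max-VAF 0 and GA count 0, so Δ statistics
(later − earlier) are defined for every paired patient; Δ is antisymmetric
by construction. The four clearance classes partition all status pairs.
Detection rates are reported as 1-decimal percentages to match the field's
presentation. Gene-level alteration frequencies count each patient once per
gene and report genes altered in strictly more than 10% of the cohort.
Concordance fractions are computed over the union of tissue and plasma GAs.

## Statistical tests

Two-sided p-values throughout. Wilcoxon signed-rank drops zero differences
and uses exact 2^m sign-pattern enumeration for m ≤ 25 without ties, else
the normal approximation with tie and continuity corrections; the rank-sum
test uses exact enumeration when the smaller sample has ≤ 10 observations
and the pooled data are tie-free. Both delegate to scipy.stats, whose exact
paths coincide with these conventions (verified against independent
enumeration oracles in the test suite). Contingency tables use Pearson
chi-square without continuity correction, falling back to Fisher's exact
(two-sided by the point-probability method) for 2×2 tables with any
expected count < 5, and to a hand-written full conditional enumeration for
larger sparse tables with total ≤ 200. Mean comparisons use the
pooled-variance t-test (2 groups) or one-way ANOVA (≥ 3).

Kaplan–Meier estimation and the weighted log-rank family are implemented
in-package. The KM estimator counts subjects censored at an event time as at
risk for that time; S(t) is the right-continuous step function, and 3-year
overall survival is S(36 months). The group comparison is the weighted
log-rank with weight = total number at risk at each event time
(Gehan–Breslow–Wilcoxon), χ² statistic with groups − 1 degrees of freedom
via the multivariate hypergeometric covariance; weight ≡ 1 recovers the
standard log-rank, and both weightings are cross-checked against lifelines
in the tests. No Cox regression or hazard-ratio estimation is exposed: the
monitored cohort's survival analysis is KM + GBW.

## Synthetic cohort generator

The generator defines the study conditions; every stochastic quantity is
drawn from `numpy.random.Generator` seeded by the configuration.

* **Cohort**: 79 patients; response mix PR 0.32 / SD 0.63 / PD 0.05
  (the paired-sample composition of the monitored cohort: 21/41/3).
* **Variant truth**: per patient, Poisson(8) panel variants assigned to
  shared / tissue-only / plasma-only categories at 0.338 / 0.562 / 0.095.
  The printed fractions sum to 0.995 (rounding in the source); the
  configuration accepts them verbatim and renormalizes.
* **Trajectories**: baseline max-VAF is log-normal with cohort mean 0.50%
  and log-scale spread 1.5 — the spread places ~40% of patients below the
  ~0.1% detection limit at 2500 consensus molecules, reproducing a ~60%
  baseline detection rate while keeping the stated cohort mean. Other
  plasma variants scale by fixed per-variant relative fractions in
  (0.15, 1]. Post-NACT multiplicative factors by class: PR ×0.16 (matching
  the 0.50% → 0.08% responder means), SD ×1.0, PD ×2.5, each with
  log-normal noise (σ = 0.25) but clamped to the class direction, so the
  decline/rise holds per patient by construction. Post-surgery factors
  PR ×0.6 / SD ×0.9 / PD ×1.8 are package stand-ins: no per-class
  post-surgery dynamics are published, only an overall detection rate.
* **Background errors**: 10% of panel sites carry one error-prone
  substitution with a log-normal rate, mean 1e-4 (σ_log = 1), at the
  consensus-molecule level. Duplex consensus suppresses raw sequencing
  error by orders of magnitude; 1e-4 is a field-typical residual
  background for barcode-groomed cfDNA assays and is the regime in which a
  per-candidate α = 0.01 noise rule plus the ≥ 6-molecule naive threshold
  yields variant-free sample-level false-positive rates below 5%, the
  specificity the calling chain is specified to have. Raising the mean
  toward 1e-3 makes sample-level specificity collapse at panel scale no
  matter the polishing — a useful reminder that the method's specificity
  claim is conditional on duplex-grade backgrounds.
* **Read emission**: each consensus molecule yields one family row per
  sequenced strand (duplex fraction 0.8, reversed tag order on the minus
  strand, family size 1 + Poisson(1)); a 0.002 single-strand artifact rate
  injects strand-discordant errors that the duplex decoder removes.
  Germline variants (~50% VAF) and, with probability 0.15 per patient,
  a clonal-hematopoiesis variant (~2% VAF) appear in both plasma and the
  WBC control to exercise the filter.
* **Survival**: exponential, baseline hazard 0.00874/month (so the
  ctDNA-negative stratum has S(36 mo) ≈ 0.73), multiplied by 3.4 when the
  post-NACT tumor fraction reaches the 0.1% detectability proxy; early
  loss to follow-up with probability 0.2 (uniform on 4.9–36 months, the
  floor being the cohort's minimum follow-up) plus administrative
  censoring at 60 months. This is a testing harness for KM/GBW machinery,
  not a claim about the cohort's true hazard structure.

### What the generator does and does not emulate

It reproduces the statistical skeleton the analysis relies on: depth-limited
binomial sampling of molecule counts, position-specific background errors
shared between donors and patients, tissue/plasma overlap structure,
response-class VAF dynamics, and status-dependent survival. It does not
model fragment-length or trinucleotide-context error features, GC or
coverage bias, library-size variation between samples, contamination,
clonal evolution (variants never appear or vanish except through VAF
scaling), or correlated errors across positions. Passing tests therefore
demonstrate that the pipeline's logic and statistics behave as specified
under idealized molecule-count sampling — not that the thresholds would
achieve the same operating characteristics on real cfDNA.

## Scaling choices

Two equivalent sampling paths exist. The read-level path emits family rows
per molecule and is the one grooming operates on; it is exercised at single
sites and small panels where molecule resolution is the point. The
consensus-level path (`simulate_sample_pileup`) draws the same per-site
binomial counts directly and backs the cohort-scale workflow
(`ctdnamon.workflows.analyze_cohort`), replicate studies and the acceptance
script; a 79-patient, 3-timepoint cohort runs in seconds this way. The
file-based pipeline demo (`examples/cohort.yaml`) uses 8 patients, a
300-position panel and 1200 molecules per site so a full read-level run
finishes in well under a minute. Problem sizes used by the acceptance
script: 200 replicates per spiked VAF, 10⁴ pooled alterations for overlap
recovery, 500 variant-free samples for specificity, 1000 null and 200
alternative replicates for GBW size and power.

## Numerical and degenerate-input conventions

Exact binomial tails are computed as survival functions, never normal
approximations. All-zero signed-rank inputs return p = 1 with a degeneracy
note. Empty pileups produce empty candidate lists; an empty union of GAs
reports zero concordance fractions with an explicit flag. Zero-margin
contingency rows/columns are dropped with a warning; all-zero tables are
errors. Survival times must be finite and positive; a cohort with no events
is an error for the GBW test and a flat S(t) = 1 curve for KM. Gzip outputs
are written without timestamps so repeated seeded pipeline runs are
byte-identical, which the manifest checksums assert.

## Known limitations

The duplex decoder contract (agreement thresholds, rejection semantics) is
this package's explicit stand-in for the proprietary grooming protocol it
abstracts, whose exact rules are unpublished. The noise rule's test choice
is likewise a documented decision, not a reconstruction. Per-class
trajectory parameters beyond the responder means are stand-ins exposed in
configuration. The positivity rule is per-variant; no aggregate sub-threshold
MRD scoring is attempted.
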