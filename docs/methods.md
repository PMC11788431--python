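# Methods

This note documents the models, rules, and numerical choices behind
`screenhit`, and what the synthetic data can and cannot establish.

## Screen enrichment model

Each guide is tested on the 2×2 table (guide reads vs all other reads) ×
(sorted vs unsorted sample). No normalization is applied before testing:
the Fisher exact test conditions on the table margins, so sequencing depth
enters through the margins rather than through scaled counts.

**Two-tailed p.** The point-probability definition: with margins fixed,
sum the hypergeometric probabilities of all tables whose point probability
is at most the observed one, within a relative tolerance of 1+1e−7 that
guards floating-point ties. Implementation: the support of the observed
margin family is enumerated once, point probabilities are computed from
log-binomial coefficients (`gammaln`), sorted, and cumulatively summed;
the per-table p is then a binary search. A shared log-factorial table makes
repeated screens at the same depth cheap, and families are memoized for
workloads that revisit the same margins. When every table in the family
falls inside the tail set the p-value is returned as exactly 1 (the
analytic value) rather than the accumulated float sum. Agreement with
exact-integer enumeration is ≤ 2×10⁻¹³ over all tables with margins ≤ 60,
and with `scipy.stats.fisher_exact` to ~1e−12 on random tables.

**Odds ratio.** The sample odds ratio ad/bc. When any cell is zero, 0.5 is
added to every cell (Haldane) so the ratio stays finite for thresholding;
the correction never touches the p-value, which comes from exact
enumeration of the uncorrected table.

**Multiplicity.** BH step-up over a single family: all testable guides of
the screen. Guides with zero counts in both samples are untestable and are
excluded from the family size m — a documented, configurable choice; with
~4 guides per gene and typical depths the difference from including them
is negligible, but the exclusion keeps q-values interpretable as FDR over
tests actually performed.

**Selection rules.** A guide is enriched iff odds ratio ≥ 2 AND BH-adjusted
p < 0.05 (both defaults configurable). Enrichment is one-directional:
depleted guides can be highly significant but are never "enriched". A gene
is a hit at ≥ 4 enriched guides and a candidate of interest at ≥ 2; the
hit rule is interpreted as *at least* four. Non-targeting controls are
excluded from gene aggregation. Gene ranking is by best adjusted p, then
number of enriched guides, then gene symbol (deterministic ties).

## Read extraction and assignment

Reads are searched for the literal vector anchor
`GGCTTTATATATCTTGTGGAAAGGACGAAACACCG`; the 20 bases after its first
occurrence are the candidate protospacer. The anchor match is exact and
reads are not reverse-complemented — the assay fixes the orientation.
Assignment is unique-best Hamming matching with a ≤ 3-mismatch budget:
exact hits to a protospacer that is duplicated in the library are
ambiguous; two or more guides tying at the minimum distance are ambiguous;
`N` never matches. The mismatch search uses pigeonhole chunking (four
chunks for budget 3 — any in-budget match is exact in at least one chunk),
so counting streams reads in a single pass with memory proportional to the
library only. Every read is tallied under exactly one of: assigned,
no_anchor, short_tail, no_match, ambiguous.

## Synthetic screen generator

The generator emulates a single-pool sorted screen at the count level:

- **Library skew**: per-guide unsorted abundances ~ log-normal(0, σ),
  normalized. Default σ = 1.0, a heavy-tailed representation typical of
  lentiviral libraries.
- **Selection**: guides of planted hit genes get their abundance
  multiplied by the enrichment factor in the sorted pool, then abundances
  are renormalized. Default: 50 hit genes of 1000, factor 8 — a strong,
  FACS-scale enrichment.
- **Sequencing**: one multinomial draw of `reads_per_sample` (default
  2×10⁶, i.e. ~250× mean guide coverage at 4000 guides twice over) per
  sample, conditioning on total depth like a sequencing lane.
- **Reads**: per counted unit, a 0–5-nt random stagger + anchor +
  protospacer + constant scaffold suffix; substitution errors at a per-base
  rate everywhere except the anchor, so extraction failures are introduced
  only through explicit junk-read injection.

All randomness flows from a single integer seed; identical configurations
give byte-identical FASTQ.

What the simulator does **not** model: infection multiplicity and
clonal dynamics, sorter impurity, PCR jackpotting (counts are multinomial,
not over-dispersed per guide beyond the library skew), guide-efficacy
variation within a gene, and anchor-region sequencing errors. Passing
round-trip and power tests therefore demonstrates correctness of the
pipeline's bookkeeping and statistics under the stated model, not
performance on real screens with those additional noise sources.

Problem sizes used in the checked-in tests and the acceptance script
(1000 genes × 4 guides, 2×10⁶ reads/sample; 100–200 null replicates;
100 random survival cohorts of n = 30–200; margins ≤ 60 for the exhaustive
Fisher sweep) are the package's reference desk-scale conditions.

## Survival analysis

Kaplan–Meier is the standard product-limit estimator; at tied times events
are processed before censorings. The log-rank test is the Mantel–Haenszel
form with grouped hypergeometric treatment of ties; zero total variance
(no events, degenerate risk sets) yields an undefined-test flag rather
than a number.

Fixed grouping rules: median, mean, first quartile, last quartile, and
first-vs-last quartile (middle half excluded). Quartiles use linear
interpolation; values equal to a threshold always go to the low group, so
splits are deterministic under ties.

**Scan method.** Candidate cutoffs are midpoints between consecutive
distinct expression values; a cutoff is admissible when both groups keep at
least max(3, ⌈0.1·n⌉) samples. The minimum group size is this package's
guard (no rule is inherent to the method) — without it, extreme cutoffs
with 1–2 samples produce unstable maxima. Ties on the statistic break
toward the more balanced split, then the lower cutoff. The reported p is
the nominal log-rank p of the winning cutoff, uncorrected for having
scanned many cutoffs; it is anti-conservative under the null (empirically
the type-I error at nominal 0.05 exceeds 0.05 by construction of a maximum
over correlated tests), so `n_scanned` is part of the result and of every
output table.

## Motif scanning

The GLI consensus `GACCACCCA` is matched with its last five residues
(`ACCCA`) required exactly — they are the binding-critical core — and a
configurable mismatch budget (default 1) on the four-residue 5′ prefix.
This hard-core/soft-prefix rule reflects that functional sites diverge
from the full 9-mer mainly at the 5′ end. Both strands are scanned; hits
are reported at plus-strand, 0-based half-open coordinates with the
matched sequence in motif orientation (BED6: name = matched sequence,
score = mismatch count). Windows containing non-ACGT characters are
skipped with a warning. The expected exact-match count in uniform random
DNA, 2·(L−8)·4⁻⁹ for both strands, is exposed for rate sanity checks.

## Assay formulas

- **Percent input**: `100·2^((ct_input − log2(1/f)) − ct_ip)` with input
  fraction f required as a parameter (default 0.01, a documented
  assumption — the fraction is assay-specific).
- **2^−ΔΔCt**: Livak form; ΔCt per sample, control group summarized by the
  arithmetic mean ΔCt (so the control's geometric-mean fold is exactly 1);
  replicate folds should be aggregated geometrically.
- **Tumor volume**: L·W²/2 in mm³.
- **Half-life**: unconstrained least squares of ln(level) on time;
  t½ = ln2/(−slope). A slope ≥ −1e−12 (no decay within numerical
  precision) is flagged undefined instead of returning a huge or negative
  half-life. A two-point series reduces to the exact closed form.

## Numerical and design notes

- Fisher p-values: float agreement with exact enumeration degrades slowly
  with margin size (≈1e−13 at margins ≤ 60, ≈1e−12 at margins ~10³);
  all thresholds in the pipeline act at scales far above this.
- `bh_adjust` validates inputs strictly ([0,1], no NaN) — untestable
  entries must be excluded by the caller, as `call_guides` does.
- Library parsing auto-detects comma/tab, requires a header, rejects rows
  with non-20-nt or non-ACGT sequences (counted, with reasons), and flags
  duplicate protospacers, which downstream counting treats as inherently
  ambiguous.
- The simulated null screens in the test suite share one library across
  replicates and vary only the count draw — the quantity under test is the
  false-call rate of the statistics, not library-generation variance.
- Known limitation: with a single sorted and a single unsorted pool there
  is no replicate-based dispersion estimate; the Fisher model treats count
  variation as purely sampling variation, which is exactly the analysis
  contract this package implements (MAGeCK-style negative-binomial
  modeling is out of scope).
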