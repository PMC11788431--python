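# screenhit

Hit calling for fluorescence-sorted pooled CRISPR knockout screens, with
companion analyses: maximally selected survival cutpoints, GLI consensus
motif scanning, and the closed-form assay quantifications that surround a
screen's validation experiments.

## Who this is for

A pooled knockout screen sorts a library-transduced cell population on a
reporter phenotype and asks which guides are over-represented in the sorted
pool relative to the unsorted bulk. This package implements that analysis
end to end for people who have (or simulate) such screens:

1. **Guide library** — parse and validate a Brunello-style annotation table
   (guide id, gene symbol, 20-nt protospacer); non-targeting controls are
   kept under a reserved label and excluded from gene-level calls.
2. **Counting** — extract the 20 bp following the fixed vector anchor
   `GGCTTTATATATCTTGTGGAAAGGACGAAACACCG` from each FASTQ read and assign it
   to the unique best library guide within 3 mismatches (ties and
   duplicated protospacers are discarded as ambiguous, mirroring unique
   best-stratum alignment with `-m 1 --best -v 3`).
3. **Enrichment** — per guide, a two-tailed Fisher exact test on the 2×2
   table (guide vs all other reads × sorted vs unsorted), Benjamini–
   Hochberg FDR across all testable guides, and the selection rule
   *odds ratio ≥ 2 AND adjusted p < 0.05*. A gene is a **hit** when ≥ 4 of
   its guides are enriched, and a *candidate of interest* at ≥ 2.
4. **Simulation** — a seeded generator plants hit genes at a chosen
   enrichment factor under log-normal library skew and multinomial
   sequencing, and can emit the reads as FASTQ, so the whole pipeline is
   testable against known ground truth.
5. **Survival** — Kaplan–Meier estimation, the Mantel–Haenszel log-rank
   test, five fixed expression-grouping rules, and the *scan method*: the
   expression cutoff maximizing the log-rank statistic, reported with its
   nominal p and the number of cutoffs scanned.
6. **Motif scanning** — occurrences of the GLI consensus `GACCACCCA` with
   the binding-critical last five residues required exactly and a mismatch
   budget on the 5′ prefix; strand-aware BED output.
7. **Assay quantification** — percent-input ChIP recovery, 2^−ΔΔCt relative
   expression, caliper tumor volume (L·W²/2), and cycloheximide-chase
   half-life.

## The statistics at the core

For guide *g* with *a* reads in the sorted sample (total *N_s*) and *c* in
the unsorted sample (total *N_u*), the 2×2 table is
(*a*, *N_s*−*a*; *c*, *N_u*−*c*). The two-tailed p-value sums
hypergeometric point probabilities (margins fixed) over all tables whose
point probability is ≤ the observed one (relative tolerance 1+1e−7); the
odds ratio is *ad/bc* with Haldane's +0.5 applied to every cell only when
some cell is zero, and only for the ratio — never for p. BH adjustment is
the standard step-up `q_(i) = min_{j≥i} m·p_(j)/j`, one family per screen
over all testable guides.

The scan method maximizes the log-rank statistic
`U²/V`, `U = Σ_i (d_{A,i} − e_i)`, `V = Σ_i v_i` (hypergeometric mean and
variance at each distinct event time) over all cutoffs for which both
groups keep ≥ max(3, ⌈0.1·n⌉) samples; values equal to the cutoff go to the
low group.

## Worked example

The numbered drivers under `analysis/` reproduce the project's analyses;
large intermediates (FASTQ) go to `scratch/`, summaries to `results/`.

```bash
python analysis/01_simulate_screen.py
python analysis/03_call_hits.py
```

On the reference simulation (1000 genes × 4 guides, 50 hit genes planted at
8-fold enrichment, 2×10⁶ reads per sample, seed 1) the hit caller prints:

```json
{
  "n_guides_tested": 4000,
  "n_guides_enriched": 200,
  "n_hit_genes_called": 50,
  "n_hit_genes_planted": 50,
  "recovery_pct": 100.0,
  "false_hit_genes": [],
  "n_candidates_of_interest": 50
}
```

All 200 guides of the 50 planted genes pass the OR ≥ 2 & padj < 0.05 rule,
every planted gene reaches the four-guide hit rule, and no unplanted gene
is called — the conjunction of four independent guide-level tests makes the
gene rule very conservative under the null. `analysis/02_count_reads.py`
confirms the read-space round trip: error-free FASTQ emission reproduces
the planted counts exactly, and at 1% per-base error 99.995% of
anchor-bearing reads are still assigned within the 3-mismatch budget.

The survival driver (`analysis/04_survival_scan.py`) shows the scan
method's character on a 120-sample cohort: with a real expression effect
the scan finds log-rank statistic 17.57 (nominal p = 2.8×10⁻⁵, 97 cutoffs
scanned) where the median split gives 8.85 (p = 0.0029); on a null cohort
the scan's best statistic is still 2.65 — the maximum over 97 correlated
tests is anti-conservative, which is why `n_scanned` is always reported
alongside the nominal p.

Command-line equivalents exist for every stage, e.g.:

```bash
screenhit simulate --genes 1000 --hits 50 --factor 8 --seed 1 --out scratch/demo
screenhit test --counts scratch/demo/counts.tsv --sorted sorted --unsorted unsorted --out scratch/demo/hits
screenhit motif --fasta promoter.fa --consensus GACCACCCA --core 5 --prefix-mm 1 --out sites.bed
```

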