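# Methods

## Problem and data model

The package analyzes case-control cohorts of tuberous sclerosis complex
(TSC) patients, each carrying exactly one germline *TSC1* or *TSC2* variant
described in coding-DNA HGVS notation, with a binary renal angiomyolipoma
(RAML) phenotype. Records with multiple variants are rejected at ingest:
when two variants are present the pathogenic one cannot be determined from
the record alone, so no tie-break is invented.

Coordinates are 1-based inclusive throughout. CDS position *p* belongs to
residue ⌈p/3⌉. The packaged transcript geometry uses the true coding
lengths (TSC1: 3,495 nt / 1,164 aa; TSC2: 5,424 nt / 1,807 aa), with TSC1
exons 1–2 non-coding and TSC2 numbered over its 41 coding exons (one
non-coding guiding exon outside the numbering).

### Synthetic exon boundaries

Published domain definitions tie amino-acid intervals to exon ranges
(e.g. TAD1 = aa 1163–1259 = exons 29–30) but exact exon boundary
coordinates are only available from transcript databases. The packaged
tables (`exons_*.synthetic.tsv`) are therefore **constructed**: boundaries
were chosen once so that every stated aa↔exon attribution holds, exon spans
tile the CDS exactly, and each file says so in its header. Every
association-level result in this package is independent of the exact
boundaries (they enter only through exon/region labels of synthetic
variants); for positionally exact annotation of real cohorts, drop
coordinate-accurate tables (same columns, named `exons_<gene>.tsv`) into a
directory and pass `reference_dir`. `validate_reference` enforces, per
gene: exon spans disjoint/ordered/tiling `[1, cds_length]`;
`protein_length == cds_length/3 − 1`; domain aa intervals inside the
protein and, translated to nucleotides, occupying exactly their stated exon
range; regions partitioning the coding exons.

## Variant classification

Order of precedence, applied to a parsed variant plus an optional declared
protein consequence:

1. **Splice-site**: any intronic offset within ±2 (the canonical
   donor/acceptor dinucleotides; window configurable). A declared missense
   consequence overrides a splice offset — dual-effect variants are tallied
   once, as declared. Offsets beyond the window with no declared label are
   classified splice-site with a `low_confidence` flag (or raise in strict
   mode): a deep-intronic substitution has no other slot in the six-type
   taxonomy, and a silent missense guess would be worse.
2. **Large fragment**: deletions/duplications/delins affecting ≥ 50 nt or
   containing at least one whole exon (both configurable). The 50-nt cut
   matches common large-rearrangement conventions; real large-fragment
   events in these cohorts are multi-exon.
3. **Frame**: remaining indels are frameshift iff `length_change % 3 ≠ 0`,
   else in-frame.
4. **Missense vs nonsense**: substitutions are resolved from the declared
   p.-notation (Ter/*/X ⇒ nonsense). Without a declared consequence the
   call is missense with `low_confidence` (never a silent guess); strict
   mode raises instead. No CDS sequence is packaged, so translation-based
   resolution is not attempted.

PT/NT is a total, exclusive function of the six types: PT = {frameshift,
splice-site, nonsense, large-fragment}, NT = {missense, in-frame}.

## Annotation

Exon lookup is a binary search over exon start positions; intronic offsets
anchor to their coding position (so a donor-site variant belongs to its
exon — which side of the junction such variants were tallied on in source
reports is generally unstated, and the anchoring rule is this package's
fixed choice). Domain membership is intersection of the variant's residue
interval with the domain's aa interval; exon-only domains (TSC1's TID) use
exon intervals. TAD2 and CaBD overlap at aa 1740–1744 and are always
reported as the merged label `TAD2+CaBD` (merged span 1690–1755). Region
membership is by exon, with multi-exon variants assigned to their 5′-most
exon and flagged `region_ambiguous` when they straddle a boundary — a
near-irrelevant case in practice because large fragments are excluded from
all domain/region comparisons. Exon 15 sits on the N-terminal side of the
TSC1 split (the published convention "split by exon 15" does not name a
side; the table is editable).

Membership is decided by the lesion's own position, not by downstream
consequence: a truncating variant upstream of a domain does not count as
hitting it (tallies place each mutation where it occurs). Propagation of
truncating lesions to all downstream domains is available as an option
(`propagate_truncation`) and off by default.

Two coordinate systems, one consistency guarantee: because domains do not
occupy the full length of their bounding exons, aa-based and exon-based
membership cannot coincide as sets (a variant can sit in exon 29 yet
upstream of aa 1163). The invariant the package enforces and tests is
one-directional: **an aa-interval hit always lies within the domain's
stated exon range** — the two views never contradict each other.

## Statistics

Orientation contract: rows exposure, columns outcome, `a` = exposed ∧ RAML,
OR = ad/bc. All comparisons are category-vs-rest 2×2 tables (domain rows
are separate comparisons, not a partition — a variant hitting two domains
counts in both).

* **Expected counts**: row × column totals / N.
* **Test selection**: Fisher's exact if min expected < 1 *or* N < 40
  (Fisher's condition takes precedence); Yates-corrected χ² if
  min expected < 5; plain χ² otherwise. This precedence reproduces every
  method marker in the reference tables.
* **χ²**: closed forms N(ad−bc)²/(r₁r₂c₁c₂), with Yates replacing |ad−bc|
  by max(|ad−bc| − N/2, 0) — the floor at zero is what yields p = 1 for
  heavily discrete tables. p from the df = 1 upper tail
  (`scipy.stats.chi2.sf`).
* **Fisher**: two-sided by the probability-mass rule (sum of tables, at
  fixed margins, no more probable than observed). Implemented with exact
  integer hypergeometric weights `C(r₁,k)·C(r₂,c₁−k)` and integer
  comparisons, so ties are exact; the `tie_rel_tol` parameter (default
  1e-7) exists for parity with floating-point implementations and has no
  effect on integer weights. Degenerate margins give p = 1.
* **Woolf OR**: exp(ln OR ± z₁₋α/₂·√(1/a+1/b+1/c+1/d)). Any zero cell
  leaves the OR undefined (reports print "−") rather than silently
  continuity-corrected; an explicit Haldane–Anscombe option adds 0.5 to
  every cell and flags the result.
* **Crude logistic OR**: maximum-likelihood fit of outcome ~ exposure via
  `statsmodels` GLM/Binomial with frequency weights (IRLS tolerance 1e-12
  so the saturated-model identity with the Woolf result holds to < 1e-6
  relative). A zero cell is separation and raises.
* **Multiplicity**: none by default (raw p-values, as is conventional for
  this exploratory design); `bh=True` annotates Benjamini–Hochberg adjusted
  values without changing the primary output.

Pipeline conventions: the sex comparison drops unknown-sex records (and
only that comparison does); mutation-type and PT/NT comparisons use the
full per-gene cohort; domain and region comparisons exclude large-fragment
variants, whose breakpoints cannot be localized to a domain — so their
denominators are the per-gene totals minus the large-fragment counts.

## Packaged example data

`datasets.published_tables()` ships the aggregate 2×2 counts of a
261-patient literature-curated cohort (54 *TSC1* / 207 *TSC2*, 148 of known
sex). `datasets.example_cohort()` reconstructs a patient-level cohort from
those aggregates: variant positions are representative placements inside
the intended domain/region intervals, sex is assigned to match the known
margins independently of genotype, and the TSC2 domain table is reproduced
exactly. The source aggregates are internally inconsistent in one place:
the RAML-side region counts (HID-TID 41 / middle 34 / GAP 21) cannot
coexist with the RAML-side domain counts (GAPD 8 + TAD2/CaBD 14 = 22
lesions, all necessarily in the GAP region). The reconstruction gives
priority to the domain table — it carries the headline TAD1 association —
and its RAML-side region counts come out 41 / 33 / 22 (the non-RAML side,
47 / 27 / 26, is consistent and reproduced exactly).

## Synthetic cohorts

`SimConfig` defaults are the reference-study conditions: n = 54/207,
per-gene type frequencies from that cohort's breakdown, P(female | known
sex) = 85/148 with 113/261 unknown, baseline log-odds ln(126/135) (the
cohort prevalence). Effects default to none; `default_study_config()`
switches on a TAD1 odds ratio of 3.5 and a female odds ratio of 2.5.
Positions are uniform over the CDS by default (per-exon weights available);
mutational hotspots, CpG bias and literature-ascertainment bias are
deliberately not modelled, so passing recovery tests demonstrate correct
estimation under the assumed logistic model, not robustness to real-world
sampling artifacts. Generated variants satisfy a round-trip contract —
the classifier always maps them back to the intended type — which is what
makes the generator usable as ground truth.

A single seeded `numpy` Generator is threaded through all draws in a fixed
order (per gene: type vector first, then per patient: variant draws, sex
uniform(s), RAML uniform). `recovery_experiment` spawns per-replicate seeds
from a `SeedSequence`, and summarizes mean/bias/RMSE of the log-OR,
empirical Woolf-CI coverage, and rejection rate of the rule-selected test.

## Problem sizes and numerical checks

The test suite verifies the Fisher implementation against an independent
exact-Fraction enumeration oracle over **all** 635,375 tables with N ≤ 60,
the logistic–Woolf identity on 1,000 random tables to 1e-6 relative, and
the annotation layer against brute-force interval scans. Simulation-based
checks use n = 20,000 for single-cohort effect recovery, 400 replicates of
n = 400 for CI coverage, and 1,000 replicates of n = 200 for null
rejection; a direct 200,000-replicate simulation of the null comparison
puts the true type-I error of the selected test at 0.052, so a 1,000-rep
estimate carries a Monte-Carlo standard error of ±0.007 and individual
batches can graze 0.06.

## Known limitations

* No genomic (g.) coordinates, no inversions or complex alleles, no
  protein-level parsing beyond Ter detection; no pathogenicity assessment.
* Substitutions without a declared protein consequence cannot be resolved
  to missense vs nonsense without a CDS sequence; they are flagged, not
  guessed.
* The crude logistic OR is unadjusted by design; cohorts assembled from
  literature reports rarely carry complete covariates, and no multivariable
  adjustment is attempted.
* r×c tables beyond 2×2 are out of scope; every comparison is
  category-vs-rest.
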