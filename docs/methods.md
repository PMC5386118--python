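# Methods

## Scope and model

`colocna` re-implements, as a deterministic and testable pipeline, the
strategy of discovering recurrent DNA copy-number alterations (CNAs)
along the colon mucosa–adenoma–carcinoma sequence and corroborating
candidate genes through three independent lines of evidence: relative
quantification of DNA/transcript levels (comparative CT), loss of
heterozygosity at intragenic SNP markers, and bisulfite-clone promoter
methylation. Patient array data of this kind are generally not publicly
deposited, so the package is exercised on a synthetic cohort generator
that reproduces the study's *statistical structure* — trio design,
planted aberrations, marker allele frequencies, clone counts — plus the
published table of 20 candidate regions, which ships as a fixture.

## Copy-number segmentation

* **Contrast.** `log2((test + ε)/(reference + ε))` per probe, ε = 1e−6
  to guard against zero intensities in simulated or degenerate input.
* **References.** Pairwise: the patient's own mucosa. Non-pairwise: the
  probe-wise mean of the k = 10 controls with the smallest SD of the
  test-vs-control log ratio. Ranking is greedy per control (stable
  under ties) rather than an exhaustive subset search: the greedy rule
  is deterministic, O(#controls), and coincides with the exhaustive
  optimum whenever control noise levels are nested, which a unit test
  verifies by brute force on 6-control panels.
* **Smoothing.** Centered arithmetic mean over w = 5 consecutive SNPs.
  Whether such a window should be centered or trailing is a genuinely
  open choice; centered was chosen (and is configurable through `w`).
  Windows never cross chromosome boundaries, and edge probes without a
  full window are *undefined* rather than computed from a shrunken
  window — this keeps the brute-force window oracle exact.
* **Calling.** Maximal runs of ≥ 5 defined probes strictly beyond the
  gain/loss thresholds ±0.2 log2 units. The thresholds sit between the
  single-copy expectation (|log2(3/2)| ≈ 0.58 for a gain,
  |log2(1/2)| = 1 for a loss) and the smoothed noise floor
  (0.15/√5 ≈ 0.07); `min_snps` = 5 matches the window so a single
  smoothed excursion cannot create a call alone. Both are configurable.
* **Conservation.** A pairwise segment counts as conserved when
  same-sign non-pairwise segments of the same sample cover ≥ 50% of its
  length; the statistic is the conserved fraction, undefined (reported
  as not-applicable) for an empty pairwise set. Note that pairwise
  contrasts carry the noise of two arrays (σ√2), so at the default
  noise level the pairwise analysis produces occasional borderline
  5-probe calls that the quieter panel contrast does not reproduce;
  the conservation fraction on default synthetic runs is therefore
  markedly lower than on noise-free runs (where it is 1.0).

## Minimal common regions

An MCR is formalized as a **maximal interval with a constant
supporting-sample set** of size ≥ 2 for one aberration sign, extracted
by a sweep line over segment endpoints. Adjacent intervals whose
supporter sets differ are *not* merged, so the minimal shared core of
any overlap is always its own record. Sizes are strict > 1 kb at
extraction and ≤ 3 Mb (inclusive) at the candidate filter. Support is
counted per sample, not per patient: an adenoma and a carcinoma of the
same patient contribute 2. Confirmation follows the two-caller idea:
consensus regions recomputed from a centered moving-*median* caller
(same window and thresholds) must overlap the MCR reciprocally by
≥ 50%. The median smoother is a genuinely different statistic from the
mean — a single outlier probe moves the mean by 1/w but the median not
at all — so agreement between the two is informative.

## Candidate integration

* **Annotation** is a browser-style any-overlap (≥ 1 bp) query of gene
  models against regions, with chromosome labels normalized for the
  `chr` prefix and an assembly tag that must match between the two
  sides (no liftover is attempted). Composite symbols such as
  `TMEM189-UBE2V1` are single entries; alias symbols printed in
  parentheses in the shipped table are stripped.
* **Expression filtering** generalizes the in-silico survey of public
  expression datasets to a two-sided Welch test per gene on a provided
  two-group matrix at α = 0.001; querying the databases themselves is
  out of scope. Zero-variance degenerate genes get p = 1 when group
  means are equal, else p = 0 with a `degenerate` flag.
* **Comparative CT.** ΔCT subtracts the reference gene's CT from the
  target's within a sample (`GAPDH` for genomic templates, `DDX5` for
  cDNA); ΔΔCT = ΔCT(normal) − ΔCT(lesion). Relative abundance of the
  lesion is `2^ΔΔCT` — the *mirror* of the widespread `2^(−ΔΔCT)`
  habit, and a direct consequence of the normal-minus-lesion order.
  The ternary status call uses |ΔΔCT| ≥ 1 (two-fold), boundaries
  inclusive; the cutoff is configurable since binary published calls
  rarely state one.

## Two-hit evidence

* **LOH.** Heterozygous (AB) normals only are informative. LOH
  requires both tumor duplicates to agree on the same homozygote —
  discordant duplicates (AA/BB) and any duplicate no-call are
  *non-evaluable*, excluded from the frequency denominator but counted,
  so LOH + retention + non-informative + non-evaluable always equals
  the number of pairs. A duplicate pair of one heterozygote and one
  no-call is treated as non-evaluable rather than retention: a failed
  replicate should not rescue a call. Frequencies are rounded half-up
  to integer percent (5/12 → 42%, 11/19 → 58%).
* **Methylation.** The published class bands ("at least 5 clones"
  extensive, "2–5" moderate) overlap at 5; 5 is resolved to extensive,
  making moderate effectively 2–4. When the clone total differs from
  10 the cutoffs scale as ⌈n/2⌉ and ⌈n/5⌉. What makes a single *clone*
  methylated is not formally defined anywhere; the rule here is a
  methylated-CpG fraction ≥ 0.25 (configurable). The boundary is only
  load-bearing near it: the generator plants methylated clones well
  above and scattered clones strictly below the fraction, and the
  fraction is exposed (`clone_rule_fraction`) for sensitivity
  analysis. Cohort percentages truncate to one decimal (4/26 → 15.3%),
  matching how such fractions are conventionally printed.

## Synthetic cohort: what it does and does not emulate

The generator reproduces: the trio design (N/A/T per patient, extra
adenomas, healthy controls), planted gain/loss segments as log2-ratio
shifts with i.i.d. Gaussian probe noise (default sd 0.15, a typical
mid-density SNP-array figure; the true probe-noise magnitude of the
original arrays is unknown), Hardy–Weinberg genotypes at minor-allele
frequencies 0.244 and 0.356 with planted LOH realized in both tumor
duplicates, clone matrices built to a target methylation class, and CT
tables constructed by inverting the ΔΔCT model (reference CT constant,
target CT shifted by −log2 f) so that noise-free tables round-trip
exactly. qPCR CT noise defaults to 0 — exact recovery *is* the test
surface — and is configurable.

Not emulated: array chemistry, restriction-fragment length selection,
GC waves, allele-specific intensities, genotype-calling from raw
probes, and spatial correlation of probe noise. Passing tests therefore
demonstrate the correctness of the *analysis logic* under the stated
noise model, not robustness to real-array artifacts.

Desk-scale defaults (4 trios + 3 extra adenomas + 12 controls, two
chromosomes × 500 probes at 10 kb spacing, three planted segments) keep
a full pipeline run under two seconds; the full 8/6/95 design is one
configuration away. The LOH cohort defaults to 39 pairs with LOH
planted at 5 and 8 pairs for the two markers, and the methylation
cohort to 26 assayed tumors with 4 extensive and 4 moderate truths —
the study-scale composition.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive internally; BED exports are 0-based
  half-open.
* Segments use strict threshold comparisons, so a probe smoothing to
  exactly ±0.2 (e.g. one unit-delta probe in a 5-window) does not
  extend a call; planted-boundary error is ≤ (w−1)/2 = 2 probes.
* Undefined (edge) smoothed values never contribute to runs.
* An empty pairwise segment set makes the conservation statistic
  undefined (`None`), never 0 or 1; zero informative LOH cases and an
  empty methylation cohort are likewise refused rather than reported
  as zero.
* Every generator and the orchestrator are pure functions of their
  inputs and a seed; summaries are byte-identical across runs.

## Known limitations

* The confirmation caller shares the ratio tracks with the primary
  caller; it is an independent *statistic*, not an independent
  *measurement platform* as a second array-analysis program would be.
* The greedy best-fit reference can differ from the exhaustive-subset
  optimum on adversarial panels (correlated control noise).
* MCR extraction under noise splits recurrent cores at every supporter
  change, producing small flanking regions with subset support;
  downstream recovery scoring therefore measures coverage of the
  expected core by fully-supported regions rather than exact interval
  identity.
* No statistical significance is attached to recurrence (plain counts,
  no GISTIC-style q-values), matching the method being reproduced.
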