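# Methods

## The analysis

Each patient carries two *WFS1*-style alleles given as protein-level HGVS
descriptors. The pipeline bins every allele into one of two classes:
**NSFS** (nonsense or frameshift — predicted truncating) or **in-frame**
(missense, in-frame insertion, deletion or delins — reading-frame
preserving). Variant kinds outside this scheme (start-loss, stop-loss,
synonymous, splice-style or cDNA-level strings) are deliberately *not*
forced into either bin: they classify `OTHER`, and the patient is excluded
from dose analyses as lacking usable genetic information. This is the
conservative reading of a two-bin scheme — silence about a variant kind is
not a license to guess its bin.

Eligibility is evaluated per manifestation (diabetes mellitus DM, optic
atrophy OA, diabetes insipidus DI, hearing loss HL): a patient enters the
analysis for manifestation m only with (i) both allele descriptors present
and parsing to a usable class and (ii) a numeric onset age for m.
Non-numeric onset entries ("childhood") are treated as absent, with a
warning. A patient can therefore be eligible for DM and ineligible for HL.
Every exclusion is logged with a machine-readable reason
(`missing_allele` / `unparseable_allele` / `missing_onset`) and surfaces in
the run manifest.

**NSFS dose** is the number of NSFS alleles (0/1/2); homozygous genotypes
are written as the same descriptor twice and each allele counts. Among
genotypes with at least one in-frame allele, **TM dose** counts the
in-frame alleles whose affected residue interval overlaps an annotated
transmembrane range.

### TM overlap semantics

TM ranges are 1-based, closed intervals (protein convention). A missense
variant affects its single substituted residue; an in-frame deletion or
delins affects the deleted block; a pure insertion has no reference
residue of its own and is attributed to its two flanking residues. A
variant is TM if **any** affected residue lies in **any** TM range —
overlap, not containment. For the single-residue missense case (the large
majority) this reduces to simple membership; for multi-residue variants
overlap is the conservative generalization, and the test suite checks it
against a brute-force per-residue membership scan on randomized
variant/table pairs. Two consequences worth knowing: enlarging a TM range
can never flip a variant from TM to non-TM (monotonicity), and an empty
domain table classifies every variant non-TM.

The bundled `wfs1_tm_domains.synthetic.tsv` is a synthetic stand-in with
nine TM helices of realistic span, shipped so the package is runnable
out of the box; its header says so explicitly. Real analyses must load a
dated database export — the loader enforces a non-empty provenance header
precisely so a table of unknown origin cannot slip in, and results on real
data can shift between annotation releases.

### Statistics

Per group, onset ages are summarized by median and quartiles with
1.5×IQR whiskers clamped to observed data points; observations beyond the
whiskers are outliers. Quartile interpolation is configurable among
`linear` (default — interpolation between order statistics, the common
statistical default), `lower` and `midpoint`, because published quartiles
such as fractional values on integer-ish ages depend on this unstated
convention; medians at odd n are method-independent.

Pairwise group differences use the two-sided Wilcoxon rank-sum test.

* **Exact mode** enumerates the null distribution of the rank sum W by
  dynamic programming over subset sums of ranks 1..n (O(n_x · n_x n)
  states), and reports the doubled smaller tail,
  p = min(1, 2·min P(W ≤ w), P(W ≥ w)); the null rank-sum distribution is
  symmetric for untied data, so this equals the usual "count splits at
  least as extreme on both sides" definition. Exact mode assumes distinct
  values; on tied data it falls back to the approximation with a logged
  note.
* **Normal approximation** uses mid-ranks, the tie-corrected variance
  Var U = (n_x n_y / 12)·[(n+1) − Σ(t³−t)/(n(n−1))], and no continuity
  correction by default (configurable; recorded in the run manifest via
  the config block). A fully tied pooled sample yields p = 1 with a
  degeneracy warning.
* **auto** (the pipeline default) picks exact for untied data up to a
  combined n of 20, otherwise the approximation.

Multiple-testing adjustment is Bonferroni with the family defined as the
pairwise tests within one manifestation × one grouping (m = 3 for three
dose groups, m = 1 for two): figures in this literature annotate
per-manifestation pairwise brackets, and no cross-manifestation family is
defined anywhere, so the smallest defensible family is used and both raw
and adjusted p-values are always reported. Tests are two-sided throughout
— directional claims ("earlier onset") are read off the medians, not baked
into the test. Comparisons with fewer than two non-empty groups are
reported as "not testable" rather than raising.

## The synthetic registry generator

The generator is a first-class module, not a fixture: it defines the
conditions under which the pipeline's statistical behaviour is validated.

* **Onset model.** Ages are log-normal: onset = M·exp(σZ) with Z standard
  normal, M the cell's median in years and σ a log-scale SD. Log-normal
  gives strictly positive, right-skewed ages matching the asymmetry of
  onset-age box plots. Dose and sex effects subtract from log M — i.e. act
  multiplicatively on the median — with an additive-in-years option
  (truncated at 0) for sensitivity checks.
* **Defaults as study conditions.** A registry of 350 patients; each
  allele independently NSFS with probability 0.53; in-frame alleles TM
  with probability 0.5. Baseline medians anchor the zero-NSFS zero-TM
  cell (DM 11, OA 15.3, DI 13, HL 14 years; σ = 0.585, 0.64, 0.44, 0.565)
  so that the *marginal* group medians — mixtures over TM dose — land near
  the registry values a real cohort of this kind reports (DM ≈ 8/7/5 years
  for 0/1/2 NSFS alleles). Per-allele shifts: NSFS log(11/5)/2 for DM and
  log(15.3/10)/2 for OA; TM log(11/6)/2 (DM) and log(15.3/9)/2 (OA); DI
  and HL have zero dose shifts, reflecting the absence of a dose effect
  for those manifestations. Males get a log(8/6.5) ≈ −1.5-year DM shift.
  Missingness: 5%/8% of DM/OA onsets and roughly half of DI/HL onsets
  absent (later-onset manifestations are under-recorded in registries),
  plus 5% of rows lacking one allele descriptor. `nsfs_shift`/`tm_shift`
  accept scalars or per-manifestation maps.
* **Descriptor synthesis.** Allele strings are drawn from the full
  supported grammar (1- and 3-letter codes, `*`/`Ter` stops, `fs`,
  `fs*N`, del/ins/delins) for a fictitious 800-residue protein with nine
  synthetic TM helices; in-frame intervals are sampled entirely inside or
  entirely outside TM ranges, so each allele's TM status is unambiguous
  ground truth. Residue 1 is never mutated (that would be a start-loss,
  not a missense).
* **What it does not emulate.** Real cohorts show an excess of
  class-homozygous genotypes (consanguinity and recurrent alleles) —
  here the two alleles are independent draws, so the dose distribution is
  binomial rather than U-shaped. There is no linkage, no realistic allele
  catalog, no correlation between manifestations beyond shared dose, and
  the log-normal family is a modelling choice about the generator, not a
  claim about Wolfram syndrome biology. Passing tests therefore validate
  the *pipeline's* correctness and calibration, not any clinical claim.

`run_power_study` generates balanced fixed-dose cohorts (dose is part of
the study design there), pushes each replicate through the complete
pipeline — descriptor parsing included — and reports per-comparison
rejection rates with binomial standard errors and the mean recovered
median gap.

## Numerical and design choices

* Exact-test feasibility cutoff: combined n ≤ 20 in `auto` (the DP itself
  scales much further; the cutoff keeps the default path predictable).
  The DP table is memoized per (n_x, n) since the null distribution
  depends only on the sample sizes.
* Approximation p-values are floored at the smallest positive float so a
  valid p is never exactly 0.
* Report tables print floats at 4 decimals, enough to represent
  interpolated quartiles of fractional ages exactly as published tables
  do.
* Duplications (`dup`) are treated as in-frame insertions attributed to
  the last duplicated residue and its successor.
* Sex values outside male/female map to unknown and drop only from
  sex-stratified comparisons, never from dose analyses.
* Exit codes of the CLI: 0 success, 2 schema/validation failure, 3
  nothing testable.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` validate at desk scale, chosen
as the sizes at which the checked properties are already sharp: exhaustive
exact-vs-oracle comparison at combined n ≤ 10 (2,026 splits); ≥ 1,200
synthetic patients for classification round-trips; 1,000 randomized
variant/table pairs for TM overlap; 1,000 null replicates at n = 50/group
for type-I error; 200 replicates at n = 100/group for power against a
3-year median gap.

## Known limitations

* The parser covers protein-level descriptors only; cDNA (`c.`) input is
  reported as unusable rather than lifted over (no transcript mapping).
* No survival modelling: age of onset is compared directly between
  groups, so censoring (patients who have not yet developed a
  manifestation) is handled by exclusion, exactly as in the emulated
  analysis — a Kaplan–Meier treatment would be a different study.
* No covariate adjustment beyond stratification by sex or dose.
* The shipped TM table is synthetic; real-data conclusions inherit the
  version of whatever annotation snapshot the user supplies.
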