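# wolfram-gp

Genotype–phenotype analysis of biallelic *WFS1* variants in Wolfram
syndrome: allele classification, transmembrane-domain annotation, and
allele-dose effects on age of onset.

Wolfram syndrome is an autosomal recessive disorder (diabetes mellitus,
optic atrophy, diabetes insipidus, sensorineural hearing loss) caused by
biallelic variants in *WFS1*, which encodes the ER membrane glycoprotein
wolframin. Clinical severity varies widely between patients, and part of
that variability tracks the kind of variant each allele carries. This
package implements, as a tested and reusable pipeline, the registry-style
analysis that quantifies this:

1. **Allele classification.** Each protein-level variant descriptor
   (`p.Arg558Cys`, `p.Trp613*`, `p.Val412Serfs*29`, `p.Phe883del`, …) is
   parsed and binned as **NSFS** (nonsense/frameshift — predicted
   truncating) or **in-frame** (missense, in-frame insertion/deletion).
   A patient's *NSFS dose* is the number of NSFS alleles, 0/1/2.
2. **Transmembrane annotation.** In-frame variants are classified as
   transmembrane (TM) or not by closed-interval overlap of their affected
   residue range with the protein's annotated TM helices (1-based,
   inclusive coordinates). The *TM dose* counts TM in-frame alleles.
3. **Dose-group statistics.** For each manifestation m and each grouping
   (NSFS dose; TM dose among two-in-frame and among one-in-frame
   genotypes; sex), onset ages are summarized as box statistics (median,
   quartiles, 1.5×IQR whiskers, outliers) and compared pairwise with
   two-sided Wilcoxon rank-sum tests; within each family of k pairwise
   tests, Bonferroni adjustment `p_adj = min(1, k·p)` is applied.
4. **Synthetic registry generator.** A log-normal onset model with
   per-allele multiplicative dose shifts, a sex effect, and configurable
   missingness generates registry files with known ground truth, so the
   whole pipeline — including its type-I error and power — is testable
   with no patient data.

The Wilcoxon test offers an exact mode (dynamic-programming enumeration of
the rank-sum null distribution; used automatically for small untied
samples) and a tie-corrected normal approximation on mid-ranks.

## Worked example

Generate a synthetic registry and run the full analysis (the numbered
scripts under `analysis/` chain these steps):

```sh
python analysis/01_simulate_registry.py --seed 1
python analysis/03_dose_effect_analysis.py
```

which prints (synthetic data, seed 1):

```
whole-cohort median onset (years):
  DM: median 5.9 (Q1 3.7, Q3 8.7, n=322)
  OA: median 10.9 (Q1 6.9, Q3 17.4, n=310)
  DI: median 11.8 (Q1 8.7, Q3 16.5, n=155)
  HL: median 15.5 (Q1 10.3, Q3 21.5, n=185)

adjusted p-values, NSFS2 vs NSFS0:
  DM: p_adj = 0.0000 (significant)
  OA: p_adj = 0.4606 (n.s.)
  DI: p_adj = 0.6395 (n.s.)
  HL: p_adj = 1.0000 (n.s.)

DM onset by TM dose among two-in-frame patients:
  NTM0: median 11.6 y (n=23)
  NTM1: median 7.7 y (n=42)
  NTM2: median 5.3 y (n=23)
  NTM0 vs NTM1: p_adj = 0.4667
  NTM0 vs NTM2: p_adj = 0.0081
  NTM1 vs NTM2: p_adj = 0.0438
```

Diabetes mellitus emerges earlier the more truncating alleles a synthetic
patient carries, and — among patients whose two alleles are both
in-frame — earlier the more of those alleles fall in TM helices, while
diabetes insipidus and hearing loss show no dose effect: exactly the
structure the generator was configured to produce. The report directory
also holds the full group-summary and pairwise-test TSVs, SVG box plots,
and a `manifest.json` recording configuration, input checksums and every
excluded patient with a machine-readable reason.

The same pipeline runs on a real registry via the CLI:

```sh
wolfram-gp analyze --registry registry.tsv --domains tm_domains.tsv --out report/
```

The registry schema is TSV/CSV with columns `patient_id`, `sex`,
`allele1`, `allele2`, `onset_dm`, `onset_oa`, `onset_di`, `onset_hl`
(ages in years; empty cells mean absent). The domain table is a 3-column
TSV (`start`, `end`, `label`) with `# protein_id:` and `# provenance:`
header lines; the bundled
`src/wolfram_gp/data/wfs1_tm_domains.synthetic.tsv` is a synthetic
stand-in — substitute a dated UniProt export of the wolframin TM
annotation before analyzing real data.

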