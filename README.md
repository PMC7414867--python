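# hrdscar

Genomic-scar scoring of homologous recombination deficiency (HRD) from
allele-specific copy-number segmentations, with a full cross-platform
concordance toolkit and a synthetic paired-cohort generator.

## The problem

Tumours deficient in homologous recombination (HR) DNA repair — most
prominently *BRCA1*/*BRCA2*-inactivated breast and ovarian cancers — are
sensitive to platinum chemotherapy and PARP inhibitors. Because direct
functional readouts are impractical, HR deficiency is inferred from the
structural scars it leaves on the tumour genome. The HRD score sums
three scar counts computed from an allele-specific copy-number profile
(per-segment major/minor allele counts, as produced by ASCAT from SNP
arrays or ascatNgs from whole-genome sequencing):

* **NtAI** — number of regions of allelic imbalance (nMajor ≠ nMinor)
  that extend to a telomere, do not cross the centromere and do not span
  the whole chromosome;
* **HRD-LOH** — number of loss-of-heterozygosity regions
  (nMinor = 0, major allele retained) longer than 15 Mb that do not span
  the whole chromosome;
* **LST** — number of large-scale state transitions: chromosome breaks
  between adjacent segments of ≥ 10 Mb each (after 3 Mb smoothing,
  per chromosome arm, inter-segment gap ≤ 3 Mb).

```
HRD = NtAI + HRD-LOH + LST ;   HRD ≥ 42 ⇒ HR deficient
```

Whether the score is computed from array or from (possibly shallow)
sequencing data changes the segmentation noise, and therefore potentially
the score and the deficient/proficient call. `hrdscar` provides both the
scoring and the method-comparison statistics used to quantify that
platform effect — Pearson/OLS, Bland-Altman limits of agreement,
ICC(3,1), Fleiss' kappa, classification concordance, contribution and
distribution tests — plus signal-quality metrics (dLRS, MAPD, 10 kb
binned Log2 deviation/correlation) and a simulator that produces paired
array-like and WGS-like views of the same tumour genomes with known
ground-truth event counts.

It is aimed at cancer-genomics analysts who have segmentation output
(ASCAT/ascatNgs-style tables) and need reproducible scar scores and a
defensible platform-agreement analysis without access to raw data.

## Worked example

Simulate a 67-sample paired cohort, score both platform views, and run
the full agreement battery:

```bash
hrdscar reproduce-synthetic-study --n 67 --seed 7 --qc-samples 2 --out demo/
```

prints

```
samples: 67 (array vs wgs70x), seed 7
HRD score: Pearson r = 0.999, R^2 = 0.997, ICC(3,1) = 0.999
Bland-Altman bias = 0.72 [-2.09, 3.53], 94.03% within limits
HR classification: concordance = 98.51%, Fleiss kappa = 0.970 (p = 2.02e-15)
discordant samples: 1
```

Reading: the two platform views of the same tumours correlate almost
perfectly (r = 0.999) and are mutually consistent (ICC close to 1); the
WGS-like view scores on average 0.72 points higher than the array-like
view (the mean bias), with 95% limits of agreement from −2.09 to +3.53;
66/67 samples get the same deficient/proficient call, and the single
discordant sample sits next to the threshold of 42. `demo/` contains the
per-platform score tables (`scores_*.tsv`), segment tables, the QC
metrics, the JSON agreement report and a truth manifest with the
injected event counts per sample.

Scoring real segmentation output works the same way through the library
or the CLI:

```bash
hrdscar score --segments tumour.copynumber.caveman.csv --dialect ascatngs --out scores.tsv
hrdscar compare --scores-a scores_array.tsv --scores-b scores_wgs.tsv --out report.json
```

The score table carries one row per sample:

```
sample_id  ntai  hrd_loh  lst  hrd_score  hr_status   contrib_ntai_pct ...
SYN002     18    6        45   69         deficient   26.09 ...
```

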