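# ttnvar

A toolkit for the quantitative interpretation of rare missense variants in
*TTN*, the gene encoding titin — the largest human protein, whose truncating
variants (TTNtv) are established causes of recessive skeletal myopathy while
the contribution of its tens of thousands of possible missense variants
remains hard to assess. `ttnvar` is aimed at clinical-genetics analysts and
neuromuscular researchers who need to move from raw variant annotations
(AlphaMissense score, gnomAD MAF, exon usage) to reproducible evidence and
cohort-level statistics.

## What it computes

* **Calibrated evidence banding.** An AlphaMissense score s in [0,1] maps to
  a calibrated PP3/BP4 evidence band with signed points: s <= 0.070 gives
  Benign (-3) up through s >= 0.990 giving Pathogenic Strong (+4), with the
  pathogenic side starting at s >= 0.792 (+1). Points from multiple ACMG/AMP
  criteria sum and classify on the point scale (Pathogenic >= 10, Likely
  pathogenic 6-9, VUS 0-5, Likely benign -6..-1, Benign <= -7), with a PM3
  recurrence rule for variants in trans with a pathogenic truncating allele.
* **Cohort pipeline.** The study inclusion filter (missense MAF < 0.010,
  score >= 0.792, outside the HMERF/TMD exons 344/364, truncating partner in
  trans), cohort summaries, recurrent-variant detection, exact haplotype
  intersection across families, and exon-usage (PSI) flags.
* **Substitution landscape.** For a table of all possible missense SNVs:
  band counts, band x MAF crosstabs, and the 20x20 map of
  possibly-pathogenic fractions per amino-acid pair — e.g. tryptophan's
  codon TGG admits 7 missense SNVs, so titin's 466 Trp residues yield
  466 x 7 = 3,262 possible missense changes.
* **Burden model.** The population prevalence of compound TTNtv +
  high-scoring-missense genotypes,
  `P = p_tv_carrier x (1 - prod(1 - q_i)^2) x p_trans`,
  excluding alleles observed in homozygosity.
* **Imaging quantification.** Segmentation of GFP fluorescence images and
  the Jaccard index of nuclear overlap with the whole-cell mask, comparing
  wild-type (diffuse, nuclear-enriched) against variant (punctate,
  nucleus-excluded) expression with a Student's t-test.
* **Synthetic data.** Seeded generators for every input above with planted
  ground truth, so the full pipeline runs and is tested offline.

## Worked example

The packaged cohort fixture (`src/ttnvar/data/cohort_tables_1_2.tsv`)
contains 30 patients from 26 families, each combining a candidate missense
variant with a truncating variant in trans:

```sh
$ ttnvar cohort
{
  "n_patients": 30,
  "n_families": 26,
  "n_distinct_missense": 22,
  "n_distinct_ttntv": 26,
  "recurrent_variants": {
    "c.21068a>c": ["F1", "F2", "F3", "F4", "F5", "F6"],
    "c.14486a>c": ["F7", "F8"]
  },
  "n_recurrent_families": 8,
  "n_excluded": 0
}
```

All 30 patients pass the inclusion filter; the 22 distinct missense and 26
distinct truncating variants include two recurrent missense alleles —
c.21068A>C p.(Gln7023Pro) in six families and c.14486A>C p.(Gln4829Pro) in
two — spanning 8 unrelated families in total.

Classifying the recurrent p.(Gln7023Pro) (score 0.81) with its supporting
criteria (PM3 at Strong for six unrelated trans probands, PS3 functional
evidence at Moderate, PM2_supporting):

```sh
$ ttnvar classify --score 0.81 --criteria PM3:4,PS3:2,PM2_supporting:1
{
  "score": 0.81,
  "band": "Pathogenic Supporting",
  "band_points": 1,
  "criteria": {"PP3": 1, "PM3": 4, "PS3": 2, "PM2_supporting": 1},
  "total_points": 8,
  "label": "Likely pathogenic"
}
```

The score lands in the Pathogenic Supporting band (+1); the summed 8 points
classify the variant as Likely pathogenic.

Other subcommands: `ttnvar annotate` (per-variant evidence report),
`ttnvar landscape` (band counts, MAF crosstab, substitution heatmap),
`ttnvar burden` (compound-genotype prevalence), `ttnvar imaging`
(Jaccard quantification of image directories) and `ttnvar simulate`
(synthetic inputs with embedded ground truth). The same operations are
available as library functions (`import ttnvar`).

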