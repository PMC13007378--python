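# Methods

`ttnvar` implements a quantitative framework for interpreting rare missense
variants in *TTN*, the gene encoding titin. The package is organised along
the analysis workflow: codon-level substitution arithmetic, calibrated
computational-evidence banding with ACMG point aggregation, cohort inclusion
and recurrence analysis, an exhaustive substitution-landscape summary, a
compound-heterozygote population-burden model, and fluorescence-image
quantification of domain aggregation. This note records the models, their
assumptions, the tunable parameters, and the design choices made where the
design was genuinely open.

## Codon-level substitution enumeration (`core`)

Every coding codon admits exactly 9 single-nucleotide substitutions
(3 positions x 3 alternative bases), classified against the standard genetic
code (NCBI translation table 1; the initiator codon receives no special
handling) as missense, synonymous or nonsense. Tryptophan's unique codon TGG
yields 7 missense and 2 nonsense changes and no synonymous escape, which is
why Trp substitutions dominate the pathogenic end of the landscape: titin's
466 Trp residues contribute 466 x 7 = 3,262 possible missense SNVs.

Positions are 1-based residue coordinates on the canonical titin isoform
(UniProt Q8WZ42-1, 35,991 residues). Exon numbers are carried as annotations
and never recomputed; no transcript or genome mapping is attempted. HGVS
parsing is deliberately "lite": simple substitutions are parsed fully
(three-letter codes per IUPAC, `Ter`/`*` accepted for stop), frameshifts and
delins blocks to class level (a delins introducing a stop is classified
truncating), and intronic cDNA substitutions carry their offset. The full
HGVS grammar is out of scope.

## Calibrated evidence banding and point aggregation (`evidence`)

AlphaMissense scores in [0,1] map to calibrated PP3/BP4 evidence bands with
signed points:

| interval | label | points |
|---|---|---|
| <= 0.070 | Benign | -3 |
| 0.071 - 0.099 | Benign Moderate | -2 |
| 0.100 - 0.169 | Benign Supporting | -1 |
| 0.170 - 0.791 | Indeterminate | 0 |
| 0.792 - 0.905 | Pathogenic Supporting | +1 |
| 0.906 - 0.971 | Pathogenic Moderate | +2 |
| 0.972 - 0.989 | Pathogenic | +3 |
| >= 0.990 | Pathogenic Strong | +4 |

The published interval bounds are quoted to three decimals and leave formal
gaps (e.g. (0.905, 0.906)); scores are therefore rounded to 3 decimals
before lookup, which closes every gap while keeping the printed closed
intervals intact. The band table is a validated, configurable object
(ordering, coverage of [0,1] after rounding, and monotone points are
enforced at construction). The benign side is emitted as BP4, the
computational-evidence benignity criterion.

Criterion points aggregate by summation with a duplicate-code guard, and
classify on the ClinGen point scale: Pathogenic >= 10, Likely pathogenic
6-9, VUS 0-5, Likely benign -6..-1, Benign <= -7. PM3 (variant in trans
with a pathogenic allele in a recessive disease) scales with unrelated
probands: +2 for one, capped at +4 (Strong) for two or more; both numbers
are parameters.

MAF handling: categories absent / <=0.01% / (0.01%,0.1%] / (0.1%,1%] / >1%,
and strict-inequality rarity cut-offs per onset tier — congenital < 1e-4
(severe early-onset disease should be near-absent from population
databases), childhood and adult < 1e-2 (the study-wide inclusion cut-off).
A variant absent from gnomAD passes every tier.

## Cohort pipeline (`cohort`)

A patient genotype couples 1-2 candidate missense alleles on one haplotype
(two when in cis) with a truncating variant (nonsense, frameshift or
canonical splice) on the other. Phase is an input recorded upstream
(segregation or population co-occurrence evidence); the pipeline never
infers it. The inclusion filter requires: at least one missense allele with
MAF < 0.010 (or absent), AlphaMissense score >= 0.792, outside exons 344
and 364 (reserved for the dominant titinopathies HMERF and TMD); a
truncating partner; and confirmed or presumed trans phase. Every failed
clause is named in the returned reason codes, so decisions are auditable
and reason completeness is property-tested (fixing exactly the named
attribute flips the decision).

Variant distinctness is keyed on the whitespace/case-normalised cDNA string
(protein string as fallback). Recurrence reports missense variants seen in
two or more families together with the family union. Haplotype analysis is
an exact set intersection over fully-typed family variant sets; a family
with only pre-filtered data can be supplied as a held-out partial set whose
overlap with the shared core is reported without constraining the
intersection.

PSI flags: an exon is `developmentally_decreasing` when postnatal PSI falls
at least 30% below the prenatal level (relative, not absolute: a 6-point
drop from PSI 7% to 1% is a strong down-regulation while an 11-point drop
from 96% to 85% is not — a relative criterion is the only single threshold
that reproduces every annotated and unannotated row of the packaged cohort
tables), and `low_usage` when both values are below 30%. Both thresholds
are parameters. Residue burial uses relative solvent accessibility < 0.25
(conventional cut-off, configurable, strict inequality).

The packaged fixture (`data/cohort_tables_1_2.tsv`) transcribes the
30-patient / 26-family cohort; numeric annotations that are not
individually published (most per-variant scores and MAFs, and the
exon/PSI of the recurrent c.21068A>C allele) are representative synthetic
placeholders consistent with the inclusion thresholds, as stated in the
file header. They do not affect the counting targets.

## Substitution landscape (`landscape`)

The landscape operates on a table with one row per possible missense SNV
(an amino-acid change reachable by several distinct SNVs contributes one
row each — consistent with the 3,262 Trp arithmetic). Summaries: band
counts (marginals conserved by construction and cross-checked against a
one-pass interval recount), a band x MAF-category crosstab, and a 20x20
(ref x alt) matrix of counts and possibly-pathogenic fractions at a
threshold (default 0.792, the weakest pathogenic band's lower bound).
Pairs unreachable by any SNV are structurally impossible and reported as
NaN. `possible_pairs_from_cds` enumerates the reachable pairs directly from
a coding sequence and is tied to the per-codon oracle by a conservation
test. Fractions are reported to 3 decimals in emitted tables; the numbers,
not plots, are the contract.

## Burden model (`burden`)

The prevalence of compound TTNtv + high-scoring-missense genotypes is
`P = p_tv_carrier x f x p_trans` with defaults `p_tv_carrier = 0.0005`
(0.05%, interpreted as the carrier frequency of a truncating variant in a
constitutively expressed, high-PSI exon; an allele-frequency interpretation
is selectable) and `p_trans = 0.5` (a flat multiplier; no linkage
modelling). The cumulative missense carrier frequency is the exact
Hardy-Weinberg form `f = 1 - prod(1 - q_i)^2` over qualifying alleles,
alongside the rare-allele approximation `2 * sum(q_i)`. Alleles observed in
homozygosity are excluded before aggregation (a variant tolerated
homozygous is unlikely to act as a severe recessive allele); exclusion uses
the observed-homozygote flag, not an expected-homozygote model. The model
is property-tested for monotonicity in every parameter and for the
approximation bound; the headline "1 in 9,150" figure is reproduced by a
round-trip (back-solving the implied carrier frequency, ~0.44, and running
it forward), since the underlying allele list is an external database
extract.

## Imaging quantification (`imaging`)

Widefield GFP images are segmented with two filters: Gaussian smoothing
(sigma 4 px) + Otsu for the whole-cell mask, and Gaussian smoothing (sigma
2 px) + an in-cell percentile threshold (90th) for the bright mask — the
simplest pair that separates a cell from background and its brightest
structures from the cytoplasm; all parameters sit in `SegmentationConfig`.
Nuclei are bright connected components passing an area window (default
80-5000 px^2) and roundness `4*pi*A/P^2 >= 0.6`. The expression-pattern
statistic is the Jaccard index of the nuclear mask against the whole-cell
mask: diffuse expression with nuclear enrichment gives a compact, round,
accepted nuclear component (Jaccard ~ nucleus/cell area ratio, ~0.1 on the
synthetic scenes), while punctate, nucleus-excluded aggregation leaves only
small or irregular bright components that fail the nucleus rules (Jaccard
near 0). Nuclei are detected in the GFP channel itself (single-mask
workflow); a DAPI image can be substituted as the segmentation input where
available. Groups are compared with the two-sided pooled-variance Student's
t-test on per-image Jaccard values.

## Synthetic data (`synthetic`)

All generators are pure functions of a seeded configuration and return
their planted truth.

* Score tables: a three-component mixture (benign / indeterminate /
  possibly-pathogenic, weights 0.39 / 0.40 / 0.21) with draws confined to
  windows that 3-decimal rounding cannot move across a component boundary;
  MAF 90% absent with a log-uniform [1e-6, 2e-2] tail. The weights mirror
  the global proportions expected of titin (~21% of SNVs possibly
  pathogenic, ~40% indeterminate); they are configuration, not constants.
* Cohorts: one patient per family, a recurrent missense planted in the
  first k families, optional in-cis pairs, all alleles constructed to pass
  the inclusion filter (unless the phase is set otherwise); distinct
  variants draw from disjoint position pools so identity keys never
  collide.
* Haplotypes: a shared core (default 45 variants) plus per-family private
  variants from disjoint pools, so the intersection equals the core
  exactly.
* Cell scenes: one elliptical cell (radii 42x34 px in a 128x128 field) with
  an elliptical nucleus (13x11 px, ~10% of the cell area); diffuse scenes
  set cytoplasm/nucleus/background intensities 40/120/5, punctate scenes
  dim the cytoplasm to 30, keep the nucleus at background (nuclear
  exclusion) and add 12 Gaussian puncta (amplitude 150, sigma 1.2 px)
  outside the nucleus; additive Gaussian noise (SD 3) emulates camera
  noise.

What the generators do not emulate: real sequence context and codon usage,
linkage disequilibrium between haplotype variants, microscope optics (PSF,
uneven illumination, multiple or touching cells), and the correlation
structure of real AlphaMissense scores along the protein. Passing tests
therefore demonstrate the correctness of the arithmetic, filters and
statistics under controlled conditions — not the field performance of the
segmentation on real micrographs, nor the calibration of AlphaMissense
itself.

## Numerical choices and degenerate inputs

Scores are rounded half-away-from-boundary only through Python's 3-decimal
rounding; band membership is inclusive as printed. The Jaccard of two empty
masks is defined as 0. A blank (zero-variance) image raises "no foreground"
rather than returning an empty record. Degenerate single-pixel components
are treated as round. MAF cut-offs are strict inequalities exactly as
specified. `SubstitutionCounts` enforces the 9-substitution conservation
law at construction. The t-test requires n >= 2 per group.

## Problem sizes

The test suite and acceptance script run on in-package inputs: the
62-row cohort fixture, synthetic score tables of 8,000-20,000 rows
(the summaries are linear-time, so row count does not change the logic
exercised), and 20 replicate imaging batteries of 30+30 images at 128x128.

## Known limitations

* The ACMG combiner is criterion-agnostic by design; it does not implement
  PVS1 decision trees, benign/pathogenic co-occurrence logic, or Bayesian
  posteriors.
* The burden model ignores penetrance and treats trans probability as a
  constant; it cannot reproduce database-derived figures without the
  underlying allele-frequency extract.
* Exon annotations are trusted as given; variants in the meta-transcript
  exons are outside the model.
* The imaging statistic quantifies nuclear overlap only; colocalisation
  with proteostasis markers is not quantified.
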