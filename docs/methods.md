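# Methods

## The measurement model

A methylation-sensitive SNP array (MSNP) experiment genotypes each
individual three times:

* **(G)** undigested genomic DNA — the genotype reference;
* **(D)** genomic DNA digested with a cocktail of methylation-sensitive
  restriction enzymes (MSREs): HpaII (C^CGG), HhaI (GCG^C) and AciI
  (C^CGC).  An MSRE cleaves its site only when the internal CpG is
  unmethylated, so a methylated allele survives digestion and an
  unmethylated one is destroyed;
* **(U)** whole-genome-amplified DNA (amplification erases methylation)
  digested the same way — the control for cutting efficiency and for SNPs
  that sit inside a cut site.

For a probe with allele channels A and B the **relative allele score** is
RAS = A/(A + B), the allelic analogue of a B-allele frequency.  In a
heterozygote, allele-specific methylation (ASM) protects one allele in
(D), so RAS moves between (G) and (D).  The per-probe ASM statistic is

ΔRAS̄ = mean over heterozygotes of |RAS_D − RAS_G|,

with the signed mean retained separately.  A probe is called ASM when
ΔRAS̄ > 0.1.  Using the absolute difference inside the average makes the
statistic sensitive to imprinting (shifts in both directions across
individuals) as well as cis-ASM (one direction); the two are separated
afterwards by the direction classifier, not by the detection statistic.

Two exclusion criteria, applied before detection, use the Euclidean norm
("distance") of the mean (Ā, B̄) pair per condition:

1. distance(Ḡ)/distance(Ū) < 1.2 → excluded: the unmethylated control was
   not reduced relative to genomic DNA, so the probe is not informatively
   cut (or cross-hybridizes after cutting);
2. distance(D̄)/distance(Ū) < 1.2 → excluded: digested DNA lost as much
   signal as the fully unmethylated control, i.e. both alleles are
   unmethylated and there is nothing allele-specific to detect.

The means are taken over *all* samples assayed, regardless of genotype:
the criteria describe cutting and hybridization physics, not allele state.

## The candidate funnel

Stages, each a strict subset of the previous: (1) analysis population —
probes with ≥1 MSRE site on either allele, established by in-silico
digestion of the probe flank with each allele substituted; (2) exclusion
criteria; (3) ΔRAS̄ > 0.1 over ≥ `min_het` (default 2) heterozygotes with
valid G/D signal pairs; (4) probes within ±100 kbp (inclusive) of a
susceptibility-gene interval — tag-SNP mode is available by supplying
zero-width intervals; (5) quality control.

Manual inspection of signal cluster plots is replaced by three numeric
rules: a probe is dropped when (i) the heterozygote RAS in (U) deviates
from RAS in (G) by more than 0.1 — digesting *unmethylated* DNA should not
shift allele balance unless the SNP itself makes or breaks a cut site;
(ii) the coefficient of variation of the per-sample (G) signal distance
exceeds 1.0 — unstable hybridization; (iii) fewer than 4 informative
heterozygotes.  Cluster plots are still emitted for review when requested.

Direction is classified from the per-heterozygote signed shifts with
magnitude ≥ 0.05: **monoallelic** (cis-ASM: genotype fixes the methylated
allele) when ≥ 90% of qualifying shifts share a sign; **biallelic**
(imprinting: parental origin fixes it) when each sign holds ≥ 10%;
otherwise indeterminate.  The rule is symmetric under negating all
shifts.  Candidates are reported with their direction label rather than
silently dropping biallelic probes, since an imprinted region is a true
ASM finding — just not a cis-regulated one.

## Pyrosequencing validation statistics

Allele-specific PCR yields separate amplicons per allele of a
heterozygote; pyrosequencing then reads a methylation percentage per CpG
per allele.  Two comparisons are provided:

* **Heterozygotes only** — paired t-test on the per-individual C − T
  differences (n − 1 degrees of freedom, two-sided).  Pairing within
  individuals cancels environmental methylation variation, which is the
  point of the within-individual design.  A zero-variance difference
  vector is reported as a degenerate p (1 when all differences are zero)
  with a warning rather than NaN.
* **Heterozygotes plus homozygotes' single alleles** — the groups are
  unpaired and of unequal size, so the comparison is a Wilcoxon rank-sum
  (Mann–Whitney) test computed *exactly*: the null distribution of the
  group rank sum is enumerated over every assignment of the pooled
  midranks (ties therefore need no correction), and the two-sided p is
  the probability of a rank sum at least as far from its null mean as
  observed.  Enumeration is used up to 2×10⁶ assignments; beyond that the
  normal approximation with tie correction and continuity correction is
  used.  Completely tied groups give p = 1.

The packaged measurement table (4 C/T heterozygotes, 1 C/C, 3 T/T, two
CpGs) reproduces its published summary statistics: heterozygote means/SDs
82.5/6.4 vs 69.3/13.7 (CpG1) and 77.3/8.5 vs 62.3/14.1 (CpG2), paired-t p
of 0.111 and 0.057, and combined means 82.4 vs 66.7 and 77.0 vs 60.4.
Sample standard deviations use the n − 1 denominator, which is what
reproduces the published SDs.  The source tables' own combined-comparison
SD columns and p-values are internally inconsistent (the printed SDs match
neither sample SDs nor standard errors of the underlying values, and two
different p-value pairs are printed for the same comparison); they are
recorded nowhere as expectations.

An allele-specific PCR run is accepted when the fraction of reads carrying
the targeted allele at the control SNP reaches 85%.

## Expression association

Genes whose [start, end] interval intersects a ±500 kbp window around the
SNP (inclusive, same chromosome) are each regressed by OLS:
FPKM ~ dosage, with dosage the 0/1/2 count of the alternate allele.
Reported per gene: slope, intercept, two-sided slope p, R², adjusted
R² = 1 − (1 − R²)(n − 1)/(n − 2).  Genes with mean FPKM below 1.0 are
reported unanalyzed.  Constant expression is defined to have slope 0,
R² 0, p 1.  Note the interval-intersection rule is applied literally: a
gene whose printed span begins 755 kbp from the SNP is outside every
±500 kbp window, whatever a source table may list.

## The synthetic-data generator

`SimulationConfig` defaults define the study conditions: 1,000 probes,
15 individuals, heterozygote frequency 0.45 (common variants, MAF ≈ 0.35),
5% planted cis-ASM and 5% imprinted probes, 10% unmethylated and 10%
site-free probes, allelic methylation contrast 0.9 vs 0.1, and a 5%
residual escape from digestion at unmethylated sites.

Per probe, baseline intensity I0 is log-normal (median 2,000 units, log-sd
0.5).  For an allele with copy number c and k sites per copy,
E[G] = c·I0; per-site survival is s = m + (1 − m)·residual for copy
methylation m, multiplied independently across sites, summed over copies
for E[D]; the control E[U] = c·I0_U·residual^k with I0_U an independent
multiplicative perturbation of I0 (log-sd 0.05) modelling the distinct DNA
source of the control.  An additive background floor (50 units) is applied
to every channel, which is what gives homozygote clusters their offset
from the axes.

Multiplicative noise (total CV 0.2) is split into a component shared by
the two allele channels of a probe on one array — hybridization and
amplification efficiency, which cancels in RAS — and an independent
per-channel component carrying 25% of the variance.  This decomposition
matters: were the full CV channel-independent, the null expectation of
ΔRAS̄ would be ≈ 0.08 and the 0.1 threshold would be uninformative; with
the split, per-channel CV is 0.1, the null ΔRAS̄ expectation ≈ 0.04, and
null probes essentially never cross the threshold while planted cis-ASM
probes shift by ≈ 0.36 per site.

Imprinted probes methylate one randomly chosen chromosome copy per
individual, independent of genotype — heterozygotes shift in a random
direction, homozygotes lose half their digested signal.

What the generator does **not** emulate: probe-specific cross-
hybridization, batch and plate effects, genotype-calling error, correlated
noise across probes, allele-frequency spectra, and linkage between
probes.  Passing recovery tests therefore demonstrates the statistical
machinery under the stated noise model, not performance on raw array data.

Pyrosequencing simulation adds Gaussian noise (sd 8 percentage points by
default, matching the spread of the packaged measurements) to planted
per-allele means, truncated to [0, 100].  Expression simulation is
intercept + slope·dosage + Gaussian noise floored at 0; the type-I-error
calibration uses an intercept (100) large enough that flooring is
negligible, since flooring would distort the null.

## Numerical choices

* RAS is undefined at A + B = 0; such records are dropped per record (with
  a log message), and a probe needs ≥ `min_het` surviving pairs.
* Exclusion thresholds (1.2), the ΔRAS̄ threshold (0.1) and both window
  sizes (100 kbp, 500 kbp) are configuration values defaulting to the
  study constants.
* No between-array normalization is applied by default: RAS and the
  distance ratios are scale-free within an array.  A median-scaling switch
  exists but is off.
* All window boundaries are inclusive ("within" reads as ≤); coordinates
  are 1-based inclusive internally, BED input is converted at the reader.
* Exact rank-sum enumeration compares |ranksum − mean| with a 1e-9 slack
  to make tie-boundary cases deterministic.
* Multiple-testing correction is applied nowhere by default (none was
  applied in the source design); a Benjamini–Hochberg option exists for
  the expression stage.
* Table outputs use a fixed float format so identical seeds give
  byte-identical files.

## Problem sizes

The recovery studies run on the default panel (1,000 probes × 15
individuals × 3 conditions, ≈ 45,000 intensity records, a few seconds on
one core).  The regression calibration uses 500 replicates of an
11-sample cohort (6/4/1 genotype split).  The exact rank-sum oracle
checks cover pooled sizes up to 12, where full enumeration is 792
assignments.

## Known limitations

* The direction classifier is undersized below 4 informative
  heterozygotes: two same-signed shifts are unanimous by chance half the
  time.  The QC stage's minimum-heterozygote rule (4) guards the final
  candidate list; upstream classifications on fewer shifts should be read
  as provisional.
* The exclusion criteria assume the control (U) baseline tracks the
  genomic baseline within a factor well inside 1.2; a control channel
  with a substantially different hybridization scale per probe would
  erode criterion 2.
* ΔRAS̄ is a magnitude statistic: a probe where exactly half the
  heterozygotes shift each way (imprinting) passes detection, by design,
  and must be separated by the direction label.
* The exact test's enumeration bound (2×10⁶) keeps worst-case runtime
  modest; larger groups silently use the corrected normal approximation.
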