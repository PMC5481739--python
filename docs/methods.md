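# Methods

`tscpipe` re-implements, as a tested pipeline over synthetic data, the
multi-omic analysis chain used to characterize tuberous sclerosis complex
(TSC) hamartomas: two-hit TSC1/TSC2 genotyping across sequencing and
SNP-array evidence, somatic mutation burden, allelic copy-number and
copy-neutral-LOH calling, methylation statistics, differential expression
and signature-based cell-type deconvolution.  No patient data are used
anywhere; every stage runs against a generator whose ground truth makes
recovery testable.

## The synthetic cohort

The generator draws a cohort of patients, one lesion each, on a compact
three-chromosome genome carrying a TSC1-like locus on 9q and a TSC2-like
locus on 16p (`tscpipe.config`).  Defaults encode the cohort structure of
the study the pipeline models:

| parameter | default | meaning |
|---|---|---|
| `gene_split` | 0.849 / 0.121 / 0.03 | germline TSC2 / TSC1 / no mutation |
| `second_hit_prob` | TUB 0.35, others 0.67 | per-lesion-type second-hit probability |
| `second_hit_class_weights` | point 0.35, deletion 0.15, CN-LOH 0.50 | CN-LOH is the most common somatic event |
| `somatic_rate_per_mb` | 0.31 | background somatic SNV/INDEL rate per callable Mb |
| `deletion_size_log_median` | 48.6 kb | log-normal deletion sizes, truncated to [462 bp, 4.8 Mb] (`deletion_size_log_sd` = 1.6 on the natural-log scale; only median and range are anchored, the shape is a modelling choice) |
| `purity_range` | (0.2, 0.9) | uniform per-lesion tumour purity — a stated assumption, not an inferred quantity |
| `mosaic_rate` | 0.03 | germline variants mosaic at VAF ~ U(0.005, 0.045) |
| `depth_mean` / `targeted_depth_mean` | 100 / 1000 | WES vs deep targeted sequencing (the deep assay is what makes sub-5% mosaics visible in normal tissue) |
| `probe_spacing`, `baf_sd`, `lrr_sd` | 2 kb, 0.03, 0.15 | array density and Gaussian probe noise |

Coordinates are 0-based half-open internally; the VCF-dialect variant
table is 1-based, with symbolic `<DEL>` alleles carrying an explicit
0-based half-open `END`.

**Allelic signal model.** For tumour allele copy numbers (nA, nB) at
purity p,

    BAF = ((1-p) + p*nB) / (2(1-p) + p(nA+nB)),
    LRR = log2((2(1-p) + p(nA+nB)) / 2),

with the mirror branch (B on the other parental chromosome) chosen per
probe.  CN-LOH (2,0) therefore leaves LRR at 0 while BAF diverges from
0.5 — the defining signature the caller looks for.  Germline deletions
use the generalized mixture with an aberrant normal component.

**Other layers.** Allele depths are Binomial(Poisson-depth, expected
VAF); a clonal heterozygous somatic variant at purity p has expected VAF
p/2 on a diploid locus (0.13 at p = 0.26, the calibration the defaults
target).  Matched-normal alt counts at somatic loci are exactly zero,
which is what makes the zero-variant-reads filter a clean specificity
check.  Betas are Beta-distributed, low (mean ~0.04) at probes
unmethylated in normals, with disjoint lesion-type-specific spike sets
(~0.8); counts are Gamma-Poisson (NB, dispersion 0.1) mixtures of
per-cell-type reference profiles whose marker blocks are disjoint; true
mixing fractions are tight Dirichlets around lesion-type means (SEN/SEGA
leukocyte mean 12.3%, tubers and normal brain ~1%).  TSC1/TSC2
transcript rows scale as 1 − 0.35 × (truncating allele count), so the
genotype-grouped expression tests have signal to find.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: read-level artifacts (mapping, strand,
base-quality structure beyond the stated post-quality depths), linkage
between SNP probes, array batch/normalization effects, subclonal
copy-number mixtures, mixed or multi-lesion patients, and real genome
annotation.  Recovery rates here are upper bounds for real cohorts.

## Variant filters

Pathogenic TSC-hit acceptance requires total depth strictly >10 and
either a database flag in {pathogenic, probably_pathogenic} or — for
variants absent from (or "unknown" in) the database — absence from
population panels plus moderate/high functional impact; database
"not pathogenic" entries are always excluded; large deletions and CN-LOH
over the loci are always accepted as detrimental.  Somatic SNVs need
tumour depth >10 and zero variant reads in the normal; somatic INDELs
need depth >5 in both samples, >5 supporting reads, zero normal reads
and VAF >0.10.  All thresholds are exclusive, as printed in the source
criteria.  The burden statistic is (SNVs + INDELs) per megabase with >5x
depth in both tumour and normal; base-quality masking is a simulator
contract (depths are post-quality), not recomputed.

## Copy-number and CN-LOH calling

Segmentation is binary segmentation minimizing a least-squares cost
jointly on LRR (all probes) and mirrored BAF (mBAF = |BAF−0.5|+0.5,
heterozygous-in-normal probes only — homozygous probes carry no LOH
information).  Both channels are normalized by robust noise variances
estimated from successive differences; a split is kept when the cost
reduction exceeds `penalty * log(n)` (default penalty 12), a BIC-style
rule.  This deliberately replaces the tangent-normalization / ASCAT /
genoCN tool chain of real SNP-array work with a simplified, testable
equivalent.

Classification thresholds (config-exposed; the source work gives no
numeric cutoffs): CN-LOH iff mBAF ≥ 0.60 and |LRR| ≤ 0.10; deletion iff
LRR ≤ −0.15 with mBAF at least mildly elevated (≥ 0.55 — half the LOH
divergence; the full 0.10 divergence would miss a true (1,0) loss at
purity 0.3, whose expected mBAF is 0.588); gain iff LRR ≥ 0.15; segments
without heterozygous probes fall back to LRR alone.  On noise-free
expected signals the classifier returns the generating state for purity
≥ 0.3.  Events below these purity/size limits are treated as
unrecoverable rather than guessed — the analogue of events the original
analysts could only validate visually.

Arm-level events follow the longest-run rule: merge adjacent same-state
segments within an arm and report 3n (gain) or 1n (loss) iff the longest
non-normal run covers strictly more than 50% of the arm.  Purity, when
not taken from truth, is a 1-D grid search (step 0.01) matching the
largest aberrant segment's (mBAF, LRR) to the expectations for (1,0),
(2,0) or (2,1).  Deletion fine-mapping takes binned targeted read-depth
profiles and returns the longest run of bins at sample/panel ratio
≤ 0.65 (heterozygous-loss expectation) spanning ≥ 3 bins; zero-coverage
panel bins are masked and break runs.

## Two-hit integration

With a matched normal, origin is exact: present in the normal ⇒ germline
(mosaic if normal VAF < 5%), absent ⇒ somatic.  Without one, origin is
*predicted* (labels carry the `predicted_` prefix) from allele
frequencies: VAF in [0.35, 0.65] on a copy-neutral locus ⇒ germline;
inside a CN-LOH/deletion segment the wild-type allele is lost and a
germline mutation rises to (1+p)/2 or 1/(2−p), which exceeds 0.6 for any
purity, so the in-segment germline threshold is 0.6 (without copy-state
context the fallback demands ≥ 0.9).  Because a tumour carries at most
one germline allele per gene, predictions are then made jointly: among
several copy-neutral predicted-germline point calls on one gene, only the
VAF-closest-to-0.5 keeps the label.  Mosaic variants are excluded from
unmatched-accuracy claims: at VAF ≈ p/2 they are indistinguishable from
somatic hits without normal tissue.  All windows are pipeline choices
(the original decision rules live in unpublished supplementary material)
and are config-exposed.

Integration deduplicates pathogenic events per gene (an array deletion
segment overlapping an already-recorded deletion call is the same
event), counts CN-LOH over a locus as a hit only alongside another hit
on that gene, preserves trans-heterozygous (both-gene) cases verbatim,
and computes the truncating-allele count with the rule that CN-LOH
duplicates a truncating germline allele (germline truncating + CN-LOH
⇒ 2 truncating alleles).  Cohort tallies admit 1-hit lesions to the
two-hit denominator only when all DNA platforms completed; "2+" hit
lists collapse to 2 in tallies but the raw list is preserved.
Genotype-grouped transcript comparisons use pair-wise Welch t-tests
(Welch–Satterthwaite df) with Benjamini–Hochberg correction, reporting
Bartlett's statistic as the rationale for avoiding pooled ANOVA.

## Methylation

The hypermethylation fraction of a lesion is the share of probes with
beta > 0.3 among probes whose maximum beta across a ≥2-sample normal
panel is < 0.1 (both cutoffs follow common array practice and are
config-exposed).  Lesion-specific probes require mean Δβ ≥ 0.2 and
BH-adjusted Welch p < 0.05 with ≥3 samples per group.  The
methylation–expression association is the Pearson chi-square on a 2×2
gene table **without** continuity correction:
χ² = n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)).  On the published worked example
(13, 114, 1156, 15125) this gives 1.873 on 1 df (p ≈ 0.17); the
Yates-corrected value (~1.43) does not reproduce the printed statistic,
which fixes the uncorrected form as the default.  Promoter-methylation
screening of TSC1/TSC2 is a presence/absence report over probes mapped
to those genes, not a new statistic.

## Expression

TMM scale factors are computed against the sample whose upper-quartile
count fraction is closest to the cohort mean, trimming 30% of each tail
of the log-ratios M and 5% of each tail of the abundances A
(the edgeR convention; verified against `edgeR::calcNormFactors` in the
test suite), weighting by inverse delta-method binomial variances and
rescaling to geometric mean 1; log2-CPM uses TMM-effective library sizes
and a 0.5 prior count.  Genes pass a CPM > 1 in ≥ 3 samples filter
before testing (the source work does not state its filter; this default
is reported with results).

The moderated t shrinks pooled two-group variances toward a prior:
s²_post = (d0·s0² + d_g·s²_g)/(d0 + d_g), referred to d0 + d_g df, with
(d0, s0²) estimated by moment matching on log s²_g via digamma/trigamma
identities of the log-F distribution (numerically the same estimator the
limma empirical-Bayes fit uses; cross-checked against `limma::eBayes`).
The d0 → ∞ and d0 = 0 limits recover the pooled-variance and ordinary t
(tested).  Precision weights of the voom method are *not* implemented;
plain log-CPM feeds the moderated t — a declared simplification that
affects power, not the statistic's definition.  DEGs require
|log2FC| > 2 and BH-adjusted p < 0.001.

## Deconvolution

Signatures take, per cell type, the top-k genes (default 40–50) by
log-fold of that type's mean CPM over the maximum of the other types,
requiring ≥2-fold and ≥5 markers per type; the matrix holds mean linear
CPM over the marker union and reports its condition number.  Fractions
solve min‖Sf − m‖² s.t. f ≥ 0 (scipy NNLS) and normalize to sum 1 —
a declared stand-in for the ν-SVR of the cited virtual-sorting
framework; acceptance is recovery on synthetic mixtures, not agreement
with that tool.  The empirical p refits on `n_perm` random same-size
gene subsets of the mixture and counts goodness-of-fit correlations
exceeding the observed one.  Group enrichment divides mean fractions,
tests with a two-tailed Student t, BH-adjusts across cell types, and
flags types with fold > 3 (or < 1/3) and adjusted p < 0.05.
Single-replicate reference profiles are accepted with a warning rather
than requiring column duplication.

## Numerical and degenerate-input choices

Segmentation is deterministic (ties in the split search resolve to the
first argmax); tracks shorter than 2×`min_probes` return one segment
with a warning.  The trigamma inverse is a Newton iteration; a
non-positive moment estimate for d0 falls back to the pooled-variance
limit with a log message.  Welch pairs with two zero-variance groups
return t = 0, p = 1 when the means agree and ±∞, p = 0 otherwise.
Degenerate 2×2 tables (zero marginal), zero callable bases, all-zero
mixture on marker genes and invalid configs raise typed errors naming
the offending field.  All randomness flows from the single config seed
through spawned `numpy` SeedSequences; identical (config, seed) yields
byte-identical bundles.

## Problem sizes

The bundled analyses use a 66-patient cohort (the modelled study's
size).  Recovery checks use the sizes at which their claims are stated:
40–42 tumour/normal pairs for the burden median, 120 CN-LOH tracks of
100–800 probes at purity 0.4–0.9 plus 1,000 diploid tracks for the
caller, ~370 eligible tubers for the two-hit tally, 20 null simulations
of 10,000 genes for DE calibration, and 100 noisy mixtures for
deconvolution.  Marginal-rate recoveries (gene split) use n = 500
patients so the binomial sampling error is small compared to the
recovered rates.

## Known limitations

Real-data mode is exercised through per-stage CLI subcommands on the
declared file formats rather than a single orchestrated run; the
simplified segmentation has no tangent normalization and will be less
robust than ASCAT-class tools on wavy real arrays; unmatched origin
prediction degrades as purity approaches 1 (germline and somatic VAFs
merge) and cannot see mosaics; the NNLS deconvolution inherits the usual
collinearity sensitivity between transcriptionally similar cell types.
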