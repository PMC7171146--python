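# Methods

`uvmtk` re-implements, at desk scale and with planted-truth validation, the
computational analyses used to characterize metastatic uveal melanoma
cohorts: arm-level somatic copy-number enrichment between a metastatic and
a reference cohort, copy-number-driven driver prioritization, mutational
signature refitting with strand-bias testing, transcriptomic k-NN
classification, neoantigen candidate filtering, and TCR clonotype
diversity. This note records the models, the defaults and why, the
numerical choices, and what the synthetic experiments do and do not show.

## Coordinate and data conventions

On-disk genomic intervals are 1-based inclusive (the SEG convention);
in-memory intervals are 0-based half-open. The readers/writers in
`uvmtk.io` are the only translation point. Absolute copy numbers are
converted to log2 ratios relative to the diploid state; zeros are replaced
by the sample's smallest observed non-zero copy value before the
transform, so homozygous deletions stay finite. Arm geometry comes from a
built-in GRCh37 table (chromosome lengths and centromere midpoints);
chromosome 3 is treated as a single event unit because recurrent events in
this disease span the whole chromosome rather than one arm.

## Arm-level events and cohort enrichment

A copy-number change qualifies as arm-level when |log2| >= 0.2 (relative
to diploid) and its width is at least half the shortest autosome arm
(about 6.6 Mb on GRCh37, from the 21p arm). A sample carries an
(arm, direction) event when any retained change of that direction overlaps
the arm; a stricter minimum overlap fraction is available
(`arm_cover_fraction`) but defaults to zero, since the per-sample presence
rule is the only part of the region construction that is not fully
determined by the cross-sample definition.

Every (arm, direction) event observed at least once in either cohort is
testable; events never observed anywhere are excluded from the test family
rather than entered as p = 1 rows. The test is the two-tailed Fisher exact
test with the "sum of hypergeometric probabilities <= observed" two-sided
rule (the convention of R's `fisher.test`, matched by scipy; verified
against exhaustive enumeration in the tests). BH correction is applied
across all (arm, direction) tests as one family. The log odds ratio in the
output is Haldane-corrected and purely descriptive.

## Driver prioritization

Within each recurrent region (an externally supplied (arm, direction)
list; recomputing GISTIC-style significance is out of scope):

1. **Normalization.** Counts are RPKM-normalized using robust
   median-of-ratios size factors: the per-gene reference is the geometric
   mean across samples (genes with any zero excluded from factor
   computation); the effective library size is the size factor times the
   geometric mean of raw library sizes; RPKM = count x 1e9 /
   (effective library x max mature transcript length). Doubling one
   sample's counts doubles its effective library and leaves all RPKM
   values unchanged (checked algebraically in tests). When no gene has
   all-positive counts the code falls back to plain library-size factors
   with a warning.
2. **Frequency filter.** A gene's alteration frequency is the fraction of
   samples reaching |log2| >= 0.2 in the event direction; genes at or
   above the third quartile (type-7/linear quantile) of their event's
   frequency distribution are retained. The filter is computed on the
   reference cohort, and metastatic-cohort genes are intersected with the
   surviving set, mirroring study designs that filter the
   large reference dataset first.
3. **Association.** Per gene and cohort, OLS of log2(RPKM + 1) on the
   gene's copy-number status with tumor purity as an additive covariate
   (purity multiplies the copy-number effect physically, but the adjusted
   regression uses it additively, the plainest reading of "adjusting for
   purity"). The copy-number status per gene and sample is the signed log2
   of the overlapping segment with the largest |log2|; ties between +x and
   -x break toward the segment covering more of the gene, then toward the
   loss. Genes with zero variance in predictor or response, or fewer than
   3 complete samples, are dropped. A constant-purity design drops the
   purity column instead of failing on collinearity.
4. **Combination and retention.** Per-cohort p values are combined with
   Fisher's method (chi-square, 4 df; zero p clamped to the smallest
   positive float with a warning) and BH-adjusted across all tested genes
   in all regions jointly. Retained candidates need q < 0.05, raw p < 0.05
   in each cohort, and a positive expression~copy-number slope in both
   cohorts. The slope requirement is positive for loss regions too: a
   dosage-driven tumor suppressor loses expression together with the lost
   copy, which is a positive slope of expression on copy number.
5. **Ranking.** Retained candidates are ordered within their region by
   protein-interaction degree (descending; genes missing from the degree
   table count as zero), then by a consistent worse-survival flag from a
   univariate Cox fit on reference-cohort expression (Efron ties, Wald p;
   gain candidates need coefficient > 0 at p < 0.05, loss candidates
   coefficient < 0 — survival is a tie-break only, never a filter), then
   by combined q, then gene name. Cox models use continuous expression.

## Mutational signatures

Somatic SNVs enter the spectrum when autosomal, absent from population
variant resources, and with alt-allele read support >= 10 (synonymous
variants are deliberately included). Trinucleotide context is a required
input column so no reference genome is needed at analysis time;
purine-reference mutations are reverse-complemented into the 96
pyrimidine-reference channels (substitution class major, then 5' and 3'
flank, alphabetical). The refit solves min ||S w - m||2 subject to w >= 0
with an active-set NNLS solver and reports absolute and relative (sum = 1)
contributions; the tests require the objective to match an independent
accelerated projected-gradient solver to 1e-6 on random instances.

Transcriptional strand bias uses the exact conditional form of the
two-sample Poisson rate comparison: conditioned on the total, the
transcribed-strand count is Binomial(n, 1/2) under equal rates, so the
reported p is the exact two-sided binomial p value, BH-adjusted across the
tested mutation classes. Sites not inside an annotated transcript (or
ambiguous, bidirectionally transcribed ones) carry the "intergenic" label
and are excluded from the bias test.

## Transcriptomic k-NN classification

Spearman rank correlation (average ranks for ties) between the query and
every reference sample over the shared gene set; the k = 6 best-correlated
references vote, and a tied vote is resolved by repeatedly dropping the
worst-correlating member of the neighbor set and re-voting. Equal rho at
the k-th position admits all tied samples before the drop-worst loop, with
deterministic ordering by sample id. Rank-based correlation makes the
label invariant under any strictly increasing transform of the query. The
gene universe is taken from the supplied panel.

## Neoantigen candidate filtering

For each missense substitution a 17-residue window centered on the mutant
position is built, truncated (never padded) at protein termini, and
scanned into all 9-mers that contain the mutant residue (exactly nine for
interior mutations). Binding affinity predictions and transcript
expression are inputs; candidates are retained when predicted affinity is
strictly below 500 nM and transcript expression is strictly above zero
(the cutoff is exposed as `min_expression`). Synonymous, stop-gain and
frameshift records are rejected with a reason.

## TIL clonotypes

A cell is a doublet when externally flagged or expressing more than two
alpha or more than two beta chains (2a+2b alone is not a doublet).
Cell-type labels are corrected by three marker rules — memory-CD4 cells
without CD4 but with CD8A move to the best-scoring non-CD4 type; predicted
non-T cells with any TCR chain move to the best-scoring T type; dendritic
cells expressing CD3G or NCAM1 move to the best-scoring non-dendritic type
— applied in order and iterated to a fixpoint (at most 3 rounds; a cell
whose label cycles becomes "unassigned"), which makes the operation
idempotent. "Expressing" means marker count > 0 (threshold configurable).
Diversity is the Shannon entropy of clonotype frequencies divided by
ln(number of unique clonotypes), defined as 0 for a single clonotype, and
is computed on CD8-positive cells after doublet removal by default.

## Synthetic cohort generator

The generator emulates the study design: a metastatic-like cohort (n = 32)
and a reference cohort (n = 80). Default event frequencies mirror the
recurrent events of the disease (8q gain in every metastatic sample; loss
of chromosome 3, 6q, 17p and gain of 5p at decreasing frequencies, all
rarer in the reference cohort). Each planted event is one whole-arm
segment at the planted amplitude (gain +0.58 ~ one extra copy, loss -1.0 ~
one lost copy, small Gaussian jitter); all other arms are written as
explicit diploid segments. Purity is uniform on [0.3, 0.9].

Expression counts are negative binomial (size 10) around
baseline x 2^(beta x purity x cn): purity multiplies the copy-number
effect, the physical reading of tumor-fraction dilution; baselines are
log-normal. Planted drivers get beta = `driver_beta` and the top
protein-interaction degree; all other genes beta = 0 by default. Survival
in the reference cohort is exponential with log-hazard optionally coupled
to standardized driver expression (sign matching the event direction) and
administrative censoring. Mutation catalogs are multinomial draws from
S w for a synthetic signature set (sparse-Dirichlet columns — synthetic
stand-ins, not any published catalog) with configurable strand asymmetry.
Clonotype frequencies are symmetric-Dirichlet; cells are assigned
multinomially with one alpha and one beta chain, and doublets are injected
as three-alpha cells at a configurable rate.

What the generator does **not** emulate: focal events and realistic
breakpoints (whole arms only, by design), allele fractions and raw reads,
subclonality, purity effects on the segment values themselves,
batch effects, and any dependence between genes beyond shared copy number.
Passing tests therefore demonstrate that the pipeline recovers planted
arm-level structure under the stated noise model, not that it is robust to
segmentation artifacts or focal-event contamination in real profiles.

## Validation experiments and problem sizes

`uvmtk.validation` holds the independent reference routes and the
experiment runners used by both the test suite and
`scripts/acceptance.py`:

- **Oracle equivalence.** Fisher p vs exhaustive hypergeometric
  enumeration over every 2x2 table with total <= 30 (~46k tables) plus
  4,000 random tables with totals up to 60; BH vs a direct step-up
  computation on 200 random lists; NNLS vs accelerated projected gradient
  on 100 random 96x10 instances (objective gap < 1e-6).
- **Closed forms.** Fisher combination of (0.05, 0.05) = exp(-x/2)(1+x/2)
  at x = -4 ln 0.05, i.e. 0.0175; exact binomial two-sided p for (15, 5) =
  2 x 21700 / 2^20 = 0.0414; normalized entropy of (1/2, 1/4, 1/4) =
  1.5 ln 2 / ln 3 = 0.9464.
- **Mixture recovery.** 100 catalogs of 10,000 mutations from a planted
  0.6/0.3/0.1 mixture; mean L1 error of the refit relative contributions
  (typically ~0.012, required < 0.05).
- **Driver recovery.** 100 two-cohort datasets, five regions of 200 genes,
  one planted driver per region. The recovery design plants a strong
  signal (event frequencies 0.5/0.35, amplitudes +-1.0, driver beta 1.5):
  at the default frequencies the 8q event is present in every metastatic
  sample, which removes all within-cohort copy-number contrast and makes
  the association unidentifiable there — an instructive property of the
  retention rule, but not a test of the ranking machinery. Required: the
  planted driver is rank 1 in its region in >= 95% of driver instances.
- **Null error control.** 200 replicates with identical event frequencies
  in both cohorts and no expression coupling; the fractions of arm events
  flagged at q < 0.05 and genes retained at q < 0.05 must not exceed the
  nominal level (plus a 99% binomial margin). Both are conservative in
  practice: the discrete Fisher test rarely reaches q < 0.05 at these
  sample sizes, and candidate retention stacks four conditions.

Problem sizes (exhaustive enumeration bound, replicate counts, genes per
arm in the null runs) are chosen so the full validation completes in a few
minutes on one CPU; all experiments are seeded and deterministic.

## Known limitations

- Segmentation workflows often re-center noisy profiles and apply extra
  amplitude-based filtering with tool-specific, undocumented rules; only a
  manual per-sample re-centering offset is supported here and no automated
  variant is attempted.
- The upstream single-cell classifier (and the code error it contained) is
  not reproduced; its correlation scores are inputs and only the stated
  correction rules are applied.
- Real VCF/MAF ingestion is limited to the MAF-lite TSV; context
  extraction from a reference FASTA, alignment, variant calling, HLA
  typing and binding prediction are all upstream of this package.
- Headline numbers of real metastatic uveal melanoma cohorts (e.g. the specific
  signature contribution of the UV-dominated sample, differential
  expression counts) derive from controlled-access data and are not
  recomputable here; validation is property-based on synthetic cohorts.
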