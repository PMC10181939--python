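# Methods

This note documents the models and procedures implemented in `gie-scan`, the
assumptions behind them, the parameters that matter, and the design choices
made where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Event-calling model

A sample's immune-escape status is the union of per-gene calls over a 21-gene
registry grouped into six pathways: HLA-I (HLA-A, HLA-B, HLA-C), antigen
presentation (B2M, CALR, TAP1, TAP2, TAPBP, NLRC5, CIITA, RFX5), IFN-γ (JAK1,
JAK2, IRF2, IFNGR1, IFNGR2, APLNR, STAT1), PD-L1 (CD274), CD58 and SETDB1.
CD274 and SETDB1 are gain-type (escape via amplification); all others are
loss-type.

Thresholds, with rationale:

| quantity | threshold | meaning |
|---|---|---|
| HLA-I LOH | minor allele ploidy < 0.3 and major > 0.7 | one parental allele lost, the other retained; the 0.3/0.7 margins tolerate purity/ploidy estimation noise |
| homozygous deletion | minimum tumor CN < 0.5 | both copies lost after rounding noise |
| amplification | minimum tumor CN > 3 × mean sample ploidy (strict) | ploidy-relative, so whole-genome duplication does not masquerade as amplification |
| inactivating mutation | clonal LoF (frameshift, stop gained/lost, splice acceptor/donor/region, start lost), mono- or biallelic; or biallelic clonal nonsynonymous non-LoF | monoallelic missense is not treated as inactivating |
| HLA nonsynonymous | any protein-altering consequence, clonality not required | the HLA calls come from allele-resolved typing, where any coding change can disturb presentation |

Boundary conventions: all comparisons above are strict on the calling side
(minor = 0.3 does not call LOH; min CN = 3 × ploidy does not call
amplification). QC retains samples with purity ≥ 0.2 and TMB ≥ 50 (inclusive
on the retained side; the thresholds are configurable). Coordinates are
0-based half-open throughout (BED convention).

Homozygous deletions of HLA-I are reported inside the `LOH_HLA` event class
with a `homozygous_deletion` sub-flag, so prevalence groups them with LOH while
downstream analyses (e.g. the allele-loss bias, which needs exactly one lost
allele) can separate them.

Focality of a copy-number event: *nonfocal* when the segment covers more than
75% of at least one chromosome arm it overlaps (a centromere-spanning segment
is nonfocal if either arm qualifies), otherwise *focal*, and additionally
*highly focal* when shorter than 3 Mb. Highly focal implies focal; exactly 75%
of an arm is focal.

## Positive-selection scan for copy-number events

For event type E ∈ {LOH, HD, AMP} at one focality scale, per sample the
qualifying segments on the autosomes are gathered (samples with none are
ignored) and re-placed along the autosomes in `n_rand = 10` independent
randomizations. The autosomes are tiled into fixed 100-kb bins (the shipped
hg19 build gives 28,823 bins; the exact count depends on the chromosome-length
table, so the tested contract is the tiling identity — bin widths sum exactly
to the autosome length — rather than a specific count). An event increments
every bin it overlaps, not just a representative position; this makes nonfocal
events span many bins, as they do in per-chromosome event-distribution plots.

Each bin's observed total O is tested against an expected count with the
two-category G-test (in-bin vs not-in-bin, one degree of freedom, 0·ln 0 ≡ 0),
and p-values are BH-adjusted over all bins of the scan. The expected count is
the **global simulated mean** across all bins and randomizations rather than
the per-bin simulated mean: per-bin means are depleted near chromosome starts
(an interval's valid start positions exclude those that would run past the
chromosome end), which would bias bin-specific comparisons; the per-bin
simulated means are still emitted for diagnostics. Bins are flagged `enriched`
only when O exceeds the expectation, since the question is higher-than-expected
recurrence. Gene-level q is the minimum q over the bins overlapping the gene's
coding span — two genes sharing a bin necessarily share a q.

**Shuffle algorithm.** Non-overlapping placement uses gap-based sequential
placement: intervals are placed longest first, each uniformly over the start
positions that keep it inside a remaining free gap (gap chosen with probability
proportional to its number of valid starts). This conserves the number and
length multiset of intervals exactly, never extends past a chromosome end,
needs no retry loop, and handles even an exact genome tiling — a property the
simulated-GIE control relies on (a genome fully covered by LOH must remain
LOH-positive under any re-placement). For a single interval the placement is
exactly uniform over all valid (chromosome, start) pairs, which is the
distributional contract the calibration tests check. When no free gap can host
an interval the whole placement falls back to independent overlapping mode,
flagged in the result and logged; the scan also pre-emptively uses overlapping
mode for samples with more than 10,000 events. Sequential gap placement is not
exactly uniform over the set of all non-overlapping configurations, but at
realistic event densities (genome coverage per sample well below 10%) the
deviation is negligible against Poisson counting noise.

**Calibration diagnostic.** G-test p-values on integer counts are discrete, so
their null distribution cannot be uniform in the KS sense at any realistic
event density. The scan therefore also emits `p_smooth`, a randomized
(U-smoothed) upper-tail p-value computed under Poisson(global mean):
p = P(X > O) + U·P(X = O), which is exactly U(0, 1) when the per-bin counts are
Poisson with the estimated mean. The null-calibration test checks KS uniformity
of `p_smooth`; `p` itself remains the inferential quantity.

Per-sample randomization seeds derive deterministically from
(run seed, sample index, randomization index) via `numpy.random.SeedSequence`.

## Neoepitope allele-loss bias

For every sample with HLA-I LOH, each LOH-targeted gene contributes one record
with nr = neo(A1)/(neo(A1)+neo(A2)). Allele numbering is randomized per record
with the run seed. Homozygous genes are excluded (nr ≡ 0.5); records where
both alleles (homozygous deletions) or neither allele has tumor CN < 0.3 are
dropped and logged, as are records with no predicted neoepitopes. Records are
grouped into eight nr buckets with left-open/right-closed bounds
(0–0.35], (0.35–0.4], (0.4–0.45], (0.45–0.5], (0.5–0.55], (0.55–0.6],
(0.6–0.65], (0.65–1], so nr = 0.5 falls in (0.45–0.5].

Per bucket, 100 bootstraps subsample ⌊0.75·n⌋ records without replacement;
F_A1loss is the subsample's allele-1 loss fraction and F_A1exp reassigns loss
by a fair coin per subsampled record. Buckets with n < 2 are reported with
missing F values. Per-bucket random draws are seeded from a hash of the
bucket's record identities, so globally relabeling alleles — which mirrors
every bucket onto its counterpart with the same record set — replays identical
subsamples and yields exactly mirrored F_A1loss values (tested element-wise).

**The KS p-value and its calibration.** The default test is the classical
two-sample KS on the pooled bootstrap-level F values (all buckets × 100
bootstraps per arm), with a bucket-means variant (8 values per arm) emitted for
sensitivity. The pooled variant treats up to 800 values per arm as independent
observations, but bootstrap replicates within a bucket reuse the same records
and are strongly dependent; its p-value is therefore **anticonservative** —
under a fair-coin null it rejects at the 5% level in the large majority of
runs, and the package's own acceptance suite documents this as a failing
calibration test rather than hiding it. `calibrated_bias_test` keeps the same
pooled D statistic but computes its null distribution by Monte Carlo over
record-level fair-coin reassignments (default 199 replicates, pseudocount
(1+x)/(1+R)); this empirical p is calibrated by construction. Its power is
correspondingly lower: the bias signal is directional across buckets, which a
KS distance aggregates inefficiently, so moderate biases that the classical
p-value flags spectacularly may need several times more records to reach
significance under the calibrated test. Both numbers are reported; analysts
should treat the classical p as a ranking score and the calibrated p as the
inferential one.

## Prevalence, cohort comparison, mutual exclusivity

Prevalence is the number of samples with at least one event in a pathway over
the cohort size, per cohort × cancer type, plus a combined `any` row (a sample
counts once per pathway and once overall). Cohort comparison runs a two-sided
Fisher exact test per cancer type × pathway on the escaped/not × cohort table,
BH-adjusted in one family per invocation; log2 odds ratios apply Haldane's 0.5
correction when a cell is zero; cancer types absent from either cohort are
skipped and logged.

Mutual exclusivity of HLA-I LOH versus other escape events uses (i) a
left-sided Fisher exact test on the 2×2 of group memberships and (ii) an
empirical p from 10,000 per-sample independent Bernoulli randomizations at the
observed group frequencies, with the (1+x)/(1+N) pseudocount. The direction as
literally stated in the field — randomizations with *less* co-occurrence than
observed — is the complement of an exclusivity test, so both directions are
emitted: `empirical_p` (≤, small when co-occurrence is deficient, i.e.
exclusivity) and `empirical_p_ge`.

## Burden buckets and the simulated-GIE background

log10(burden) is split into 20 evenly spaced buckets (10 in cancer-type mode)
between the 1st and 99th percentile; assignment is left-open/right-closed,
values above the top edge go to the last bucket and values at or below the
bottom edge to the first (the symmetric catch-all is our choice; only the
above-top rule is forced). Mutation counts are displayed per megabase by
dividing by 3,000. Per bucket, escape frequency is bootstrapped with 1,000
subsamples of ⌊0.5·n⌋ without replacement (implemented exactly as a
hypergeometric draw). When excluding nonfocal HLA-I LOH, the exclusion is
event-level: bucket membership keeps all samples, only escape status changes,
so excluding events can never raise a bucket's frequency. On the neoepitope
axis, putative neoantigen counts are estimated as 1% and 5% of each bucket's
summed predicted neoepitopes.

The simulated-GIE background asks how much escape the same alteration burden
would produce if it were placed at random. Per iteration and sample: (i) the
observed coding-mutation count — derived from TMB as
round(TMB × footprint/3,000 Mb) with a 30-Mb default coding footprint — is
redistributed by a multinomial over the registry genes plus the rest of the
footprint, with per-gene probability proportional to coding length;
consequence, clonality and biallelic flags are resampled from the sample's own
observed mutations (cohort mix as fallback); (ii) the sample's qualifying
LOH/HD/AMP intervals are re-placed with the same gap-based shuffle; (iii) the
standard calling rules are re-applied to the simulated profile. The mutation
burden (total coding count) and the CNV length multiset are conserved exactly.
This background is deliberately signature-agnostic: real mutation placement is
modulated by trinucleotide context, replication timing and chromatin, none of
which a length-proportional model captures; the placement policy is a single
function and can be swapped for a context-aware one without touching the rest
of the control.

## Synthetic cohort generator

The generator is the package's stand-in for controlled-access tumor cohorts
and defines the conditions under which every analysis is validated. Defaults
(all configurable):

- **Samples**: purity ~ Beta(6, 2) (mean 0.75), resampled to ≥ 0.2 unless QC
  failures are requested; mean ploidy ~ Normal(2.0, 0.35) truncated at 1;
  TMB ~ log-normal with log10 mean 3.9 and s.d. 0.45 per cancer type
  (≈ 2.6 mutations/Mb at the median, metastatic-like); clonal fraction 0.8;
  biallelic fraction 0.1.
- **Copy number**: diploid (1, 1) baseline; arm-level events at rate 0.05 per
  arm (60% LOH, 40% gain); focal LOH at Poisson mean 3.5 per sample with
  exponential lengths of mean 500 kb clipped to [100 kb, 2.9 Mb]; focal HD
  and amplification at Poisson means 0.3 and 0.5. Later events overwrite
  earlier ones; adjacent equal-state segments merge, so every sample's
  segments tile each autosome exactly.
- **Locus enrichment**: a multiplier m on gene g injects extra focal-LOH
  events overlapping g at Poisson rate (m−1)·rate·p_g with
  p_g = (mean length + gene length)/autosome length, making the expected
  event count over the gene's bins ≈ m × the genome average (verified by
  direct counting in the tests).
- **Escape injection**: per pathway, P(inject) = logistic(logit(base rate) +
  slope·(log10 TMB − 4)); pathway 1 injects a focal LOH segment containing a
  random HLA gene, loss-type pathways inject clonal mutations (or an HD
  segment 25% of the time), gain pathways an amplification segment.
- **HLA model**: two alleles per gene from a 30-allele pool, homozygous with
  probability 0.1; per-allele neoepitope counts 1 + NegBin(mean 150,
  dispersion 4), giving an nr spread that populates all eight buckets. At a
  gene in an LOH state, allele 1 is lost with probability
  logistic(β·(nr − 0.5)); β = 0 is unbiased, β = 2 is the recovery condition
  used in validation. Per-allele CN and the segment profile are derived from
  the same event list, so copy-number-based and allele-based calls agree by
  construction.
- Every injected event and every designated lost allele is recorded in a
  truth table.

What the generator does **not** emulate: mutational signatures and context
effects, subclonal copy-number structure and purity-driven estimation error
(CN values are exact), germline HLA allele-frequency structure and linkage,
read-level data, RNA expression, and fusion/viral neoepitope sources.
Consequently, passing recovery and calibration tests demonstrates that the
statistical machinery is correct and well calibrated under the stated
generative assumptions — not that those assumptions hold in any real cohort.

## Validation problem sizes

The test suite validates at desk scale, chosen to give the statistical checks
adequate power while keeping the suite fast: null calibration of the selection
scan on a 4 × 50 Mb toy genome (2,000 bins), 200 samples × 20 seeds;
enrichment recovery on hg19 with 100 samples at 100 focal LOH events per
sample (a chromosomally unstable, metastatic-like load) and 10× HLA
enrichment; allele-bias recovery and null calibration with ~500 focal LOH
records per run; burden-bucket and background checks with 600–1,500 samples
and 100 simulation iterations. `scripts/acceptance.py` uses 500 + 300 samples.

## Known limitations

- The classical pooled KS p-value of the allele-loss bias test is
  anticonservative (see above); the calibrated variant is underpowered at a
  few hundred records. There is no free lunch between the two with this
  statistic; a likelihood-based directional test would dominate both but is
  outside the analysis family implemented here.
- Adjacent qualifying segments with different copy-number states are counted
  as separate events in the selection scan; a merged-event definition would
  shift absolute counts but both observed and randomized sides identically.
- The simulated-GIE background inherits the length-proportional mutation
  placement assumption; in real data, hypermutated regions could inflate the
  background escape rate relative to this model.
- Gene coordinates and coding lengths ship at approximate (kb) precision,
  which is immaterial at 100-kb bin resolution but too coarse for
  exon-resolution work, which is out of scope.
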