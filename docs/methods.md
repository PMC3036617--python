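# Methods

This note documents the models and procedures implemented in `zdimorph`,
the parameter choices that matter, what the synthetic data generator does
and does not emulate, and the numerical decisions taken where the design
was genuinely open.

## The analysis problem

Male birds are ZZ, females ZW, and dosage compensation in birds is
incomplete: many Z-linked genes are expressed more highly in males simply
because males carry two copies. A brain-expression scan comparing the
sexes on a large EST array therefore expects (i) a modest number of
sex-biased transcripts, (ii) a strong male excess among them, (iii) a
strong concentration on the Z chromosome, and (iv) small fold changes
(around 1.1–1.3), because brain tissue is far less dimorphic than gonads.
When a second, related species is hybridised to the same array, probes
overlapping diverged sequence must be masked, and the comparison of the
two species' sex-biased gene sets asks how conserved the underlying
regulation (or the pattern of dosage compensation) is.

`zdimorph` implements that chain end to end: preprocessing, filtering, the
significance test, gene-level aggregation, chromosomal enrichment, and
cross-species concordance, with a generator that plants known effects so
each stage's behaviour can be measured against truth.

## Preprocessing

**Quantile normalization.** All arrays are forced to a common empirical
intensity distribution: rank r in each column is replaced by the mean of
the rank-r order statistics across columns. Ties within a column receive
the mean of the target values they would occupy, which makes the transform
deterministic regardless of sort stability; the grand sum of the matrix is
preserved, and the operation is idempotent.

**Summarization.** Per EST, the additive model
`log2 y[p,s] = μ + probe_p + sample_s + r[p,s]` is fitted by Tukey median
polish (tol 0.01 on the log2 scale, at most 10 full iterations — the
conventional robust-average settings); the EST's expression in sample *s*
is `μ + sample_s`. Sweeps start with the sample (column) medians. This
ordering was chosen deliberately: the first column sweep absorbs any
per-array constant shift, so summarization is *exactly* equivariant — 
adding c to every log2 intensity of one array adds exactly c to that
array's EST expression values. With probe-first sweeps the equivariance
would only be approximate at a finite iteration cap. For exactly additive
tables both orderings recover the same decomposition.

**Background correction.** Full RMA-style normal+exponential background
deconvolution is omitted by default. The downstream analysis is a
between-sex contrast within one normalized array set, which a global
background shift leaves essentially unchanged; an optional global
percentile shift (`background_shift`) is available.

**Replicate QC.** Within each species, pairwise Pearson correlations of
the EST-level expression are computed; a sample whose mean correlation to
its same-species replicates falls below a threshold (default 0.9) is
flagged. Flagging is report-only — exclusion is a pipeline option
(`drop_flagged`) — and a non-positive threshold disables it. The threshold
is our quantitative stand-in for what is usually an eyeball judgement of
"deviating" correlation plots.

## Filtering

Two rules, applied in this order, with exact accounting
(`n_input = removed_SD + removed_retention + remaining` always holds):

1. **Relative-SD filter.** An EST is removed when the standard deviation
   of its signal across arrays exceeds 30% of the median of that signal.
   Both statistics are computed per EST on the unlogged (2^x) scale of the
   normalized expression, with the sample standard deviation (ddof 1).
   The rule is strict (`>`): an EST sitting exactly at the bound is kept.
   Whether the original rule operated on logged or unlogged, per-EST or
   array-wide medians is not specified anywhere we know of; per-EST
   unlogged is this package's reading, and both the threshold and the
   scale are parameters.
2. **CGH mask and retention filter.** Probes that failed cross-species
   genomic hybridisation are masked; each EST is annotated with its
   retained probe count, and only ESTs retaining at least `min_probes`
   (default 8) are analysed. The floor is an absolute count — a short
   (8-probe) EST that loses any probe is removed — matching the
   convention that probe sets need 8 informative probes. Mask entries not
   present in the design are reported and ignored, not fatal.

## The SAM test

For EST *i* with female (treatment) and male (control) groups:

    d_i = (x̄_F,i − x̄_M,i) / (s_i + s0)
    s_i = sqrt{ (1/n_M + 1/n_F) · [SS_M + SS_F] / (n_M + n_F − 2) }

At `s0 = 0`, `d_i` is the pooled-variance two-sample t statistic. The
fudge factor `s0` stabilises `d` at low variance: candidates are taken at
the percentiles {0, 5, …, 95} of the `s_i` distribution and the candidate
minimising the coefficient of variation of windowed MADs of `d` (100
`s`-quantile windows) is chosen — deterministic, ties to the smallest
candidate. `pi0` (the null fraction) defaults to 1.0, conservative; an
optional estimator uses the fraction of observed `d` inside the
permutation interquartile band, capped at 1.

**Permutation null.** Sample labels are permuted jointly across all ESTs,
preserving inter-gene correlation. When the number of distinct label
assignments is at most the permutation budget (500 by default) all of them
are enumerated — so small designs are fully deterministic; otherwise
assignments are sampled uniformly without replacement. Expected order
statistics `d̄_(i)` are the means of the i-th smallest permuted scores.
With full enumeration the assignment set is closed under complement, which
makes the null exactly symmetric and the results invariant to which sex is
entered as the control group; with sampled assignments that invariance
holds up to Monte-Carlo error.

**Operating point.** For each Δ in a grid (0.05–5.0, step 0.01), `cutup`
is the smallest observed order statistic exceeding its expectation by more
than Δ and `cutlow` the largest falling below by more than Δ; ESTs outside
(cutlow, cutup) are called. The FDR estimate is
`pi0 · median_b(#permuted scores outside the cutoffs) / #called`. The
chosen Δ minimises |FDR − target| (target 0.03 by default). Two numerical
decisions:

* Ties break toward the smallest Δ. The median-based estimate plateaus at
  exactly zero over long Δ ranges; breaking ties upward would shrink the
  call set to a single extreme EST for no inferential gain.
* Operating points with estimated FDR above `max_fdr` (default 0.5) are
  not considered usable. Without this guard, data with no real group
  difference would "choose" an operating point calling everything at an
  estimated FDR near 1; with it, the null outcome is an empty significant
  set and a warning.

**Directions and fold changes.** A called EST is male-biased iff its male
mean exceeds its female mean (invariant to the control/treatment
designation). Fold changes are computed on unlogged data for the called
set as mean male over mean female expression, so FC > 1 means male-biased.

## Gene collapse, enrichment, comparison

ESTs sharing an annotation id are the same gene; ESTs without one are each
their own non-redundant gene. A gene with both male- and female-biased
significant member ESTs is *ambiguous*; ambiguous Z-linked genes carry a W
flag (female-biased members may in fact be W-chromosome homologues — no
sequence comparison is attempted). Gene-level FC is the arithmetic mean of
member significant ESTs' FCs. Summary-table percentages use all
significant ESTs as the EST denominator and the unambiguous directional
genes as the gene denominator, rounded to two significant figures for
display.

Chromosome class comes from the annotated chromosome at BLAST E ≤ 1e-20;
weaker or absent hits are "none". When members of one gene disagree, the
majority class wins (tie → "none") with a warning.

Enrichment is a two-sided Fisher exact test (method of small p-values; the
implementation delegates to `scipy.stats.fisher_exact`, which matches
exact enumeration to < 1e-12 on small tables) on
`[[obs_Z, obs_A], [bg_Z − obs_Z, bg_A − obs_A]]` per direction, using
unambiguous genes only; the background is the EST-level annotation count
by default (a gene-level background is a parameter). The "no annotation"
class is excluded from the 2×2 table and reported alongside. The odds
ratio is the sample OR; a Haldane (+0.5) version is reported separately
when a cell is zero.

Cross-species comparison partitions the union of the two species' gene
sets into shared-same-direction, shared-ambiguous, reversed, unique-A and
unique-B, each with chromosome-class counts. A gene ambiguous in one
species and directional in the other counts as shared only when the
directional call matches the ambiguous gene's majority direction;
otherwise it lands in an auditable "discordant-ambiguous" bucket. Genes
un-testable in species B (all member ESTs filtered away there) are
reported as such rather than as evidence of species specificity. A
population-contrast SAM run within species B, intersected with the sex
calls, checks that the sex signal is not driven by sampling population.

## The synthetic generator

`simulate_experiment` draws, per probe and sample,

    log2 y = baseline_est + effect_est·[male] + pop_effect_est·[pop2, B only]
             + affinity_probe + ε,   ε ~ N(0, noise_sd),  intensity = 2^signal

with probe affinities shared between species (same physical array).
Defaults are the study conditions: 11 probes per EST with a small tail at
8–10 (148/23,136), 4.6% Z-linked ESTs, 4,107/23,136 unannotated,
9,827/254,430 probes CGH-masked, six replicates per sex per species, and a
male dosage effect of mean log2(1.2) on 33% of Z-linked genes; 0.2% of
autosomal genes are sex-biased (magnitude 0.6 log2, either sign). Half of
all planted effects are shared between the species, the rest present in
only one. Effects are drawn per gene (coefficient of variation 0.25) so
redundant ESTs agree in direction; a small fraction of genes (0.5%)
carries an independent population effect in species B, giving the
population cross-check something real to find. Baselines are
N(8.0, 1.5) log2 units, probe affinities N(0, 0.7), residual noise
N(0, 0.25) — values chosen once to mimic the dynamic range and replicate
correlation of RMA-processed oligo arrays. CGH-masked probes are *not*
deleted: they are replaced by a depressed noisy background draw
(N(4.0, 0.7) log2), so removing their influence is the filter's job, not
the generator's — and median polish's robustness means up to 3 such probes
do not distort an EST's summary. The default generated scale is 2,000
ESTs; the full 23,136-EST array is a parameter away.

What the generator does **not** emulate: spatial array artifacts, probe
sequence thermodynamics (GC content, cross-hybridisation between related
probes), intensity-dependent variance beyond the log-normal model,
correlated gene networks, and partial dosage compensation gradients along
the Z chromosome. Tests passing on this generator therefore demonstrate
the pipeline's statistical behaviour under its stated model, not
performance on any real hybridisation.

## Determinism and seeds

All randomness flows from `numpy.random.default_rng` generators seeded
explicitly. The pipeline derives a child seed per stage from the global
seed and the stage name, so stages can be re-run independently and a full
run is byte-for-byte reproducible. Simulation with equal configs is
byte-identical.

## Problem sizes used in the test suite

The statistical acceptance checks run at 2,000 ESTs with six replicates
per sex and 500 permutations: 50 replicates for the global-null
calibration and 20 seeds for planted-effect recovery. At these sizes the
null check and recovery check each complete in well under a minute on one
CPU; the generator's full 23,136-EST scale is exercised for the filter
accounting arithmetic, where only counting is at stake.

## Known limitations

* The SAM plugin originally used for this kind of analysis is not
  numerically reproduced — its exact `s0`, `pi0` and tie conventions are
  unpublished. The operating point (Δ, estimated FDR) is therefore
  implementation-specific even though the procedure is the same.
* The FDR estimate is the set-level permutation estimate; no per-gene
  q-values are computed.
* The SD filter's scale (unlogged, per-EST median) is an interpretation;
  both scale and threshold are parameters.
* Enrichment treats genes as exchangeable; no correction for gene length,
  expression level or probe count is attempted.
* Multi-class, paired and survival SAM modes are out of scope.
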