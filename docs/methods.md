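# Methods

## Data model and coordinates

All coordinates are 0-based half-open. A CpG dyad is addressed by the
plus-strand position of its C; strand merging (`merge_dyad_strands`) is
explicit and optional, since extractor output is usually already
dyad-merged. Read counts are authoritative: a file's (rounded) rate column
is recomputed from counts when coverage is positive and rejected if it
disagrees by more than 0.5 percentage points. Chromosome names are matched
by exact string equality; no alias table (known limitation).

## Domain calling

A dyad qualifies for a HypoMD iff its rate is strictly < 40% and for a
HyperMD iff strictly > 60%; rates exactly at a threshold qualify for
neither. Genomic CGs without a valid (coverage ≥ 5×) call are
*undetermined*. A domain is a segment that (a) begins and ends on
qualifying dyads, (b) contains ≥ 10 qualifying dyads, and (c) contains at
most 4 non-qualifying-or-undetermined dyads in total. The interleave limit
is read as a total budget per domain; a consecutive-run variant is
available via `CallerParams.interleave_mode="run"` for sensitivity
analysis.

Scanning is greedy left-to-right: from the leftmost qualifying dyad that
admits a feasible segment, the segment is extended as far right as
feasibility allows (leftmost-longest), emitted, and the scan resumes after
it. Domain coordinates run from the first qualifying C to the last
qualifying C + 2, covering both bases of the terminal dyad. Hypo and hyper
calls are made independently; overlaps between the two kinds are reported,
never resolved.

`call_domains_bruteforce` re-derives the same selection rule from an
exhaustive enumeration of all feasible index intervals (prefix-sum
feasibility checks, O(n²)) and is used to cross-validate the scanner on
randomized tracks. Two numerical caveats are deliberate properties of the
greedy rule, not bugs: maximal feasible intervals *can* overlap (e.g.
Q×10 N×4 Q×10 N×4 Q×10), and raising the interleave budget can *decrease*
total covered qualifying dyads, because a longer first domain may strand a
later dyad. The tested monotonicity invariant is therefore stated on the
feasible-interval coverage set, which does grow with the budget.

## Spectrum SVM

The featurizer counts every length-k window (k = 6 by default, 1 ≤ k ≤ 8)
consisting solely of A/C/G/T; windows containing N are skipped, which is
how CpG masking (CG → NN) removes CpG-adjacent windows. Reverse-complement
pairs are pooled into one canonical feature (the lexicographically smaller
of the pair; 2080 features at k = 6) because genomic strand is arbitrary.
Vectors are L2-normalized by default so that segment length does not
dominate the margin. The classifier is a linear soft-margin SVM
(scikit-learn `LinearSVC`, C = 1) with per-class weights {positive: n₋/n₊,
negative: 1}; with the published domain counts that ratio is 12.56.

AUPRC uses the average-precision estimator (step-wise precision summed
over recall increments) — conservative under class imbalance and free of
trapezoidal optimism. Cross-validation is stratified 10-fold with a fixed
shuffle seed; per-fold curves, fold min/max and a pooled curve over
concatenated held-out decision values are all reported, since either
convention is defensible. Note that with fully tied scores the
average-precision estimator returns the prevalence, so the "worst
ranking" lower bound is only attained by tie-free orderings.

For CpG-context classification (did an individual CpG lose its
pre-methylation or keep it?), each matched CpG contributes its
[pos − 10, pos + 12) window; windows beyond chromosome bounds are dropped
and counted. "Demethylated" means ectopic rate < 40%, "maintained" > 60%
(the domain thresholds reused; both configurable), the middle band
excluded.

## Ectopic analysis

Matching pairs every fragment CpG (fragment start + offset) with the
endogenous call at that position; CpGs without a valid endogenous call are
dropped and counted. Ectopic evidence from multiple integration events is
pooled per (position, library) by summing read counts, reflecting deep
pooled-embryo sequencing. Rank correlations are Spearman's ρ and
Kendall's τ-b — the tie-corrected variant, because observed rates pile up
at exactly 0 and 100. Constant inputs yield a flagged undefined report
rather than an exception. Histograms use 100 bins of 1%, with 100.0
assigned to the last bin so counts conserve n.

DHS stratification is at CpG level (inside/outside), except that a
fragment crossing a DHS boundary labels all its CpGs "spanning-fragment";
the fraction of non-spanning fragments is reported alongside. Fragment-level
stratification classifies a fragment as endogenously hypomethylated
(mean matched endogenous rate < 40%) or hypermethylated (> 60%), with the
middle excluded and counted.

## Sanger quantification

Methylation per CpG is 100·C/(C+T) from the bisulfite-frame trace; editing
per PAM is 100·C/(C+G) at the PAM third base on the native-frame trace
(NGG → NGC substitution marks edited alleles). The locus editing rate
aggregates PAM sites by unweighted mean (median exposed as an option); the
source protocol reports one rate per locus over six PAMs without stating
the aggregation. Normalized methylation = methylation ÷ editing; because
low editing rates inflate the quotient, values above 100% are capped and
flagged rather than silently truncated. CpG sites are annotated on the
bisulfite frame and PAM sites on the native frame, so the two peak tables
are separate inputs. Sites with zero informative signal are reported as
undetermined (methylation) or skipped with a warning (editing); all PAMs
uninformative is an error.

## Synthetic world

Defaults are chosen once to match the emulated biology and are not tuning
knobs:

- **Genome**: GC fraction 0.40 and background CpG density 20/kb (fish-like;
  the emulated genome has ~23 CpG and ~1 MspI site per kb). Accidental CGs
  are stripped and CG dinucleotides planted as a Bernoulli process so
  realized density is exactly controlled; islands carry a 5× density
  multiplier. `n_cpg_rich_hyper` embeds CpG-dense patches that stay
  hypermethylated — real genomes contain these, and they are what makes an
  MspI capture sample hypo- and hypermethylated CpGs about equally; they
  default to 0 so the island/background contrast equals the configured
  multiplier exactly.
- **Methylome**: true rates are Beta(1,9)·100 in islands and Beta(9,1)·100
  outside, reproducing the strongly bimodal rate distributions of real
  embryos; coverage is negative-binomial with mean 8 (dispersion n = 4),
  the post-filter mean coverage being emulated, so a realistic fraction of
  dyads fails the 5× filter and becomes undetermined.
- **Capture**: full C^CGG digestion (fragments tile the genome), internal
  fragments only, retained at 40–220 bp, adapter extension +144 bp
  (→ 184–364 bp). Dam labeling/DpnI counter-selection is abstracted away
  (a purification step, not an analytical one).
- **Integration models**: maintenance flips the library state per CpG with
  gain/loss rates γ = δ = 0.02 (the observed spontaneous losses — 4 of 202
  CpGs — suggest this order of magnitude; it is a free parameter, not a
  calibrated one); sequence-determined adds N(0, 5²) percentage points to
  the endogenous true rate; default-hypermethylation draws Beta(9,1)·100
  regardless of library. Ectopic coverage is negative-binomial with mean
  250 (the emulated assays averaged 292× and 208×).
- **Classifier segments**: the two domain classes share one length
  distribution (lognormal, median 1 kb, σ = 0.6, clipped to 0.2–5 kb) and
  one GC fraction, because real hypo- and hypermethylated domains are not
  separable by length or GC; per-segment CpG densities are Gamma(shape 4)
  draws with means 45/kb vs 15/kb — overlapping distributions with a
  ~3× median ratio. One CpG-free motif (TGATAA) is planted at 2/kb vs
  0.2/kb. These choices are what keeps the CpG-masked classifier
  informative but strictly weaker than the unmasked one; with fixed
  lengths/densities the count of masked windows alone would leak density
  and saturate the masked model.
- **Traces**: peak heights proportional to the rate/editing mixtures with
  multiplicative lognormal noise; zero noise recovers truth exactly.

What a green test does *not* establish: the generator draws island
sequences i.i.d. around planted signals, so it contains no repeat
structure, no mappability artifacts, no bisulfite non-conversion, no PCR
bias, and its motif vocabulary is a single planted word rather than a
transcription-factor lexicon. Classifier scores on this world say the
pipeline recovers planted signal at realistic signal-to-noise, not that
real domains are this separable. Likewise the integration-model
discrimination uses the generator's endogenous truth as the reference
track; re-measuring the endogenous side at 8× coverage adds binomial noise
that attenuates ρ (to ≈ 0.88 for the sequence-determined model) without
changing which model is supported.

## Degenerate inputs and tie-breaks

Empty tracks, empty region sets and empty histograms are valid and return
empty results; single-class label vectors, classes smaller than the fold
count, fragments outside the genome, and zero-signal normalization are
errors. k-mer importance ties are broken lexicographically. All
random-number use flows through `numpy.random.default_rng(seed)`;
cross-validation folds are reproducible given the seed.
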