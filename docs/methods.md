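# Methods

## The analysis problem

After depletion of the H4K20 monomethyltransferase PR-Set7, Drosophila
cells accumulate replication-stress DNA damage marked by phosphorylated
H2A.v (γ-H2A.v, the fly analog of γ-H2AX). The question this pipeline
answers is *where* that damage lands: is it concentrated in discrete
genomic domains, and do those domains coincide with late-replicating
chromatin? The package implements the computational chain needed for
that question — binned coverage quantification, differential signal,
domain segmentation, and replication-timing integration — plus the two
supporting arms used for S-phase histone-mark dynamics (H4K20me1 in
early vs late S) and replication-origin activity (BrdU-seq under
hydroxyurea arrest).

## Coverage and normalization

Aligned reads (BED intervals) are counted into fixed-width genomic bins
by **fragment midpoint**: a read contributes to every bin containing
`floor((start+end)/2)`. Two binnings are used, following the analysis
conventions: 10 kb windows stepping every 1 kb (sliding) for the broad
histone-mark and BrdU profiles, and non-overlapping 5 kb bins for the
damage-mark differential. Counts are normalized to RPKM,

    RPKM_i = count_i / ((w/10^3) * (N/10^6)),

with `w` the bin width and `N` the number of aligned reads supplied (no
mappability modeling). Partial terminal bins are dropped so the RPKM
denominator is uniform; bins with zero reads keep value 0. Replicates
are combined by per-bin arithmetic mean, with pairwise Pearson
correlations recorded in the run manifest.

Midpoint assignment was chosen over 5′-end counting because it is
strand-symmetric and centers fragment enrichment; the difference only
shifts profiles by ~half a fragment length.

## Cross-sample scaling and the differential statistic

To compare samples whose global signal level genuinely differs (early-
vs late-S H4K20me1), per-million normalization is insufficient: it
erases global shifts. The two tracks are therefore put on a common scale
by matching their mean signal over the union `U` of each track's
top-ranked bins (default: top 5% by value, ties broken by genomic
order):

    scale_factor = mean(reference over U) / mean(sample over U).

This is a rank-based operationalization of "scaling on the top of
detected peaks"; it is reproducible and has a single parameter
(`top_frac`). The assumption is that the strongest-signal regions
(e.g. TSS peaks) are comparable between conditions while the background
may not be.

The damage differential is the pseudocounted log-ratio per 5 kb bin:

    d_i = log2(treatment RPKM_i + 1) - log2(control RPKM_i + 1).

Positive values mean more γ-H2A.v after depletion. The pseudocount of
exactly 1 RPKM keeps every value finite and damps ratios in
near-empty bins; no alternative stabilization is offered.

## Domain segmentation: two-state Gaussian HMM

The differential track is segmented with a two-state hidden Markov
model whose states ("negative" = 0, "positive" = 1) emit the per-bin
value from state-specific normal distributions N(μ_k, σ_k²).

* **Initialization** is a deterministic quantile split: values are
  sorted and halved at the median rank; each half seeds one state's mean
  and variance. Initial state probabilities are (0.5, 0.5) and
  transitions start sticky (0.9 self, 0.1 cross) because the target
  domains span many consecutive bins.
* **Training** is Baum–Welch EM run jointly over all chromosomes, each
  an independent observation sequence sharing one parameter set (a
  single genome-wide model). Forward/backward use per-position scaling;
  the log-likelihood is the sum of log scaling constants. Convergence:
  relative log-likelihood change below `tol` (default 1e-6) or
  `max_iter` (default 500); non-convergence is reported via a flag, not
  an exception. A variance floor of 1e-6 (signal units squared)
  prevents emission collapse onto single observations. After fitting,
  states are relabeled so the positive state has the larger mean.
* **Decoding** uses the Viterbi algorithm (log space; exact ties break
  toward the lower state index), because the maximum-probability path is
  inherently a set of discrete runs. Posterior decoding is available as
  the per-bin positive-state posteriors in the result object but is not
  used for domain boundaries.
* **Model selection.** A two-state Gaussian HMM fit to pure noise will
  happily split it into two near-identical states and call ~half the
  genome "positive". `segment` therefore compares the fitted model by
  BIC against a one-state Gaussian (2 vs 7 free parameters); when one
  state suffices the result is flagged degenerate and every bin is
  decoded negative, so a null experiment yields no positive domains.
  This guard can be disabled (`model_selection=False`).

Maximal same-state runs are merged into domains; positive runs shorter
than `min_bins` (default 1, i.e. no size filter) are reassigned to
negative before merging; chromosome boundaries always break domains.
Domains are written as BED6 with the state as name and
1000 × mean positive posterior as score.

## Replication-timing integration

* **Overlap accounting.** Damage domains vs late-replicating domains
  are intersected reciprocally; "overlap" means ≥ `min_bp` shared base
  pairs (default 1, the weakest defensible reading — no threshold is
  canonical here), and each domain counts once however many partners it
  touches.
* **Per-bin correlation.** The timing profile is resampled onto the
  differential track's exact 5 kb bins by length-weighted mean; bins
  without timing coverage are excluded pairwise; the sample Pearson
  correlation and the number of pairs are reported. Constant inputs
  raise rather than silently returning 0.
* **Metadomain profile.** Each late domain of length L is divided into
  50 inner meta-bins of width L/50 (fractional widths allowed), with 25
  flanking meta-bins of the same width on each side (100 positions
  total). A meta-bin's value is the length-weighted mean of overlapping
  track bins, which makes the profile independent of the track's step;
  meta-bins beyond chromosome ends contribute nothing. Per-position
  means are taken across domains; domains shorter than 50 bp are
  skipped with a warning.

## Annotation-anchored summaries

Aggregate profiles cut `[pos - flank, pos + flank)` around each anchor
(TSS or ORC/origin site) into an odd number of equal windows (default
±2 kb, 81 windows) and average the length-weighted window means across
anchors; minus-strand anchors are mirrored first so profiles read 5′→3′.
The genic/intergenic partition merges gene spans strand-agnostically,
classifies bins by midpoint, and compares the two value sets with a
two-sided Mann–Whitney U test (exact null enumeration when both classes
are small and tie-free, normal approximation otherwise). The rank-sum
test was chosen for robustness to the heavy right skew of RPKM values;
the original analysis does not name its test, so this is an
interpretation.

## Synthetic data: what it emulates and what it does not

The generator builds small multi-chromosome genomes (default: two 10 Mb
chromosomes) in which early/late replication-timing domains tile each
chromosome exactly — five late domains of 200–400 kb per chromosome,
uniformly placed with at least 1 bp of early sequence between them —
plus uniformly placed TSS (600, stranded) and origins (150). Timing is
encoded as a two-level track (+1 early, −1 late, higher = earlier; an
optional box smoothing is off by default) because the analysis uses only
the sign structure and the domain boundaries.

Reads are fixed-length fragments (200 bp) placed by midpoint, drawn from
a piecewise-constant intensity: background × 4 inside late domains for
the depleted damage condition, × 8 within ±500 bp of TSS for the
S-phase mark (the late-S sample's background is instead elevated ~3×
relative to its peaks, which is what the top-peak scaling is designed to
expose), and × 6 within ±1 kb of origins for BrdU. Default depth is
200 000 reads per replicate (~100 reads per 5 kb bin over the 20 Mb
genome, a typical ChIP coverage density), two replicates per condition.
Midpoint placement makes expected bin counts exactly proportional to the
configured intensity, so enrichment ratios are recoverable to
multinomial sampling error.

Not modeled: sequencing errors, mappability and GC bias, duplicate
reads, chromatin-input background structure, continuous replication
timing, and unclassified timing gaps (the analysis modules tolerate
gaps; the simulator does not produce them). Passing tests on this
material demonstrates the correctness of the computational chain under
its stated model — not robustness to the artifacts of real libraries.

## Numerical choices and degenerate inputs

Emission densities are max-shifted per position before the scaled
forward/backward recursions; Viterbi runs fully in log space with
log(0) = −inf permitted in transitions. EM updates derive variances from
posterior-weighted second moments and floor them at 1e-6. Pearson
correlations refuse constant inputs; scaling refuses a zero mean over
the top-bin union; the simulator refuses an all-zero intensity;
infeasible late-domain placement fails naming the chromosome. Ties in
top-bin ranking resolve to the earlier genomic bin; exact Viterbi ties
resolve to the negative state.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the segmentation-recovery
simulation on a 2 × 10 Mb genome at 5 kb bins (4 000 bins, 10 planted
domains, emission shift 0.5 at sd 0.25), the full read-level damage arm
at 4 replicate read sets of 200 000 reads, EM monotonicity on 100 random
initializations of a T = 2000 sequence, exhaustive-enumeration
equivalence on 500 instances with T ≤ 8, and BrdU replicate agreement at
1 000 000 reads per condition (where multinomial noise leaves replicate
correlation above 0.95). These sizes were chosen so the whole
verification runs on a laptop in a couple of minutes while keeping every
statistical margin wide.

## Reproducing the original full-scale result

The deposited data behind the original finding (GEO accession GSE73668,
dm3 assembly, external replication-timing domain calls) are not shipped
or downloaded here. Applying the pipeline to them — 5 kb bins for
γ-H2A.v control/depleted duplicates, log2 difference, HMM segmentation,
overlap against the 166 published late-replicating domains — is the
full-scale reproduction path. Expect the exact domain count to be
somewhat initialization-sensitive: the published analysis reports
neither fitted HMM parameters nor a minimum domain size, and the
quantile initialization used here is one defensible choice among
several.

## Known limitations

* "Detected peaks" for cross-sample scaling is rank-operationalized
  (top 5% bins); the original peak-calling recipe is not recoverable.
* The HMM is strictly two-state with univariate normal emissions; no
  autoregressive or multivariate extensions.
* Overlap accounting has no permutation-based enrichment test; the
  counts are descriptive.
* RPKM uses supplied read counts as the "per million" denominator;
  mappability masking is out of scope.
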