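# Methods

This note documents the models implemented in prophagekit, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that affect results.

## Coordinates and interval lengths

Internally every interval is 0-based half-open. Published prophage
coordinates are typically 1-based inclusive, and the literature is not
always consistent about whether a printed "size" means `end - start + 1`
or `end - start`; the same interval can be reported as 36,053 bp under one
convention and 36,052 bp under the other. `att.region_length` therefore
takes the convention as an explicit argument and never guesses; the IO
layer provides the `printed_to_internal` / `internal_to_printed` pair,
which are mutually inverse.

## Site-specific recombination model

The att model is a single reciprocal crossover with exact sequence
matching. The crossover parameter `k` counts the leading positions
contributed by the donor site (0-based half-open slicing), which makes the
observed attP of an impaired core reachable and the inference problem well
defined: the set of `k` consistent with an observed attP is provably
contiguous, and is reported as an interval (for the published impaired
26-bp site it is [12, 23]). Gene-conversion tracts and staggered-cut
overhangs are not modelled; the observed site sequences do not require
them. Core discovery (`find_att_core`) looks for the longest *exact*
direct repeat with one copy near each region boundary (window 1000 bp,
minimum 10 bp); a mismatch-tolerant mode is deliberately out of scope.
Absence of a repeat is an explicit no-core result, not an error.

Excision conserves sequence material exactly: the host keeps one attB copy
and the circle one attP copy, so `len(host) + len(circle) = len(genome)`.
Relative to the naive arithmetic of "remove the region, add a core" the
books balance by exactly one core copy, because attB and attP together
contain precisely the bases of attL and attR. Integration is the exact
inverse; the circle may be supplied in any rotation.

## Coverage enrichment

Supernatant sequencing depths are in arbitrary units, so every statistic
is a ratio and is invariant to scaling the track by a positive constant.

- **Background.** The default estimator is the median, robust when the
  enriched regions are unknown. For *quantification* the pipeline switches
  to the mean outside detected regions: depths are integer counts, and the
  median of a skewed counting distribution sits below its mean (for a
  negative binomial with mean 10 and size 10 the median is 9, a 10%
  understatement), which would bias every fold estimate. Detection is
  insensitive to this because the 3x threshold is far from the background
  either way; unbiased fold and ratio estimates are not.
- **Detection.** Smoothing is a centered running mean (default window
  501 bp, odd, edges truncated); runs above `min_fold x background`
  (default 3) closer than 1000 bp are merged and runs under 5000 bp
  dropped. Smoothing can shift raw segment edges by up to half a window;
  boundary refinement corrects this.
- **Boundary refinement.** Each boundary moves to the split point
  minimising the total squared error of a two-segment piecewise-constant
  fit within +-1000 bp. This step fit was chosen over generic change-point
  packages so the behaviour is fully specified and checkable against an
  exhaustive split scan; under the default noise model the refined
  boundary lands on the true junction to within tens of bases.
- **Between-phage ratio.** Uses excess enrichment `(fold - 1)` because
  phage DNA adds on top of the residual host background rather than
  replacing it; the plain fold ratio is selectable. A denominator with no
  excess enrichment yields NaN (undefined), not an exception.

## qPCR quantification

Standard curves are ordinary least squares of Ct on log10(concentration)
over all replicate points (not per-level means). Acceptance requires a
negative slope and r² > 0.95; rejection raises an error that carries the
fitted curve for inspection. Efficiency is `10^(-1/slope) - 1`; perfect
doubling corresponds to a slope of `-1/log10(2) = -3.3219` cycles per
decade. Technical replicates are inverted to the concentration scale
individually and averaged there (geometric averaging on the Ct scale),
matching standard practice. A missing Ct is the no-amplification sentinel
and quantifies as amount 0 — it is never imputed as a late Ct, which would
bias curve fits and ratios.

Normalisation to the reference gene is a division,
`N = amount_target / amount_reference`: its purpose is to cancel DNA input
mass, which only a ratio can do. SPI fractions and strain ratios are
ratios of normalised amounts times 100 and are therefore invariant to
rescaling all amounts by a common factor; values above 100% are reported
as-is. The phage:genome copy ratio converts amounts to copy numbers via
amplicon length, with the mass-per-bp constant cancelling.

In-silico PCR is exact-match on both strands and requires a unique product
of at most 5000 bp; ambiguity reports all candidate loci. Degenerate bases
and mismatch tolerance are out of scope.

## Competition model

The minimal model consistent with a continuous loss of lysogens: a strain
with per-generation lysis probability `s` multiplies by `2(1 - s)` per
generation. Each batch cycle runs `log2(dilution_factor)` generations
(stationary phase is assumed reached every cycle, as in a twice-daily
transfer of stationary cultures), so 12 cycles at 1:200 give 91.7 (~90)
generations. Growth-rate differences are supported — a strain at fraction
rho of the fastest rate completes rho of the generations per cycle — but
default to equal. The deterministic mode propagates exact fractions in log
space; the stochastic mode tracks integer counts with binomial lysis per
generation (whole generations, then one fractional step preserving the
expected multiplier) and a multinomial bottleneck at each transfer.

`estimate_selection` inverts the closed form
`ratio_final = ratio_initial * (1 - s)^(-n)` and is the exact inverse of
the deterministic simulator. The model attributes the entire fitness
difference to `s`; it cannot separate the SPI cost from other effects of
prophage carriage (e.g. a costly phage gene product), and salt or media
effects enter only as user-set rate scenarios.

## Genome comparison

Sketches store the `s` smallest 64-bit hashes of the distinct canonical
k-mers (k = 21, s = 1000 defaults). The hash is splitmix64 applied to the
2-bit-packed k-mer code — fixed, bijective on 64 bits (distinct k-mers can
never collide) and identical across platforms and runs. Jaccard is
estimated from the shared hashes among the bottom-s of the merged union,
and the distance is `-ln(2j/(1+j))/k`, capped at 1 when no hashes are
shared; when `s` exceeds both k-mer set sizes the estimate equals the
exact Jaccard. "Similarity" is defined as `100(1 - d)` — one reasonable
reading of a percent-similarity threshold on Mash output — with the
hit threshold (default 70%) inclusive and configurable.

ANI follows common fragment-based practice: consecutive 1020-bp fragments,
local alignment with match +1, mismatch -1, gap open -5, gap extend -2,
filters at 70% identity and 70% fragment coverage, mean identity x 100.
These scoring values are documented defaults of this implementation, not
literature constants. No fragment passing gives an undefined ANI, which
the species classifier treats as "different". Clustering is a plain
agglomerative implementation (average linkage default) with deterministic
tie-breaking by sorted label tuples; merge heights agree with scipy's
implementation, which serves as an independent cross-check in the tests.

## Synthetic data: what it emulates and what it does not

`generate_host_genome` builds an i.i.d. background at a requested GC
(default 0.45) and implants prophages whose att core is an exact direct
repeat at the region's first and last positions; the generator resamples a
single flanking base where the random context would accidentally extend
the repeat, so the implanted core *is* the longest flanking repeat by
construction. The default chromosome is 200 kb with a 20-kb and a 35-kb
prophage — a desk-scale stand-in for a multi-Mb replicon that keeps every
Monte-Carlo test in seconds.

Default condition parameters:

- **Induction scenario** (supernatant coverage): induced fraction 0.9 for
  both phages, burst sizes 10 and 70, background depth 10x, negative
  binomial with size 10 (sequencing is overdispersed relative to Poisson).
  This yields in-region means of 10x and 64x background and an excess
  enrichment ratio of exactly 7, the reported burst-size asymmetry between
  the two phages; absolute supernatant depths and burst sizes are not
  separately identifiable from published data, so only this ratio is
  calibrated.
- **Spontaneous induction** (qPCR): truth fractions 0.0013 and 0.0061,
  the measured exponential-phase SPI values of the two prophages; Ct noise
  0.15 cycles; standards as five 1:10 dilutions from 1 ng/ul (down to
  1e-5 ng/ul) in technical duplicates.
- **Competition:** per-generation induction rate 0.006 for the lysogen
  (consistent with the summed SPI fractions) and 0 for the prophage-free
  strain; 12 cycles at 1:200.

The generator does not simulate reads (no FASTQ), sequencing errors,
mapping artefacts, library-prep or GC biases, primer-efficiency
differences between assays, or qPCR inhibition. Passing tests therefore
demonstrate that the estimators are correct and unbiased under the assumed
noise model — overdispersed counting noise and log-normal qPCR noise — not
that real libraries are free of the biases excluded here.

## Problem sizes and tolerances in the test suite

Monte-Carlo tests use 20-300 replicates on the 200-kb chromosome (or
smaller constructed tracks), chosen so closed-form expectations are tested
at 3 standard errors of the replicate mean. Oracle-equivalence tests run
the exhaustive counterpart (dynamic-programming longest common substring,
split-point scan, full k-mer-set Jaccard, scipy agglomerative clustering)
on instances small enough to enumerate exactly. Exact identities (e.g. the
fully-induced-control SPI fraction of 100%, the deterministic
selection-estimator inverse) are asserted at or near machine precision.

## Known limitations

- Exact-repeat core discovery will truncate a biological core that
  contains an internal mismatch (it returns the longest exact repeat).
- The enrichment module assumes one background level per replicon; no
  cross-library normalisation or significance testing is provided.
- The competition model has no phage reinfection, lysis kinetics or
  mechanistic osmolarity dependence.
- ANI on short or highly diverged sequences is undefined rather than
  extrapolated; Mash distances saturate at 1 with no shared hashes.
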