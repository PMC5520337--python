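# Methods

## The measurement model

Each alternative splicing event (ASE) is a cassette exon assayed by RT-PCR
with a single primer pair, yielding an inclusion amplicon and an exclusion
amplicon whose size difference equals the alternative region length. The
instrument reports a fluorescence-versus-migration-time electropherogram per
well. The analysis reconstructs what instrument software does:

1. **Sizing.** Migration time is mapped to fragment size by piecewise-linear
   interpolation of log10(size) against time through the ladder points
   (exact at every knot, monotone in between; evaluation outside the ladder
   range extrapolates the terminal segment and warns). Real instruments use
   proprietary fits; log-linear mobility is the standard approximation for
   this size range.
2. **Peak detection and integration.** Local maxima of the
   baseline-corrected signal above `min_height`, separated by at least
   `min_separation` time units; apices closer than that merge into the
   taller peak. The baseline is a constant offset estimated as the trace's
   5th percentile — deliberately simpler than instrument software, adequate
   because synthetic and chip baselines are flat. Areas are trapezoid
   integrals between flanking valleys (the signal minima toward neighbouring
   peaks, or the trace ends).
3. **Molar correction.** Intercalating-dye fluorescence is proportional to
   DNA mass, so molar amount = area / called size. Isoform ratios must be
   molar; a 500 bp inclusion product otherwise looks brighter than a 450 bp
   exclusion product at equal copy number.
4. **Amplicon assignment.** Each of the event's two expected sizes is
   matched to the detected peak nearest in relative size error within
   `rel_tol` (default 0.10, motivated by typical expected-vs-found size
   discrepancies on microfluidic chips); ties on distance go to the larger
   area, and one peak can fill only one slot (a shared best candidate goes
   to the slot it matches better, the other slot falls back to its next
   best). If the two expected sizes are themselves within `rel_tol` of each
   other no called size could be attributed unambiguously, and the
   configuration is rejected up front. Peaks beyond the two expected
   amplicons — e.g. a slower-migrating third isoform such as the SMN
   transcript that skips the 54-nt exon 7 but retains the 109-nt exon 6B —
   are ignored and never enter ψ.

## ψ, Δψ and the change rule

ψ = 100 · inclusion / (inclusion + exclusion) on molar amounts, so ψ is the
inclusion-isoform percentage and Δψ > 0 means a shift toward inclusion. ψ is
"not evaluable" (missing) when both amplicons are absent or the molar total
falls below `min_total` (default 0.05 of the per-well total in simulator
units); a single missing slot counts as zero only when the other slot alone
clears the floor — one isoform can genuinely be absent, but two weak signals
are not trusted.

Δψ subtracts the mock-transfected control processed on the same batch day,
cancelling day-level handling effects. A missing same-day mock is a hard
pairing error naming the sample, not a silent skip.

An (event, cell line) pair is **changed** when both siRNA Δψ values are
present, share a nonzero sign, and both magnitudes reach the threshold
(default 8 percentage points, inclusive). The threshold is a screen-design
constant established from control-reaction Z-scores in prior array work; it
is configurable but not re-derived here. The both-must-pass reading is the
conservative interpretation of "a change of eight points or more" combined
with a same-direction requirement; a `lenient` mode (one siRNA ≥ threshold
plus concordant sign) is provided because the wording also admits that
reading. Pairs with a missing Δψ are "not evaluable": excluded from changed
counts but still counted in the screen denominator.

Report formatting keeps raw fractions and renders percentages either
nearest-integer (half-up) or truncated to one decimal — both conventions
appear in published screen reports (e.g. 5/28 printed as 18%, 11/14 as
78.5%), so both are implemented and the choice is explicit per call.

## The simulator

The synthetic-data module generates the study conditions the analysis
assumes, with planted ground truth:

* **Catalog.** Amplicon pairs in 150–700 bp; alternative region ≥ 20 bp and
  ≥ 12% of the exclusion size, so every pair stays discriminable at the
  default 10% matching tolerance (a screen designer would enforce the same
  constraint when choosing primers). About 4% of events re-use another
  event's gene (96 events from 92 genes), so gene-level and event-level
  universes differ, as they do downstream in enrichment. A fixed SMN-like
  fixture (exclusion 276 bp, inclusion 330 bp; 54-nt alternative exon) is
  provided for deterministic examples.
* **Truth.** A `prop_null` fraction (default 0.6) of events never respond.
  Each true target draws one direction — toward inclusion with probability
  0.68, matching the inclusion-biased direction fractions such screens
  report — which is shared by every responsive cell line, since a
  factor-dependent exon shifts the same way wherever it responds. Lines
  respond independently with probability 0.5 (at least one guaranteed), and
  magnitudes are |N(20, 6)| percentage points: centred well above the
  8-point threshold, with a tail of sub-threshold effects that should not be
  called. Effects are planted on the ψ scale and molar amounts back-computed
  from ψ, because the screen's statistic lives on ψ.
* **Knockdown scaling.** The default knockdown table is the five-cell-line,
  two-transfection protein-level KD grid this screen design reports (e.g.
  MCF-7 67%/60%, SKOV-3 80%/93% at 96 h). The realized per-siRNA shift is
  the planted effect × kd_fraction / max(kd_fraction in that line): the
  stronger knockdown expresses the full effect, the weaker a proportional
  fraction — a within-line normalization chosen because only a qualitative
  dose relationship (more knockdown, larger shift) is established.
  Knockdown ψ values are clamped to [0, 100].
* **Discordance.** A `discordant_rate` fraction (default 0.05) of true
  targets respond with opposite signs in the two siRNAs, emulating
  off-target responses; the concordance rule must veto them, and tests check
  it does.
* **Noise.** Per-isoform molar amounts carry lognormal noise with CV 0.05;
  at mid-ψ this makes the null Δψ sd ≈ 2.5 points, placing the 8-point
  threshold ≈ 3.2 sd into the tail — consistent with a threshold chosen to
  make single-assay false shifts rare. Sizing error is one multiplicative
  lognormal factor (sd 0.02) shared by both peaks of a well, reflecting that
  sizing calibration drifts per run rather than per fragment; it cancels in
  ψ and in the molar ratio. Trace synthesis adds N(0, 50) baseline noise,
  about 1/50–1/70 of a typical peak amplitude. Gaussian peaks have sd 0.02
  time units on a default grid of step 0.004 spanning the 135–725 bp window
  of a 50–1000 bp ladder laid out log-linearly (12·log10(size)).
* **Sample sheet.** One mock per (cell line, batch day); both siRNAs share
  the mock's day by default, mirroring the same-day control convention. A
  `split_sirna_days` option gives each siRNA its own day and mock, which
  makes the two Δψ noise terms independent — the configuration used for the
  null false-call analysis below.

What the simulator does **not** model: PCR amplification bias and
saturation, heteroscedastic or drifting instrument baselines, three-isoform
events and heteroduplex bands, primer failure, cross-contamination, or
correlated biological replicates. Passing tests therefore demonstrate that
the analysis logic is correct under the stated noise model, not that the
pipeline is robust to every failure mode of real chips.

## Clustering

Rows are events changed in at least one cell line; the entry for (event,
line) is the mean of the two per-siRNA Δψ values. Missing entries are
imputed as 0 before computing Euclidean distances — 0 is the neutral "no
shift" value on the Δψ scale — with pairwise-complete distances available
behind a flag. Linkages: UPGMA ("average") and classic Ward ("ward.D": the
Lance–Williams Ward update applied to unsquared input distances). The
ward.D variant is computed by passing square-rooted distances through
scipy's Ward recursion and squaring the resulting heights, which is
algebraically identical to the classic recursion; tests verify both linkages
against a naive full-matrix Lance–Williams oracle to 1e-8 on matrices up to
8 rows. Merge order is deterministic given the input row order (scipy's
nearest-neighbour-chain ordering resolves exact ties; with continuous Δψ
data ties have measure zero). With sign-coherent planted effects the k=2
cut separates inclusion-shifted from exclusion-shifted events exactly
(adjusted Rand index 1 at zero noise), the structure such screens observe as
two major heatmap clusters.

## Enrichment

One-sided hypergeometric over-representation: universe N = genes represented
in the assayed event pool (gene-level — a gene with two events counts once;
using the genome instead would inflate significance for any array-biased
category), K = pathway genes in the universe, n = changed genes,
p = P(X ≥ k), Benjamini–Hochberg adjusted across sets. Sets are intersected
with the universe first; sets disjoint from it are skipped and logged.
Published screens of this design have reported pathway p-values from
in-house annotation tools whose universe and statistic are not fully
specified; this implementation documents its canonical choice rather than
claiming to reproduce any particular printed p-value.

## Verification problem sizes

The test suite and acceptance script use: a 200-event × 5-cell-line
noise-free screen synthesized at the trace level (calls must equal planted
truth exactly); a 1000-event single-line null screen with default noise and
split siRNA days, whose false-call rate is compared against the analytic
ceiling — the product of the two per-siRNA tail probabilities
P(|Δψ| ≥ 8) under the delta-method noise model sd(Δψ) = 2·ψ(100−ψ)/100·CV,
valid because split days make the two Δψ independent and the same-sign
requirement only tightens it; an 80-event zero-noise screen for cluster
recovery; exact enumeration of hypergeometric tails up to N = 12; and
Lance–Williams oracles up to 8 rows. These sizes make the whole suite run in
well under a minute while keeping every binomial/tail bound meaningful.

## Known limitations

* The valley-to-valley integrator slightly mis-splits heavily overlapping
  peaks; with the default peak width (sd 0.02 time units) and the catalog's
  minimum log-size gap (≈ 0.15 time units ≈ 7.5 sd) the induced ψ error is
  < 0.05 points, but narrower gaps or wider peaks would need deconvolution.
* ψ values clamped near 0/100 by a planted effect can lose their weak
  amplicon below the detection floor; the missing-slot rule then reports
  exactly 0 or 100, which is faithful for calling but compresses extreme ψ.
* The enrichment module tests gene sets independently; no topology-aware or
  cluster-conditional statistics are attempted.
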