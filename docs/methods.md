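# Methods

## Production kinetics

**Growth-phase anchor (T0).** All production times are reported relative
to T0, the time a culture's OD600 departs from exponential growth.
Detection is a sliding-window rule on log(OD600): every window of
`window_points` consecutive observations (default 5) is fitted by least
squares; among windows with R² ≥ `r2_min` (default 0.99) the one with the
largest slope is the exponential reference; T0 is the earliest later time
at which observed OD falls relatively below the extrapolated exponential
by more than `deviation_frac` (default 0.05) for `run_length` consecutive
points (default 3). Pure-exponential input raises a no-transition error
rather than returning a guess.

A practical caveat, quantified in the test suite: with additive OD noise
of 0.01 the points below OD ≈ 0.1 are noise-dominated, so the reference
window necessarily sits in mid-growth where the logistic already bends.
Detected T0 is therefore biased late by ~1–2 h and jitters by up to ±3
sampling intervals across noise realizations (SD ≲ 1.5 h at 0.5 h
sampling). Downstream orderings of production start times are robust to
this (verified over multiple master seeds), but absolute T0-anchored
times carry that uncertainty.

**Production model.** A410 courses are fitted with the Zwietering
modified-Gompertz curve

y(t) = y0 + (K − y0)·exp(−exp( μmax·e·(λ − t)/(K − y0) + 1 )),

chosen so the parameters have their conventional kinetic meanings: y0
baseline absorbance, K plateau (maximum pigment), μmax the slope at the
inflection (maximum production rate, absorbance/h), λ lag (h). Fitting is
bounded nonlinear least squares (scipy `curve_fit`), initialized from the
data (y0 = min, K = max, μmax = steepest secant, λ = first rise above 10%
of range). Non-convergence is flagged on the result, never silent; a
dynamic range below 0.02 absorbance raises a degenerate-fit error since
no sigmoid is identifiable. On noise-free generated curves all four
parameters are recovered to 1e-3 relative (50-set recovery suite), with
the caveat that K is only identifiable when the curve approaches its
plateau inside the observation window.

**Derived quantities.** Production duration uses the inflection-tangent
construction — the interval between the tangent's crossings of y0 and K —
which for this parameterization is exactly (K − y0)/μmax (verified
against a numeric tangent construction to 1e-6). Production start is the
earliest grid time (default step 0.1 h) at which the predicted mutant
A410 exceeds the predicted reference (wild-type) A410 by more than δ,
sustained for two grid points; δ defaults to max(3 × reference residual
SD, 0.005 absorbance). Mutant replicate *i* is compared against the
reference fit of the same replicate index using the mutant replicate's
own T0. The reference strain itself has no start time (a curve never
deviates from itself) and is excluded from start-time statistics.

**Comparisons.** Pairwise two-sided Welch t-tests per parameter, computed
from the per-strain replicate means/SDs/n; Bonferroni adjustment
p_adj = min(1, p·m) over the m pairs in the table. Identical degenerate
groups (zero variance, zero difference) report p = 1, non-significant.

## Reporter gating

The gate threshold is the maximum fluorescence of the negative control,
and "positive" means strictly greater than that threshold — a convention
that guarantees the control gates to exactly 0% against itself and makes
percent-positive monotone non-increasing in the threshold. Events are a
single fluorescence channel on a linear scale; medians are computed
untransformed. Scatter-based debris exclusion and compensation are out of
scope.

## Differential footprinting

**Peak detection.** Interior points strictly greater than both neighbors;
plateaus resolve to their leftmost point; candidates are filtered by
height and by topographic prominence (scipy `peak_prominences`). The
detector is tested against an exhaustive neighbor-comparison oracle.

**Size calibration.** The N tallest ladder-channel peaks (N = number of
ladder fragments; default the 16 GeneScan-500 LIZ sizes, 35–500 bp) are
assigned the known sizes in scan order and joined by a monotone
piecewise-linear scan→bp map with linear extrapolation beyond the
terminal anchors. Local-Southern-style local fits are a possible
extension; on mildly nonlinear synthetic separations the piecewise-linear
map is accurate to < 0.5 bp. Fewer candidate peaks than ladder sizes, or
a non-monotone assignment, raise a calibration error that the pipeline
propagates with the detected peak count.

**Matching and differential.** Peaks from the two traces are paired by
greedy nearest-size matching within 0.5 bp (each peak used once).
Heights are sum-normalized **over the matched peaks only** — so ladder
carry-over or unmatched signal cannot distort the statistic — and the
differential is D_i = n_i(with) − n_i(without). Protection (less
cleavage under bound protein) is negative, hypersensitivity positive;
the profile sums to zero by construction.

**Region calling.** Because each trace is normalized to total 1, the
magnitude of any single D_i scales like 1/N for a probe yielding N
matched peaks (~253 here): an absolute threshold would need retuning for
every probe. The calling rule therefore thresholds the *relative*
differential N·D_i — the fold deviation from the mean normalized height
1/N: positions with N·D_i ≤ −τ (or ≥ +τ) in maximal runs of at least
`min_run` consecutive matched positions become protected (hypersensitive)
regions, with bounds at the run's first and last promoter positions.
Defaults τ = 0.02, min_run = 3. Profile values themselves stay on the
sum-to-1 scale; only the comparison against τ is rescaled.

One structural consequence of sum-normalization: attenuating peaks inside
a footprint necessarily raises every normalized height outside it, so
strong protection produces weak positive flanking values that can exceed
a small τ and be reported as hypersensitive runs. Protected-region calls
are unaffected; users interpreting hypersensitivity should either raise τ
or inspect the profile. Conversely, a footprint covering nearly the whole
analyzed probe would partially self-cancel under sum-normalization — the
method presumes the protected fraction of total signal is well below 1.

**Coordinates.** Promoter positions are zero-free (−1 is adjacent to +1;
TSS = +1). Fragment size s maps to the s-th probe position from the
labeled 5′ end (the small-fragment end); calibrated sizes are rounded to
the nearest integer before mapping. The TSS offset relative to the ATG is
a required configuration value — for the synthetic yvmC probe fixture
(−244..+9 relative to the ATG, 253 bp) it is set to −60 so the probe
spans −184..+69 relative to the TSS and covers all three preset windows.
Deletion probes record a coordinate gap: sizes map across the gap onto
original promoter coordinates, and the Δ59 construction (deleting
−14..+45) shortens the probe by exactly 59 positions.

## Synthetic data

The generators encode the study conditions and are bit-reproducible per
seed; a pipeline master seed derives per-call seeds by fixed offsets.

* **Growth**: logistic OD600 (shared across genotypes: OD0 = 0.005,
  ODmax = 2.0, r = 0.5/h, chosen so the 5%-deviation transition falls
  ~6 h after inoculation with sampling every 0.5 h over 30 h) plus
  additive Gaussian noise (default SD 0.01), floored at 1e-4.
* **Production**: modified-Gompertz A410 anchored on a background
  baseline of 0.01 (pigment-free cultures absorb weakly at 410 nm) plus
  Gaussian noise (default SD 0.005). The wild-type preset has K = 0.10
  with duration 18 h beginning at the transition. Mutant presets are
  constrained only by reported orderings, not printed values; they are
  fixed so that, noise-free, the triple mutant deviates from wild type at
  the first sampled timepoint (6.5 h before T0) and uniquely earliest,
  ΔpchR has the highest single-mutant plateau (0.50), the scoC abrB
  double the highest rate (0.06/h), and the triple the longest duration.
* **Flow**: two-component log10-normal mixture; negative component
  mean 1.0 (log10 a.u.), SD 0.25; positive component mean 3.0, SD 0.3;
  wild-type positive fraction 0.698. The components are well separated so
  gating error is dominated by binomial sampling, not overlap.
* **Traces**: one Gaussian peak (SD 2 scans) per probe position, spaced
  10 scans/bp from scan offset 100 (optionally quadratically curved);
  ladder peaks at the LIZ500 sizes in a second channel. Without-protein
  heights are 100 × a per-position log-normal jitter (default SD 0.05)
  shared between the traces — emulating sequence-dependent DNase cutting
  preference, which cancels in the differential but not in raw heights;
  with-protein heights are additionally multiplied by the window
  attenuation (preset 0.3) and by per-site hypersensitivity factors.
  Additive channel noise is independent per trace.

What the generators do **not** emulate: instrument artifacts (baseline
drift, saturation, dye pull-up), aggregate/debris events and multichannel
scatter in flow, DNase sequence specificity beyond stationary jitter,
partial-digestion kinetics, and plate-reader evaporation or drift.
Passing recovery tests therefore demonstrates correctness of the
analysis chain under its stated model, not robustness to every failure
mode of real instruments.

## Problem sizes and numerical choices

Desk scale throughout: 61 timepoints per curve, 3 replicates, 8 strains;
10^4–10^5 events per flow sample; 253-peak probes with 16-anchor ladders
(~5.7k scans per trace). The full synthetic study runs in seconds.
Ties in peak plateaus resolve leftmost; greedy matching breaks distance
ties by with-trace then without-trace order; Gompertz fits clip
initializations into bounds derived from the data range; comparisons with
zero variance in both groups are reported as p = 1 rather than NaN.
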