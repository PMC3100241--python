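# Methods

## Scope and model of the data

The package analyses spontaneous multi-unit activity of dissociated
neocortical cultures on planar MEAs (60 electrodes on an 8 × 8 grid,
200 µm pitch, sampled at 25 kHz) and already-scored dendritic-spine
records. From about 7 days in vitro (DIV) such cultures fire in a
characteristic regime: long stretches of near-silence punctuated by
network-wide bursts, sometimes arriving as doublets or triplets separated
by gaps only just longer than the intra-burst ISIs. All burst analysis is
per electrode; network-level burst merging is deliberately out of scope.

## Spike detection

- **Filter.** Zero-phase (forward–backward) Butterworth high-pass,
  order 2, cutoff 25 Hz. Zero-phase filtering preserves spike timing; the
  effective amplitude response is the squared Butterworth magnitude, which
  the tests verify against the closed form r⁴/(1+r⁴), r = f/f_c.
- **Noise floor.** σ = MAD/0.6745 per channel. A plain SD is inflated
  roughly two-fold by bursty spike content at realistic rates (tested);
  the MAD tracks the spike-free noise floor, which is what a "biological
  noise" threshold should scale. Threshold k·σ with k = 5, negative
  polarity by default (extracellular somatic spikes are dominantly
  negative-going).
- **Event formation.** Candidate spikes are local minima at or below −kσ;
  a greedy pass in time order suppresses candidates within the 1 ms dead
  time of the last accepted spike. Local-minimum candidates make the
  detected count provably monotone in the threshold (lowering k only adds
  candidates, and greedy earliest-first acceptance never loses events),
  a property the suite asserts. Timestamps sit at waveform extrema, which
  is stable across amplitudes.
- **Dead channels** (zero noise estimate) are reported as undetectable and
  excluded; other channels are unaffected.

## Burst and IBI analysis

A burst = maximal run of consecutive spikes with every ISI ≤ 20 ms,
kept if ≥ 20 spikes. The boundary is inclusive — an ISI of exactly 20 ms
joins a burst — and a small absolute slack (1 ps) keeps float round-off
from splitting runs built from exact-interval arithmetic. IBIs are
end-of-burst → start-of-next on the same electrode; this convention is the
one under which the short IBI peak lands just above the 20 ms ISI cutoff.
IBIs are pooled across electrodes before histogramming. Motif labelling
groups consecutive bursts with connecting IBIs ≤ 50 ms, greedily left to
right, closing each group at three bursts (so a run of four gaps ≤ 50 ms
counts as a triplet plus a leftover).

## Culture summaries and inference

The unit of analysis for burst statistics is the individual burst pooled
over electrodes: reported SEMs (sample SD/√n) at realistic burst counts
(thousands per 10-minute culture) are then of the sub-millisecond to
few-millisecond order seen in practice. An electrode is active if it has
at least one detected burst in the window. One-way fixed-effects ANOVA is
computed from sums of squares, with p from the F distribution; tests
cross-check it against an independent permutation oracle and
`scipy.stats.f_oneway`. p-values are raw — no multiple-testing
correction is applied, matching common practice for these figure-level
contrasts. Electrode/culture nesting is not modelled (no mixed effects).

Histogram defaults: burst duration 25 ms linear bins, spikes/burst bins
of 10, IBIs log₁₀ with 10 bins/decade. Mode finding on IBI histograms
uses coarser bins (5/decade) plus a 3-bin boxcar and a prominence floor of
25% of the tallest bin: when network-wide silences are shared across
electrodes, a single culture carries only tens of independent long gaps
replicated 60-fold, and finer histograms split the long-silence peak into
lumps. Only mode locations and bimodality are asserted, not peak widths.

## The synthetic generator

- **Silences.** Log-normal, parameterised by median (20 s at 7 DIV, 10 s
  at 14 DIV, slightly longer for EphA4 conditions) and log-SD. Strictly
  positive and right-skewed, matching observed IBI spreads.
- **Events.** Onsets are shared across electrodes with Gaussian jitter
  (default 10 ms), since bursts are grid-wide; each electrode realizes the
  event independently (own motif size, spike count, duration, ISIs), so
  pooled statistics have the full effective sample size. An independent
  per-electrode scheduling mode exists (`synchronize=False`).
- **Motifs.** An event is a doublet/triplet with configured probabilities;
  member gaps are uniform on (22, 50) ms — "just over" the 20 ms cutoff.
- **Spikes per burst.** Shifted negative binomial, 20 + NB(r = 1.5, mean
  set per condition): support respects the detector minimum and the right
  tail is exponential-like, as duration/spike-count histograms of such
  cultures are.
- **Durations.** Gamma. `calibrate_burst_duration_dist` solves the shape
  (scale = mean/shape) so the CDF at a cutoff matches a target fraction,
  by bracketed root finding over shape ∈ [0.01, 10⁴] with residuals
  < 10⁻⁶. Shapes below 0.01 put essentially all mass at zero and are not
  burst-like, so the search domain is bounded; when the quantile pair
  admits two roots the caller chooses the more symmetric (larger shape) or
  more skewed root. Control 7 DIV uses mean 182.5 ms with 65% ≤ 200 ms
  (shape ≈ 8.5); EphA4 7 DIV mean 211.2 ms with 53% ≤ 200 ms (shape ≈ 3.6,
  right-skewed; the source report bounds this fraction only as "under
  55%"). No quantile is published for 14 DIV, so those shapes are
  calibration choices: 20 (near-normal control) and 4 (right-skewed
  EphA4).
- **Spike placement.** n−1 ISIs = optional refractory floor plus
  truncated-exponential excesses, rescaled to the drawn duration and
  redrawn if any rescaled ISI would exceed 20 ms (uniform spacing as a
  deterministic fallback after 200 rejections). A (count, duration) pair
  is redrawn until (n−1)·floor < duration ≤ (n−1)·20 ms; with the fixture
  distributions the rejection probability is ≈1%, so means are not
  measurably biased. Generated bursts therefore satisfy the detector's
  definition exactly, and bursts are separated by > 20 ms by construction
  — the recovery test (detected bursts ≡ ground truth) is exact, not
  approximate.
- **Refractory floor.** `min_isi_ms` defaults to 0 for the statistical
  fixtures. The voltage-level detection benchmark sets it to 2 ms: with a
  1 ms detector dead time, ground truth containing sub-millisecond ISIs is
  unresolvable in principle, and a recall benchmark against it would
  measure the generator, not the detector.
- **Voltage.** Gaussian noise per channel plus a biphasic template
  (Gaussian trough, σ = 0.1 ms, small positive afterwave, ~1.6 ms) at each
  spike time; overlaps sum. Default benchmark SNR is 6 (template peak
  6 × noise SD), just above the 5σ threshold so detection is exercised
  non-trivially.
- **Spines.** Per-cell spine counts Poisson(13) truncated ≥ 1; classes
  i.i.d. categorical over 8 shapes; PSD-95 flags Bernoulli. Fixture
  probabilities: classes 6/7 at the published per-class means (0.16/0.08
  control, 0.22/0.12 EphA4), class 8 the remainder of the published mature
  totals (0.30/0.44); the immature split over classes 1–5 and the PSD-95
  probabilities (0.55/0.65, published only as "a slight increase") are
  calibration choices.

**What the generator does not emulate:** biophysics (no membrane or
synapse dynamics), electrode cross-talk, slow non-stationarity within a
recording, culture-to-culture variability beyond the seed, spike-waveform
diversity, and culture decline after 14 DIV. Passing recovery tests shows
the pipeline is correct and well-calibrated under these statistical
assumptions — not that real recordings satisfy them.

## Problem sizes and numerics

Full-scale fixture runs (600 s × 60 electrodes, spike level) complete in
under a second each, so the parameter-recovery checks use the full
published geometry; voltage-level checks use 60 s × 8 channels at 25 kHz,
which preserves the per-channel detection problem exactly while keeping
the synthesized matrix small. Times are carried internally in seconds as
float64 and converted to milliseconds only at reporting boundaries.
Recovery tolerances are 2% or 3 standard errors, whichever is larger;
exact contracts (determinism, detector equivalence with a brute-force
scanner, calibration residuals < 10⁻⁶) are asserted exactly.

## Known limitations

- Per-electrode burst definition only; network-burst detection and
  alternative detectors (surprise-based, log-ISI valley) are non-goals.
- The ANOVA ignores nesting of bursts within electrodes and cultures;
  with thousands of pooled bursts its p-values are anti-conservative for
  culture-level claims.
- Spine shape classification itself (image analysis, inter-rater
  reconciliation) is upstream of this package; records arrive already
  scored.
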