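# Methods

This note documents the models, parameter choices and numerical decisions
behind `roifinder`, and what the synthetic validation does and does not show
about clinical data.

## Signal model and preprocessing

Recordings are per-electrode unipolar voltages (mV, reference at Wilson's
central terminal in the clinical setting), nominally 30 s at 1 kHz. The
acquisition rate of clinical systems is not standardized; 1 kHz is the
package default and anything ≥ 500 Hz is accepted. Conditioning is a
band-pass at 2–240 Hz with a 60 Hz mains notch and nothing else. Only the
corner frequencies are clinically specified, so the filter family is our
choice: a 4th-order Butterworth band-pass plus a second-order notch
(quality 30, configurable to 50 Hz mains), applied forward–backward
(`sosfiltfilt`). Zero-phase application matters: any group delay would bias
every local activation time by the same amount *per frequency content*, i.e.
differently for sharp and blunt deflections, corrupting the "earlier than
its neighbors" comparison.

## Activation annotation

The clinical reference annotator ("wavelet analysis") is proprietary; we use
the standard unipolar convention instead and isolate it behind
`annotate.detect_activations` so another annotator can be swapped in. An
activation is a local maximum of −dV/dt on a Gaussian-smoothed trace
(σ = 3 ms) above an adaptive threshold
`max(0.01 mV/ms, 4 × σ̂_slope)`, where `σ̂_slope` is the robust (MAD)
noise level of the smoothed derivative of that channel; a 60 ms blanking
period enforces one event per deflection. The adaptive part makes detection
amplitude-scale invariant and robust across channels with different local
signal strength; the absolute floor keeps near-flat channels silent.

Morphology: R is the maximal positive deflection in the 20 ms before the
LAT, S the maximal negative deflection in the ±20 ms window. Both are
reduced by a per-channel noise floor (2 × MAD-σ of the smoothed trace,
floored at zero) before forming `r_fraction = R/(R+S)`; an event is QS when
`r_fraction ≤ 0.10`. The subtraction operationalizes "QS = no *significant*
initial positivity": without it, noise excursions of a few tenths of the
deflection amplitude would relabel genuinely monophasic beats. Events with
no energy in either lobe are non-QS with a degenerate flag.

Channel gating mirrors the clinical behavior (unannotatable electrodes are
ignored, not repaired). Defaults — ≥ 15 beats per 30 s (scaled to the actual
duration), SNR ≥ 3 (median event amplitude over MAD-σ), peak-to-peak
≥ 0.05 mV, dominant frequency of the rectified smoothed trace within
3–12 Hz — are package assumptions; the clinical thresholds are unpublished.
Failing channels keep their quality report but contribute no timings.

## The ROI detector

For each gated event at time *t* on electrode *e*, each quality-passed
neighbor contributes its earliest event in `(t − 20 ms, t + 50 ms]`. The
backward window exists so a neighbor that fired *just before* the candidate
is bound with a negative offset and vetoes "leading"; leading is strict
(tolerance 0 ms), so two adjacent electrodes can never both claim a source.
Candidates with fewer than 3 bound neighbors are *ineligible* (distinct from
*not focal*): poorly covered electrodes must not become false sources.

"Neighbors" defaults to the catheter's structural adjacency (along-spline
plus same-rank on adjacent splines for the basket; along-spline for the
five-spline star); a metric ball (6–10 mm radius suggested) is available for
aggregated sequential maps. Neither is claimed canonical — the clinical
definition is unpublished.

Runs: successive focal events on one electrode extend a run when separated
by at most 1.5 × that electrode's median inter-event interval; a non-focal
event or an over-gap closes it. Runs of length ≥ `min_consecutive`
(default 2) are counted; an electrode with any counted run is a site, and
sites within 10 mm merge into the one with most occurrences — the same
10 mm used by the site-correlation rule, for internal consistency. A
radial-spread check is available per cycle: all first-ring neighbors after
the source and the second ring later on average than the first.

Sequential aggregation pools per-recording sites by greedy centroid
clustering at the same 10 mm radius, keeping pooled run lists.

## Driver metrics and statistics

Consistency = maps showing the driver / maps covering its site (uncovered
maps leave the denominator only). Temporal stability = mean counted run
length; recurrence rate = mean occurrences per 30-s map where present.
Exact binomial CIs are Clopper–Pearson via beta quantiles (Wilson optional);
the Fisher test sums hypergeometric probabilities of margin-fixed tables no
more probable than the observed one. Both are cross-checked in the test
suite against independent oracles (CDF bisection; full enumeration).
Specificity needs true negatives, which the clinical study never defines;
we require explicit control sites at least twice the correlation threshold
from every reference and document this as a divergence. Percentages print
rounded half-up, matching the clinical presentation convention. Ancillary
rules: AF cycle length = mean of the first 30 annotated intervals; ablation
response = termination, else cycle-length slowing when post − pre ≥ 30 ms;
low-voltage zone = bipolar voltage strictly < 0.5 mV.

## The simulator

Propagation is kinematic: arrival time = onset + geodesic surface distance /
conduction velocity (default 0.9 mm/ms, atrial range). The chamber is a
closed convex ellipsoid; the default is its spherical special case with
radius 25 mm, matching the basket radius so electrodes sit on the wall —
a deployed basket conforms to the chamber, and the spherical case keeps the
morphology model well-posed at every electrode. General ellipsoids are
supported (geodesics via a finely sampled projected polyline, exact on
spheres). Reentry is modeled as a rotating phase around a circuit (radius
5–25 mm, period ≥ 100 ms) plus a radial delay outside the core; planar
wavefronts as a swept projection.

Rendering: each arrival stamps a two-lobe Gaussian template (width 24 ms)
whose steepest negative slope falls exactly at the arrival time regardless
of morphology, so annotation accuracy is morphology-independent by
construction. Morphology is geometric: QS (no positive lobe) within 5 mm of
the originating point, RS (target r-fraction 0.45) beyond; planar and
reentrant wavefronts have no origin and render RS everywhere — which is the
physical reason the detector rejects them. Amplitude depends only mildly on
source distance (floor 0.6 of the 1 mV template) because unipolar amplitude
is dominated by the wavefront passing locally beneath each electrode. White
noise (RMS = template amplitude / SNR, default SNR 10) and a 0.1 mV 60 Hz
mains component are added *before* filtering to exercise the notch.

The AF scenario interleaves a focal driver with disorganized background:
occurrences per 30 s are Poisson (mean 11), run lengths 2 + Poisson(1)
(mean 3), runs placed without overlap via Dirichlet gaps; background planar
wavelets arrive at Gaussian-jittered intervals (mean 145 ms — the left
atrial appendage cycle-length scale in persistent AF) from random
directions, suppressed during driver runs (plus a 120 ms travel margin)
because a firing driver entrains its surroundings. Focal sources are placed
2.5 mm tangentially from a catheter electrode: detection is only defined at
electrode resolution, so sources sit where the array has coverage — the
situation the clinical validation arm (all focal tachycardias detected)
describes. All randomness flows from one `numpy` Generator per recording;
identical seeds give byte-identical bundles.

**What passing tests do not show.** Real AF background is richer than
jittered planar wavelets (meander, wavebreak, collision); real baskets
deform and lose contact; far-field ventricular activity is absent (the
clinical chain has no QRS subtraction either); and the geometric QS rule is
an idealization of true source electrophysiology. The synthetic results
demonstrate that the *algorithm* recovers the defined signature under its
stated model, not that the signature is always present in patients.

## Problem sizes and numerical choices

The validation suite uses 30-s recordings for the simulation analogs of the
clinical arms (15 focal maps, 35 reentrant maps, 20 AF maps) and 10–15 s
recordings for property sweeps (noise-degradation grid, bulk focal
recovery), sizes chosen to keep the full suite around two minutes while
leaving every statistical margin wide. Ties in "leading" reject the
candidate (conservative). Degenerate inputs: flat traces annotate to empty
lists; gating never raises; empty reference lists flag sensitivity as
undefined rather than guessing a denominator; recordings shorter than two
cycles yield no sites. Site merging and aggregation are order-stable
(sorted by occurrence count, then id), so exports are byte-deterministic.
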