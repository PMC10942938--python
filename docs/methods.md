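# Methods

This note documents the models, parameter choices, and numerical conventions
behind `vesselsound`, and what the synthetic-data validation does and does
not demonstrate about real recordings.

## Spectral processing

All spectral quantities are carried as linear mean-square pressure
(µPa²/Hz or µPa²) and converted to decibels only at reporting boundaries;
medians and means are therefore taken in the physically meaningful domain.
The dB→linear→dB round trip is exact to better than 1e-9 dB.

**PSD from audio.** Each non-overlapping 1-s segment is Hann-windowed and
transformed with the segment length equal to the sample rate, giving exactly
1 Hz bins.  The one-sided periodogram is normalized by the window power
(`fs · Σw²`), which makes the per-second sum of PSD bins equal the segment's
window-weighted mean-square pressure — Parseval-consistent to within ~1% for
broadband or many-cycle tonal content.  This is the simplest construction
that yields the 1 Hz / 1 s product; no overlap or multitapering is used.
Exactly-zero bins (digital silence) are floored at 1e-10 µPa²/Hz so dB
values stay finite; the floor is far below any oceanic level of interest.
A single broadband calibration offset per deployment is supported;
frequency-dependent calibration curves are out of scope.

**Decidecade bands.** Nominal centres map to the nearest base-10 decidecade
band: exact centre `10^(n/10)` Hz, edges `centre · 10^(∓1/20)`.  The nominal
125 Hz band therefore spans 112.2–141.3 Hz.  A 1 Hz bin belongs to a band
iff its centre satisfies `lower ≤ f < upper` (half-open), so adjacent bands
never share a bin.  Bands below nominal 125 Hz can be excluded with a guard
flag, since flow noise and mooring strum commonly contaminate them.

**Summaries and coverage.** Minute and hourly levels are
`10·log10(median of linear per-second values)` on UTC wall-clock bins.
Hourly bins require ≥ 1800 s of data (at least half the hour); the
minute-level requirement is not standardized anywhere we know of, so the
package mirrors the 50% rule with ≥ 30 s per minute.  Bins failing coverage
are reported as NaN with their actual coverage seconds, never dropped
silently.

## Ship detector

The detector screens an LTSA (5 s × 48 Hz cells; each cell the linear mean
of its PSD block, trailing partial blocks dropped) using three
band-averaged series.  Defaults: low 40–200 Hz, medium 200–1000 Hz, high
1000–5000 Hz.  These are generic coastal choices; deployments differ, and
every detector parameter is a config field because site-specific tuning by
an analyst is part of the intended workflow.

**Adaptive threshold.** Per analysis window (default 7200 s) a background
level is estimated from the distribution of the window's dB values and the
threshold is background + offset.  Two statistics are available:

* *percentile* (default, 2nd percentile): loud passages elevate the band
  level slightly for a long time before and after the event proper (the
  approach/departure "haze"), which biases central statistics upward.  A low
  percentile anchors near the window's quietest portion while remaining
  robust to individual noise excursions (with ~1400 cells per window the
  2nd percentile averages over ~30 values).
* *mode*: the modal bin of a fixed-width histogram (1 dB bins on an absolute
  grid, ties toward the lowest bin), refined by the median of values within
  ±1.5 bins of the modal centre to undo bin quantization.  Kept as an option;
  it is the more traditional choice but measurably haze-biased in
  traffic-heavy records.

The default offset is 4.8 dB = `10·log10(1 + 10^(3/10))`: a source exactly
3 dB above background raises the *total* measured level by 4.8 dB, so event
boundaries delimited at this offset correspond to a 3 dB
source-over-background margin.

**Criteria.** Candidates are maximal runs of low-band exceedance, after
merging runs separated by < 60 s (one passage should not fragment on brief
fades).  A candidate is labelled `vessel` iff:

* *duration shape*: the above-threshold duration in the high band is shorter
  than in the medium band, **or** the low- and medium-band durations both
  exceed a minimum time (default 30 s) with the medium shorter than the low.
  Click trains (long high-band exceedance) and broadband weather steps
  (equal durations in all bands) fail this test;
* *background ratio*: the event's mean low-band mean-square exceeds
  `(1 + weather_percentage)` times the window's background mean-square
  (default 0.5, i.e. +1.76 dB), where the background is the mean over the
  window's below-threshold cells (a bin-level mask, independent of how
  candidates are grouped).

Failed candidates are retained with label `non-vessel` so an analyst
relabelling pass (which records the provenance chain and sets a verified
flag) can review them.

**Block processing.** Records are processed in blocks (default 6 h) with
buffers (default 30 min).  Threshold windows are anchored to the global
record start and each block's PSD slice is extended to window-aligned
boundaries covering the buffered range, so per-window statistics equal those
of a single pass; candidate runs intersecting the block core are kept and
boundary duplicates removed by exact interval.  Output is identical to an
unblocked run provided the buffer is at least the longest merged event
(config invariant; the oracle-equivalence test exercises boundary-spanning
and duplicated events).

## Indicator metrics

* An hour (or minute) counts as a *vessel* bin if any vessel-labelled event
  overlaps it, however briefly (any-overlap rule).
* Hourly exceedance uses the **median** of hourly dB levels by default, with
  an optional mean: the median is the operational definition used for
  categorization, being robust to the skewed hourly distributions produced
  by intermittent sources.  Both exceedance metrics are invariant under
  adding a constant to all levels.
* The minute-exceedance baseline is a vessel-free window with the same
  number of minute bins as the event, chosen by exhaustive scan over the
  minute grid: smallest time gap to the event wins, the earlier window
  breaks ties.  The baseline level is the linear power mean of the window
  converted to dB (an "average sound level" is an energy average).  The
  baseline never overlaps any vessel event; if no qualifying window exists
  (event spans the record) the metric is undefined and raised as such.
* Hour-of-day profiles average, over the days of a month, the count of
  minute bins of each clock hour overlapped by vessel events; SE is the
  sample standard deviation across days over √(days).  Days with < 50%
  minute coverage are excluded when a minute series is supplied.

## AIS summarization

Great-circle distances use the haversine formula with the WGS84 mean radius
6371.0088 km — at 10 km scales the sphere approximation errs well under 1%.
Tracks are interpolated linearly in latitude/longitude between reports
≤ 6 h apart (no interpolation across longer gaps; duplicated timestamps are
skipped); each segment is sampled every 30 s and buffer crossings are
refined by bisection to 1 s, which catches entry-and-exit within a single
long segment.  Length classes: small < 20 m, medium 20–100 m inclusive on
both boundaries, large > 100 m, unknown when length is missing.  Daily
summaries count unique vessels per class (a vessel entering twice counts
once); operational hours sum in-buffer durations across vessels, so two
vessels inside for an hour contribute two hours.

## Categorization and comparison

Quadrant thresholds are deliberately caller-supplied — appropriate values
depend on management objectives, and the framework is threshold-agnostic.
Values exactly at a threshold classify as "high" (deterministic tie rule).
ECDF quantiles are lower empirical quantiles (smallest sample value whose
cumulative fraction reaches q, no interpolation), so "75% of the time at or
below x" reads literally off the curve.  Change classification thresholds
each delta at a caller tolerance; both-null → no change (black), and the
(increase, increase) pattern gets an explicit `increase-both` label rather
than being forced into an existing class.  When exactly one axis is within
tolerance its raw sign breaks the tie (zero counts as a reduction) so the
mapping is total.

## Synthetic soundscape generator

The generator is the package's validation instrument; its defaults describe
a moderate coastal site.

* **Ambient**: spectral density 72 dB re 1 µPa²/Hz at 100 Hz with a
  −12 dB/decade slope (typical of wind-driven coastal spectra between
  40 Hz and a few kHz), plus a piecewise-constant broadband wind schedule
  in dB and a diel chorus (additive dB in a 60–300 Hz band during configured
  UTC hours) emulating fish choruses.
* **Passages**: straight-line constant-speed transits.  Received spectral
  density = source spectrum at 1 m − `20·log10 r(t)` − `α·r(t)` with
  `r(t) = √(CPA² + (v(t − t_CPA))²)`.  The effective attenuation
  α = 0.5 dB/km represents the bottom-interaction and scattering losses of
  coastal waveguides that spherical spreading alone understates; without it
  a loud passage measurably elevates the background for hours around its
  transit and no window contains a clean background at all.  True
  propagation modelling is explicitly out of scope.
* **Source spectra**: flat to a knee frequency, rolling off above it; the
  knee/roll-off default by length class — large (150 Hz, 22 dB/decade),
  medium (175 Hz, 20), small (200 Hz, 18) — so that band signal-to-ambient
  decreases with frequency for every class while small craft retain
  relatively more high-frequency energy.  A helper derives the source level
  required for a requested low-band signal-to-background margin at CPA.
* **Noise**: optional per-cell log-normal variability (default σ = 2 dB),
  a stand-in for the chi-squared fluctuation of 1 s spectral estimates.
  Averaging in the LTSA reduces it to ~0.1 dB per band cell, comparable to
  real 5 s × 48 Hz products.
* **Ground truth**: a passage's true event is the span where its received
  low-band (40–200 Hz) level exceeds the vessel-free background by a margin
  (default 3 dB, matching the detector's offset convention).  Noiseless
  minute/hourly 125 Hz band series and analytic dominance/exceedance are
  computed through the same metric code paths used on detections.
  Identical scenario configurations (including seed) produce bit-identical
  PSD, truth, and AIS tables.

**Recovery battery.**  Validation runs 20 seeded scenarios of 3 h at a
6 kHz frequency span (the detector's bands end at 5 kHz; the reduced span
keeps each scenario's PSD near 350 MB and the whole battery under a minute),
each with 1–6 passages slotted across the record — CPA log-uniform
0.5–8 km, low-band CPA margins 12–25 dB, speeds 6–13 m/s, mixed sizes, 70%
AIS-equipped.  A passage whose predicted event would exceed 30% of its slot
(or 15 min) has its CPA, then margin, shrunk so events stay separable and
vessel-free reference windows exist.  Against analytic truth the pipeline
achieves 100% passage recall, zero false vessel events (battery and
vessel-free scenes), dominance within ±2 percentage points per scenario,
and scenario-level minute exceedance (median over events) within ±1 dB
(typically ±0.5).

**What this does and does not show.**  The generator emulates the
*structure* of vessel-dominated coastal soundscapes — CPA level profiles,
wind/chorus confounds, size-dependent spectra, AIS-consistent geometry —
but real recordings add propagation multipath and convergence, correlated
(non-lognormal) noise, biological transients, overlapping passages of
unmodelled source types, mooring self-noise, and calibration drift.
Passing recovery therefore demonstrates internal consistency of
detector + metrics under known physics, not field performance; on real data
the detector's settings are expected to need per-site tuning and analyst
verification, which the relabelling hook supports.  The recovery battery
deliberately excludes chorus/wind steps to isolate passage recovery;
detector behaviour under those confounds is exercised separately in the
unit tests (chorus and weather candidates are rejected by the duration and
background-ratio criteria).

## Other numerical conventions

* Histogram bins (mode statistic) lie on an absolute dB grid, ties toward
  the lowest bin, so thresholds are independent of block slicing.
* Event endpoints lie on the 5 s LTSA grid and serialize at second
  precision; event CSV round trips are exact.
* Monthly station comparisons require > 95% of the month's days to have
  valid hourly levels; the rule is surfaced as an eligibility flag rather
  than a hard failure so partial months remain inspectable.
* All timestamps are ISO-8601 UTC; levels are dB re 1 µPa² (band) or
  dB re 1 µPa²/Hz (PSD), stated in column headers.

## Known limitations

* No hybrid millidecade products, no bands above nominal 20 kHz, no
  frequency-dependent calibration.
* The detector estimates one background per band per window; records whose
  background changes faster than the window (storm onsets) will mis-delimit
  events near the transition.
* Minute-exceedance baselines prefer temporal proximity over spectral
  similarity; in strongly diel soundscapes the nearest window may still be
  a different regime.
* AIS interpolation is linear in lat/lon, adequate at 10 km buffers and
  ≤ 6 h gaps but not for transoceanic segments.
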