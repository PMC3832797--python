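# Methods

This note documents the models, measurement definitions, default parameters
and numerical choices behind `vsdikit`, in the spirit of a methods section:
everything here is implemented and exercised by the test suite; no number is
claimed that the code does not compute.

## The circuit being quantified

The piriform cortex (PCtx) has three layers: layer II holds the excitatory
pyramidal cells, layer III is almost entirely inhibitory interneurons that
innervate layer II, and beneath the cortex lies the dorsal endopiriform
nucleus (DEn), whose inhibitory cells project into layer III.  Stimulating
the lateral olfactory tract (LOT) with a 1 s pulse train produces three
stereotyped responses in VSDI recordings: a depolarization of layer II, a
depolarization of the DEn roughly 50 ms later (Lag 1), and a
*hyperpolarization* of layer III roughly 200 ms after the layer II onset
(Lag 2) — the disinhibition.  The circuit engages selectively at β–γ train
frequencies: the layer II excitation is half-maximal near 40 Hz and the
layer III inhibition near 20 Hz.  Kindling (an experimental-epilepsy model)
increases the gain of all three responses; cutting the slice just below
layer II silences the DEn and converts the layer III response into a
feed-forward excitation.

## Preprocessing

**ΔF/F.** Per pixel, `F₀` is the mean count over the pre-stimulus baseline
window (default: the full 2 s baseline epoch; the estimator window is
configurable because the background definition is an analysis choice, not a
physical constant).  `value(t) = 100·(F(t) − F₀)/F₀`, multiplied by −1 by
default so that depolarization — which dims the dye — reads positive.
Pixels with `F₀ = 0` are flagged invalid and carried as NaN through every
later stage; they are excluded from averages, never imputed as zeros.  A
movie with more than 5 % invalid pixels (configurable) is rejected as
unusable.

**Bleach correction.** The mean ΔF/F trace of a user-designated,
stimulus-unresponsive reference region is subtracted frame-wise from every
pixel.  This removes any frame-wide common-mode signal (bleaching, lamp
drift) *exactly* — the corrected reference trace is identically zero — at
the cost of adding the reference region's noise everywhere.  Direct
subtraction was chosen over fitting an exponential because it is assumption
free; the reference region must be chosen by the user (it reflects anatomy,
not statistics).  Correcting twice is refused.

**Binning.** Non-overlapping 3×3 pixel blocks are averaged per frame;
trailing rows/columns that do not fill a block are dropped (the simplest
deterministic edge policy).  The recorded pixel size scales with the
factor.  Region masks defined on the raw grid are mapped to the binned grid
conservatively: a binned pixel belongs to a region only if *all* its source
pixels do, so binned traces never mix regions.

**Voltage calibration.** Perfusing high-K⁺ solution depolarizes the tissue
from rest (≈ −70 mV) to ≈ 0 mV and dims the dye by ≈ 6.3 %, giving
0.9 % ΔF/F per 10 mV.  `calibrate(total_percent, span_mV)` stores this
ratio and `dff_to_mV` applies it; the conversion is linear and exactly
invertible.

## Response measurements

All measurements operate on region or stripe traces (unweighted means over
pixels; a stripe is an ordered chain of exactly 10 pixels, 250 µm at
25 µm/pixel, for quantifying responses along a line before and after a
cut).  An undefined measurement is reported as `None`, never silently as
zero.

**Magnitude and polarity.** The response scalar is the signed extremum of
largest absolute deviation from the pre-stimulus baseline mean within the
response window (stimulus onset → +10 s by default; earliest frame wins
ties).  Peak was chosen over an integral because response traces in this
preparation are characterized by their amplitude.  Polarity is the sign of
the extremum, or `none` when it does not exceed `k` = 3 baseline standard
deviations (configurable).  A floor of 1e-9 % ΔF/F guards the degenerate
noise-free case where the baseline SD itself is zero up to float rounding.

**Onset.** First time at or after stimulus onset at which the absolute
deviation reaches 20 % of the peak deviation and stays there for 2
consecutive frames (both configurable).  The relative-threshold reading of
"20 % above baseline" was chosen over an absolute one because it makes the
onset invariant to amplitude rescaling (dye loading); the persistence
requirement resists single-frame noise.  Onsets are reported in ms relative
to stimulus onset and are quantized to the frame interval.

**Lags.** `Lag 1 = onset(DEn) − onset(layerII)`,
`Lag 2 = onset(layerIII) − onset(layerII)`.  Because all regions share the
same response kinetics, the systematic delay between a response's true
start and its 20 %-criterion crossing cancels in the differences; lag
estimates are therefore unbiased up to frame quantization.

**Normalization.** Magnitudes are divided by the absolute magnitude of the
same slice and region's 20 Hz response; the reference entry maps to exactly
±1.  This removes slice-to-slice dye-loading differences and is the unit in
which all input/output relations are expressed ("fold of the 20 Hz
response").

**Rate of rise.** Least-squares slope through the samples between the 20 %
and 80 % crossings of the peak deviation, in % ΔF/F per second, signed like
the response.  A step sampled too coarsely (fewer than two samples between
crossings) is undefined.

## Input/output curves

Normalized magnitudes versus train frequency are fitted with a Hill-type
sigmoid on linear frequency,

    R(f) = base + (top − base) / (1 + (f_half / f)^hill),

so that `R(f_half) = (base + top)/2` exactly — `f_half` *is* the
half-maximal stimulation frequency.  A logistic-in-log-frequency variant is
available behind the `model="log"` switch.  Initialization is
deterministic (base = min, top = max, `f_half` = frequency nearest the
half-range crossing, hill = 2) with positivity bounds on `f_half` and
`hill`, so fits are reproducible and order-invariant.  Fits are refused
(`converged = False`) when the data's dynamic range is below 0.2 — a flat
curve has no meaningful midpoint — and at least four distinct frequencies
are required.  Inhibitory (layer III) curves are fitted on the absolute
normalized magnitude so that "activation of the inhibition" increases with
frequency.

**Kindled-vs-control contrast.** Per slice, the difference between the
normalized response at 40/60/80 Hz and the (unit) 20 Hz response; group
means, SEMs and the kindled-minus-control gap are reported.  Hypothesis
testing is deliberately out of scope — the tables feed standard ANOVA
tooling.

## Spike-train analysis

Spikes are detected as upward threshold crossings (default −20 mV absolute)
with a 2 ms refractory window, on uniformly sampled voltage traces; the
detector is deliberately simple because the analysis only needs counts, not
waveforms.  Rates are binned counts divided by bin width.  The suppression
statistic compares the mean rate in the 5 s before train onset with the
5 s after train *offset* — "after the train" reads most naturally as after
it ends — as `100·(rate_pre − rate_post)/rate_pre`, undefined when the
baseline is silent.

## The synthetic forward generator

The generator exists so that every stage of the analysis can be validated
against known ground truth; its defaults encode the circuit's documented
physiology.

**Temporal model.** Each region's noiseless ΔF/F is
`polarity · A(f) · (1 − e^{−t/τ_rise}) · e^{−t/τ_decay}` from its onset,
with τ_rise = 100 ms and τ_decay = 4 s (so activity persists on the
~10 s scale after the train).  Onsets are stimulus onset + 20 ms for layer
II, +Lag 1 = 50 ms for the DEn and +Lag 2 = 200 ms for layer III.  The
ground truth records both these programmed latencies and the time at which
the noiseless trace crosses the 20 %-of-peak criterion — the latter is what
"true onset" means to the estimator, since with a 100 ms rise the criterion
is necessarily crossed ~20 ms after the kernel starts.

**Frequency gain.** The per-region gain is the same Hill sigmoid the
analysis fits, expressed relative to the 20 Hz response:
`G(f) = b + (T − b)·s(f)` with `s(f) = 1/(1 + (f_half/f)^hill)`.  The
floor `b` and plateau `T` are solved from two anchors: `G(20 Hz) = 1` (the
normalization reference) and `G(80 Hz) = top_fold` (the frequency at which
fold changes are conventionally read off, responses having plateaued
above 80 Hz).  This anchoring is what makes the programmed `top_fold`
equal the fold change the *pipeline* measures.  When the anchors are
infeasible with a nonnegative floor the floor is clamped to zero and only
the 20 Hz anchor is kept: with the midpoint at the anchor frequency
(layer III, `f_half` = 20 Hz) the 80/20 ratio of any nonnegative sigmoid
is capped at 2, so the layer III request of 2.5 saturates at ≈ 2.0, and
the kindled DEn request of 10 saturates at 8 (the cap is `2^hill`).  The
half-maximal frequencies — the quantities of record — are exact in all
cases.  A consequence of the cap is that the kindled and control layer III
curves coincide; the kindled-vs-control gain contrast is therefore carried
by layer II and the DEn, where it is large.

**Defaults** (per region: fold at 80 Hz relative to 20 Hz, `f_half`,
hill, polarity, |ΔF/F| at 20 Hz):

| region   | control            | kindled            | cut                |
|----------|--------------------|--------------------|--------------------|
| layerII  | 3.5, 40 Hz, 3, +, 1.0 % | 6.0, 40 Hz, 3, +, 1.0 % | 2.0, 40 Hz, 3, +, 0.6 % |
| DEn      | 5.0, 40 Hz, 3, +, 0.6 % | 10 (realized 8), 40 Hz, 3, +, 0.6 % | silent |
| layerIII | 2.5 (realized 2.0), 20 Hz, 3, −, 0.5 % | 4.5 (realized 2.0), 20 Hz, 3, −, 0.5 % | 2.0, 40 Hz, 3, **+**, 0.3 % |

**Acquisition model.** Counts are
`F₀ · (1 − ΔF/F/100) · e^{−t/τ_bleach} + noise` — the dye dims with
depolarization, bleaching is a common-mode exponential (τ = 100 s), and
noise is independent Gaussian per pixel-frame with SD 0.3 % of
`F₀ = 3000` counts (mid-range of a 16-bit camera run at 50–80 %
saturation).  Frames are 64×64 at 5 ms/frame (within the 3–10 ms/frame
acquisition range; 100×100 available via `frame_shape`), 25 µm/pixel, laid
out as four horizontal bands (layer II, DEn, layer III, reference) that
remain pure under 3×3 binning.  With noise enabled, counts are rounded to
integers as a real sensor would deliver; at zero noise they stay
continuous, so that zero-noise parameter-recovery tests measure the
analysis, not quantization.  `simulate_slice` draws one lognormal
dye-loading factor (σ = 0.2) per slice, shared across that slice's
frequencies — the variability that motivates 20 Hz normalization.

**Spike trains.** Spontaneous layer III firing is an inhomogeneous Poisson
process (sampled by thinning): baseline rate uniform in 8–10 Hz per cell,
suppressed to a floor of 1.5 Hz during and immediately after the train,
relaxing back with τ = 8 s.  These two numbers were calibrated once,
analytically, so that the *5 s post-window mean rate* is ≈ 3.4 Hz (the
"about 4 Hz" scale of suppressed firing), the expected pre/post reduction
is 61.9 % (matching the 62 ± 13 % statistic), and the rate at the 20 s
sweep end is 85 % of baseline (recovered to within 20 %).  The patch
protocol places the train after a 5 s baseline within a 20 s sweep so both
5 s windows fit.

**Determinism.** A single integer seed drives one `numpy` Generator;
slice-level simulation derives per-movie seeds from it.  Identical seeds
and parameters reproduce byte-identical movies and spike trains.

## What the synthetic data do not emulate

Responses are spatially uniform within rectangular bands (no activation
spreading, no heterogeneous foci); noise is white in space and time (no
shot-noise scaling, no correlated lamp flicker); the response kernel is a
single rise–decay product (no per-pulse EPSP structure, no oscillatory
content); rounding aside, the camera is ideal (no saturation clipping, no
dark current); spike trains have no refractory structure or bursting.
Passing tests therefore demonstrate that the *analysis* recovers known
parameters under realistic amplitude, timing, noise and bleaching
conditions — not that it is robust to every artifact of real recordings
(motion, focus drift, electrode artifacts are explicitly out of scope).

## Problem sizes

The validation suite and the acceptance script use desk-scale batches: 20
movies for lag recovery, 8 slices × 7 frequencies for gain-curve recovery,
8 + 8 slices for the kindled contrast, 16 trains for the spike statistic,
and ≥ 100 randomized fixtures for the brute-force oracle-equivalence
checks.  These sizes keep a full run in the minutes range on one CPU while
leaving the statistics comfortably inside the tolerances tested.
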