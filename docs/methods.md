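# Methods

`owlsync` has two halves: a set of spike-train patterning metrics, and a
population model of the barn owl's auditory midbrain sound-localization
pathway whose purpose is to show how stimulus-dependent spike-time
patterning shapes the population readout of interaural time difference
(ITD). This note documents the models, their assumptions, the tunable
parameters, the numerical choices, and what the synthetic data and the
reduced problem sizes do and do not establish.

## Spike-train metrics

### Shuffled autocorrelogram (SAC) reproducibility

The SAC is the histogram of time intervals between every spike of one trial
and every spike of the *other* trials. Counts in each lag bin are divided by
`N(N−1)·Δ·D` (N trials, bin width Δ, analysis duration D), giving a
coincidence density in (spikes/s)² whose expectation for independent
Poisson trains is the squared mean rate `m²`. Reproducibility is

    R = ∫_{−w}^{+w} (SAC(τ) − m²) dτ / m ,

which is ≈0 for unpatterned spiking and ≈1 for perfectly repeated trains
(narrow window), independent of rate. The density normalization is chosen
so the subtraction of `m²` is dimensionally consistent and zero-mean for
independent trains; this is the only normalization under which the formula
above behaves as intended.

Defaults: 100-µs bins and a 1-ms integration half-width for ICcl-like
precision, 2-ms bins and a 10-ms half-width for space-map (OT-like)
precision — the integration windows are the reported median center-peak
half-widths for those regions. The half-width estimator measures full width
at half height above the flank mean (flanks: |lag| ∈ [20, 50] ms), with
linear interpolation and outermost-crossing tie-breaks; a center peak is
"significant" when the zero-lag value exceeds the flank mean by more than
2 flank SD. The first 50 ms after stimulus onset are excluded from every
patterning analysis (onset responses would otherwise dominate).

### Victor–Purpura (VP) distance and chance correction

The VP distance is computed with the standard dynamic-programming
recurrence (insert/delete cost 1, shift cost `q·|Δt|`, default `q` =
100 s⁻¹); the exhaustive transformation-enumeration oracle appears only in
tests. Trial-set distance is the mean over all unordered pairs of non-empty
trials; empty trials are omitted because the metric is degenerate against
an empty train.

Because the expected distance between unrelated trains grows with spike
count, distances are corrected by subtracting a chance expectation:
pairs of uniform-random trains are generated with a base count `n1` ~
U{0..52} and a partner count `n2 = round(n1·U(1/3, 3))` (the count
*difference* can reach twice the base count, modelling across-trial rate
disparity), and the VP distance is regressed on the geometric-mean count
with a zero-intercept quartic. The polynomial argument is the **GM spike
count within the analysis window** (= GM rate × duration): with the
argument read as a rate in spikes/s the published 100-ms coefficients
produce impossible values (negative above ~86 spikes/s, larger than any
attainable pairwise distance below it), while the count reading reproduces
the published curves from the generation procedure to within a few percent
over counts 5–40. A residual ~15% deviation persists near the top of the
fit range (counts ≈ 45–50), where the published quartic's negative leading
coefficient bends downward; no tested reading of the generation procedure
reproduces that bend. Models for 100/200/400-ms windows ship with the
published coefficients; other durations trigger a fresh Monte-Carlo fit.

### Cross-correlogram (CCG) synchrony

Coincidences between two simultaneously recorded units are counted on a
1-ms lag grid (binned-count cross-correlation, equivalent to a ±1-ms
coincidence rule), smoothed with a 5-ms boxcar, and normalized by bin width
times the geometric-mean (GM) firing rate. Smoothing is mass-conserving:
each bin's counts are redistributed over the neighbors that exist, so edge
truncation never loses coincidences. Synchrony is the integral of the
normalized CCG over ±10 ms; in the package's units (rates in spikes/s,
durations in s) it is dimensionless — coincidences per expected GM spike —
and two independent Poisson trains give `0.021·GM` (21 bins at chance
level). Reported values of this quantity in the literature this package follows
use the GM rate expressed per millisecond (a millisecond-based convention),
i.e. 1000× smaller; `scripts/acceptance.py` converts to that convention
when reporting the side-peak synchrony value.

The shift predictor pairs trial *n* of one unit with trial *n+1* of the
other; the pairing wraps the last trial to the first so all N trials
contribute. The corrected CCG subtracts shifted from standard counts
bin-wise on the raw counts, before smoothing and normalization.

### Up states

Multiunit spike times are binned at 10 ms; each interior bin is replaced by
the median of its 10 neighbors (5 per side, center excluded). The
even-count median takes the **lower** middle order statistic, so the
filtered value exceeds zero exactly when six or more of the ten
neighboring bins contain spikes — the stated detection criterion. Edge bins
carry no filtered value and never open or close a state.

### Correlation machinery

Per-unit correlations are Fisher-z transformed for group tests and
converted back to r for reporting (so a "mean r" is `tanh(mean z)`).
Pooled reproducibility-vs-rate analyses normalize each unit's rates and
metric by the unit maximum before pooling (units differ in dynamic range);
pooled synchrony-vs-GM analyses for the model are computed on raw values,
because synchrony in these units scales with GM at chance and that
proportionality is part of the relation being measured — a per-pair
normalization would remove it and cannot produce the near-degenerate
correlations the space-map layer exhibits. Distance-vs-rate analyses use
Spearman rank correlation (corrected distances are heteroscedastic with
MAD-flagged outliers). Normality (D'Agostino–Pearson) gates parametric
versus rank tests where both are offered.

## The circuit model

### Periphery

Stimuli are band-limited (0.2–12 kHz) Gaussian noise tokens at 40 kHz with
the right channel delayed by the stimulus ITD (FFT fractional delay). A
frozen token is replayed on every trial of a condition; trial-to-trial
variability enters only through neuron-specific input noise downstream.

Each ear's signal passes through a fourth-order gammatone filterbank
(cascaded complex one-pole resonators), center frequencies spanning
1–9 kHz (41 channels at full scale). Owl-specific auditory filter widths
are not tabulated anywhere accessible, so bandwidths follow a configurable
power law `Q(cf) = 2.2·(cf/1 kHz)^0.5` — a few hundred Hz at low cf to
~1.5 kHz at 9 kHz, in the range of owl cochlear sharpness estimates.

Binaural cross-correlation: for each channel and each candidate lag λ the
left signal delayed by λ is multiplied with the right signal and lowpassed
(one-pole, time constant 5 cycles of the center frequency). Gain control
divides by the token's static channel power plus a fixed semisaturation
constant (0.02, comparable to the per-channel power of a unit-RMS token),
so output amplitude grows compressively with stimulus level while the fast
envelope fluctuations — the temporal patterning everything downstream locks
to — are preserved. An output gain of 0.4 sets the scale of ξ(t) for the
spiking stage. The time-averaged ξ is quasi-periodic in lag with period
1/cf: the phase ambiguity whose resolution the space map exists for.

### ICcl stage

One adaptive-exponential integrate-and-fire neuron per (frequency, lag)
channel. Membrane: τ = 60 ms, leak −75 mV, excitatory reversal 0 mV,
slope factor 1 mV, reset −55 mV, 1-ms refractory hold; exponential-Euler
integration at dt = 0.05 ms. The dynamic threshold relaxes with
τ_θ = 5 ms toward `V1 + k1·ln(1+exp((V−V2)/k2))` (V1 = −57 mV,
V2 = −67 mV). Two alternative parameterizations of these threshold dynamics fail
outright when taken literally: without the relaxation (−θ) term the
threshold diverges, and with a 5-mV gain against a 1-mV activation width
the threshold outruns the membrane at every drive level and the cell can
never fire repetitively (verified by direct f–I simulation). The package
uses gain k1 = 5 mV with width k2 = 5 mV, consistent with fitted
threshold-adaptation dynamics in the owl midbrain; this yields a rheobase
near g ≈ 6 and a graded f–I curve over the conductance range the a = 45
input gain naturally produces.

Input: `s(t) = a·[exp(ξ(t)) − b]₊` with a = 45 and b the mean of exp(ξ)
over a fixed calibration ensemble (frozen tokens on a reference ITD grid),
plus neuron-specific Gaussian noise, flat to 1 kHz, independent across
neurons and trials. The noise RMS is a **per-neuron constant**,
`c·sqrt(RMS(s))` with the RMS taken over the same calibration ensemble:
across neurons the signal-to-noise ratio grows as the square root of the
signal level, while within a neuron SNR tracks the stimulus-driven signal
directly — which is what makes reproducibility rise with firing rate by
construction. A per-condition noise level would instead silence neurons at
non-preferred stimuli rather than decorrelate them. c = 4 and the ξ gain
0.4 were fixed once so that nearly the whole population responds
(rates ~10–320 spikes/s) with within-neuron reproducibility increasing
with rate; they were not revisited afterwards.

### Space map and readout

81 space-map neurons with best ITDs tiling ±320 µs. Best frequency follows
the map's frequency-ITD gradient, `BF = clip(6500 − 20·|ITD µs|, 1000,
9000)` Hz. ITD weights are a Mexican hat: a center Gaussian (σ = 10 µs at
full scale) minus two half-amplitude Gaussians displaced by half the period
of the neuron's own best frequency; frequency weights are a Gaussian with
σ_F = 6500 − 20·|ITD µs| Hz (the absolute value keeps the width positive
and mirror-symmetric across the midline). The magnitude of the product is
the weight; its sign routes the synapse to the excitatory (0 mV) or
inhibitory (−80 mV) reversal. Synapses are exponential conductances
(τ_s = 5 ms, unit jump per spike) scaled by a global gain calibrated per
problem size (the drive scales with the number of afferents). When the lag
grid is subsampled, the Mexican-hat σ follows half the lag spacing so the
center/side-lobe structure survives the coarser grid.

The output layer pools space-map spikes with a Gaussian weight over
preferred ITD. The conversion between map degrees and ITD is 2.5 µs/°; the
experiments use a 12° (30 µs) pooling SD — inside the stated 5–75° robust
range — because at the reduced scale the default 30° (75 µs) pooling width
is comparable to the ~145 µs main/side-peak separation, and the main-peak
drive then holds side-position readout neurons in depolarization block.
The readout curve is mean spike count versus preferred ITD; side peaks are
measured relative to the main peak after subtracting the curve minimum,
with main/side regions segmented by walking from the main peak to its
flanking troughs (with 10% hysteresis against micro-bumps) and retaining
side maxima that carry at least 5% of the main response.

### Synchrony-equalization experiment

For a given stimulus, side-peak space-map neurons are those whose preferred
ITD falls in the side region of the space-map population response. The
stimulus interval is tiled with 25-ms segments; within each segment and
trial the mean spike time of the pooled side-peak spikes defines a
template, and every side-peak spike moves a fraction α of the way toward
its template (clipped inside its segment, re-sorted afterwards). Spike
counts per neuron and trial are conserved exactly; main-peak responses are
never touched. α is calibrated by bisection until side-peak standard-CCG
synchrony matches the main peak's (tolerance 2% relative), saturating at
α = 1 with a warning when the target is unreachable; when the initial
side synchrony already meets the target the procedure returns α = 0.

### Problem sizes

The full-scale circuit (41 × 65 = 2665 ICcl neurons, 100+ trials) is
configurable but the packaged experiments run reduced instances chosen to
preserve the mechanisms: 11 × 33 ICcl channels with 50 trials for the
reproducibility/synchrony analyses (three independent instantiations for
pooled statistics), and 21 × 49 channels with 30 trials for the space-map
and readout experiments — the denser sheet is needed because side-peak
space-map responses are carried by multiple neighboring lag channels and
several high-frequency rows. Readout experiments use stimulus ITDs ±160
and ±240 µs, whose half-period side peaks fall well inside the modeled
±320 µs span. The frequency span, ITD span, and all cellular and synaptic
constants are unchanged from the full-scale configuration.

### Known limitations

At the reduced scale the space-map main response saturates near the 1-ms
refractory ceiling. Two consequences: (i) per-GM-spike synchrony of
saturated main-peak pairs is depressed (regular trains under-coincide per
spike), so the α calibration often saturates at α = 1 or returns α = 0;
(ii) the 60-ms membrane of the readout neurons recovers slowly between the
25-ms template volleys, so equalized side-peak synchrony raises the readout
side peak from ≈0% to only a few percent of the main peak rather than to
the tens of percent seen at full scale with these mechanisms. The
*direction* of the manipulation effect and the exact conservation laws are
reproduced and tested; the magnitude of the side-peak restoration is not.

## Synthetic spike trains

The generators produce inhomogeneous Poisson trains by thinning (exact for
these intensity functions). The default envelope is half-wave-rectified
0–150 Hz lowpass Gaussian noise, matching the envelope statistics of a
narrowband channel under broadband noise. Locking strength κ interpolates
between homogeneous Poisson (κ = 0) and fully envelope-modulated (κ = 1);
tuning curves (quasi-periodic ITD, sigmoidal ILD, Gaussian space) set the
per-condition rate, optionally coupling κ to the normalized rate. Tetrode
sites mix a shared and a private envelope in proportion ρ, so pair
synchrony arises *only* from shared stimulus-locked patterning — there is
no spike-level coupling. What passing tests on these fixtures shows: the
metrics recover known patterning, locking ranks, and shared-envelope ranks.
What they do not show: robustness to bursting, refractory structure beyond
the optional dead time, non-Poisson count statistics, or electrode
artifacts of real recordings.
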