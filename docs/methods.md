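# Methods

`thetalab` implements, end to end, the signal-analysis chain used to
characterise hippocampal theta oscillations of type 1 (movement-related,
~7–10 Hz, atropine-resistant) and type 2 (arousal-related, ~6–8 Hz,
atropine-sensitive) in ventral CA1, together with a synthetic session
generator that provides ground truth for every stage and a single-cell
biophysical model of how rhythmic dendritic inhibition produces a
perisomatic theta current source. This note documents the models, the
numerical choices, and what the synthetic tests do and do not establish
about real recordings.

## Synthetic sessions (`thetalab.synth`)

A session is laminar LFP + tracking + stimulation epochs + spike trains,
fully determined by a `SessionConfig` and its seed.

**Oscillators.** Each rhythm is a gated sinusoid with speed-dependent
instantaneous frequency `f(t) = base_freq + speed_slope · speed(t)`. The
phase is obtained by integrating `f(t)` (cumulative sum over samples), so
speed changes shift frequency continuously without phase slips. Gates
(`always`, `stim_on`, `zone_set`, `immobility`) are binary masks smoothed
with a 100-ms Hann ramp to avoid spectral splatter at transitions. A
laminar profile assigns each channel a gain and phase offset; the default
places a phase reversal three-quarters of the way down the probe,
mimicking the transition from the pyramidal layer to stratum
lacunosum-moleculare.

**Speed–frequency operating points.** The preset conditions tie the
oscillators to published operating points through a single linear law:
treadmill theta1 7.9 Hz at 10 cm/s (base 6.9, slope 0.1 Hz per cm/s) with a
stimulation-gated theta2 at 6.8 Hz; arena theta1 7.3 Hz at 7 cm/s rising to
9.5 Hz at 25 cm/s (slope 2.2/18 ≈ 0.122 Hz per cm/s) with an inner-zone
theta2 reaching 8 Hz at 25 cm/s. Theta2 amplitude defaults to equal
theta1's (0.1 mV); no quantitative amplitude ratio is established for the
two rhythms, so equality is the neutral choice and is configurable.

**Gamma.** Phase–amplitude coupling multiplies a stochastic narrow-band
carrier by the envelope `amplitude · (1 + depth · cos(φ_theta − φ₀)) / 2`.
The carrier is Gaussian-spectrum noise centred on `amp_center_freq`
(default bandwidth 20 Hz, i.e. a 60–80 Hz gamma band), not a pure tone: a
deterministic tone plus its modulation sidebands remains fully modulated in
*any* analysis band that captures the tone and one sideband, which makes
the comodulogram maximum ill-defined; a spectrally peaked stochastic band
is both more realistic and localizable.

**Background.** 1/f^α noise (default α = 1, RMS 0.02 mV) is synthesised by
spectral shaping of white Gaussian noise, independently per channel.

**Spikes.** Units fire as inhomogeneous Bernoulli processes on the sample
grid with rate `λ(t) ∝ exp(κ cos(φ(t) − φ_pref))`, the von Mises modulation
whose concentration κ is solved from the target mean resultant length via
`|R| = I₁(κ)/I₀(κ)`. This makes the configured coupling exact in
expectation, which the recovery tests exploit. Waveform templates are sums
of two Gaussians (negative trough, delayed positive after-peak); an
internal fixed-point calibration adjusts the trough width and peak
amplitude so the *measured* half-width and trough/after-peak ratio equal
the requested parameters exactly despite the Gaussians' overlap.

**Trajectories.** The treadmill model moves at constant speed. The arena
model is a correlated random walk with bout structure: the animal
alternates between wall-hugging bouts and excursions toward a random inner
radius, with `wall_bias` the probability that the next bout targets the
wall annulus (0.8 gives ≥ 70% wall occupancy). Steering rotates the heading
(step length stays `v·dt`, so displacement speed equals path speed), and
speed relaxes toward a per-zone target (defaults: 7 cm/s in the Wall
annulus, 25 cm/s in the inner zones, time constant 0.25 s) — the observed
behaviour that animals cross the open centre at a run. Speeds the analyses
see are always recomputed from the tracked positions, exactly as for a real
recording.

**What the generator does not emulate:** optical stimulation artifacts,
electrode drift, volume conduction (the biophysical module handles fields
properly for one cell), non-stationary background spectra, bursting spike
trains, or overlapping-unit waveform superposition. Passing tests therefore
demonstrate correctness of the analysis implementations under the assumed
signal model, not robustness to every pathology of in vivo data.

## Spectral analysis (`thetalab.spectral`)

Welch PSDs use 3-s Hamming windows with 2.5-s overlap (0.33 Hz
resolution), per-segment constant detrend, mean averaging. Normalization
divides a spectrum by the baseline spectrum's integrated 0–14 Hz power, so
a baseline normalized by itself integrates to exactly 1 over 0–14 Hz. Band
powers are trapezoidal integrals with interpolated band edges (exactly
additive over band splits).

Theta peaks are local maxima in 4–12 Hz that exceed 1.5× a 1/f background
fitted (log–log least squares) over 2–20 Hz excluding the 4–12 Hz window;
peak frequencies are refined by parabolic interpolation of log power
around the maximum bin, which brings localization well inside the ±0.2 Hz
recovery tolerance despite the 0.33 Hz grid. At most two peaks are
returned (theta2 below theta1), sorted by frequency.

## Cross-frequency coupling (`thetalab.cfc`)

The modulation index divides phase into 18 bins (20°), normalizes the mean
amplitude per bin to a distribution P, and computes
`MI = (log N − H(P)) / log N`. MI is 0 for phase-independent amplitude, 1
when all amplitude sits in one bin, and invariant to amplitude rescaling.

Comodulograms scan 0.5-Hz phase bands stepped by 0.25 Hz and 10-Hz
amplitude bands stepped by 2.5 Hz. Filtering is least-squares linear-phase
FIR (`firls`) with 15% transition bands, applied by centred convolution of
the symmetric kernel — exactly zero-phase. The filter length is the larger
of three periods of the low cutoff and what the transition width requires
(≈ 3.3/Δf_trans seconds); the first rule alone, inherited from common EEG
toolboxes, cannot realize a 10-Hz-wide gamma band at fs = 1000 Hz and lets
theta leak into the gamma envelope. Phase and envelope are the angle and
modulus of the analytic (Hilbert) signal.

A caveat documented here because it shapes the tests: with a spectrally
pure theta, every 0.5-Hz phase band returns the *same* phase trace (a
linear filter scales a single tone, it cannot change its phase), so MI is
constant along the phase axis and the argmax there is degenerate. On
realistic theta with finite bandwidth the phase coordinate localizes to
about ±0.5 Hz; the amplitude coordinate localizes to one 2.5-Hz step, and
that is the axis the gamma-frequency claims rest on. A
circular-time-shift surrogate utility (shifts ≥ 1 s) provides the null
distribution for MI significance.

## Units (`thetalab.units`)

Spike detection band-passes 500–5000 Hz (3rd-order Butterworth, zero
phase), estimates the noise SD robustly as `median(|x|)/0.6745`, detects
negative crossings of `−k·SD` with a 1-ms lockout, aligns to the local
trough, and cuts ±0.8 ms snippets *from the raw wideband trace* — the
narrowband trace would destroy the slow after-potential that the
peak/trough ratio measures. Note that at a 3-SD threshold Gaussian noise
itself produces of order tens of crossings per second (Rice's formula);
threshold detection bounds sensitivity, and separating noise events from
units is the job of downstream clustering, which is out of scope here.

Features: half-width is the width of the principal negative deflection at
half its amplitude with linearly interpolated crossings (sub-sample
precision, needed for the ±0.01 ms recovery tolerance at a 0.04 ms sample
interval); the amplitude ratio is |trough| / |first following positive
peak|, the direction in which regular-spiking cells (~12) separate from
interneurons (~1.4). Classification is by mean rate with the boundary rate
of exactly 10 spikes/s assigned to IN (the published strict inequalities
leave it undefined); the boundary is configurable.

Spike–field coupling assigns each spike the instantaneous phase of the
3–8 Hz filtered LFP; `|R|` is the modulus of the mean unit phasor and the
preferred phase its argument. Fewer than 10 spikes raises an error rather
than returning an unstable estimate.

## Current-source density (`thetalab.csd`)

The standard second spatial difference
`csd_i = −(V_{i−1} − 2V_i + V_{i+1})/h²` with positive values plotted as
sources. No Vaknin edge padding and no spatial smoothing by default; both
are options. `band_csd_amplitude` gives the per-channel RMS of the
band-filtered CSD, which is how the dominant laminar source is located.

## Speed–frequency analysis (`thetalab.speedfreq`)

Sessions are divided into 200-ms time bins labelled with mean speed (and
majority zone); the speed distribution is divided into 30 equal-width
bins. For each speed bin the LFP stretches of its member time bins are
concatenated and a single DFT power spectrum taken. Concatenation is
deliberate: running speed is strongly autocorrelated, so members of a
speed bin are mostly contiguous in time and the concatenated record stays
nearly coherent, whereas averaging per-200-ms periodograms (1.5 theta
cycles per rectangular window) biases the ridge frequency by up to
~0.5 Hz. Rows are smoothed over 1 Hz (Hann kernel, configurable) and
normalized to unit sum over the analysis band (default 1–20 Hz, the
figure-style display range).

Per frequency, relative power is regressed on speed-bin centres by
weighted least squares (weights = time-bin counts); frequencies with
p < 0.001 are classed positive or negative by slope sign. The published
"two-way ANOVA" is under-specified; the per-frequency weighted regression
with its F/t test is the implemented reading and behaves as the figure
describes (positive classes at the upper ridge frequencies, negative
below) on session-like synthetic input.

## Closed-loop theta2 trigger (`thetalab.closedloop`)

Faithful offline replay of the real-time controller: 30-s baseline, 6–8 Hz
band, 1/8-s chunks, power threshold 2.5, speed criterion 5 cm/s, movement
and immobility modes. A 0.125-s chunk has 8-Hz intrinsic resolution, so
the chunk periodogram is zero-padded to 1 s (configurable) and band power
is the sum of padded bins inside 6–8 Hz inclusive; baseline and chunks use
the identical estimator, which makes the power ratio of an
amplitude-scaled chunk exact. All comparisons are strict ("higher than",
"greater/less than"), so the switching points sit exactly at ratio 2.5 and
at 5 cm/s; the laser state holds only for the triggering chunk. Chunk
speed is the tracked centroid displacement across the chunk divided by the
chunk duration. `validate` scores a trigger log against known theta2-on
intervals at chunk resolution (sensitivity, specificity, median onset
latency in chunks).

## Behaviour (`thetalab.behavior`)

The arena is a disc with concentric zones; the default 25-cm radius with
boundaries at 8 and 16 cm (Center, Intermediate, Wall) is a configurable
convention — no published dimensions exist — and an `extended()` variant
adds the Extended Intermediate ring at 80% of the radius. Boundary points
belong to the inner zone. Zone labels are median-filtered over 0.2 s
before crossings are counted, suppressing tracker jitter at boundaries;
speed is a centred finite difference, smoothed over 0.2 s with
edge-normalized windows (constant-speed paths stay exactly constant at the
ends). LFP windows (3 s, 2.5 s overlap) are labelled by majority zone and
mean speed; an optional continuous-walking filter keeps only windows fully
inside walking bouts (speed ≥ 5 cm/s) lasting ≥ 2 s.

## Biophysical model (`thetalab.biophys`)

A soma (20 × 20 µm) plus a 150-µm apical dendrite (10 segments, 2 µm
diameter), Ra = 150 Ω·cm, Cm = 1 µF/cm². Channels are HH-style with smooth
Boltzmann steady states and first-order kinetics: Na and delayed-rectifier
K in soma and dendrites, A-type K and the M-current in the soma, and Ih as
absolute conductances of 0.01 µS each in the soma and the distal segment.
All kinetic parameters live in one editable dictionary
(`DEFAULT_CHANNELS`); they are standard-literature shapes tuned for a
stable rest near −65 mV, a ~−50 mV spike threshold and an Ih sag/rebound —
the claims this model supports are qualitative (rebound, source location),
not kinetically exact. Synapses are alpha conductances with the published
parameters: excitatory τ = 0.1 ms, 0.05 µS, 0 mV (temporoammonic/Schaffer,
dendritic targets); inhibitory τ = 0.3 ms, 0.05 µS, −75 mV (OLM on the
distal dendrite, basket on the soma, antiphase by default when both are
used).

Integration is backward Euler on the tridiagonal cable system (Thomas
algorithm) with channel conductances frozen within the 0.025-ms step and
exponential (Rush–Larsen) gate updates; halving dt changes subthreshold
peak Vm by well under 1%. The per-compartment membrane current
`I = C dV/dt + I_ion + I_syn` equals the axial inflow, so its spatial sum
vanishes to machine precision — the point-source sum
`φ_e = (1/4πσ) Σ I_k/r_k` (σ = 0.3 S/m) is therefore dipolar at a
distance, as for a real neuron (1 nA at 100 µm gives 2.65 µV).

**The perisomatic theta source.** OLM drive is modelled as theta-frequency
bursts (default 10 events at 3-ms intervals per cycle, matching
high-frequency-stimulated OLM firing) onto the distal, HCN-rich segment,
through ~10 convergent synapses. Purely passive responses to such distal
inhibition leave the dominant theta dipole at the distal site. The
perisomatic source emerges from the active response: with aperiodic
Poisson background excitation holding the cell at a realistic operating
point (the only *rhythmic* input remains OLM), spikes cluster on the
Ih-supported rebound after each inhibitory volley, and the theta-locked
somatic action currents dominate the 5–9 Hz field — the perisomatic
electrode then exceeds the distal one, and the laminar CSD shows its main
theta source at the soma with an attenuated secondary source at the
distal end, the pattern recorded for type 2 theta. Post-inhibitory rebound
amplitude increases monotonically with g_Ih (0, 0.005, 0.01 µS) when the
resting potential is held fixed; without holding, the g_Ih = 0 cell rests
below the −75 mV GABA reversal and the comparison is confounded.

## Known limitations

- The generator's oscillators are sinusoidal with deterministic
  speed-frequency laws; real theta has cycle-by-cycle frequency and
  amplitude variability and asymmetric waveforms (which themselves create
  harmonics in comodulograms).
- The comodulogram's phase-axis resolution is limited to ~0.5 Hz by the
  0.5-Hz analysis bands; gamma modulated faster than ~5 Hz loses sideband
  energy outside the 10-Hz amplitude windows, attenuating MI for fast
  modulators.
- Spike detection is threshold-only; overlapping spikes and units below
  ~4 noise SD are not separable without clustering, which is out of scope.
- The biophysical model is a single reduced cell; network contributions,
  volume-conduction geometry beyond a homogeneous infinite medium, and
  morphological detail are not modelled.
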