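# Methods

This note documents the models inside the package, the choices behind their
parameters, and what the synthetic preparation can and cannot say about a
living one.

## The closed loop

The platform couples four components at a 1 kHz control tick, with
extracellular synthesis batched at 20 kHz per tick and a one-tick delay on
the motor and stimulation pathways (the hardware loop it models has ~1 ms
latency):

1. **Decoder** — amplitude thresholding of the efferent electrode trace
   (V_thresh defaults to 5× the configured noise RMS; the only hard
   requirement is that it exceed stimulation crosstalk), a 1 ms refractory
   collapse so one action potential counts once, tumbling 50 ms bins, and a
   100 ms TTL per bin reaching 3 spikes.  Bins evaluated while a pulse is
   active cannot emit a new one; a sliding-bin variant is config-surfaced.
2. **Plant** — the tendon-driven finger and its PID controller are reduced
   to asymmetric first-order tracking (flexion τ = 25 ms, release
   τ = 200 ms — tendon return is slower), with contact at θ_c = 25° of the
   0–45° span and a linear elastic fingertip: F_DC = 0.05·max(0, θ−θ_c)
   contact units, F_AC its centered discrete derivative (units/s).  Forces
   are normalized; full flexion against the surface gives F_DC = 1.
3. **Encoder** — one Izhikevich neuron per session (published parameter
   set: a 0.1, b 0.2, c −65 mV, d 8, polynomial 0.04/5/140), forward Euler
   at dt = 0.5 ms, two substeps per tick.  Drives: SA = β + k_SA·F_DC +
   k_RA·|F_AC|; RA = α + k_RA·|F_AC|.
4. **Culture surrogate** — below.

### Encoder gains

β = 3, α = 2 (both subthreshold: the encoder is silent off contact;
rheobase is ≈ 3.7), k_SA = 6 per contact unit, k_RA = 0.5 per contact
unit/s.  These were chosen so that SA fires tonically at ~40–60 Hz through
a sustained hold and RA fires a handful of spikes per contact edge, the
qualitative firing-pattern contrast of SA/RA mechanoreceptors.  The force
rate enters rectified (|F_AC|) by default: a release transient is a
vibration burst to a fingertip afferent, and RA units respond to both
contact make and break.  Setting `EncoderGains(rectify_f_ac=False)`
restores the signed variant, which silences RA at release.

Forward Euler at the default 0.5 ms step carries a first-order bias of
roughly 10% in the tonic firing period (measured against a 10× finer
reference; the bias shrinks linearly with dt and is under 5% at 0.1 ms).
The encoder's role is qualitative patterning, and the gains were calibrated
at the default step, so this bias is absorbed by the calibration.

## The culture surrogate

A ~400-neuron Izhikevich network (80% regular-spiking excitatory with the
canonical heterogeneity, 20% fast-spiking inhibitory), dense-random
connectivity at p = 0.1, current-based exponential synapses (τ = 5 ms)
plus a slow NMDA-like excitatory component (τ = 120 ms, 0.3× the fast
increment) that sustains burst reverberation for a few hundred ms, as
mature cultures do.  Three slow processes shape the rhythm:

* short-term synaptic depression on excitatory outputs (use 0.3/spike,
  recovery 4 s);
* a slow spike-triggered adaptation current (0.5/spike, τ = 3 s);
* a stimulation-induced suppression current on the stimulated cells
  (8 units per delivered pulse, τ = 1.5 s) — activity-dependent fatigue of
  the driven population.  This is the explicitly flagged modeling choice
  through which sustained afferent drive lengthens the following
  inter-burst interval.

**Burst ignition is spatially gated.**  MEA cultures initiate population
bursts at localized "leader" sites; here the burst-initiation zone is the
48 neurons nearest the afferent (stimulation) electrode, which receive
essentially all of the Poisson background drive (12.5 Hz per zone neuron
vs 0.005 Hz elsewhere).  Because ignition runs through this zone, the
stimulation dose it absorbs during a tap directly delays the next
spontaneous burst: SA's sustained trains (~25 pulses/tap) delay it more
than RA's edge clusters (~9 pulses/tap).  This is the mechanism behind the
model's inter-tap-interval effect, and the package makes no claim that a
living culture implements it this way — only that it reproduces the
platform-level phenomenon (SA tapping significantly slower than RA in
closed loop, no such effect without feedback).

**Trace synthesis.**  Each spike deposits a stereotyped positive-first
biphasic template (~1.2 ms) at nearby electrodes, amplitude lognormal
(median 200 µV at the soma) and attenuated as exp(−d/100 µm), with a fixed
per-neuron deposit latency (0–2 ms) standing in for conduction jitter —
without it, substep-synchronous burst spikes superpose into unphysically
large deflections.  Gaussian noise at 15 µV RMS (the rig's accepted band is
10–20 µV).  The stimulation site is modeled as cell-sparse (no somata
within 400 µm): its trace carries the stimulation artifacts (300 µV
biphasic, spatial constant 100 µm — neighbors see well under half the
site amplitude) over the noise floor, which is what the real platform's
afferent channel shows.  Only the efferent and afferent electrodes are
synthesized by default; any of the 60 sites can be requested.

## Event detection and coherence

The detector follows the platform's recipe exactly: complex Morlet CWT at
log-spaced center frequencies over 100–4000 Hz, amplitude-squared power,
global scaling to [0,1], clipping to [0.05, 0.4] (saturating; a zeroing
variant is config-surfaced), frequency-axis mean per time point, 50 ms
moving mean, renormalization, and peak picking at threshold 0.5 with 0.5 s
minimum separation.  "Mean across time and frequency" is implemented as a
frequency-axis mean per time point — averaging over both axes would yield a
scalar and leave nothing to run peak detection on.  Events are detected on
the efferent envelope (the signal that elicits taps); the channel is
overridable.  The CWT itself is a single-precision frequency-domain
implementation (L1-normalized, one signal FFT shared across scales,
chunked for long records) validated per-scale against PyWavelets; 64
voices by default, fewer in the study scripts since the envelope is
insensitive to the voice count.

Wavelet coherence uses the same analytic Morlet, smoothed with a
scale-proportional moving mean in time and a 5-voice mean across scales,
with a cone of influence masked at the e⁻² power folding time
(t = s·√B).  The denominator carries a per-scale power floor (10⁻³ of that
scale's peak) — without it, stretches of envelope clipped to an exactly
constant floor make the estimator an ill-conditioned 0/0.  Micro
(per-event) TFIs take the 1 s window 300 ms before to 700 ms after each
event at the native 20 kHz and image coherence over 4–64 Hz: the
50 ms-smoothed envelope has no structure above ~100 Hz and the COI removes
everything below ~4 Hz in a 1 s window.  Macro (session) coherence
downsamples the envelopes to 2 kHz (FIR low-pass at 0.8× the target
Nyquist, zero-phase) and spans 0.1–100 Hz.  Images are 227×227×3, fixed
viridis colormap pinned to coherence 0–1, low frequency at the bottom, no
axes; rendering is byte-deterministic.

## Classification and statistics

The classifier mirrors the transfer-learning recipe — generic early layers
kept fixed, final layers trained: two fixed banks of seeded random
convolutional filters (8 then 16, 5×5, ReLU, 2×2 max-pool, on 4×
block-averaged images) feed a logistic head trained by minibatch SGD
(constant rate 10⁻³, batch 16, 10 epochs).  Training images are augmented
with random vertical-axis flips and translations up to 30 px (two
augmented copies appended per image); the split is stratified 70/30; the
reported accuracy averages the final 10 validation evaluations (one per
epoch).  Everything is deterministic under a fixed seed.

A single 70/30 split carries several points of sampling variance on
information-free data (the chance-level case), so
`ClassifierConfig(n_runs=R)` optionally repeats the whole
split/train/validate cycle R times with fresh splits and averages the
headline accuracy (the sd then spans run means); the fixed features are
extracted once and shared.  The default is the single-split protocol; the
study scripts use R = 5.

ITI and accuracy comparisons use the fixed-effects one-way ANOVA
(`scipy.stats.f_oneway`), which tolerates unequal group sizes; significance
at 0.05.  Degenerate (zero-variance) inputs raise rather than return an
undefined F.

## Study protocol and problem sizes

A recording day simulates one culture (one network seed) shared by that
day's sessions, each session with its own drive/noise realization — as on
the physical platform, where the same culture is re-recorded per
configuration.  The full protocol is 3 days × {CL, AD, ES} × {SA, RA} = 18
sessions of 5 min.  The study scripts run CL and AD days at 360 s per
session so that every encoding yields 80+ imaged events at the model's
~2.5–4.5 s tap rhythm, and the test suite runs reduced 220 s sessions;
these sizes are the package's own accuracy/runtime trade-off and are
plain parameters.

## What the generator does and does not emulate

Emulated: spontaneous culture-like population bursts and their slow
rhythm; stimulation-evoked responses and activity-dependent suppression;
multi-unit extracellular traces with realistic amplitudes, noise floor and
stimulation artifacts; the complete sensorimotor loop with its latencies;
session and day structure.

Not emulated: development across days in vitro (replicate days differ only
by seed), synaptic plasticity beyond depression/adaptation, biophysical
channel detail, spatially structured connectivity, electrode impedance
drift, or any claim about how a real culture differentiates SA from RA
feedback.  Passing tests therefore demonstrate that the pipeline recovers
the platform's phenomena from signals with realistic statistics — not that
a living preparation would show effects of the same size.

## Degenerate inputs and numerical conventions

All-zero traces produce all-zero envelopes (divide-by-zero guard) and no
events; empty force streams produce empty trigger trains; stimulation
triggers closer than one biphasic pulse width are dropped (later trigger
loses); fewer than two events yield an empty ITI list; single-class image
sets and zero-variance ANOVA groups raise.  Seeds are mandatory for every
stochastic component — a culture cannot be built without one — and derived
child seeds stay below 2³¹.
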