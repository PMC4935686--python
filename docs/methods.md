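# Methods

`measleep` analyzes long-term micro-electrode-array (MEA) recordings of
dissociated cortical cultures, which spontaneously express a slow-wave,
sleep-like state: brief network-wide bursts (50–100 ms) recurring at
0.16–3 Hz, separated by near-quiescence, with LFP power concentrated in the
delta band. Cholinergic activation (e.g., carbachol) desynchronizes this
state — bursts fragment, isolated spikes multiply, pairwise correlation and
low-frequency power collapse, with slow partial recovery. The package
quantifies that transition along three branches (multi-unit activity,
functional connectivity, LFP spectra) and ships a seeded generator so every
stage can be validated end to end without recordings.

## Data model

Raw recordings are int16 count matrices (`samples × channels`) with a μV
scale factor (`lsb_uV`), sampled at 10 kHz by default, stored as flat
little-endian binary plus a JSON sidecar. Spike trains are per-channel
strictly increasing timestamp arrays over a half-open span `[t0, t1)`;
all windows and intervals in the package are half-open. Electrode labels
are opaque strings; the standard 8×8-minus-corners layout (59 recording
sites, one reference) is available as optional `(row, col)` metadata used
only for connectivity-map plotting.

## MUA branch

The >300 Hz component is isolated with an order-2 Butterworth high-pass
(default cutoff 300 Hz), applied forward-backward so timestamps carry no
group delay (a causal single-pass mode reproduces online-filter behavior).
Noise SD per channel is estimated robustly as `median(|x|)/0.6745`; the MAD
is insensitive to the sparse large deflections spikes contribute, whereas a
raw SD would inflate with firing rate. Spikes are detected at a hard
threshold of `−5σ_n` (negative polarity; factor and polarity configurable),
timestamped at the extremum within a 2 ms dead time that also suppresses
re-triggering.

Bursts are maximal runs of ≥3 spikes with consecutive inter-spike intervals
≤100 ms. These two values follow the convention of ISI-threshold burst
detectors for cortical cultures; they are config-exposed because no single
standard exists.

Network metrics per analysis window:

* **MFR** — spikes/s per channel, network value = mean over *all* channels
  (the active-channel filter applies only to connectivity, below);
* **IBR** — percentage of spikes outside any burst of their own channel,
  pooled over channels (IBR + in-burst percentage = 100 exactly);
* **BI** — network spikes binned at 1 s (bins aligned to the window start),
  `f15` = spike fraction in the `⌈0.15·n_bins⌉` most populated bins,
  `BI = (f15 − 0.15)/0.85` clipped to [0, 1]. Network-pooled counts are
  used (the original formulation); a per-channel variant can be built from
  the same primitive. Ceiling is used for the top-bin count for
  determinism.

Metrics are normalized per experiment to the basal reference (mean over
basal windows); a zero or undefined reference flags the normalized value as
missing rather than producing a silent 0. Percent change between two
values is `100·(x_end − x_start)/x_start`, undefined (flagged) at
`x_start = 0`.

## Connectivity branch

Pairwise correlation uses the spike time tiling coefficient

    STTC = ½ [ (P_A − T_B)/(1 − P_A·T_B) + (P_B − T_A)/(1 − P_B·T_A) ]

with `T_X` the fraction of the span tiled by ±Δt windows around X's spikes
(computed by analytic interval union, clipped to the span) and `P_X` the
fraction of X's spikes within ±Δt of the other train. Degenerate
denominators (|1 − P·T| < 1e-12) zero that term; an empty train makes the
coefficient undefined for that window. The tiling half-window Δt is not
standardized; the default 0.05 s is of the order of in-burst co-activation
and is mandatory in configs and recorded in every output.

Tracking: STTC matrices are computed hourly over channels with
MFR > 0.01 spike/s (strict inequality), the 100 edges with the largest
basal coefficients are selected (reference = mean over basal windows where
defined; a max-over-windows mode exists; ties at the cutoff break
lexicographically by electrode pair), and each is followed through
treatment. An edge "decreases" in a window when
`(basal − current)/basal × 100 > 20`; the fixed 20% cutoff is the decision
rule, and the data-driven mean + 3 SD of pooled basal-to-basal decreases is
computed and reported alongside (falling back to the fixed value when fewer
than two basal windows or no decreases exist). An edge is "deleted" when
its coefficient is undefined because an endpoint fell inactive; deleted in
every post-treatment window = permanently lost. This inactivity reading is
an explicit interpretation choice, recorded here because no formal
definition is standard.

## LFP branch

Wide-band signals are low-passed below 500 Hz with a Hamming-window FIR of
order 30 (31 taps — order = taps − 1, the usual convention), group-delay
compensated (15 samples), and decimated to 1 kHz. PSD uses Welch's method:
5 s Hamming segments, 50% overlap, zero-padded to 8192 DFT points, giving
df = 1000/8192 ≈ 0.12 Hz and a segment span dt = 8.192 s. Density scaling
includes the taper power correction so the integrated one-sided PSD equals
the signal variance (Parseval; verified to 5% in tests). Band powers are
trapezoidal integrals over delta [1, 4), theta [4, 11), beta [11, 30) and
gamma [30, 55) Hz — half-open to avoid double-counting shared edges.

Band-limited traces use linear-phase Hamming FIR band-passes of length
20000 (delta), 10000 (theta, beta) and 5000 (gamma) taps at 1 kHz, shifted
by half the filter length to cancel the delay; the half-length stretches at
both ends are marked invalid. The even tap counts put the compensated
output half a sample early, a phase error below 0.5° at delta frequencies.

## Synthetic generator

The generator reproduces the phenomenology with Poisson building blocks —
deliberately no biophysical network model, which would add parameters the
analyses cannot constrain. Network-burst events are homogeneous Poisson at
`network_burst_rate_hz`; each burst recruits each channel independently
with probability `participation`; a recruited channel fires a Poisson
barrage at `in_burst_rate_hz` for `burst_duration_ms` from a jittered
onset; independent tonic Poisson spikes are superimposed; a 2 ms refractory
period is enforced by thinning.

Defaults define the two study regimes:

| parameter | sleep-like | desynchronized | rationale |
|---|---|---|---|
| network_burst_rate_hz | 0.2 | 0.2 | low end of the 0.16–3 Hz range: strongly synchronized slow regime |
| burst_duration_ms | 75 | 75 | midpoint of 50–100 ms |
| in_burst_rate_hz | 150 | 50 | ~11 spikes/burst/channel vs fragmented barrages |
| tonic_rate_hz | 0.05 | 1.5 | near-quiescence vs many isolated spikes |
| participation | 0.9 | 0.25 | network-wide vs fragmented recruitment |
| jitter_ms | 5 | 10 | tight vs loose burst alignment |

Raw rendering adds Gaussian noise (default σ = 5 μV), a biphasic ~1 ms
waveform (peak −50 μV, i.e., 10:1 SNR at the default threshold) at each
spike time, and sinusoidal LFP components at band centers. Component
amplitudes follow `A = √(2P)` from typical mean band powers of slow-wave-
dominant cultures (≈8.9/4.2/2.0/1.5 μV² for delta/theta/beta/gamma) and of
cholinergically desynchronized ones (≈3.3/1.2/1.0/0.9 μV²). In the
sleep-like regime the delta component is amplitude-modulated by a smooth
burst-locked envelope (unit RMS, so mean power is preserved).

The protocol generator concatenates a basal phase and a treatment phase
whose regime interpolates linearly from the desynchronized parameters back
toward basal with mixing fraction `desync_depth · exp(−u/τ)` at time `u`
after onset; the recovery constant τ is a free parameter with no claimed
default (the underlying biology does not pin it down) — infinite τ freezes
the treated regime. The phase is generated piecewise (60 s segments,
regime frozen at each midpoint) with per-segment seeds derived from the
master seed, all below 2³¹; identical `(params, seed)` reproduce identical
spike trains exactly.

What the generator does *not* emulate: spike-waveform diversity and
overlap, non-stationary noise, electrode-distance-dependent correlation
structure, 1/f LFP background, and any pharmacokinetics. Passing tests
therefore demonstrate that the pipeline recovers the parameters and
contrasts it was pointed at, not that it is robust to every artifact of
real recordings.

## Pipeline, windows and statistics

Both phases are tiled with contiguous windows (3600 s at full scale), the
treatment tiling starting after the discard interval (600 s by default,
emulating the pipetting artifact at drug application); trailing partial
windows are dropped. Key windows — start, middle (the window containing
the phase midpoint), end — are computed, never hand-picked. A control arm
(identical regime throughout) is a first-class mode, implemented as
`desync_depth = 0`.

Group comparison follows the conventional rule: Kolmogorov–Smirnov
normality on each sample (moments estimated from the sample), two-sample
t-test when both pass, two-sided Mann–Whitney otherwise — exact for
tie-free samples of ≤8, tie-corrected normal approximation (without
continuity correction, so identical samples give p = 1 exactly) above.
Significance is reported at α = 0.05, not decided for the caller. No
multiple-testing correction is applied, matching the scope of the emulated
study design.

## Problem sizes and numerical choices

The shipped validation protocol is a scaled-down version of the 7 h + 24 h
design: 600 s basal + 1200 s treatment, 180 s windows, 60 s discard,
59 channels, with 30 s LFP segments per key window — sizes chosen so the
full suite exercises every stage in well under a minute while keeping
≥3 windows per phase for the statistics. STTC against its brute-force
interval-union oracle agrees to 1e-12; Welch Parseval holds to 5%;
filter responses match closed-form Butterworth magnitudes to 1%.
Degenerate inputs (empty trains, all-zero channels, zero basal references)
yield flagged NaNs or warnings, never silent zeros.

## Known limitations

* Sinusoidal LFP components make band powers nearly deterministic; real
  spectra are broadband and the percent-change estimates would be noisier.
* The burst detector is a single-ISI-threshold variant; adaptive detectors
  behave differently at low rates.
* "Deleted" connectivity is defined through channel inactivity only.
* The KS normality test with estimated moments is liberal; with the small
  per-phase window counts of scaled runs the Mann–Whitney branch is the
  one that matters in practice.
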