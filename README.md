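# measleep

Analysis of sleep-like network states in micro-electrode-array (MEA)
recordings of cortical cultures.

Dissociated cortical networks on MEAs spontaneously fire in a synchronized,
slow-wave-like pattern: brief network-wide bursts (50–100 ms) at
0.16–3 Hz separated by near-quiescence, with local-field-potential (LFP)
power concentrated in the delta band (1–4 Hz) — an in-vitro analogue of
NREM sleep. Cholinergic agonists such as carbachol desynchronize this
state: bursts fragment, isolated spikes multiply, pairwise correlations and
low-frequency power collapse, and the network recovers only partially over
hours. `measleep` provides the full quantitative toolchain for tracking
that transition, plus a seeded synthetic generator so the whole pipeline is
testable without recordings. It is aimed at electrophysiologists and
methods developers working with long-term multichannel culture recordings.

## What it computes

**Multi-unit activity (MUA).** Order-2 Butterworth high-pass at 300 Hz,
spike detection at a hard −5σₙ threshold (σₙ via the spike-robust
MAD/0.6745 estimator), ISI burst detection (≤100 ms, ≥3 spikes), and the
network metrics

* MFR — mean firing rate (spike/s),
* IBR — inverse burst ratio, the percentage of spikes outside bursts,
* BI — burstiness index, `BI = (f15 − 0.15)/0.85` where `f15` is the spike
  fraction in the 15% most populated 1 s bins (0 tonic, 1 fully bursty),

each normalized to the basal reference, with percent changes
`100·(x_end − x_start)/x_start`.

**Functional connectivity.** The spike time tiling coefficient

    STTC = ½ [ (P_A − T_B)/(1 − P_A·T_B) + (P_B − T_A)/(1 − P_B·T_A) ]

computed hourly over active channels (MFR > 0.01 spike/s), tracking of the
100 largest basal edges, the fraction decreasing by more than 20% of their
basal value (with the mean + 3 SD basal-variation threshold reported
alongside), permanently deleted connections, and connectivity-map export on
the 8×8 electrode layout.

**LFP spectra.** Anti-alias FIR low-pass (Hamming, order 30, <500 Hz),
decimation to 1 kHz, Welch PSD (5 s windows, 50% overlap, 8192-point DFT;
df ≈ 0.12 Hz, dt ≈ 8.19 s), band powers over delta/theta/beta/gamma
(1–4/4–11/11–30/30–55 Hz), and delay-compensated band-limited traces
(FIR lengths 20000/10000/10000/5000).

**Protocol orchestration.** Hourly windowing of a basal + treatment design
(7 h + 24 h at full scale, first 10 min after treatment discarded),
start/middle/end key windows, KS-gated t/Mann–Whitney group comparison, and
deterministic CSV + JSON-manifest outputs.

## Worked example

Simulate 10 minutes of each regime and compare:

```python
import measleep as m
from measleep import mua, connectivity as conn

sleep = m.generate_spikes(m.sleep_like(), n_channels=59, duration_s=600, seed=11)
cch   = m.generate_spikes(m.cch_like(),   n_channels=59, duration_s=600, seed=12)

for name, s in [("sleep", sleep), ("cch", cch)]:
    bursts = mua.detect_bursts_all(s)
    print(name,
          f"BI={mua.burstiness_index(s, (0, 600)):.3f}",
          f"IBR={mua.inverse_burst_ratio(s, bursts, (0, 600)):.1f}%")

p = conn.SttcParams()  # dt = 0.05 s
for name, s in [("sleep", sleep), ("cch", cch)]:
    mat = conn.sttc_matrix(s, p, (0, 300))
    top = conn.select_top_edges([mat], 100)
    print(name, f"top-100 STTC mean = {top.basal_reference.mean():.3f}")
```

prints

```
sleep BI=0.875 IBR=3.4%
cch BI=0.087 IBR=86.0%
sleep top-100 STTC mean = 0.925
cch top-100 STTC mean = 0.059
```

— the synchronized regime is strongly bursty (BI near 1, almost all spikes
inside bursts, near-perfectly tiled spike pairs), while the desynchronized
regime inverts every signature.

The same workflow runs from the shell:

```
measleep simulate --regime sleep --duration 600 --channels 59 --seed 11 --raw --out sim/sleep
measleep detect --in sim/sleep.bin --out sim/spikes.csv
measleep metrics --spikes sim/spikes.csv --window-s 60 --out sim/metrics.csv
measleep lfp --in sim/sleep.bin --out sim/psd.csv
measleep run --config experiment.yaml --out results/
```

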