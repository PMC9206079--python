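# gluquanta

Quantal analysis of glutamate release imaged with the fluorescent sensor
SF-iGluSnFR, plus an experimentally constrained model of presynaptic
vesicle fusion.

## The problem

Expressing SF-iGluSnFR on an axon and imaging at 250 Hz (4 ms/frame,
183.3 nm pixels) makes every glutamate-releasing bouton of a single neuron
visible: each vesicle fusion produces a fluorescence transient with a
quasi-instantaneous rise and an exponential decay (τ = 68 ms). Turning such
movies into per-synapse release statistics requires a chain of non-trivial
steps, which this package implements:

- **Bouton detection** — temporal smoothing, 0.5–30 Hz Gaussian band-pass,
  3×3 median filtering and a maximal projection reveal every active bouton.
- **Event detection** — per-bouton traces are deconvolved against the
  unitary response `f(t) = exp(-t/τ)` in the frequency domain; quantal
  release events are local maxima above θ = 4σ_BN, where σ_BN is the SD of
  a zero-centred Gaussian fitted to the trace's all-point histogram.
- **Quantal analysis** — event amplitudes are bootstrapped (m = 100,000
  draws with added baseline noise) and fitted with a 4-Gaussian mixture
  whose centres follow the saturating ladder μ_i = Σ_{k≤i} λ^(k−1) μ₁
  (λ ≈ 0.9), yielding the quantal size q and per-event vesicle counts.
  Events ≤ 10 ms after an action potential are synchronous, later ones
  asynchronous; per-bouton efficacies n_T = n_S + n_A (quanta per AP), the
  modified paired-pulse ratio PPR = 2N₂/(N₁+N₂) ∈ [0, 2], and the binomial
  summary P_rel = 1 − (1 − p_v)^m, n_T = m·p_v follow.
- **Sub-pixel localization** — single-quantum events (amplitude < 1.25 q)
  are localized by à-trous B-spline wavelet filtering and integrated
  2D-Gaussian fitting, with a per-event empirical precision δ estimated
  from 50 refits under added background noise (events with δ > 100 nm are
  excluded).
- **Spatial statistics** — release sites from 100 nm hierarchical
  clustering, convex-hull release areas per mode, and a label-reshuffling
  comparison of synchronous vs asynchronous dispersion.
- **Presynaptic model** — buffered Ca²⁺ reaction–diffusion in a
  truncated-sphere bouton with clustered voltage-gated Ca²⁺ channels (nine
  active-zone geometries), an allosteric model of Ca²⁺-triggered fusion
  giving position-dependent synchronous release probabilities p_s, the
  overall map p_v = p_s + (1 − p_s)·p_a, and Monte-Carlo release trains
  (51 APs, site occupancy p_oc = 0.5) whose output feeds the same analysis
  pipeline.

Every stage is testable without data downloads: the `synthetic` module
generates traces, single-event image patches and multi-bouton movies with
ground truth attached, at experiment-like signal-to-noise.

## Worked example

Simulate one bouton through a 5 Hz train of 51 APs and run the full
trace-analysis chain:

```python
import numpy as np
from gluquanta import (APTrain, QuantalMixtureModel, bouton_stats,
                       classify_modes, deconvolve, detect_events,
                       estimate_noise, make_unitary_kernel, quantize_events)
from gluquanta.synthetic import generate_trace, noise_sd_for_snr

kernel = make_unitary_kernel(tau=68.0, frame_interval=4.0)
train = APTrain.train_5hz(51)
rng = np.random.default_rng(0)

events = []
for t_ap in train.ap_times:          # ~40% release, 25% asynchronous
    if rng.random() < 0.4:
        n_q = 1 + (rng.random() < 0.3)
        lat = rng.uniform(0, 2) if rng.random() > 0.25 else 10 + rng.exponential(50)
        events.append((float(t_ap + lat), int(n_q)))
noise_sd = noise_sd_for_snr(1.0, 10.0, 2550, kernel)
trace, truth = generate_trace(events, kernel, 10_200.0, q=1.0, lam=0.9,
                              noise_sd=noise_sd, seed=1)

d = deconvolve(trace, kernel)
estimate_noise(d)                     # sigma_BN and theta = 4 sigma_BN
detected = detect_events(d, train)
fit = QuantalMixtureModel([e.amplitude for e in detected], d.sigma_BN).fit(seed=2)
quantize_events(detected, fit.fit)
classify_modes(detected, train)
stats = bouton_stats(detected, train)

print(f"sigma_BN = {d.sigma_BN:.3f}, theta = {d.theta:.3f}")
print(f"events detected: {len(detected)} (simulated: {len(events)})")
print(f"quantal size q = {fit.fit.q:.3f}, lambda = {fit.fit.lam:.3f}")
print(f"n_T = {stats.n_T:.3f}, n_A/n_T = {stats.frac_async:.3f}")
```

Output:

```
sigma_BN = 0.112, theta = 0.446
events detected: 18 (simulated: 18)
quantal size q = 0.941, lambda = 0.909
n_T = 0.431, n_A/n_T = 0.182
```

All 18 simulated events are recovered; the fitted quantal size (0.94,
truth 1.0) and saturation factor (0.91, truth 0.9) come back within the
mixture fit's expected scatter, and the release efficacy n_T counts quanta
per action potential. `fit.summary()` prints the full mixture table.

A command-line interface mirrors the library (`gluquanta simulate-traces`,
`detect-boutons`, `detect-events`, `quantal-fit`, `group-size-mc`,
`model`, `simulate-release`, ...); every subcommand takes `--seed` where
randomness is involved.

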