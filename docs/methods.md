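# Methods

This note records the scientific conventions, parameter choices and known
limitations behind `gluquanta`. Units: ms, nm/µm, Hz; fluorescence
amplitudes are arbitrary units; model concentrations are µM.

## Unitary response and filter chain

A single vesicle fusion produces an SF-iGluSnFR transient modelled as an
instantaneous rise followed by `exp(-t/τ)` with τ = 68 ms, sampled at the
frame interval (4 ms default). The same sampled kernel object drives both
the synthetic-data generator and the deconvolution, so the simulation and
detection models cannot drift apart.

The band-pass "Gaussian" filter with corners (0.5, 30) Hz is realized in
the frequency domain as

    H(f) = exp(-f² / (2·30²)) · (1 − exp(-f² / (2·0.5²))),   H(0) = 0.

The corners are 1-σ (gain 0.607) points; gain is ≥ 0.94 between 2 and
10 Hz and < 0.005 at 100 Hz. The transfer function is frozen so that the
deconvolution gain and noise calibration below are exact consequences of
it.

## Deconvolution, noise calibration and detection

Traces are band-passed, divided in the frequency domain by the kernel
transform (with a relative floor of 1e−6 on |K(f)| — the raw quotient is
unstable where the kernel transform is near zero), and band-passed again.
Deconvolved traces are normalized by the chain's peak response to a unit
quantal event, g = max IFFT(H²), so an isolated one-quantum event reads
out its generator-scale amplitude directly; this also makes the SNR used
by the generator (q/σ_BN) and the analyzer's 5σ bouton-inclusion statistic
the same number by construction.

The baseline noise SD σ_BN is fitted as a zero-centred Gaussian to the
all-point histogram of the deconvolved trace *before* the final band-pass
(robust range: ±4 scaled-MAD, bin width σ/10-ish over 80 bins), while
events are strict local maxima above θ = 4σ_BN on the final filtered
trace; plateau ties resolve to the earlier frame. Because the final
band-pass removes additional noise power, the effective threshold on the
detection trace is ≈ 6.5 of its own σ. This two-stage convention is what
makes a 4σ threshold essentially abolish false positives on event-free
traces (0–5 per 1000 simulated 10.2 s traces) while keeping the missed
fraction at the 5σ inclusion boundary near ~10–20%; calibrating σ on the
final trace instead would produce tens of false positives per 1000 traces
at 4σ.

Event amplitude is the value at the local maximum (not an integral).
Latency is measured from the preceding somatic action potential using the
frame whose exposure window contains the maximum; events ≤ 10 ms after an
AP are synchronous, later ones (before the next AP) asynchronous; events
in unstimulated recordings are spontaneous and never enter n_T.

## Quantal mixture

Per bouton, detected amplitudes are bootstrapped (default m = 100,000;
each draw = resampled amplitude + N(0, σ_BN)) into a quasi-continuous
distribution, binned at σ_BN/10, and fitted by least squares in density
space with the 4-Gaussian mixture: centres μ_i = Σ_{k≤i} λ^(k−1)·μ₁,
common variance σ² = σ_BN² + σ_AN², weights A₁..A₄ ≥ 0. Initialization:
μ₁ at the kernel-density mode of the sub-1.5×-median amplitudes, λ = 0.9,
σ_AN = σ_BN/2; bounds λ ∈ [0.6, 1.1]. The bootstrap removes the histogram
bin-size sensitivity of a direct fit; least squares on the fine density
grid is the objective (the fit target is smooth by construction).
Non-convergence flags the bouton for downstream exclusion. The fit is
exposed statsmodels-style (`QuantalMixtureModel(...).fit()` →
results with parameter table, Gauss–Newton standard errors, `summary()`).

Quantization assigns each amplitude to the nearest centre (midpoint
boundaries — the maximum-likelihood rule for equal-variance Gaussians),
capped at 4 quanta; the localization gate for single-quantum events is
amplitude < 1.25 q.

For paired-pulse protocols, N₁/N₂ sum the quanta assigned to first/second
pulses within one inter-spike interval (50 ms); events landing in the 10 s
inter-sweep gaps keep their asynchronous label but are excluded from
PPR = 2N₂/(N₁+N₂). Cell summaries require ≥ 21 boutons with ≥ 2 events,
split boutons into n_T terciles and use a 20-point moving average of
n_A/n_T over n_T-sorted boutons.

## Synthetic data

The generator emulates: quantal amplitudes on the saturating ladder
(λ = 0.9 default), i.i.d. Gaussian pixel/frame noise, continuous event
times assigned to the exposure window containing the onset (frames sample
the fluorescence instantaneously at frame times; the camera-phase jitter
this leaves in peak amplitudes is the σ_AN of the quantal model), and
single-event image patches F(x,y,t) = F_BG + ΔF·G(x,y; σ_xy)·exp(−Δt/τ)
with σ_xy ∈ [250, 450] nm on the 183.3 nm grid. The SNR knob is defined on
the analysis side (q/σ_BN of the deconvolved disc-averaged trace) and
converted to raw noise analytically from the chain's white-noise gain;
the default validation range is 5–15, spanning upward from the 5σ
inclusion threshold. Not emulated: photobleaching, drift, Poisson/EMCCD
shot noise, structured (bouton-shaped, fluctuating) backgrounds, focus
tilt. Passing tests therefore demonstrate correctness of the analysis
chain under its stated noise model, not robustness to every real-world
degradation; localization in particular is *easier* on this synthetic data
than in experiments (see below).

## Localization

Event images average 3 deconvolved frames centred at the response peak.
Approximate positions come from the second-scale à-trous B-spline (order
3) wavelet plane (kernel [1,4,6,4,1]/16, then the same kernel with holes
of one); symmetric reflection at borders. The bouton-specific threshold is
calibrated on a 1000-image background stack (each image = mean of 3 random
event-free deconvolved frames, ≥ 15 frames from any event): descend by
halving until the stack yields detections, then ascend in steps of 1/250
of that level until zero maxima. Images with zero or ≥ 2 maxima are
rejected. Sub-pixel fits use the integrated 2D Gaussian (erf form; free
x, y, σ, amplitude, offset) on the 7×7 window, least squares. The
empirical precision δ is the distance between the initial fit and the mean
of 50 refits with added background noise; events with δ > 100 nm (or > 50%
failed refits) are excluded and the averaged position is the final
location.

On artificial event images with SNR 5–15 the pipeline localizes included
events with a median error of ~35 nm while excluding roughly 30–50% of
events (multiple-maxima, refit failures and the δ filter) — consistent
with the design goal that the δ ≤ 100 nm envelope bounds the attainable
error from above. Under the i.i.d. Gaussian noise model this sits below
the 50–100 nm achieved on real recordings, where shot noise, structured
background and active-zone tilt add error sources that are out of scope
here.

## Spatial statistics

Release sites: average-linkage hierarchical clustering cut at 100 nm, then
a refinement pass enforcing the definition "every event within 100 nm of
its cluster centroid" (events violating it are reassigned to the nearest
admissible centroid or become singletons). Boutons with centroids ≥ 700 nm
apart carry two active zones and are excluded from spatial analyses.
Convex-hull areas (µm²) are computed per mode for boutons with ≥ 5
included events and both modes present; hulls of < 3 non-collinear points
count as degenerate area 0. The reshuffle statistic permutes mode labels
over observed positions (n_shuffles = 1000 default), normalizes each
mode's observed area by its mean shuffled area, and evaluates both modes
on the same shuffle set (a paired comparison); > 50% degenerate shuffles
exclude the bouton.

## Presynaptic model

Geometry: truncated sphere (R = 0.5 µm, cut at z = 0.42 µm) with a
circular AZ on the cut face, area 0.03–0.15 µm². VGCC clusters: radius
30 nm, 16 channels each (7 P/Q + 8 N + 1 R), overall density ~500 µm⁻²;
nine layout cases with 1–5 clusters placed centrally (one at the centre
plus a ring at 0.45 AZ radii; the "tight" variant at 0.30) or peripherally
(ring at 0.75 AZ radii). These coordinates reconstruct the published
layout classes from their description. RRP sites: uniform in the AZ at
100 µm⁻², count clamped to 3–15.

Ca²⁺ solver: operator-split on a regular grid — backward-Euler diffusion
per species on a zero-flux masked Laplacian (sparse LU factorized once),
then local reactions: each buffer relaxes exponentially toward its
instantaneous equilibrium at the current Ca²⁺ (exactly mass-conserving by
construction), surface extrusion k_extr = 640 µm/s toward the 50 nM rest
everywhere except the AZ face, and influx spread over each cluster's
footprint (so the source does not sharpen as the mesh is refined). The
AP-evoked influx is a Gaussian of 0.3 ms FWHM carrying 2000 ions per
cluster (≈ 250 ions/channel × 16 channels × ~0.5 open probability).
Buffer tables ship as editable JSON defaults (single-site approximations
from the standard literature values): endogenous — calmodulin 100 µM
(k_on 1e8 M⁻¹s⁻¹, K_d 100 µM, D 20 µm²/s), calbindin-D28k 40 µM
(7.5e7 M⁻¹s⁻¹, K_d 0.39 µM, D 20), ATP 400 µM (5e8 M⁻¹s⁻¹, K_d 200 µM,
D 220); pipette — EGTA 1 mM (2.7e6 M⁻¹s⁻¹, K_d 185 nM, D 220) plus ATP.
[Ca²⁺](t) is recorded across the AZ at a fixed 20 nm depth below the
membrane (interpolated between voxel layers), the scale of the vesicular
Ca²⁺ sensor — recording raw voxel centres would make the effective sensor
depth mesh-dependent.

Fusion: the phenomenological allosteric model — five sequential binding
steps (k_on 1e8 M⁻¹s⁻¹, k_off 4000 s⁻¹, cooperativity b = 0.5) with
fusion rate l₊·f^n (l₊ = 2e−4 s⁻¹, f = 31.3) from the n-bound state,
shipped as a data file. p_s is the cumulative fusion probability over the
10 ms window from AP onset (RK4 on the master equation, 2 µs steps,
vectorized over AZ positions; verified against a 0.1 µs explicit-Euler
oracle). p_a is uniform: 0.03 with endogenous buffers, 0.02 with the
pipette buffer; p_v = p_s + (1 − p_s)·p_a.

Release Monte Carlo: per AP and site, synchronous release with probability
p_oc·p_s (p_oc = 0.5, matching ~2-fold steady-state depression at 5 Hz),
asynchronous with probability p_a only upon synchronous failure; no
replenishment dynamics beyond the static occupancy. Imaging emulation
drops all events sharing a detection frame within one AP (multi-vesicular
exclusion; asynchronous latencies are exponential with a 50 ms constant,
truncated at the next AP) and blurs surviving positions with isotropic
75 nm noise.

### Desk-scale resolution

The default production resolution is a 40–50 nm mesh with 5–10 µs steps
and 5 ms Ca²⁺ transients (the nanodomain collapses within ~2 ms; p_s over
the 10 ms window is unchanged to 4 decimals versus a 10 ms simulation).
The reference resolution for this class of model is a 10 nm fully implicit
cluster-scale run; at desk scale the mean p_s for a representative
two-cluster geometry converges as 0.227 / 0.270 / 0.318 / 0.311 at
60/50/40/30 nm — i.e. the 50 nm default carries a systematic of roughly
15–25% in absolute mean p_s, while the 40 → 30 nm step changes it by ~2%.
All comparative claims the model is used for (p_s increasing with AZ size,
decreasing with vesicle–cluster coupling distance, central > peripheral
layouts, the inverse n_A/n_T–n_T relationship across geometries) are
stable across this mesh range; absolute p_s values at desk scale should be
read with that tolerance.

## Numerical conventions and degenerate inputs

- Pixel coordinates are 0-based; positions are nm from the centre of the
  patch's top-left pixel.
- The 5-px circular trace mask covers 21 grid pixels.
- Strict local maxima with earlier-frame tie-breaks (traces); 8-neighbour
  ≥-maxima (images).
- PPR is undefined (None) when N₁ + N₂ = 0; such boutons leave PPR
  analyses. Constant traces raise on noise estimation. Empty movies yield
  empty bouton lists, not errors.
- All randomness flows through explicit seeds / numpy Generators;
  identical seeds give bit-identical outputs.

## Known limitations

- The noise model is additive i.i.d. Gaussian; shot noise, sensor
  nonlinearity beyond λ-saturation, photobleaching and drift are not
  modelled, so synthetic benchmarks bound the pipeline's algorithmic error,
  not its full experimental error.
- Buffer kinetics and the influx waveform are literature-sourced defaults
  (flagged in the output metadata), not fitted quantities; swapping the
  JSON tables changes the model accordingly.
- The nine AZ layouts are reconstructions of the published layout classes;
  at 50 nm mesh, two geometrically distinct central variants can snap to
  the same source voxels.
- Desk-scale meshes under-resolve the nanodomain core (see above);
  absolute p_s carries a ~20% systematic at the default resolution.
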