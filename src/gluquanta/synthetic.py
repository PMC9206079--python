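"""Ground-truth synthetic SF-iGluSnFR data.

Generates single-bouton traces, single-event image patches and multi-bouton
movies with a known event list attached, replicating the validation
simulations used to characterise the detection pipeline: instantaneous-rise
/ exponential-decay unitary responses (tau = 68 ms), quantal amplitudes
with progressive sensor saturation (factor lambda, population mean 0.9),
a Gaussian spatial profile with width sigma_xy in the 250-450 nm range on a
183.3 nm pixel grid, and i.i.d. Gaussian baseline noise.

Noise is parameterized either directly (``noise_sd``, raw units) or through
the analysis-side signal-to-noise ratio SNR = q / sigma_BN of the
deconvolved trace, converted analytically with :func:`noise_sd_for_snr`;
the default SNR sampling range for validation populations is 5-15, spanning
upward from the 5-sigma bouton inclusion threshold.

True event times are continuous; the truth table assigns each event to the
exposure window (frame) containing its onset. Frames sample the
fluorescence instantaneously at the frame times, and the residual
camera-phase jitter this leaves in peak amplitudes is the amplitude-noise
component sigma_AN of the quantal model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deconv import chain_gains
from .kernel import UnitaryResponse
from .movie import APTrain, Movie

SIGMA_XY_RANGE_NM = (250.0, 450.0)
SNR_RANGE = (5.0, 15.0)
DEFAULT_LAMBDA = 0.9


@dataclass(frozen=True)
class SyntheticEventSpec:
    """Ground truth for one generated release event."""

    x0: float  # nm, from the centre of the top-left pixel
    y0: float  # nm
    t0: float  # ms, continuous
    n_quanta: int = 1
    sigma_xy: float = 350.0  # nm
    dF: float = 1.0  # peak amplitude, fluorescence units
    F_BG: float = 0.0  # background level per pixel
    bouton_id: int = 0
    mode: str | None = None

    def __post_init__(self) -> None:
        if self.n_quanta < 1:
            raise ValueError("n_quanta must be >= 1")
        if self.sigma_xy <= 0:
            raise ValueError("sigma_xy must be positive")
        if self.dF < 0:
            raise ValueError("dF must be non-negative")


@dataclass
class SyntheticTruth:
    """Event list + noise metadata attached to generated data."""

    events: list[SyntheticEventSpec]
    noise_sd: float
    snr: float | None = None
    seed: int | None = None
    frame_interval: float = 4.0
    pixel_size: float = 183.3

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            rows.append(
                {
                    "bouton_id": e.bouton_id,
                    "t0_ms": e.t0,
                    "frame": int(e.t0 // self.frame_interval),
                    "x0_nm": e.x0,
                    "y0_nm": e.y0,
                    "n_quanta": e.n_quanta,
                    "mode": e.mode,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["bouton_id", "t0_ms", "frame", "x0_nm", "y0_nm", "n_quanta", "mode"],
        )

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def quantal_amplitude(q: float, lam: float, n_quanta: int) -> float:
    """Mean amplitude of an ``n``-quantum event: mu_n = q * sum lambda^(k-1).

    With lambda = 1 this is exactly ``n * q``; lambda < 1 models progressive
    sensor saturation during multi-vesicular release.
    """
    return q * float(np.sum(lam ** np.arange(n_quanta)))


def noise_sd_for_snr(
    q: float,
    snr: float,
    n_frames: int,
    kernel: UnitaryResponse,
    sampling_hz: float | None = None,
) -> float:
    """Raw-trace Gaussian noise SD that yields ``q / sigma_BN = snr``.

    Uses the analytic white-noise gain of the band-pass/deconvolution chain,
    so generator SNR and the analyzer's bouton-inclusion SNR agree by
    construction.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    fs = sampling_hz if sampling_hz is not None else 1000.0 / kernel.frame_interval
    _, c_pre, _ = chain_gains(n_frames, fs, kernel)
    return q / (snr * c_pre)


def generate_trace(
    events: list[tuple[float, int]],
    kernel: UnitaryResponse,
    duration: float,
    q: float = 1.0,
    lam: float = DEFAULT_LAMBDA,
    sigma_AN: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Simulate a single-bouton trace from a list of ``(t0_ms, n_quanta)``.

    Each event contributes ``mu_{n_quanta} * exp(-(t - t0)/tau)`` for
    t >= t0, sampled at the frame times; events at identical times sum.
    i.i.d. Gaussian noise of SD ``noise_sd`` is added on top.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if q <= 0:
        raise ValueError("quantal amplitude q must be positive")
    dt = kernel.frame_interval
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    rng = np.random.default_rng(seed)
    trace = np.zeros(n)
    specs = []
    for t0, nq in events:
        if not (0 <= t0 < duration):
            raise ValueError(f"event time {t0} outside [0, {duration})")
        amp = quantal_amplitude(q, lam, nq)
        if sigma_AN > 0:
            amp = max(amp + rng.normal(0.0, sigma_AN), 1e-12)
        live = t >= t0
        trace[live] += amp * np.exp(-(t[live] - t0) / kernel.tau)
        specs.append(
            SyntheticEventSpec(x0=0.0, y0=0.0, t0=float(t0), n_quanta=int(nq), dF=amp)
        )
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=n)
    truth = SyntheticTruth(
        events=specs, noise_sd=noise_sd, seed=seed, frame_interval=dt
    )
    return trace, truth


def _event_movie_data(
    spec: SyntheticEventSpec,
    shape: tuple[int, int],
    n_frames: int,
    pixel_size: float,
    frame_interval: float,
    tau: float,
) -> np.ndarray:
    rows, cols = shape
    y = np.arange(rows)[:, None] * pixel_size
    x = np.arange(cols)[None, :] * pixel_size
    spatial = np.exp(
        -((x - spec.x0) ** 2 + (y - spec.y0) ** 2) / (2.0 * spec.sigma_xy**2)
    )
    t = np.arange(n_frames) * frame_interval
    temporal = np.where(t >= spec.t0, np.exp(-(t - spec.t0) / tau), 0.0)
    return spec.dF * temporal[:, None, None] * spatial[None, :, :]


def generate_event_movie(
    spec: SyntheticEventSpec,
    shape: tuple[int, int] = (21, 21),
    n_frames: int = 256,
    pixel_size: float = 183.3,
    frame_interval: float = 4.0,
    tau: float = 68.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[Movie, SyntheticTruth]:
    """Movie patch of a single fusion event.

    The fluorescence follows a Gaussian-in-space (width ``sigma_xy``),
    instantaneous-rise / exponential-decay-in-time model on the pixel grid,
    on top of the constant background ``F_BG``, with additive Gaussian
    noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    data = spec.F_BG + _event_movie_data(
        spec, shape, n_frames, pixel_size, frame_interval, tau
    )
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    movie = Movie(
        data=data, pixel_size=pixel_size, frame_interval=frame_interval
    )
    truth = SyntheticTruth(
        events=[spec],
        noise_sd=noise_sd,
        seed=seed,
        frame_interval=frame_interval,
        pixel_size=pixel_size,
    )
    return movie, truth


@dataclass(frozen=True)
class BoutonReleaseParams:
    """Per-bouton release statistics used by the field generator."""

    m: int = 5  # RRP size (number of release sites)
    p_v: float = 0.1  # per-site release probability per AP
    frac_async: float = 0.25  # probability a released vesicle is asynchronous
    async_tau_ms: float = 50.0  # latency constant of asynchronous events
    sync_jitter_ms: float = 1.5  # sync latency (uniform 0..jitter after AP)


def generate_bouton_field(
    n_boutons: int,
    protocol: APTrain,
    params: BoutonReleaseParams | list[BoutonReleaseParams] | None = None,
    spacing_px: int = 20,
    q: float = 1.0,
    lam: float = DEFAULT_LAMBDA,
    sigma_xy: float = 350.0,
    noise_sd: float = 0.05,
    F_BG: float = 0.0,
    pixel_size: float = 183.3,
    frame_interval: float = 4.0,
    tau: float = 68.0,
    duration: float | None = None,
    seed: int | None = None,
    render: bool = True,
) -> tuple[Movie | None, SyntheticTruth]:
    """Full-ROI movie with several boutons releasing during a stimulus train.

    Boutons are placed on a line with ``spacing_px`` separation. Per AP and
    per site, release is Bernoulli(p_v); synchronously released vesicles of
    one AP merge into a single multi-quantum event, each asynchronous
    vesicle forms its own delayed event (exponential latency, truncated at
    the next AP). With ``render=False`` only the truth table is produced
    (for release-statistics studies with long protocols).
    """
    if params is None:
        params = BoutonReleaseParams()
    if isinstance(params, BoutonReleaseParams):
        params = [params] * n_boutons
    if len(params) != n_boutons:
        raise ValueError("need one BoutonReleaseParams per bouton")
    if duration is None:
        last = protocol.ap_times[-1] if protocol.n_ap else 0.0
        duration = last + 400.0
    n_frames = int(round(duration / frame_interval))
    margin = 12
    rows = 2 * margin + 1
    cols = margin * 2 + spacing_px * max(n_boutons - 1, 0) + 1
    rng = np.random.default_rng(seed)
    data = np.full((n_frames, rows, cols), float(F_BG)) if render else None
    specs: list[SyntheticEventSpec] = []
    for b in range(n_boutons):
        r, c = margin, margin + b * spacing_px
        if c >= cols or r >= rows:
            raise ValueError("bouton placed outside the frame")
        x0, y0 = c * pixel_size, r * pixel_size
        p = params[b]
        for ap in protocol.ap_times:
            released = rng.random(p.m) < p.p_v
            n_rel = int(released.sum())
            if n_rel == 0:
                continue
            is_async = rng.random(n_rel) < p.frac_async
            n_sync = int((~is_async).sum())
            nxt = protocol.ap_times[protocol.ap_times > ap]
            t_max = float(nxt[0]) if nxt.size else duration - frame_interval
            ev_list = []
            if n_sync:
                ev_list.append((ap + rng.uniform(0.0, p.sync_jitter_ms), n_sync, "synchronous"))
            for _ in range(int(is_async.sum())):
                lat = rng.exponential(p.async_tau_ms)
                t0 = ap + 10.0 + lat
                if t0 >= t_max:
                    continue
                ev_list.append((t0, 1, "asynchronous"))
            for t0, nq, mode in ev_list:
                if t0 >= duration:
                    continue
                spec = SyntheticEventSpec(
                    x0=x0,
                    y0=y0,
                    t0=float(t0),
                    n_quanta=nq,
                    sigma_xy=sigma_xy,
                    dF=quantal_amplitude(q, lam, nq),
                    F_BG=F_BG,
                    bouton_id=b,
                    mode=mode,
                )
                specs.append(spec)
                if render:
                    data += _event_movie_data(
                        spec, (rows, cols), n_frames, pixel_size, frame_interval, tau
                    )
    movie = None
    if render:
        if noise_sd > 0:
            data = data + rng.normal(0.0, noise_sd, size=data.shape)
        movie = Movie(data=data, pixel_size=pixel_size, frame_interval=frame_interval)
    truth = SyntheticTruth(
        events=specs,
        noise_sd=noise_sd,
        seed=seed,
        frame_interval=frame_interval,
        pixel_size=pixel_size,
    )
    return movie, truth


def save_config(path: str | Path, **config) -> None:
    """Write a generation config as JSON for provenance."""
    Path(path).write_text(json.dumps(config, indent=2, default=str))
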