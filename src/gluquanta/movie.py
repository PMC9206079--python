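"""Movie container, bouton detection and per-bouton trace extraction.

A movie is a (frames, height, width) fluorescence stack with fixed
calibration (183.3 nm/pixel, 4 ms/frame by default). Active boutons are
found on the maximal projection of the filtered stack (temporal smooth ->
band-pass -> spatial median), using a prominence criterion analogous to
ImageJ's Find Maxima, deliberately permissive: false positives from
background noise are tolerated here and culled later by quantal analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import h_maxima

from .filters import bandpass_filter, spatial_median, temporal_smooth

DEFAULT_PIXEL_SIZE_NM = 183.3
DEFAULT_FRAME_INTERVAL_MS = 4.0
TRACE_MASK_DIAMETER_PX = 5
PATCH_SIZE_PX = 21
NEIGHBOR_EXCLUSION_PX = 16


@dataclass
class Movie:
    """Fluorescence time-lapse stack with spatial/temporal calibration."""

    data: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM
    frame_interval: float = DEFAULT_FRAME_INTERVAL_MS
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be (t, y, x), got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie intensities must be finite")
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames) * self.frame_interval
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.size != self.n_frames:
                raise ValueError("frame_times length must match the number of frames")
            if np.any(np.diff(self.frame_times) <= 0):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def sampling_hz(self) -> float:
        return 1000.0 / self.frame_interval

    def save_tiff(self, path: str | Path) -> None:
        """Write the stack as a 16-bit multi-page TIFF (clipped/scaled)."""
        import tifffile

        lo, hi = self.data.min(), self.data.max()
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        tifffile.imwrite(str(path), ((self.data - lo) * scale).astype(np.uint16))

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        pixel_size: float = DEFAULT_PIXEL_SIZE_NM,
        frame_interval: float = DEFAULT_FRAME_INTERVAL_MS,
    ) -> "Movie":
        import tifffile

        return cls(
            data=tifffile.imread(str(path)).astype(float),
            pixel_size=pixel_size,
            frame_interval=frame_interval,
        )


@dataclass(frozen=True)
class APTrain:
    """Action-potential stimulus timing (ms, sorted, non-negative)."""

    ap_times: np.ndarray
    protocol_id: str = "custom"

    def __post_init__(self) -> None:
        times = np.asarray(self.ap_times, dtype=float)
        if times.size and (np.any(times < 0) or np.any(np.diff(times) <= 0)):
            raise ValueError("AP times must be sorted, distinct and non-negative")
        object.__setattr__(self, "ap_times", times)

    @property
    def n_ap(self) -> int:
        return self.ap_times.size

    @classmethod
    def train_5hz(cls, n_ap: int = 51, start_ms: float = 100.0) -> "APTrain":
        """51 APs at 5 Hz: the standard train stimulation protocol."""
        return cls(start_ms + np.arange(n_ap) * 200.0, protocol_id="5hz")

    @classmethod
    def paired_pulse(
        cls,
        n_pairs: int = 10,
        isi_ms: float = 50.0,
        inter_trial_ms: float = 10_000.0,
        start_ms: float = 100.0,
    ) -> "APTrain":
        """Pairs of APs at 20 Hz (50 ms ISI) separated by long gaps."""
        t0 = start_ms + np.arange(n_pairs) * inter_trial_ms
        times = np.sort(np.concatenate([t0, t0 + isi_ms]))
        return cls(times, protocol_id="paired")

    @classmethod
    def from_csv(cls, path: str | Path, protocol_id: str = "custom") -> "APTrain":
        df = pd.read_csv(path)
        col = "ap_time_ms" if "ap_time_ms" in df.columns else df.columns[0]
        return cls(np.sort(df[col].to_numpy(dtype=float)), protocol_id=protocol_id)


def _disc_offsets(diameter: int = TRACE_MASK_DIAMETER_PX) -> np.ndarray:
    """Pixel offsets of a disc of the given diameter on the grid."""
    r = diameter / 2.0
    half = diameter // 2
    dy, dx = np.mgrid[-half : half + 1, -half : half + 1]
    keep = dy**2 + dx**2 <= r**2
    return np.stack([dy[keep], dx[keep]], axis=1)


@dataclass(frozen=True)
class BoutonROI:
    """Detected bouton: a 5-px circular trace mask + a 21x21 analysis patch."""

    bouton_id: int
    center: tuple[int, int]  # (row, col), 0-based
    mask_diameter: int = TRACE_MASK_DIAMETER_PX
    patch_size: int = PATCH_SIZE_PX

    def mask_pixels(self, shape: tuple[int, int]) -> np.ndarray:
        px = _disc_offsets(self.mask_diameter) + np.asarray(self.center)
        if (
            px.min() < 0
            or px[:, 0].max() >= shape[0]
            or px[:, 1].max() >= shape[1]
        ):
            raise ValueError(f"bouton {self.bouton_id}: trace mask outside image bounds")
        return px

    def patch_slices(self, shape: tuple[int, int]) -> tuple[slice, slice]:
        half = self.patch_size // 2
        r, c = self.center
        if r - half < 0 or c - half < 0 or r + half >= shape[0] or c + half >= shape[1]:
            raise ValueError(f"bouton {self.bouton_id}: {self.patch_size}px patch outside bounds")
        return slice(r - half, r + half + 1), slice(c - half, c + half + 1)


def filter_stack(movie: Movie) -> Movie:
    """Apply the fixed detection filter chain: smooth -> band-pass -> median."""
    out = temporal_smooth(movie.data, axis=0)
    out = bandpass_filter(out, movie.sampling_hz, axis=0)
    out = spatial_median(out)
    return Movie(
        data=out,
        pixel_size=movie.pixel_size,
        frame_interval=movie.frame_interval,
        frame_times=movie.frame_times.copy(),
    )


def max_projection(movie: Movie) -> np.ndarray:
    return movie.data.max(axis=0)


def detect_boutons(
    movie: Movie,
    noise_tolerance: float,
    already_filtered: bool = False,
) -> list[BoutonROI]:
    """Detect active boutons on the maximal projection of the filtered stack.

    Maxima with prominence >= ``noise_tolerance`` above their surroundings
    are reported (h-maxima construction, the Find-Maxima analog). The
    tolerance should be permissive; spurious ROIs are removed downstream.
    Boutons whose 5-px trace mask would leave the image are dropped.
    """
    filtered = movie if already_filtered else filter_stack(movie)
    proj = max_projection(filtered)
    if noise_tolerance <= 0:
        raise ValueError("noise_tolerance must be positive")
    peaks = h_maxima(proj, noise_tolerance)
    labels, n = ndimage.label(peaks)
    if n == 0:
        return []
    centers = ndimage.maximum_position(proj, labels, index=range(1, n + 1))
    rois = []
    half = TRACE_MASK_DIAMETER_PX // 2
    for i, (r, c) in enumerate(sorted(centers)):
        if (
            r - half < 0
            or c - half < 0
            or r + half >= proj.shape[0]
            or c + half >= proj.shape[1]
        ):
            continue
        rois.append(BoutonROI(bouton_id=len(rois), center=(int(r), int(c))))
    return rois


def neighbor_excluded(rois: list[BoutonROI], min_dist_px: float = NEIGHBOR_EXCLUSION_PX) -> set[int]:
    """IDs of boutons closer than ``min_dist_px`` to a neighbour.

    Such boutons stay in trace/quantal analysis but are excluded from
    sub-pixel localization (their 21-px patches would overlap).
    """
    out: set[int] = set()
    centers = np.array([r.center for r in rois], dtype=float)
    for i in range(len(rois)):
        d = np.hypot(*(centers - centers[i]).T)
        d[i] = np.inf
        if np.any(d < min_dist_px):
            out.add(rois[i].bouton_id)
    return out


def extract_trace(movie: Movie, roi: BoutonROI) -> np.ndarray:
    """Mean intensity over the 5-px circular mask, one value per frame."""
    px = roi.mask_pixels(movie.shape[1:])
    return movie.data[:, px[:, 0], px[:, 1]].mean(axis=1)


def rois_to_frame(rois: list[BoutonROI]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bouton_id": [r.bouton_id for r in rois],
            "row": [r.center[0] for r in rois],
            "col": [r.center[1] for r in rois],
        }
    )
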