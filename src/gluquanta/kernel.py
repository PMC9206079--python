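"""Unitary SF-iGluSnFR response kernel.

A single vesicular release event produces a fluorescence transient with a
quasi-instantaneous rise (glutamate binding) followed by an exponential
decay (glutamate unbinding from the sensor), decay constant ``tau`` = 68 ms
for SF-iGluSnFR.A184V at room temperature. The same sampled kernel is used
by the synthetic-data generator and by the deconvolution analyzer, so the
simulation and detection models cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_TAU_MS = 68.0
DEFAULT_FRAME_INTERVAL_MS = 4.0


@dataclass(frozen=True)
class UnitaryResponse:
    """Peak-normalized sampled unitary response.

    Attributes
    ----------
    tau : float
        Decay time constant, ms.
    frame_interval : float
        Sampling interval, ms/frame.
    kernel : np.ndarray
        ``kernel[k] = exp(-k * frame_interval / tau)``; ``kernel[0] == 1``.
    """

    tau: float
    frame_interval: float
    kernel: np.ndarray = field(repr=False)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.kernel.size


def make_unitary_kernel(
    tau: float = DEFAULT_TAU_MS,
    frame_interval: float = DEFAULT_FRAME_INTERVAL_MS,
    length: int = 256,
) -> UnitaryResponse:
    """Sample the unitary response ``exp(-t/tau)`` on the frame grid.

    Parameters
    ----------
    tau : float
        Decay time constant in ms; must be positive.
    frame_interval : float
        Frame interval in ms; must be positive.
    length : int
        Number of samples (>= 1).
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if frame_interval <= 0:
        raise ValueError(f"frame_interval must be positive, got {frame_interval}")
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    k = np.arange(length, dtype=float)
    kernel = np.exp(-k * frame_interval / tau)
    return UnitaryResponse(tau=tau, frame_interval=frame_interval, kernel=kernel)
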