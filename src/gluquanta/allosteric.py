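"""Allosteric model of Ca2+ activation of vesicle fusion.

A vesicle carries five sequential Ca2+ binding sites; from the n-bound
state it fuses with rate l+ * f^n (a small basal willingness amplified
f-fold per bound ion), and unbinding is slowed by the allosteric
cooperativity factor b:

    on_n  = (5 - n) * kon * [Ca](t)
    off_n = n * koff * b^(n-1)
    fuse_n = l+ * f^n

The synchronous release probability p_s of a vesicle at a given active-zone
position is the cumulative fusion probability of this master equation
driven by the local [Ca2+](t) transient over the 10 ms window after AP
onset. Parameters ship as a data file with the published values of the
phenomenological model (kon 1e8 /M/s, koff 4000 /s, b 0.5, l+ 2e-4 /s,
f 31.3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

SYNC_WINDOW_MS = 10.0


@dataclass(frozen=True)
class AllostericParams:
    kon: float  # 1/(uM ms)
    koff: float  # 1/ms
    b: float
    l_plus: float  # 1/ms
    f: float
    n_sites: int = 5

    @classmethod
    def published(cls) -> "AllostericParams":
        path = resources.files("gluquanta.data").joinpath("allosteric_fusion.json")
        d = json.loads(path.read_text())
        d.pop("description", None)
        return cls(**d)


def _rates(params: AllostericParams):
    n = np.arange(params.n_sites + 1)
    off = n * params.koff * params.b ** np.maximum(n - 1, 0)
    fuse = params.l_plus * params.f**n
    return n, off, fuse


def _derivative(p: np.ndarray, ca: np.ndarray, params: AllostericParams, off, fuse):
    """dp/dt for state occupancies p of shape (n_pos, n_sites+2); the last
    column is the absorbing fused state."""
    ns = params.n_sites
    on = (ns - np.arange(ns + 1))[None, :] * params.kon * ca[:, None]
    states = p[:, : ns + 1]
    dp = np.zeros_like(p)
    flow_up = on[:, :-1] * states[:, :-1]  # n -> n+1
    flow_down = off[None, 1:] * states[:, 1:]  # n -> n-1
    dp[:, : ns + 1] -= (on + off[None, :] + fuse[None, :]) * states
    dp[:, 1 : ns + 1] += flow_up
    dp[:, : ns] += flow_down
    dp[:, ns + 1] = (fuse[None, :] * states).sum(axis=1)
    return dp


def allosteric_ps(
    times: np.ndarray,
    ca: np.ndarray,
    params: AllostericParams | None = None,
    window: float = SYNC_WINDOW_MS,
    dt: float = 0.002,
) -> np.ndarray:
    """Cumulative fusion probability over the synchronous window.

    Parameters
    ----------
    times : (n_t,) ms, increasing, covering [0, window] (values outside are
        clamped to the endpoints).
    ca : (n_t,) or (n_t, n_pos) local [Ca2+] in uM; must be non-negative.
    dt : RK4 integration step, ms.

    Returns p_s per position (scalar input -> scalar array of shape (1,)).
    """
    if params is None:
        params = AllostericParams.published()
    times = np.asarray(times, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if ca.ndim == 1:
        ca = ca[:, None]
    if np.any(ca < 0):
        raise ValueError("negative Ca2+ concentration")
    n_pos = ca.shape[1]
    _, off, fuse = _rates(params)
    p = np.zeros((n_pos, params.n_sites + 2))
    p[:, 0] = 1.0
    n_steps = int(round(window / dt))

    def ca_at(t: float) -> np.ndarray:
        return np.array(
            [np.interp(t, times, ca[:, j]) for j in range(n_pos)]
        ) if n_pos > 1 else np.atleast_1d(np.interp(t, times, ca[:, 0]))

    # precompute interpolated Ca on the half-step grid (vectorized)
    grid = np.arange(2 * n_steps + 1) * (dt / 2.0)
    ca_grid = np.empty((grid.size, n_pos))
    for j in range(n_pos):
        ca_grid[:, j] = np.interp(grid, times, ca[:, j])
    for s in range(n_steps):
        c0, ch, c1 = ca_grid[2 * s], ca_grid[2 * s + 1], ca_grid[2 * s + 2]
        k1 = _derivative(p, c0, params, off, fuse)
        k2 = _derivative(p + 0.5 * dt * k1, ch, params, off, fuse)
        k3 = _derivative(p + 0.5 * dt * k2, ch, params, off, fuse)
        k4 = _derivative(p + dt * k3, c1, params, off, fuse)
        p = p + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        np.clip(p, 0.0, 1.0, out=p)
    return p[:, -1].copy()


def ps_map_from_field(ca_field, params: AllostericParams | None = None) -> np.ndarray:
    """p_s at every recorded AZ position of a :class:`~gluquanta.calcium.CaField`."""
    return allosteric_ps(ca_field.times, ca_field.ca, params=params)
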