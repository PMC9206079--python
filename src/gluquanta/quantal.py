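"""Quantal analysis: quantal size, event quantization, release statistics.

The amplitudes of deconvolved release events at one bouton are modelled as
a finite mixture of 4 Gaussians whose centres follow the saturating
quantal ladder

    mu_i = sum_{k=1..i} lambda^(k-1) * mu_1,      i = 1..4

with common variance sigma^2 = sigma_BN^2 + sigma_AN^2 (baseline noise +
amplitude noise). Fitting operates on a quasi-continuous amplitude
distribution built by bootstrapping the observed amplitudes with added
bouton-specific Gaussian noise (m = 100,000 draws by default), which
removes the sensitivity of the fit to any histogram bin choice; the
bootstrap density is evaluated on a fine grid (bin width sigma_BN / 10)
and the mixture is fitted by least squares in density space.

The module also derives per-bouton release statistics: quanta per AP
(n_T = n_S + n_A), the modified paired-pulse ratio PPR = 2 N2/(N1 + N2)
(bounded in [0, 2]; 0 = pure depression, 2 = pure facilitation), the
binomial release summary P_rel = 1 - (1 - p_v)^m with n_T = m p_v, and
cell-level tercile/moving-average summaries of the asynchronous fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .deconv import ReleaseEvent
from .movie import APTrain

N_PEAKS = 4
SINGLE_QUANTUM_FACTOR = 1.25
SYNC_WINDOW_MS = 10.0
LAMBDA_BOUNDS = (0.6, 1.1)
MOVING_AVERAGE_SPAN = 20
MIN_EVENTS_PER_BOUTON = 2
MIN_BOUTONS_PER_CELL = 21


def bootstrap_histogram(
    amplitudes: np.ndarray,
    sigma_BN: float,
    m: int = 100_000,
    seed: int | None = None,
) -> np.ndarray:
    """Quasi-continuous amplitude sample: resample + add Gaussian noise.

    Each draw is a uniformly resampled observed amplitude plus
    N(0, sigma_BN) noise, i.e. the empirical amplitude distribution
    convolved with the bouton's baseline-noise Gaussian.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size == 0:
        raise ValueError("no amplitudes to bootstrap")
    if sigma_BN < 0:
        raise ValueError("sigma_BN must be >= 0")
    rng = np.random.default_rng(seed)
    draws = rng.choice(a, size=m, replace=True)
    if sigma_BN > 0:
        draws = draws + rng.normal(0.0, sigma_BN, size=m)
    return draws


def _mixture_centers(mu1: float, lam: float, n: int = N_PEAKS) -> np.ndarray:
    return mu1 * np.cumsum(lam ** np.arange(n))


def _mixture_density(x: np.ndarray, mu1, lam, sigma_AN, weights, sigma_BN) -> np.ndarray:
    mu = _mixture_centers(mu1, lam)
    sigma = np.sqrt(sigma_BN**2 + sigma_AN**2)
    out = np.zeros_like(x)
    for A, m in zip(weights, mu):
        out += A / (sigma * np.sqrt(2 * np.pi)) * np.exp(-((x - m) ** 2) / (2 * sigma**2))
    return out


@dataclass
class QuantalFit:
    """Fitted per-bouton quantal model."""

    q: float  # mu_1, quantal amplitude in deconvolved units
    lam: float  # saturation factor
    sigma_AN: float  # amplitude-noise SD
    sigma_BN: float  # baseline-noise SD (input)
    A: np.ndarray  # 4 peak weights (sum ~ 1)
    converged: bool = True
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if self.converged and self.q <= 0:
            raise ValueError("quantal size q must be positive")

    @property
    def mu(self) -> np.ndarray:
        """Peak centres mu_1 < mu_2 < mu_3 < mu_4."""
        return _mixture_centers(self.q, self.lam)

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma_BN**2 + self.sigma_AN**2))


class QuantalMixtureModel:
    """Constrained 4-Gaussian quantal mixture for one bouton's amplitudes.

    Parameters
    ----------
    amplitudes : array-like
        Detected event amplitudes (deconvolved units), >= 2 values.
    sigma_BN : float
        Baseline noise SD of the bouton's deconvolved trace.

    ``fit()`` returns a :class:`QuantalMixtureResults` carrying the
    parameter estimates, their approximate standard errors and the fit
    diagnostics; ``results.fit`` is the plain :class:`QuantalFit` record
    used downstream.
    """

    def __init__(self, amplitudes: np.ndarray, sigma_BN: float):
        self.amplitudes = np.asarray(amplitudes, dtype=float)
        if self.amplitudes.size < 2:
            raise ValueError("need >= 2 detected amplitudes")
        if sigma_BN <= 0:
            raise ValueError("sigma_BN must be positive")
        self.sigma_BN = float(sigma_BN)

    def _initial_mu1(self) -> float:
        a = self.amplitudes
        sub = a[a < 1.5 * np.median(a)]
        if sub.size == 0:
            sub = a
        # mode of a kernel-smoothed histogram of the sub-1.5*median amplitudes
        grid = np.linspace(sub.min() - self.sigma_BN, sub.max() + self.sigma_BN, 256)
        dens = np.exp(
            -((grid[:, None] - sub[None, :]) ** 2) / (2 * self.sigma_BN**2)
        ).sum(axis=1)
        return float(grid[np.argmax(dens)])

    def fit(self, m: int = 100_000, seed: int | None = None) -> "QuantalMixtureResults":
        sample = bootstrap_histogram(self.amplitudes, self.sigma_BN, m=m, seed=seed)
        bw = self.sigma_BN / 10.0
        lo = min(0.0, sample.min())
        hi = sample.max() + bw
        edges = np.arange(lo, hi + bw, bw)
        dens, edges = np.histogram(sample, bins=edges, density=True)
        x = 0.5 * (edges[:-1] + edges[1:])

        mu1_0 = max(self._initial_mu1(), 2 * self.sigma_BN)
        counts0 = np.bincount(
            np.clip(np.round(self.amplitudes / mu1_0).astype(int) - 1, 0, N_PEAKS - 1),
            minlength=N_PEAKS,
        )
        w0 = np.clip(counts0 / counts0.sum(), 1e-3, None)
        p0 = np.concatenate([[mu1_0, 0.9, self.sigma_BN / 2.0], w0])
        lb = [0.25 * mu1_0, LAMBDA_BOUNDS[0], 0.0] + [0.0] * N_PEAKS
        ub = [4.0 * mu1_0, LAMBDA_BOUNDS[1], 10.0 * self.sigma_BN] + [1.5] * N_PEAKS

        def resid(p):
            return _mixture_density(x, p[0], p[1], p[2], p[3:], self.sigma_BN) - dens

        sol = optimize.least_squares(resid, p0, bounds=(lb, ub), method="trf")
        converged = bool(sol.success) and sol.x[0] > 0
        fit = QuantalFit(
            q=float(sol.x[0]),
            lam=float(sol.x[1]),
            sigma_AN=float(sol.x[2]),
            sigma_BN=self.sigma_BN,
            A=np.asarray(sol.x[3:]),
            converged=converged,
            rss=float(np.sum(sol.fun**2)),
        )
        return QuantalMixtureResults(self, fit, sol, x, dens)


class QuantalMixtureResults:
    """Results wrapper: estimates, approximate SEs, diagnostics, summary()."""

    def __init__(self, model, fit: QuantalFit, sol, grid_x, grid_density):
        self.model = model
        self.fit = fit
        self.grid_x = grid_x
        self.grid_density = grid_density
        self.success = fit.converged
        self.nfev = sol.nfev
        # Gauss-Newton covariance approximation on the density grid
        try:
            J = sol.jac
            dof = max(grid_x.size - J.shape[1], 1)
            s2 = np.sum(sol.fun**2) / dof
            cov = s2 * np.linalg.pinv(J.T @ J)
            self.bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except Exception:  # pragma: no cover - degenerate jacobians
            self.bse = np.full(3 + N_PEAKS, np.nan)

    @property
    def params(self) -> pd.Series:
        f = self.fit
        names = ["q", "lambda", "sigma_AN"] + [f"A{i+1}" for i in range(N_PEAKS)]
        return pd.Series(np.concatenate([[f.q, f.lam, f.sigma_AN], f.A]), index=names)

    def predict(self, x: np.ndarray) -> np.ndarray:
        f = self.fit
        return _mixture_density(np.asarray(x, float), f.q, f.lam, f.sigma_AN, f.A, f.sigma_BN)

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Quantal mixture fit (4 Gaussians, saturating ladder)",
            "-" * 52,
            f"events: {self.model.amplitudes.size:>6d}    sigma_BN: {f.sigma_BN:.4g}",
            f"converged: {self.success}    RSS: {f.rss:.4g}",
            "",
            f"{'param':<10}{'estimate':>12}{'std err':>12}",
        ]
        for name, val, se in zip(self.params.index, self.params.values, self.bse):
            lines.append(f"{name:<10}{val:>12.4f}{se:>12.4f}")
        lines.append("")
        mu = ", ".join(f"{m:.3f}" for m in f.mu)
        lines.append(f"peak centres mu_1..4: {mu}")
        lines.append(f"peak SD sigma = sqrt(sigma_BN^2 + sigma_AN^2) = {f.sigma:.4f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.grid_x, self.grid_density, alpha=0.4, label="bootstrap density")
        ax.plot(self.grid_x, self.predict(self.grid_x), "k-", label="mixture fit")
        for m in self.fit.mu:
            ax.axvline(m, color="grey", ls=":", lw=0.8)
        ax.set_xlabel("deconvolved amplitude")
        ax.set_ylabel("density")
        ax.legend()
        return ax


def fit_quantal_mixture(
    amplitudes: np.ndarray,
    sigma_BN: float,
    m: int = 100_000,
    seed: int | None = None,
) -> QuantalFit:
    """Functional wrapper around :class:`QuantalMixtureModel`."""
    res = QuantalMixtureModel(amplitudes, sigma_BN).fit(m=m, seed=seed)
    if not res.success:
        warnings.warn("quantal mixture fit did not converge; bouton should be excluded")
    return res.fit


def quantize_events(events: list[ReleaseEvent], fit: QuantalFit) -> list[ReleaseEvent]:
    """Assign each event the quantal count of the nearest mixture centre.

    Decision boundaries sit at midpoints between adjacent centres (the
    maximum-likelihood rule for equal-variance Gaussians). Amplitudes above
    mu_4 + sigma are capped at 4 quanta with a warning. The single-quantum
    flag used by localization is amplitude < 1.25 q.
    """
    mu = fit.mu
    bounds = 0.5 * (mu[:-1] + mu[1:])
    capped = 0
    for e in events:
        e.n_quanta = int(np.searchsorted(bounds, e.amplitude) + 1)
        if e.amplitude > mu[-1] + fit.sigma:
            capped += 1
    if capped:
        warnings.warn(f"{capped} event(s) above mu_4 + sigma capped at 4 quanta")
    return events


def is_single_quantum(event: ReleaseEvent, fit: QuantalFit) -> bool:
    return event.amplitude < SINGLE_QUANTUM_FACTOR * fit.q


def classify_modes(
    events: list[ReleaseEvent],
    ap_train: APTrain | None,
    sync_window: float = SYNC_WINDOW_MS,
) -> list[ReleaseEvent]:
    """Label events synchronous (latency <= 10 ms), asynchronous, or
    spontaneous (no stimulation). Events preceding the first AP of a
    stimulated sweep are flagged and excluded from the release efficacies.
    """
    stimulated = ap_train is not None and ap_train.n_ap > 0
    for e in events:
        if not stimulated:
            e.mode = "spontaneous"
        elif e.flagged or e.latency is None:
            e.mode = None
        elif e.latency <= sync_window:
            e.mode = "synchronous"
        else:
            e.mode = "asynchronous"
    return events


@dataclass
class BoutonStats:
    """Per-bouton release statistics (quanta per AP unless noted)."""

    bouton_id: int
    n_T: float
    n_S: float
    n_A: float
    frac_async: float
    N1: int = 0
    N2: int = 0
    PPR: float | None = None
    spont_rate: float | None = None  # Hz
    n_events: int = 0


def _ppr(N1: int, N2: int) -> float | None:
    if N1 + N2 == 0:
        return None
    return 2.0 * N2 / (N1 + N2)


def bouton_stats(
    events: list[ReleaseEvent],
    ap_train: APTrain | None,
    duration_ms: float | None = None,
    pair_window_ms: float = 50.0,
) -> BoutonStats:
    """Release efficacies n_T / n_S / n_A, PPR and spontaneous rate.

    ``n_T`` divides the summed quanta of all mode-classified events by the
    number of APs; spontaneous events never count toward it. For
    paired-pulse protocols, N1/N2 sum the quanta assigned to first/second
    pulses; events whose latency exceeds one inter-spike interval (the
    inter-sweep gaps) keep their asynchronous label but are excluded from
    N1/N2.
    """
    bouton_id = events[0].bouton_id if events else 0
    if ap_train is None or ap_train.n_ap == 0:
        n_ev = sum(1 for e in events if e.mode == "spontaneous")
        quanta = sum(e.n_quanta or 1 for e in events if e.mode == "spontaneous")
        rate = None
        if duration_ms:
            rate = 1000.0 * n_ev / duration_ms
        return BoutonStats(
            bouton_id, 0.0, 0.0, 0.0, 0.0, spont_rate=rate, n_events=n_ev
        )
    n_ap = ap_train.n_ap
    qS = sum(e.n_quanta or 1 for e in events if e.mode == "synchronous")
    qA = sum(e.n_quanta or 1 for e in events if e.mode == "asynchronous")
    n_S, n_A = qS / n_ap, qA / n_ap
    n_T = n_S + n_A
    N1 = N2 = 0
    if ap_train.protocol_id == "paired":
        ap = ap_train.ap_times
        for e in events:
            if e.mode is None or e.latency is None or e.latency > pair_window_ms:
                continue
            k = np.searchsorted(ap, e.time, side="right") - 1
            if k < 0:
                continue
            if k % 2 == 0:
                N1 += e.n_quanta or 1
            else:
                N2 += e.n_quanta or 1
    return BoutonStats(
        bouton_id=bouton_id,
        n_T=n_T,
        n_S=n_S,
        n_A=n_A,
        frac_async=(n_A / n_T) if n_T > 0 else 0.0,
        N1=N1,
        N2=N2,
        PPR=_ppr(N1, N2),
        n_events=sum(1 for e in events if e.mode in ("synchronous", "asynchronous")),
    )


def binomial_release(p_v: float, m: int) -> tuple[float, float]:
    """Binomial release summary: P_rel = 1 - (1 - p_v)^m and n_T = m p_v."""
    if not 0.0 <= p_v <= 1.0:
        raise ValueError("p_v must lie in [0, 1]")
    if m < 1 or int(m) != m:
        raise ValueError("m must be a positive integer")
    return 1.0 - (1.0 - p_v) ** m, m * p_v


def two_vesicle_outcomes(p_sync: float = 0.5) -> dict[str, float]:
    """Exact outcome probabilities for a bouton releasing exactly 2 vesicles,
    each independently synchronous with probability ``p_sync``."""
    return {
        "both_sync": p_sync**2,
        "one_each": 2 * p_sync * (1 - p_sync),
        "both_async": (1 - p_sync) ** 2,
    }


def group_summaries(
    stats: "pd.DataFrame | list[BoutonStats]",
    min_events: int = MIN_EVENTS_PER_BOUTON,
    min_boutons: int = MIN_BOUTONS_PER_CELL,
    span: int = MOVING_AVERAGE_SPAN,
) -> dict:
    """Cell-level summary: terciles of n_T and the n_A/n_T moving average.

    Boutons with fewer than ``min_events`` events are dropped; cells with
    fewer than ``min_boutons`` eligible boutons are rejected. Boutons are
    sorted by n_T and split into three near-equal terciles (T1 low, T2
    intermediate, T3 high); the moving average of the asynchronous fraction
    uses a 20-point span over the sorted boutons.
    """
    if not isinstance(stats, pd.DataFrame):
        stats = pd.DataFrame([vars(s) for s in stats])
    df = stats[stats["n_events"] >= min_events].sort_values("n_T").reset_index(drop=True)
    n = len(df)
    if n < min_boutons:
        raise ValueError(
            f"cell excluded: only {n} boutons with >= {min_events} events "
            f"(need {min_boutons})"
        )
    sizes = [n // 3] * 3
    for i in range(n % 3):
        sizes[i] += 1
    labels = np.repeat(["T1", "T2", "T3"], sizes)
    df = df.assign(tercile=labels)
    terc = (
        df.groupby("tercile", sort=True)
        .agg(
            n_T_mean=("n_T", "mean"),
            n_T_sem=("n_T", "sem"),
            frac_async_mean=("frac_async", "mean"),
            frac_async_sem=("frac_async", "sem"),
            n=("n_T", "size"),
        )
        .reset_index()
    )
    ma = df["frac_async"].rolling(span, center=True, min_periods=max(span // 2, 1)).mean()
    rho = stats_spearman(df["n_T"].to_numpy(), df["frac_async"].to_numpy())
    return {
        "boutons": df,
        "terciles": terc,
        "moving_average": pd.DataFrame({"n_T": df["n_T"], "frac_async_ma": ma}),
        "spearman_rho": rho,
        "cell_frac_async": float(df["n_A"].sum() / df["n_T"].sum())
        if df["n_T"].sum() > 0
        else 0.0,
    }


def stats_spearman(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 3 or np.allclose(y, y[0]):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)
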