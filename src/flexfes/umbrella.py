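"""Umbrella-sampling free-energy estimation.

The pipeline mirrors standard practice for 1D potentials of mean force
(PMFs): evenly spaced harmonic windows along a collective variable (CV),
staged equilibration that walks the restraint center from a start value to
each window's target, decorrelation of the window time series through the
statistical inefficiency g, pooling of subsampled data across independent
starting conformers, and the self-consistent Weighted Histogram Analysis
Method (WHAM) with Monte-Carlo bootstrap confidence intervals.

Energies are handled in kJ/mol internally; PMFs are reported in kcal/mol,
min-shifted to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .constants import DEFAULT_TEMPERATURE, KJ_PER_KCAL, kt
from .core import CVDefinition


class ScheduleError(ValueError):
    """Invalid window schedule request."""


class DegenerateSeriesError(ValueError):
    """Time series is constant or too short for autocorrelation analysis."""


class AggregationError(ValueError):
    """Per-conformer window schedules do not match."""


class ConnectivityError(ValueError):
    """Adjacent window histograms do not overlap."""


class BootstrapError(RuntimeError):
    """Too many bootstrap trials failed."""


@dataclass(frozen=True)
class UmbrellaWindow:
    """A harmonic restraint U = 1/2 k (x - center)^2 at fixed temperature.

    center : nm; force_constant : kJ/(mol nm^2); temperature : K.
    """

    center: float
    force_constant: float
    temperature: float = DEFAULT_TEMPERATURE
    cv: Optional[CVDefinition] = None

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0 (0 = unbiased)")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    def bias_energy(self, x):
        """Bias energy at CV value(s) x, kJ/mol."""
        d = np.asarray(x, dtype=float) - self.center
        return 0.5 * self.force_constant * d * d


@dataclass
class CVSeries:
    """A sampled collective-variable time series.

    times : (n,) ns; values : (n,) nm (or (n, 2) for two CVs);
    window : the restraint under which it was sampled, if any;
    source : free-form provenance tag (conformer id, replica).
    """

    times: np.ndarray
    values: np.ndarray
    window: Optional[UmbrellaWindow] = None
    source: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape[0] != self.values.shape[0]:
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CV values must be finite")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class WHAMResult:
    """A 1D PMF with optional bootstrap confidence band (kcal/mol)."""

    bin_centers: np.ndarray
    free_energy: np.ndarray
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None
    n_iterations: int = 0
    converged: bool = False
    window_free_energies: Optional[np.ndarray] = None
    counts: Optional[np.ndarray] = None
    n_dropped: int = 0
    n_bootstrap_discarded: int = 0
    n_bootstrap_trials: int = 0


def make_window_schedule(
    interval: Sequence[float],
    n_windows: int,
    force_constant: float,
    temperature: float = DEFAULT_TEMPERATURE,
    cv: Optional[CVDefinition] = None,
) -> list[UmbrellaWindow]:
    """Evenly spaced windows over [lo, hi], endpoints included."""
    lo, hi = float(interval[0]), float(interval[1])
    if hi <= lo:
        raise ScheduleError(f"interval must satisfy hi > lo, got [{lo}, {hi}]")
    if n_windows < 2:
        raise ScheduleError("need at least 2 windows")
    centers = np.linspace(lo, hi, n_windows)
    return [
        UmbrellaWindow(float(c), force_constant, temperature, cv) for c in centers
    ]


def make_staged_equilibration(
    window: UmbrellaWindow,
    start_center: float,
    n_stages: int = 20,
    stage_length: float = 2.5,
) -> list[tuple[float, float]]:
    """Linear restraint-center schedule from ``start_center`` to the window.

    Stage i (1-based) sits at start + i/n * (target - start); the final stage
    is exactly at the target, and the total duration is n_stages *
    stage_length (ns). With the defaults (20 stages of 2.5 ns) that is 50 ns
    of equilibration per window.
    """
    if n_stages < 1:
        raise ScheduleError("need at least 1 stage")
    step = (window.center - start_center) / n_stages
    return [
        (start_center + step * (i + 1), float(stage_length))
        for i in range(n_stages)
    ]


def statistical_inefficiency(series) -> float:
    """Statistical inefficiency g of a correlated time series.

    g = 1 + 2 * sum_t (1 - t/n) * rho(t), with the normalized autocorrelation
    rho estimated per lag (unbiased normalization) and the sum truncated at
    the first negative estimate. A series of n correlated samples carries
    roughly n/g independent observations; g is clamped to >= 1.
    """
    x = np.asarray(getattr(series, "values", series), dtype=float).ravel()
    n = x.size
    if n < 10:
        raise DegenerateSeriesError(f"need at least 10 samples, got {n}")
    x = x - x.mean()
    # FFT autocovariance: acov_raw[t] = sum_i x_i x_{i+t}
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov_raw = np.fft.irfft(f * np.conj(f))[:n]
    if acov_raw[0] <= 0:
        raise DegenerateSeriesError("constant series has undefined g")
    rho = (acov_raw / (n - np.arange(n))) / (acov_raw[0] / n)
    neg = np.nonzero(rho[1:] < 0)[0]
    t_max = (neg[0] + 1) if neg.size else n
    t = np.arange(1, t_max)
    g = 1.0 + 2.0 * np.sum((1.0 - t / n) * rho[1:t_max])
    return float(max(g, 1.0))


def subsample(series: CVSeries, g: float) -> CVSeries:
    """Keep every ceil(g)-th sample starting at the first."""
    if g < 1:
        raise ValueError("g must be >= 1")
    stride = int(np.ceil(g))
    return CVSeries(
        times=series.times[::stride],
        values=series.values[::stride],
        window=series.window,
        source=series.source,
    )


def _windows_match(a: UmbrellaWindow, b: UmbrellaWindow, tol: float = 1e-9) -> bool:
    return (
        abs(a.center - b.center) <= tol
        and abs(a.force_constant - b.force_constant) <= tol
        and abs(a.temperature - b.temperature) <= tol
    )


def aggregate_conformers(
    per_source: Sequence[Sequence[CVSeries]],
) -> list[CVSeries]:
    """Pool per-window series across sources sharing one window schedule.

    Each element of ``per_source`` is one conformer's (or replica's) list of
    window series, all in the same window order. Returns one pooled series
    per window with concatenated samples and a union source tag.
    """
    if not per_source:
        raise AggregationError("no sources to aggregate")
    ref = per_source[0]
    pooled = []
    for w_idx in range(len(ref)):
        win = ref[w_idx].window
        times, values, tags = [], [], []
        for s_idx, source in enumerate(per_source):
            if len(source) != len(ref):
                raise AggregationError(
                    f"source {s_idx} has {len(source)} windows, expected {len(ref)}"
                )
            s = source[w_idx]
            if win is None or s.window is None or not _windows_match(s.window, win):
                raise AggregationError(
                    f"window {w_idx}: schedule mismatch between source 0 and "
                    f"source {s_idx}"
                )
            times.append(s.times)
            values.append(s.values)
            if s.source:
                tags.append(s.source)
        pooled.append(
            CVSeries(
                times=np.concatenate(times),
                values=np.concatenate(values),
                window=win,
                source="+".join(dict.fromkeys(tags)),
            )
        )
    return pooled


def wham_from_histograms(
    counts: np.ndarray,
    bias: np.ndarray,
    temperature: float,
    tolerance: float = 1e-6,
    max_iterations: int = 100_000,
    f_init: Optional[np.ndarray] = None,
):
    """Self-consistent WHAM iteration on precomputed histograms.

    counts : (K, B) per-window bin counts; bias : (K, B) window bias energies
    at the bin centers, kJ/mol; tolerance in kcal/mol on the window free
    energies f_k.

    Returns (free_energy_kcal (B,), f_window_kcal (K,), n_iter, converged,
    log_p (B,) unnormalized). The PMF is -kT ln p_b, min-shifted; empty bins
    give +inf.
    """
    counts = np.asarray(counts, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if counts.shape != bias.shape:
        raise ValueError("counts and bias must have equal (K, B) shapes")
    kT = kt(temperature)
    tol_kj = tolerance * KJ_PER_KCAL
    n_k = counts.sum(axis=1)
    if np.any(n_k == 0):
        empty = np.nonzero(n_k == 0)[0]
        raise ConnectivityError(f"windows {empty.tolist()} have no samples in range")
    with np.errstate(divide="ignore"):
        log_nb = np.log(counts.sum(axis=0))
        log_nk = np.log(n_k)
    c_kb = -bias / kT
    f = np.zeros(counts.shape[0]) if f_init is None else np.array(f_init, dtype=float)

    # The WHAM equations are the stationarity conditions of a convex
    # likelihood in the reduced window free energies g = f/kT; minimizing it
    # directly converges orders of magnitude faster than fixed-point
    # iteration when window overlap is thin. The self-consistent iteration
    # below then certifies convergence against `tolerance`.
    m_b = counts.sum(axis=0)
    occ = m_b > 0

    def objective(g):
        a = log_nk[:, None] + g[:, None] + c_kb[:, occ]
        lse = logsumexp(a, axis=0)
        phi = -(n_k * g).sum() + (m_b[occ] * lse).sum()
        w = np.exp(a - lse)
        grad = -n_k + (m_b[occ] * w).sum(axis=1)
        return phi, grad

    from scipy.optimize import minimize

    opt = minimize(objective, f / kT, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10})
    f = (opt.x - opt.x[0]) * kT

    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        denom = logsumexp(log_nk[:, None] + f[:, None] / kT + c_kb, axis=0)
        log_p = log_nb - denom
        f_new = -kT * logsumexp(log_p[None, :] + c_kb, axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol_kj:
            converged = True
            break
    with np.errstate(invalid="ignore"):
        fe = -kT * log_p / KJ_PER_KCAL
    finite = np.isfinite(fe)
    if finite.any():
        fe = fe - fe[finite].min()
    return fe, f / KJ_PER_KCAL, it, converged, log_p


class WHAM(BaseEstimator):
    """Weighted Histogram Analysis Method estimator for 1D PMFs.

    Parameters
    ----------
    cv_range : (lo, hi), nm
        Histogram support. Samples outside are dropped (counted in
        ``n_dropped_``); the analysis range may legitimately differ from the
        sampling range.
    n_bins : int, default 40
        Evenly spaced bins over ``cv_range``; half-open [edge, edge) with the
        final bin closed.
    temperature : float, K
    tolerance : float, kcal/mol
        Convergence threshold on the change of the window free energies.
    max_iterations : int
    refine : int, default 10
        Internal histogram refinement. The self-consistent equations are
        solved on ``n_bins * refine`` fine bins, and the fine-bin
        probabilities are summed into the ``n_bins`` output bins. With stiff
        springs the bias varies by several kT across one output bin;
        resolving the histogram at the scale of the window width removes the
        resulting discretization error while the reported PMF stays on the
        requested grid. Set to 1 to iterate directly on the output bins.
    bias_quadrature : int, default 8
        Gauss–Legendre points used to bin-average the Boltzmann factor of
        each window bias on the internal grid (effective bias
        U_eff = -kT ln <exp(-U/kT)>_bin). 1 = plain bin-center evaluation.

    Attributes (after :meth:`fit`)
    ------------------------------
    bin_centers_, bin_edges_, free_energy_ (kcal/mol, min = 0),
    window_free_energies_ (kcal/mol), counts_ (K, B), n_iter_, converged_,
    n_dropped_.
    """

    def __init__(
        self,
        cv_range=None,
        n_bins: int = 40,
        temperature: float = DEFAULT_TEMPERATURE,
        tolerance: float = 1e-6,
        max_iterations: int = 100_000,
        refine: int = 10,
        bias_quadrature: int = 8,
    ):
        self.cv_range = cv_range
        self.n_bins = n_bins
        self.temperature = temperature
        self.tolerance = tolerance
        self.max_iterations = max_iterations
        self.refine = refine
        self.bias_quadrature = bias_quadrature

    def _effective_bias(self, windows, centers, width):
        """Per-window effective bias at each bin, kJ/mol (bin-averaged
        Boltzmann factor via Gauss–Legendre quadrature)."""
        if self.bias_quadrature <= 1:
            return np.stack([w.bias_energy(centers) for w in windows])
        kT = kt(self.temperature)
        nodes, wts = np.polynomial.legendre.leggauss(self.bias_quadrature)
        xs = centers[:, None] + 0.5 * width * nodes[None, :]  # (B, Q)
        out = np.empty((len(windows), centers.size))
        for k, w in enumerate(windows):
            u = w.bias_energy(xs)
            u0 = u.min(axis=1, keepdims=True)
            mean_boltz = 0.5 * np.sum(wts * np.exp(-(u - u0) / kT), axis=1)
            out[k] = u0[:, 0] - kT * np.log(mean_boltz)
        return out

    def _histograms(self, windows, data):
        """Per-window histograms on the fine internal grid."""
        lo, hi = map(float, self.cv_range)
        if hi <= lo or self.n_bins < 2:
            raise ValueError("need hi > lo and n_bins >= 2")
        n_fine = self.n_bins * max(int(self.refine), 1)
        edges = np.linspace(lo, hi, n_fine + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = np.zeros((len(windows), n_fine))
        dropped = 0
        for k, series in enumerate(data):
            v = np.asarray(series.values, dtype=float).ravel()
            inside = (v >= lo) & (v <= hi)
            dropped += int((~inside).sum())
            counts[k], _ = np.histogram(v[inside], bins=edges)
        return edges, centers, counts, dropped

    def _aggregate_free_energy(self, log_p_fine):
        """Sum fine-bin probabilities into output bins; PMF in kcal/mol."""
        refine = max(int(self.refine), 1)
        kT = kt(self.temperature)
        log_pc = logsumexp(log_p_fine.reshape(self.n_bins, refine), axis=1)
        with np.errstate(invalid="ignore"):
            fe = -kT * log_pc / KJ_PER_KCAL
        finite = np.isfinite(fe)
        if finite.any():
            fe = fe - fe[finite].min()
        return fe

    @staticmethod
    def _check_connectivity(counts):
        occupied = [np.nonzero(row > 0)[0] for row in counts]
        for k in range(len(occupied) - 1):
            a, b = occupied[k], occupied[k + 1]
            lo_b, hi_a = b.min(), a.max()
            lo_a, hi_b = a.min(), b.max()
            # occupied bin ranges must overlap or be adjacent
            if lo_b > hi_a + 1 or lo_a > hi_b + 1:
                raise ConnectivityError(
                    f"histogram gap between windows {k} and {k + 1} "
                    f"(bins {hi_a}..{lo_b})"
                )

    def fit(self, X, y=None, windows=None, f_init=None):
        """Fit on a list of per-window :class:`CVSeries`.

        X : sequence of CVSeries, one per window, ordered like ``windows``.
        windows : sequence of UmbrellaWindow; taken from ``series.window``
            when omitted.
        """
        data = list(X)
        if windows is None:
            windows = [s.window for s in data]
            if any(w is None for w in windows):
                raise ValueError("series without attached windows; pass windows=")
        if len(windows) != len(data):
            raise ValueError("one series per window required")
        if self.cv_range is None:
            raise ValueError("cv_range must be set")
        # sort by window center so the connectivity check walks the CV axis
        order = np.argsort([w.center for w in windows])
        windows = [windows[i] for i in order]
        data = [data[i] for i in order]

        refine = max(int(self.refine), 1)
        fine_edges, fine_centers, fine_counts, dropped = self._histograms(
            windows, data
        )
        counts = fine_counts.reshape(len(windows), self.n_bins, refine).sum(axis=2)
        if np.any(counts.sum(axis=1) == 0):
            empty = np.nonzero(counts.sum(axis=1) == 0)[0]
            raise ConnectivityError(
                f"windows at centers "
                f"{[round(windows[i].center, 4) for i in empty]} have no "
                f"samples in range {tuple(self.cv_range)}"
            )
        self._check_connectivity(counts)
        bias = self._effective_bias(
            windows, fine_centers, fine_edges[1] - fine_edges[0]
        )
        _, f_win, n_iter, converged, log_p = wham_from_histograms(
            fine_counts,
            bias,
            self.temperature,
            self.tolerance,
            self.max_iterations,
            f_init=f_init,
        )
        fe = self._aggregate_free_energy(log_p)
        if not converged:
            warnings.warn(
                f"WHAM did not converge in {self.max_iterations} iterations",
                RuntimeWarning,
            )
        self.windows_ = windows
        self.bin_edges_ = np.linspace(*map(float, self.cv_range), self.n_bins + 1)
        self.bin_centers_ = 0.5 * (self.bin_edges_[:-1] + self.bin_edges_[1:])
        self.counts_ = counts
        self.fine_counts_ = fine_counts
        self.bias_ = bias
        self.free_energy_ = fe
        self.window_free_energies_ = f_win
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_dropped_ = dropped
        return self

    def result(self) -> WHAMResult:
        return WHAMResult(
            bin_centers=self.bin_centers_,
            free_energy=self.free_energy_,
            n_iterations=self.n_iter_,
            converged=self.converged_,
            window_free_energies=self.window_free_energies_,
            counts=self.counts_,
            n_dropped=self.n_dropped_,
        )


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    data: Sequence[CVSeries],
    cv_range,
    n_bins: int = 40,
    tolerance: float = 1e-6,
    max_iterations: int = 100_000,
    temperature: Optional[float] = None,
    refine: int = 10,
    bias_quadrature: int = 8,
) -> WHAMResult:
    """Solve the WHAM equations for one pooled window dataset."""
    if temperature is None:
        temperature = windows[0].temperature
    est = WHAM(
        cv_range=cv_range,
        n_bins=n_bins,
        temperature=temperature,
        tolerance=tolerance,
        max_iterations=max_iterations,
        refine=refine,
        bias_quadrature=bias_quadrature,
    ).fit(data, windows=windows)
    return est.result()


def bootstrap_pmf(
    windows: Sequence[UmbrellaWindow],
    data: Sequence[CVSeries],
    cv_range,
    n_bins: int = 40,
    n_trials: int = 100,
    seed: Optional[int] = None,
    tolerance: float = 1e-6,
    max_iterations: int = 100_000,
    temperature: Optional[float] = None,
) -> WHAMResult:
    """Monte-Carlo bootstrap 95% confidence band for a WHAM PMF.

    Each trial resamples, within every window, the decorrelated samples with
    replacement (equivalently: a multinomial redraw of the window histogram
    including its out-of-range mass), re-solves WHAM warm-started from the
    point estimate, and min-shifts the trial PMF. The band is the 2.5/97.5
    percentile envelope; trials that lose window connectivity are discarded
    (an error is raised if more than 20% are).
    """
    if temperature is None:
        temperature = windows[0].temperature
    est = WHAM(
        cv_range=cv_range,
        n_bins=n_bins,
        temperature=temperature,
        tolerance=tolerance,
        max_iterations=max_iterations,
    ).fit(data, windows=windows)
    f_point_kj = est.window_free_energies_ * KJ_PER_KCAL

    rng = np.random.default_rng(seed)
    fine_counts = est.fine_counts_
    refine = max(int(est.refine), 1)
    n_windows = len(est.windows_)
    n_total = np.array(
        [len(np.asarray(s.values).ravel()) for s in [data[i] for i in
         np.argsort([w.center for w in windows])]],
        dtype=float,
    )
    # per-window category probabilities: fine bins + one out-of-range category
    n_out = n_total - fine_counts.sum(axis=1)
    probs = np.concatenate([fine_counts, n_out[:, None]], axis=1) / n_total[:, None]

    trials = []
    discarded = 0
    for _ in range(n_trials):
        c = np.stack(
            [rng.multinomial(int(n_total[k]), probs[k])[:-1] for k in range(n_windows)]
        ).astype(float)
        try:
            coarse = c.reshape(n_windows, est.n_bins, refine).sum(axis=2)
            if np.any(coarse.sum(axis=1) == 0):
                raise ConnectivityError("empty window in bootstrap trial")
            WHAM._check_connectivity(coarse)
            _, _, _, _, log_p = wham_from_histograms(
                c,
                est.bias_,
                temperature,
                tolerance,
                max_iterations,
                f_init=f_point_kj,
            )
        except ConnectivityError:
            discarded += 1
            continue
        trials.append(est._aggregate_free_energy(log_p))
    if discarded > 0.2 * n_trials:
        raise BootstrapError(
            f"{discarded}/{n_trials} bootstrap trials lost connectivity"
        )
    if len(trials) == 1:
        warnings.warn(
            "bootstrap with a single trial gives a degenerate zero-width CI",
            RuntimeWarning,
        )
    trials_arr = np.array(trials)
    ci_low = np.percentile(trials_arr, 2.5, axis=0)
    ci_high = np.percentile(trials_arr, 97.5, axis=0)
    if len(trials) > 1:
        # the band brackets the point estimate (except the degenerate
        # single-trial case, which is a zero-width band by construction)
        ci_low = np.minimum(ci_low, est.free_energy_)
        ci_high = np.maximum(ci_high, est.free_energy_)
    return WHAMResult(
        bin_centers=est.bin_centers_,
        free_energy=est.free_energy_,
        ci_low=ci_low,
        ci_high=ci_high,
        n_iterations=est.n_iter_,
        converged=est.converged_,
        window_free_energies=est.window_free_energies_,
        counts=est.counts_,
        n_dropped=est.n_dropped_,
        n_bootstrap_discarded=discarded,
        n_bootstrap_trials=n_trials,
    )
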