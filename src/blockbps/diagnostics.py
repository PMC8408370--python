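"""Discretization of trajectories and mixing diagnostics.

The continuous trajectory is piecewise linear, so sampling it on a regular
grid of spacing ``delta`` is exact interpolation, not quadrature.  The
diagnostics are the usual ones for comparing samplers on smoothing problems:
mean squared jumping distance of a coordinate, running mean-square error
against exact smoothing means, autocorrelation-based effective sample size,
and the log-posterior trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .engine import TrajectorySkeleton
from .errors import ParameterError, ShapeError
from .models import PotentialModel

__all__ = [
    "DiscretizedChain",
    "discretize_trajectory",
    "mean_square_jump_distance",
    "mse_vs_reference",
    "autocorrelation",
    "ess",
    "ess_batch_means",
    "mcse_mean",
    "mcse_var",
    "log_posterior_trace",
]

DEFAULT_BURN_IN = 0.25  # fraction of samples discarded by default


@dataclass
class DiscretizedChain:
    """Regularly thinned samples of a trajectory.

    ``samples`` has shape (n, d, N); ``times[j] = j * delta``.
    """

    times: np.ndarray
    samples: np.ndarray
    delta: float

    def __len__(self) -> int:
        return self.samples.shape[0]

    def coordinate(self, k: int, n: int) -> np.ndarray:
        """1-d series of spatial row k, time column n (0-based)."""
        return self.samples[:, k, n]

    def burn(self, fraction: float = DEFAULT_BURN_IN) -> "DiscretizedChain":
        cut = int(len(self) * fraction)
        return DiscretizedChain(
            times=self.times[cut:], samples=self.samples[cut:], delta=self.delta
        )


def discretize_trajectory(
    skeleton: TrajectorySkeleton, delta: float, phi: np.ndarray | None = None
) -> DiscretizedChain:
    """Sample the trajectory at t_j = j * delta by exact linear interpolation.

    The slope of each piece is phi * v, taken from the skeleton; the last
    partial interval beyond the final grid point is dropped.
    """
    if delta <= 0:
        raise ParameterError("delta must be positive")
    if phi is not None and phi.shape != skeleton.phi.shape:
        raise ShapeError("phi override has the wrong shape")
    n_samples = int(np.floor(skeleton.horizon / delta + 1e-12)) + 1
    times = np.arange(n_samples) * delta
    d, N = skeleton.x0.shape
    out = np.empty((n_samples, d, N))
    j = 0
    for t0, t1, x, u in skeleton.segments():
        while j < n_samples and times[j] <= t1 + 1e-12:
            out[j] = x + (times[j] - t0) * u
            j += 1
        if j >= n_samples:
            break
    return DiscretizedChain(times=times, samples=out, delta=delta)


def mean_square_jump_distance(
    chain: DiscretizedChain,
    coordinate: tuple[int, int],
    burn_in: float = DEFAULT_BURN_IN,
) -> float:
    """Average squared successive difference of one coordinate after burn-in."""
    series = chain.burn(burn_in).coordinate(*coordinate)
    if series.size < 2:
        raise ParameterError("need at least 2 samples after burn-in")
    return float(np.mean(np.diff(series) ** 2))


def mse_vs_reference(
    chain: DiscretizedChain,
    reference_means: np.ndarray,
    burn_in: float = 0.0,
) -> np.ndarray:
    """Squared error of the running posterior-mean estimate, averaged over
    all d*N coordinates, as a time series (one value per retained sample)."""
    samples = chain.burn(burn_in).samples
    ref = np.asarray(reference_means, dtype=float)
    if samples.shape[1:] != ref.shape:
        raise ShapeError(
            f"reference shape {ref.shape} does not match samples {samples.shape[1:]}"
        )
    running = np.cumsum(samples, axis=0) / np.arange(1, len(samples) + 1)[:, None, None]
    return ((running - ref) ** 2).mean(axis=(1, 2))


def autocorrelation(series: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Empirical autocorrelation via FFT (lag 0 .. max_lag)."""
    x = np.asarray(series, dtype=float)
    n = x.size
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        raise ParameterError("constant series has no autocorrelation")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    acf = acov / acov[0]
    if max_lag is not None:
        acf = acf[: max_lag + 1]
    return acf


def ess(series: np.ndarray) -> float:
    """Effective sample size with initial-positive-sequence truncation.

    n / (1 + 2 sum rho_k), summing paired autocorrelations
    Gamma_m = rho_{2m} + rho_{2m+1} while they remain positive; the result
    is clipped to (0, n].  A (numerically) constant chain is reported as 0
    with a warning.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 50:
        raise ParameterError("need at least 50 samples for an ESS estimate")
    if np.ptp(x) == 0 or np.var(x) < 1e-300:
        warnings.warn("constant chain: ESS reported as 0", RuntimeWarning)
        return 0.0
    acf = autocorrelation(x)
    # initial positive sequence on paired sums
    s = 0.0
    m = 0
    while 2 * m + 1 < n:
        gamma = acf[2 * m] + acf[2 * m + 1]
        if gamma <= 0:
            break
        s += gamma
        m += 1
    tau = max(2.0 * s - 1.0, 1.0 / n)  # = 1 + 2 sum_{k>=1} rho_k with rho_0 = 1
    return float(min(n / tau, n))


def ess_batch_means(series: np.ndarray, n_batches: int = 30) -> float:
    """Batch-means ESS: n * Var(x) / (B * Var(batch means)); cross-check
    estimator for :func:`ess`."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2 * n_batches:
        raise ParameterError("series too short for the requested batches")
    B = n // n_batches
    means = x[: B * n_batches].reshape(n_batches, B).mean(axis=1)
    var_bm = means.var(ddof=1)
    if var_bm == 0:
        warnings.warn("constant batch means: ESS reported as 0", RuntimeWarning)
        return 0.0
    # Var(mean of batch) ~ sigma_chain^2 / B_eff  =>  ESS = n_batches * s^2 / var_bm
    return float(min(x.var(ddof=1) / var_bm * n_batches, n))


def mcse_mean(series: np.ndarray) -> float:
    """Monte-Carlo standard error of the chain mean (ESS-based)."""
    x = np.asarray(series, dtype=float)
    n_eff = ess(x)
    if n_eff == 0:
        return np.inf
    return float(np.std(x, ddof=1) / np.sqrt(n_eff))


def mcse_var(series: np.ndarray) -> float:
    """Monte-Carlo standard error of the chain marginal-variance estimate,
    obtained by applying the mean MCSE to the centred squares."""
    x = np.asarray(series, dtype=float)
    return mcse_mean((x - x.mean()) ** 2)


def log_posterior_trace(
    model: PotentialModel, chain: DiscretizedChain
) -> np.ndarray:
    """-U evaluated at every thinned sample."""
    return np.array([-model.potential(s) for s in chain.samples])
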