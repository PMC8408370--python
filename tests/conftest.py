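import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import blockbps as bb

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


class LGSSMCase:
    """A linear-Gaussian smoothing problem with its exact oracle."""

    def __init__(self, d, N, sigma2=5.0, psi=0.1, data_seed=123):
        self.params = bb.LGSSMParams(d=d, N=N, sigma2=sigma2, psi=psi)
        self.x_true, self.y = bb.simulate_lgssm(self.params, data_seed)
        self.model = bb.LinearGaussianSSM(self.params, self.y)
        self.means, self.covs = bb.kalman_rts_smoother(self.params, self.y)
        self.marginal_var = np.array(
            [np.diag(self.covs[n]) for n in range(N)]
        ).T

    @property
    def shape(self):
        return (self.params.d, self.params.N)


@pytest.fixture(scope="session")
def lgssm_3x50():
    """The d=3, N=50 AR(1) smoothing problem used for stationarity checks."""
    return LGSSMCase(d=3, N=50)


@pytest.fixture(scope="session")
def lgssm_2x20():
    return LGSSMCase(d=2, N=20)


def obm_se(series, batch=1000):
    """Overlapping-batch-means standard error of the series mean."""
    x = np.asarray(series, dtype=float)
    n = x.size
    batch = min(batch, n // 4)
    c = np.cumsum(np.concatenate([[0.0], x]))
    bm = (c[batch:] - c[:-batch]) / batch
    v = np.sum((bm - x.mean()) ** 2) * batch / ((n - batch) * (n - batch + 1))
    return float(np.sqrt(v))


def smooth_se(se, window=9):
    """Temporal smoothing of per-coordinate squared SEs (d x N array)."""
    se2 = np.asarray(se, dtype=float) ** 2
    pad = window // 2
    padded = np.pad(se2, ((0, 0), (pad, pad)), mode="edge")
    kernel = np.ones(window) / window
    out = np.array([np.convolve(row, kernel, "valid") for row in padded])
    return np.sqrt(out)


def chain_moment_z(chain, means, marginal_var, batch=1000, window=9):
    """Per-coordinate z-scores of chain means and variances vs an oracle.

    Returns (z_mean, z_var), each d x N, using OBM standard errors smoothed
    along the temporal axis.
    """
    d, N = means.shape
    se_m = np.empty((d, N))
    se_v = np.empty((d, N))
    for k in range(d):
        for n in range(N):
            s = chain.samples[:, k, n]
            se_m[k, n] = obm_se(s, batch)
            se_v[k, n] = obm_se((s - s.mean()) ** 2, batch)
    se_m = smooth_se(se_m, window)
    se_v = smooth_se(se_v, window)
    z_mean = np.abs(chain.samples.mean(axis=0) - means) / se_m
    z_var = np.abs(chain.samples.var(axis=0, ddof=1) - marginal_var) / se_v
    return z_mean, z_var
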