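"""Potential-energy models for differentiable state-space smoothing.

The latent state is a d x N real matrix ``x`` (rows = spatial dimensions,
columns = time).  A model exposes the potential U(x) = -log p(x | y) — the
negative log joint density of the latent states given the observations,
including all normalization constants — and its gradient as a d x N matrix
map.  Two concrete models are provided:

* :class:`LinearGaussianSSM` — the AR(1) Gaussian model with a kernel
  autoregressive matrix, identity state/observation noise and x_1 ~ N(0, I).
  Exact smoothing oracles (Kalman/RTS and a dense joint-Gaussian solve) are
  included for validating sampler stationarity.
* :class:`StochasticVolatilitySSM` — a heavy-tailed stochastic volatility
  model with leverage: log-volatilities follow a diagonal AR(1), returns are
  scaled by Gamma mixing variables (t-distributed marginals), and negative
  cross-covariance between state and observation noise produces the leverage
  effect.  Inference conditions on the mixing variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .blocking import Block
from .errors import NumericalConditioningError, ParameterError, ShapeError

__all__ = [
    "PotentialModel",
    "LGSSMParams",
    "SVParams",
    "SVDataset",
    "LinearGaussianSSM",
    "StochasticVolatilitySSM",
    "build_ar_matrix",
    "lgssm_potential",
    "lgssm_grad",
    "simulate_lgssm",
    "kalman_rts_smoother",
    "lgssm_joint_precision",
    "dense_gaussian_smoother",
    "sample_lgssm_posterior",
    "sv_potential",
    "sv_grad",
    "simulate_sv",
    "as_state_matrix",
]

_LOG_2PI = math.log(2.0 * math.pi)


def as_state_matrix(x, d: int, N: int) -> np.ndarray:
    """Validate and return ``x`` as a float (d, N) array with finite entries."""
    x = np.asarray(x, dtype=float)
    if x.shape != (d, N):
        raise ShapeError(f"expected state matrix of shape ({d}, {N}), got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ShapeError("state matrix contains non-finite entries")
    return x


class PotentialModel:
    """Interface of a differentiable smoothing target.

    Subclasses define ``potential`` (U) and ``grad`` (the d x N gradient
    matrix map).  ``quadratic`` declares that U is a quadratic form in x, in
    which case ``grad_linear`` must implement the linear part of the gradient
    (grad(x + w) - grad(x), independent of x) and the event engines use exact
    endpoint rate bounds.  ``grad_temporal_reach`` is the number of columns
    beyond a block's temporal range that its gradient depends on (1 for
    Markovian transitions); the engines use it to decide which rate bounds a
    reflection invalidates.
    """

    d: int
    N: int
    quadratic: bool = False
    grad_temporal_reach: int = 1

    def potential(self, x: np.ndarray) -> float:
        raise NotImplementedError

    def grad(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def grad_linear(self, w: np.ndarray) -> np.ndarray:
        raise NotImplementedError(
            "grad_linear is only defined for quadratic potentials"
        )

    def block_grad(self, x: np.ndarray, block: Block) -> np.ndarray:
        """Submatrix of the gradient for one block (index identity)."""
        return self.grad(x)[block.slices]


# ---------------------------------------------------------------------------
# Linear-Gaussian AR(1) model
# ---------------------------------------------------------------------------


def build_ar_matrix(d: int, sigma2: float, psi: float) -> np.ndarray:
    """Kernel autoregressive matrix A_ij = kern(i,j) / (psi + sum_l kern(i,l))
    with kern(i,j) = exp(-|i-j|^2 / (2 sigma2)).

    Entries are strictly positive and every row sums to less than one, so the
    latent AR(1) process is stable.
    """
    if d < 1:
        raise ParameterError("d must be >= 1")
    if sigma2 <= 0:
        raise ParameterError("sigma2 must be positive")
    if psi <= 0:
        raise ParameterError("psi must be positive")
    idx = np.arange(d, dtype=float)
    kern = np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2.0 * sigma2))
    return kern / (psi + kern.sum(axis=1, keepdims=True))


@dataclass(frozen=True)
class LGSSMParams:
    """Linear-Gaussian AR(1) model: x_n = A x_{n-1} + eta_n, y_n = x_n + eps_n.

    State and observation noise are standard normal; x_1 ~ N(0, I_d); A is
    derived from the squared-exponential kernel bandwidth ``sigma2`` and the
    normalization constant ``psi``.
    """

    d: int
    N: int
    sigma2: float
    psi: float

    def __post_init__(self) -> None:
        if self.d < 1 or self.N < 1:
            raise ParameterError("d and N must be >= 1")
        if self.sigma2 <= 0 or self.psi <= 0:
            raise ParameterError("sigma2 and psi must be positive")

    @cached_property
    def A(self) -> np.ndarray:
        return build_ar_matrix(self.d, self.sigma2, self.psi)


def lgssm_potential(params: LGSSMParams, y: np.ndarray, x: np.ndarray) -> float:
    """U(x) = -log p(x, y) for the AR(1) Gaussian model, constants included.

    U = 1/2 ||x_1||^2 + 1/2 sum_n ||x_n - A x_{n-1}||^2
      + 1/2 sum_n ||y_n - x_n||^2 + d N log(2 pi).
    """
    d, N = params.d, params.N
    x = as_state_matrix(x, d, N)
    y = as_state_matrix(y, d, N)
    r = x[:, 1:] - params.A @ x[:, :-1]
    quad = 0.5 * (
        float(x[:, 0] @ x[:, 0]) + float((r * r).sum()) + float(((y - x) ** 2).sum())
    )
    return quad + d * N * _LOG_2PI


def lgssm_grad(params: LGSSMParams, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`lgssm_potential` (d x N matrix)."""
    d, N = params.d, params.N
    x = as_state_matrix(x, d, N)
    y = as_state_matrix(y, d, N)
    A = params.A
    g = x - y
    g[:, 0] += x[:, 0]
    if N > 1:
        r = x[:, 1:] - A @ x[:, :-1]
        g[:, 1:] += r
        g[:, :-1] -= A.T @ r
    return g


class LinearGaussianSSM(PotentialModel):
    """Smoothing target of the AR(1) Gaussian model for fixed observations."""

    quadratic = True

    def __init__(self, params: LGSSMParams, y: np.ndarray):
        self.params = params
        self.d, self.N = params.d, params.N
        self.y = as_state_matrix(y, self.d, self.N)

    def potential(self, x: np.ndarray) -> float:
        return lgssm_potential(self.params, self.y, x)

    def grad(self, x: np.ndarray) -> np.ndarray:
        return lgssm_grad(self.params, self.y, x)

    def grad_linear(self, w: np.ndarray) -> np.ndarray:
        # grad is affine in x with the observation entering only additively,
        # so the linear part is the gradient at y = 0.
        d, N = self.d, self.N
        w = np.asarray(w, dtype=float)
        A = self.params.A
        g = w.copy()
        g[:, 0] += w[:, 0]
        if N > 1:
            r = w[:, 1:] - A @ w[:, :-1]
            g[:, 1:] += r
            g[:, :-1] -= A.T @ r
        return g


def simulate_lgssm(params: LGSSMParams, seed) -> tuple[np.ndarray, np.ndarray]:
    """Draw (x_true, y) from the AR(1) Gaussian model.

    ``seed`` may be an int, a Generator or a SeedSequence.
    """
    rng = np.random.default_rng(seed)
    d, N = params.d, params.N
    A = params.A
    x = np.empty((d, N))
    x[:, 0] = rng.standard_normal(d)
    for n in range(1, N):
        x[:, n] = A @ x[:, n - 1] + rng.standard_normal(d)
    y = x + rng.standard_normal((d, N))
    return x, y


def kalman_rts_smoother(
    params: LGSSMParams, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact smoothing means and marginal covariances of p(x_n | y_{1:N}).

    Standard Kalman filter followed by the Rauch-Tung-Striebel backward
    recursion.  Returns ``(means, covs)`` with shapes (d, N) and (N, d, d).
    """
    d, N = params.d, params.N
    y = as_state_matrix(y, d, N)
    A = params.A
    I = np.eye(d)

    m_filt = np.empty((N, d))
    P_filt = np.empty((N, d, d))
    m_pred = np.empty((N, d))
    P_pred = np.empty((N, d, d))

    m, P = np.zeros(d), I.copy()
    for n in range(N):
        if n > 0:
            m = A @ m
            P = A @ P @ A.T + I
        m_pred[n], P_pred[n] = m, P
        S = P + I
        try:
            cS = cho_factor(S, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise NumericalConditioningError(
                f"innovation covariance not PD at step {n}"
            ) from exc
        K = cho_solve(cS, P).T
        m = m + K @ (y[:, n] - m)
        P = P - K @ P
        P = 0.5 * (P + P.T)
        m_filt[n], P_filt[n] = m, P

    means = np.empty((d, N))
    covs = np.empty((N, d, d))
    means[:, N - 1] = m_filt[N - 1]
    covs[N - 1] = P_filt[N - 1]
    for n in range(N - 2, -1, -1):
        G = np.linalg.solve(P_pred[n + 1], A @ P_filt[n]).T
        means[:, n] = m_filt[n] + G @ (means[:, n + 1] - m_pred[n + 1])
        covs[n] = P_filt[n] + G @ (covs[n + 1] - P_pred[n + 1]) @ G.T
        covs[n] = 0.5 * (covs[n] + covs[n].T)
    return means, covs


def lgssm_joint_precision(
    params: LGSSMParams, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Dense precision Q and linear term b of the joint Gaussian posterior.

    The state is vectorized time-major: coordinate (k, n) maps to n*d + k.
    U(x) = 1/2 z'Qz - b'z + const with z = vec(x).
    """
    d, N = params.d, params.N
    y = as_state_matrix(y, d, N)
    A = params.A
    I = np.eye(d)
    Q = np.zeros((d * N, d * N))
    for n in range(N):
        sl = slice(n * d, (n + 1) * d)
        Q[sl, sl] += I  # observation
        if n == 0:
            Q[sl, sl] += I  # initial prior
        if n >= 1:
            Q[sl, sl] += I  # transition into n
        if n <= N - 2:
            Q[sl, sl] += A.T @ A  # transition out of n
            nxt = slice((n + 1) * d, (n + 2) * d)
            Q[sl, nxt] += -A.T
            Q[nxt, sl] += -A
    b = y.T.reshape(-1).copy()
    return Q, b


def dense_gaussian_smoother(
    params: LGSSMParams, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothing means/marginal covariances by dense precision-matrix solve.

    Independent of :func:`kalman_rts_smoother`; intended for small instances.
    """
    d, N = params.d, params.N
    Q, b = lgssm_joint_precision(params, y)
    cov = np.linalg.inv(Q)
    mean = cov @ b
    means = mean.reshape(N, d).T
    covs = np.empty((N, d, d))
    for n in range(N):
        sl = slice(n * d, (n + 1) * d)
        covs[n] = cov[sl, sl]
    return means, covs


def sample_lgssm_posterior(
    params: LGSSMParams, y: np.ndarray, size: int, seed
) -> np.ndarray:
    """Exact draws from the joint smoothing posterior (dense Cholesky).

    Returns an array of shape (size, d, N).  Cost is O((dN)^3) once plus
    O(size (dN)^2); intended for moderate d*N.
    """
    rng = np.random.default_rng(seed)
    d, N = params.d, params.N
    Q, b = lgssm_joint_precision(params, y)
    L = np.linalg.cholesky(Q)
    mean = cho_solve((L, True), b)
    z = rng.standard_normal((d * N, size))
    dev = solve_triangular(L.T, z, lower=False)
    draws = (mean[:, None] + dev).T
    return draws.reshape(size, N, d).transpose(0, 2, 1)


# ---------------------------------------------------------------------------
# Heavy-tailed stochastic volatility with leverage
# ---------------------------------------------------------------------------


def _default_sigma_eps(d: int) -> np.ndarray:
    idx = np.arange(d, dtype=float)
    return np.exp(-np.abs(idx[:, None] - idx[None, :]) / 2.0)


def default_sv_params(d: int, N: int, nu: int = 10) -> "SVParams":
    """Synthetic-demo parameter set: persistent volatilities (alpha = 0.9),
    weakly cross-correlated state noise, exponentially decaying return
    correlations and a mild negative leverage cross-covariance."""
    alpha = np.full(d, 0.9)
    Sigma_eta = 0.1 * (0.3 * np.ones((d, d)) + 0.7 * np.eye(d))
    Sigma_eps = _default_sigma_eps(d)
    Sigma_rho = -0.05 * np.eye(d)
    return SVParams(
        d=d, N=N, alpha=alpha, Sigma_eta=Sigma_eta, Sigma_eps=Sigma_eps,
        Sigma_rho=Sigma_rho, nu=nu,
    )


@dataclass(frozen=True)
class SVParams:
    """Stochastic volatility model with leverage.

    x_{n+1} = A x_n + eta_n with A = diag(alpha); y_n = gamma_n^{-1/2}
    Lambda_n eps_n, Lambda_n = diag(exp(x_n / 2)); (eta_n, eps_n) jointly
    N(0, Sigma_hat) with blocks [[Sigma_eta, Sigma_rho], [Sigma_rho,
    Sigma_eps]]; gamma_n ~ Gamma(nu/2, rate nu/2) independent across time,
    giving the returns multivariate-t marginals with nu degrees of freedom.
    """

    d: int
    N: int
    alpha: np.ndarray
    Sigma_eta: np.ndarray
    Sigma_eps: np.ndarray
    Sigma_rho: np.ndarray
    nu: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        for name in ("Sigma_eta", "Sigma_eps", "Sigma_rho"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        d = self.d
        if self.alpha.shape != (d,) or np.any(self.alpha < 0) or np.any(self.alpha >= 1):
            raise ParameterError("alpha must be a length-d vector with entries in [0, 1)")
        for name in ("Sigma_eta", "Sigma_eps", "Sigma_rho"):
            if getattr(self, name).shape != (d, d):
                raise ParameterError(f"{name} must be d x d")
        if self.nu < 1:
            raise ParameterError("nu must be a positive integer")
        Sig = self.Sigma_hat
        if not np.allclose(Sig, Sig.T, atol=1e-10):
            raise ParameterError("joint noise covariance must be symmetric")
        try:
            np.linalg.cholesky(Sig)
            np.linalg.cholesky(self.cond_cov)
        except np.linalg.LinAlgError as exc:
            raise ParameterError(
                "joint noise covariance (or its conditional Schur complement) "
                "is not positive definite"
            ) from exc

    @cached_property
    def Sigma_hat(self) -> np.ndarray:
        return np.block(
            [[self.Sigma_eta, self.Sigma_rho], [self.Sigma_rho, self.Sigma_eps]]
        )

    @cached_property
    def leverage_gain(self) -> np.ndarray:
        """M = Sigma_rho Sigma_eps^{-1}: feedback of the realized return
        innovation into the next state mean."""
        return np.linalg.solve(self.Sigma_eps.T, self.Sigma_rho.T).T

    @cached_property
    def cond_cov(self) -> np.ndarray:
        """Conditional transition covariance Sigma_eta - M Sigma_rho."""
        C = self.Sigma_eta - self.leverage_gain @ self.Sigma_rho
        return 0.5 * (C + C.T)

    @cached_property
    def stationary_cov(self) -> np.ndarray:
        """Stationary covariance of the AR(1) state: Sigma_eta,ij / (1 - a_i a_j)."""
        a = self.alpha
        return self.Sigma_eta / (1.0 - a[:, None] * a[None, :])


@dataclass(frozen=True)
class SVDataset:
    """Observed log-returns with their Gamma mixing variables.

    ``y_gamma`` holds the rescaled observations y_n^gamma = sqrt(gamma_n) y_n
    used for inference once the mixing variables are known.
    """

    y: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float))
        if self.y.ndim != 2:
            raise ShapeError("y must be a d x N matrix")
        if self.gamma.shape != (self.y.shape[1],):
            raise ShapeError("gamma must have length N")
        if np.any(self.gamma <= 0):
            raise ParameterError("gamma must be strictly positive")

    @cached_property
    def y_gamma(self) -> np.ndarray:
        return np.sqrt(self.gamma)[None, :] * self.y


def _sv_prep(params: SVParams, data: SVDataset, x: np.ndarray):
    d, N = params.d, params.N
    x = as_state_matrix(x, d, N)
    if data.y.shape != (d, N):
        raise ShapeError(f"data has shape {data.y.shape}, expected ({d}, {N})")
    z = data.y_gamma * np.exp(-0.5 * x)  # Lambda_n^{-1} y_n^gamma, columnwise
    return x, z


def sv_potential(params: SVParams, data: SVDataset, x: np.ndarray) -> float:
    """Negative log joint density of x given (y^gamma, gamma), constants
    included (in particular the x-dependent log det Lambda_n Sigma_eps
    Lambda_n = sum_k x_n^k + log det Sigma_eps)."""
    d, N = params.d, params.N
    x, z = _sv_prep(params, data, x)
    A = np.diag(params.alpha)
    M = params.leverage_gain
    C = params.cond_cov
    cC = cho_factor(C, lower=True)
    cE = cho_factor(params.Sigma_eps, lower=True)
    P1 = params.stationary_cov

    # observation terms: 1/2 z' Sigma_eps^{-1} z + 1/2 sum_k x_n^k + const
    obs_quad = 0.5 * float(np.sum(z * cho_solve(cE, z)))
    logdet_eps = 2.0 * float(np.sum(np.log(np.diag(cE[0]))))
    obs = obs_quad + 0.5 * float(x.sum()) + N * 0.5 * (logdet_eps + d * _LOG_2PI)

    # transitions: residual r_n = x_n - A x_{n-1} - M z_{n-1}
    if N > 1:
        r = x[:, 1:] - A @ x[:, :-1] - M @ z[:, :-1]
        cCl = cC[0]
        trans_quad = 0.5 * float(np.sum(r * cho_solve(cC, r)))
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cCl))))
        trans = trans_quad + (N - 1) * 0.5 * (logdet_C + d * _LOG_2PI)
    else:
        trans = 0.0

    # initial state: x_1 ~ N(0, stationary covariance)
    cP = cho_factor(P1, lower=True)
    init = 0.5 * float(x[:, 0] @ cho_solve(cP, x[:, 0]))
    init += 0.5 * (2.0 * float(np.sum(np.log(np.diag(cP[0])))) + d * _LOG_2PI)
    return obs + trans + init


def sv_grad(params: SVParams, data: SVDataset, x: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`sv_potential`, including the chain-rule
    terms from Lambda_{n-1}^{-1} in the next-step transition mean and from
    the observation log-determinant."""
    d, N = params.d, params.N
    x, z = _sv_prep(params, data, x)
    A = np.diag(params.alpha)
    M = params.leverage_gain
    cC = cho_factor(params.cond_cov, lower=True)
    cE = cho_factor(params.Sigma_eps, lower=True)

    g = np.empty((d, N))
    # observation: d/dx [1/2 z'E^{-1}z] = -1/2 z * (E^{-1} z); log det adds 1/2
    Sz = cho_solve(cE, z)
    g[:] = -0.5 * z * Sz + 0.5

    if N > 1:
        r = x[:, 1:] - A @ x[:, :-1] - M @ z[:, :-1]
        R = cho_solve(cC, r)  # C^{-1} r_n, d x (N-1)
        g[:, 1:] += R
        g[:, :-1] += -(A.T @ R) + 0.5 * z[:, :-1] * (M.T @ R)

    cP = cho_factor(params.stationary_cov, lower=True)
    g[:, 0] += cho_solve(cP, x[:, 0])
    return g


def simulate_sv(params: SVParams, seed) -> tuple[np.ndarray, SVDataset]:
    """Draw (x_true, dataset) from the SV model; seed-reproducible."""
    rng = np.random.default_rng(seed)
    d, N = params.d, params.N
    gamma = rng.gamma(shape=params.nu / 2.0, scale=2.0 / params.nu, size=N)
    L = np.linalg.cholesky(params.Sigma_hat)
    noise = (L @ rng.standard_normal((2 * d, N)))  # rows 0:d eta, d:2d eps
    eta, eps = noise[:d], noise[d:]
    P1c = np.linalg.cholesky(params.stationary_cov)
    x = np.empty((d, N))
    x[:, 0] = P1c @ rng.standard_normal(d)
    for n in range(1, N):
        x[:, n] = params.alpha * x[:, n - 1] + eta[:, n - 1]
    y = (gamma ** -0.5)[None, :] * np.exp(0.5 * x) * eps
    return x, SVDataset(y=y, gamma=gamma)


class StochasticVolatilitySSM(PotentialModel):
    """Smoothing target of the SV model conditional on known mixing variables.

    An outer Gibbs step for the mixing variables is an extension hook a user
    can add on top; the sampler itself only needs this conditional target.
    """

    quadratic = False

    def __init__(self, params: SVParams, data: SVDataset):
        self.params = params
        self.d, self.N = params.d, params.N
        self.data = data

    def potential(self, x: np.ndarray) -> float:
        return sv_potential(self.params, self.data, x)

    def grad(self, x: np.ndarray) -> np.ndarray:
        return sv_grad(self.params, self.data, x)
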