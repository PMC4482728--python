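"""Self-consistent mean-field firing rates of degree-classed LIF networks.

Each in-degree class k is treated as a homogeneous population with
stationary rate r_k given by the Siegert transfer function of its Gaussian
input, whose moments couple the classes through the joint degree matrix
N_kk':

    mu_k   = J*tau*(nu_thr*s + sum_k' N_kk' r_k')      [mV]
    sigma_k^2 = J*mu_k                                  [mV^2]
    r_k    = phi(mu_k, sigma_k)                         [spikes/ms]

Fixed points are found by damped Picard iteration with optional Anderson
acceleration; the active (upper) branch is selected by starting from a
high-rate initial condition and, for response curves, sweeping the
stimulus downward by continuation.  Rates cross the module boundary in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import erfcx

from . import _siegert
from .degreenet import ConnectionKernel, DegreeDistribution
from .params import NeuronParams

__all__ = [
    "ConvergenceError",
    "PopulationRates",
    "ResponseCurve",
    "siegert_rate",
    "siegert_rate_quad",
    "input_moments",
    "solve_selfconsistent",
    "solve_scalar_uncorrelated",
    "response_curve",
    "stimulus_threshold",
    "firing_rate_distribution",
]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration did not reach the requested residual."""

    def __init__(self, msg: str, residual_hz: float | None = None):
        super().__init__(msg)
        self.residual_hz = residual_hz


# ---------------------------------------------------------------------------
# transfer function


def siegert_rate(mu: float, sigma: float, params: NeuronParams) -> float:
    """Stationary LIF firing rate (Hz) for Gaussian input with mean ``mu``
    (mV) and standard deviation ``sigma`` (mV).

    ``sigma=0`` falls back to the noiseless closed form
    1/(tau_ref + tau*ln((mu-V_reset)/(mu-theta))) above threshold and 0
    below; negative ``sigma`` is an error.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    r = _siegert.siegert_rate_kernel(
        float(mu), float(sigma), params.tau, params.tau_ref, params.theta, params.v_reset
    )
    return 1000.0 * r


def siegert_rate_quad(mu: float, sigma: float, params: NeuronParams) -> float:
    """Reference evaluation of the same transfer function with adaptive
    scipy quadrature (independent of the numba kernel); Hz."""
    if sigma <= 0:
        return siegert_rate(mu, sigma, params)
    a = (params.v_reset - mu) / sigma
    b = (params.theta - mu) / sigma
    if b > 8.0:
        return 0.0
    val, _ = quad(lambda x: erfcx(-x), a, b, limit=200)
    return 1000.0 / (params.tau_ref + params.tau * np.sqrt(np.pi) * val)


def input_moments(
    kernel: ConnectionKernel,
    rates_hz: np.ndarray,
    s: float,
    params: NeuronParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian input moments per degree class.

    Returns (mu_k in mV, sigma_k^2 in mV^2) for population rates in Hz:
    mu_k = J*tau*(nu_thr*s + sum_k' N_kk' r_k'), sigma_k^2 = J*mu_k.
    """
    rates_hz = np.asarray(rates_hz, dtype=float)
    if rates_hz.shape != kernel.degrees.shape:
        raise ValueError("rates must align with the kernel degree support")
    if np.any(rates_hz < 0):
        raise ValueError("negative rates")
    r_ms = rates_hz / 1000.0
    mu = params.J * params.tau * (params.nu_thr * s + kernel.counts @ r_ms)
    return mu, params.J * mu


# ---------------------------------------------------------------------------
# results containers


@dataclass
class PopulationRates:
    """Stationary per-class rates r_k (Hz) at stimulus ``s``."""

    degrees: np.ndarray
    rates_hz: np.ndarray
    s: float
    weights: np.ndarray | None = None
    converged: bool = True
    residual_hz: float = 0.0
    n_iter: int = 0

    def _w(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.degrees.shape, 1.0 / self.degrees.size)
        return self.weights

    def mean_hz(self) -> float:
        return float(np.sum(self._w() * self.rates_hz))

    def sigma_hz(self) -> float:
        m = self.mean_hz()
        return float(np.sqrt(np.sum(self._w() * (self.rates_hz - m) ** 2)))


@dataclass
class ResponseCurve:
    """Mean rate and population spread on a stimulus grid.

    ``branch`` records the continuation direction used ("down" starts at
    the largest s from a high-rate state: the active/upper branch).
    """

    s_grid: np.ndarray
    r_mean_hz: np.ndarray
    sigma_hz: np.ndarray
    rates_hz: np.ndarray  # (n_s, K)
    degrees: np.ndarray
    weights: np.ndarray
    branch: str


# ---------------------------------------------------------------------------
# fixed-point solvers


def _anderson_step(X, G, rmax):
    """Anderson(m) extrapolation from iterate/image histories."""
    F = [g - x for x, g in zip(X, G)]
    dF = np.stack([F[i + 1] - F[i] for i in range(len(F) - 1)], axis=1)
    dG = np.stack([G[i + 1] - G[i] for i in range(len(G) - 1)], axis=1)
    gamma, *_ = np.linalg.lstsq(dF, F[-1], rcond=None)
    cand = G[-1] - dG @ gamma
    return np.clip(cand, 0.0, rmax)


def solve_selfconsistent(
    kernel: ConnectionKernel,
    s: float,
    params: NeuronParams,
    init_hz: np.ndarray | float | None = None,
    tau_x: float = 3.0,
    dt: float | None = None,
    tol_hz: float = 1e-6,
    t_max_factor: float = 2000.0,
    accelerate: bool = True,
    anderson_depth: int = 5,
    raise_on_fail: bool = True,
) -> PopulationRates:
    """Solve the coupled self-consistent rate equations at stimulus ``s``.

    Iterates the relaxation map r <- r + (dt/tau_x)*(Phi(r) - r) (dt
    defaults to tau_x, i.e. plain Picard), optionally Anderson-accelerated,
    until the fixed-point residual max_k |phi_k(r) - r_k| falls below
    ``tol_hz``.  The default high-rate initial condition (0.8/tau_ref)
    selects the active upper branch where one exists.
    """
    if tau_x <= 0:
        raise ValueError("tau_x must be positive")
    dt = tau_x if dt is None else dt
    relax = dt / tau_x
    if not 0 < relax <= 1:
        raise ValueError("dt must lie in (0, tau_x]")
    K = kernel.degrees.size
    rmax_ms = 1.0 / params.tau_ref
    if init_hz is None:
        r = np.full(K, 0.8 * rmax_ms)
    else:
        r = np.asarray(np.broadcast_to(np.asarray(init_hz, float) / 1000.0, (K,))).copy()
    if np.any(r < 0) or np.any(r > rmax_ms):
        raise ValueError("initial rates outside the refractory bound")
    counts = np.ascontiguousarray(kernel.counts)
    tol_ms = tol_hz / 1000.0
    max_iter = max(1, int(round(t_max_factor / relax)))

    def phi(x: np.ndarray) -> np.ndarray:
        return _siegert.phi_coupled(
            counts, x, float(s), params.tau, params.tau_ref, params.theta,
            params.v_reset, params.J,
        )

    X: list[np.ndarray] = []
    G: list[np.ndarray] = []
    best = np.inf
    res = np.inf
    it = 0
    stagnant = 0
    use_accel = accelerate
    # Anderson near a fold chases the ghost of a vanished fixed point;
    # plain Picard is the relaxation dynamics itself and, the transfer
    # function being monotone in the rates, converges from above to the
    # largest remaining fixed point -- slowly, so it serves as fallback.
    picard_budget = 10 * max_iter
    for it in range(1, max_iter + picard_budget + 1):
        g = phi(r)
        res = float(np.max(np.abs(g - r)))
        if res < tol_ms:
            r = g
            break
        # collapse to quiescence: decaying everywhere and already tiny
        if float(np.max(g)) < tol_ms and float(np.max(g - r)) <= 0.0:
            r = g
            res = float(np.max(np.abs(phi(r) - r)))
            break
        if res < 0.99 * best:
            stagnant = 0
        else:
            stagnant += 1
        if use_accel and (stagnant > 300 or it > max_iter):
            use_accel = False  # fall back to pure relaxation
            X.clear()
            G.clear()
        if not use_accel and it > max_iter + picard_budget:
            break
        if res > 10.0 * best:  # acceleration went astray: restart history
            X.clear()
            G.clear()
        best = min(best, res)
        if use_accel:
            X.append(r)
            G.append(g)
            if len(X) > anderson_depth + 1:
                X.pop(0)
                G.pop(0)
            if len(X) >= 2:
                r = _anderson_step(X, G, rmax_ms)
                if not np.all(np.isfinite(r)):
                    r = X[-1] + relax * (G[-1] - X[-1])
            else:
                r = r + relax * (g - r)
        else:
            r = r + relax * (g - r)
    converged = res < tol_ms
    if not converged and raise_on_fail:
        raise ConvergenceError(
            f"no fixed point within {max_iter} iterations at s={s}: "
            f"residual {1000 * res:.3g} Hz",
            residual_hz=1000 * res,
        )
    return PopulationRates(
        degrees=kernel.degrees.copy(),
        rates_hz=1000.0 * r,
        s=float(s),
        weights=None if kernel.weights is None else kernel.weights.copy(),
        converged=converged,
        residual_hz=1000.0 * res,
        n_iter=it,
    )


def solve_scalar_uncorrelated(
    dist: DegreeDistribution,
    s: float,
    params: NeuronParams,
    init_hz: float = 400.0,
    tol_hz: float = 1e-6,
    max_iter: int = 20000,
) -> float:
    """One-dimensional self-consistent mean rate (Hz) for the network with
    independently drawn in/out degrees: r = sum_k P(k) phi_k(r) with
    mu_k = J*tau*(nu_thr*s + k*r)."""
    r, converged, _ = _siegert.scalar_mean_iteration(
        dist.degrees.astype(np.float64),
        dist.pmf,
        float(s),
        params.tau,
        params.tau_ref,
        params.theta,
        params.v_reset,
        params.J,
        init_hz / 1000.0,
        tol_hz / 1000.0,
        max_iter,
    )
    if not converged:
        raise ConvergenceError(f"scalar iteration did not converge at s={s}")
    return 1000.0 * r


def response_curve(
    kernel: ConnectionKernel,
    s_grid: np.ndarray,
    params: NeuronParams,
    direction: str = "down",
    init_hz: float | None = None,
    **solver_kwargs,
) -> ResponseCurve:
    """Sweep the stimulus by continuation and record r_mean(s), sigma(s).

    Each solve starts from the neighboring solution; ``direction='down'``
    (default) starts at the largest s from a high-rate state, which tracks
    the stable upper branch until it folds.  sigma(s) is the
    degree-distribution-weighted standard deviation of the class rates.
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    s_grid = np.sort(np.asarray(s_grid, dtype=float))
    order = s_grid[::-1] if direction == "down" else s_grid
    K = kernel.degrees.size
    if kernel.weights is None:
        raise ValueError("kernel must carry class weights for a response curve")
    rates = np.empty((s_grid.size, K))
    init: np.ndarray | float | None = init_hz
    sols = []
    for s in order:
        sol = solve_selfconsistent(kernel, s, params, init_hz=init, **solver_kwargs)
        sols.append(sol)
        init = sol.rates_hz
    if direction == "down":
        sols = sols[::-1]
    for i, sol in enumerate(sols):
        rates[i] = sol.rates_hz
    w = kernel.weights
    r_mean = rates @ w
    sigma = np.sqrt(np.maximum(((rates - r_mean[:, None]) ** 2) @ w, 0.0))
    return ResponseCurve(
        s_grid=s_grid,
        r_mean_hz=r_mean,
        sigma_hz=sigma,
        rates_hz=rates,
        degrees=kernel.degrees.copy(),
        weights=w.copy(),
        branch=direction,
    )


def stimulus_threshold(curve: ResponseCurve, epsilon_hz: float = 0.1) -> tuple[float, float]:
    """Extinction point of sustained activity on a downward-continuation
    curve: the midpoint of the grid interval across which the mean rate
    rises through ``epsilon_hz``; the half-uncertainty is the grid step."""
    if curve.branch != "down":
        raise ValueError("threshold is defined on the downward-continuation branch")
    r = curve.r_mean_hz
    s = curve.s_grid
    below = r < epsilon_hz
    hits = np.nonzero(below[:-1] & ~below[1:])[0]
    if hits.size == 0:
        raise ValueError("mean rate never crosses epsilon on the grid")
    i = int(hits[-1])
    return 0.5 * (s[i] + s[i + 1]), float(s[i + 1] - s[i])


def firing_rate_distribution(
    pop: PopulationRates, bins: int | np.ndarray = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of single-neuron rates implied by the class rates: each
    r_k occurs with probability P(k).  Returns (bin_edges, mass) with the
    mass normalized to 1."""
    if isinstance(bins, int) and bins < 1:
        raise ValueError("need at least one bin")
    w = pop._w()
    hist, edges = np.histogram(pop.rates_hz, bins=bins, weights=w)
    tot = hist.sum()
    if tot > 0:
        hist = hist / tot
    return edges, hist
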