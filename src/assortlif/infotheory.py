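"""Mutual information of the stimulus -> population-rate channel.

The network response r to a stationary stimulus s is modeled as the mean
rate of n randomly sampled neurons: Gaussian with mean r_mean(s) and
variance sigma^2(s)/n, where sigma^2 is the degree-distribution-weighted
variance of the per-class rates.  With a uniform prior over sub-threshold
stimuli, I(s; r) quantifies how well the population code transmits weak
inputs.

Two evaluations are provided.  The primary one integrates the defining
double integral directly with Gauss-Hermite nodes per stimulus, which is
robust to the atom at r = 0 that a sub-threshold dead network produces
(the mean-field solution is exactly quiescent below the stimulus
threshold, so the response there is a point mass, not a narrow Gaussian).
The small-noise expansion I = H - H_noise, obtained by expanding the
integral in powers of the readout noise, is implemented alongside; its
change-of-variables density P(r_hat) = P(s)/(dr_hat/ds) is ill-defined on
flat segments of the response curve, which are assigned to discrete
symbols whose mass enters H as -w*log2(w).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .degreenet import (
    DegreeDistribution,
    bin_kernel,
    configuration_model,
    metropolis_rewire,
    pearson_in_degree_correlation,
    sample_degree_sequence,
    sample_joint_degree,
)
from .meanfield import ResponseCurve, response_curve
from .params import NeuronParams

__all__ = [
    "ChannelModel",
    "MIResult",
    "conditional_response_pdf",
    "mutual_information_direct",
    "mutual_information_small_noise",
    "assortativity_sweep",
]

_LOG2E = np.log2(np.e)


@dataclass
class ChannelModel:
    """Gaussian readout channel built on a mean-field response curve.

    The stimulus prior is uniform on (s_lo, s_hi) (default the
    sub-threshold interval (0, 1)); only curve grid points inside the
    prior support enter the quadratures.  Stimuli whose mean rate falls
    below ``dead_rate_hz`` are treated as exactly quiescent: they
    contribute a point mass at r = 0.
    """

    curve: ResponseCurve
    n: int
    s_lo: float = 0.0
    s_hi: float = 1.0
    dead_rate_hz: float = 0.1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("readout size n must be >= 1")
        if self.s_hi <= self.s_lo:
            raise ValueError("empty stimulus support")

    def quadrature(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(s, prior weights, response means, response sds) on the grid.

        Weights are trapezoidal and normalized to 1; sd = sigma(s)/sqrt(n).
        """
        m = (self.curve.s_grid >= self.s_lo) & (self.curve.s_grid <= self.s_hi)
        s = self.curve.s_grid[m]
        if s.size < 3:
            raise ValueError("too few curve points inside the stimulus support")
        w = np.zeros(s.size)
        w[1:] += 0.5 * np.diff(s)
        w[:-1] += 0.5 * np.diff(s)
        w /= w.sum()
        means = self.curve.r_mean_hz[m].copy()
        sds = self.curve.sigma_hz[m] / np.sqrt(self.n)
        dead = means < self.dead_rate_hz
        means[dead] = 0.0
        sds[dead] = 0.0
        return s, w, means, sds


@dataclass
class MIResult:
    """Mutual information decomposition in bits."""

    I: float
    H: float
    H_noise: float
    method: str
    n: int


@dataclass
class ConditionalResponse:
    """P(r|s): Gaussian with mean r_hat(s) and sd sigma(s)/sqrt(n); a
    quiescent stimulus yields the degenerate point mass at 0."""

    mean: float
    sd: float

    @property
    def is_atom(self) -> bool:
        return self.sd == 0.0

    def pdf(self, r: np.ndarray) -> np.ndarray:
        if self.is_atom:
            raise ValueError("degenerate (delta) conditional has no density")
        return norm.pdf(r, self.mean, self.sd)


def conditional_response_pdf(channel: ChannelModel, s: float) -> ConditionalResponse:
    """Conditional response distribution at stimulus ``s`` (nearest grid
    point of the channel's curve)."""
    sg, _, means, sds = channel.quadrature()
    if not (sg[0] <= s <= sg[-1]):
        raise ValueError("s outside the channel support")
    i = int(np.argmin(np.abs(sg - s)))
    return ConditionalResponse(mean=float(means[i]), sd=float(sds[i]))


def _gauss_hermite(order: int) -> tuple[np.ndarray, np.ndarray]:
    z, w = np.polynomial.hermite.hermgauss(order)
    return z, w / np.sqrt(np.pi)


def mutual_information_direct(
    channel: ChannelModel,
    gh_order: int = 64,
    sd_floor_hz: float = 1e-9,
) -> MIResult:
    """Direct quadrature of I = int ds int dr P(s) P(r|s) log2(P(r|s)/P(r)).

    The marginal splits into an atom at r = 0 of mass w0 (quiescent
    stimuli) and a continuous mixture of the active Gaussians.  The atom
    contributes w0*log2(1/w0) exactly; each active stimulus contributes a
    Gauss-Hermite expectation of the log density ratio.  H and H_noise are
    reported as the (mixed) marginal response entropy and the mean
    conditional entropy, with I = H - H_noise.
    """
    _, w, means, sds = channel.quadrature()
    dead = sds == 0.0
    w0 = float(w[dead].sum())
    aw = w[~dead]
    am = means[~dead]
    asd = np.maximum(sds[~dead], sd_floor_hz)
    H_noise = float(np.sum(aw * 0.5 * np.log2(2 * np.pi * np.e * asd**2)))
    if aw.size == 0:
        return MIResult(I=0.0, H=0.0, H_noise=0.0, method="direct_quadrature", n=channel.n)
    z, gw = _gauss_hermite(gh_order)
    # marginal continuous density evaluated at the GH nodes of component i
    # r_nodes[i, q] = m_i + sqrt(2) sd_i z_q
    r_nodes = am[:, None] + np.sqrt(2.0) * asd[:, None] * z[None, :]
    diff = r_nodes[:, :, None] - am[None, None, :]
    comp = np.exp(-0.5 * (diff / asd[None, None, :]) ** 2) / (
        np.sqrt(2 * np.pi) * asd[None, None, :]
    )
    p_c = comp @ aw  # (n_active, gh)
    log_pc = np.log2(np.maximum(p_c, 1e-300))
    H_cont = -float(np.sum(aw[:, None] * gw[None, :] * log_pc))
    H_atom = -w0 * np.log2(w0) if w0 > 0 else 0.0
    H = H_cont * (1.0) + H_atom
    I = H - H_noise
    return MIResult(I=I, H=H, H_noise=H_noise, method="direct_quadrature", n=channel.n)


def mutual_information_small_noise(
    channel: ChannelModel,
    deriv_tol_hz: float = 1e-6,
) -> MIResult:
    """Small-noise expansion I = H - H_noise.

    H is the entropy of the noiseless response density
    P(r_hat) = P(s) / (dr_hat/ds) (central differences on the stimulus
    grid), plus -w*log2(w) for each flat segment treated as a discrete
    symbol; H_noise averages (1/2)*log2(2*pi*e*sigma^2/n) over the
    increasing part, with quiescent (sigma = 0) symbols contributing no
    noise entropy.  A negative I is possible for coarse or pathological
    curves and is flagged, never clipped.
    """
    s, w, means, sds = channel.quadrature()
    drds = np.gradient(means, s)
    flat = np.abs(drds) <= deriv_tol_hz
    if np.all(flat):
        raise ValueError("response curve is flat everywhere: small-noise "
                         "expansion inapplicable")
    aw = w[~flat]
    H_inc = float(np.sum(aw * np.log2(np.abs(drds[~flat]))))
    # prior density P(s) on its support: uniform 1/(s_hi - s_lo); the
    # trapezoid weights already integrate it, so log2 P(s) is a constant
    span = channel.s_hi - channel.s_lo
    H_inc += float(aw.sum() * np.log2(span))
    # flat runs become discrete symbols
    H_atoms = 0.0
    Hn_atoms = 0.0
    i = 0
    while i < s.size:
        if flat[i]:
            j = i
            while j + 1 < s.size and flat[j + 1]:
                j += 1
            mass = float(w[i : j + 1].sum())
            if mass > 0:
                H_atoms -= mass * np.log2(mass)
                seg_sd = sds[i : j + 1]
                act = seg_sd > 0
                if np.any(act):
                    Hn_atoms += float(
                        np.sum(w[i : j + 1][act] * 0.5
                               * np.log2(2 * np.pi * np.e * seg_sd[act] ** 2))
                    )
            i = j + 1
        else:
            i += 1
    act_sd = np.maximum(sds[~flat], 1e-300)
    H_noise = float(np.sum(aw * 0.5 * np.log2(2 * np.pi * np.e * act_sd**2))) + Hn_atoms
    H = H_inc + H_atoms
    I = H - H_noise
    if I < 0:
        warnings.warn("small-noise mutual information is negative; the "
                      "expansion is unreliable for this curve")
    return MIResult(I=I, H=H, H_noise=H_noise, method="small_noise", n=channel.n)


def assortativity_sweep(
    dist: DegreeDistribution,
    p_levels,
    n: int,
    params: NeuronParams,
    seed: int = 0,
    N: int = 10_000,
    s_grid: np.ndarray | None = None,
    method: str = "direct",
    n_bins: int | None = None,
    saturation_attempts_per_edge: int = 400,
    **mi_kwargs,
) -> pd.DataFrame:
    """Mutual information along an assortativity ladder.

    Builds one configuration-model network (equal in/out degrees from
    ``dist``), then runs the g=1 assortative Metropolis chain once,
    snapshotting when the online-tracked Pearson coefficient crosses each
    requested level (so levels must be nondecreasing and >= the
    configuration-model baseline); at each snapshot the joint degree
    matrix is sampled from the adjacency, the mean-field response curve is
    solved by downward continuation on [0, 1], and I, H, H_noise are
    computed for a readout of ``n`` neurons under the uniform
    sub-threshold prior.  Unreachable levels are reported with the
    achieved p (the chain saturates).  Returns a DataFrame with columns
    p_target, p_achieved, I_bits, H_bits, Hnoise_bits.
    """
    if method not in ("direct", "smallnoise"):
        raise ValueError("method must be 'direct' or 'smallnoise'")
    p_levels = np.asarray(sorted(p_levels), dtype=float)
    if s_grid is None:
        # fine stimulus step: the direct quadrature treats each grid point
        # as a mixture component, so the spacing of neighboring response
        # means must stay below the readout noise scale sigma/sqrt(n)
        s_grid = np.arange(0.0, 1.0 + 1e-9, 0.0025)
    seq = sample_degree_sequence(dist, N, seed)
    net = configuration_model(seq, seed + 1)
    E = net.n_edges
    rows = []
    for li, level in enumerate(p_levels):
        p_now = pearson_in_degree_correlation(net).p
        if p_now < level:
            net, _ = metropolis_rewire(
                net,
                "assortative",
                g=1.0,
                n_attempts=saturation_attempts_per_edge * E,
                seed=seed + 100 + li,
                p_target=float(level),
                plateau_window=10,
                inplace=True,
            )
        p_achieved = pearson_in_degree_correlation(net).p
        kernel = sample_joint_degree(net)
        if n_bins is not None:
            kernel = bin_kernel(kernel, n_bins)
        curve = response_curve(kernel, s_grid, params, direction="down")
        channel = ChannelModel(curve, n=n)
        if method == "direct":
            res = mutual_information_direct(channel, **mi_kwargs)
        else:
            res = mutual_information_small_noise(channel, **mi_kwargs)
        rows.append(
            {
                "p_target": level,
                "p_achieved": p_achieved,
                "I_bits": res.I,
                "H_bits": res.H,
                "Hnoise_bits": res.H_noise,
            }
        )
    return pd.DataFrame(rows)
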