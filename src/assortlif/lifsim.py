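"""Direct forward-Euler simulation of the LIF network.

This is the verification oracle for the mean-field solver: each neuron
integrates a leaky membrane at fixed step dt, receives an independent
external Poisson train of rate s*nu_thr whose events depolarize by J, and
recurrent spikes arrive as J-increments after their per-edge delay
(rounded to the integration grid, delivered through a circular buffer).
A threshold crossing emits a spike, resets the membrane to V_reset and
clamps it there for tau_ref, during which all input is discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .degreenet import DirectedNetwork
from .meanfield import PopulationRates
from .params import NeuronParams, SimConfig

__all__ = ["SpikeRecord", "simulate", "population_rates", "readout_sample"]


@dataclass
class SpikeRecord:
    """Per-neuron spike counts over the measurement window."""

    counts: np.ndarray
    T_ms: float
    config: SimConfig

    @property
    def rates_hz(self) -> np.ndarray:
        return self.counts * (1000.0 / self.T_ms)


@njit(cache=True)
def _simulate_core(
    out_ptr,
    out_tgt,
    out_dly,  # per-edge delay in steps (>= 1)
    N,
    n_steps,
    burn_steps,
    dt,
    tau,
    ref_steps,
    theta,
    v_reset,
    J,
    lam_ext,
    seed,
    D,
):
    np.random.seed(seed)
    V = np.empty(N)
    for i in range(N):
        V[i] = v_reset + (theta - v_reset) * np.random.random()
    refr = np.zeros(N, dtype=np.int64)
    buf = np.zeros((D, N))
    counts = np.zeros(N, dtype=np.int64)
    decay = dt / tau
    p0 = np.exp(-lam_ext)  # P(no external event this step)
    for t in range(n_steps):
        idx = t % D
        for i in range(N):
            if refr[i] > 0:
                refr[i] -= 1
                V[i] = v_reset  # inputs during refractoriness are discarded
                continue
            v = V[i] - V[i] * decay
            # external Poisson events by CDF inversion (lam_ext << 1, so a
            # single uniform draw resolves most steps)
            u = np.random.random()
            if u >= p0:
                nev = 0
                cum = p0
                pk = p0
                while u >= cum:
                    nev += 1
                    pk *= lam_ext / nev
                    cum += pk
                v += J * nev
            v += buf[idx, i]
            if v >= theta:
                if t >= burn_steps:
                    counts[i] += 1
                v = v_reset
                refr[i] = ref_steps
                for e in range(out_ptr[i], out_ptr[i + 1]):
                    buf[(t + out_dly[e]) % D, out_tgt[e]] += J
            V[i] = v
        for i in range(N):
            buf[idx, i] = 0.0
    return counts


def simulate(
    network: DirectedNetwork, params: NeuronParams, config: SimConfig
) -> SpikeRecord:
    """Integrate the network and count spikes after the burn-in.

    The external drive is a per-neuron Poisson event count per step with
    mean s*nu_thr*dt, each event adding J to the membrane.
    """
    if config.dt > params.tau_ref:
        raise ValueError("dt must not exceed the refractory period")
    dsteps = np.rint(network.delay_ms / config.dt).astype(np.int64)
    if network.n_edges and np.any((network.delay_ms > 0) & (dsteps == 0)):
        warnings.warn("some delays are below the dt resolution; rounded up")
    dsteps = np.maximum(dsteps, 1)  # same-step self-reexcitation is excluded

    order = np.argsort(network.src, kind="stable")
    src_sorted = network.src[order]
    out_tgt = network.tgt[order]
    out_dly = dsteps[order]
    out_ptr = np.zeros(network.N + 1, dtype=np.int64)
    np.add.at(out_ptr, src_sorted + 1, 1)
    out_ptr = np.cumsum(out_ptr)

    n_steps = int(round((config.T + config.burn_in) / config.dt))
    burn_steps = int(round(config.burn_in / config.dt))
    D = int(dsteps.max()) + 1 if network.n_edges else 2
    counts = _simulate_core(
        out_ptr,
        out_tgt,
        out_dly,
        network.N,
        n_steps,
        burn_steps,
        config.dt,
        params.tau,
        int(round(params.tau_ref / config.dt)),
        params.theta,
        params.v_reset,
        params.J,
        config.s * params.nu_thr * config.dt,
        int(config.seed) & 0x7FFFFFFF,
        D,
    )
    return SpikeRecord(counts=counts, T_ms=config.T, config=config)


def population_rates(record: SpikeRecord, network: DirectedNetwork) -> PopulationRates:
    """Average the single-neuron rates within each realized in-degree
    class; weights are the class node fractions."""
    if record.counts.shape[0] != network.N:
        raise ValueError("record and network are inconsistent")
    kin = network.in_degree
    degrees, inverse, n_per = np.unique(kin, return_inverse=True, return_counts=True)
    if np.any(n_per == 0):
        raise ValueError("empty degree class")
    sums = np.bincount(inverse, weights=record.rates_hz, minlength=degrees.size)
    return PopulationRates(
        degrees=degrees.astype(float),
        rates_hz=sums / n_per,
        s=record.config.s,
        weights=n_per / network.N,
    )


def readout_sample(
    record: SpikeRecord, n: int, n_draws: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Network responses r: mean rate of n neurons sampled without
    replacement, repeated n_draws times."""
    N = record.counts.shape[0]
    if n > N:
        raise ValueError("readout size exceeds network size")
    if n < 1 or n_draws < 1:
        raise ValueError("n and n_draws must be positive")
    rng = np.random.default_rng(seed)
    rates = record.rates_hz
    if n == N:
        return np.full(n_draws, rates.mean())
    out = np.empty(n_draws)
    chunk = max(1, min(n_draws, int(2e7 // N)))
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        keys = rng.random((m, N))
        part = np.argpartition(keys, n, axis=1)[:, :n]
        out[done : done + m] = rates[part].mean(axis=1)
        done += m
    return out
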