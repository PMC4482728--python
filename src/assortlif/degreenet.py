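"""Degree distributions, directed network construction and correlation
statistics.

The networks studied here are directed graphs whose nodes carry a
truncated power-law in-degree distribution P(k) = Z*k**alpha on the
integer range [k_min, k_max], with each node's out-degree equal to its
in-degree (the convention suggested by C. elegans connectivity data).
Construction is a two-stage procedure: a directed configuration model
(random stub pairing followed by removal of self-loops and duplicate
edges) and an optional Metropolis target-swapping stage that imposes
assortative or disassortative in-degree correlations while preserving
every node's in- and out-degree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._rewire import metropolis_chain

__all__ = [
    "DegreeDistribution",
    "DirectedNetwork",
    "ConnectionKernel",
    "CorrelationStats",
    "DegenerateCorrelationError",
    "truncated_powerlaw",
    "degree_moments",
    "sample_degree_sequence",
    "configuration_model",
    "metropolis_rewire",
    "pearson_in_degree_correlation",
    "pearson_literal_shifted",
    "sample_joint_degree",
    "analytic_kernel",
]


class DegenerateCorrelationError(ValueError):
    """Raised when the degree correlation coefficient is undefined
    (zero variance of the in-degrees at the link ends)."""


# ---------------------------------------------------------------------------
# degree distributions


@dataclass(frozen=True)
class DegreeDistribution:
    """Truncated power-law pmf over integer degrees [k_min, k_max].

    pmf(k) = Z * k**alpha on the support, 0 elsewhere, with
    Z = 1 / sum_{k=k_min}^{k_max} k**alpha (discrete normalization).
    """

    alpha: float
    k_min: int
    k_max: int
    degrees: np.ndarray = field(repr=False)
    pmf: np.ndarray = field(repr=False)
    Z: float

    def mean(self) -> float:
        return float(np.sum(self.degrees * self.pmf))

    def variance(self) -> float:
        m = self.mean()
        return float(np.sum(self.degrees**2 * self.pmf) - m * m)


def truncated_powerlaw(alpha: float, k_min: int, k_max: int) -> DegreeDistribution:
    """Build P(k) = Z*k**alpha on the integers k_min..k_max."""
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    degrees = np.arange(k_min, k_max + 1, dtype=np.int64)
    w = degrees.astype(float) ** alpha
    Z = 1.0 / w.sum()
    return DegreeDistribution(
        alpha=alpha, k_min=k_min, k_max=k_max, degrees=degrees, pmf=w * Z, Z=Z
    )


def degree_moments(dist: DegreeDistribution) -> tuple[float, float]:
    """Exact discrete mean and variance of the degree distribution."""
    return dist.mean(), dist.variance()


def sample_degree_sequence(
    dist: DegreeDistribution, N: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw N i.i.d. degrees from the pmf (used for both in- and
    out-degrees under the equal in/out convention)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.choice(dist.degrees, size=N, p=dist.pmf)


# ---------------------------------------------------------------------------
# directed networks


@dataclass
class DirectedNetwork:
    """Directed graph with per-edge synaptic delays.

    Edges are stored as parallel arrays (src, tgt, delay_ms); direction is
    source -> target with "input of target" semantics.  Node ids are
    0-based integers below N.
    """

    N: int
    src: np.ndarray
    tgt: np.ndarray
    delay_ms: np.ndarray

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=np.int64)
        self.tgt = np.asarray(self.tgt, dtype=np.int64)
        self.delay_ms = np.asarray(self.delay_ms, dtype=np.float64)
        if not (self.src.shape == self.tgt.shape == self.delay_ms.shape):
            raise ValueError("edge arrays must have equal length")
        if self.n_edges and (self.src.min() < 0 or self.src.max() >= self.N):
            raise ValueError("source ids out of range")
        if self.n_edges and (self.tgt.min() < 0 or self.tgt.max() >= self.N):
            raise ValueError("target ids out of range")

    @property
    def n_edges(self) -> int:
        return int(self.src.shape[0])

    @property
    def in_degree(self) -> np.ndarray:
        return np.bincount(self.tgt, minlength=self.N)

    @property
    def out_degree(self) -> np.ndarray:
        return np.bincount(self.src, minlength=self.N)

    def validate(self) -> None:
        """Check the no-self-loop / no-duplicate-edge invariants."""
        if np.any(self.src == self.tgt):
            raise ValueError("self-loop present")
        keys = self.src * np.int64(self.N) + self.tgt
        if np.unique(keys).size != keys.size:
            raise ValueError("duplicate edge present")

    def copy(self) -> "DirectedNetwork":
        return DirectedNetwork(
            self.N, self.src.copy(), self.tgt.copy(), self.delay_ms.copy()
        )

    # -- plain-text round trip ---------------------------------------------
    def to_edgelist(self, path: str | Path, comment: str | None = None) -> None:
        """Write a TSV edge list (columns source, target, delay_ms)."""
        with open(path, "w") as fh:
            fh.write(f"# directed edge list, N={self.N}\n")
            if comment:
                fh.write(f"# {comment}\n")
            fh.write("source\ttarget\tdelay_ms\n")
            for s, t, d in zip(self.src, self.tgt, self.delay_ms):
                fh.write(f"{s}\t{t}\t{d:.6g}\n")

    @classmethod
    def from_edgelist(cls, path: str | Path, N: int | None = None) -> "DirectedNetwork":
        src, tgt, dly = [], [], []
        header_N = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "N=" in line:
                        header_N = int(line.split("N=")[1].split()[0])
                    continue
                if line.startswith("source"):
                    continue
                a, b, d = line.split("\t")
                src.append(int(a))
                tgt.append(int(b))
                dly.append(float(d))
        if N is None:
            N = header_N if header_N is not None else (max(max(src), max(tgt)) + 1)
        return cls(N, np.array(src), np.array(tgt), np.array(dly))


def configuration_model(
    degree_sequence: np.ndarray,
    seed: int | np.random.Generator,
    out_degree_sequence: np.ndarray | None = None,
    delay_max_ms: float = 6.0,
) -> DirectedNetwork:
    """Random directed graph by uniform in/out stub pairing.

    Each node owns ``degree_sequence[i]`` in-stubs and (by default) the
    same number of out-stubs; stubs are paired uniformly at random and
    self-loops / duplicate (src, tgt) pairs are removed afterwards, so
    realized degrees may fall slightly below targets.  Per-edge delays are
    uniform on [0, delay_max_ms].
    """
    degree_sequence = np.asarray(degree_sequence, dtype=np.int64)
    if degree_sequence.size == 0:
        raise ValueError("empty degree sequence")
    out_seq = (
        degree_sequence
        if out_degree_sequence is None
        else np.asarray(out_degree_sequence, dtype=np.int64)
    )
    if degree_sequence.sum() != out_seq.sum():
        raise ValueError("total in-stubs must equal total out-stubs")
    rng = np.random.default_rng(seed)
    N = degree_sequence.size
    nodes = np.arange(N, dtype=np.int64)
    in_stubs = np.repeat(nodes, degree_sequence)
    out_stubs = np.repeat(nodes, out_seq)
    rng.shuffle(out_stubs)
    src, tgt = out_stubs, in_stubs
    keep = src != tgt
    src, tgt = src[keep], tgt[keep]
    keys = src * np.int64(N) + tgt
    _, idx = np.unique(keys, return_index=True)
    idx.sort()
    src, tgt = src[idx], tgt[idx]
    delays = rng.uniform(0.0, delay_max_ms, size=src.size)
    return DirectedNetwork(N, src, tgt, delays)


def metropolis_rewire(
    network: DirectedNetwork,
    mode: str,
    g: float = 1.0,
    n_attempts: int | None = None,
    seed: int = 0,
    p_target: float | None = None,
    plateau_tol: float = 1e-3,
    plateau_window: int = 10,
    check_interval: int | None = None,
    inplace: bool = False,
) -> tuple[DirectedNetwork, np.ndarray]:
    """Degree-preserving Metropolis target swaps toward (dis)assortativity.

    Repeatedly picks two random edges with origin in-degrees k_i, k_j and
    target in-degrees m_i, m_j.  With probability ``g`` the targets are
    swapped only if the swap moves the in-degree correlation in the desired
    direction (assortative: k_i*m_i + k_j*m_j < k_i*m_j + k_j*m_i;
    disassortative: the reversed inequality); with probability 1-g they are
    swapped unconditionally.  Swaps that would create a self-loop or a
    duplicate edge are rejected and count as attempts.  In- and out-degree
    of every node are conserved exactly.

    Parameters
    ----------
    n_attempts : int, optional
        Swap-attempt budget; defaults to 100*|edges|.
    p_target : float, optional
        Early stop once the (online-tracked) Pearson coefficient crosses
        this level in the desired direction.
    plateau_tol, plateau_window :
        Stop when p changed by less than ``plateau_tol`` over the last
        ``plateau_window`` windows of |edges| attempts each; set
        plateau_window=0 to disable.
    check_interval : int, optional
        Attempts between checkpoints of the online p; defaults to |edges|,
        or |edges|/64 when a ``p_target`` is set (limits the overshoot
        past the target).

    Returns
    -------
    (network, p_trace) : the rewired network and the checkpoint trace of
    the Pearson coefficient (element 0 is the initial value).
    """
    if mode not in ("assortative", "disassortative"):
        raise ValueError("mode must be 'assortative' or 'disassortative'")
    if not 0.0 <= g <= 1.0:
        raise ValueError("g must lie in [0, 1]")
    if network.n_edges < 2:
        raise ValueError("need at least 2 edges to swap")
    net = network if inplace else network.copy()
    if n_attempts is None:
        n_attempts = 100 * net.n_edges
    sign = 1.0 if mode == "assortative" else -1.0
    if p_target is None:
        p_stop = sign * 2.0  # unreachable
    else:
        p_stop = float(p_target)
    if check_interval is None:
        check_interval = (
            net.n_edges if p_target is None else max(net.n_edges // 64, 1024)
        )
    # plateau horizon is defined in windows of |edges| attempts
    window_checks = plateau_window * max(net.n_edges // check_interval, 1)
    kin = net.in_degree.astype(np.int64)
    _, _, trace = metropolis_chain(
        net.src,
        net.tgt,
        kin,
        np.int64(net.N),
        sign,
        float(g),
        int(n_attempts),
        int(seed) & 0x7FFFFFFF,
        p_stop,
        float(plateau_tol),
        int(window_checks),
        int(check_interval),
    )
    return net, trace


# ---------------------------------------------------------------------------
# correlation statistics


@dataclass
class CorrelationStats:
    """In-degree correlation summary of a directed network.

    ``p`` is the Pearson correlation of (origin in-degree, target
    in-degree) over directed edges — the convention-consistent form of the
    link-end correlation coefficient, bounded by [-1, 1].  ``e`` is the
    empirical joint probability that a random directed link ends in a
    neuron of in-degree ``degrees[i]`` and originates from one of
    in-degree ``degrees[j]``.  ``Q_in`` is the excess in-degree
    distribution (k+1)P(k+1)/<k> evaluated on the realized node degree
    distribution, and ``sigma_in_sq`` its variance, reported for
    comparison with the shifted-distribution normalization convention.
    """

    p: float
    degrees: np.ndarray
    e: np.ndarray
    Q_in: np.ndarray
    Q_degrees: np.ndarray
    sigma_in_sq: float


def _edge_end_degrees(network: DirectedNetwork) -> tuple[np.ndarray, np.ndarray]:
    kin = network.in_degree
    return kin[network.src], kin[network.tgt]


def pearson_in_degree_correlation(network: DirectedNetwork) -> CorrelationStats:
    """Edge-counted in-degree correlation statistics.

    Raises :class:`DegenerateCorrelationError` when all link-end in-degrees
    at either end are identical (zero variance: p undefined).
    """
    if network.n_edges < 1:
        raise ValueError("network has no edges")
    x, y = _edge_end_degrees(network)  # origin, target in-degrees per edge
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        raise DegenerateCorrelationError(
            "link-end in-degrees have zero variance; p is undefined"
        )
    cov = (x * y).mean() - x.mean() * y.mean()
    p = float(cov / np.sqrt(vx * vy))

    degrees = np.unique(np.concatenate([x, y]))
    K = degrees.size
    e = np.zeros((K, K))
    ix = np.searchsorted(degrees, y)  # target degree -> row
    jx = np.searchsorted(degrees, x)  # origin degree -> column
    np.add.at(e, (ix, jx), 1.0)
    e /= network.n_edges

    kin = network.in_degree
    counts = np.bincount(kin)
    P = counts / network.N
    kk = np.arange(counts.size)
    mean_k = np.sum(kk * P)
    # excess distribution (k+1)P(k+1)/<k>
    Qdeg = kk[:-1]
    Q = (Qdeg + 1) * P[1:] / mean_k
    keepq = Q > 0
    Qdeg, Q = Qdeg[keepq], Q[keepq]
    mq = np.sum(Qdeg * Q)
    sigma_in_sq = float(np.sum(Qdeg**2 * Q) - mq * mq)
    return CorrelationStats(
        p=p, degrees=degrees, e=e, Q_in=Q, Q_degrees=Qdeg, sigma_in_sq=sigma_in_sq
    )


def pearson_literal_shifted(network: DirectedNetwork) -> float:
    """Diagnostic: the correlation formula evaluated with the edge-counted
    joint over full in-degrees but the shifted excess distribution
    (k+1)P(k+1)/<k> as the marginal, as printed in the undirected
    convention.  Inconsistent marginals push this slightly outside [-1, 1]
    on strongly assortative graphs; kept only for comparison."""
    st = pearson_in_degree_correlation(network)
    mq = float(np.sum(st.Q_degrees * st.Q_in))
    kk = st.degrees.astype(float)
    ejoint = float(kk @ st.e @ kk)  # sum over k,k' of k*k'*e_kk'
    return (ejoint - mq * mq) / st.sigma_in_sq


# ---------------------------------------------------------------------------
# connection kernels


@dataclass
class ConnectionKernel:
    """Joint degree structure of inputs per in-degree class.

    ``f[i, j]`` is the probability that an incoming link of a
    ``degrees[i]``-neuron originates from a ``degrees[j]``-neuron; rows sum
    to 1.  ``counts`` (N_kk') is ``degrees[i] * f[i, j]``: the average
    number of degree-``degrees[j]`` inputs of a degree-``degrees[i]``
    neuron, with row sums equal to the degree.  ``weights`` holds the node
    fraction per degree class (used to average class rates).
    """

    degrees: np.ndarray
    f: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        # float degrees: coarse-grained kernels label classes by the mean
        # degree of a bin, which is generally non-integer
        self.degrees = np.asarray(self.degrees, dtype=np.float64)
        self.f = np.asarray(self.f, dtype=np.float64)
        K = self.degrees.size
        if self.f.shape != (K, K):
            raise ValueError("f must be square over the degree support")
        if np.any(self.f < -1e-15):
            raise ValueError("f entries must be nonnegative")
        rows = self.f.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > 1e-9:
            raise ValueError("rows of f must sum to 1")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=np.float64)

    @property
    def counts(self) -> np.ndarray:
        """N_kk' = k * f(k, k')."""
        return self.degrees[:, None].astype(float) * self.f

    def to_csv(self, path: str | Path) -> None:
        """Kernel file: CSV matrix of N_kk' with degree labels on the
        first row and column."""
        K = self.degrees.size
        M = np.zeros((K + 1, K + 1))
        M[0, 1:] = self.degrees
        M[1:, 0] = self.degrees
        M[1:, 1:] = self.counts
        header = "N_kk' matrix; first row/column hold degree labels"
        np.savetxt(path, M, delimiter=",", header=header)

    @classmethod
    def from_csv(cls, path: str | Path, weights: np.ndarray | None = None):
        M = np.loadtxt(path, delimiter=",")
        degrees = M[0, 1:]
        counts = M[1:, 1:]
        f = counts / degrees[:, None]
        return cls(degrees=degrees, f=f, weights=weights)


def sample_joint_degree(network: DirectedNetwork) -> ConnectionKernel:
    """Estimate N_kk' from the adjacency: count directed links E_kk' from
    in-degree-k' nodes into in-degree-k nodes, then
    N_kk' = k * E_kk' / sum_k'' E_kk'' (row sums equal k by construction).
    Class weights are the realized node fractions per in-degree."""
    kin = network.in_degree
    node_degrees, node_counts = np.unique(kin, return_counts=True)
    if node_degrees[0] == 0:
        raise ValueError(
            "degree class k=0 has no incoming links; its kernel row is undefined"
        )
    degrees = node_degrees
    K = degrees.size
    x, y = _edge_end_degrees(network)
    ix = np.searchsorted(degrees, y)  # target class row
    jx = np.searchsorted(degrees, x)  # origin class column
    E = np.zeros((K, K))
    np.add.at(E, (ix, jx), 1.0)
    row_tot = E.sum(axis=1)
    if np.any(row_tot == 0):
        raise ValueError("represented degree class with zero incoming links")
    f = E / row_tot[:, None]
    weights = node_counts / network.N
    return ConnectionKernel(degrees=degrees, f=f, weights=weights)


_KERNEL_KINDS = (
    "independent_inout",
    "uncorrelated_equal_inout",
    "assortative_delta",
    "disassortative_delta",
)


def analytic_kernel(dist: DegreeDistribution, kind: str) -> ConnectionKernel:
    """Closed-form connection kernels on the support of ``dist``.

    - ``independent_inout``: f(k,k') = P(k') (in- and out-degrees drawn
      independently; inputs sample the plain degree distribution).
    - ``uncorrelated_equal_inout``: f(k,k') = k'P(k')/<k> (equal in/out
      degree per node, no in-degree correlations; inputs sample the
      link-weighted distribution).
    - ``assortative_delta``: f(k,k') = delta(k,k') (maximally assortative;
      the network segregates into per-degree subnetworks).
    - ``disassortative_delta``: f(k,k') = delta(k, k_min*k_max/k'), the
      peak-position fit for the maximally disassortative network; the
      generally non-integer partner degree is mapped to the nearest degree
      in the support, ties toward the smaller degree.
    """
    if kind not in _KERNEL_KINDS:
        raise ValueError(f"unknown kernel kind {kind!r}; choose from {_KERNEL_KINDS}")
    deg = dist.degrees
    K = deg.size
    P = dist.pmf
    if kind == "independent_inout":
        f = np.tile(P, (K, 1))
    elif kind == "uncorrelated_equal_inout":
        row = deg * P
        row = row / row.sum()
        f = np.tile(row, (K, 1))
    elif kind == "assortative_delta":
        f = np.eye(K)
    else:  # disassortative_delta
        f = np.zeros((K, K))
        partners = dist.k_min * dist.k_max / deg.astype(float)
        for i, part in enumerate(partners):
            j = int(np.searchsorted(deg, part))
            if j >= K:
                j = K - 1
            elif j > 0:
                lo, hi = deg[j - 1], deg[j]
                # nearest degree; ties toward the smaller one
                j = j - 1 if (part - lo) <= (hi - part) else j
            f[i, j] = 1.0
    return ConnectionKernel(degrees=deg.copy(), f=f, weights=P.copy())


def bin_kernel(kernel: ConnectionKernel, n_bins: int) -> ConnectionKernel:
    """Coarse-grain a kernel onto logarithmically spaced degree bins.

    Classes are merged weighted by their node fractions; the merged class
    is labeled by the weight-averaged degree, so the row-sum identity
    sum_k' N_kk' = k holds exactly with k the bin's mean degree.  Used to
    speed up the coupled solver when several hundred distinct degrees are
    present; empty bins are dropped.
    """
    if kernel.weights is None:
        raise ValueError("binning requires class weights")
    deg = kernel.degrees
    if deg.size <= n_bins:
        return kernel
    edges = np.geomspace(deg.min(), deg.max() + 1.0, n_bins + 1)
    assign = np.clip(np.searchsorted(edges, deg, side="right") - 1, 0, n_bins - 1)
    used = np.unique(assign)
    B = used.size
    remap = {int(b): i for i, b in enumerate(used)}
    idx = np.array([remap[int(b)] for b in assign])
    w = kernel.weights
    counts = kernel.counts
    W = np.zeros(B)
    np.add.at(W, idx, w)
    kbar = np.zeros(B)
    np.add.at(kbar, idx, w * deg)
    kbar /= W
    # expected inputs of a bin-b node from bin b'
    M = np.zeros((B, B))
    for i in range(deg.size):
        M[idx[i]] += w[i] * np.bincount(idx, weights=counts[i], minlength=B)
    M /= W[:, None]
    f = M / M.sum(axis=1, keepdims=True)
    return ConnectionKernel(degrees=kbar, f=f, weights=W)
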