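"""Model parameters and run configuration.

Units are millivolts and milliseconds throughout the internal computation;
firing rates are reported in Hz.  The stimulus ``s`` is dimensionless and
expressed in units of the threshold rate ``nu_thr = theta / (J * tau)``,
the external Poisson rate at which the mean drive alone reaches threshold.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire single-neuron constants.

    Attributes
    ----------
    tau : float
        Membrane time constant in ms.
    tau_ref : float
        Absolute refractory period in ms.
    theta : float
        Firing threshold in mV.
    v_reset : float
        Reset potential in mV.
    J : float
        Postsynaptic potential amplitude per spike in mV.
    """

    tau: float = 20.0
    tau_ref: float = 2.0
    theta: float = 20.0
    v_reset: float = 10.0
    J: float = 0.1

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.tau_ref <= 0 or self.J <= 0:
            raise ValueError("tau, tau_ref and J must be positive")
        if self.theta <= self.v_reset:
            raise ValueError("theta must exceed v_reset")

    @property
    def nu_thr(self) -> float:
        """Threshold rate theta/(J*tau) in spikes/ms (10 kHz for defaults)."""
        return self.theta / (self.J * self.tau)

    @property
    def rate_max_hz(self) -> float:
        """Refractory bound on the firing rate, in Hz."""
        return 1000.0 / self.tau_ref


@dataclass(frozen=True)
class SimConfig:
    """Direct-simulation settings (ms units; ``s`` in units of nu_thr)."""

    dt: float = 0.01
    T: float = 1000.0
    burn_in: float = 200.0
    s: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.T <= 0 or self.burn_in < 0:
            raise ValueError("dt and T must be positive, burn_in nonnegative")


@dataclass
class RunConfig:
    """Complete, file-round-trippable configuration of a run."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    sim: SimConfig = field(default_factory=SimConfig)
    # degree distribution / network
    alpha: float = -2.0
    k_min: int = 10
    k_max: int = 500
    N: int = 100_000
    delay_max_ms: float = 6.0
    # solver
    tau_x: float = 3.0
    dt_ratio: float = 1.0
    tol_hz: float = 1e-6
    t_max_factor: float = 2000.0
    # grids
    s_min: float = 0.0
    s_max: float = 1.2
    ds: float = 0.02
    dead_rate_hz: float = 0.1
    # readout
    n_readout: int = 5000
    seed: int = 0
    out_dir: str = "."

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["neuron"] = NeuronParams(**d["neuron"])
        d["sim"] = SimConfig(**d["sim"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_paper_config() -> RunConfig:
    """Reference parameter set: tau=20 ms, tau_ref=2 ms, V_reset=10 mV,
    J=0.1 mV, theta=20 mV, N=1e5, dt=0.01 ms, delays uniform on [0, 6] ms."""
    return RunConfig()
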