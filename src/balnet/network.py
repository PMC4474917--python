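"""Random balanced network construction.

The network is a sparse random graph of leaky integrate-and-fire neurons,
80% excitatory and 20% inhibitory by default.  Synapses are delta-current
("jump") synapses parameterized directly by the postsynaptic-potential
amplitude in mV; inhibitory synapses are ``g`` times stronger than
excitatory ones (inhibition dominance).  Each neuron carries a preferred
orientation (PO) inherited from its feedforward input; POs are uniformly
spaced on [0, 180) within each population and neurons are indexed in
ascending PO order, so connectivity matrices can be read as
orientation-sorted maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["NetworkConfig", "Network", "build_network"]


@dataclass
class NetworkConfig:
    """Parameters of the network model (amplitudes in mV, times in ms).

    ``J_inh`` is derived as ``-g * J_exc``; ``eps_*`` are out-connection
    probabilities per ordered (pre, post) pair, drawn independently.
    """

    N: int = 500
    f: float = 0.8               # excitatory fraction
    eps_EE: float = 0.30
    eps_EI: float = 0.30
    eps_IE: float = 1.0
    eps_II: float = 1.0
    J_exc: float = 0.5           # EPSP amplitude, mV
    g: float = 8.0               # inhibition dominance, J_inh = -g*J_exc
    J_ffw: float = 1.0           # feedforward EPSP, mV
    tau_m: float = 20.0          # membrane time constant, ms
    u_th: float = 20.0           # spike threshold, mV
    u_rest: float = 0.0          # reset / resting potential, mV
    t_ref: float = 0.0           # refractory period, ms
    dt: float = 1.0              # integration step, ms
    init_weight_mode: str = "fixed"   # "fixed" | "gaussian"

    @property
    def J_inh(self) -> float:
        return -self.g * self.J_exc

    @property
    def N_exc(self) -> int:
        return int(round(self.f * self.N))

    @property
    def N_inh(self) -> int:
        return self.N - self.N_exc

    def validate(self) -> None:
        if not (0.0 < self.f < 1.0):
            raise ValueError(f"excitatory fraction f={self.f} must be in (0,1)")
        for name in ("eps_EE", "eps_EI", "eps_IE", "eps_II"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.J_exc <= 0:
            raise ValueError("J_exc must be positive")
        if self.g <= 0:
            raise ValueError("g must be positive (J_inh = -g*J_exc < 0)")
        if self.dt <= 0 or self.tau_m <= 0:
            raise ValueError("dt and tau_m must be positive")
        if self.init_weight_mode not in ("fixed", "gaussian"):
            raise ValueError(f"unknown init_weight_mode {self.init_weight_mode!r}")
        if self.N_exc < 1 or self.N_inh < 1:
            raise ValueError("both populations must be non-empty")

    def copy(self, **changes) -> "NetworkConfig":
        return replace(self, **changes)


@dataclass
class Network:
    """A wired network: signed weights, population labels and input POs.

    ``W[j, i]`` is the PSP amplitude (mV) of the synapse from presynaptic
    neuron ``j`` to postsynaptic neuron ``i``; 0 means no synapse, and a
    zero entry at construction stays zero forever (no structural
    plasticity).  Rows of excitatory neurons are >= 0, rows of inhibitory
    neurons are <= 0.  ``plastic_mask`` marks the synapses the voltage
    rule may modify (by default E->E, E->I and I->E; I->I frozen).
    """

    config: NetworkConfig
    W: np.ndarray                 # (N, N) signed PSP amplitudes, mV
    pop: np.ndarray               # (N,) 'E'/'I' labels
    PO: np.ndarray                # (N,) preferred orientation, deg in [0,180)
    plastic_mask: np.ndarray = field(default=None)  # (N, N) bool

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def exc(self) -> np.ndarray:
        """Boolean mask of excitatory neurons."""
        return self.pop == "E"

    @property
    def inh(self) -> np.ndarray:
        return self.pop == "I"

    @property
    def conn(self) -> np.ndarray:
        """Boolean existing-synapse mask (structural graph)."""
        return self._conn

    def set_conn(self, conn: np.ndarray) -> None:
        self._conn = conn

    def copy(self) -> "Network":
        net = Network(self.config, self.W.copy(), self.pop.copy(),
                      self.PO.copy(), self.plastic_mask.copy())
        net.set_conn(self.conn.copy())
        return net


def _uniform_pos(n: int) -> np.ndarray:
    """n POs uniformly spaced on [0, 180), ascending."""
    return 180.0 * np.arange(n) / n


def build_network(config: NetworkConfig, seed: int) -> Network:
    """Wire a random balanced network; deterministic given ``seed``.

    Each ordered pair (pre, post) without autapse receives a synapse with
    the class probability eps_XY (X = pre population, Y = post
    population).  Existing excitatory synapses start at ``J_exc`` (or, in
    ``gaussian`` mode, at draws from N(J_exc, J_exc) with negative values
    clipped to 0 while the synapse itself persists); inhibitory synapses
    start at ``-g * J_exc``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    N, nE = config.N, config.N_exc
    exc = np.zeros(N, dtype=bool)
    exc[:nE] = True
    pop = np.where(exc, "E", "I")

    # class-wise Bernoulli wiring, no autapses
    prob = np.empty((N, N))
    prob[np.ix_(exc, exc)] = config.eps_EE
    prob[np.ix_(exc, ~exc)] = config.eps_EI
    prob[np.ix_(~exc, exc)] = config.eps_IE
    prob[np.ix_(~exc, ~exc)] = config.eps_II
    conn = rng.random((N, N)) < prob
    np.fill_diagonal(conn, False)

    W = np.zeros((N, N))
    if config.init_weight_mode == "gaussian":
        Jdraw = rng.normal(config.J_exc, config.J_exc, size=(N, N))
        np.clip(Jdraw, 0.0, None, out=Jdraw)
        W[exc] = Jdraw[exc]
    else:
        W[exc] = config.J_exc
    W[~exc] = config.J_inh
    W[~conn] = 0.0

    PO = np.concatenate([_uniform_pos(nE), _uniform_pos(N - nE)])

    # default plastic classes: E->E, E->I, I->E; I->I frozen
    plastic = conn.copy()
    plastic[np.ix_(~exc, ~exc)] = False

    net = Network(config, W, pop, PO, plastic)
    net.set_conn(conn)
    return net
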