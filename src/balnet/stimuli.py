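"""Orientation-tuned feedforward drive and stimulation schedules.

All feedforward synapses onto a neuron are lumped into one Poisson
channel whose rate follows a cosine tuning curve of the stimulus
orientation theta and the neuron's input preferred orientation theta*:

    s(theta, theta*) = s_b * [1 + mu * cos(2*(theta - theta*))]

with baseline s_b = 2 kHz and relative modulation mu_exc = 20% for
excitatory and mu_inh = 2% for inhibitory targets.  A protocol is an
ordered list of constant-rate segments (an orientation, or UNTUNED
background), grouped into batches at whose boundaries weights are
snapshotted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "InputParams", "Segment", "StimulusProtocol", "input_rate",
    "make_learning_protocol", "make_tuning_probe",
    "make_spontaneous_protocol", "apply_connectivity_factor",
    "cardinal_biased_weights", "PROBE_ORIENTATIONS",
]

#: the 8 probe orientations used for tuning curves (deg)
PROBE_ORIENTATIONS = tuple(np.arange(8) * 22.5)


@dataclass(frozen=True)
class InputParams:
    """Feedforward input parameters (rates in kHz, amplitudes in mV)."""

    s_b: float = 2.0        # untuned baseline rate, kHz
    mu_exc: float = 0.20    # relative modulation, excitatory targets
    mu_inh: float = 0.02    # relative modulation, inhibitory targets
    J_ffw: float = 1.0      # feedforward EPSP, mV
    C: int = 1              # connectivity factor (input rescaling)

    def validate(self) -> None:
        if self.s_b < 0:
            raise ValueError("baseline rate must be >= 0")
        if not (0 <= self.mu_exc <= 1 and 0 <= self.mu_inh <= 1):
            raise ValueError("modulation ratios must lie in [0, 1]")
        if self.C < 1:
            raise ValueError("connectivity factor C must be >= 1")


@dataclass(frozen=True)
class Segment:
    """One constant-rate stimulation segment.

    ``orientation`` is in degrees, or None for an UNTUNED segment whose
    rate is ``baseline`` (kHz) for every neuron regardless of PO.
    """

    orientation: Optional[float]
    duration_ms: float
    baseline: Optional[float] = None  # only used when orientation is None

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("segment duration must be positive")


@dataclass
class StimulusProtocol:
    segments: list
    batch_boundaries: list            # segment indices starting each batch
    input_params: InputParams = field(default_factory=InputParams)
    orientation_weights: Optional[dict] = None   # orientation -> probability

    @property
    def n_batches(self) -> int:
        return len(self.batch_boundaries)

    @property
    def total_duration_ms(self) -> float:
        return float(sum(s.duration_ms for s in self.segments))

    def rates(self, PO: np.ndarray, exc: np.ndarray, segment: Segment) -> np.ndarray:
        """Per-neuron feedforward rate (kHz) during ``segment``."""
        p = self.input_params
        if segment.orientation is None:
            base = p.s_b / 2.0 if segment.baseline is None else segment.baseline
            return np.full(PO.shape, base)
        mu = np.where(exc, p.mu_exc, p.mu_inh)
        return input_rate(segment.orientation, PO, p, mu=mu)

    def to_table(self) -> "np.ndarray":
        """(segment_index, orientation_or_nan, duration_ms) audit table."""
        rows = [(i, np.nan if s.orientation is None else s.orientation,
                 s.duration_ms) for i, s in enumerate(self.segments)]
        return np.array(rows)


def input_rate(theta_deg, theta_star_deg, params: InputParams,
               population_label: str = "E", mu=None):
    """Cosine-tuned feedforward rate in kHz; angles wrap mod 180 degrees.

    ``mu`` overrides the population choice (used for vectorized per-neuron
    evaluation); otherwise ``population_label`` selects mu_exc or mu_inh.
    """
    params.validate()
    if mu is None:
        mu = params.mu_exc if population_label == "E" else params.mu_inh
    d = np.deg2rad(np.asarray(theta_deg, dtype=float)
                   - np.asarray(theta_star_deg, dtype=float))
    return params.s_b * (1.0 + mu * np.cos(2.0 * d))


def learning_orientations(n_orientations: int = 20) -> np.ndarray:
    if 180.0 % n_orientations and not np.isclose(180.0 % n_orientations, 0):
        raise ValueError("n_orientations must divide 180 deg evenly")
    return 180.0 * np.arange(n_orientations) / n_orientations


def cardinal_biased_weights(n_orientations: int = 20) -> dict:
    """Stimulus statistics with 0 and 90 deg jointly making up 50%.

    P(0) = P(90) = 0.25; the remaining probability mass is spread
    uniformly over the other orientations.
    """
    oris = learning_orientations(n_orientations)
    cardinal = {0.0, 90.0}
    rest = [o for o in oris if o not in cardinal]
    w = {o: 0.25 for o in cardinal}
    for o in rest:
        w[o] = 0.5 / len(rest)
    return w


def make_learning_protocol(n_batches: int, n_orientations: int = 20,
                           stim_ms: float = 100.0,
                           orientation_weights: Optional[dict] = None,
                           seed: int = 0,
                           input_params: Optional[InputParams] = None,
                           ) -> StimulusProtocol:
    """Batched random sequences of oriented stimuli.

    Under uniform statistics each batch is a random permutation of the
    ``n_orientations`` equally spaced orientations (9 deg spacing by
    default); under biased statistics each batch is ``n_orientations``
    i.i.d. draws from ``orientation_weights``.
    """
    rng = np.random.default_rng(seed)
    oris = learning_orientations(n_orientations)
    segments = []
    boundaries = []
    for _ in range(n_batches):
        boundaries.append(len(segments))
        if orientation_weights is None:
            batch = rng.permutation(oris)
        else:
            keys = np.array(sorted(orientation_weights))
            p = np.array([orientation_weights[k] for k in keys])
            if not np.isclose(p.sum(), 1.0) or (p < 0).any():
                raise ValueError("orientation_weights must be a probability "
                                 "distribution")
            batch = rng.choice(keys, size=n_orientations, p=p)
        segments.extend(Segment(float(o), stim_ms) for o in batch)
    return StimulusProtocol(segments, boundaries,
                            input_params or InputParams(),
                            orientation_weights)


def make_tuning_probe(n_orientations: int = 8, trial_ms: float = 2000.0,
                      n_trials: int = 10,
                      input_params: Optional[InputParams] = None,
                      ) -> StimulusProtocol:
    """Fixed orientation-major probe: n_trials x n_orientations segments.

    Weights are meant to be frozen while probing (pass plasticity=None to
    the simulator).  With ``n_trials == 1`` the per-orientation trial
    spread is undefined and reported as NaN downstream.
    """
    oris = 180.0 * np.arange(n_orientations) / n_orientations
    segments = [Segment(float(o), trial_ms)
                for o in oris for _ in range(n_trials)]
    # one batch per orientation block keeps snapshot bookkeeping regular
    boundaries = [i * n_trials for i in range(n_orientations)]
    return StimulusProtocol(segments, boundaries,
                            input_params or InputParams())


def make_spontaneous_protocol(n_batches: int,
                              params: Optional[InputParams] = None,
                              batch_ms: float = 2000.0,
                              baseline: Optional[float] = None,
                              ) -> StimulusProtocol:
    """Untuned background drive (spontaneous state), batched for snapshots.

    Default baseline is s_b/2 with mu = 0 for both populations; the
    denser-connectivity variant uses the full s_b (pass ``baseline``).
    """
    params = params or InputParams()
    base = params.s_b / 2.0 if baseline is None else baseline
    segments = [Segment(None, batch_ms, baseline=base)
                for _ in range(n_batches)]
    return StimulusProtocol(segments, list(range(n_batches)), params)


def apply_connectivity_factor(params: InputParams, C: int) -> InputParams:
    """Rescale input for an effective connectivity increase by factor C.

    The baseline scales with C, the relative excitatory modulation with
    1/C, and the feedforward synaptic strength with 1/C, so the absolute
    modulation s_b*mu_exc*J_ffw is invariant; mu_inh is unchanged.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    return replace(params, s_b=params.s_b * C, mu_exc=params.mu_exc / C,
                   J_ffw=params.J_ffw / C, C=C)
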