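"""Voltage-based Hebbian plasticity and the inhibitory rate rule.

The main rule is a voltage-triplet rule: per plastic synapse i with
presynaptic spike train X_i(t), presynaptic trace x_i(t) and postsynaptic
voltage filters u-(t), u+(t),

    dw_i/dt = - A_LTD(uu) * X_i(t) * [u-(t) - theta-]+
              + A_LTP * x_i(t) * [u(t) - theta+]+ * [u+(t) - theta-]+

with hard bounds per class.  A_LTD is homeostatic: it scales with the
square of the mean depolarization uu of the postsynaptic neuron over a
trailing 0.1 s window, relative to a reference u_ref^2.  Depression fires
as one discrete jump per delivered presynaptic spike; potentiation is
integrated with forward Euler at dt.  The rule is applied identically to
E->E, E->I and I->E synapses; inhibitory weights evolve in magnitude
(potentiation of inhibition = larger IPSP amplitude) inside [0, 5] mV,
excitatory weights inside [0, 2] mV.

The alternative I->E rule (rate-homeostatic, Vogels-Sprekeler type)
updates the IPSP magnitude by eta*(x_post - alpha) on presynaptic spikes
and eta*x_pre on postsynaptic spikes; its fixed point sets the excitatory
firing rate to alpha/(2*k*tau_x) where k is the per-spike trace
increment, i.e. 5 Hz for the defaults with k = 1/tau_x.

The functions here are the transparent numpy reference implementation;
the production simulator applies the identical update order inside a
compiled kernel (see ``engine``) and is tested against a scalar
transcription of these steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PlasticityParams", "VogelsParams", "homeostatic_amplitude",
    "update_filters", "voltage_rule_step", "vogels_rule_step",
]

#: hard weight-magnitude bounds per presynaptic class, mV
W_BOUNDS = {"E": (0.0, 2.0), "I": (0.0, 5.0)}


@dataclass(frozen=True)
class PlasticityParams:
    """Voltage-rule parameters (Table-of-parameters defaults)."""

    A_LTD: float = 14e-5        # depression amplitude
    A_LTP: float = 8e-5         # potentiation amplitude
    A_LTP_exc: float = None     # per-class override (pre = E), else A_LTP
    A_LTP_inh: float = None     # per-class override (pre = I), else A_LTP
    theta_minus: float = -20.0  # mV, depression voltage threshold
    theta_plus: float = 7.5     # mV, potentiation voltage threshold
    tau_minus: float = 10.0     # ms, slow voltage filter
    tau_plus: float = 7.0       # ms, fast voltage filter
    tau_x: float = 15.0         # ms, presynaptic trace
    u_ref_sq: float = 70.0      # mV^2, homeostatic reference
    homeo_window: float = 100.0  # ms, trailing mean-depolarization window
    homeo_exponential: bool = False  # exponential variant of the window
    w_max_exc: float = 2.0      # mV, excitatory hard bound
    w_max_inh: float = 5.0      # mV, inhibitory magnitude hard bound
    rule_IE: str = "voltage"    # {"voltage", "vogels", "frozen"}
    vogels: "VogelsParams" = None

    def __post_init__(self):
        for name in ("tau_minus", "tau_plus", "tau_x", "homeo_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.A_LTD < 0 or self.A_LTP < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.w_max_exc <= 0 or self.w_max_inh <= 0:
            raise ValueError("bounds must be ordered (w_max > 0)")
        if self.rule_IE not in ("voltage", "vogels", "frozen"):
            raise ValueError(f"unknown rule_IE {self.rule_IE!r}")
        if self.rule_IE == "vogels" and self.vogels is None:
            object.__setattr__(self, "vogels", VogelsParams(tau_x=self.tau_x))

    @property
    def a_ltp_exc(self) -> float:
        return self.A_LTP if self.A_LTP_exc is None else self.A_LTP_exc

    @property
    def a_ltp_inh(self) -> float:
        return self.A_LTP if self.A_LTP_inh is None else self.A_LTP_inh

    @property
    def trace_increment(self) -> float:
        """Per-spike jump of the presynaptic trace (impulse response)."""
        return 1.0 / self.tau_x

    def copy(self, **changes) -> "PlasticityParams":
        return replace(self, **changes)

    @classmethod
    def zero(cls) -> "PlasticityParams":
        """Rule with both amplitudes zero (dynamics identical to frozen)."""
        return cls(A_LTD=0.0, A_LTP=0.0)


@dataclass(frozen=True)
class VogelsParams:
    """Rate-homeostatic inhibitory rule parameters."""

    eta: float = 0.1     # learning rate
    alpha: float = 0.01  # depression factor (per-ms target-rate scale)
    tau_x: float = 15.0  # ms, spike-trace time constant (shared)

    def __post_init__(self):
        if self.eta <= 0 or self.alpha < 0:
            raise ValueError("eta must be > 0 and alpha >= 0")


def homeostatic_amplitude(u_dblbar, params: PlasticityParams):
    """Depression amplitude A_LTD * uu^2 / u_ref^2 (homeostatic gate)."""
    u_dblbar = np.asarray(u_dblbar, dtype=float)
    if not np.all(np.isfinite(u_dblbar)):
        raise ValueError("mean depolarization must be finite")
    return params.A_LTD * u_dblbar ** 2 / params.u_ref_sq


def update_filters(u_minus, u_plus, x_bar, u_now, presyn_spikes, dt,
                   params: PlasticityParams):
    """One step of the three exponential filters (returns new values).

    u- and u+ relax toward the current voltage with tau- and tau+; the
    presynaptic trace decays with tau_x and jumps by 1/tau_x per
    delivered presynaptic spike (``presyn_spikes`` are per-neuron
    counts).
    """
    dm = np.exp(-dt / params.tau_minus)
    dp = np.exp(-dt / params.tau_plus)
    dx = np.exp(-dt / params.tau_x)
    u_minus = u_minus * dm + (1.0 - dm) * u_now
    u_plus = u_plus * dp + (1.0 - dp) * u_now
    x_bar = x_bar * dx + np.asarray(presyn_spikes) * params.trace_increment
    return u_minus, u_plus, x_bar


def voltage_rule_step(W_mag, conn_mask, pre_spikes, u_post, u_minus_post,
                      u_plus_post, x_bar_pre, u_dblbar_post, a_ltp_pre,
                      dt, params: PlasticityParams):
    """Weight-magnitude deltas for one step of the voltage rule.

    ``W_mag`` is the (pre, post) magnitude block of plastic synapses with
    structural mask ``conn_mask``; ``pre_spikes`` are delivered
    presynaptic spike counts this step.  Returns the delta matrix (not
    yet clipped); entries outside the mask are zero.
    """
    u_post = np.asarray(u_post, dtype=float)
    u_minus_post = np.asarray(u_minus_post, dtype=float)
    u_plus_post = np.asarray(u_plus_post, dtype=float)
    x_bar_pre = np.asarray(x_bar_pre, dtype=float)
    a_ltp_pre = np.asarray(a_ltp_pre, dtype=float)
    ltd_post = homeostatic_amplitude(u_dblbar_post, params) \
        * np.maximum(u_minus_post - params.theta_minus, 0.0)
    dW = -np.outer(np.asarray(pre_spikes, dtype=float), ltd_post)
    gate = np.maximum(u_post - params.theta_plus, 0.0) \
        * np.maximum(u_plus_post - params.theta_minus, 0.0)
    dW += dt * np.outer(a_ltp_pre * x_bar_pre, gate)
    dW[~conn_mask] = 0.0
    if not np.all(np.isfinite(dW)):
        raise FloatingPointError("non-finite plasticity update "
                                 "(parameter blow-up?)")
    return dW


def vogels_rule_step(W_IE_mag, conn_mask, spikes_pre_I, spikes_post_E,
                     x_bar_pre_I, x_bar_post_E, params_v: VogelsParams):
    """Magnitude deltas of the rate-homeostatic inhibitory rule.

    Presynaptic (inhibitory) spikes change the magnitude by
    eta*(x_post - alpha); postsynaptic (excitatory) spikes by eta*x_pre.
    Deltas are zero outside the structural mask.
    """
    pre = np.asarray(spikes_pre_I, dtype=float)
    post = np.asarray(spikes_post_E, dtype=float)
    x_post = np.asarray(x_bar_post_E, dtype=float)
    x_pre = np.asarray(x_bar_pre_I, dtype=float)
    dW = params_v.eta * np.outer(pre, x_post - params_v.alpha)
    dW += params_v.eta * np.outer(x_pre, post)
    dW[~conn_mask] = 0.0
    return dW
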