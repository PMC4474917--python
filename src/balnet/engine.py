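"""Leaky integrate-and-fire network simulator with online plasticity.

Integration uses the exact propagator of the leak ODE at a fixed step dt:
between spikes u(t+dt) = u(t)*exp(-dt/tau_m), and every delivered spike
adds its PSP amplitude instantaneously (delta synapses).  Spikes emitted
at step t are delivered at step t+1 (one-step effective delay; the model
itself has no synaptic delay in continuous time); feedforward Poisson
counts drawn for a step are delivered within that step.  Synaptic input
is accumulated in ascending presynaptic-index order, which fixes the
floating-point accumulation order and makes runs bit-reproducible for a
given (network, protocol, seed).

At a spike step the voltage entering the plasticity filters and the
[u - theta+]+ factor is clamped to the threshold u_th; the reset to
u_rest is applied after the filter and weight updates.  Update order
within a step: leak -> recurrent delivery -> feedforward -> spike
detection -> voltage filters and homeostatic window -> LTD (per
delivered presynaptic spike) -> presynaptic-trace update -> LTP ->
inhibitory rate rule (if enabled) -> reset -> recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .network import Network
from .plasticity import PlasticityParams
from .stimuli import StimulusProtocol

__all__ = ["RecordSpec", "SimState", "SimResult", "simulate",
           "free_potential_decomposition"]


@dataclass
class RecordSpec:
    """What to record beyond spikes and snapshots."""

    voltage_ids: Sequence[int] = ()     # neurons with full u(t) traces
    no_threshold_ids: Sequence[int] = ()  # neurons with spiking disabled
    components: bool = False            # E/I input components for voltage_ids


@dataclass
class SimState:
    """Carry-over dynamical state between simulation phases."""

    u: np.ndarray
    u_minus: np.ndarray
    u_plus: np.ndarray
    x_bar: np.ndarray
    u_dblbar: np.ndarray
    boxbuf: np.ndarray
    boxsum: np.ndarray
    boxptr: int
    pending: np.ndarray      # spikes awaiting delivery next step
    refcnt: np.ndarray

    @classmethod
    def initial(cls, N: int, win_steps: int) -> "SimState":
        return cls(u=np.zeros(N), u_minus=np.zeros(N), u_plus=np.zeros(N),
                   x_bar=np.zeros(N), u_dblbar=np.zeros(N),
                   boxbuf=np.zeros((win_steps, N)), boxsum=np.zeros(N),
                   boxptr=0, pending=np.zeros(N),
                   refcnt=np.zeros(N, dtype=np.int64))


@dataclass
class SimResult:
    spike_times: np.ndarray          # ms, ascending
    spike_ids: np.ndarray
    weight_snapshots: list           # signed W at batch boundaries
    rates: np.ndarray                # (n_segments, N) Hz
    segments: list
    voltage: dict = field(default_factory=dict)
    state: SimState = None
    config_meta: dict = field(default_factory=dict)

    def spikes(self) -> np.ndarray:
        """(time_ms, neuron_id) two-column array."""
        return np.column_stack([self.spike_times, self.spike_ids])


@njit(cache=True)
def _run_segment(A, sign, mask_v, mask_g, wmax, exc_flag, no_spike,
                 u, uminus, uplus, xbar, ubar, boxbuf, boxsum, boxptr,
                 pending, refcnt, ffw_counts, J_ffw,
                 decay_m, u_th, u_rest, refrac_steps,
                 dm, dp, dx, k_x, a_ltd, uref2, th_m, th_p, altp_pre,
                 dt, plastic_on, vogels_on, homeo_exp, dh, eta, alpha,
                 rec_ids, rec_u, rec_ue, rec_ui, rec_comp, ue, ui,
                 spike_step, spike_id, counts_out, step0):
    N = A.shape[0]
    T = ffw_counts.shape[0]
    nr = rec_ids.shape[0]
    win = boxbuf.shape[0]
    cnew = np.zeros(N)
    ueff = np.zeros(N)
    ltd = np.zeros(N)
    gate = np.zeros(N)
    ns = 0
    for t in range(T):
        # leak (exact propagator) on actual and component potentials
        for i in range(N):
            u[i] *= decay_m
        if rec_comp:
            for r in range(nr):
                ue[r] *= decay_m
                ui[r] *= decay_m
        # recurrent delivery of last step's spikes, pre-index ascending
        for j in range(N):
            cj = pending[j]
            if cj > 0.0:
                sj = sign[j]
                for i in range(N):
                    u[i] += sj * A[j, i] * cj
                if rec_comp:
                    for r in range(nr):
                        i = rec_ids[r]
                        psp = sj * A[j, i] * cj
                        if sj > 0.0:
                            ue[r] += psp
                        else:
                            ui[r] += psp
        # feedforward Poisson input (excitatory source)
        for i in range(N):
            u[i] += J_ffw * ffw_counts[t, i]
        if rec_comp:
            for r in range(nr):
                ue[r] += J_ffw * ffw_counts[t, rec_ids[r]]
        # refractory clamp
        if refrac_steps > 0:
            for i in range(N):
                if refcnt[i] > 0:
                    u[i] = u_rest
                    refcnt[i] -= 1
        # threshold crossing
        for i in range(N):
            if u[i] >= u_th and no_spike[i] == 0 and \
                    (refrac_steps == 0 or refcnt[i] == 0):
                cnew[i] = 1.0
                spike_step[ns] = step0 + t
                spike_id[ns] = i
                ns += 1
                counts_out[i] += 1
                ueff[i] = u_th
            else:
                cnew[i] = 0.0
                ueff[i] = u[i]
        # voltage filters and homeostatic mean depolarization
        for i in range(N):
            uminus[i] = uminus[i] * dm + (1.0 - dm) * ueff[i]
            uplus[i] = uplus[i] * dp + (1.0 - dp) * ueff[i]
        if homeo_exp:
            for i in range(N):
                ubar[i] = ubar[i] * dh + (1.0 - dh) * ueff[i]
        else:
            for i in range(N):
                boxsum[i] += ueff[i] - boxbuf[boxptr, i]
                boxbuf[boxptr, i] = ueff[i]
                ubar[i] = boxsum[i] / win
            boxptr = (boxptr + 1) % win
        if plastic_on:
            # LTD: one jump per delivered presynaptic spike
            for i in range(N):
                ltd[i] = a_ltd * (ubar[i] * ubar[i] / uref2) * \
                    max(uminus[i] - th_m, 0.0)
            for j in range(N):
                cj = pending[j]
                if cj > 0.0:
                    for i in range(N):
                        if mask_v[j, i] and ltd[i] > 0.0:
                            a = A[j, i] - cj * ltd[i]
                            A[j, i] = a if a > 0.0 else 0.0
        if plastic_on or vogels_on:
            # presynaptic trace: decay plus impulse-response jumps
            for j in range(N):
                xbar[j] = xbar[j] * dx + pending[j] * k_x
        if plastic_on:
            # LTP: forward-Euler integration of the triplet term
            for i in range(N):
                gate[i] = max(ueff[i] - th_p, 0.0) * \
                    max(uplus[i] - th_m, 0.0)
            for j in range(N):
                xa = altp_pre[j] * xbar[j] * dt
                if xa > 0.0:
                    wj = wmax[j]
                    for i in range(N):
                        if mask_v[j, i] and gate[i] > 0.0:
                            a = A[j, i] + xa * gate[i]
                            A[j, i] = a if a < wj else wj
        if vogels_on:
            # inhibitory rate rule on I->E magnitudes, delivery-time events
            for j in range(N):
                cj = pending[j]
                if cj > 0.0 and sign[j] < 0.0:
                    for i in range(N):
                        if mask_g[j, i]:
                            a = A[j, i] + eta * (xbar[i] - alpha) * cj
                            if a < 0.0:
                                a = 0.0
                            elif a > wmax[j]:
                                a = wmax[j]
                            A[j, i] = a
            for i in range(N):
                ci = pending[i]
                if ci > 0.0 and exc_flag[i] == 1:
                    for j in range(N):
                        if mask_g[j, i]:
                            a = A[j, i] + eta * xbar[j] * ci
                            A[j, i] = a if a < wmax[j] else wmax[j]
        # reset and schedule delivery
        for i in range(N):
            if cnew[i] > 0.0:
                u[i] = u_rest
                if refrac_steps > 0:
                    refcnt[i] = refrac_steps
            pending[i] = cnew[i]
        for r in range(nr):
            rec_u[t, r] = u[rec_ids[r]]
            if rec_comp:
                rec_ue[t, r] = ue[r]
                rec_ui[t, r] = ui[r]
    return ns, boxptr


def _steps(duration_ms: float, dt: float) -> int:
    n = duration_ms / dt
    n_int = int(round(n))
    if abs(n - n_int) > 1e-9:
        raise ValueError(
            f"segment duration {duration_ms} ms is not a multiple of "
            f"dt = {dt} ms")
    return n_int


def simulate(network: Network, protocol: StimulusProtocol,
             plasticity: Optional[PlasticityParams] = None,
             seed: int = 0, record: Optional[RecordSpec] = None,
             state: Optional[SimState] = None,
             keep_state: bool = False,
             input_counts=None) -> SimResult:
    """Run a protocol through the network; returns spikes, rates, snapshots.

    With ``plasticity=None`` the weights are frozen (all snapshots equal
    the initial matrix).  The network's weight matrix ``network.W`` is
    updated in place when plasticity is on, so learning phases can be
    chained; pass ``network.copy()`` to keep the original.  ``seed``
    controls the feedforward Poisson realization only (wiring has its own
    seed in ``build_network``).  ``input_counts``, if given, is a callable
    ``(segment_index, n_steps, N) -> count array`` replacing the Poisson
    draw — scripted drive for calibration and testing.
    """
    cfg = network.config
    record = record or RecordSpec()
    pl = plasticity
    dt = cfg.dt
    N = network.N
    exc = network.exc
    sign = np.where(exc, 1.0, -1.0)
    A = np.abs(network.W)

    plastic_on = pl is not None and (pl.A_LTD > 0 or pl.a_ltp_exc > 0
                                     or pl.a_ltp_inh > 0)
    vogels_on = pl is not None and pl.rule_IE == "vogels"
    if pl is not None:
        mask_v = network.plastic_mask.copy()
        if pl.rule_IE != "voltage":
            mask_v[~exc, :] = False
        wmax = np.where(exc, pl.w_max_exc, pl.w_max_inh)
        altp_pre = np.where(exc, pl.a_ltp_exc, pl.a_ltp_inh)
        dm, dp, dx = (np.exp(-dt / tau) for tau in
                      (pl.tau_minus, pl.tau_plus, pl.tau_x))
        dh = np.exp(-dt / pl.homeo_window)
        win = max(1, int(round(pl.homeo_window / dt)))
        k_x = pl.trace_increment
        a_ltd, uref2 = pl.A_LTD, pl.u_ref_sq
        th_m, th_p = pl.theta_minus, pl.theta_plus
        homeo_exp = pl.homeo_exponential
        if vogels_on:
            eta, alpha = pl.vogels.eta, pl.vogels.alpha
            mask_g = network.conn & ~exc[:, None] & exc[None, :]
        else:
            eta = alpha = 0.0
            mask_g = np.zeros((N, N), dtype=bool)
    else:
        mask_v = np.zeros((N, N), dtype=bool)
        mask_g = np.zeros((N, N), dtype=bool)
        wmax = np.full(N, np.inf)
        altp_pre = np.zeros(N)
        dm = dp = dx = dh = 1.0
        win = 1
        k_x = a_ltd = 0.0
        uref2, th_m, th_p = 1.0, 0.0, 0.0
        homeo_exp = False
        eta = alpha = 0.0

    if state is None:
        state = SimState.initial(N, win)
    elif state.boxbuf.shape[0] != win:
        raise ValueError("carried-over state has a different homeostatic "
                         "window size")

    no_spike = np.zeros(N, dtype=np.uint8)
    for i in record.no_threshold_ids:
        no_spike[int(i)] = 1
    rec_ids = np.asarray(sorted(set(map(int, record.voltage_ids))),
                         dtype=np.int64)
    if rec_ids.size and (rec_ids.min() < 0 or rec_ids.max() >= N):
        raise IndexError("recorded neuron id out of range")
    rec_comp = bool(record.components) and rec_ids.size > 0
    ue = np.zeros(rec_ids.size)
    ui = np.zeros(rec_ids.size)

    refrac_steps = int(round(cfg.t_ref / dt))
    decay_m = np.exp(-dt / cfg.tau_m)
    mask_v8 = mask_v.astype(np.uint8)
    mask_g8 = mask_g.astype(np.uint8)
    exc8 = exc.astype(np.uint8)

    rng = np.random.default_rng(seed)
    boundaries = set(protocol.batch_boundaries)
    snapshots = [sign[:, None] * A]  # copy of initial signed W
    all_t, all_i = [], []
    rates = np.zeros((len(protocol.segments), N))
    trace_u, trace_ue, trace_ui = [], [], []
    step0 = 0
    for k, seg in enumerate(protocol.segments):
        if k in boundaries and k > 0:
            snapshots.append(sign[:, None] * A)
        T = _steps(seg.duration_ms, dt)
        rate_khz = protocol.rates(network.PO, exc, seg)
        if input_counts is not None:
            ffw = np.ascontiguousarray(input_counts(k, T, N),
                                       dtype=np.float64)
            if ffw.shape != (T, N):
                raise ValueError("input_counts must return a (T, N) array")
        else:
            ffw = rng.poisson(rate_khz * dt, size=(T, N)).astype(np.float64)
        spike_step = np.empty(T * N, dtype=np.int64)
        spike_id = np.empty(T * N, dtype=np.int32)
        counts = np.zeros(N, dtype=np.int64)
        rec_u = np.zeros((T if rec_ids.size else 0, rec_ids.size))
        rec_ue = np.zeros_like(rec_u) if rec_comp else np.zeros((0, 0))
        rec_ui = np.zeros_like(rec_ue)
        ns, state.boxptr = _run_segment(
            A, sign, mask_v8, mask_g8, wmax, exc8, no_spike,
            state.u, state.u_minus, state.u_plus, state.x_bar,
            state.u_dblbar, state.boxbuf, state.boxsum, state.boxptr,
            state.pending, state.refcnt, ffw, protocol.input_params.J_ffw,
            decay_m, cfg.u_th, cfg.u_rest, refrac_steps,
            dm, dp, dx, k_x, a_ltd, uref2, th_m, th_p, altp_pre,
            dt, plastic_on, vogels_on, homeo_exp, dh, eta, alpha,
            rec_ids, rec_u, rec_ue, rec_ui, rec_comp, ue, ui,
            spike_step, spike_id, counts, step0)
        if not np.all(np.isfinite(state.u)):
            raise FloatingPointError(
                "non-finite membrane potential (parameter blow-up); "
                f"segment {k}")
        all_t.append(spike_step[:ns] * dt)
        all_i.append(spike_id[:ns])
        rates[k] = counts / (seg.duration_ms / 1000.0)
        if rec_ids.size:
            trace_u.append(rec_u)
            if rec_comp:
                trace_ue.append(rec_ue)
                trace_ui.append(rec_ui)
        step0 += T
    snapshots.append(sign[:, None] * A)

    network.W[:] = sign[:, None] * A
    voltage = {}
    if rec_ids.size:
        voltage["ids"] = rec_ids
        voltage["u"] = np.concatenate(trace_u, axis=0)
        if rec_comp:
            voltage["u_exc"] = np.concatenate(trace_ue, axis=0)
            voltage["u_inh"] = np.concatenate(trace_ui, axis=0)
    return SimResult(
        spike_times=np.concatenate(all_t) if all_t else np.empty(0),
        spike_ids=np.concatenate(all_i) if all_i else np.empty(0, np.int32),
        weight_snapshots=snapshots, rates=rates,
        segments=list(protocol.segments), voltage=voltage,
        state=state if keep_state else None,
        config_meta={"seed": seed, "dt": dt, "N": N})


def free_potential_decomposition(network: Network,
                                 protocol: StimulusProtocol,
                                 neuron_ids: Sequence[int],
                                 seed: int = 0):
    """Free-membrane-potential traces for designated neurons.

    Re-simulates the protocol with the spiking threshold disabled for
    ``neuron_ids`` only (the rest of the network spikes normally), and
    records, per designated neuron, the leaky integrals of the
    excitatory-source input (feedforward + recurrent E) and of the
    inhibitory-source input separately.  Returns a dict with the actual
    potential ``u`` (threshold disabled, so free-running) and components
    ``u_exc``, ``u_inh`` with u = u_exc + u_inh.
    """
    ids = [int(i) for i in neuron_ids]
    if any(i < 0 or i >= network.N for i in ids):
        raise IndexError("neuron id out of range")
    rec = RecordSpec(voltage_ids=ids, no_threshold_ids=ids, components=True)
    res = simulate(network.copy(), protocol, plasticity=None, seed=seed,
                   record=rec)
    return res.voltage
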