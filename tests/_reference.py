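"""Transparent step-by-step reference simulator (independent oracle).

A literal scalar/numpy transcription of the documented per-step update
order, written without the compiled kernel, used to validate the
production engine on small networks.
"""

import numpy as np

from balnet.plasticity import homeostatic_amplitude


def reference_simulate(network, protocol, pl, seed):
    """Return (spike list [(t_ms, id)], final signed W)."""
    cfg = network.config
    N, dt = network.N, cfg.dt
    exc = network.exc
    sign = np.where(exc, 1.0, -1.0)
    A = np.abs(network.W).copy()
    mask_v = network.plastic_mask.copy()
    vogels = pl is not None and pl.rule_IE == "vogels"
    if pl is not None and pl.rule_IE != "voltage":
        mask_v[~exc, :] = False
    mask_g = (network.conn & ~exc[:, None] & exc[None, :]) if vogels \
        else np.zeros((N, N), dtype=bool)
    plastic = pl is not None and (pl.A_LTD > 0 or pl.a_ltp_exc > 0
                                  or pl.a_ltp_inh > 0)
    if pl is not None:
        wmax = np.where(exc, pl.w_max_exc, pl.w_max_inh)
        altp = np.where(exc, pl.a_ltp_exc, pl.a_ltp_inh)
        win = int(round(pl.homeo_window / dt))
    else:
        win = 1

    rng = np.random.default_rng(seed)
    u = np.zeros(N)
    um = np.zeros(N)
    up = np.zeros(N)
    xb = np.zeros(N)
    buf = np.zeros((win, N))
    bsum = np.zeros(N)
    ptr = 0
    pending = np.zeros(N)
    spikes = []
    step0 = 0
    for seg in protocol.segments:
        T = int(round(seg.duration_ms / dt))
        rates = protocol.rates(network.PO, exc, seg)
        ffw = rng.poisson(rates * dt, size=(T, N)).astype(np.float64)
        for t in range(T):
            u = u * np.exp(-dt / cfg.tau_m)
            for j in range(N):
                if pending[j] > 0:
                    u = u + sign[j] * A[j] * pending[j]
            u = u + protocol.input_params.J_ffw * ffw[t]
            s = u >= cfg.u_th
            ueff = np.where(s, cfg.u_th, u)
            if pl is not None:
                dm = np.exp(-dt / pl.tau_minus)
                dp = np.exp(-dt / pl.tau_plus)
                um = um * dm + (1.0 - dm) * ueff
                up = up * dp + (1.0 - dp) * ueff
                bsum = bsum + (ueff - buf[ptr])
                buf[ptr] = ueff
                ubar = bsum / win
                ptr = (ptr + 1) % win
            if plastic:
                ltd = homeostatic_amplitude(ubar, pl) * \
                    np.maximum(um - pl.theta_minus, 0.0)
                for j in range(N):
                    if pending[j] > 0:
                        for i in range(N):
                            if mask_v[j, i] and ltd[i] > 0:
                                A[j, i] = max(A[j, i] - pending[j] * ltd[i],
                                              0.0)
            if plastic or vogels:
                xb = xb * np.exp(-dt / pl.tau_x) + \
                    pending * pl.trace_increment
            if plastic:
                gate = np.maximum(ueff - pl.theta_plus, 0.0) * \
                    np.maximum(up - pl.theta_minus, 0.0)
                for j in range(N):
                    xa = altp[j] * xb[j] * dt
                    if xa > 0:
                        for i in range(N):
                            if mask_v[j, i] and gate[i] > 0:
                                A[j, i] = min(A[j, i] + xa * gate[i],
                                              wmax[j])
            if vogels:
                eta, alpha = pl.vogels.eta, pl.vogels.alpha
                for j in range(N):
                    if pending[j] > 0 and sign[j] < 0:
                        for i in range(N):
                            if mask_g[j, i]:
                                a = A[j, i] + eta * (xb[i] - alpha) * \
                                    pending[j]
                                A[j, i] = min(max(a, 0.0), wmax[j])
                for i in range(N):
                    if pending[i] > 0 and exc[i]:
                        for j in range(N):
                            if mask_g[j, i]:
                                A[j, i] = min(A[j, i] + eta * xb[j] *
                                              pending[i], wmax[j])
            for i in range(N):
                if s[i]:
                    spikes.append(((step0 + t) * dt, i))
                    u[i] = cfg.u_rest
            pending = s.astype(np.float64)
        step0 += T
    return spikes, sign[:, None] * A
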