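"""Selectivity and connectivity statistics.

Orientation selectivity is quantified globally as OSI = 1 - circular
variance = |sum_k r_k exp(2i*theta_k)| / sum_k r_k (theta in radians,
period 180 deg): 0 for a flat tuning curve, 1 for a response confined to
a single orientation.  Connectivity specificity is measured by the
weight-vs-dPO profile (dPO = circular PO difference in [0, 90] deg), its
three-group means (similar < 30 deg, indifferent 30-60 deg, dissimilar
> 60 deg), and a weighted bidirectionality index WBI = mean over
unordered neuron pairs of w_ij * w_ji, normalized by its shuffle
expectation (WBI_norm = 1 at chance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "TuningCurve", "ConnectivityReport", "tuning_curves", "osi",
    "population_average_tuning", "membrane_tuning", "weight_vs_dpo",
    "wbi", "wbi_norm", "weight_evolution", "delta_po",
]


@dataclass
class TuningCurve:
    orientations: np.ndarray       # deg
    mean_rate: np.ndarray          # Hz
    trial_sd: np.ndarray           # Hz (NaN if a single trial)
    preferred_input_orientation: float = np.nan

    def __post_init__(self):
        if len(self.orientations) != len(self.mean_rate):
            raise ValueError("length mismatch")
        if np.any(np.asarray(self.mean_rate) < 0):
            raise ValueError("rates must be >= 0")


@dataclass
class ConnectivityReport:
    weight_vs_dpo: pd.DataFrame    # columns: dpo (deg), weight (mV)
    group_means: dict              # 'similar'/'indifferent'/'dissimilar'
    binned_dpo: np.ndarray = None  # bin centers, deg
    binned_weight: np.ndarray = None
    weight_tuning_osi: float = np.nan
    wbi: float = np.nan
    wbi_norm: float = np.nan


def tuning_curves(sim_result, probe_protocol) -> list:
    """Per-neuron tuning curves from a probe simulation.

    Segments of the probe sharing an orientation are treated as trials;
    the mean and SD over trials of the per-segment firing rate give the
    curve.  An empty spike set yields valid all-zero curves.
    """
    oris = np.array([s.orientation for s in probe_protocol.segments],
                    dtype=float)
    uniq = np.unique(oris)
    rates = sim_result.rates            # (n_segments, N)
    N = rates.shape[1]
    mean = np.empty((len(uniq), N))
    sd = np.empty((len(uniq), N))
    for k, o in enumerate(uniq):
        trials = rates[oris == o]
        mean[k] = trials.mean(axis=0)
        sd[k] = trials.std(axis=0, ddof=1) if trials.shape[0] > 1 \
            else np.nan
    return [TuningCurve(uniq.copy(), mean[:, i], sd[:, i]) for i in range(N)]


def osi(curve) -> float:
    """Orientation selectivity index, 1 - circular variance, in [0, 1].

    Accepts a TuningCurve or an (orientations_deg, rates) pair; an
    all-zero curve has no defined selectivity and returns NaN.
    """
    if isinstance(curve, TuningCurve):
        theta, r = curve.orientations, curve.mean_rate
    else:
        theta, r = curve
    theta = np.deg2rad(np.asarray(theta, dtype=float))
    r = np.asarray(r, dtype=float)
    total = r.sum()
    if total <= 0:
        return np.nan
    return float(np.abs(np.sum(r * np.exp(2j * theta))) / total)


def population_average_tuning(curves, POs, n_bins: int = 180):
    """Average tuning curve after aligning each neuron to its input PO.

    Every sample of every curve is shifted so the neuron's PO falls at
    the center (90 deg) of the [0, 180) axis, then binned into ``n_bins``
    bins; returns (bin_centers_deg, mean, sd, osi_of_mean).  The
    construction is equivariant under a common shift of all POs and
    stimulus labels.
    """
    if len(curves) == 0:
        raise ValueError("need at least one curve")
    width = 180.0 / n_bins
    acc = [[] for _ in range(n_bins)]
    for curve, po in zip(curves, POs):
        rel = np.mod(curve.orientations - po + 90.0, 180.0)
        idx = np.minimum((rel / width).astype(int), n_bins - 1)
        for b, r in zip(idx, curve.mean_rate):
            acc[b].append(r)
    centers = (np.arange(n_bins) + 0.5) * width
    mean = np.array([np.mean(a) if a else np.nan for a in acc])
    sd = np.array([np.std(a) if a else np.nan for a in acc])
    ok = ~np.isnan(mean)
    return centers, mean, sd, osi((centers[ok], mean[ok]))


def membrane_tuning(voltage_by_orientation, rates_hz, tau_m_ms: float = 20.0,
                    u_th: float = 20.0):
    """Mean-voltage tuning and its free-potential correction.

    ``voltage_by_orientation`` maps orientation -> voltage trace (mV) of
    one neuron; ``rates_hz`` maps orientation -> mean firing rate.  The
    reset charge lost to spiking is restored by
    u_free = <u> + tau_m * u_th * r (tau_m in seconds, r in Hz).
    """
    oris = np.array(sorted(voltage_by_orientation))
    u_mean = np.array([np.mean(voltage_by_orientation[o]) for o in oris])
    r = np.array([rates_hz[o] for o in oris])
    u_free = u_mean + (tau_m_ms / 1000.0) * u_th * r
    return oris, u_mean, u_free


def delta_po(po_pre, po_post) -> np.ndarray:
    """Circular PO difference on the orientation metric, in [0, 90] deg."""
    d = np.abs(np.asarray(po_pre, dtype=float)
               - np.asarray(po_post, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


_GROUPS = (("similar", 0.0, 30.0), ("indifferent", 30.0, 60.0),
           ("dissimilar", 60.0, 90.0))


def weight_vs_dpo(W, POs, pre_mask, post_mask, conn=None,
                  n_bins: int = 18) -> ConnectivityReport:
    """Weight structure versus PO difference for one synapse class.

    Uses existing synapses only (``conn`` defaults to W != 0).  Group
    means are the mean weight magnitudes over the similar / indifferent /
    dissimilar dPO ranges; ``weight_tuning_osi`` treats the binned
    mean-magnitude profile as a tuning curve over 2*dPO in [0, 180) (the
    dPO half-axis mirrored onto a full orientation period) and applies
    the circular-variance formula.
    """
    W = np.asarray(W, dtype=float)
    POs = np.asarray(POs, dtype=float)
    if conn is None:
        conn = W != 0
    sel = conn & np.asarray(pre_mask)[:, None] & np.asarray(post_mask)[None, :]
    np.fill_diagonal(sel, False)
    pre_idx, post_idx = np.nonzero(sel)
    if pre_idx.size == 0:
        return ConnectivityReport(
            pd.DataFrame({"dpo": [], "weight": []}),
            {name: np.nan for name, *_ in _GROUPS})
    dpo = delta_po(POs[pre_idx], POs[post_idx])
    w = np.abs(W[pre_idx, post_idx])
    table = pd.DataFrame({"dpo": dpo, "weight": w})
    groups = {}
    for name, lo, hi in _GROUPS:
        m = (dpo >= lo) & (dpo < hi) if hi < 90 else (dpo >= lo)
        groups[name] = float(w[m].mean()) if m.any() else np.nan
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    binned = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = (dpo >= edges[b]) & (dpo < edges[b + 1]) if b < n_bins - 1 \
            else (dpo >= edges[b]) & (dpo <= edges[b + 1])
        if m.any():
            binned[b] = w[m].mean()
    ok = ~np.isnan(binned)
    tuning_osi = osi((2.0 * centers[ok], binned[ok]))
    return ConnectivityReport(table, groups, centers, binned, tuning_osi)


def _pair_product_sum(W_block: np.ndarray) -> float:
    """Sum over unordered pairs of |w_ij|*|w_ji| (diagonal excluded)."""
    A = np.abs(W_block)
    prod = A * A.T
    return 0.5 * (prod.sum() - np.trace(prod))


def wbi(W, scope_mask=None) -> float:
    """Weighted bidirectionality index over unordered in-scope pairs.

    ``scope_mask`` selects the neurons (default: all); the index is the
    mean of |w_ij|*|w_ji| over all unordered pairs in scope, so a
    strictly unidirectional matrix scores 0.
    """
    W = np.asarray(W, dtype=float)
    if scope_mask is not None:
        W = W[np.ix_(scope_mask, scope_mask)]
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least two neurons in scope")
    return _pair_product_sum(W) / (n * (n - 1) / 2.0)


def wbi_norm(W, scope_mask=None, n_shuffles: int = 100,
             seed: int = 0) -> float:
    """WBI normalized by its expectation under weight shuffling.

    The non-zero entries of the scoped block are placed uniformly at
    random among all off-diagonal positions of the block (preserving the
    weight multiset); the observed WBI is divided by the mean over
    ``n_shuffles`` surrogates.  Returns NaN for an all-zero scope.
    """
    W = np.asarray(W, dtype=float)
    if scope_mask is not None:
        W = W[np.ix_(scope_mask, scope_mask)]
    n = W.shape[0]
    observed = wbi(W)
    vals = W[(W != 0) & ~np.eye(n, dtype=bool)]
    if vals.size == 0:
        return np.nan
    rng = np.random.default_rng(seed)
    off = np.nonzero(~np.eye(n, dtype=bool))
    flat_sum = 0.0
    for _ in range(n_shuffles):
        S = np.zeros((n, n))
        pos = rng.choice(off[0].size, size=vals.size, replace=False)
        S[off[0][pos], off[1][pos]] = vals
        flat_sum += wbi(S)
    rand = flat_sum / n_shuffles
    if rand == 0:
        return np.nan
    return observed / rand


def weight_evolution(snapshots, class_masks) -> dict:
    """Per-class mean |dw| per batch and per-batch weight histograms.

    ``snapshots`` is the ordered list of weight matrices at batch
    boundaries; ``class_masks`` maps class name -> boolean synapse mask
    (existing synapses of that class).  Returns
    {'mean_abs_dw': DataFrame (batch x class),
     'histograms': {class: (bin_edges, counts (n_batches+1, n_bins))}}.
    """
    if len(snapshots) < 2:
        raise ValueError("need at least two snapshots")
    shapes = {s.shape for s in snapshots}
    if len(shapes) != 1:
        raise ValueError("snapshot shape mismatch")
    cols = {}
    hists = {}
    for name, m in class_masks.items():
        deltas = [np.abs(b[m] - a[m]).mean() if m.any() else np.nan
                  for a, b in zip(snapshots[:-1], snapshots[1:])]
        cols[name] = deltas
        mags = [np.abs(s[m]) for s in snapshots]
        top = max(1e-9, max(x.max() for x in mags))
        edges = np.linspace(0.0, top, 51)
        hists[name] = (edges, np.array([np.histogram(x, bins=edges)[0]
                                        for x in mags]))
    return {"mean_abs_dw": pd.DataFrame(cols), "histograms": hists}
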