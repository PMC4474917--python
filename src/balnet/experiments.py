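"""End-to-end experiment orchestration and named presets.

An experiment is a sequence of phases run on one network: a frozen-weight
tuning probe, a plastic learning phase of batched oriented stimuli, a
second probe, optionally a spontaneous (untuned background) continuation
of the plastic phase, and a final probe.  One master seed fans out, via
``numpy.random.SeedSequence``, into independent sub-seeds for wiring,
stimulus order and input spikes, so stimulus randomness can be held
fixed across parameter sweeps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .engine import RecordSpec, simulate
from .metrics import (osi, population_average_tuning, tuning_curves,
                      wbi_norm, weight_evolution, weight_vs_dpo)
from .network import Network, NetworkConfig, build_network
from .plasticity import PlasticityParams, VogelsParams
from .stimuli import (InputParams, apply_connectivity_factor,
                      cardinal_biased_weights, make_learning_protocol,
                      make_spontaneous_protocol, make_tuning_probe)

__all__ = ["ExperimentSpec", "PRESETS", "get_preset", "run_experiment",
           "compare_runs", "sub_seeds", "config_hash"]

N_SHUFFLES = 100  # surrogates for WBI normalization


@dataclass
class ExperimentSpec:
    name: str = "default"
    network: NetworkConfig = field(default_factory=NetworkConfig)
    plasticity: Optional[PlasticityParams] = field(
        default_factory=PlasticityParams)
    input_params: InputParams = field(default_factory=InputParams)
    n_learn_batches: int = 40
    probe_trials: int = 10
    spontaneous_batches: int = 0
    spontaneous_baseline: Optional[float] = None  # None -> s_b/2
    orientation_weights: Optional[dict] = None
    shared_probe_inputs: bool = True   # reuse input realization across probes
    seeds: tuple = (1,)

    def copy(self, **changes) -> "ExperimentSpec":
        return replace(self, **changes)


def _preset_default(**kw) -> ExperimentSpec:
    return ExperimentSpec(**kw)


def get_preset(name: str, seeds=(1,)) -> ExperimentSpec:
    """Resolve a named preset (one per protocol variant of the study)."""
    key = name.lower()
    net = NetworkConfig()
    pl = PlasticityParams()
    if key == "default":
        return ExperimentSpec("default", net, pl, seeds=seeds,
                              n_learn_batches=40, spontaneous_batches=10)
    if key == "fig7":
        return ExperimentSpec("fig7", net, pl, seeds=seeds,
                              n_learn_batches=40,
                              orientation_weights=cardinal_biased_weights())
    if key == "fig8_g4":
        return ExperimentSpec("fig8_g4", net.copy(g=4.0), pl, seeds=seeds,
                              n_learn_batches=20)
    if key == "s1":
        return ExperimentSpec(
            "s1", net.copy(eps_EI=0.80, J_exc=0.1, g=4.0),
            pl.copy(rule_IE="frozen"), seeds=seeds, n_learn_batches=20)
    if key == "s2":
        return ExperimentSpec("s2", net.copy(init_weight_mode="gaussian"),
                              pl, seeds=seeds, n_learn_batches=40,
                              spontaneous_batches=10)
    if key == "s3":
        return ExperimentSpec("s3", net, pl.copy(A_LTP_exc=9.6e-5),
                              seeds=seeds, n_learn_batches=20)
    if key == "s4":
        return ExperimentSpec("s4", net, pl.copy(A_LTP_inh=9.6e-5),
                              seeds=seeds, n_learn_batches=20)
    if key == "s5":
        return ExperimentSpec(
            "s5", net.copy(eps_EI=0.80, J_exc=0.1, g=2.0,
                           init_weight_mode="gaussian"),
            pl.copy(rule_IE="vogels", vogels=VogelsParams()),
            seeds=seeds, n_learn_batches=40, spontaneous_batches=10,
            spontaneous_baseline=InputParams().s_b)
    raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")


PRESETS = ("default", "fig7", "fig8_g4", "s1", "s2", "s3", "s4", "s5")


def sub_seeds(master_seed: int, n: int = 4) -> list:
    """Fan one master seed out into independent 31-bit sub-seeds."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2 ** 31) for s in
            ss.generate_state(n, dtype=np.uint64)]


def config_hash(spec: ExperimentSpec) -> str:
    payload = json.dumps(asdict(spec), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _bundle_metrics(net_init: Network, net_final: Network,
                    curves_before, curves_after, shuffle_seed: int) -> dict:
    exc = net_init.exc
    osi_before = np.array([osi(c) for c in curves_before])
    osi_after = np.array([osi(c) for c in curves_after])
    rep_before = weight_vs_dpo(net_init.W, net_init.PO, exc, exc,
                               conn=net_init.conn)
    rep_after = weight_vs_dpo(net_final.W, net_final.PO, exc, exc,
                              conn=net_final.conn)
    return {
        "mean_osi_exc_before": float(np.nanmean(osi_before[exc])),
        "mean_osi_exc_after": float(np.nanmean(osi_after[exc])),
        "mean_osi_inh_before": float(np.nanmean(osi_before[~exc])),
        "mean_osi_inh_after": float(np.nanmean(osi_after[~exc])),
        "wbi_norm_before": wbi_norm(net_init.W, exc, N_SHUFFLES,
                                    shuffle_seed),
        "wbi_norm_after": wbi_norm(net_final.W, exc, N_SHUFFLES,
                                   shuffle_seed),
        "group_means_before": rep_before.group_means,
        "group_means_after": rep_after.group_means,
        "weight_tuning_osi_after": rep_after.weight_tuning_osi,
    }


def run_experiment(spec: ExperimentSpec, verbose: bool = False) -> dict:
    """Execute all phases for each seed; returns a bundle of artifacts.

    Per seed the bundle holds the initial and final networks, tuning
    curves before/after learning, weight snapshots of the plastic phases
    and the scalar metric summary.  Probes always run with frozen
    weights.
    """
    per_seed = {}
    for master in spec.seeds:
        wiring_seed, order_seed, input_seed, shuffle_seed = sub_seeds(master)
        net = build_network(spec.network, wiring_seed)
        net_init = net.copy()

        probe = make_tuning_probe(n_trials=spec.probe_trials,
                                  input_params=spec.input_params)
        learn = make_learning_protocol(
            spec.n_learn_batches, seed=order_seed,
            orientation_weights=spec.orientation_weights,
            input_params=spec.input_params)

        if verbose:
            print(f"[{spec.name}] seed {master}: probe (before)")
        res_before = simulate(net.copy(), probe, plasticity=None,
                              seed=input_seed)
        curves_before = tuning_curves(res_before, probe)

        if verbose:
            print(f"[{spec.name}] seed {master}: learning "
                  f"({spec.n_learn_batches} batches)")
        res_learn = simulate(net, learn, plasticity=spec.plasticity,
                             seed=input_seed + 1, keep_state=True)
        snapshots = list(res_learn.weight_snapshots)

        res_spont = None
        if spec.spontaneous_batches:
            if verbose:
                print(f"[{spec.name}] seed {master}: spontaneous "
                      f"({spec.spontaneous_batches} batches)")
            spont = make_spontaneous_protocol(
                spec.spontaneous_batches, spec.input_params,
                baseline=spec.spontaneous_baseline)
            res_spont = simulate(net, spont, plasticity=spec.plasticity,
                                 seed=input_seed + 2, state=res_learn.state)

        if verbose:
            print(f"[{spec.name}] seed {master}: probe (after)")
        probe_seed = input_seed if spec.shared_probe_inputs \
            else input_seed + 3
        res_after = simulate(net.copy(), probe, plasticity=None,
                             seed=probe_seed)
        curves_after = tuning_curves(res_after, probe)

        metrics = _bundle_metrics(net_init, net, curves_before,
                                  curves_after, shuffle_seed)
        metrics["mean_rate_exc_learn_hz"] = float(
            res_learn.rates[:, net.exc].mean())
        per_seed[master] = {
            "network_init": net_init, "network_final": net,
            "curves_before": curves_before, "curves_after": curves_after,
            "learn_snapshots": snapshots,
            "spont_snapshots": (res_spont.weight_snapshots
                                if res_spont else None),
            "learn_rates": res_learn.rates,
            "spont_rates": res_spont.rates if res_spont else None,
            "metrics": metrics,
        }
    return {"spec": spec, "hash": config_hash(spec), "seeds": per_seed}


def compare_runs(bundle_a: dict, bundle_b: dict) -> pd.DataFrame:
    """Tabulate scalar-metric differences between two bundles.

    Metrics are averaged over seeds within each bundle; the report lists
    value_a, value_b and their difference for every scalar metric both
    bundles share.
    """
    def collect(bundle):
        rows = []
        for data in bundle["seeds"].values():
            flat = {}
            for k, v in data["metrics"].items():
                if isinstance(v, dict):
                    flat.update({f"{k}.{kk}": vv for kk, vv in v.items()})
                else:
                    flat[k] = v
            rows.append(flat)
        return pd.DataFrame(rows).mean()

    a, b = collect(bundle_a), collect(bundle_b)
    common = sorted(set(a.index) & set(b.index))
    if not common:
        raise ValueError("bundles share no metrics")
    return pd.DataFrame({"value_a": a[common], "value_b": b[common],
                         "delta": b[common] - a[common]})


def probe_with_factor(network: Network, C: int, seed: int,
                      base: Optional[InputParams] = None,
                      n_trials: int = 10):
    """Frozen-weight tuning probe under connectivity-factor-scaled input."""
    params = apply_connectivity_factor(base or InputParams(), C)
    probe = make_tuning_probe(n_trials=n_trials, input_params=params)
    res = simulate(network.copy(), probe, plasticity=None, seed=seed)
    return tuning_curves(res, probe), probe
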