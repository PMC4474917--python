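"""Shared fixtures: the expensive learning simulations are run once per
session and reused by the behavioral and acceptance tests."""

import numpy as np
import pytest

from balnet import (NetworkConfig, PlasticityParams, build_network,
                    make_learning_protocol, make_spontaneous_protocol,
                    make_tuning_probe, simulate, tuning_curves)
from balnet.experiments import get_preset, sub_seeds

SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def default_learning():
    """Default-network learning (g=8, 40 batches of oriented stimuli),
    three independent master seeds."""
    out = {}
    for m in SEEDS:
        ws, order_s, input_s, shuffle_s = sub_seeds(m)
        net = build_network(NetworkConfig(), ws)
        net_init = net.copy()
        proto = make_learning_protocol(40, seed=order_s)
        res = simulate(net, proto, PlasticityParams(), seed=input_s,
                       keep_state=True)
        out[m] = dict(net_init=net_init, net_final=net, res=res,
                      input_seed=input_s, shuffle_seed=shuffle_s)
    return out


@pytest.fixture(scope="session")
def default_probes(default_learning):
    """8-orientation, 10-trial tuning probes of the seed-1 network before
    and after learning (frozen weights, shared input realization)."""
    d = default_learning[SEEDS[0]]
    probe = make_tuning_probe()
    res_b = simulate(d["net_init"].copy(), probe, None, seed=d["input_seed"])
    res_a = simulate(d["net_final"].copy(), probe, None,
                     seed=d["input_seed"])
    return dict(probe=probe,
                curves_before=tuning_curves(res_b, probe),
                curves_after=tuning_curves(res_a, probe), **d)


@pytest.fixture(scope="session")
def spontaneous_run(default_learning):
    """Plasticity continued for 10 untuned background batches (s_b/2,
    mu=0) from the end of the seed-1 learning phase."""
    d = default_learning[SEEDS[0]]
    spont = make_spontaneous_protocol(10)
    res = simulate(d["net_final"].copy(), spont, PlasticityParams(),
                   seed=d["input_seed"] + 2, state=d["res"].state)
    return dict(spont=res, learning=d)


@pytest.fixture(scope="session")
def s5_learning():
    """Denser-E->I variant with the rate-homeostatic I->E rule,
    three master seeds, 40 learning batches."""
    spec = get_preset("s5")
    out = {}
    for m in SEEDS:
        ws, order_s, input_s, _ = sub_seeds(m)
        net = build_network(spec.network, ws)
        proto = make_learning_protocol(spec.n_learn_batches, seed=order_s)
        res = simulate(net, proto, spec.plasticity, seed=input_s)
        out[m] = dict(net=net, res=res)
    return out


@pytest.fixture()
def small_net():
    """A 40-neuron network for fast structural tests."""
    return build_network(NetworkConfig(N=40), seed=5)
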