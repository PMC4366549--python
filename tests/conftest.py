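"""Shared fixtures: small networks, quick protocol configs."""

from __future__ import annotations

import numpy as np
import pytest

from percycles.engine import ProtocolConfig, Simulation, seed_streams
from percycles.model_core import NeuronParams
from percycles.network import LayerSpec, NetworkSpec, SynapseClassSet


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def isolated_cell_sim(cfg: ProtocolConfig) -> Simulation:
    """A single excitatory cell with no synaptic partners.

    The inhibitory pool is present but disconnected, so the cell's
    dynamics reduce to leak + adaptation + injected current.
    """
    layer = LayerSpec(n_exc=1, n_inh=1, p_ElE=0.0, p_IE=0.0, p_EI=0.0,
                      lateral_plastic=False)
    spec = NetworkSpec(layers=(layer,), synapses=SynapseClassSet.defaults())
    return Simulation(cfg, seed_streams(cfg.seed), spec=spec)


@pytest.fixture
def quick_one_layer_cfg() -> ProtocolConfig:
    """A deliberately tiny one-layer protocol for plumbing tests."""
    return ProtocolConfig(experiment="one_layer", seed=3, n_train_per_cat=2,
                          n_epochs=1, t_cue_train=40.0, t_cue_test=80.0)
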