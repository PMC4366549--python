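"""Engine tests: kernel correctness, protocols, gating, reproducibility."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from percycles.engine import (
    ProtocolConfig,
    Simulation,
    one_layer_config,
    run_one_layer_experiment,
    seed_streams,
    sweep,
    two_layer_config,
)
from percycles.model_core import (
    AdaptationParams,
    CellState,
    calcium_step,
    conductance_step,
    lif_isi,
    membrane_step,
    spike_and_reset,
)
from percycles.network import LayerSpec, NetworkSpec, SynapseClassSet
from percycles.plasticity import trace_step, weight_step

from conftest import isolated_cell_sim


def small_spec(seeded_weights: bool = False) -> NetworkSpec:
    layer = LayerSpec(n_exc=16, n_inh=4, p_ElE=0.5)
    return NetworkSpec(layers=(layer,), synapses=SynapseClassSet.defaults())


def reference_segment(sim: Simulation, I_ext: np.ndarray, duration: float,
                      plastic: bool) -> tuple[np.ndarray, np.ndarray]:
    """Step-by-step composition of the model_core / plasticity operations.

    Independent of the compiled kernel: same documented operation order,
    same noise stream consumption (one (n_steps x n) block per population
    in declaration order).  Returns the E and I spike rasters.
    """
    cfg = sim.cfg
    dt = cfg.dt
    n_steps = int(round(duration / dt))
    exc, inh = sim.pops["exc0"], sim.pops["inh0"]
    pE, pI = sim.spec.exc_params, sim.spec.inh_params
    adapt, stdp = cfg.adaptation, cfg.stdp
    proj = {p.name: p for p in sim.projections}
    ele, ie, ei = proj["ElE0"], proj["IE0"], proj["EI0"]
    noiseE = sim.streams["noise"].standard_normal((n_steps, exc.n))
    noiseI = sim.streams["noise"].standard_normal((n_steps, inh.n))
    prevE = np.zeros(exc.n, dtype=bool)
    prevI = np.zeros(inh.n, dtype=bool)
    outE = np.zeros((n_steps, exc.n), dtype=bool)
    outI = np.zeros((n_steps, inh.n), dtype=bool)
    no_adapt = AdaptationParams.disabled()
    for k in range(n_steps):
        conductance_step(ele.g, ele.sc, ele.dg, ele.mask, prevE, dt)
        conductance_step(ie.g, ie.sc, ie.dg, ie.mask, prevI, dt)
        conductance_step(ei.g, ei.sc, ei.dg, ei.mask, prevE, dt)
        calcium_step(exc, adapt, prevE, dt)
        if plastic:
            weight_step(ele.plast, stdp, prevE, prevE, dt, mask=ele.mask)
        trace_step(ele.plast, stdp, prevE, prevE, dt)
        syn_e = (ele.g * (ele.sc.E_syn - exc.V) + ie.g * (ie.sc.E_syn - exc.V))
        syn_i = ei.g * (ei.sc.E_syn - inh.V)
        membrane_step(exc, pE, adapt, syn_e, I_ext, noiseE[k], dt)
        membrane_step(inh, pI, no_adapt, syn_i, 0.0, noiseI[k], dt)
        prevE, _ = spike_and_reset(exc, pE, adapt)
        prevI, _ = spike_and_reset(inh, pI, no_adapt)
        outE[k] = prevE
        outI[k] = prevI
    return outE, outI


class TestKernelEquivalence:
    def test_kernel_matches_reference_composition(self):
        """The compiled loop reproduces the op-by-op reference: identical
        spikes and near-identical state over a driven, plastic segment."""
        cfg = ProtocolConfig(experiment="one_layer", seed=17)
        spec = small_spec()
        I_ext = np.zeros(16)
        I_ext[:10] = 750.0

        sim_k = Simulation(cfg, seed_streams(cfg.seed), spec=spec)
        rec = sim_k.run_segment({"exc0": I_ext}, 60.0, plastic=("ElE0",),
                                record=["exc0", "inh0"])

        sim_r = Simulation(cfg, seed_streams(cfg.seed), spec=spec)
        outE, outI = reference_segment(sim_r, I_ext, 60.0, plastic=True)

        rows, cols = np.nonzero(outE)
        np.testing.assert_array_equal(rec.spikes["exc0"][0], cols)
        np.testing.assert_allclose(rec.spikes["exc0"][1],
                                   (rows + 1) * cfg.dt)
        rows_i, cols_i = np.nonzero(outI)
        np.testing.assert_array_equal(rec.spikes["inh0"][0], cols_i)
        np.testing.assert_allclose(sim_k.pops["exc0"].V, sim_r.pops["exc0"].V,
                                   rtol=0, atol=1e-9)
        np.testing.assert_allclose(sim_k.weights("ElE0"),
                                   sim_r.weights("ElE0"), atol=1e-12)
        assert rec.spikes["exc0"][0].size > 0      # the segment actually fired


class TestRunSegment:
    def test_zero_duration_segment(self):
        cfg = ProtocolConfig(experiment="one_layer", seed=0, noise=False)
        sim = isolated_cell_sim(cfg)
        v0 = sim.pops["exc0"].V.copy()
        rec = sim.run_segment({}, 0.0, record=["exc0"])
        assert rec.spikes["exc0"][0].size == 0
        np.testing.assert_array_equal(sim.pops["exc0"].V, v0)

    def test_isolated_cell_isi_matches_closed_form(self):
        """0.75 nA drive, no adaptation, no noise: ISI within 2 % of the
        closed-form LIF period (~9.35 ms, ~107 Hz)."""
        cfg = ProtocolConfig(experiment="one_layer", seed=0, noise=False,
                             gK_alpha=0.0)
        sim = isolated_cell_sim(cfg)
        rec = sim.run_segment({"exc0": np.array([750.0])}, 150.0,
                              record=["exc0"])
        times = rec.spikes["exc0"][1]
        isis = np.diff(times)
        T = lif_isi(sim.spec.exc_params, 750.0)
        assert T == pytest.approx(9.3545, abs=1e-3)
        assert isis.size >= 10
        assert np.all(np.abs(isis - T) / T < 0.02)

    def test_adaptation_slows_firing_toward_plateau(self):
        """With the calcium-gated potassium current on, inter-spike
        intervals grow monotonically and level off."""
        cfg = ProtocolConfig(experiment="one_layer", seed=0, noise=False,
                             gK_alpha=6.0, tau_Ca=50.0)
        sim = isolated_cell_sim(cfg)
        rec = sim.run_segment({"exc0": np.array([750.0])}, 600.0,
                              record=["exc0"])
        isis = np.diff(rec.spikes["exc0"][1])
        assert isis.size >= 8
        # monotone growth up to one-time-step discretisation jitter
        assert np.all(np.diff(isis) >= -cfg.dt - 1e-9)
        assert isis[-1] > isis[0] * 1.5                # clearly adapted
        late = isis[-4:]
        assert np.ptp(late) / late.mean() < 0.05       # plateau

    def test_unknown_plastic_projection_rejected(self):
        cfg = ProtocolConfig(experiment="one_layer", seed=0)
        sim = isolated_cell_sim(cfg)
        with pytest.raises(KeyError):
            sim.run_segment({}, 1.0, plastic=("EfE9",))


class TestProtocols:
    def test_one_layer_experiment_reproducible_and_gated(self,
                                                         quick_one_layer_cfg):
        res1 = run_one_layer_experiment(quick_one_layer_cfg)
        res2 = run_one_layer_experiment(quick_one_layer_cfg)
        np.testing.assert_array_equal(res1.post_test.spikes["exc0"][0],
                                      res2.post_test.spikes["exc0"][0])
        np.testing.assert_array_equal(res1.post_test.spikes["exc0"][1],
                                      res2.post_test.spikes["exc0"][1])
        np.testing.assert_array_equal(res1.w_after, res2.w_after)
        # weights start at zero and tests run with plasticity off
        np.testing.assert_array_equal(res1.w_before, 0.0)

    def test_zero_epochs_leave_weights_untouched(self, quick_one_layer_cfg):
        cfg = dataclasses.replace(quick_one_layer_cfg, n_epochs=0)
        res = run_one_layer_experiment(cfg)
        np.testing.assert_array_equal(res.w_before, res.w_after)
        np.testing.assert_array_equal(res.w_after, 0.0)

    def test_frozen_projection_is_bit_identical(self):
        cfg = ProtocolConfig(experiment="one_layer", seed=4, n_train_per_cat=2,
                             n_epochs=1, t_cue_train=30.0, t_cue_test=30.0)
        streams = seed_streams(cfg.seed)
        sim = Simulation(cfg, streams)
        sim.net.layers[0].w_ElE[:] = 0.3        # nonzero so drift would show
        w0 = sim.weights("ElE0")
        I = np.zeros(512)
        I[:128] = 750.0
        sim.run_segment({"exc0": I}, 50.0, plastic=())
        np.testing.assert_array_equal(sim.weights("ElE0"), w0)
        sim.run_segment({"exc0": I}, 50.0, plastic=("ElE0",))
        assert (sim.weights("ElE0") != w0).any()

    def test_recording_is_complete(self):
        cfg = ProtocolConfig(experiment="one_layer", seed=6, n_train_per_cat=2)
        sim = Simulation(cfg, seed_streams(cfg.seed))
        I = np.zeros(512)
        I[:200] = 750.0
        rec = sim.run_segment({"exc0": I}, 120.0, record=["exc0", "inh0"])
        recorded = sum(rec.spikes[k][0].size for k in rec.spikes)
        assert recorded == sim.total_spikes > 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ProtocolConfig(experiment="three_layer")
        with pytest.raises(ValueError):
            ProtocolConfig(t_cue_test=0.0)
        with pytest.raises(ValueError):
            from percycles.engine import run_two_layer_experiment
            run_two_layer_experiment(one_layer_config())


class TestSweep:
    def test_single_point_single_seed(self, quick_one_layer_cfg):
        table = sweep(quick_one_layer_cfg, "lam_ElE", [12.0],
                      metric=lambda r: float(r.post_test.spikes["exc0"][0].size),
                      seeds=[3])
        assert len(table) == 1
        assert table["sem"].iloc[0] == 0.0
        assert table["n_seeds"].iloc[0] == 1

    def test_deterministic_metric_same_seeds_identical(self,
                                                       quick_one_layer_cfg):
        kw = dict(metric=lambda r: float(np.sum(r.w_after)), seeds=[3, 4])
        t1 = sweep(quick_one_layer_cfg, "gK_alpha", [3.0, 6.0], **kw)
        t2 = sweep(quick_one_layer_cfg, "gK_alpha", [3.0, 6.0], **kw)
        assert t1.equals(t2)

    def test_derived_parameters_and_unknown_name(self, quick_one_layer_cfg):
        from percycles.engine import _apply_param
        c = _apply_param(quick_one_layer_cfg, "alpha_ratio", 2.0)
        assert c.alpha_D / c.alpha_C == pytest.approx(2.0)
        assert c.alpha_C * c.alpha_D == pytest.approx(0.25)
        c = _apply_param(quick_one_layer_cfg, "tau_CD_asym", 30.0)
        assert (c.tau_C, c.tau_D) == (30.0, 50.0)
        c = _apply_param(quick_one_layer_cfg, "tau_CD_sym", 40.0)
        assert (c.tau_C, c.tau_D) == (40.0, 40.0)
        with pytest.raises(KeyError):
            _apply_param(quick_one_layer_cfg, "lambda_nonsense", 1.0)
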