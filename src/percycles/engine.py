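"""Simulation orchestration: the Euler loop, training/testing protocols and sweeps.

The clock-driven loop advances every population and projection with a
shared time step (0.02 ms by default).  Within one step:

1. every projection's conductance total and every excitatory calcium
   trace is Euler-decayed and incremented by the *previous* step's
   spikes (so a spike influences postsynaptic potentials from the next
   step -- a one-step effective delay);
2. plastic projections apply the STDP weight update for those spikes
   (when gated on) and then advance their activity traces;
3. membranes are integrated and thresholded, producing this step's
   spikes, which are recorded.

Protocols follow the two study designs: the one-layer segmentation
experiment (train lateral weights on category examples, test on a
compound of two novel examples) and the two-layer invariance experiment
(Phase I trains lateral weights on translating stimuli; Phase II freezes
them, trains feed-forward weights on the compound novel pair, and tests
each novel stimulus per transform individually).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import stimuli as stim_mod
from ._kernel import step_layer_chunk
from .model_core import (
    AdaptationParams,
    CellState,
    NeuronParams,
    NumericalInstabilityError,
    SynapseClassParams,
)
from .network import (
    BuiltNetwork,
    NetworkSpec,
    build_network,
    default_one_layer,
    default_two_layer,
)
from .plasticity import PlasticityState, STDPParams
from .stimuli import StimulusSet, compound_pattern, to_current, transforms_of

__all__ = [
    "ProtocolConfig",
    "one_layer_config",
    "two_layer_config",
    "SegmentRecord",
    "Simulation",
    "OneLayerResult",
    "TwoLayerResult",
    "run_one_layer_experiment",
    "run_two_layer_experiment",
    "sweep",
    "seed_streams",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Everything needed to replay an experiment bit-exactly.

    Durations in ms, currents in nA, conductances in nS.  The scalar
    synaptic/adaptation/STDP fields are the sweepable knobs; they are
    folded into the network spec and parameter objects at build time.
    """

    experiment: str = "one_layer"            # "one_layer" | "two_layer"
    seed: int = 0
    I_cue_nA: float = 0.75
    t_cue_train: float = 500.0
    t_cue_test: float = 1000.0
    n_epochs: int = 10
    n_epochs_phase2: int | None = None   # None: same as n_epochs
    dt: float = 0.02
    n_train_per_cat: int = 10
    n_transforms: int = 5
    shared_rows: int = 0
    lam_ElE: float = 12.0
    lam_IE: float = 5.0
    lam_EfE: float = 3.0
    gK_alpha: float = 6.0
    tau_Ca: float = 50.0
    alpha_C: float = 0.5
    alpha_D: float = 0.5
    tau_C: float = 15.0
    tau_D: float = 25.0
    tau_dg: float = 0.1
    noise: bool = True
    reset_between_presentations: bool = False
    record_inhibitory: bool = False

    def __post_init__(self) -> None:
        if self.experiment not in ("one_layer", "two_layer"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if min(self.t_cue_train, self.t_cue_test) <= 0 or self.dt <= 0:
            raise ValueError("durations and dt must be positive")

    @property
    def adaptation(self) -> AdaptationParams:
        return AdaptationParams(gK_alpha=self.gK_alpha, tau_Ca=self.tau_Ca)

    @property
    def stdp(self) -> STDPParams:
        return STDPParams(alpha_C=self.alpha_C, alpha_D=self.alpha_D,
                          tau_C=self.tau_C, tau_D=self.tau_D,
                          tau_dg=self.tau_dg)

    def network_spec(self) -> NetworkSpec:
        if self.experiment == "one_layer":
            return default_one_layer(lam_ElE=self.lam_ElE, lam_IE=self.lam_IE)
        return default_two_layer(lam_ElE=self.lam_ElE, lam_IE=self.lam_IE,
                                 lam_EfE=self.lam_EfE)


def one_layer_config(**kw) -> ProtocolConfig:
    """Default one-layer protocol (10 examples/category, 10 epochs)."""
    kw.setdefault("n_train_per_cat", 10)
    return ProtocolConfig(experiment="one_layer", **kw)


def two_layer_config(**kw) -> ProtocolConfig:
    """Default two-layer protocol (8 stimuli/category, 5 transforms).

    The lateral conductance scale defaults to 6 nS here (the input layer
    is all-to-all, so half the one-layer value keeps lam_ElE * p fixed).
    """
    kw.setdefault("n_train_per_cat", 8)
    kw.setdefault("lam_ElE", 6.0)
    return ProtocolConfig(experiment="two_layer", **kw)


def seed_streams(master_seed: int) -> dict[str, np.random.Generator]:
    """Independent named RNG streams spawned from one master seed.

    Changing e.g. the noise stream leaves connectivity and stimulus draws
    untouched.
    """
    names = ("connectivity", "stimuli", "noise", "order", "decoder")
    children = np.random.SeedSequence(master_seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class SegmentRecord:
    """All spikes of the recorded populations during one protocol segment.

    ``spikes`` maps a population name (``"exc0"``, ``"inh0"``, ``"exc1"``,
    ...) to ``(neuron_ids, times_ms)`` arrays, times relative to segment
    start and non-decreasing.  ``label`` carries the protocol context
    (phase, stimulus, transform, epoch).
    """

    label: dict
    duration: float
    spikes: dict[str, tuple[np.ndarray, np.ndarray]]
    n_neurons: dict[str, int]

    def counts(self, pop: str) -> np.ndarray:
        ids, _ = self.spikes[pop]
        return np.bincount(ids, minlength=self.n_neurons[pop])


@dataclass
class _Projection:
    """Runtime state of one projection (weights, mask, conductance total)."""

    name: str
    sc: SynapseClassParams
    pre: str            # population key, e.g. "exc0"
    post: str
    mask: np.ndarray | None
    dg: np.ndarray | None          # None means fixed Delta-g = 1
    g: np.ndarray = None           # type: ignore[assignment]
    plast: PlasticityState | None = None

    def effective_dg(self) -> np.ndarray:
        """Dense (post x pre) Delta-g with the mask applied."""
        n_post, n_pre = self._shape
        dg = np.ones((n_post, n_pre)) if self.dg is None else self.dg.copy()
        if self.mask is not None:
            dg = dg * self.mask
        return dg

    @property
    def _shape(self) -> tuple[int, int]:
        if self.dg is not None:
            return self.dg.shape
        return self.mask.shape


class Simulation:
    """A built network plus all runtime state, advanced segment by segment."""

    #: Steps per compiled-kernel chunk (bounds the noise/raster buffers).
    CHUNK_STEPS = 5000

    def __init__(self, cfg: ProtocolConfig,
                 streams: dict[str, np.random.Generator] | None = None,
                 spec: NetworkSpec | None = None):
        self.cfg = cfg
        self.streams = streams if streams is not None else seed_streams(cfg.seed)
        self.spec = spec if spec is not None else cfg.network_spec()
        self.net: BuiltNetwork = build_network(self.spec, self.streams["connectivity"])
        self.total_spikes = 0
        self._step_count = 0

        self.pops: dict[str, CellState] = {}
        self.pop_params: dict[str, NeuronParams] = {}
        self.pop_adapt: dict[str, AdaptationParams | None] = {}
        for l, bl in enumerate(self.net.layers):
            self.pops[f"exc{l}"] = bl.exc
            self.pop_params[f"exc{l}"] = self.spec.exc_params
            self.pop_adapt[f"exc{l}"] = cfg.adaptation
            self.pops[f"inh{l}"] = bl.inh
            self.pop_params[f"inh{l}"] = self.spec.inh_params
            self.pop_adapt[f"inh{l}"] = None

        syn = self.spec.synapses
        self.projections: list[_Projection] = []
        for l, bl in enumerate(self.net.layers):
            if bl.mask_ElE is not None:
                p = _Projection(name=f"ElE{l}", sc=syn.ElE, pre=f"exc{l}",
                                post=f"exc{l}", mask=bl.mask_ElE, dg=bl.w_ElE)
                p.plast = PlasticityState(C=np.zeros(bl.spec.n_exc),
                                          D=np.zeros(bl.spec.n_exc), dg=bl.w_ElE)
                self.projections.append(p)
            self.projections.append(_Projection(
                name=f"IE{l}", sc=syn.IE, pre=f"inh{l}", post=f"exc{l}",
                mask=bl.mask_IE, dg=None))
            self.projections.append(_Projection(
                name=f"EI{l}", sc=syn.EI, pre=f"exc{l}", post=f"inh{l}",
                mask=bl.mask_EI, dg=None))
        for gap, (mask, w) in enumerate(zip(self.net.mask_EfE, self.net.w_EfE)):
            p = _Projection(name=f"EfE{gap}", sc=syn.EfE, pre=f"exc{gap}",
                            post=f"exc{gap + 1}", mask=mask, dg=w)
            p.plast = PlasticityState(C=np.zeros(w.shape[1]),
                                      D=np.zeros(w.shape[0]), dg=w)
            self.projections.append(p)
        for p in self.projections:
            p.g = np.zeros(self.pops[p.post].n)

        self._prev_spikes: dict[str, np.ndarray] = {
            k: np.zeros(s.n, dtype=bool) for k, s in self.pops.items()}

    # -- state management ------------------------------------------------

    def reset_state(self) -> None:
        """Hard reset of all dynamic state (weights are kept).

        V back to rest, conductances, calcium, refractory clocks and STDP
        traces to zero.  Used to let the network settle between test
        presentations so one transform cannot bleed into the next.
        """
        for key, st in self.pops.items():
            p = self.pop_params[key]
            st.V[:] = p.E_L
            st.Ca[:] = 0.0
            st.refractory_remaining[:] = 0.0
            st.last_spike_flag[:] = False
            self._prev_spikes[key][:] = False
        for pr in self.projections:
            pr.g[:] = 0.0
            if pr.plast is not None:
                pr.plast.C[:] = 0.0
                pr.plast.D[:] = 0.0

    def weights(self, name: str) -> np.ndarray:
        """Copy of a plastic projection's current weight matrix."""
        for pr in self.projections:
            if pr.name == name and pr.dg is not None:
                return pr.dg.copy()
        raise KeyError(f"no weighted projection named {name!r}")

    # -- the Euler loop ---------------------------------------------------

    def run_segment(
        self,
        currents: dict[str, np.ndarray],
        duration: float,
        plastic: Iterable[str] = (),
        record: Iterable[str] = (),
        label: dict | None = None,
    ) -> SegmentRecord:
        """Advance the whole network for ``duration`` ms.

        ``currents`` maps population names to external current vectors in
        pA (missing populations receive none).  ``plastic`` names the
        projections whose weights may change; traces evolve regardless.
        ``record`` names the populations whose spikes are kept.
        """
        cfg = self.cfg
        dt = cfg.dt
        n_steps = int(round(duration / dt))
        plastic = set(plastic)
        record = tuple(record)
        known = {p.name for p in self.projections}
        unknown = plastic - known
        if unknown:
            raise KeyError(f"unknown plastic projections {sorted(unknown)}")

        stdp = cfg.stdp
        adapt = cfg.adaptation
        syn = self.spec.synapses
        pE, pI = self.spec.exc_params, self.spec.inh_params
        noise_rng = self.streams["noise"] if cfg.noise else None
        proj = {p.name: p for p in self.projections}
        n_layers = len(self.net.layers)

        rec_ids: dict[str, list[np.ndarray]] = {k: [] for k in record}
        rec_steps: dict[str, list[np.ndarray]] = {k: [] for k in record}
        d_mask = np.zeros((1, 1), dtype=bool)
        d_w = np.zeros((1, 1))
        d_vec = np.zeros(1)
        d_bool = np.zeros(1, dtype=bool)
        d_noise = np.zeros((0, 0))

        done = 0
        while done < n_steps:
            m = min(self.CHUNK_STEPS, n_steps - done)
            # noise drawn in canonical population order, independent of the
            # per-layer execution order below
            noise: dict[str, np.ndarray] = {}
            for key, st in self.pops.items():
                noise[key] = (noise_rng.standard_normal((m, st.n))
                              if noise_rng is not None else d_noise)
            # feed-forward carry: the lower layer's spikes at the last step
            # before this chunk, captured before any kernel runs
            ff_carry = {l: self._prev_spikes[f"exc{l - 1}"].copy()
                        for l in range(1, n_layers)}
            rasters: dict[int, np.ndarray] = {}
            for l in range(n_layers):
                exc = self.pops[f"exc{l}"]
                inh = self.pops[f"inh{l}"]
                ele = proj.get(f"ElE{l}")
                ie = proj[f"IE{l}"]
                ei = proj[f"EI{l}"]
                ff = proj.get(f"EfE{l - 1}") if l > 0 else None
                outE = np.zeros((m, exc.n), dtype=bool)
                outI = np.zeros((m, inh.n), dtype=bool)
                status = step_layer_chunk(
                    dt, m,
                    exc.V, exc.Ca, exc.refractory_remaining,
                    self._prev_spikes[f"exc{l}"],
                    pE.C_m, pE.g_0, pE.E_L, pE.Theta, pE.V_H, pE.tau_R,
                    pE.noise_std(dt) if cfg.noise else 0.0,
                    adapt.gK_alpha, adapt.E_K, adapt.tau_Ca,
                    inh.V, inh.refractory_remaining,
                    self._prev_spikes[f"inh{l}"],
                    pI.C_m, pI.g_0, pI.E_L, pI.Theta, pI.V_H, pI.tau_R,
                    pI.noise_std(dt) if cfg.noise else 0.0,
                    syn.ElE.E_syn, syn.IE.E_syn,
                    1 if ele is not None else 0,
                    ele.mask if ele is not None else d_mask,
                    ele.dg if ele is not None else d_w,
                    ele.g if ele is not None else d_vec,
                    syn.ElE.lam, syn.ElE.tau_g,
                    ie.mask, ie.g, syn.IE.lam, syn.IE.tau_g,
                    ei.mask, ei.g, syn.EI.lam, syn.EI.tau_g,
                    1 if ff is not None else 0,
                    rasters[l - 1] if ff is not None else d_mask,
                    ff_carry[l] if ff is not None else d_bool,
                    ff.mask if ff is not None else d_mask,
                    ff.dg if ff is not None else d_w,
                    ff.g if ff is not None else d_vec,
                    syn.EfE.lam if syn.EfE is not None else 0.0,
                    syn.EfE.tau_g if syn.EfE is not None else 1.0,
                    1 if (ele is not None and ele.name in plastic) else 0,
                    1 if (ele is not None and ele.plast is not None) else 0,
                    ele.plast.C if ele is not None and ele.plast else d_vec,
                    ele.plast.D if ele is not None and ele.plast else d_vec,
                    1 if (ff is not None and ff.name in plastic) else 0,
                    1 if (ff is not None and ff.plast is not None) else 0,
                    ff.plast.C if ff is not None and ff.plast else d_vec,
                    ff.plast.D if ff is not None and ff.plast else d_vec,
                    stdp.alpha_C, stdp.alpha_D, stdp.tau_C, stdp.tau_D,
                    stdp.eta(dt),
                    1 if cfg.noise else 0,
                    noise[f"exc{l}"], noise[f"inh{l}"],
                    np.asarray(currents.get(f"exc{l}", np.zeros(exc.n)),
                               dtype=float),
                    np.asarray(currents.get(f"inh{l}", np.zeros(inh.n)),
                               dtype=float),
                    outE, outI,
                )
                if status >= 0:
                    raise NumericalInstabilityError(
                        f"non-finite membrane potential in layer {l} at "
                        f"segment step {done + status} "
                        f"(label={label!r}); state dump: "
                        f"V_exc range [{np.nanmin(exc.V)}, {np.nanmax(exc.V)}]")
                rasters[l] = outE
                self.total_spikes += int(outE.sum()) + int(outI.sum())
                for key, raster in ((f"exc{l}", outE), (f"inh{l}", outI)):
                    if key in rec_ids:
                        rows, cols = np.nonzero(raster)
                        rec_ids[key].append(cols)
                        rec_steps[key].append(rows + done)
                self._prev_spikes[f"exc{l}"] = outE[-1].copy()
                self._prev_spikes[f"inh{l}"] = outI[-1].copy()
            done += m
            self._step_count += m

        def _cat(parts: list[np.ndarray], dtype) -> np.ndarray:
            if parts:
                return np.concatenate(parts).astype(dtype)
            return np.array([], dtype=dtype)

        spikes_out = {
            k: (_cat(rec_ids[k], np.int64),
                (_cat(rec_steps[k], np.float64) + 1.0) * dt)
            for k in record
        }
        return SegmentRecord(
            label=dict(label or {}),
            duration=duration,
            spikes=spikes_out,
            n_neurons={k: self.pops[k].n for k in record},
        )


# -- experiment protocols --------------------------------------------------


@dataclass
class OneLayerResult:
    """Pre/post test records, training trace and weight snapshots."""

    cfg: ProtocolConfig
    stimulus_set: StimulusSet
    pre_test: SegmentRecord
    post_test: SegmentRecord
    w_before: np.ndarray
    w_after: np.ndarray
    test_groups: tuple[tuple[int, ...], tuple[int, ...]]
    training_records: list[SegmentRecord] = field(default_factory=list)


def run_one_layer_experiment(
    cfg: ProtocolConfig,
    stimulus_set: StimulusSet | None = None,
    record_training: bool = False,
) -> OneLayerResult:
    """The one-layer segmentation protocol.

    Pre-training test (compound of the two novel examples, plasticity
    off), then ``n_epochs`` of the training examples presented
    individually in random order with the lateral E-E weights plastic,
    then the same compound test again.  Test segments start from a fully
    settled (reset) state; state carries over between training
    presentations within the run.
    """
    streams = seed_streams(cfg.seed)
    if stimulus_set is None:
        stimulus_set = stim_mod.generate_static_set(
            n_train_per_cat=cfg.n_train_per_cat, seed=streams["stimuli"])
    sim = Simulation(cfg, streams)
    n_in = sim.pops["exc0"].n
    rec_pops = ["exc0"] + (["inh0"] if cfg.record_inhibitory else [])

    tests = stimulus_set.testing()
    if len(tests) != 2:
        raise ValueError("the segmentation test needs one novel example per category")
    groups = (tests[0].features, tests[1].features)
    compound = compound_pattern(*groups)
    I_test = {"exc0": to_current(compound, n_in, cfg.I_cue_nA)}

    sim.reset_state()
    pre = sim.run_segment(I_test, cfg.t_cue_test, plastic=(), record=rec_pops,
                          label={"phase": "pre_test", "stimulus": "compound"})
    w_before = sim.weights("ElE0")

    training_records: list[SegmentRecord] = []
    train = stimulus_set.training()
    sim.reset_state()
    for epoch in range(cfg.n_epochs):
        order = streams["order"].permutation(len(train))
        for idx in order:
            s = train[idx]
            I = {"exc0": to_current(s.features, n_in, cfg.I_cue_nA)}
            if cfg.reset_between_presentations:
                sim.reset_state()
            rec = sim.run_segment(
                I, cfg.t_cue_train, plastic=("ElE0",),
                record=rec_pops if record_training else (),
                label={"phase": "training", "epoch": epoch,
                       "stimulus": s.label})
            if record_training:
                training_records.append(rec)
    w_after = sim.weights("ElE0")

    sim.reset_state()
    post = sim.run_segment(I_test, cfg.t_cue_test, plastic=(), record=rec_pops,
                           label={"phase": "post_test", "stimulus": "compound"})
    return OneLayerResult(cfg=cfg, stimulus_set=stimulus_set,
                          pre_test=pre, post_test=post,
                          w_before=w_before, w_after=w_after,
                          test_groups=groups,
                          training_records=training_records)


@dataclass
class TwoLayerResult:
    """Phase records and weight snapshots of the two-layer protocol.

    ``test_before`` / ``test_after`` map ``(category_id, transform)`` to
    the 1000 ms individual-presentation record bracketing Phase II.
    """

    cfg: ProtocolConfig
    stimulus_set: StimulusSet
    test_before: dict[tuple[int, int], SegmentRecord]
    test_after: dict[tuple[int, int], SegmentRecord]
    w_ElE_after_phase1: np.ndarray
    w_EfE_before: np.ndarray
    w_EfE_after: np.ndarray


def _transform_tests(sim: Simulation, cfg: ProtocolConfig,
                     tests: Sequence, n_in: int,
                     phase: str) -> dict[tuple[int, int], SegmentRecord]:
    out: dict[tuple[int, int], SegmentRecord] = {}
    rec = ["exc0", "exc1"]
    for s in tests:
        for tr in transforms_of(s, cfg.n_transforms):
            sim.reset_state()
            I = {"exc0": to_current(tr.active_neurons, n_in, cfg.I_cue_nA)}
            out[(s.category_id, tr.transform_index)] = sim.run_segment(
                I, cfg.t_cue_test, plastic=(), record=rec,
                label={"phase": phase, "stimulus": s.label,
                       "transform": tr.transform_index})
    return out


def run_two_layer_experiment(
    cfg: ProtocolConfig,
    stimulus_set: StimulusSet | None = None,
) -> TwoLayerResult:
    """The two-layer invariance protocol.

    Phase I: the training stimuli of both categories translate across the
    input layer (transforms in order, stimuli in random order) for
    ``n_epochs`` epochs with only the lateral input-layer weights plastic.
    Phase II: step 1 tests every (novel stimulus, transform) individually
    from a settled state; step 2 presents the two novel stimuli as a
    translating compound with only the feed-forward weights plastic;
    step 3 repeats the tests.
    """
    if cfg.experiment != "two_layer":
        raise ValueError("config must have experiment='two_layer'")
    streams = seed_streams(cfg.seed)
    if stimulus_set is None:
        stimulus_set = stim_mod.generate_translating_set(
            n_train_per_cat=cfg.n_train_per_cat,
            shared_rows=cfg.shared_rows, seed=streams["stimuli"])
    sim = Simulation(cfg, streams)
    n_in = sim.pops["exc0"].n

    # Phase I: train lateral weights on translating category examples.
    train = stimulus_set.training()
    sim.reset_state()
    for epoch in range(cfg.n_epochs):
        order = streams["order"].permutation(len(train))
        for idx in order:
            s = train[idx]
            if cfg.reset_between_presentations:
                sim.reset_state()
            for tr in transforms_of(s, cfg.n_transforms):
                I = {"exc0": to_current(tr.active_neurons, n_in, cfg.I_cue_nA)}
                sim.run_segment(I, cfg.t_cue_train, plastic=("ElE0",),
                                record=(),
                                label={"phase": "phase1", "epoch": epoch,
                                       "stimulus": s.label,
                                       "transform": tr.transform_index})
    w_ele = sim.weights("ElE0")

    tests = stimulus_set.testing()
    if len(tests) != 2:
        raise ValueError("phase II needs one novel stimulus per category")

    # Phase II step 1: per-transform individual tests (plasticity off).
    test_before = _transform_tests(sim, cfg, tests, n_in, "phase2_test_before")
    w_efe_before = sim.weights("EfE0")

    # Phase II step 2: compound novel pair translating, EfE plastic.
    tr_by_stim = [transforms_of(s, cfg.n_transforms) for s in tests]
    n_epochs2 = (cfg.n_epochs if cfg.n_epochs_phase2 is None
                 else cfg.n_epochs_phase2)
    sim.reset_state()
    for epoch in range(n_epochs2):
        if cfg.reset_between_presentations:
            sim.reset_state()
        for t_idx in range(cfg.n_transforms):
            active = compound_pattern(
                *(trs[t_idx].active_neurons for trs in tr_by_stim))
            I = {"exc0": to_current(active, n_in, cfg.I_cue_nA)}
            sim.run_segment(I, cfg.t_cue_train, plastic=("EfE0",), record=(),
                            label={"phase": "phase2_train", "epoch": epoch,
                                   "transform": t_idx + 1})
    w_efe_after = sim.weights("EfE0")

    # Phase II step 3: per-transform individual tests again.
    test_after = _transform_tests(sim, cfg, tests, n_in, "phase2_test_after")

    return TwoLayerResult(cfg=cfg, stimulus_set=stimulus_set,
                          test_before=test_before, test_after=test_after,
                          w_ElE_after_phase1=w_ele,
                          w_EfE_before=w_efe_before, w_EfE_after=w_efe_after)


# -- parameter sweeps ------------------------------------------------------

#: Derived sweep parameters that touch more than one config field.
_DERIVED_PARAMS = ("alpha_ratio", "tau_CD_asym", "tau_CD_sym")


def _apply_param(cfg: ProtocolConfig, name: str, value: float) -> ProtocolConfig:
    if name == "alpha_ratio":
        # alpha_D / alpha_C = value with the geometric mean kept at 0.5.
        root = float(np.sqrt(value))
        return replace(cfg, alpha_C=0.5 / root, alpha_D=0.5 * root)
    if name == "tau_CD_asym":
        # tau_C = value with the default 15:25 ratio preserved.
        return replace(cfg, tau_C=float(value), tau_D=float(value) * 25.0 / 15.0)
    if name == "tau_CD_sym":
        return replace(cfg, tau_C=float(value), tau_D=float(value))
    if name in {f.name for f in dataclasses.fields(ProtocolConfig)}:
        return replace(cfg, **{name: value})
    raise KeyError(
        f"unknown sweep parameter {name!r}; addressable: "
        f"{sorted(f.name for f in dataclasses.fields(ProtocolConfig))} "
        f"plus {_DERIVED_PARAMS}")


def sweep(
    cfg: ProtocolConfig,
    param: str,
    grid: Sequence[float],
    metric: Callable[[object], float | dict[str, float]],
    n_seeds: int = 10,
    seeds: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Run one full experiment per (parameter value, seed) and aggregate.

    ``metric`` maps an experiment result to a scalar or a dict of named
    scalars.  Returns a tidy frame with one row per (value, metric name)
    carrying the across-seed mean and standard error (SEM = 0 for a
    single seed).
    """
    if seeds is None:
        seeds = [cfg.seed + k for k in range(n_seeds)]
    runner = (run_one_layer_experiment if cfg.experiment == "one_layer"
              else run_two_layer_experiment)
    rows = []
    for value in grid:
        for seed in seeds:
            c = replace(_apply_param(cfg, param, value), seed=int(seed))
            result = runner(c)
            m = metric(result)
            if not isinstance(m, dict):
                m = {"metric": float(m)}
            for name, v in m.items():
                rows.append({"param": param, "value": value, "seed": int(seed),
                             "metric": name, "score": float(v)})
    raw = pd.DataFrame(rows)
    agg = (raw.groupby(["param", "value", "metric"], as_index=False)
              .agg(mean=("score", "mean"),
                   sem=("score", lambda s: s.sem() if len(s) > 1 else 0.0),
                   n_seeds=("score", "size")))
    agg.attrs["raw"] = raw
    return agg
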