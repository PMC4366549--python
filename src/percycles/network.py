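"""Network assembly: one- and two-layer architectures.

Each layer pairs a pool of excitatory pyramidal cells with a pool of
inhibitory interneurons (E:I = 4:1 by default).  Within a layer the
excitatory cells may be laterally interconnected (ElE, plastic); E and I
pools are reciprocally fully connected with fixed-strength conductance
synapses (EI, IE); interneurons do not synapse onto each other.  In the
two-layer model a feed-forward excitatory projection (EfE, plastic) links
the excitatory cells of consecutive layers.

Connectivity is sampled Bernoulli per ordered cell pair (self-synapses
disallowed on ElE); there is no distance-dependent or topological wiring
-- any structure must self-organise through learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import CellState, NeuronParams, SynapseClassParams

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "SynapseClassSet",
    "BuiltLayer",
    "BuiltNetwork",
    "build_network",
    "default_one_layer",
    "default_two_layer",
]


@dataclass(frozen=True)
class LayerSpec:
    """One layer: pool sizes, spatial shape and connection probabilities."""

    n_exc: int
    n_inh: int
    exc_shape: tuple[int, int] | None = None
    p_ElE: float = 0.5
    p_IE: float = 1.0
    p_EI: float = 1.0
    p_II: float = 0.0
    lateral_plastic: bool = True

    def __post_init__(self) -> None:
        for name in ("p_ElE", "p_IE", "p_EI", "p_II"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.exc_shape is not None:
            rows, cols = self.exc_shape
            if rows * cols != self.n_exc:
                raise ValueError(
                    f"exc_shape {self.exc_shape} incompatible with n_exc={self.n_exc}"
                )
        if self.p_II != 0.0:
            raise ValueError("I->I synapses are not modelled (p_II must be 0)")


@dataclass(frozen=True)
class SynapseClassSet:
    """Synaptic class constants for every projection type."""

    ElE: SynapseClassParams
    IE: SynapseClassParams
    EI: SynapseClassParams
    EfE: SynapseClassParams | None = None

    @classmethod
    def defaults(
        cls,
        lam_ElE: float = 12.0,
        lam_IE: float = 5.0,
        lam_EI: float = 5.0,
        lam_EfE: float | None = None,
    ) -> "SynapseClassSet":
        """Default constants.

        tau_EE = 1 ms, tau_IE = 5 ms, tau_EI = 2 ms; excitatory reversal
        0 mV, inhibitory reversal -70 mV (shunting inhibition).  The
        inhibitory conductance scales are fixed at 5 nS; lam_ElE defaults
        to 12 nS, the midpoint of the anti-phase operating window (see
        docs/methods.md for how that window was located).
        """
        efe = None
        if lam_EfE is not None:
            efe = SynapseClassParams(lam=lam_EfE, tau_g=1.0, E_syn=0.0, plastic=True)
        return cls(
            ElE=SynapseClassParams(lam=lam_ElE, tau_g=1.0, E_syn=0.0, plastic=True),
            IE=SynapseClassParams(lam=lam_IE, tau_g=5.0, E_syn=-70.0, plastic=False),
            EI=SynapseClassParams(lam=lam_EI, tau_g=2.0, E_syn=0.0, plastic=False),
            EfE=efe,
        )


@dataclass(frozen=True)
class NetworkSpec:
    """Full architecture: ordered layers plus projection constants."""

    layers: tuple[LayerSpec, ...]
    synapses: SynapseClassSet
    p_EfE: float = 1.0
    efe_plastic: bool = True
    exc_params: NeuronParams = field(default_factory=NeuronParams.excitatory)
    inh_params: NeuronParams = field(default_factory=NeuronParams.inhibitory)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("at least one layer required")
        if not 0.0 <= self.p_EfE <= 1.0:
            raise ValueError("p_EfE outside [0, 1]")
        if len(self.layers) > 1 and self.synapses.EfE is None:
            raise ValueError("multi-layer spec requires EfE synapse parameters")

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def default_one_layer(
    lam_ElE: float = 12.0,
    lam_IE: float = 5.0,
    gK_alpha: float = 6.0,  # noqa: ARG001 (documented entry point; engine reads it)
) -> NetworkSpec:
    """Default one-layer architecture: 512 E + 128 I cells.

    ElE connectivity probability 0.5 (no self-synapses), E and I pools
    fully reciprocally connected, no I->I synapses.
    """
    layer = LayerSpec(n_exc=512, n_inh=128, exc_shape=None,
                      p_ElE=0.5, p_IE=1.0, p_EI=1.0, lateral_plastic=True)
    return NetworkSpec(layers=(layer,),
                       synapses=SynapseClassSet.defaults(lam_ElE=lam_ElE,
                                                         lam_IE=lam_IE))


def default_two_layer(
    lam_ElE: float = 6.0,
    lam_IE: float = 5.0,
    lam_EfE: float = 3.0,
) -> NetworkSpec:
    """Default two-layer architecture.

    Input layer: 512 E (32 rows x 16 columns) + 128 I, lateral E-E
    probability 1.0.  Output layer: 64 E (8 x 8) + 16 I, no lateral E-E.
    Feed-forward E->E projection fully connected, plastic, with maximum
    conductance increment ``lam_EfE`` (3 nS by default).

    ``lam_ElE`` defaults to 6 nS, half the one-layer value: the input
    layer here is all-to-all (p = 1.0 versus 0.5), and holding
    lam_ElE * p fixed keeps the expected lateral drive per cell -- and
    with it the anti-phase operating point -- the same across the two
    architectures (see docs/methods.md).
    """
    l1 = LayerSpec(n_exc=512, n_inh=128, exc_shape=(32, 16),
                   p_ElE=1.0, p_IE=1.0, p_EI=1.0, lateral_plastic=True)
    l2 = LayerSpec(n_exc=64, n_inh=16, exc_shape=(8, 8),
                   p_ElE=0.0, p_IE=1.0, p_EI=1.0, lateral_plastic=False)
    return NetworkSpec(
        layers=(l1, l2),
        synapses=SynapseClassSet.defaults(lam_ElE=lam_ElE, lam_IE=lam_IE,
                                          lam_EfE=lam_EfE),
        p_EfE=1.0,
        efe_plastic=True,
    )


@dataclass
class BuiltLayer:
    """Realised masks, weights and cell states of one layer.

    Masks and weight matrices are (post x pre).  IE/EI weights are fixed
    at Delta-g = 1; ElE weights start at 0 and are shaped by learning.
    """

    spec: LayerSpec
    mask_ElE: np.ndarray | None
    mask_IE: np.ndarray
    mask_EI: np.ndarray
    w_ElE: np.ndarray | None
    exc: CellState
    inh: CellState


@dataclass
class BuiltNetwork:
    """A realised network: layers plus inter-layer feed-forward pieces."""

    spec: NetworkSpec
    layers: list[BuiltLayer]
    mask_EfE: list[np.ndarray]  # one per layer gap, (post_exc x pre_exc)
    w_EfE: list[np.ndarray]


def _bernoulli_mask(rng: np.random.Generator, n_post: int, n_pre: int,
                    p: float, no_self: bool = False) -> np.ndarray:
    if p >= 1.0:
        mask = np.ones((n_post, n_pre), dtype=bool)
    elif p <= 0.0:
        mask = np.zeros((n_post, n_pre), dtype=bool)
    else:
        mask = rng.random((n_post, n_pre)) < p
    if no_self:
        np.fill_diagonal(mask, False)
    return mask


def build_network(spec: NetworkSpec, seed: int | np.random.Generator) -> BuiltNetwork:
    """Sample connectivity and initialise weights and cell states.

    ElE weights start at 0 (structure emerges through STDP); EfE weights
    are drawn uniformly on [0, 1] (scaled by lam_EfE at conductance time);
    IE/EI weights are fixed at 1.  Same seed, same network.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    layers: list[BuiltLayer] = []
    for ls in spec.layers:
        mask_ele = None
        w_ele = None
        if ls.p_ElE > 0.0:
            mask_ele = _bernoulli_mask(rng, ls.n_exc, ls.n_exc, ls.p_ElE,
                                       no_self=True)
            w_ele = np.zeros((ls.n_exc, ls.n_exc))
        mask_ie = _bernoulli_mask(rng, ls.n_exc, ls.n_inh, ls.p_IE)
        mask_ei = _bernoulli_mask(rng, ls.n_inh, ls.n_exc, ls.p_EI)
        layers.append(BuiltLayer(
            spec=ls,
            mask_ElE=mask_ele,
            mask_IE=mask_ie,
            mask_EI=mask_ei,
            w_ElE=w_ele,
            exc=CellState.resting(ls.n_exc, spec.exc_params),
            inh=CellState.resting(ls.n_inh, spec.inh_params),
        ))

    masks_efe: list[np.ndarray] = []
    w_efe: list[np.ndarray] = []
    for lower, upper in zip(spec.layers[:-1], spec.layers[1:]):
        masks_efe.append(_bernoulli_mask(rng, upper.n_exc, lower.n_exc, spec.p_EfE))
        w_efe.append(rng.uniform(0.0, 1.0, size=(upper.n_exc, lower.n_exc)))

    return BuiltNetwork(spec=spec, layers=layers, mask_EfE=masks_efe, w_EfE=w_efe)
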