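"""Single-time-step dynamics of conductance-based LIF (gLIF) neurons.

A gLIF membrane integrates a leak current, a calcium-gated potassium
(adaptation) current, conductance-based synaptic currents and an injected
external current, plus small Gaussian voltage noise.  Upon crossing its
firing threshold a cell emits a spike, is reset to its after-spike
hyperpolarisation potential and held there for an absolute refractory
period.  Excitatory spikes additionally increment a dimensionless calcium
trace whose product with ``gK_alpha`` is the adaptation conductance.

All dynamics are discretised with an explicit Forward-Euler scheme
(default time step 0.02 ms); exponential relaxations use the
multiplicative factor ``1 - dt/tau``.

Unit conventions (consistent set -- no hidden conversion factors):
potentials mV, time ms, conductance nS, capacitance pF, current pA
(nS*mV = pA; pA*ms/pF = mV).  Public APIs that quote cue currents in nA
convert once at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "AdaptationParams",
    "SynapseClassParams",
    "CellState",
    "NumericalInstabilityError",
    "membrane_step",
    "spike_and_reset",
    "calcium_step",
    "conductance_step",
    "lif_isi",
]

#: Noise amplitude as a fraction of the threshold-to-reset distance.
SIGMA_FRACTION = 0.015


class NumericalInstabilityError(RuntimeError):
    """Raised when a membrane potential becomes non-finite."""


@dataclass(frozen=True)
class NeuronParams:
    """Cellular constants of one neuron class.

    Parameters
    ----------
    C_m:
        Somatic capacitance (pF).
    g_0:
        Leak conductance (nS).
    E_L:
        Resting potential (mV).
    Theta:
        Firing threshold potential (mV).
    V_H:
        After-spike hyperpolarisation (reset) potential (mV).
    tau_R:
        Absolute refractory period (ms).
    cell_class:
        ``"excitatory"`` or ``"inhibitory"``.

    The noise amplitude ``sigma`` is fixed at 1.5 % of ``Theta - V_H`` and
    the membrane time constant ``tau_m`` is the derived ratio ``C_m/g_0``.
    """

    C_m: float
    g_0: float
    E_L: float
    Theta: float
    V_H: float
    tau_R: float
    cell_class: str = "excitatory"

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if self.g_0 <= 0:
            raise ValueError("g_0 must be positive")
        if not self.V_H < self.Theta:
            raise ValueError("V_H must lie below the firing threshold Theta")
        if self.cell_class not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown cell_class {self.cell_class!r}")

    @property
    def sigma(self) -> float:
        """Membrane noise amplitude (mV): 0.015 * (Theta - V_H)."""
        return SIGMA_FRACTION * (self.Theta - self.V_H)

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m / g_0 (ms)."""
        return self.C_m / self.g_0

    def noise_std(self, dt: float) -> float:
        """Per-step membrane noise kick (mV): sigma * sqrt(dt).

        The membrane noise is an independent Wiener process added to V
        whose increments have standard deviation ``sigma`` per sqrt(ms)
        (diffusion sigma^2 per ms), discretised Euler-Maruyama style.
        With the leak this gives stationary voltage fluctuations of
        ``sigma * sqrt(tau_m / 2)`` (~0.2 mV for the default excitatory
        constants) -- enough jitter to desynchronise symmetric cell
        assemblies while leaving inhibition-paced population volleys
        coherent.  docs/methods.md discusses the alternative
        discretisations and why this one is used.
        """
        return self.sigma * float(np.sqrt(dt))

    @classmethod
    def excitatory(cls) -> "NeuronParams":
        """Default excitatory (pyramidal) cell constants."""
        return cls(C_m=500.0, g_0=25.0, E_L=-74.0, Theta=-53.0, V_H=-57.0,
                   tau_R=2.0, cell_class="excitatory")

    @classmethod
    def inhibitory(cls) -> "NeuronParams":
        """Default inhibitory interneuron constants."""
        return cls(C_m=214.0, g_0=18.0, E_L=-82.0, Theta=-53.0, V_H=-58.0,
                   tau_R=2.0, cell_class="inhibitory")


@dataclass(frozen=True)
class AdaptationParams:
    """Calcium-gated potassium adaptation constants.

    ``gK_alpha`` is the increase in adaptation conductance per spike (nS);
    the calcium trace counts recent spikes, so the instantaneous adaptation
    conductance is ``gK_alpha * Ca``.  ``E_K`` is the potassium reversal
    potential (mV) and ``tau_Ca`` the calcium decay time constant (ms).
    """

    gK_alpha: float = 6.0
    E_K: float = -80.0
    tau_Ca: float = 50.0

    def __post_init__(self) -> None:
        if self.gK_alpha < 0:
            raise ValueError("gK_alpha must be non-negative")
        if self.tau_Ca <= 0:
            raise ValueError("tau_Ca must be positive")

    @classmethod
    def disabled(cls) -> "AdaptationParams":
        return cls(gK_alpha=0.0)


@dataclass(frozen=True)
class SynapseClassParams:
    """Per-projection-class synaptic constants.

    ``lam`` scales the conductance increment per presynaptic spike (nS),
    ``tau_g`` is the conductance decay constant (ms), ``E_syn`` the
    synaptic reversal potential (mV).  ``plastic`` marks whether the
    weights Delta-g of this class may be modified by STDP.
    """

    lam: float
    tau_g: float
    E_syn: float
    plastic: bool = False

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.tau_g <= 0:
            raise ValueError("tau_g must be positive")


@dataclass
class CellState:
    """Mutable per-population state vectors.

    ``V`` membrane potentials (mV), ``Ca`` dimensionless adaptation traces
    (recent-spike counts), ``refractory_remaining`` (ms) and
    ``last_spike_flag`` (bool) per cell.
    """

    V: np.ndarray
    Ca: np.ndarray
    refractory_remaining: np.ndarray
    last_spike_flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.last_spike_flag is None:
            self.last_spike_flag = np.zeros(self.V.shape, dtype=bool)

    @classmethod
    def resting(cls, n: int, p: NeuronParams) -> "CellState":
        """All cells at rest: V = E_L, no calcium, not refractory."""
        return cls(
            V=np.full(n, p.E_L, dtype=float),
            Ca=np.zeros(n, dtype=float),
            refractory_remaining=np.zeros(n, dtype=float),
            last_spike_flag=np.zeros(n, dtype=bool),
        )

    @property
    def n(self) -> int:
        return self.V.shape[0]

    def copy(self) -> "CellState":
        return CellState(self.V.copy(), self.Ca.copy(),
                         self.refractory_remaining.copy(),
                         self.last_spike_flag.copy())


def membrane_step(
    state: CellState,
    p: NeuronParams,
    a: AdaptationParams,
    syn_current: np.ndarray | float,
    I_ext: np.ndarray | float,
    noise_draw: np.ndarray | None,
    dt: float,
    step_index: int | None = None,
) -> CellState:
    """Advance the membrane potentials by one Forward-Euler step (in place).

    ``syn_current`` is the precomputed total synaptic current
    ``sum_classes g_total * (E_syn - V)`` in pA; ``I_ext`` is the injected
    current in pA.  ``noise_draw`` is a standard-normal draw per cell (or
    None for noise off); membrane noise adds ``noise_std(dt) * z`` to V
    each step (Euler-Maruyama step of the white-noise drive; see
    :meth:`NeuronParams.noise_std` and docs/methods.md).  Cells within
    their absolute refractory period are not integrated: V is clamped at
    ``V_H`` while ``refractory_remaining`` counts down (synaptic
    conductances keep evolving elsewhere).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    refractory = state.refractory_remaining > 0.0

    I_total = (
        p.g_0 * (p.E_L - state.V)
        + a.gK_alpha * state.Ca * (a.E_K - state.V)
        + syn_current
        + I_ext
    )
    dV = (dt / p.C_m) * I_total
    if noise_draw is not None:
        dV = dV + p.noise_std(dt) * noise_draw
    state.V += np.where(refractory, 0.0, dV)

    state.V[refractory] = p.V_H
    state.refractory_remaining[refractory] -= dt
    np.clip(state.refractory_remaining, 0.0, None, out=state.refractory_remaining)

    if not np.all(np.isfinite(state.V)):
        at = "" if step_index is None else f" at step {step_index}"
        raise NumericalInstabilityError(
            f"non-finite membrane potential{at}; "
            f"offending cells: {np.flatnonzero(~np.isfinite(state.V))[:10]}"
        )
    return state


def spike_and_reset(
    state: CellState, p: NeuronParams, a: AdaptationParams
) -> tuple[np.ndarray, CellState]:
    """Threshold crossing, spike emission and after-spike reset (in place).

    Cells at or above ``Theta`` that are not refractory spike: V is reset
    to ``V_H`` and the refractory clock set to ``tau_R``.  Calcium
    increments are the province of :func:`calcium_step`, which the engine
    calls with the returned flags.
    """
    spikes = (state.V >= p.Theta) & (state.refractory_remaining <= 0.0)
    state.V[spikes] = p.V_H
    state.refractory_remaining[spikes] = p.tau_R
    state.last_spike_flag = spikes
    return spikes, state


def calcium_step(
    state: CellState, a: AdaptationParams, spikes: np.ndarray, dt: float
) -> CellState:
    """Euler-decay the calcium trace, then add one unit per spike (in place).

    The per-spike calcium increment alpha is folded into ``gK_alpha`` (only the
    product matters), so Ca literally counts exponentially-discounted
    recent spikes.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.Ca *= 1.0 - dt / a.tau_Ca
    if spikes is not None and np.any(spikes):
        state.Ca[spikes] += 1.0
    return state


def conductance_step(
    g: np.ndarray,
    sc: SynapseClassParams,
    dg: np.ndarray,
    mask: np.ndarray | None,
    pre_spikes: np.ndarray,
    dt: float,
) -> np.ndarray:
    """One Euler step of the per-target total conductance of one class.

    ``g`` holds the summed conductance per postsynaptic cell (nS).  Each
    presynaptic spike of cell ``j`` adds ``lam * dg[i, j]`` to every target
    ``i`` connected through ``mask``.  Because all synapses of a class
    share ``tau_g``, integrating the per-target totals is exact.

    ``dg`` is the (post x pre) weight matrix in [0, 1], or None for a
    fixed projection (Delta-g = 1 everywhere); ``mask`` a boolean
    connectivity matrix of the same shape (None means fully connected).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g *= 1.0 - dt / sc.tau_g
    cols = np.flatnonzero(pre_spikes)
    if cols.size:
        if dg is None:  # fixed projection: Delta-g = 1 at every synapse
            w = mask[:, cols] if mask is not None else 1.0
            inc = w.sum(axis=1) if mask is not None else float(cols.size)
        else:
            w = dg[:, cols]
            if mask is not None:
                w = w * mask[:, cols]
            inc = w.sum(axis=1)
        g += sc.lam * inc
    if np.any(g < 0):
        raise NumericalInstabilityError("negative synaptic conductance")
    return g


def lif_isi(p: NeuronParams, I_ext: float) -> float:
    """Closed-form inter-spike interval of a noiseless, non-adapting LIF.

    For constant suprathreshold current ``I_ext`` (pA),
    ``T = tau_m * ln[(I/g0 + E_L - V_H) / (I/g0 + E_L - Theta)] + tau_R``.
    Used as an independent oracle for the simulated dynamics.
    """
    drive = I_ext / p.g_0 + p.E_L
    if drive <= p.Theta:
        raise ValueError("current is subthreshold; the cell never spikes")
    return p.tau_m * np.log((drive - p.V_H) / (drive - p.Theta)) + p.tau_R
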