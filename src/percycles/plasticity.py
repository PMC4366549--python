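"""Online multiplicative (soft-bound) STDP for excitatory synapses.

Each plastic projection carries a presynaptic trace C (glutamate released
into the cleft by recent presynaptic spikes) and a postsynaptic trace D
(proportion of unblocked NMDA receptors following recent postsynaptic
spikes).  Both traces saturate softly toward 1: a spike moves the trace up
by ``alpha * (1 - trace)`` and it decays back to 0 with its own time
constant.

Weights Delta-g in [0, 1] are updated at spike times only:

* postsynaptic spike at synapse ij -> LTP:  dg += eta * (1 - dg) * C_j
* presynaptic  spike at synapse ij -> LTD:  dg -= eta * dg * D_i

with per-spike gain ``eta = dt / tau_dg``.  The (1 - dg) and dg factors
are the multiplicative soft bounds: they keep weights interior instead of
piling them at the extremes as additive STDP does.

Because the trace dynamics depend only on the spikes of one side, C is
stored per presynaptic cell and D per postsynaptic cell (exactly
equivalent to the per-synapse formulation with zero initial conditions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["STDPParams", "PlasticityState", "trace_step", "weight_step"]


@dataclass(frozen=True)
class STDPParams:
    """STDP constants.

    alpha_C / alpha_D are the fractional trace increments per pre-/post-
    synaptic spike; tau_C / tau_D their decay constants (ms); tau_dg sets
    the learning rate through the per-spike gain eta = dt / tau_dg.
    """

    alpha_C: float = 0.5
    alpha_D: float = 0.5
    tau_C: float = 15.0
    tau_D: float = 25.0
    tau_dg: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_C < 1.0:
            raise ValueError("alpha_C must lie in [0, 1)")
        if not 0.0 <= self.alpha_D < 1.0:
            raise ValueError("alpha_D must lie in [0, 1)")
        if min(self.tau_C, self.tau_D, self.tau_dg) <= 0:
            raise ValueError("all time constants must be positive")

    def eta(self, dt: float) -> float:
        """Per-spike learning gain for time step ``dt`` (0.2 at defaults)."""
        return dt / self.tau_dg


@dataclass
class PlasticityState:
    """Traces and weights of one plastic projection.

    ``C``: presynaptic trace per presynaptic cell, in [0, 1).
    ``D``: postsynaptic trace per postsynaptic cell, in [0, 1).
    ``dg``: weight matrix (post x pre) in [0, 1].
    """

    C: np.ndarray
    D: np.ndarray
    dg: np.ndarray

    @classmethod
    def zeros(cls, n_post: int, n_pre: int,
              dg: np.ndarray | None = None) -> "PlasticityState":
        if dg is None:
            dg = np.zeros((n_post, n_pre))
        return cls(C=np.zeros(n_pre), D=np.zeros(n_post), dg=dg)

    def copy(self) -> "PlasticityState":
        return PlasticityState(self.C.copy(), self.D.copy(), self.dg.copy())


def trace_step(
    ps: PlasticityState,
    sp: STDPParams,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    dt: float,
) -> PlasticityState:
    """Euler-decay both traces, then apply this step's spike increments.

    C <- C * (1 - dt/tau_C), then C <- C + alpha_C * (1 - C) per
    presynaptic spike; D analogously with tau_D, alpha_D and postsynaptic
    spikes.  In the integration loop this is called *after*
    :func:`weight_step`, so a spike never pairs with its own trace
    increment.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ps.C *= 1.0 - dt / sp.tau_C
    ps.D *= 1.0 - dt / sp.tau_D
    if np.any(pre_spikes):
        ps.C[pre_spikes] += sp.alpha_C * (1.0 - ps.C[pre_spikes])
    if np.any(post_spikes):
        ps.D[post_spikes] += sp.alpha_D * (1.0 - ps.D[post_spikes])
    return ps


def weight_step(
    ps: PlasticityState,
    sp: STDPParams,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    dt: float,
    mask: np.ndarray | None = None,
) -> PlasticityState:
    """Apply LTP/LTD weight updates for this step's spikes (in place).

    Uses the traces as they stood *before* this step's trace increments
    (order-independence within a step: if pre and post fire together, both
    terms apply with the pre-update traces).  Weights are clipped to
    [0, 1] afterwards as a numerical belt-and-braces; the multiplicative
    rule itself cannot overshoot for eta <= 1.
    """
    eta = sp.eta(dt)
    rows = np.flatnonzero(post_spikes)
    cols = np.flatnonzero(pre_spikes)
    if rows.size:
        ltp = eta * (1.0 - ps.dg[rows, :]) * ps.C[np.newaxis, :]
        if mask is not None:
            ltp *= mask[rows, :]
        ps.dg[rows, :] += ltp
    if cols.size:
        ltd = eta * ps.dg[:, cols] * ps.D[:, np.newaxis]
        if mask is not None:
            ltd *= mask[:, cols]
        ps.dg[:, cols] -= ltd
    if rows.size or cols.size:
        np.clip(ps.dg, 0.0, 1.0, out=ps.dg)
    return ps
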