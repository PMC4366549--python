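"""Compiled inner loop for one layer over a chunk of Euler steps.

The network graph is feed-forward between layers (layer 2 never projects
back), so a simulation advances layer by layer: each layer's excitatory
spike raster for a chunk is computed in full and then handed to the next
layer as its feed-forward presynaptic input.

The kernel reproduces the reference step semantics of
:mod:`percycles.model_core` and :mod:`percycles.plasticity` exactly (same
operation order; floating-point rounding may differ at machine epsilon):

1. decay all conductance totals and calcium, apply the previous step's
   spike increments;
2. plastic weight updates (when gated) then trace updates, both driven
   by the previous step's spikes;
3. membrane Euler update (refractory cells clamped at V_H), threshold,
   reset.

Spike rasters are dense boolean (n_steps x n_cells) chunk buffers.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["step_layer_chunk"]


@njit(cache=True)
def step_layer_chunk(  # noqa: PLR0913 - flat argument list keeps numba simple
    dt,
    n_steps,
    # excitatory pool state
    VE, CaE, refE, prevE,
    CmE, g0E, ELE, ThE, VHE, tauRE, sigE,
    gK, EK, tauCa,
    # inhibitory pool state
    VI, refI, prevI,
    CmI, g0I, ELI, ThI, VHI, tauRI, sigI,
    # synaptic reversals
    EsynE, EsynI,
    # lateral E->E
    has_ele, maskElE, wElE, gElE, lamElE, tauEE,
    # I->E
    maskIE, gIE, lamIE, tauIE,
    # E->I
    maskEI, gEI, lamEI, tauEI,
    # feed-forward E->E from the layer below (pre-spike raster for the chunk)
    has_ff, ffpre, prevFF, maskFF, wFF, gFF, lamFF, tauFF,
    # plasticity (ElE / feed-forward): gate flags, traces, constants
    ele_plastic, trace_ele, C_ele, D_ele,
    ff_plastic, trace_ff, C_ff, D_ff,
    aC, aD, tauC, tauD, eta,
    # pre-drawn standard-normal noise, (n_steps x n) or (0 x 0) when off
    use_noise, noiseE, noiseI,
    # external currents (pA)
    IextE, IextI,
    # output spike rasters, (n_steps x n), zero-initialised
    outE, outI,
):
    """Advance one layer for ``n_steps``; returns -1 or the failing step."""
    nE = VE.shape[0]
    nI = VI.shape[0]
    nFF = wFF.shape[1]

    decEE = 1.0 - dt / tauEE
    decIE = 1.0 - dt / tauIE
    decEI = 1.0 - dt / tauEI
    decFF = 1.0 - dt / tauFF
    decCa = 1.0 - dt / tauCa
    decC = 1.0 - dt / tauC
    decD = 1.0 - dt / tauD
    kE = dt / CmE
    kI = dt / CmI
    nzE = sigE
    nzI = sigI

    pE = prevE.copy()
    pI = prevI.copy()
    pFF = prevFF.copy()

    for k in range(n_steps):
        # -- 1. decay conductances / calcium, add previous-step spikes ----
        if has_ele:
            for i in range(nE):
                gElE[i] *= decEE
            for j in range(nE):
                if pE[j]:
                    for i in range(nE):
                        if maskElE[i, j]:
                            gElE[i] += lamElE * wElE[i, j]
        for i in range(nE):
            gIE[i] *= decIE
        for j in range(nI):
            if pI[j]:
                for i in range(nE):
                    if maskIE[i, j]:
                        gIE[i] += lamIE
        for i in range(nI):
            gEI[i] *= decEI
        for j in range(nE):
            if pE[j]:
                for i in range(nI):
                    if maskEI[i, j]:
                        gEI[i] += lamEI
        if has_ff:
            for i in range(nE):
                gFF[i] *= decFF
            for j in range(nFF):
                if pFF[j]:
                    for i in range(nE):
                        if maskFF[i, j]:
                            gFF[i] += lamFF * wFF[i, j]

        for i in range(nE):
            CaE[i] *= decCa
            if pE[i]:
                CaE[i] += 1.0

        # -- 2. plasticity: weights first (pre-update traces), then traces
        if trace_ele:
            if ele_plastic:
                for i in range(nE):          # LTP on postsynaptic spikes
                    if pE[i]:
                        for j in range(nE):
                            if maskElE[i, j]:
                                w = wElE[i, j] + eta * (1.0 - wElE[i, j]) * C_ele[j]
                                wElE[i, j] = min(max(w, 0.0), 1.0)
                for j in range(nE):          # LTD on presynaptic spikes
                    if pE[j]:
                        for i in range(nE):
                            if maskElE[i, j]:
                                w = wElE[i, j] - eta * wElE[i, j] * D_ele[i]
                                wElE[i, j] = min(max(w, 0.0), 1.0)
            for j in range(nE):
                C_ele[j] *= decC
                if pE[j]:
                    C_ele[j] += aC * (1.0 - C_ele[j])
            for i in range(nE):
                D_ele[i] *= decD
                if pE[i]:
                    D_ele[i] += aD * (1.0 - D_ele[i])
        if trace_ff:
            if ff_plastic:
                for i in range(nE):
                    if pE[i]:
                        for j in range(nFF):
                            if maskFF[i, j]:
                                w = wFF[i, j] + eta * (1.0 - wFF[i, j]) * C_ff[j]
                                wFF[i, j] = min(max(w, 0.0), 1.0)
                for j in range(nFF):
                    if pFF[j]:
                        for i in range(nE):
                            if maskFF[i, j]:
                                w = wFF[i, j] - eta * wFF[i, j] * D_ff[i]
                                wFF[i, j] = min(max(w, 0.0), 1.0)
            for j in range(nFF):
                C_ff[j] *= decC
                if pFF[j]:
                    C_ff[j] += aC * (1.0 - C_ff[j])
            for i in range(nE):
                D_ff[i] *= decD
                if pE[i]:
                    D_ff[i] += aD * (1.0 - D_ff[i])

        # -- 3. membranes, thresholds, resets -----------------------------
        for i in range(nE):
            if refE[i] > 0.0:
                VE[i] = VHE
                refE[i] -= dt
                if refE[i] < 0.0:
                    refE[i] = 0.0
            else:
                v = VE[i]
                syn = gIE[i] * (EsynI - v)
                if has_ele:
                    syn += gElE[i] * (EsynE - v)
                if has_ff:
                    syn += gFF[i] * (EsynE - v)
                I_tot = (g0E * (ELE - v) + gK * CaE[i] * (EK - v)
                         + syn + IextE[i])
                dv = kE * I_tot
                if use_noise:
                    dv += nzE * noiseE[k, i]
                VE[i] = v + dv
                if not np.isfinite(VE[i]):
                    return k
            if VE[i] >= ThE and refE[i] <= 0.0:
                outE[k, i] = True
                VE[i] = VHE
                refE[i] = tauRE

        for i in range(nI):
            if refI[i] > 0.0:
                VI[i] = VHI
                refI[i] -= dt
                if refI[i] < 0.0:
                    refI[i] = 0.0
            else:
                v = VI[i]
                I_tot = g0I * (ELI - v) + gEI[i] * (EsynE - v) + IextI[i]
                dv = kI * I_tot
                if use_noise:
                    dv += nzI * noiseI[k, i]
                VI[i] = v + dv
                if not np.isfinite(VI[i]):
                    return k
            if VI[i] >= ThI and refI[i] <= 0.0:
                outI[k, i] = True
                VI[i] = VHI
                refI[i] = tauRI

        # next step's "previous spikes"
        pE = outE[k]
        pI = outI[k]
        if has_ff:
            pFF = ffpre[k]

    return -1
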