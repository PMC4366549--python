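# Methods

`percycles` simulates two small cortical circuits in which spike-timing
dynamics solve a perceptual binding problem: lateral excitatory plasticity
learns stimulus *categories*, the learned lateral connections temporally
segment simultaneously presented novel stimuli into anti-phase population
oscillations ("perceptual cycles"), and a second layer of neurons reads
the alternating volleys out into separate translation-invariant object
representations.  This note records the model equations as implemented,
the numerical conventions, the parameter choices that were genuinely open,
and what the desk-scale protocols do and do not demonstrate.

## Neuron and synapse model

Cells are conductance-based leaky integrate-and-fire (gLIF) neurons in an
excitatory (E) and an inhibitory (I) class.  The membrane obeys

    C_m dV/dt = g_0 (E_L - V) + g_K·Ca·(E_K - V)
              + Σ_E g(t)(E_syn^E - V) + Σ_I g(t)(E_syn^I - V)
              + I_ext + membrane noise,

with threshold Θ, after-spike reset to V_H and an absolute refractory
period τ_R = 2 ms during which V is clamped at V_H (synaptic conductances
keep evolving; only the voltage integration is suspended).  Default
constants (cortical slice estimates): excitatory C_m = 500 pF, g_0 =
25 nS (τ_m = 20 ms), E_L = −74 mV, Θ = −53 mV, V_H = −57 mV; inhibitory
C_m = 214 pF, g_0 = 18 nS (τ_m ≈ 11.9 ms), E_L = −82 mV, Θ = −53 mV,
V_H = −58 mV.

Firing-rate adaptation (E cells only): each spike increments a calcium
trace Ca by 1; Ca decays with τ_Ca = 50 ms; the adaptation conductance is
gK_alpha·Ca with gK_alpha = 6 nS per unit of Ca, reversing at E_K =
−80 mV.  Only the product of the per-spike calcium increment and the
potassium conductance gain is identifiable, so the increment is fixed at
1 and the whole scale carried by `gK_alpha`.  Adaptation is the model's
delayed self-inhibition: it is what makes a stimulus representation
release the network after a few volleys so the competing representation
can take over.

Synapses are conductance pulses: a presynaptic spike at a synapse of
class k adds λ_k·Δg to the target's class-k conductance, which decays
with τ_EE = 1 ms (E→E, lateral and feed-forward), τ_IE = 5 ms (I→E,
shunting, E_syn = −70 mV) or τ_EI = 2 ms (E→I, E_syn = 0 mV).  Weights
Δg ∈ [0, 1] are plastic on E→E projections and fixed at 1 on I→E / E→I
(λ_IE = λ_EI = 5 nS).  Because all synapses of a class share one decay
constant, the per-target class totals are integrated instead of
per-synapse conductances — an exact reformulation, not an approximation.

## Multiplicative STDP

Plastic projections carry a presynaptic trace C_j (per presynaptic cell)
and a postsynaptic trace D_i (per postsynaptic cell), each jumping by
α·(1 − trace) at its own side's spikes (α_C = α_D = 0.5) and decaying
with τ_C = 15 ms / τ_D = 25 ms.  At a postsynaptic spike every incoming
synapse potentiates by η·(1 − Δg)·C_j; at a presynaptic spike every
outgoing synapse depresses by η·Δg·D_i.  The soft bounds (1 − Δg) and Δg
keep the stationary weight distribution interior and unimodal rather
than bimodal-at-the-rails as in additive STDP.

The learning-rate constant is quoted as a time constant τ_Δg = 0.1 ms.
Read with Dirac spikes this would move weights by amounts ≫ 1 per spike
pair; the implementation reads the spike sums as unit impulses per Euler
step, giving a per-spike gain η = Δt/τ_Δg = 0.2 at the defaults.  With
volley rates of ~12–25 Hz this produces gradual weight structuring over
a few training epochs without single-presentation saturation, which is
the behaviour the protocols require.

Within a step the weight update runs before the trace update, so a spike
never pairs with its own trace increment, and simultaneous pre+post
spikes apply both LTP and LTD using the pre-update traces
(order-independence within a step).

## Integration scheme

Everything is discretised with Forward Euler at Δt = 0.02 ms.  Per step:

1. all conductance totals, calcium and STDP traces decay by (1 − Δt/τ),
   and the increments of the *previous* step's spikes are applied (a
   spike therefore influences its targets from the following step — a
   one-step, 0.02 ms effective delay; there are no conduction delays);
2. gated plastic projections apply the weight updates for those spikes,
   then the traces advance;
3. membranes integrate and threshold, yielding this step's spikes.

Because the inter-layer projection is strictly feed-forward, layers are
advanced sequentially (layer 1's spike raster for a chunk of steps is
computed in full, then fed to layer 2).  The inner loop is compiled with
numba; the pure-numpy single-step operations remain the reference
implementation and the test suite checks the compiled path against an
op-by-op composition of them, spike for spike.

## Membrane noise

The noise term is specified as zero-mean Gaussian white noise on the
membrane potential with σ = 0.015·(Θ − V_H) (0.06 mV for E cells), but
its printed form is dimensionally ambiguous and the discretisation
materially changes the dynamics.  The implementation adds an independent
Wiener increment σ·√Δt·z per step (σ per √ms), giving stationary voltage
fluctuations of σ·√(τ_m/2) ≈ 0.19 mV.  This convention was fixed by a
regime analysis of the coherent alternatives:

* σ·√(Δt/τ_m)·z (≈ 0.04 mV stationary): untrained networks synchronise
  globally, and the one-layer trained network forms anti-phase cycles,
  but in the two-layer configuration (all-to-all lateral connectivity)
  the two stimulus assemblies are dynamical twins and the in-phase state
  never breaks — the segmentation the model is about cannot occur.
* σ·√(τ_m·Δt)·z or larger (≳ 0.85 mV): assemblies desynchronise so
  strongly that the untrained network's global synchrony (and the
  within-stimulus synchrony of weakly coupled trained networks) is
  destroyed.
* σ·√Δt·z (≈ 0.19 mV): the only tested convention under which all three
  reported regimes coexist — untrained global synchrony, trained
  one-layer anti-phase cycles, and two-layer segmentation of translating
  compounds.

The choice was made once, on these qualitative regime checks, and not
revisited.

## Architectures

One-layer network: 512 E cells + 128 I cells; lateral E→E connectivity
sampled Bernoulli with p = 0.5 per ordered pair (no self-synapses),
weights initialised to 0; E and I pools fully reciprocally connected;
no I→I synapses.

Two-layer network: input layer 512 E (32 rows × 16 columns) + 128 I with
all-to-all lateral E→E (p = 1.0, weights 0); output layer 64 E (8 × 8) +
16 I with no lateral E→E; feed-forward E→E fully connected with weights
drawn uniformly on [0, 1] and conductance scale λ_EfE = 3 nS.

### Lateral conductance scale λ_ElE

The maximum lateral conductance increment is the one constant the source
tables leave as an explored range ([0.05, 500] nS) rather than a value,
with the anti-phase regime reported as robust over about two orders of
magnitude.  The one-layer default was calibrated once by reproducing
that sweep at desk scale: anti-phase segmentation (between-stimulus
Spearman ≈ −0.6, within ≈ +0.7, group period ≈ 87 ms) holds for λ_ElE ≈
8–20 nS under the reduced one-layer protocol, with in-phase collapse
below and unstable winner-dominance far above.  The one-layer default is
the window midpoint, λ_ElE = 12 nS.

The two-layer input layer is all-to-all (p(ElE) = 1.0 versus 0.5), so
the same λ would double the expected lateral drive per cell and push the
layer out of its operating window (volleys then ignite one large joint
assembly of both categories and their pools, and the output layer
saturates).  The two-layer default holds λ_ElE·p fixed instead:
λ_ElE = 6 nS.  At this point a cued 96-neuron stimulus volley recruits a
modest number of additional same-category pool cells (volleys of ≈
96–120 spikes, ≳ 90 % from a single group), and the feed-forward scale
is balanced against exactly this volley size: λ_EfE = 3 nS makes a
category volley marginally suprathreshold for output cells — a fraction
of the output layer fires per volley, which is what keeps the output
competition alive — while 2.25 nS leaves the output layer silent, the
reported behaviour of the feed-forward scale.

## Stimulus protocols

Static (one-layer): the 512 inputs are split into two disjoint category
pools of 256; an example activates 128 pool neurons with 0.75 nA tonic
current.  Ten training examples plus one reserved novel example per
category at full scale; the two novel examples are presented *together*
(union of their feature sets; a shared neuron receives the single cue
current) for 1000 ms before and after training.  Training presents each
example for 500 ms, examples in fresh random order each epoch, membrane
and synaptic state carrying over between presentations; test segments
start from a fully settled state (hard reset of V, conductances, calcium
and traces) so no transform or presentation bleeds into the next.

Translating (two-layer): each category owns 16 of the 32 input rows; a
stimulus is 12 of those rows, extended over an 8-column window; transform
t occupies columns 2(t−1)+1 … 2(t−1)+8 (1-based), so consecutive
transforms overlap by 75 % and transforms 1 and 5 are disjoint.  Identity
lives in the rows, translation in the columns — the two are orthogonal by
construction.  Category-overlap variants designate 2 or 4 rows as shared
between both prototypes (16.7 % / 33.3 % neuron sharing per transform
pair).  Phase I trains the lateral weights on the translating training
stimuli (transforms in order within a stimulus, stimuli in random order);
Phase II freezes them, tests each novel stimulus individually per
transform (1000 ms each from a settled state), trains the feed-forward
weights on the two novel stimuli translating *together*, and tests again.

## Evaluation measures

Synchrony: population spike counts of the two stimulus groups in 10 ms
bins; bins with fewer than ten spikes pooled across the compared pair are
excluded (quiescent-network periods; a bin where one group volleys alone
is kept — it is the evidence of segmentation).  Between-stimuli measure:
Spearman rank correlation of the two group series.  Within-stimulus:
each group is split into two random halves and the halves correlated,
averaged over groups.  Correlograms are standard normalised auto-/
cross-correlations of the mean-subtracted series with ±z_0.975/√N bounds;
the oscillation period is the mean spacing of successive significant
peaks.  The alternation frequency of two anti-phase groups is read from
the first significant cross-correlogram peak on either side of zero lag
(at ±T/2 for group period T), whose inverse is the volley-alternation
rate; the spacing between successive cross-peaks recovers T itself.

Information: firing rates per (cell, stimulus, transform) from the
settled 1000 ms tests.  Stimulus-specific single-cell information uses
rates quantised into 10 equal-width bins over each cell's own range
(results are insensitive to this with the near-binary responses the
trained network produces); its maximum is log2(N_S) = 1 bit for two
stimuli.  Multiple-cell information decodes held-out responses with
jack-knifed Gaussian fits per cell and stimulus (std floored at 0.1 Hz),
soft-accumulates the normalised posterior into a confusion table,
averages the table's mutual information over 100·(C_max − c + 1) random
ensembles of size c from the pool of the five best cells per stimulus,
subtracts the first-order finite-sampling bias term
[Σ_s(S̃_s − 1) − (S̃ − 1)]/(2·N·ln 2), and clips to [0, log2 N_S].  The
information score ι_κ is the fraction of output cells reaching
κ·log2(N_S) bits (κ = 0.95) for the least-represented stimulus — nonzero
only when every stimulus has dedicated cells.

## Desk-scale protocol sizes

Full-scale protocols (10 examples/category × 10 epochs × 500 ms, or
8 stimuli × 5 transforms × 10 epochs per phase) run in minutes; the test
suite and the acceptance script use reduced versions chosen as the
package's standard desk scale:

* one-layer: 4 examples/category, 3 epochs, 250 ms training cues,
  1000 ms tests — the anti-phase signature, its ~85 ms group period and
  ~25 Hz alternation are already stable here;
* two-layer: 4 training stimuli/category, 3 transforms, 500 ms training
  cues, 1000 ms tests; Phase I (the expensive part — all training
  stimuli of both categories) reduced to 3 epochs, Phase II (the cheap
  two-stimulus compound) kept at the full 10 epochs.  The asymmetry is
  deliberate: output differentiation under the multiplicative rule needs
  roughly 10–20 s of compound exposure, because depression of the
  non-preferred category's synapses accrues only through the small
  residue of the postsynaptic trace (D ≈ 0.02 by the next opposite-group
  volley at the ~80 ms own-group period).  Three Phase II epochs leave
  output cells unselective; ten give essentially every cell the full
  1 bit;
* sweeps: 3 random seeds per grid point with further-shortened cues,
  enough to resolve the qualitative shapes (anti-phase window interior
  to the λ_ElE grid; interior ι_κ maximum over λ_EfE; performance
  collapse for slow STDP time constants).

What the synthetic protocols do not show: the stimuli are idealised
disjoint (or controlled-overlap) feature sets with identical statistics,
translation is the only transformation, and only two stimuli are ever
presented together.  Passing tests therefore demonstrate the binding /
segmentation / invariance *mechanism* under the stated statistics, not
performance on natural images or capacity beyond two objects.

## Degenerate inputs and numerical guards

Non-finite membrane potentials abort the run with the failing step index
and a state dump.  Conductances, calcium and traces are non-negative by
construction; weights are clipped to [0, 1] after each update as a guard
although the multiplicative rule cannot overshoot at η ≤ 1.  Correlation
measures on constant or too-sparse series return flagged-undefined
results rather than silent zeros.  Zero-variance Gaussian fits in the
decoder are floored, never raised.  All randomness flows from a master
seed through independent named streams (connectivity, stimuli, noise,
presentation order, decoder sampling), so any experiment replays
bit-exactly from its config.
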