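"""Firing-rate information analyses of the output layer.

From the per-(stimulus, transform) test presentations a response table of
firing rates is built.  Three measures quantify how well output cells
combine stimulus *specificity* with transform *generality*:

* stimulus-specific single-cell information: bits a cell's quantised rate
  responses carry about one particular stimulus,
  ``I(s,R) = sum_r P(r|s) log2 [P(r|s) / P(r)]``, bounded by log2(N_S);
* multiple-cell information: the mutual information between presented and
  Bayesian-decoded stimuli, estimated per ensemble size with jack-knife
  cross-validation, first-order finite-sampling bias correction and
  clipping to the theoretical limits;
* information score iota_kappa: the fraction of output cells that reach
  at least ``kappa * log2(N_S)`` bits for the *least* well represented
  stimulus -- nonzero only when every stimulus has dedicated cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import SegmentRecord

__all__ = [
    "ResponseTable",
    "SingleCellInfo",
    "DecodingConfig",
    "MultiCellInfo",
    "rates_from_record",
    "single_cell_info",
    "decode_ensemble",
    "multi_cell_info",
    "info_score",
]


@dataclass
class ResponseTable:
    """Firing rates (Hz) on a complete (cell, stimulus, transform) grid."""

    rates: np.ndarray                  # (C, N_S, N_T)
    stimulus_ids: tuple = ()
    transform_ids: tuple = ()

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 3:
            raise ValueError("rates must be (cells, stimuli, transforms)")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.rates.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.rates.shape[1]

    @property
    def n_transforms(self) -> int:
        return self.rates.shape[2]


def rates_from_record(
    records: dict[tuple[int, int], SegmentRecord],
    pop: str = "exc1",
) -> ResponseTable:
    """Build the response table from per-(stimulus, transform) test records.

    Each record holds one settled presentation; the rate is the spike
    count divided by the segment duration.
    """
    stims = sorted({k[0] for k in records})
    trans = sorted({k[1] for k in records})
    missing = [(s, t) for s in stims for t in trans if (s, t) not in records]
    if missing:
        raise ValueError(f"incomplete test grid; missing {missing}")
    n_cells = records[(stims[0], trans[0])].n_neurons[pop]
    rates = np.zeros((n_cells, len(stims), len(trans)))
    for (s, t), rec in records.items():
        rates[:, stims.index(s), trans.index(t)] = (
            rec.counts(pop) / (rec.duration / 1000.0))
    return ResponseTable(rates=rates, stimulus_ids=tuple(stims),
                         transform_ids=tuple(trans))


@dataclass
class SingleCellInfo:
    """Per-(cell, stimulus) information in bits, bounded by log2(N_S)."""

    info: np.ndarray                   # (C, N_S)
    n_bins: int

    @property
    def per_cell_max(self) -> np.ndarray:
        return self.info.max(axis=1)


def _quantise(rates: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bins over one cell's observed rate range.

    A cell with a constant response falls entirely into one bin (and so
    carries zero information).
    """
    lo, hi = rates.min(), rates.max()
    if hi <= lo:
        return np.zeros(rates.shape, dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.clip(np.digitize(rates, edges[1:-1]), 0, n_bins - 1)


def single_cell_info(table: ResponseTable, n_bins: int = 10) -> SingleCellInfo:
    """Stimulus-specific single-cell information per (cell, stimulus).

    Rates are quantised into ``n_bins`` equal-width bins over each cell's
    own range; P(r|s) is estimated over the transforms of s and P(r) over
    all presentations with equiprobable stimuli.
    """
    if n_bins < 2:
        raise ValueError("need at least two response bins")
    C, N_S, N_T = table.rates.shape
    out = np.zeros((C, N_S))
    for c in range(C):
        q = _quantise(table.rates[c], n_bins)          # (N_S, N_T)
        p_r = np.bincount(q.ravel(), minlength=n_bins) / (N_S * N_T)
        for s in range(N_S):
            p_r_s = np.bincount(q[s], minlength=n_bins) / N_T
            nz = p_r_s > 0
            out[c, s] = np.sum(p_r_s[nz] * np.log2(p_r_s[nz] / p_r[nz]))
    return SingleCellInfo(info=out, n_bins=n_bins)


@dataclass(frozen=True)
class DecodingConfig:
    """Bayesian-decoding schedule and numerical guards.

    The ensemble pool holds up to ``5 * N_S`` cells; ensemble size c is
    averaged over ``100 * (C_max - c + 1)`` random subsets (decreasing
    linearly with c).  ``std_floor`` guards zero within-stimulus variance
    in the Gaussian fits; ``soft`` accumulates the full normalised
    posterior into the confusion table instead of its argmax.
    """

    cells_per_stimulus: int = 5
    iterations_base: int = 100
    std_floor: float = 0.1
    soft: bool = True

    def c_max(self, n_stimuli: int) -> int:
        return self.cells_per_stimulus * n_stimuli

    def n_iterations(self, c: int, n_stimuli: int) -> int:
        return self.iterations_base * (self.c_max(n_stimuli) - c + 1)


def decode_ensemble(
    table: ResponseTable,
    ensemble: np.ndarray | list[int],
    cfg: DecodingConfig = DecodingConfig(),
    prior: np.ndarray | None = None,
) -> np.ndarray:
    """Jack-knifed Bayesian decoding -> confusion table P(s, s').

    Every (stimulus, transform) response vector is held out in turn.  Per
    cell, each stimulus-conditional rate distribution is fitted as a
    Gaussian over that stimulus's *other* transforms (the held-out
    response never informs its own stimulus's fit).  The posterior
    ``P(s'|r) ~ P(s') * prod_c N(r_c; mu_c(s'), sd_c(s'))`` is normalised
    and accumulated into row s of the confusion table, which is finally
    normalised to total mass 1.
    """
    ens = np.asarray(ensemble, dtype=int)
    if ens.size == 0:
        raise ValueError("ensemble must be non-empty")
    C, N_S, N_T = table.rates.shape
    if N_T < 2:
        raise ValueError("jack-knife needs at least two transforms per stimulus")
    if prior is None:
        prior = np.full(N_S, 1.0 / N_S)
    r = table.rates[ens]               # (c, N_S, N_T)

    mu_all = r.mean(axis=2)            # (c, N_S)
    conf = np.zeros((N_S, N_S))
    idx = np.arange(N_T)
    for t in range(N_T):
        rest = idx[idx != t]
        mu_loo = r[:, :, rest].mean(axis=2)            # leave-one-out mean
        sd_loo = r[:, :, rest].std(axis=2)
        sd_all = r.std(axis=2)
        for s in range(N_S):
            x = r[:, s, t]                             # held-out vector (c,)
            # conditional fits: stimulus s uses the jack-knifed moments,
            # other stimuli use all their transforms
            mu = mu_all.copy()
            sd = sd_all.copy()
            mu[:, s] = mu_loo[:, s]
            sd[:, s] = sd_loo[:, s]
            sd = np.maximum(sd, cfg.std_floor)
            loglik = (-0.5 * ((x[:, None] - mu) / sd) ** 2
                      - np.log(sd)).sum(axis=0)        # (N_S,)
            loglik += np.log(prior)
            loglik -= loglik.max()
            post = np.exp(loglik)
            post /= post.sum()
            if cfg.soft:
                conf[s] += post
            else:
                conf[s, np.argmax(post)] += 1.0
    return conf / conf.sum()


def _mutual_information(conf: np.ndarray) -> float:
    """Mutual information (bits) of a joint probability table."""
    p_s = conf.sum(axis=1, keepdims=True)
    p_sp = conf.sum(axis=0, keepdims=True)
    nz = conf > 0
    return float(np.sum(conf[nz] * np.log2(conf[nz] / (p_s @ p_sp)[nz])))


def _bias_correction(conf: np.ndarray, n_trials: int) -> float:
    """First-order finite-sampling correction (bits).

    The classic first-order term for a decoded confusion table,
    ``[sum_s (S_tilde_s - 1) - (S_tilde - 1)] / (2 * N_trials * ln 2)``,
    where S_tilde_s counts decoded categories carrying probability mass
    for true stimulus s and S_tilde those with mass overall.  It vanishes
    for a clean diagonal table (a perfect decoder is not penalised) and
    approaches (S-1)^2 / (2 N ln 2) for a fully occupied one.
    """
    occupied = conf > 1e-12           # ignore soft-posterior float dust
    s_tilde_s = occupied.sum(axis=1)
    s_tilde = int(np.sum(occupied.any(axis=0)))
    return (float(np.sum(s_tilde_s - 1)) - (s_tilde - 1)) / (
        2.0 * n_trials * np.log(2.0))


@dataclass
class MultiCellInfo:
    """Bias-corrected mutual information per ensemble size."""

    ensemble_sizes: np.ndarray
    info: np.ndarray                   # bits, clipped to [0, log2 N_S]
    pool: np.ndarray                   # cell indices decoding was drawn from
    confusion: np.ndarray              # averaged table at the largest size


def multi_cell_info(
    table: ResponseTable,
    cfg: DecodingConfig = DecodingConfig(),
    seed: int | np.random.Generator = 0,
    sci: SingleCellInfo | None = None,
) -> MultiCellInfo:
    """Multiple-cell information across ensemble sizes c = 1..C_max.

    The decoding pool is the union of the ``cells_per_stimulus`` best
    cells per stimulus by single-cell information (duplicates removed).
    For each c the mutual information of the jack-knifed confusion table
    is averaged over ``n_iterations(c)`` random c-subsets, bias-corrected
    and clipped to [0, log2 N_S].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sci is None:
        sci = single_cell_info(table)
    C, N_S, N_T = table.rates.shape
    top: list[int] = []
    for s in range(N_S):
        order = np.argsort(sci.info[:, s])[::-1]
        top.extend(order[: cfg.cells_per_stimulus].tolist())
    pool = np.unique(np.asarray(top, dtype=int))

    c_max = min(cfg.c_max(N_S), pool.size)
    sizes = np.arange(1, c_max + 1)
    info = np.zeros(sizes.size)
    n_trials = N_S * N_T
    last_conf = np.zeros((N_S, N_S))
    for k, c in enumerate(sizes):
        n_iter = cfg.n_iterations(int(c), N_S)
        vals = np.zeros(n_iter)
        conf_acc = np.zeros((N_S, N_S))
        for it in range(n_iter):
            ens = rng.choice(pool, size=int(c), replace=False)
            conf = decode_ensemble(table, ens, cfg)
            conf_acc += conf
            vals[it] = _mutual_information(conf) - _bias_correction(conf, n_trials)
        info[k] = np.clip(vals.mean(), 0.0, np.log2(N_S))
        last_conf = conf_acc / n_iter
    return MultiCellInfo(ensemble_sizes=sizes, info=info, pool=pool,
                         confusion=last_conf)


def info_score(
    sci: SingleCellInfo,
    kappa: float = 0.95,
    n_output_cells: int | None = None,
) -> float:
    """Information score iota_kappa.

    Per stimulus, count cells whose single-cell information reaches
    ``kappa * log2(N_S)``; return the minimum count over stimuli as a
    fraction of the output layer size.
    """
    if not 0.0 < kappa <= 1.0:
        raise ValueError("kappa must lie in (0, 1]")
    C, N_S = sci.info.shape
    if n_output_cells is None:
        n_output_cells = C
    threshold = kappa * np.log2(N_S)
    counts = (sci.info >= threshold).sum(axis=0)
    return float(counts.min() / n_output_cells)
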