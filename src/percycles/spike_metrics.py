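"""Spike-train analyses: binning, synchrony correlations, correlograms.

The central quantity is the per-group population spike-count series in
10 ms bins.  Bins where the two compared series hold fewer than ten
spikes in total are excluded, so that quiescent stretches of the network
do not dominate the rank correlation (a bin where one group volleys
while the other is silent is informative and is kept).

* between-stimuli synchrony: Spearman rank correlation of the two
  groups' series over jointly valid bins (negative = anti-phase);
* within-stimulus synchrony: each group is split into two random halves
  and the halves' series correlated, averaged over groups;
* correlograms: normalised auto-/cross-correlation of the mean-subtracted
  series with +-z(0.975)/sqrt(N) bounds under the no-correlation null;
* dominant period: mean spacing of successive significant correlogram
  peaks, read off as an oscillation period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .engine import SegmentRecord

__all__ = [
    "BinnedSeries",
    "SyncResult",
    "CorrelogramResult",
    "bin_spikes",
    "sync_measure",
    "correlogram",
    "dominant_period",
    "alternation_frequency",
    "psth",
]

#: The two compared series must hold at least this many spikes in total
#: for a bin to enter a correlation.
MIN_SPIKES_PER_BIN = 10


@dataclass
class BinnedSeries:
    """Per-neuron spike counts in fixed-width bins, plus group structure.

    ``counts`` is (n_neurons x n_bins) over the union of the group
    members; ``groups`` indexes rows of ``counts``.  Group-level series
    and their validity flags (>= 10 spikes) are derived on demand.
    """

    bin_ms: float
    counts: np.ndarray
    neuron_ids: np.ndarray
    groups: list[np.ndarray]          # row indices into counts, per group

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def group_series(self, g: int | np.ndarray) -> np.ndarray:
        rows = self.groups[g] if isinstance(g, int) else np.asarray(g)
        return self.counts[rows].sum(axis=0)

    @staticmethod
    def valid_pair(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Bins where the compared pair of series is not quiescent."""
        return (a + b) >= MIN_SPIKES_PER_BIN


@dataclass
class SyncResult:
    """Within/between-stimulus Spearman synchrony measures."""

    within: float
    between: float
    n_valid_bins: int
    defined: bool = True
    per_group_within: tuple[float, ...] = ()


def bin_spikes(
    record: SegmentRecord,
    groups: list | tuple,
    pop: str = "exc0",
    bin_ms: float = 10.0,
) -> BinnedSeries:
    """Bin one population's spikes per neuron.

    ``groups`` is a sequence of neuron-id collections (e.g. the feature
    sets of the two test stimuli); they must not overlap.  A 1000 ms
    segment at the default width yields 100 bins.
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    gsets = [np.asarray(sorted(set(int(i) for i in g)), dtype=int) for g in groups]
    flat = np.concatenate(gsets) if gsets else np.array([], dtype=int)
    if len(set(flat.tolist())) != flat.size:
        raise ValueError("groups must be disjoint")
    n_bins = int(np.ceil(record.duration / bin_ms - 1e-9))
    ids, times = record.spikes[pop]
    row_of = {int(n): r for r, n in enumerate(flat)}
    counts = np.zeros((flat.size, n_bins))
    keep = np.isin(ids, flat)
    if np.any(keep):
        rows = np.array([row_of[int(i)] for i in ids[keep]])
        bins = np.minimum((times[keep] / bin_ms).astype(int), n_bins - 1)
        np.add.at(counts, (rows, bins), 1.0)
    offsets = np.cumsum([0] + [g.size for g in gsets])
    group_rows = [np.arange(offsets[k], offsets[k + 1]) for k in range(len(gsets))]
    return BinnedSeries(bin_ms=bin_ms, counts=counts, neuron_ids=flat,
                        groups=group_rows)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def sync_measure(
    series: BinnedSeries,
    seed: int | np.random.Generator = 0,
    n_splits: int = 1,
) -> SyncResult:
    """Within- and between-group Spearman synchrony.

    Between: the two group series correlated over bins holding at least
    ten spikes pooled across the pair (quiescent-network bins are
    excluded; a bin where one group volleys alone is kept -- it is the
    very evidence of anti-phase firing).  Within: each group's members
    are split into two random halves (drawn from ``seed``); the halves'
    series are correlated over their own valid bins and the values
    averaged across groups (and across ``n_splits`` independent
    re-splits).  Returns ``defined=False`` when fewer than three valid
    bins remain.
    """
    if len(series.groups) < 2:
        raise ValueError("need at least two groups")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    s0 = series.group_series(0)
    s1 = series.group_series(1)
    joint = series.valid_pair(s0, s1)
    between = _spearman(s0[joint], s1[joint]) if joint.sum() >= 3 else np.nan

    per_group: list[float] = []
    for rows in series.groups:
        vals = []
        for _ in range(n_splits):
            perm = rng.permutation(rows)
            half = perm.size // 2
            a = series.counts[perm[:half]].sum(axis=0)
            b = series.counts[perm[half:]].sum(axis=0)
            ok = series.valid_pair(a, b)
            if ok.sum() >= 3:
                vals.append(_spearman(a[ok], b[ok]))
        vals = [v for v in vals if np.isfinite(v)]
        per_group.append(float(np.mean(vals)) if vals else np.nan)
    finite = [v for v in per_group if np.isfinite(v)]
    within = float(np.mean(finite)) if finite else np.nan

    defined = np.isfinite(between) and np.isfinite(within)
    return SyncResult(within=within, between=between,
                      n_valid_bins=int(joint.sum()), defined=bool(defined),
                      per_group_within=tuple(per_group))


@dataclass
class CorrelogramResult:
    """Lagged correlation values with 95 % no-correlation bounds."""

    lags_ms: np.ndarray
    values: np.ndarray
    bound: float                      # +-bound around zero
    bin_ms: float
    kind: str                         # "auto" | "cross"
    defined: bool = True

    @property
    def significant_peak_lags(self) -> np.ndarray:
        """Lags (ms) of local maxima exceeding the upper bound (lag != 0
        for autocorrelograms, whose zero-lag value is 1 by construction)."""
        if not self.defined:
            return np.array([])
        idx, _ = signal.find_peaks(self.values, height=self.bound)
        lags = self.lags_ms[idx]
        if self.kind == "auto":
            lags = lags[lags != 0]
        return lags


def correlogram(
    x: np.ndarray,
    y: np.ndarray | None = None,
    max_lag_bins: int | None = None,
    bin_ms: float = 10.0,
    confidence: float = 0.95,
) -> CorrelogramResult:
    """Normalised auto- (y None) or cross-correlation of binned series.

    Standard sample (cross-)correlation of the mean-subtracted series,
    normalised by N*sx*sy, evaluated at lags -L..L bins.  The bounds are
    the usual +-z_{(1+conf)/2}/sqrt(N) white-noise band.  A constant
    series has no defined correlogram (flagged, not raised).
    """
    x = np.asarray(x, dtype=float)
    kind = "auto" if y is None else "cross"
    y = x if y is None else np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    n = x.size
    if max_lag_bins is None:
        max_lag_bins = n // 2
    if n < 2 * max_lag_bins:
        raise ValueError("series shorter than twice the maximum lag")
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    bound = z / np.sqrt(n)
    xd = x - x.mean()
    yd = y - y.mean()
    sx, sy = xd.std(), yd.std()
    if sx == 0 or sy == 0:
        return CorrelogramResult(lags_ms=lags * bin_ms,
                                 values=np.full(lags.size, np.nan),
                                 bound=bound, bin_ms=bin_ms, kind=kind,
                                 defined=False)
    full = signal.correlate(yd, xd, mode="full") / (n * sx * sy)
    centre = n - 1
    values = full[centre - max_lag_bins: centre + max_lag_bins + 1]
    return CorrelogramResult(lags_ms=lags * bin_ms, values=values,
                             bound=bound, bin_ms=bin_ms, kind=kind)


@dataclass
class PeriodResult:
    period_ms: float
    frequency_hz: float
    peak_lags_ms: np.ndarray
    defined: bool = True


def dominant_period(corr: CorrelogramResult) -> PeriodResult:
    """Oscillation period from the spacing of significant correlogram peaks.

    The period is the mean spacing between successive significant peaks
    (positive lags; the autocorrelogram is symmetric).  With a single
    significant peak its lag is used directly.  Undefined (flagged) when
    no significant peak exists.
    """
    peaks = corr.significant_peak_lags
    pos = peaks[peaks > 0]
    if pos.size == 0:
        return PeriodResult(np.nan, np.nan, peaks, defined=False)
    if pos.size == 1:
        period = float(pos[0])
    else:
        period = float(np.mean(np.diff(pos)))
    return PeriodResult(period_ms=period, frequency_hz=1000.0 / period,
                        peak_lags_ms=peaks)


def alternation_frequency(cross: CorrelogramResult) -> PeriodResult:
    """Frequency at which two anti-phase groups take turns firing.

    When two groups alternate, each group's own period T shows up in the
    cross-correlogram as significant peaks at +-T/2, +-3T/2, ...; the
    groups trade volleys every T/2 ms.  The alternation period is
    therefore the mean magnitude of the first significant cross-
    correlation peak on either side of zero lag, and the alternation
    frequency its reciprocal.
    """
    peaks = cross.significant_peak_lags
    if peaks.size == 0:
        return PeriodResult(np.nan, np.nan, peaks, defined=False)
    first = []
    pos = peaks[peaks > 0]
    neg = -peaks[peaks < 0]
    if pos.size:
        first.append(pos.min())
    if neg.size:
        first.append(neg.min())
    if not first:  # only a zero-lag peak: in-phase, no alternation
        return PeriodResult(np.nan, np.nan, peaks, defined=False)
    period = float(np.mean(first))
    return PeriodResult(period_ms=period, frequency_hz=1000.0 / period,
                        peak_lags_ms=peaks)


def psth(series: BinnedSeries, g: int) -> np.ndarray:
    """Per-bin mean spike rate (Hz per neuron) of one group."""
    rows = series.groups[g]
    return series.group_series(g) / (rows.size * series.bin_ms / 1000.0)
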