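"""Tests for the firing-rate information measures and Bayesian decoding."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from percycles.engine import SegmentRecord
from percycles.info_metrics import (
    DecodingConfig,
    ResponseTable,
    decode_ensemble,
    info_score,
    multi_cell_info,
    rates_from_record,
    single_cell_info,
)


def brute_force_single_cell_info(rates: np.ndarray, n_bins: int) -> np.ndarray:
    """Independent re-derivation of the stimulus-specific information.

    Enumerates the full probability tables from first principles:
    quantise one cell's (N_S x N_T) rates into equal-width bins, then
    I(s) = sum_r P(r|s) log2 P(r|s)/P(r) with equiprobable stimuli.
    """
    N_S, N_T = rates.shape
    lo, hi = rates.min(), rates.max()
    if hi <= lo:
        return np.zeros(N_S)
    edges = np.linspace(lo, hi, n_bins + 1)
    q = np.clip(np.digitize(rates, edges[1:-1]), 0, n_bins - 1)
    out = np.zeros(N_S)
    for s in range(N_S):
        acc = 0.0
        for r in range(n_bins):
            p_r_s = np.mean(q[s] == r)
            p_r = np.mean(q == r)
            if p_r_s > 0:
                acc += p_r_s * np.log2(p_r_s / p_r)
        out[s] = acc
    return out


class TestResponseTable:
    def test_rates_from_records(self):
        recs = {}
        for s, t in itertools.product(range(2), range(1, 4)):
            ids = [0] * (10 * s + t)      # cell 0 spikes a known count
            recs[(s, t)] = SegmentRecord(
                label={}, duration=1000.0,
                spikes={"exc1": (np.asarray(ids, int),
                                 np.linspace(1, 999, len(ids)))},
                n_neurons={"exc1": 4})
        table = rates_from_record(recs)
        assert table.rates.shape == (4, 2, 3)
        assert table.rates[0, 1, 2] == pytest.approx(13.0)   # 13 spikes / s
        assert table.rates[1].sum() == 0.0

    def test_incomplete_grid_rejected(self):
        rec = SegmentRecord(label={}, duration=1000.0,
                            spikes={"exc1": (np.array([], int), np.array([]))},
                            n_neurons={"exc1": 2})
        with pytest.raises(ValueError):
            rates_from_record({(0, 1): rec, (1, 2): rec})

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            ResponseTable(rates=-np.ones((2, 2, 2)))


class TestSingleCellInfo:
    def test_flat_cell_carries_no_information(self):
        table = ResponseTable(rates=np.full((3, 2, 5), 7.0))
        sci = single_cell_info(table)
        np.testing.assert_array_equal(sci.info, 0.0)

    def test_perfect_discriminator_reaches_log2_ns(self):
        rates = np.zeros((1, 2, 5))
        rates[0, 0, :] = 50.0
        sci = single_cell_info(ResponseTable(rates=rates))
        assert sci.info[0, 0] == pytest.approx(1.0)
        assert sci.info[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_on_handmade_table(self):
        # rates {s1: 10, 10; s2: 10, 0} with 2 bins: knowing r=0 identifies
        # s2's off-transform
        rates = np.array([[[10.0, 10.0], [10.0, 0.0]]])
        sci = single_cell_info(ResponseTable(rates=rates), n_bins=2)
        expect = brute_force_single_cell_info(rates[0], 2)
        np.testing.assert_allclose(sci.info[0], expect, atol=1e-12)
        # hand arithmetic: P(r=1|s2)=1/2 pairs with P(r=1)=1/4
        assert sci.info[0, 1] == pytest.approx(0.5 * np.log2(2) + 0.5 * np.log2(2 / 3))

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(20):
            rates = rng.integers(0, 6, size=(4, 3, 4)).astype(float) * 10.0
            table = ResponseTable(rates=rates)
            sci = single_cell_info(table, n_bins=5)
            for c in range(4):
                np.testing.assert_allclose(
                    sci.info[c], brute_force_single_cell_info(rates[c], 5),
                    atol=1e-12)
            assert np.all(sci.info <= np.log2(3) + 1e-12)
            assert np.all(sci.info >= -1e-12)

    def test_bin_count_guard(self):
        with pytest.raises(ValueError):
            single_cell_info(ResponseTable(rates=np.ones((1, 2, 2))), n_bins=1)


class TestDecodeEnsemble:
    def test_separable_rates_give_diagonal_confusion(self):
        rates = np.zeros((3, 2, 5))
        rates[:, 0, :] = 50.0 + np.arange(5)
        rates[:, 1, :] = np.arange(5)
        conf = decode_ensemble(ResponseTable(rates=rates), [0, 1, 2])
        assert conf[0, 0] == pytest.approx(0.5, abs=1e-6)
        assert conf[1, 1] == pytest.approx(0.5, abs=1e-6)

    def test_identical_distributions_give_uniform_confusion(self):
        rng = np.random.default_rng(0)
        base = rng.normal(20.0, 5.0, size=(2, 1, 8))
        rates = np.repeat(base, 2, axis=1)        # both stimuli identical
        conf = decode_ensemble(ResponseTable(rates=np.abs(rates)), [0, 1])
        np.testing.assert_allclose(conf, 0.25, atol=0.1)

    def test_posterior_matches_direct_bayes_arithmetic(self):
        """3-cell toy: the decoder's posterior equals Bayes' rule applied
        to the jack-knifed Gaussian fits computed by hand."""
        rates = np.array([
            [[10.0, 12.0, 14.0], [30.0, 31.0, 29.0]],
            [[5.0, 6.0, 4.0], [5.0, 5.5, 4.5]],
            [[40.0, 42.0, 44.0], [20.0, 22.0, 18.0]],
        ])
        table = ResponseTable(rates=rates)
        cfg = DecodingConfig(std_floor=0.1)
        conf = decode_ensemble(table, [0, 1, 2], cfg)

        # hand computation for held-out (s=0, t=0), accumulated below
        expected = np.zeros((2, 2))
        for t in range(3):
            rest = [u for u in range(3) if u != t]
            for s in range(2):
                logp = np.zeros(2)
                for sp in range(2):
                    for c in range(3):
                        obs = rates[c, s, t]
                        if sp == s:
                            mu = rates[c, sp, rest].mean()
                            sd = max(rates[c, sp, rest].std(), 0.1)
                        else:
                            mu = rates[c, sp, :].mean()
                            sd = max(rates[c, sp, :].std(), 0.1)
                        logp[sp] += stats.norm.logpdf(obs, mu, sd)
                    logp[sp] += np.log(0.5)
                post = np.exp(logp - logp.max())
                expected[s] += post / post.sum()
        expected /= expected.sum()
        np.testing.assert_allclose(conf, expected, atol=1e-10)

    def test_zero_variance_is_floored_not_fatal(self):
        rates = np.zeros((1, 2, 3))
        rates[0, 0, :] = 10.0                      # exactly constant
        conf = decode_ensemble(ResponseTable(rates=rates), [0])
        assert np.isfinite(conf).all()

    def test_preconditions(self):
        table = ResponseTable(rates=np.ones((2, 2, 1)))
        with pytest.raises(ValueError):
            decode_ensemble(table, [0])            # one transform: no jack-knife
        with pytest.raises(ValueError):
            decode_ensemble(ResponseTable(rates=np.ones((2, 2, 3))), [])


class TestMultiCellInfo:
    def test_iteration_schedule(self):
        cfg = DecodingConfig()
        assert cfg.c_max(2) == 10
        assert cfg.n_iterations(1, 2) == 1000     # decreasing linearly ...
        assert cfg.n_iterations(10, 2) == 100     # ... from 1000 to 100

    def test_well_separated_table_reaches_maximum_at_two_cells(self):
        """Cells split between two stimuli: 1 bit once both are covered."""
        rng = np.random.default_rng(5)
        rates = np.zeros((10, 2, 5))
        for c in range(10):
            pref = c % 2
            rates[c, pref, :] = 40.0 + rng.normal(0, 1.0, 5)
            rates[c, 1 - pref, :] = np.abs(rng.normal(0, 0.5, 5))
        mci = multi_cell_info(ResponseTable(rates=rates), seed=3)
        assert mci.info[1] == pytest.approx(1.0, abs=0.05)   # c = 2
        assert mci.info[-1] == pytest.approx(1.0, abs=0.05)

    def test_random_table_carries_no_information(self):
        rng = np.random.default_rng(8)
        rates = np.abs(rng.normal(20.0, 5.0, size=(12, 2, 5)))
        mci = multi_cell_info(ResponseTable(rates=rates), seed=4)
        assert np.all(mci.info < 0.25)

    def test_parameter_recovery_from_gaussian_table(self):
        """Synthetic well-separated Gaussian responses recover log2 N_S
        within 0.05 bits."""
        rng = np.random.default_rng(12)
        n_s = 2
        rates = np.zeros((8, n_s, 6))
        for c in range(8):
            pref = c % n_s
            for s in range(n_s):
                mu = 35.0 if s == pref else 5.0
                rates[c, s, :] = np.abs(rng.normal(mu, 1.5, 6))
        mci = multi_cell_info(ResponseTable(rates=rates), seed=1)
        assert mci.info[-1] == pytest.approx(np.log2(n_s), abs=0.05)


class TestInfoScore:
    def test_arithmetic(self):
        info = np.zeros((64, 2))
        info[:8, 0] = 1.0          # 8 cells reach the maximum for stimulus 0
        info[:20, 1] = 1.0
        sci = single_cell_info(ResponseTable(rates=np.ones((1, 2, 2))))
        sci.info = info
        assert info_score(sci) == pytest.approx(8 / 64)

    def test_threshold_is_kappa_times_log2_ns(self):
        info = np.zeros((4, 2))
        info[0] = [0.94, 0.96]
        sci = single_cell_info(ResponseTable(rates=np.ones((1, 2, 2))))
        sci.info = info
        assert info_score(sci, kappa=0.95) == 0.0   # 0.94 < 0.95 bits
        info[0] = [0.96, 0.96]
        sci.info = info
        assert info_score(sci, kappa=0.95) == pytest.approx(1 / 4)

    def test_kappa_guard(self):
        sci = single_cell_info(ResponseTable(rates=np.ones((1, 2, 2))))
        with pytest.raises(ValueError):
            info_score(sci, kappa=0.0)
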