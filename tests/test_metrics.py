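"""Phase segmentation, peaks and the Welch/Holm comparison machinery."""

import numpy as np
import pytest
from scipy import stats as sps

from coughsim.metrics import (
    compare_conditions,
    holm_adjust,
    segment_phases,
    summarize_condition,
    welch_t,
)


def square_wave(period_s, duty, n_cycles, bin_s=0.06, amplitude=100.0):
    per = int(round(period_s / bin_s))
    on = int(round(period_s * duty / bin_s))
    cycle = np.concatenate([np.full(on, amplitude), np.zeros(per - on)])
    return np.tile(cycle, n_cycles)


class TestSegmentation:
    def test_square_wave_recovery(self):
        trace = square_wave(4.0, 0.4, 8)
        seg = segment_phases(trace)
        assert seg.ti.mean() == pytest.approx(1.6, abs=0.06)
        assert seg.te.mean() == pytest.approx(2.4, abs=0.06)
        assert seg.frequency == pytest.approx(15.0, rel=0.02)

    def test_scaling_invariance(self):
        a = segment_phases(square_wave(4.0, 0.4, 8, amplitude=100.0))
        b = segment_phases(square_wave(4.0, 0.4, 8, amplitude=0.37))
        assert np.array_equal(a.onsets, b.onsets)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            segment_phases(np.zeros(500))

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            segment_phases(np.full(500, 3.0))

    def test_jittered_bursts_within_one_bin(self):
        rng = np.random.default_rng(5)
        bin_s = 0.06
        ti_true, te_true = 1.8, 2.6
        bins = []
        for _ in range(10):
            on = int(round(ti_true / bin_s))
            off = int(round(te_true / bin_s))
            burst = np.clip(80 + 20 * rng.standard_normal(on), 0, None)
            quiet = np.clip(2 + 1.5 * rng.standard_normal(off), 0, None)
            bins.extend(burst)
            bins.extend(quiet)
        seg = segment_phases(np.array(bins))
        assert abs(seg.ti.mean() - ti_true) <= 2 * bin_s
        assert abs(seg.te.mean() - te_true) <= 2 * bin_s


class TestWelchHolm:
    def test_welch_matches_hand_coded_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 9))
            b = rng.normal(loc=rng.normal(), size=rng.integers(3, 9))
            t, df, p = welch_t(a, b)
            # hand-coded Welch formulae
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df_ref = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
            p_ref = 2 * sps.t.sf(abs(t_ref), df_ref)
            assert t == pytest.approx(t_ref, abs=1e-12)
            assert df == pytest.approx(df_ref, abs=1e-9)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_degenerate_equal_groups(self):
        t, df, p = welch_t(np.zeros(4), np.zeros(4))
        assert p == 1.0

    def test_holm_two_values(self):
        adj = holm_adjust(np.array([0.01, 0.04]))
        assert adj == pytest.approx([0.02, 0.04])

    def test_holm_monotone_and_capped(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=12)
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_identical_groups_not_significant(self):
        groups = {"a": {"m": np.array([1.0, 1.0, 1.0, 1.0])},
                  "b": {"m": np.array([1.0, 1.0, 1.0, 1.0])}}
        table = compare_conditions(groups)
        assert table.iloc[0]["p_holm"] == 1.0
        assert not table.iloc[0]["significant"]

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(3)
        groups = {"a": {"m": rng.normal(0, 1e-3, 4)},
                  "b": {"m": 1 + rng.normal(0, 1e-3, 4)}}
        table = compare_conditions(groups)
        assert table.iloc[0]["significant"]

    def test_adjustment_within_metric_family(self):
        rng = np.random.default_rng(4)
        groups = {
            "a": {"m1": rng.normal(0, 1, 4), "m2": rng.normal(0, 1, 4)},
            "b": {"m1": rng.normal(0, 1, 4), "m2": rng.normal(0, 1, 4)},
            "c": {"m1": rng.normal(0, 1, 4), "m2": rng.normal(0, 1, 4)},
        }
        table = compare_conditions(groups)
        # three pairs per metric, two metrics
        assert len(table) == 6
        for _, grp in table.groupby("metric"):
            assert np.all(grp["p_holm"] >= grp["p_raw"])

    def test_requires_two_trials(self):
        groups = {"a": {"m": np.array([1.0])}, "b": {"m": np.array([2.0, 3.0])}}
        with pytest.raises(ValueError):
            compare_conditions(groups)


class TestSummary:
    def test_confidence_limits_use_t_quantile(self):
        v = np.array([10.0, 12.0, 11.0, 13.0])
        out = summarize_condition({"x": v}).iloc[0]
        half = sps.t.ppf(0.975, 3) * v.std(ddof=1) / 2.0
        assert out["mean"] == pytest.approx(11.5)
        assert out["ci_hi"] - out["mean"] == pytest.approx(half)
        assert out["cv"] == pytest.approx(v.std(ddof=1) / 11.5)

    def test_constant_trace_peak(self):
        out = summarize_condition({"x": np.full(4, 7.0)}).iloc[0]
        assert out["mean"] == 7.0
        assert out["ci_lo"] == out["ci_hi"] == 7.0
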