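"""Channel-wise activation inference and condition comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from nirsblock.stats import StatsConfig, activation_test, bh_fdr, condition_comparison, group_summary


def brute_force_bh(p, q):
    """Independent step-up oracle: find the largest k with p_(k) <= k q / m."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    reject = np.zeros(m, bool)
    reject[order[:k_max]] = True
    return reject


def _summary(values_by_channel, condition="ME", phase="early"):
    rows = []
    for cid, vals in values_by_channel.items():
        for s, v in enumerate(vals):
            rows.append(
                {"subject": f"s{s}", "condition": condition, "channel_id": cid, "phase": phase, "value": v}
            )
    return pd.DataFrame(rows)


class TestBhFdr:
    def test_single_small_p_rejected(self):
        adj, rej = bh_fdr(np.array([0.04]), q=0.05)
        assert rej[0] and adj[0] == pytest.approx(0.04)

    def test_arithmetic_ladder_no_rejections(self):
        # p_(i) = 0.01 i vs threshold 0.05 i / 16: every p exceeds it,
        # adjusted p = 0.16 across the board
        p = np.arange(1, 17) * 0.01
        adj, rej = bh_fdr(p, q=0.05)
        assert not rej.any()
        np.testing.assert_allclose(adj, 0.16)

    def test_uniform_tiny_p_all_rejected(self):
        adj, rej = bh_fdr(np.full(16, 0.001), q=0.05)
        assert rej.all()

    def test_adjusted_ge_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 50)
        adj, _ = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))
        with pytest.raises(ValueError):
            bh_fdr(np.array([-0.1]))

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            m = rng.integers(1, 20)
            p = np.round(rng.uniform(0, 1, m), 3)
            _, rej = bh_fdr(p, q=0.05)
            np.testing.assert_array_equal(rej, brute_force_bh(p, 0.05))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(2, 30))
            adj, rej = bh_fdr(p, q=0.05)
            sm_rej, sm_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(adj, sm_adj, rtol=1e-12)
            np.testing.assert_array_equal(rej, sm_rej)


class TestActivationTest:
    def test_symmetric_values_give_half_p(self):
        df = _summary({1: [-2.0, -1.0, 1.0, 2.0]})
        out = activation_test(df, "ME", "early")
        assert out.loc[0, "t"] == pytest.approx(0.0)
        assert out.loc[0, "p_raw"] == pytest.approx(0.5)

    def test_uniform_strong_positive_all_significant(self):
        vals = [1.0, 1.1, 0.9, 1.05, 0.95, 1.02]
        df = _summary({cid: vals for cid in range(1, 17)})
        out = activation_test(df, "ME", "early")
        assert out["significant"].all()

    def test_closed_form_t_and_p(self):
        vals = np.array([0.3, 0.1, 0.4, 0.2, 0.5])
        df = _summary({1: vals})
        out = activation_test(df, "ME", "early")
        n = len(vals)
        t_exp = vals.mean() / (vals.std(ddof=1) / np.sqrt(n))
        p_exp = sp_stats.t.sf(t_exp, df=n - 1)
        assert out.loc[0, "t"] == pytest.approx(t_exp)
        assert out.loc[0, "p_raw"] == pytest.approx(p_exp)
        assert out.loc[0, "n"] == n

    def test_missing_cells_dropped_with_n_recorded(self):
        df = _summary({1: [0.1, np.nan, 0.3, 0.2]})
        out = activation_test(df, "ME", "early")
        assert out.loc[0, "n"] == 3

    def test_zero_variance_error_flag_not_infinite_t(self):
        df = _summary({1: [0.2, 0.2, 0.2], 2: [0.3, 0.1, 0.5]})
        out = activation_test(df, "ME", "early")
        row = out[out.channel_id == 1].iloc[0]
        assert row["note"] == "zero-variance"
        assert np.isnan(row["t"]) and not row["significant"]
        assert out[out.channel_id == 2]["p_raw"].notna().all()

    def test_all_missing_channel_flagged(self):
        df = _summary({1: [np.nan, np.nan], 2: [0.3, 0.1, 0.5]})
        out = activation_test(df, "ME", "early")
        assert out[out.channel_id == 1].iloc[0]["note"] == "all-missing"


class TestConditionComparison:
    def _four_condition_summary(self, shift=None, n_sub=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        base = rng.normal(0.2, 0.05, n_sub)
        for cond in ("ME", "MI", "AO", "MVF"):
            for ch in (1, 2):
                for s in range(n_sub):
                    v = base[s] + rng.normal(0, 0.01)
                    if shift and cond == shift[0] and ch == shift[1]:
                        v += shift[2]
                    rows.append(
                        {"subject": f"s{s}", "condition": cond, "channel_id": ch, "phase": "early", "value": v}
                    )
        return pd.DataFrame(rows)

    def test_identical_conditions_f_zero_no_pairs(self):
        rng = np.random.default_rng(1)
        rows = []
        vals = rng.normal(0.2, 0.1, 5)
        for cond in ("ME", "MI", "AO", "MVF"):
            for s in range(5):
                rows.append(
                    {"subject": f"s{s}", "condition": cond, "channel_id": 1, "phase": "early", "value": vals[s]}
                )
        omni, pairs = condition_comparison(pd.DataFrame(rows), "early")
        assert omni.loc[0, "F"] == pytest.approx(0.0, abs=1e-10)
        assert not pairs["significant"].any()

    def test_shifted_condition_drives_its_three_pairs(self):
        df = self._four_condition_summary(shift=("MVF", 1, 5.0))
        omni, pairs = condition_comparison(df, "early")
        ch1 = pairs[pairs.channel_id == 1]
        involving = ch1[(ch1.condition_a == "MVF") | (ch1.condition_b == "MVF")]
        others = ch1[(ch1.condition_a != "MVF") & (ch1.condition_b != "MVF")]
        assert involving["significant"].all()
        assert not others["significant"].any()

    def test_paired_t_matches_closed_form(self):
        df = self._four_condition_summary(shift=("ME", 1, 0.1), seed=3)
        _, pairs = condition_comparison(df, "early")
        row = pairs[(pairs.channel_id == 1) & (pairs.condition_a == "AO") & (pairs.condition_b == "ME")].iloc[0]
        wide = df[(df.channel_id == 1)].pivot(index="subject", columns="condition", values="value")
        d = wide["AO"] - wide["ME"]
        t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert row["t"] == pytest.approx(t_exp)
        assert row["p_adj"] == pytest.approx(min(row["p_raw"] * 6, 1.0))

    def test_pair_count_is_six_per_channel(self):
        df = self._four_condition_summary()
        _, pairs = condition_comparison(df, "early")
        assert (pairs.groupby("channel_id").size() == 6).all()

    def test_too_few_complete_subjects_missing_row(self):
        df = self._four_condition_summary(n_sub=2)
        omni, pairs = condition_comparison(df, "early")
        assert omni["note"].eq("n<3").all()
        assert pairs.empty


class TestGroupSummary:
    def test_hand_computed_mean_and_sample_sd(self):
        df = _summary({1: [0.1, 0.2, 0.3]})
        out = group_summary(df)
        assert out.loc[0, "ME_mean"] == pytest.approx(0.2)
        assert out.loc[0, "ME_sd"] == pytest.approx(0.1)

    def test_single_subject_sd_is_missing(self):
        df = _summary({1: [0.4]})
        out = group_summary(df)
        assert np.isnan(out.loc[0, "ME_sd"])

    def test_full_table_shape(self):
        rng = np.random.default_rng(4)
        rows = []
        for cond in ("ME", "MI", "AO", "MVF"):
            for cid in range(1, 17):
                for s in range(3):
                    rows.append(
                        {"subject": f"s{s}", "condition": cond, "channel_id": cid,
                         "phase": "early", "value": rng.normal()}
                    )
        out = group_summary(pd.DataFrame(rows))
        assert len(out) == 16
        assert {f"{c}_mean" for c in ("ME", "MI", "AO", "MVF")} <= set(out.columns)
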