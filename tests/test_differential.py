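"""Welch tests, BH adjustment, effect sizes and significance policy."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sputodeconv import simulate
from sputodeconv.datatypes import MixedOmicsMatrix, SchemaError
from sputodeconv.deconvolution import BoxBounds, build_design, deconvolve_group
from sputodeconv.differential import (
    PAPER_POLICY,
    bh_adjust,
    call_significant,
    differential_deconvolved,
    differential_mixed,
    effects_from_estimates,
    welch_from_estimates,
    welch_from_samples,
)


def bh_oracle(p):
    """Independent hand-coded step-up: adj_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestWelchFromSamples:
    def test_identical_groups_null(self):
        t, df, p = welch_from_samples([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_closed_form_example(self):
        # mean difference 0.2 with equal variance components 0.0025 each
        # (per-group df 6): t = 0.2/sqrt(0.005), Welch-Satterthwaite df = 12
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        x = x - x.mean()
        s2_target = 0.0025 * 7                 # var/n = 0.0025 with n=7
        x = x * np.sqrt(s2_target / x.var(ddof=1))
        y = x.copy() - 0.2
        t, df, p = welch_from_samples(x + 0.0, y)
        assert t == pytest.approx(2.8284271, abs=1e-6)
        assert df == pytest.approx(12.0, abs=1e-9)
        assert p == pytest.approx(0.0152201, abs=1e-6)

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(50):
            x = rng.normal(0, 1, rng.integers(3, 12))
            y = rng.normal(0.5, 2, rng.integers(3, 12))
            t, df, p = welch_from_samples(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_df_bounded_by_group_dfs(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(3, 10, 2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            _, df, _ = welch_from_samples(x, y)
            assert min(n1 - 1, n2 - 1) - 1e-9 <= df <= n1 + n2 - 2 + 1e-9

    def test_zero_variance_degenerate_cases(self):
        t, df, p = welch_from_samples([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        t, df, p = welch_from_samples([3.0, 3.0], [2.0, 2.0])
        assert p > 0.0 and p < 1e-300


class TestWelchFromEstimates:
    def test_equal_estimates_null(self):
        t, df, p = welch_from_estimates(0.5, 0.1, 6, 0.5, 0.1, 6)
        assert t == 0.0 and p == 1.0

    def test_closed_form_example(self):
        t, df, p = welch_from_estimates(0.8, 0.05, 6, 0.6, 0.05, 6)
        assert t == pytest.approx(2.8284271, abs=1e-6)
        assert df == pytest.approx(12.0, abs=1e-9)
        assert p == pytest.approx(0.0152201, abs=1e-6)

    def test_one_sided_se_reduces_to_one_sample_t(self):
        # se2 = 0: testing b1 against the exact value b2
        t, df, p = welch_from_estimates(0.8, 0.05, 8, 0.6, 0.0, 1000)
        assert t == pytest.approx((0.8 - 0.6) / 0.05)
        assert df == pytest.approx(8.0)
        assert p == pytest.approx(2 * stats.t.sf(4.0, 8))

    def test_df_bounds(self, rng):
        for _ in range(100):
            se1, se2 = rng.uniform(0.01, 1, 2)
            df1, df2 = rng.integers(2, 30, 2)
            _, df, _ = welch_from_estimates(0.0, se1, df1, 1.0, se2, df2)
            assert min(df1, df2) - 1e-9 <= df <= df1 + df2 + 1e-9

    def test_both_ses_zero_degenerate(self):
        assert welch_from_estimates(0.5, 0, 5, 0.5, 0, 5)[2] == 1.0
        assert welch_from_estimates(0.6, 0, 5, 0.5, 0, 5)[2] < 1e-300


class TestBhAdjust:
    def test_hand_derived_example(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_unchanged(self):
        assert np.allclose(bh_adjust(np.ones(5)), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_matches_independent_step_up_oracle(self, rng):
        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.uniform(0, 1, 200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_nan_propagates(self):
        adj = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(adj[1]) and not np.isnan(adj[0])


class TestEffectsAndCalls:
    def test_deconvolved_expression_log_ratio(self):
        e = effects_from_estimates(
            "expression", pd.Series([400.0]), pd.Series([100.0]))
        assert e.iloc[0] == pytest.approx(2.0)

    def test_delta_beta_is_difference(self):
        e = effects_from_estimates(
            "methylation", pd.Series([0.7]), pd.Series([0.55]))
        assert e.iloc[0] == pytest.approx(0.15)

    def test_nonpositive_expression_estimate_asserts(self):
        with pytest.raises(AssertionError):
            effects_from_estimates("expression", pd.Series([0.0]),
                                   pd.Series([1.0]))

    @pytest.mark.parametrize("p_adj,effect,context,modality,expect", [
        (0.04, 1.6, "mixed", "expression", "up"),
        (0.002, 0.09, "deconvolved", "methylation", None),
        (0.004, -1.6, "deconvolved", "expression", "down"),
        (0.01, 1.4, "mixed", "expression", None),
    ])
    def test_policy_rules(self, p_adj, effect, context, modality, expect):
        tab = pd.DataFrame({"effect": [effect], "t": [1.0], "df": [5.0],
                            "p": [p_adj / 2], "p_adj": [p_adj]})
        out = call_significant(tab, context, modality)
        if expect is None:
            assert out.summary["n_significant"] == 0
        elif expect == "up":
            assert out.summary["n_up"] == 1
        else:
            assert out.summary["n_down"] == 1

    def test_unknown_context_rejected(self):
        tab = pd.DataFrame({"effect": [1.0], "t": [1.0], "df": [1.0],
                            "p": [0.5], "p_adj": [0.5]})
        from sputodeconv.differential import ConfigurationError
        with pytest.raises(ConfigurationError):
            call_significant(tab, "single-cell", "expression")


def null_truth(n_meth, seed):
    """Profiles rescaled into [0.1, 0.9] so measurement noise never clips:
    the null simulations probe the testing machinery, not boundary effects."""
    truth = simulate.generate_profiles(config=simulate.ProfileConfig(
        n_features_expr=2, n_features_meth=n_meth, n_markers_per_type=0,
        effects=[]), seed=seed)
    truth.methylation = 0.1 + 0.8 * truth.methylation
    return truth


class TestCalibrationAndPower:
    def test_null_type_i_error_five_percent(self):
        # no spiked effects and composition held fixed across samples:
        # per-feature values are iid Gaussian, so raw p < 0.05 must occur
        # for 5% +/- 1 point of 10,000 features and BH at 0.05 stay silent
        truth = null_truth(10_000, seed=101)
        from sputodeconv.datatypes import CellCountTable
        control = np.array([52.3, 40.3, 0.2, 2.0, 0.2, 1.6, 3.4])
        control = control / control.sum() * 100.0
        counts = CellCountTable(pd.DataFrame(
            np.tile(control, (20, 1)),
            index=[f"s{i}" for i in range(20)],
            columns=["AM", "NG", "EO", "LY", "MO", "CC", "SC"]))
        _, meth, _ = simulate.mix(truth, counts,
                                  {"methylation": 0.02, "expression": 0},
                                  seed=11)
        groups = pd.Series(["g1"] * 10 + ["g2"] * 10, index=counts.samples)
        table = differential_mixed(meth, groups, "g1", "g2")
        frac = (table.data["p"] < 0.05).mean()
        assert 0.04 <= frac <= 0.06
        assert (table.data["p_adj"] < 0.05).sum() <= 5

    def test_null_calibration_estimate_variant(self):
        # Welch on deconvolved estimates: with an exactly specified reduced
        # model (identical minor profiles) and Gaussian noise, the estimate
        # errors are Gaussian with the classical SEs, so raw p is calibrated
        truth = null_truth(10_000, seed=5)
        for ct in ("EO", "LY", "MO", "CC", "SC"):
            truth.methylation.loc[ct] = truth.methylation.loc["EO"]
        from sputodeconv.datatypes import CellCountTable
        rng = np.random.default_rng(3)
        ests = {}
        for g, seed in (("g1", 21), ("g2", 22)):
            n = 10
            am = rng.uniform(0.2, 0.7, n)
            ng = (1 - am) * rng.uniform(0.5, 0.9, n)
            minor = 1 - am - ng
            rows = np.zeros((n, 7))
            rows[:, 0], rows[:, 1], rows[:, 3] = am, ng, minor
            counts = CellCountTable(pd.DataFrame(
                rows * 100, index=[f"{g}_s{i}" for i in range(n)],
                columns=["AM", "NG", "EO", "LY", "MO", "CC", "SC"]))
            _, meth, _ = simulate.mix(truth, counts,
                                      {"methylation": 0.02, "expression": 0},
                                      seed=seed)
            design = build_design(counts, ("AM", "NG"), excluded=())
            ests[g] = deconvolve_group(meth, design, BoxBounds.methylation(),
                                       group=g)
        table = differential_deconvolved(ests["g1"], ests["g2"],
                                         "NG", "methylation")
        frac = (table.data["p"] < 0.05).mean()
        assert 0.04 <= frac <= 0.06

    def test_planted_dmp_recall_at_deconvolved_policy(self):
        # low-noise regime: spiked delta beta 0.2 in an estimable cell
        # type must be recovered with recall > 0.8 at the strict policy
        cfg = simulate.ScenarioConfig(
            n_per_group={"asthma": 10, "control": 10},
            profiles=simulate.ProfileConfig(
                n_features_expr=10, n_features_meth=2000,
                n_markers_per_type=0,
                effects=[simulate.EffectSpec("asthma", "NG", "methylation",
                                             0.2, 50)]),
            noise_sd={"expression": 25.0, "methylation": 0.005},
            apply_degradation=False)
        ds = simulate.simulate_dataset(cfg, seed=23)
        groups = ds.metadata.groups
        from sputodeconv.datatypes import CellCountTable
        ests = {}
        for g in ("asthma", "control"):
            idx = groups[groups == g].index
            counts = CellCountTable(ds.cell_counts.data.loc[idx])
            design = build_design(counts, ("AM", "NG"))
            sub = MixedOmicsMatrix(ds.methylation.data[idx], "methylation-beta")
            ests[g] = deconvolve_group(sub, design, BoxBounds.methylation(),
                                       group=g)
        table = differential_deconvolved(ests["asthma"], ests["control"],
                                         "NG", "methylation")
        planted = set(ds.truth.effect_truth["feature_id"])
        called = set(table.data.index[table.data["significant"]])
        recall = len(planted & called) / len(planted)
        assert recall > 0.8
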