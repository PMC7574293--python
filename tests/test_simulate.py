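"""Synthetic-generator contracts: simplex fractions, mixing conservation,
RIN laws, degradation model and on-disk round-trips."""

import numpy as np
import pandas as pd
import pytest

from sputodeconv import simulate
from sputodeconv.datatypes import CellCountTable, MixedOmicsMatrix, SchemaError
from sputodeconv.simulate import (
    ConfigurationError,
    DegradationModel,
    EffectSpec,
    FractionModel,
    ProfileConfig,
    generate_cell_fractions,
    generate_profiles,
    generate_rin,
    inject_degradation,
    mix,
)


class TestCellFractions:
    def test_rows_sum_to_100(self, asthma_fractions):
        assert np.allclose(asthma_fractions.data.sum(axis=1), 100.0, atol=1e-6)

    def test_column_means_converge_to_cohort_means(self):
        # cohort means (percent): AM 27.9, NG 54.7, EO 12.9 ...
        model = FractionModel.default()
        table = generate_cell_fractions("asthma", 10_000, model, seed=5)
        expected = model.mean_vector("asthma") * 100.0
        assert (table.data.mean() - expected).abs().max() < 1.0

    def test_infinite_concentration_degenerates_to_mean(self):
        model = FractionModel.default()
        model.concentration["asthma"] = np.inf
        table = generate_cell_fractions("asthma", 3, model, seed=0)
        expected = model.mean_vector("asthma") * 100.0
        for _, row in table.data.iterrows():
            assert np.allclose(row, expected, atol=1e-9)

    def test_fixed_seed_reproducible(self):
        model = FractionModel.default()
        a = generate_cell_fractions("COPD", 8, model, seed=3)
        b = generate_cell_fractions("COPD", 8, model, seed=3)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_structural_zero_cell_type_stays_zero(self):
        # COPD monocyte mean is 0 -> exactly 0 in every sample
        table = generate_cell_fractions("COPD", 50, FractionModel.default(), 1)
        assert (table.data["MO"] == 0).all()

    def test_unknown_group_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cell_fractions("psoriasis", 3, FractionModel.default(), 0)


class TestProfiles:
    def test_invariants(self, default_dataset):
        truth = default_dataset.truth
        m = truth.methylation.to_numpy()
        assert m.min() >= 0 and m.max() <= 1
        e = truth.expression.to_numpy()
        assert e.min() >= truth.dyn_lo and e.max() <= truth.dyn_hi

    def test_no_effects_gives_empty_truth_table(self):
        truth = generate_profiles(config=ProfileConfig(
            n_features_expr=50, n_features_meth=50, n_markers_per_type=2,
            effects=[]), seed=0)
        assert truth.effect_truth.empty

    def test_methylation_effect_clipped_and_achieved_recorded(self):
        cfg = ProfileConfig(n_features_expr=10, n_features_meth=200,
                            n_markers_per_type=0,
                            effects=[EffectSpec("asthma", "AM", "methylation",
                                                0.2, 150)])
        truth = generate_profiles(config=cfg, seed=2)
        et = truth.effect_truth
        assert len(et) == 150
        base = truth.methylation.loc["AM", et["feature_id"]].to_numpy()
        achieved = np.clip(base + 0.2, 0.0, 1.0) - base
        assert np.allclose(et["achieved_effect"], achieved)
        high = base > 0.8
        assert et.loc[high, "clipped"].all()
        assert not et.loc[~high, "clipped"].any()

    def test_expression_effect_bookkeeping(self):
        cfg = ProfileConfig(n_features_expr=100, n_features_meth=10,
                            n_markers_per_type=0,
                            effects=[EffectSpec("COPD", "NG", "expression",
                                                1.5, 20)])
        truth = generate_profiles(config=cfg, seed=3)
        et = truth.effect_truth
        assert set(et["cell_type"]) == {"NG"}
        assert (et["nominal_effect"] == 1.5).all()
        assert len(et["feature_id"].unique()) == 20

    def test_monocytes_carry_no_markers(self, default_dataset):
        markers = default_dataset.truth.marker_assignments.dropna()
        assert "MO" not in set(markers)


class TestMixing:
    def test_pure_sample_recovers_profile(self):
        truth = generate_profiles(config=ProfileConfig(
            n_features_expr=20, n_features_meth=20, n_markers_per_type=0), seed=0)
        counts = CellCountTable(pd.DataFrame(
            [[100.0, 0, 0, 0, 0, 0, 0]], index=["s1"],
            columns=list("X") * 0 + ["AM", "NG", "EO", "LY", "MO", "CC", "SC"]))
        expr, meth, clips = mix(truth, counts, {"expression": 0, "methylation": 0})
        assert np.allclose(expr.data["s1"], truth.expression.loc["AM"])
        assert np.allclose(meth.data["s1"], truth.methylation.loc["AM"])

    def test_linear_mixing_is_exact_without_noise(self, asthma_fractions):
        # observed = F B to machine precision with zero noise
        truth = generate_profiles(config=ProfileConfig(
            n_features_expr=50, n_features_meth=50, n_markers_per_type=0), seed=1)
        expr, meth, clips = mix(truth, asthma_fractions,
                                {"expression": 0, "methylation": 0})
        F = asthma_fractions.data[truth.cell_types].to_numpy() / 100.0
        assert np.allclose(meth.data.to_numpy(),
                           (F @ truth.methylation.to_numpy()).T, atol=1e-12)
        assert np.allclose(expr.data.to_numpy(),
                           (F @ truth.expression.to_numpy()).T, atol=1e-9)
        assert clips == {"expression": 0, "methylation": 0}

    def test_fifty_fifty_mixture_averages_betas(self):
        truth = generate_profiles(config=ProfileConfig(
            n_features_expr=5, n_features_meth=5, n_markers_per_type=0), seed=4)
        truth.methylation.loc["AM"] = 0.2
        truth.methylation.loc["NG"] = 0.6
        counts = CellCountTable(pd.DataFrame(
            [[50.0, 50.0, 0, 0, 0, 0, 0]], index=["s1"],
            columns=["AM", "NG", "EO", "LY", "MO", "CC", "SC"]))
        _, meth, _ = mix(truth, counts, None)
        assert np.allclose(meth.data["s1"], 0.4)

    def test_empirical_noise_sd_matches_request(self):
        # residual sd within 5% of the requested noise at 10,000 features
        truth = generate_profiles(config=ProfileConfig(
            n_features_expr=10_000, n_features_meth=10, n_markers_per_type=0),
            seed=6)
        counts = CellCountTable(pd.DataFrame(
            [[100.0, 0, 0, 0, 0, 0, 0]], index=["s1"],
            columns=["AM", "NG", "EO", "LY", "MO", "CC", "SC"]))
        expr, _, _ = mix(truth, counts, {"expression": 9.0, "methylation": 0},
                         seed=8)
        resid = expr.data["s1"].to_numpy() - truth.expression.loc["AM"].to_numpy()
        # exclude clipped observations from the moment check
        inner = (expr.data["s1"] > truth.dyn_lo) & (expr.data["s1"] < truth.dyn_hi)
        sd = resid[inner.to_numpy()].std()
        assert abs(sd - 9.0) / 9.0 < 0.05

    def test_mismatched_cell_types_rejected(self, asthma_fractions):
        truth = generate_profiles(config=ProfileConfig(
            n_features_expr=5, n_features_meth=5), seed=0)
        bad = CellCountTable(asthma_fractions.data.drop(columns="SC")
                             .assign(SC=asthma_fractions.data["SC"]))
        truth.cell_types = truth.cell_types + ["XX"]
        with pytest.raises(SchemaError):
            mix(truth, bad, None)


class TestRinAndDegradation:
    @pytest.mark.parametrize("route,lo,hi", [("RLT", 7.6, 9.1),
                                             ("HOPE", 3.2, 5.1)])
    def test_rin_within_bounds(self, route, lo, hi):
        vals = generate_rin(route, 1000, DegradationModel.default(), seed=2)
        assert vals.min() >= lo and vals.max() <= hi

    def test_zero_sd_gives_constant_rin(self):
        model = DegradationModel(rin_laws={"RLT": (8.6, 0.0, 7.6, 9.1)})
        assert np.allclose(generate_rin("RLT", 10, model, 0), 8.6)

    def test_unknown_preservation_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_rin("FFPE", 5, DegradationModel.default(), 0)

    def _expr(self, n_probes=3, n_samples=6):
        data = pd.DataFrame(
            np.full((n_probes, n_samples), 100.0),
            index=[f"P{i}" for i in range(n_probes)],
            columns=[f"s{i}" for i in range(n_samples)])
        return MixedOmicsMatrix(data, "expression-linear")

    def test_reference_rin_leaves_data_unchanged(self):
        expr = self._expr()
        model = DegradationModel.default()
        model.lambdas = pd.Series(1.0, index=expr.features)
        rin = pd.Series(model.rin_ref, index=expr.samples)
        out = inject_degradation(expr, rin, model)
        pd.testing.assert_frame_equal(out.data, expr.data)

    def test_zero_lambda_leaves_data_unchanged(self):
        expr = self._expr()
        model = DegradationModel.default()
        model.lambdas = pd.Series(0.0, index=expr.features)
        rin = pd.Series(np.linspace(4, 9, 6), index=expr.samples)
        out = inject_degradation(expr, rin, model)
        pd.testing.assert_frame_equal(out.data, expr.data)

    def test_log2_value_linear_in_rin(self):
        # lambda=1, rin_ref=9: log2(value) = log2(base) - (9 - RIN),
        # so the Pearson correlation with RIN is exactly +1
        expr = self._expr(n_probes=1, n_samples=6)
        model = DegradationModel(rin_laws={}, rin_ref=9.0)
        model.lambdas = pd.Series(1.0, index=expr.features)
        rin = pd.Series(np.linspace(4, 9, 6), index=expr.samples)
        out = inject_degradation(expr, rin, model)
        lg = np.log2(out.data.iloc[0].to_numpy())
        r = np.corrcoef(lg, rin.to_numpy())[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_negative_lambda_rejected(self):
        expr = self._expr()
        model = DegradationModel.default()
        model.lambdas = pd.Series(-0.1, index=expr.features)
        rin = pd.Series(5.0, index=expr.samples)
        with pytest.raises(ConfigurationError):
            inject_degradation(expr, rin, model)


class TestDatasetRoundTrip:
    def test_write_read_round_trip(self, small_dataset, tmp_path):
        simulate.write_dataset(small_dataset, tmp_path / "d")
        back = MixedOmicsMatrix.from_tsv(tmp_path / "d" / "methylation.tsv",
                                         "methylation-beta")
        pd.testing.assert_frame_equal(back.data, small_dataset.methylation.data,
                                      check_exact=False, rtol=1e-12,
                                      check_names=False)

    def test_refuses_to_clobber_without_flag(self, small_dataset, tmp_path):
        simulate.write_dataset(small_dataset, tmp_path / "d")
        with pytest.raises(FileExistsError):
            simulate.write_dataset(small_dataset, tmp_path / "d")

    def test_same_seed_identical_files(self, tmp_path):
        cfg = simulate.ScenarioConfig(
            n_per_group={"asthma": 3, "control": 3},
            profiles=ProfileConfig(n_features_expr=40, n_features_meth=40,
                                   n_markers_per_type=2, effects=[]))
        a = simulate.simulate_dataset(cfg, seed=9)
        cfg2 = simulate.ScenarioConfig(
            n_per_group={"asthma": 3, "control": 3},
            profiles=ProfileConfig(n_features_expr=40, n_features_meth=40,
                                   n_markers_per_type=2, effects=[]))
        b = simulate.simulate_dataset(cfg2, seed=9)
        simulate.write_dataset(a, tmp_path / "a")
        simulate.write_dataset(b, tmp_path / "b")
        assert (simulate.dataset_digest(tmp_path / "a")
                == simulate.dataset_digest(tmp_path / "b"))

    def test_truth_table_rows_match_spiked_features(self, small_dataset):
        cfg = small_dataset.config.profiles
        expected = sum(e.n_features for e in cfg.effects)
        assert len(small_dataset.truth.effect_truth) == expected
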