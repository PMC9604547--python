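"""Fitting, prediction and error scoring of the additive increment model."""

import numpy as np
import pytest

from ptbridge import (
    UNSUBSTITUTED,
    BaseParameters,
    BridgeParameters,
    BridgeView,
    CompoundRecord,
    CompoundSpec,
    FitError,
    IncrementKeyError,
    IncrementTable,
    ModelPrediction,
    SubstitutionPattern,
    SyntheticConfig,
    approximation_error,
    approximation_report,
    default_bases,
    estimate_distal_increments,
    fit_increments,
    generate_dataset,
    load_table3,
    predict,
)


def scaled_table(table, factor):
    return IncrementTable(
        e_sub={k: v * factor for k, v in table.e_sub.items()},
        e_ster={k: v * factor for k, v in table.e_ster.items()},
        s_sub={k: v * factor for k, v in table.s_sub.items()},
        s_ster={k: v * factor for k, v in table.s_ster.items()},
        e_dist={k: v * factor for k, v in table.e_dist.items()},
        s_dist={k: v * factor for k, v in table.s_dist.items()},
    )


def assert_tables_equal(got, want, tol=1e-9):
    for attr in ("e_sub", "e_ster", "s_sub", "s_ster"):
        want_map = getattr(want, attr)
        got_map = getattr(got, attr)
        assert set(got_map) >= set(want_map)
        for key, value in want_map.items():
            assert abs(got_map[key] - value) < tol, (attr, key)


class TestFitIncrements:
    def test_noiseless_round_trip_recovers_truth(self, noiseless_records, table3):
        fitted = fit_increments(noiseless_records)
        assert_tables_equal(fitted, table3)
        assert fitted.unfit == ()

    def test_round_trip_for_arbitrary_truth_table(self, table3):
        truth = scaled_table(table3, -0.37)
        records = generate_dataset(SyntheticConfig(truth=truth, seed=3))
        assert_tables_equal(fit_increments(records), truth)

    def test_lstsq_variant_matches_averaging_on_complete_grid(self, noiseless_records, table3):
        fitted = fit_increments(noiseless_records, method="lstsq")
        assert_tables_equal(fitted, table3)

    def test_only_unsubstituted_records_yield_empty_maps(self):
        records = []
        for g in ("para", "meta"):
            view = BridgeView(CompoundSpec(g), "A")
            records.append(CompoundRecord(view, BridgeParameters(12.0, 10.0)))
        table = fit_increments(records)
        assert table.e_sub == {} and table.e_ster == {}
        assert table.s_sub == {} and table.s_ster == {}

    def test_missing_anchor_position_marks_substituent_unfit(self):
        records = []
        for g in ("para", "meta"):
            records.append(CompoundRecord(
                BridgeView(CompoundSpec(g), "A"), BridgeParameters(12.0, 10.0)))
            # NO2 only at position 1: the pair-symmetric anchor (3) is absent
            spec = CompoundSpec(g, SubstitutionPattern("NO2", 1), UNSUBSTITUTED)
            records.append(CompoundRecord(
                BridgeView(spec, "A"), BridgeParameters(10.0, 9.0)))
        with pytest.warns(UserWarning, match="NO2"):
            table = fit_increments(records)
        assert "NO2" in table.unfit
        assert all(k[0] != "NO2" for k in table.e_sub)

    def test_missing_bases_raise(self, noiseless_records):
        mono = [r for r in noiseless_records if r.view.proximal.is_substituted]
        with pytest.raises(FitError, match="base parameters"):
            fit_increments(mono)

    def test_supplied_bases_replace_derived_ones(self, noiseless_records, table3):
        mono = [r for r in noiseless_records if r.view.proximal.is_substituted]
        fitted = fit_increments(mono, bases=default_bases(("para", "meta")))
        assert_tables_equal(fitted, table3)

    def test_ortho_inclusion_warns(self, table3):
        truth = table3
        records = generate_dataset(
            SyntheticConfig(truth=truth, groups=("para", "meta", "ortho"),
                            bases=default_bases(("para", "meta", "ortho")), seed=5)
        )
        with pytest.warns(UserWarning, match="ortho"):
            fit_increments(records, groups=("para", "meta", "ortho"))

    def test_noisy_fits_are_unbiased(self, table3, para_meta_bases):
        """Mean fitted increments over replicates stay within 3 sigma/sqrt(n)."""
        sigma, n_rep = 0.1, 60
        sums = {}
        for i in range(n_rep):
            records = generate_dataset(SyntheticConfig(
                noise_sd=sigma, seed=9000 + i,
                distal_patterns=[UNSUBSTITUTED]))
            fitted = fit_increments(records, bases=para_meta_bases)
            for key, v in fitted.e_sub.items():
                sums[key] = sums.get(key, 0.0) + v
        # each per-replicate e_sub entry averages 2 group shifts: sd = sigma/sqrt(2)
        bound = 3 * sigma / np.sqrt(2 * n_rep)
        for key, truth_v in table3.e_sub.items():
            assert abs(sums[key] / n_rep - truth_v) < bound


class TestPredict:
    def test_unsubstituted_view_returns_base(self, table3):
        base = BaseParameters("para", 11.0, 9.5)
        view = BridgeView(CompoundSpec("para"), "A")
        pred = predict(base, view, table3)
        assert pred.ea == 11.0 and pred.sm == 9.5

    def test_steric_position_adds_both_terms(self, table3):
        """Br at position 1 with EBC = 10: 10 - 0.670 - 1.199 = 8.131."""
        base = BaseParameters("para", 10.0, 10.0)
        view = BridgeView(
            CompoundSpec("para", SubstitutionPattern("Br", 1)), "A")
        pred = predict(base, view, table3)
        assert pred.ea == pytest.approx(8.131, abs=1e-12)
        assert pred.ea_components["ster"] == -1.199

    def test_non_steric_position_has_no_steric_term(self, table3):
        base = BaseParameters("para", 10.0, 10.0)
        view = BridgeView(
            CompoundSpec("para", SubstitutionPattern("Br", 3)), "A")
        pred = predict(base, view, table3)
        assert pred.ea == pytest.approx(10.0 - 0.670)
        assert pred.ea_components["ster"] == 0.0

    def test_prediction_equals_sum_of_components(self, table3):
        base = BaseParameters("meta", 12.0, 10.0)
        view = BridgeView(
            CompoundSpec("meta", SubstitutionPattern("NH2", 4)), "A")
        pred = predict(base, view, table3)
        assert pred.ea == sum(pred.ea_components.values())
        assert pred.sm == sum(pred.sm_components.values())

    def test_missing_increment_key_is_named(self):
        table = IncrementTable(e_sub={("Br", (1, 3)): -0.5})
        base = BaseParameters("para", 10.0, 8.0)
        view = BridgeView(
            CompoundSpec("para", SubstitutionPattern("NO2", 2)), "A")
        with pytest.raises(IncrementKeyError, match="NO2"):
            predict(base, view, table)

    def test_distal_term_used_when_available(self, table3):
        table = scaled_table(table3, 1.0)
        table.e_dist[SubstitutionPattern("NO2", 1)] = 0.3
        table.s_dist[SubstitutionPattern("NO2", 1)] = 0.1
        base = BaseParameters("para", 12.0, 10.0)
        view = BridgeView(
            CompoundSpec("para", UNSUBSTITUTED, SubstitutionPattern("NO2", 1)), "A")
        pred = predict(base, view, table)
        assert pred.ea == pytest.approx(12.3)
        assert pred.sm == pytest.approx(10.1)

    def test_unknown_distal_pattern_falls_back_with_warning(self, table3):
        table = scaled_table(table3, 1.0)
        table.e_dist[SubstitutionPattern("NO2", 1)] = 0.3
        base = BaseParameters("para", 12.0, 10.0)
        view = BridgeView(
            CompoundSpec("para", UNSUBSTITUTED, SubstitutionPattern("Br", 2)), "A")
        with pytest.warns(UserWarning, match="proximal-only"):
            pred = predict(base, view, table)
        assert pred.ea == 12.0

    @pytest.mark.parametrize("factor", [0.5, 2.0, -1.0])
    def test_linearity_in_table_entries(self, table3, factor):
        base = BaseParameters("para", 12.0, 10.0)
        view = BridgeView(
            CompoundSpec("para", SubstitutionPattern("NO2", 1)), "A")
        ref = predict(base, view, table3)
        scaled = predict(base, view, scaled_table(table3, factor))
        assert scaled.ea - base.e_base == pytest.approx(
            factor * (ref.ea - base.e_base))
        assert scaled.sm - base.s_base == pytest.approx(
            factor * (ref.sm - base.s_base))


class TestDistalIncrements:
    def test_noiseless_recovery_of_distal_truth(self, table3):
        truth = scaled_table(table3, 1.0)
        rng = np.random.default_rng(11)
        for pat in [SubstitutionPattern(s, p) for s in ("Br", "NH2", "NO2")
                    for p in (1, 2, 3, 4)]:
            truth.e_dist[pat] = float(rng.uniform(-0.5, 0.5))
            truth.s_dist[pat] = float(rng.uniform(-0.5, 0.5))
        records = generate_dataset(SyntheticConfig(truth=truth, seed=2))
        est = estimate_distal_increments(records, table3)
        for pat, v in truth.e_dist.items():
            assert est.e_dist[pat] == pytest.approx(v, abs=1e-9)
            assert abs(est.e_dist[pat]) <= 0.5
        for pat, v in truth.s_dist.items():
            assert est.s_dist[pat] == pytest.approx(v, abs=1e-9)

    def test_no_distally_substituted_records_leaves_maps_empty(self, table3):
        records = generate_dataset(
            SyntheticConfig(distal_patterns=[UNSUBSTITUTED], seed=2))
        est = estimate_distal_increments(records, table3)
        assert est.e_dist == {} and est.s_dist == {}


class TestApproximationError:
    def test_perfect_prediction_scores_zero(self):
        actual = BridgeParameters(10.0, 8.0)
        pred = ModelPrediction({"base": 10.0}, {"base": 8.0})
        assert approximation_error(actual, pred) == (0.0, 0.0)

    def test_two_percent_example(self):
        actual = BridgeParameters(10.0, 10.0)
        pred = ModelPrediction({"base": 9.8}, {"base": 10.0})
        ea_err, sm_err = approximation_error(actual, pred)
        assert ea_err == pytest.approx(2.0)
        assert sm_err == 0.0

    def test_zero_reference_is_flagged(self):
        actual = BridgeParameters(0.0, 0.0)
        pred = ModelPrediction({"base": 1.0}, {"base": 1.0})
        with pytest.raises(ZeroDivisionError):
            approximation_error(actual, pred)

    def test_model_is_exact_on_its_own_additive_data(
        self, noiseless_records, table3, para_meta_bases
    ):
        report = approximation_report(noiseless_records, para_meta_bases, table3)
        assert report.max_ea == 0.0
        assert report.max_sm == 0.0
        assert len(report.per_record) == len(noiseless_records)


class TestSerialization:
    def test_json_round_trip(self, tmp_path, table3):
        table = scaled_table(table3, 1.0)
        table.e_dist[SubstitutionPattern("Br", 3)] = 0.25
        path = table.to_json(tmp_path / "table.json")
        loaded = IncrementTable.from_json(path)
        assert loaded.e_sub == table.e_sub
        assert loaded.s_ster == table.s_ster
        assert loaded.e_dist == table.e_dist

    def test_long_frame_has_all_entries(self, table3):
        frame = table3.to_frame()
        assert len(frame) == 24
        assert set(frame["component"]) == {"e_sub", "e_ster", "s_sub", "s_ster"}
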