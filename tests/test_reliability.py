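"""ICC(A,1) and the study-level reliability analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuedfood import reliability, synthetic
from cuedfood.reliability import icc_a1, icc_label


def brute_force_icc_a1(mat: np.ndarray) -> float:
    """Independent ANOVA-decomposition oracle written with explicit loops."""
    n, k = mat.shape
    grand = sum(mat[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(mat[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(mat[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sst = sum((mat[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_equals_brute_force_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 40))
            k = int(rng.integers(2, 8))
            mat = (rng.normal(0, 1, (n, k)) + rng.normal(0, 1.2, (n, 1))
                   + rng.normal(0, 0.4, (1, k)))
            assert icc_a1(mat).estimate == pytest.approx(
                brute_force_icc_a1(mat), abs=1e-12)

    def test_matches_independent_package_implementation(self, rng):
        import pingouin as pg

        mat = rng.normal(0, 1, (15, 4)) + rng.normal(0, 1, (15, 1))
        mine = icc_a1(mat)
        df = (pd.DataFrame(mat).reset_index()
              .melt(id_vars="index", var_name="rater", value_name="y"))
        ref = pg.intraclass_corr(df, targets="index", raters="rater",
                                 ratings="y").set_index("Type").loc["ICC(A,1)"]
        assert mine.estimate == pytest.approx(float(ref["ICC"]), abs=1e-10)
        assert mine.f_value == pytest.approx(float(ref["F"]), abs=1e-10)

    def test_identical_columns_give_one(self, rng):
        col = rng.normal(0, 1, 8)
        res = icc_a1(np.tile(col[:, None], (1, 5)))
        assert res.estimate == pytest.approx(1.0)
        assert res.label == "Excellent"

    def test_constant_matrix_is_degenerate_not_a_crash(self):
        res = icc_a1(np.full((6, 4), 3.7))
        assert res.degenerate and np.isnan(res.estimate)
        assert res.label == "undefined"

    def test_variance_ratio_four_to_one_gives_point_eight(self, rng):
        rows = rng.normal(0, 2.0, (4000, 1))            # signal variance 4
        mat = rows + rng.normal(0, 1.0, (4000, 6))      # noise variance 1
        assert icc_a1(mat).estimate == pytest.approx(0.8, abs=0.02)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_permutation_and_shared_affine_invariance(self, seed):
        r = np.random.default_rng(seed)
        mat = r.normal(0, 1, (7, 4)) + r.normal(0, 1, (7, 1))
        base = icc_a1(mat).estimate
        perm = mat[r.permutation(7)][:, r.permutation(4)]
        assert icc_a1(perm).estimate == pytest.approx(base, abs=1e-10)
        assert icc_a1(3.0 * mat - 1.5).estimate == pytest.approx(base, abs=1e-10)

    @pytest.mark.parametrize("value,label", [
        (0.39, "Poor"), (0.40, "Fair"), (0.59, "Fair"), (0.60, "Good"),
        (0.74, "Good"), (0.75, "Excellent"), (0.99, "Excellent"),
        (-0.2, "Poor"),
    ])
    def test_interpretation_bins_left_closed(self, value, label):
        assert icc_label(value) == label

    def test_incomplete_rows_dropped_with_warning(self, rng):
        mat = rng.normal(0, 1, (8, 4))
        mat[2, 1] = np.nan
        with pytest.warns(UserWarning, match="listwise"):
            res = icc_a1(mat)
        assert res.n_rows == 7

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            icc_a1(np.zeros((1, 4)))


class TestChoiceFrequencyReliability:
    def test_stable_subjects_are_reliable(self, small_study):
        res = reliability.choice_frequency_reliability(small_study.trials)
        assert set(res) == {"natural", "health", "difference"}
        assert res["health"].label in ("Good", "Excellent")

    def test_redrawn_subjects_are_poor(self):
        study = synthetic.simulate_study(n_subjects=8, stable_subjects=False,
                                         seed=77)
        res = reliability.choice_frequency_reliability(study.trials)
        assert res["health"].estimate < 0.4
        assert res["health"].label == "Poor"

    def test_needs_five_sessions(self, small_study):
        partial = small_study.trials.query("session <= 3")
        with pytest.raises(ValueError, match="5 sessions"):
            reliability.choice_frequency_reliability(partial)


class TestRatingReliability:
    def test_noise_free_ratings_have_unit_icc(self):
        items = synthetic.gen_items(40, seed=3)
        ratings = synthetic.gen_ratings(items, n_subjects=3, within_sd=0.0,
                                        seed=3)
        res = reliability.rating_reliability(ratings, unit="subject")
        assert np.allclose(res["icc_mean"], 1.0)

    def test_target_icc_recovered_from_variance_ratio(self):
        """Generator configured for ICC ~= 0.8: latent variance 100/12 plus
        between 1.0 against within chosen by the documented formula."""
        target = 0.8
        var_signal = 100.0 / 12.0 + 1.0
        within = np.sqrt(var_signal * (1 - target) / target)
        items = synthetic.gen_items(100, seed=5)
        ratings = synthetic.gen_ratings(items, n_subjects=4, within_sd=within,
                                        seed=6)
        res = reliability.rating_reliability(ratings, unit="subject",
                                             sessions=(1, 5))
        assert res["icc_mean"].mean() == pytest.approx(target, abs=0.1)

    def test_unit_orientation_gives_distinct_analyses(self, small_study):
        by_subject = reliability.rating_reliability(small_study.ratings,
                                                    unit="subject")
        by_item = reliability.rating_reliability(small_study.ratings,
                                                 unit="item")
        assert (by_subject["n_units"] <= 5).all()
        assert (by_item["n_units"] > 50).all()
        assert not np.allclose(by_subject["icc_mean"].to_numpy(),
                               by_item["icc_mean"].to_numpy())

    def test_missing_sessions_reported(self, small_study):
        with pytest.raises(ValueError, match="absent"):
            reliability.rating_reliability(small_study.ratings,
                                           sessions=(1, 9))


def _fits_fixture(values_by_condition):
    """Build {(condition, session): FitResult}-shaped input from raw arrays."""
    from cuedfood.inference import FitResult
    from cuedfood.params import PARAM_NAMES

    out = {}
    for condition, mat in values_by_condition.items():
        n_subj, n_sess = mat.shape
        for session in range(1, n_sess + 1):
            rows = []
            for s in range(n_subj):
                for name in PARAM_NAMES:
                    value = mat[s, session - 1] if name == "w_taste" else 0.5
                    rows.append({"subject_id": s, "parameter": name,
                                 "estimate": value, "se": 0.1})
            out[(condition, session)] = FitResult(
                subject_estimates=pd.DataFrame(rows), group=pd.DataFrame(),
                diagnostics={}, condition=condition, session=session)
    return out


class TestParameterReliability:
    def test_constant_parameters_flagged_degenerate(self):
        mat = np.full((6, 5), 0.9)
        fits = _fits_fixture({"natural": mat, "health": mat})
        table = reliability.parameter_reliability(fits)
        row = table.query("parameter == 'w_taste' and condition == 'natural'")
        assert bool(row["degenerate"].iloc[0])

    def test_noisier_condition_has_lower_icc(self, rng):
        stable = rng.normal(0, 1, (10, 1)) + rng.normal(0, 0.1, (10, 5))
        noisy = rng.normal(0, 1, (10, 1)) + rng.normal(0, 2.0, (10, 5))
        fits = _fits_fixture({"health": stable, "natural": noisy})
        table = reliability.parameter_reliability(fits).set_index(
            ["parameter", "condition"])
        assert (table.loc[("w_taste", "health"), "icc"]
                > table.loc[("w_taste", "natural"), "icc"])


class TestParameterRanges:
    def test_identical_ranges_give_null_result(self):
        mat = np.cumsum(np.ones((6, 5)), axis=1)  # same range for everyone
        fits = _fits_fixture({"natural": mat, "health": mat.copy()})
        table = reliability.parameter_range_comparison(fits).set_index("parameter")
        assert table.loc["w_taste", "t_stat"] == 0.0
        assert table.loc["w_taste", "p_value"] == 1.0

    def test_matches_hand_computed_paired_t(self, rng):
        nat = rng.normal(0, 1, (6, 5))
        hea = rng.normal(0, 0.3, (6, 5))
        fits = _fits_fixture({"natural": nat, "health": hea})
        table = reliability.parameter_range_comparison(fits).set_index("parameter")
        d = (hea.max(axis=1) - hea.min(axis=1)) - (nat.max(axis=1) - nat.min(axis=1))
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert table.loc["w_taste", "t_stat"] == pytest.approx(t_oracle, abs=1e-10)
        assert table.loc["w_taste", "df"] == 5

    def test_needs_two_subjects(self):
        fits = _fits_fixture({"natural": np.ones((1, 5)),
                              "health": np.ones((1, 5))})
        with pytest.raises(ValueError, match="2 subjects"):
            reliability.parameter_range_comparison(fits)
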