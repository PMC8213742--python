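"""Regression and prediction-from-ratings analyses."""

import numpy as np
import pandas as pd
import pytest

from cuedfood import behavior


def _logistic_trials(rng, n_subjects=6, n_per_cell=120,
                     beta=None, sessions=(1, 2), rt_beta_hd=0.0):
    """Trials whose choices follow a known logistic model (no DDM involved) —
    the independent generative oracle for coefficient recovery."""
    if beta is None:
        beta = {"intercept": 0.2, "hd": 0.8, "td": -0.6, "cond": 1.0,
                "hd_cond": 0.9, "td_cond": -0.5}
    rows = []
    for s in range(n_subjects):
        for session in sessions:
            for cond in ("natural", "health"):
                c = 1.0 if cond == "health" else 0.0
                hd = rng.uniform(0.2, 4.0, n_per_cell)
                td = rng.uniform(-4.0, 4.0, n_per_cell)
                eta = (beta["intercept"] + beta["hd"] * hd + beta["td"] * td
                       + beta["cond"] * c + beta["hd_cond"] * hd * c
                       + beta["td_cond"] * td * c)
                p = 1 / (1 + np.exp(-eta))
                y = (rng.random(n_per_cell) < p).astype(int)
                rt = np.exp(rng.normal(-0.3, 0.2, n_per_cell)
                            + rt_beta_hd * (hd - hd.mean()))
                rows.append(pd.DataFrame({
                    "subject_id": s, "session": session, "condition": cond,
                    "hd": hd, "td": td, "chose_healthier": y,
                    "chose_left": y, "rt": np.clip(rt, 0.2, 2.9),
                    "censored": False, "challenge": td < 0,
                }))
    return pd.concat(rows, ignore_index=True)


class TestChoiceModel:
    def test_recovers_generative_coefficients(self, rng):
        beta = {"intercept": 0.2, "hd": 0.8, "td": -0.6, "cond": 1.0,
                "hd_cond": 0.9, "td_cond": -0.5}
        trials = _logistic_trials(rng, n_subjects=8, n_per_cell=250, beta=beta)
        res = behavior.fit_choice_model(trials)
        cond = "C(condition, Treatment('natural'))[T.health]"
        checks = {"hd": beta["hd"], "td": beta["td"], cond: beta["cond"],
                  f"hd:{cond}": beta["hd_cond"], f"td:{cond}": beta["td_cond"]}
        for term, truth in checks.items():
            lo, hi = res.interval(term)
            assert lo <= truth <= hi, f"{term}: truth {truth} outside [{lo}, {hi}]"

    def test_null_health_effect_interval_covers_zero(self, rng):
        beta = {"intercept": 0.0, "hd": 0.0, "td": 0.9, "cond": 0.3,
                "hd_cond": 0.0, "td_cond": 0.0}
        trials = _logistic_trials(rng, beta=beta)
        res = behavior.fit_choice_model(trials)
        lo, hi = res.interval("hd")
        assert lo <= 0.0 <= hi

    def test_no_taste_by_health_interaction_term(self, rng):
        res = behavior.fit_choice_model(_logistic_trials(rng))
        assert not any("hd" in t and "td" in t
                       for t in res.population["term"])

    def test_single_condition_rejected(self, rng):
        trials = _logistic_trials(rng)
        with pytest.raises(ValueError, match="condition"):
            behavior.fit_choice_model(trials[trials["condition"] == "natural"])


class TestRTModel:
    def test_recovers_hd_effect_and_null_case(self, rng):
        effect = behavior.fit_rt_model(
            _logistic_trials(rng, n_per_cell=200, rt_beta_hd=-0.08))
        null = behavior.fit_rt_model(
            _logistic_trials(rng, n_per_cell=200, rt_beta_hd=0.0))
        lo, hi = effect.interval("hd_z")
        assert hi < 0.0          # faster RTs with larger health differences
        lo0, hi0 = null.interval("hd_z")
        assert lo0 <= 0.0 <= hi0


class TestPredictionFromModel:
    def test_matches_per_trial_loop_oracle(self, rng):
        trials = _logistic_trials(rng, n_subjects=5, n_per_cell=20).head(50)
        res = behavior.fit_choice_model(_logistic_trials(rng, n_subjects=5))
        fast = behavior.predict_accuracy_model(res, trials)
        # brute-force: classify each trial individually with a python loop
        import patsy

        X = patsy.dmatrix(res.formula.split("~", 1)[1], trials,
                          return_type="dataframe")
        coefs = res.subject.pivot(index="subject_id", columns="term",
                                  values="estimate")
        pop = res.population.set_index("term")["estimate"]
        correct = []
        for pos in range(len(trials)):
            row = trials.iloc[pos]
            b = (coefs.loc[row["subject_id"]] if row["subject_id"]
                 in coefs.index else pop)
            eta = sum(float(X.iloc[pos][term]) * float(b[term])
                      for term in X.columns)
            correct.append((eta > 0) == bool(row["chose_healthier"]))
        assert fast == pytest.approx(np.mean(correct))

    def test_separable_data_approach_perfect_accuracy(self, rng):
        beta = {"intercept": 0.0, "hd": 6.0, "td": 0.0, "cond": 0.0,
                "hd_cond": 0.0, "td_cond": 0.0}
        trials = _logistic_trials(rng, beta=beta)
        res = behavior.fit_choice_model(trials)
        assert behavior.predict_accuracy_model(res, trials) > 0.95


class TestPredictionFromRatings:
    @staticmethod
    def _fixture(rng, follow="taste"):
        items = pd.DataFrame({"item_id": range(40)})
        ratings = []
        for s in range(3):
            taste = rng.uniform(-5, 5, 40)
            health = rng.uniform(-5, 5, 40)
            for attr, vals in (("taste", taste), ("health", health)):
                ratings.append(pd.DataFrame({
                    "subject_id": s, "session": 1, "item_id": items["item_id"],
                    "attribute": attr, "value": vals}))
        ratings = pd.concat(ratings, ignore_index=True)
        lookup = ratings.set_index(["subject_id", "attribute", "item_id"])["value"]
        rows = []
        for s in range(3):
            for t in range(60):
                left, right = rng.choice(40, 2, replace=False)
                key = lambda attr, item: lookup[(s, attr, item)]
                chose_left = int(key(follow, left) > key(follow, right))
                rows.append({"subject_id": s, "session": 1,
                             "condition": "natural" if t % 2 else "health",
                             "left_item": left, "right_item": right,
                             "chose_left": chose_left, "censored": False})
        return ratings, pd.DataFrame(rows)

    def test_taste_followers_are_perfectly_predicted_by_taste(self, rng):
        ratings, trials = self._fixture(rng, follow="taste")
        res = behavior.predict_accuracy_attribute(ratings, trials, "taste")
        assert (res["accuracy"] == 1.0).all()
        health = behavior.predict_accuracy_attribute(ratings, trials, "health")
        assert ((health["accuracy"] > 0.2) & (health["accuracy"] < 0.8)).all()

    def test_ties_are_excluded_and_tallied(self, rng):
        ratings, trials = self._fixture(rng)
        tied_item = int(trials.loc[0, "left_item"])
        other = int(trials.loc[0, "right_item"])
        mask = (ratings["attribute"] == "taste") & ratings["item_id"].isin(
            [tied_item, other]) & (ratings["subject_id"] == 0)
        ratings.loc[mask, "value"] = 1.23
        res = behavior.predict_accuracy_attribute(ratings, trials, "taste")
        assert res["n_excluded_ties"].sum() >= 1

    def test_invariance_to_row_order_and_side_swap(self, rng):
        ratings, trials = self._fixture(rng)
        base = behavior.predict_accuracy_attribute(ratings, trials, "taste")
        shuffled = trials.sample(frac=1.0, random_state=3)
        res_shuffled = behavior.predict_accuracy_attribute(ratings, shuffled,
                                                           "taste")
        swapped = trials.copy()
        swapped[["left_item", "right_item"]] = trials[
            ["right_item", "left_item"]].to_numpy()
        swapped["chose_left"] = 1 - trials["chose_left"]
        res_swapped = behavior.predict_accuracy_attribute(ratings, swapped,
                                                          "taste")
        for other in (res_shuffled, res_swapped):
            pd.testing.assert_frame_equal(
                base.sort_values("condition").reset_index(drop=True),
                other.sort_values("condition").reset_index(drop=True),
            )
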