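import numpy as np
import pandas as pd
import pytest
from scipy import stats

from finemotor.clinical import (
    bradykinesia_sum,
    exclude_item4_observations,
    laterality_index,
    lme_profile_on_updrs,
    lme_single_trial,
    subtype_classify,
    tukey_posthoc,
)


def record(right=(0, 0, 0, 0, 0), left=(0, 0, 0, 0, 0), tremor=(0, 0, 0, 0), item314=0):
    items = {
        item: {"right": r, "left": l}
        for item, r, l in zip(("3.4", "3.5", "3.6", "3.7", "3.8"), right, left)
    }
    items["3.14"] = item314
    for item, v in zip(("3.15", "3.16", "3.17", "3.18"), tremor):
        items[item] = v
    return {"subject_id": "S1", "items": items}


class TestLaterality:
    def test_right_dominant_negative(self):
        rec = record(right=(2, 2, 2, 1, 1), left=(1, 1, 1, 1, 1))
        assert laterality_index(rec) == -3

    def test_symmetric_zero(self):
        rec = record(right=(1, 2, 1, 0, 1), left=(1, 2, 1, 0, 1))
        assert laterality_index(rec) == 0

    def test_all_zero(self):
        assert laterality_index(record()) == 0

    def test_antisymmetry_under_side_swap(self, rng):
        right = tuple(rng.integers(0, 5, size=5))
        left = tuple(rng.integers(0, 5, size=5))
        assert laterality_index(record(right=right, left=left)) == -laterality_index(
            record(right=left, left=right)
        )

    def test_missing_item_named(self):
        rec = record()
        del rec["items"]["3.6"]
        with pytest.raises(KeyError, match="3.6"):
            laterality_index(rec)


class TestBradySum:
    def test_hand_sum(self):
        rec = record(right=(1, 2, 0, 3, 1))
        assert bradykinesia_sum(rec, "right") == 7

    def test_bounds(self):
        assert bradykinesia_sum(record(right=(4, 4, 4, 4, 4)), "right") == 20
        assert bradykinesia_sum(record(), "right") == 0

    def test_bad_side(self):
        with pytest.raises(ValueError):
            bradykinesia_sum(record(), "up")


class TestSubtype:
    def test_zero_numerator_akinetic(self):
        rec = record(right=(2, 2, 2, 2, 2), left=(2, 2, 2, 2, 2), tremor=(0, 0, 0, 0))
        label, ratio = subtype_classify(rec)
        assert label == "akinetic_rigid_dominant"

    def test_zero_denominator_tremor(self):
        rec = record(tremor=(1, 1, 1, 1))
        label, _ = subtype_classify(rec)
        assert label == "tremor_dominant"

    def test_threshold_rule(self):
        # brady mean fixed at 1.0 via all-ones items; tremor mean 1.6 / 1.4
        base = dict(
            right=(1, 1, 1, 1, 1), left=(1, 1, 1, 1, 1), item314=1
        )
        hi, _ = subtype_classify(record(**base, tremor=(2, 2, 1, 2)))  # ratio 1.75
        lo, _ = subtype_classify(record(**base, tremor=(2, 1, 1, 1)))  # ratio 1.25
        assert hi == "tremor_dominant"
        assert lo == "akinetic_rigid_dominant"

    def test_both_zero_indeterminate(self):
        label, ratio = subtype_classify(record())
        assert label == "indeterminate"
        assert np.isnan(ratio)


class TestExcludeItem4:
    def test_no_fours_unchanged(self):
        df = pd.DataFrame({"item_3_4_right": [0, 1, 2, 3], "y": range(4)})
        out, n = exclude_item4_observations(df, "item_3_4_right")
        assert n == 0 and len(out) == 4

    def test_single_four_removed(self):
        df = pd.DataFrame({"item_3_4_right": [0, 4, 2], "y": range(3)})
        out, n = exclude_item4_observations(df, "item_3_4_right")
        assert n == 1 and len(out) == 2

    def test_all_fours_empty(self):
        df = pd.DataFrame({"item_3_4_right": [4, 4], "y": range(2)})
        out, n = exclude_item4_observations(df, "item_3_4_right")
        assert n == 2 and len(out) == 0


def trial_table(seed=0, ns=8, nt=10, state_effects=(0, 0, 0, 0), subj_sd=1.0):
    rng = np.random.default_rng(seed)
    states = ["OFF/OFF", "ON/OFF", "OFF/ON", "ON/ON"]
    rows = []
    for s in range(ns):
        bs = rng.normal(0, subj_sd)
        for t in range(nt):
            bt = rng.normal(0, 0.5)
            for st, eff in zip(states, state_effects):
                rows.append(
                    dict(subject=f"S{s}", trial=t, state=st, y=eff + bs + bt + rng.normal(0, 1.0))
                )
    return pd.DataFrame(rows)


class TestLmeSingleTrial:
    def test_planted_effect_detected(self):
        detected = 0
        n_sims = 25
        for s in range(n_sims):
            df = trial_table(seed=s, state_effects=(0, 0.2, 0.3, 0.8))
            model = lme_single_trial(df, "y")
            if model.term_tests["state"][3] < 0.05:
                detected += 1
        assert detected >= int(0.85 * n_sims)

    def test_requires_two_subjects(self):
        df = trial_table(ns=1)
        with pytest.raises(ValueError, match="2 subjects"):
            lme_single_trial(df, "y")

    def test_missing_columns_named(self):
        with pytest.raises(KeyError):
            lme_single_trial(pd.DataFrame({"subject": [], "y": []}), "y")

    def test_emmeans_reproduce_cell_structure(self):
        df = trial_table(seed=1, state_effects=(0, 1, 2, 3), subj_sd=0.0)
        model = lme_single_trial(df, "y")
        means = model.emmeans
        assert means["ON/ON"] > means["OFF/ON"] > means["ON/OFF"] > means["OFF/OFF"]


class TestTukey:
    def test_identical_means_p_near_one(self):
        df = trial_table(seed=2, subj_sd=0.3)
        model = lme_single_trial(df, "y")
        table = tukey_posthoc(model)
        assert len(table) == 6
        assert (table["p_adj"] > 0.5).all()

    def test_matches_classical_hsd_oracle(self):
        # balanced one-way layout with random terms forced off: the adjusted
        # p must equal the textbook studentized-range computation from group
        # means and MSE
        df = trial_table(seed=3, state_effects=(0, 0.3, 0.6, 1.0), subj_sd=0.0)
        model = lme_single_trial(df, "y", include_subject=False, include_nested=False)
        table = tukey_posthoc(model)
        k = 4
        n_per = len(df) // k
        grand = {s: g["y"].mean() for s, g in df.groupby("state")}
        resid = df.groupby("state")["y"].transform("mean")
        mse = float(np.sum((df["y"] - resid) ** 2) / (len(df) - k))
        df_err = len(df) - k
        for row in table.itertuples():
            a, b = row.contrast.split(" - ")
            q = abs(grand[a] - grand[b]) / np.sqrt(mse / n_per)
            p_oracle = float(stats.studentized_range.sf(q, k, df_err))
            assert row.p_adj == pytest.approx(min(p_oracle, 1.0), abs=1e-6)

    def test_adjusted_never_below_unadjusted(self):
        df = trial_table(seed=4, state_effects=(0, 0.2, 0.5, 0.9))
        model = lme_single_trial(df, "y")
        table = tukey_posthoc(model)
        for row in table.itertuples():
            p_raw = 2 * stats.t.sf(abs(row.t), row.df)
            assert row.p_adj >= p_raw - 1e-12


def profile_data(seed=0, ns=15, b=3.0, noise=1.0):
    rng = np.random.default_rng(seed)
    states = ["OFF/OFF", "ON/OFF", "OFF/ON", "ON/ON"]
    rows = []
    for s in range(ns):
        for st in states:
            prof = rng.normal()
            lat = rng.normal()
            rows.append(
                dict(
                    subject=f"S{s}",
                    state=st,
                    profile=prof,
                    laterality_index=lat,
                    outcome=b * prof + 0.5 * lat + rng.normal(0, noise),
                )
            )
    return pd.DataFrame(rows)


class TestProfileOnUpdrs:
    def test_coefficient_recovery(self):
        estimates = []
        for s in range(20):
            df = profile_data(seed=s)
            model = lme_profile_on_updrs(df, "outcome")
            estimates.append(model.coef["profile"])
        assert np.mean(estimates) == pytest.approx(3.0, rel=0.10)

    def test_permuted_profile_null(self):
        ps = []
        for s in range(20):
            df = profile_data(seed=100 + s)
            rng = np.random.default_rng(s)
            df["profile"] = rng.permutation(df["profile"].to_numpy())
            df["outcome"] = 0.5 * df["laterality_index"] + rng.normal(size=len(df))
            model = lme_profile_on_updrs(df, "outcome")
            ps.append(model.term_tests["profile"][3])
        assert 0.2 < np.mean(ps) < 0.8  # roughly uniform

    def test_perfect_fit_conditional_r2(self):
        df = profile_data(seed=5, noise=1e-6)
        model = lme_profile_on_updrs(df, "outcome")
        assert model.r2_conditional > 0.999

    def test_join_mismatch_reported(self):
        df = profile_data(seed=6).drop(columns=["laterality_index"])
        with pytest.raises(KeyError, match="laterality_index"):
            lme_profile_on_updrs(df, "outcome")

    def test_interaction_term_present(self):
        df = profile_data(seed=7).rename(columns={"profile": "tap"})
        df["rot"] = np.random.default_rng(8).normal(size=len(df))
        model = lme_profile_on_updrs(
            df,
            "outcome",
            profile_cols=("tap", "rot"),
            interactions=(("tap", "rot"),),
        )
        assert "tap:rot" in model.term_tests
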