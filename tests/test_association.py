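"""Multinomial trajectory-group associations and FDR control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cordbmi.association import (
    bh_fdr,
    covariate_design,
    explore_four_groups,
    fit_multinomial,
    member_followup,
    module_association,
    sex_interaction_lrt,
)


def bh_bruteforce(p):
    """Step-up oracle: q_(i) = min over j >= i of p_(j) * n / j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        q[idx] = min(running, 1.0)
    return q


class TestBhFdr:
    def test_hand_worked_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_its_own_q(self):
        assert bh_fdr([0.37]) == pytest.approx([0.37])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            q = bh_fdr(p)
            assert q == pytest.approx(bh_bruteforce(p), abs=1e-12)
            assert np.all(q >= p - 1e-12)


class TestFitMultinomial:
    def test_saturated_fit_reproduces_cell_ratio_or(self):
        """Counts x=0:(10,10,10), x=1:(10,20,5): OR(level2 vs ref) = 2 exactly."""
        y, x = [], []
        for xv, counts in [(0.0, (10, 10, 10)), (1.0, (10, 20, 5))]:
            for level, c in zip(["ref", "lvl1", "lvl2"], counts):
                y += [level] * c
                x += [xv] * c
        fit = fit_multinomial(
            pd.Series(y), pd.Series(x, dtype=float), reference="ref",
            levels=["lvl1", "lvl2"],
        )
        assert fit.contrasts.loc["lvl1", "or_"] == pytest.approx(2.0, abs=1e-6)
        assert fit.contrasts.loc["lvl2", "or_"] == pytest.approx(0.5, abs=1e-6)

    def test_constant_exposure_reduces_to_intercept_model(self):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.choice(["a", "b", "c"], 120))
        fit = fit_multinomial(y, pd.Series(np.zeros(120)), reference="a")
        assert (fit.contrasts["beta"] == 0).all()
        # loglik equals the intercept-only multinomial loglik
        counts = y.value_counts()
        ll0 = float((counts * np.log(counts / counts.sum())).sum())
        assert fit.loglik == pytest.approx(ll0, abs=1e-6)

    def test_rescaling_exposure_rescales_beta(self):
        rng = np.random.default_rng(1)
        x = pd.Series(rng.standard_normal(300))
        y = pd.Series(
            rng.choice(["a", "b", "c"], 300, p=[0.4, 0.3, 0.3])
        )
        f1 = fit_multinomial(y, x, reference="a")
        f2 = fit_multinomial(y, 2.0 * x, reference="a")
        assert f2.contrasts["beta"].to_numpy() == pytest.approx(
            f1.contrasts["beta"].to_numpy() / 2.0, abs=1e-6
        )

    def test_separation_flagged(self):
        y = pd.Series(["a"] * 40 + ["b"] * 40 + ["c"] * 40)
        x = pd.Series([0.0] * 40 + [1.0] * 40 + [0.0] * 40)
        fit = fit_multinomial(y, x, reference="a", maxiter=200)
        assert fit.separation

    def test_parameter_recovery_on_planted_effect(self):
        """Mean estimate near the planted log-odds over repeated simulation."""
        rng = np.random.default_rng(5)
        beta_true = np.log(0.7)
        n, reps = 900, 40
        est = []
        for _ in range(reps):
            x = rng.standard_normal(n)
            logits = np.column_stack([np.zeros(n), beta_true * x, 0.2 * x])
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            y = np.array(["ref", "lvl1", "lvl2"])[
                (rng.uniform(size=(n, 1)) > probs.cumsum(axis=1)).sum(axis=1)
            ]
            fit = fit_multinomial(
                pd.Series(y), pd.Series(x), reference="ref", levels=["lvl1", "lvl2"]
            )
            est.append(fit.contrasts.loc["lvl1", "beta"])
        mc_se = np.std(est, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(est) - beta_true) < 3 * mc_se + 0.01


def make_outcome_frame(n=450, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.choice(["early-OWO", "late-OWO", "NW"], n, p=[0.4, 0.27, 0.33])
    idx = [f"c{i}" for i in range(n)]
    return pd.DataFrame({"group3": g, "group4": g}, index=idx), rng


class TestTables:
    def test_module_table_sorted_by_early_onset_q(self):
        asg, rng = make_outcome_frame()
        eigen = pd.DataFrame(
            {
                "red": (asg["group3"] == "early-OWO") * 1.0 + rng.standard_normal(len(asg)),
                "blue": rng.standard_normal(len(asg)),
            },
            index=asg.index,
        )
        table = module_association(eigen, asg)
        early = table[table["level"] == "early-OWO"]
        assert list(early["exposure"]) == ["red", "blue"]
        assert early["q"].is_monotonic_increasing
        # duplicated exposure gives identical statistics
        eigen2 = eigen.assign(red2=eigen["red"])
        t2 = module_association(eigen2, asg)
        a = t2[(t2["exposure"] == "red") & (t2["level"] == "early-OWO")].iloc[0]
        b = t2[(t2["exposure"] == "red2") & (t2["level"] == "early-OWO")].iloc[0]
        assert a["beta"] == pytest.approx(b["beta"])

    def test_four_group_exploration_collapse_flag(self):
        asg, rng = make_outcome_frame(600, seed=3)
        asg["group4"] = asg["group4"].replace(
            {"NW": rng.choice(["NW-A", "NW-B"])}
        )
        asg["group4"] = [
            g if g in ("early-OWO", "late-OWO") else rng.choice(["NW-A", "NW-B"])
            for g in asg["group4"]
        ]
        X = pd.DataFrame(
            {
                "tag_like": -0.6 * (asg["group4"] == "early-OWO")
                + rng.standard_normal(len(asg)),
                "noise1": rng.standard_normal(len(asg)),
                "noise2": rng.standard_normal(len(asg)),
            },
            index=asg.index,
        )
        table, summary = explore_four_groups(X, asg)
        assert summary["collapse_recommended"]
        assert summary["counts"]["early-OWO"]["n_q"] >= 1
        assert set(table["level"]) == {"early-OWO", "late-OWO", "NW-B"}

    def test_member_followup_family_is_selected_members(self):
        asg, rng = make_outcome_frame(500, seed=9)
        part_members = {"red": ["m1", "m2"], "blue": ["m3"]}

        class FakePartition:
            def members(self, color):
                return part_members[color]

        X = pd.DataFrame(
            {m: rng.standard_normal(len(asg)) for m in ["m1", "m2", "m3"]},
            index=asg.index,
        )
        X["m1"] += (asg["group3"] == "early-OWO") * 0.8
        module_table = pd.DataFrame(
            {"exposure": ["red", "blue"], "level": ["early-OWO"] * 2, "p": [0.001, 0.8]}
        )
        out = member_followup(X, FakePartition(), module_table, asg)
        assert sorted(out["exposure"].unique()) == ["m1", "m2"]
        assert len(out) == 4  # two members x two contrasts

    def test_member_followup_empty_without_selection(self):
        asg, rng = make_outcome_frame(500, seed=9)

        class FakePartition:
            def members(self, color):  # pragma: no cover
                return []

        module_table = pd.DataFrame({"exposure": ["red"], "level": ["early-OWO"], "p": [0.9]})
        out = member_followup(pd.DataFrame(index=asg.index), FakePartition(), module_table, asg)
        assert out.empty


class TestSexInteraction:
    def test_single_sex_rejected(self):
        asg, rng = make_outcome_frame()
        sex = pd.Series("M", index=asg.index)
        with pytest.raises(ValueError):
            sex_interaction_lrt(asg["group3"], pd.Series(0.0, index=asg.index), sex)

    def test_planted_sex_specific_effect_detected(self):
        rng = np.random.default_rng(21)
        n = 900
        idx = [f"c{i}" for i in range(n)]
        sex = pd.Series(rng.choice(["F", "M"], n), index=idx)
        x = pd.Series(rng.standard_normal(n), index=idx)
        shift = np.where(sex == "F", 0.8, 0.0) * x
        logits = np.column_stack([np.zeros(n), shift, np.zeros(n)])
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        y = pd.Series(
            np.array(["NW", "early-OWO", "late-OWO"])[
                (rng.uniform(size=(n, 1)) > probs.cumsum(axis=1)).sum(axis=1)
            ],
            index=idx,
        )
        res = sex_interaction_lrt(y, x, sex)
        assert res["df"] == 4
        assert res["p"] < 0.01
        assert min(res["interaction_p"].values()) < 0.05


def test_covariate_design_unknown_is_own_level():
    cov = pd.DataFrame(
        {
            "sex": ["F", "M", "F"],
            "race": ["Black", "White", "Others"],
            "mat_owo": ["No", "Yes", "Unknown"],
        }
    )
    design = covariate_design(cov)
    assert "mat_owo[Unknown]" in design.columns
    assert "mat_owo[No]" not in design.columns  # reference level
    assert design.shape[0] == 3
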