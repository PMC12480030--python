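"""Logistic fits, BH-FDR, stepwise selection and PGS scan plumbing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from adrpgx import association as assoc
from adrpgx import simulate as sim
from adrpgx.fixtures import two_by_two_rows


def expand_2x2(a, b, c, d):
    """Rows for a 2x2 table: exposed (a cases, b controls), unexposed (c, d)."""
    return pd.DataFrame(
        {
            "case": [True] * a + [False] * b + [True] * c + [False] * d,
            "exposed": [1.0] * (a + b) + [0.0] * (c + d),
        }
    )


class TestFitLogistic:
    def test_cross_product_oracle(self):
        df = expand_2x2(20, 10, 15, 30)
        r = assoc.fit_logistic(df, "case", "exposed", standardise=False)[0]
        assert r.or_ == pytest.approx((20 * 30) / (10 * 15), rel=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(counts=st.tuples(*[st.integers(2, 200)] * 4))
    def test_cross_product_property(self, counts):
        """No-covariate logistic fit equals the closed-form OR to 6 s.f."""
        a, b, c, d = counts
        r = assoc.fit_logistic(expand_2x2(a, b, c, d), "case", "exposed", standardise=False)[0]
        assert r.or_ == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_categorical_levels_vs_reference(self):
        df = pd.DataFrame(
            {
                "case": [True] * 30 + [False] * 30,
                "level": (["poor"] * 12 + ["normal"] * 18) + (["poor"] * 6 + ["normal"] * 24),
            }
        )
        r = assoc.fit_logistic(df, "case", "level", reference="normal")[0]
        assert r.predictor == "level:poor"
        assert r.or_ == pytest.approx((12 * 24) / (6 * 18), rel=1e-6)

    def test_categorical_without_reference_raises(self):
        df = pd.DataFrame({"case": [True, False], "level": ["a", "b"]})
        with pytest.raises(ValueError, match="reference"):
            assoc.fit_logistic(df, "case", "level")

    def test_single_class_outcome_raises(self):
        df = pd.DataFrame({"case": [True, True], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="case and one control"):
            assoc.fit_logistic(df, "case", "x")

    def test_constant_predictor_raises(self):
        df = pd.DataFrame({"case": [True, False], "x": [1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            assoc.fit_logistic(df, "case", "x")

    def test_separation_is_flagged_not_raised(self):
        df = pd.DataFrame({"case": [True] * 20 + [False] * 20, "x": [1.0] * 20 + [0.0] * 20})
        r = assoc.fit_logistic(df, "case", "x", standardise=False)[0]
        assert r.flag in {"separation", "non_converged", "fit_error"}

    def test_standardised_continuous_effect(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=8_000) * 3.0  # non-unit SD: per-SD scaling must apply
        p = 1 / (1 + np.exp(-(0.2 * (x / 3.0))))
        df = pd.DataFrame({"case": rng.random(8_000) < p, "x": x})
        r = assoc.fit_logistic(df, "case", "x")[0]
        assert r.beta == pytest.approx(0.2, abs=0.08)

    def test_wald_ci_brackets_or(self):
        r = assoc.fit_logistic(two_by_two_rows("poor"), "case", "exposed", standardise=False)[0]
        assert r.ci_low < r.or_ < r.ci_high
        assert r.q >= r.p or np.isnan(r.q)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = assoc.bh_fdr([0.01, 0.02, 0.03, 0.04], 4)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert assoc.bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert np.allclose(assoc.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_family_larger_than_observed(self):
        q = assoc.bh_fdr([0.01], family_size=10)
        assert q == pytest.approx([0.1])

    def test_family_smaller_raises(self):
        with pytest.raises(ValueError, match="family_size"):
            assoc.bh_fdr([0.1, 0.2], family_size=1)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            assoc.bh_fdr([0.5, 1.5])

    def test_order_preserving(self):
        p = np.array([0.9, 0.001, 0.04, 0.3])
        q = assoc.bh_fdr(p)
        assert np.all(np.argsort(q, kind="stable") == np.argsort(p, kind="stable"))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_reference_implementation(self, p):
        ours = assoc.bh_fdr(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-12)


class TestStepwise:
    @staticmethod
    def simulate_pair(n, seed, beta_a=0.4, beta_b=0.0, rho=0.7):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        b = rho * a + np.sqrt(1 - rho**2) * rng.normal(size=n)
        p = 1 / (1 + np.exp(-(beta_a * a + beta_b * b)))
        return pd.DataFrame({"case": rng.random(n) < p, "A": a, "B": b})

    def test_single_strong_candidate_retained(self):
        df = self.simulate_pair(5_000, 1, beta_a=0.5, rho=0.0)
        selected, results = assoc.forward_stepwise(df, "case", ["A"])
        assert selected == ["A"]
        assert results[0].p < 0.05

    def test_no_candidate_below_alpha(self):
        df = self.simulate_pair(2_000, 2, beta_a=0.0, rho=0.0)
        selected, results = assoc.forward_stepwise(df, "case", ["A", "B"])
        assert selected == []
        assert results == []

    def test_empty_candidate_set(self):
        df = self.simulate_pair(500, 3)
        assert assoc.forward_stepwise(df, "case", []) == ([], [])

    def test_order_invariance(self):
        df = self.simulate_pair(5_000, 4, beta_a=0.4, beta_b=0.2)
        s1, r1 = assoc.forward_stepwise(df, "case", ["A", "B"])
        s2, r2 = assoc.forward_stepwise(df, "case", ["B", "A"])
        assert s1 == s2
        assert [(r.predictor, r.beta) for r in r1] == [(r.predictor, r.beta) for r in r2]

    def test_correlated_null_predictor_screened_out(self):
        """With rho=0.7 and one causal score, stepwise keeps the causal one
        first and drops its correlated shadow in ≥90% of replicates."""
        hits = shadow = 0
        for rep in range(60):
            df = self.simulate_pair(20_000, 100 + rep)
            selected, _ = assoc.forward_stepwise(df, "case", ["A", "B"])
            hits += bool(selected and selected[0] == "A")
            shadow += "B" in selected
        assert hits >= 54  # ≥90%
        assert shadow <= 6


@pytest.fixture(scope="module")
def cyp_table():
    cfg = sim.cyp2c19_scenario(n_samples=6_000, seed=17, poor_or=2.0)
    c = sim.simulate_cohort(cfg, include_records=False)
    return sim.analysis_table(c, via_caller=False)


class TestCyp2c19Scan:
    def test_four_levels_vs_normal(self, cyp_table):
        res = assoc.run_cyp2c19_scan(cyp_table)
        assert sorted(r.predictor for r in res) == [
            "metaboliser:intermediate",
            "metaboliser:poor",
            "metaboliser:rapid",
            "metaboliser:ultrarapid",
        ]
        assert all(r.group == "CYP2C19_SET" for r in res)

    def test_per_drug_strata(self, cyp_table):
        only_escit = cyp_table.copy()
        for d in ("citalopram", "sertraline", "amitriptyline"):
            only_escit[f"drug_{d}"] = False
        only_escit = only_escit.loc[only_escit["drug_escitalopram"]]
        res = assoc.run_cyp2c19_scan(only_escit, per_drug=True)
        strata = {r.group for r in res}
        assert strata == {"CYP2C19_SET", "escitalopram"}


class TestPlansAndScans:
    def test_plan_family_sizes(self):
        assert assoc.psychiatric_plan().family_size == 800
        assert assoc.trait_plan().family_size == 48

    def test_grey_cells_below_case_threshold(self, records_factory):
        rec = records_factory(
            [("S1", "nortriptyline", "chills", True, "ADEQ"),
             ("S2", "nortriptyline", "chills", False, "ADEQ")]
        )
        samples = pd.DataFrame(
            {"sample_id": ["S1", "S2"], "pgs_MDD": [0.1, -0.2], "birth_year": [1970, 1980],
             "female": [1, 0], **{f"pc{i}": [0.0, 0.1] for i in range(1, 11)}}
        )
        plan = assoc.ScanPlan(
            name="tiny", outcomes=("chills",), predictors={"chills": ("MDD",)}, groups=("TCA",)
        )
        res = assoc.run_pgs_scans(rec, samples, plan)
        assert len(res) == 1
        assert res[0].flag == "not_reported"
        assert np.isnan(res[0].p)


class TestPgsCorrelations:
    def test_identical_columns(self):
        x = np.random.default_rng(0).normal(size=500)
        corr, flagged = assoc.pgs_correlations(pd.DataFrame({"pgs_A": x, "pgs_B": x}))
        assert corr.loc["pgs_A", "pgs_B"] == pytest.approx(1.0)
        assert flagged == []

    def test_constant_column_flagged(self):
        corr, flagged = assoc.pgs_correlations(
            pd.DataFrame({"pgs_A": [1.0, 1.0, 1.0], "pgs_B": [0.1, 0.2, 0.3]})
        )
        assert flagged == ["pgs_A"]
        assert np.isnan(corr.loc["pgs_A", "pgs_B"])

    def test_single_score_raises(self):
        with pytest.raises(ValueError, match="two scores"):
            assoc.pgs_correlations(pd.DataFrame({"pgs_A": [0.1, 0.2]}))

    def test_configured_correlation_recovered(self):
        cfg = sim.CohortConfig(
            n_samples=100_000, seed=8, baseline_logit={"any": 0.0},
            pgs_names=("A", "B"), pgs_corr=np.array([[1.0, 0.6], [0.6, 1.0]]),
        )
        corr, _ = assoc.pgs_correlations(sim.simulate_pgs(cfg).drop(columns="sample_id"))
        assert corr.loc["pgs_A", "pgs_B"] == pytest.approx(0.6, abs=0.02)
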