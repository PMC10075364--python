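"""Outlier masks, mixed models, interaction dropping, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h
from scipy import stats as spstats

from hippolfp import stats as st


def brute_force_bh(p, alpha=0.05):
    """Step-up Benjamini-Hochberg from the definition (oracle)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q, q <= alpha


def cell_table(values_by_cell):
    rows = []
    for (g, state, trial), vals in values_by_cell.items():
        for k, v in enumerate(vals):
            rows.append({"subject": f"{g}{k}", "genotype": g, "state": state,
                         "trial": trial, "value": v})
    return pd.DataFrame(rows)


class TestT2Outliers:
    def test_identical_points_keep_all(self):
        tab = cell_table({("WT", "exploration", 1): [1.0] * 6})
        keep = st.t2_outliers(tab, value_cols=["value"])
        assert keep.all()

    def test_gross_outlier_excluded(self):
        vals = [1.0, 1.01, 0.99, 1.02, 0.98, 1.0, 1.01, 0.99, 1.0, 11.0]
        tab = cell_table({("WT", "exploration", 1): vals})
        keep = st.t2_outliers(tab, value_cols=["value"])
        assert not keep.iloc[-1]
        assert keep.iloc[:-1].all()
        # direct Hotelling T^2 oracle (univariate case): the flagged point
        # carries the overwhelmingly largest T^2
        x = np.asarray(vals)
        t2 = (x - x.mean()) ** 2 / x.var(ddof=1)
        assert np.argmax(t2) == 9

    def test_rerun_on_retained_excludes_no_more_than_before(self):
        rng = np.random.default_rng(1)
        vals = list(rng.normal(0, 1, 12)) + [8.0]
        tab = cell_table({("WT", "exploration", 1): vals})
        keep1 = st.t2_outliers(tab, value_cols=["value"])
        retained = tab[keep1]
        keep2 = st.t2_outliers(retained, value_cols=["value"])
        assert (~keep2).sum() <= (~keep1).sum()

    def test_mask_never_applied_in_place(self):
        tab = cell_table({("WT", "exploration", 1): [1, 2, 3, 4, 100.0]})
        n_before = len(tab)
        st.t2_outliers(tab, value_cols=["value"])
        assert len(tab) == n_before


def balanced_table(rng, n_per_genotype=4, genotype_effect=0.0,
                   subject_sd=0.0, resid_sd=1.0):
    rows = []
    for si in range(2 * n_per_genotype):
        g = "WT" if si < n_per_genotype else "TG"
        u = rng.normal(0, subject_sd) if subject_sd else 0.0
        for state in ["exploration", "wake_immobility"]:
            for trial in [1, 2]:
                mu = u + (genotype_effect if g == "TG" else 0.0)
                rows.append(
                    {"subject": f"s{si}", "genotype": g, "state": state,
                     "trial": trial, "value": rng.normal(mu, resid_sd)}
                )
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_zero_variance_response(self):
        tab = balanced_table(np.random.default_rng(0))
        tab["value"] = 3.14
        res = st.fit_lmm(tab)
        assert res.converged
        assert res.params["Intercept"] == pytest.approx(3.14)
        assert res.random_intercept_var == 0.0

    def test_matches_ols_on_balanced_no_random_structure(self):
        import statsmodels.formula.api as smf

        tab = balanced_table(np.random.default_rng(3))
        res = st.fit_lmm(tab)
        ols = smf.ols(res.formula, tab).fit()
        diff = np.abs(res.params[ols.params.index] - ols.params).max()
        assert diff < 1e-6

    def test_genotype_ci_coverage(self):
        # delta = 1.0, subject SD 0.5, residual SD 0.5, 20 subjects/group:
        # the Wald CI should cover the true effect in >= 90/100 replicates
        rng = np.random.default_rng(5)
        covered = 0
        for _ in range(100):
            rows = []
            for si in range(40):
                g = "WT" if si < 20 else "TG"
                u = rng.normal(0, 0.5)
                for trial in [1, 2]:
                    mu = u + (1.0 if g == "TG" else 0.0)
                    rows.append({"subject": f"s{si}", "genotype": g,
                                 "trial": trial,
                                 "value": rng.normal(mu, 0.5)})
            res = st.fit_lmm(pd.DataFrame(rows), fixed=("genotype", "trial"),
                             interactions=False)
            name = [k for k in res.params.index if "genotype" in k][0]
            est = res.params[name]
            # Wald CI from the estimate's z and p-value
            p = res.pvalues[name]
            z = spstats.norm.ppf(1 - p / 2)
            se = abs(est) / z if z > 0 else np.inf
            covered += abs(est - 1.0) <= 1.96 * se
        assert covered >= 90

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            st.fit_lmm(pd.DataFrame({"value": [1.0]}))


class TestRefitRule:
    def two_factor_table(self, interaction=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for si in range(10):
            g = "WT" if si < 5 else "TG"
            for trial in [1, 2]:
                mu = interaction if (g == "TG" and trial == 2) else 0.0
                rows.append({"subject": f"s{si}", "genotype": g,
                             "trial": trial,
                             "value": rng.normal(mu, 0.3)})
        return pd.DataFrame(rows)

    def test_nonsignificant_interaction_dropped(self):
        tab = self.two_factor_table(interaction=0.0, seed=1)
        full = st.fit_lmm(tab, fixed=("genotype", "trial"))
        assert full.term_p("genotype:trial") >= 0.05
        res = st.refit_without_interaction(full, tab)
        assert res.reduced
        assert not any(":" in _canon_name for _canon_name in res.pvalues.index)

    def test_significant_interaction_retained(self):
        tab = self.two_factor_table(interaction=3.0, seed=2)
        full = st.fit_lmm(tab, fixed=("genotype", "trial"))
        assert full.term_p("genotype:trial") < 0.05
        res = st.refit_without_interaction(full, tab)
        assert res is full and not res.reduced

    def test_orthogonal_design_main_effects_stable(self):
        tab = self.two_factor_table(interaction=0.0, seed=3)
        full = st.fit_lmm(tab, fixed=("genotype", "trial"))
        reduced = st.refit_without_interaction(full, tab)
        # balanced two-level factors are orthogonal: the genotype cell
        # contrast is unchanged up to the dropped term's reallocation
        name_full = [k for k in full.params.index
                     if "genotype" in k and ":" not in k][0]
        name_red = [k for k in reduced.params.index if "genotype" in k][0]
        inter = [k for k in full.params.index if ":" in k][0]
        assert full.params[name_full] + full.params[inter] / 2 == \
            pytest.approx(reduced.params[name_red], abs=1e-6)


class TestBhFdr:
    def test_single_p(self):
        q, rej = st.bh_fdr([0.03])
        assert q[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_computed_example(self):
        q, rej = st.bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert rej.all()

    def test_all_ones(self):
        q, rej = st.bh_fdr([1.0, 1.0, 1.0])
        assert np.all(q == 1.0) and not rej.any()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            st.bh_fdr([0.5, 1.5])

    def test_q_never_below_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 50)
        q, _ = st.bh_fdr(p)
        assert np.all(q >= p - 1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        p=st_h.lists(
            st_h.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=30
        )
    )
    def test_matches_brute_force_oracle(self, p):
        q, rej = st.bh_fdr(p)
        q_ref, rej_ref = brute_force_bh(p)
        np.testing.assert_allclose(q, q_ref, atol=1e-12)
        np.testing.assert_array_equal(rej, rej_ref)


class TestAnalyzeMeasure:
    def test_strong_effect_reaches_posthoc(self):
        rng = np.random.default_rng(7)
        tab = balanced_table(rng, n_per_genotype=5, genotype_effect=3.0,
                             subject_sd=0.3, resid_sd=0.3)
        res = st.analyze_measure(tab, design="three_factor")
        assert res.posthoc is not None
        assert res.posthoc["reject"].any()
        assert np.all(res.posthoc["q"] >= res.posthoc["p"] - 1e-12)
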