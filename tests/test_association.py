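"""Entry extraction, GEE fitting, probability estimation, Tukey contrasts."""

import math
import random

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from vapelens import simulate
from vapelens.association import (
    AssociationEntry,
    GEEFit,
    estimate_probabilities,
    extract_entries,
    fit_gee,
    heatmap_table,
    pairwise_tukey,
)

from conftest import make_post


def entry(user, flavor, health, pid="p0"):
    return AssociationEntry(user, pid, flavor, health)


class TestExtractEntries:
    def test_one_entry_per_distinct_health_keyword(self, health_tax, flavor_tax):
        posts = [make_post("strawberry vape: cough and a headache")]
        entries = extract_entries(posts, health_tax, flavor_tax)
        got = {(e.flavor_category, e.health_category) for e in entries}
        assert got == {("Fruit", "Respiratory"), ("Fruit", "Neurological")}
        assert all(e.user_id == "u1" for e in entries)

    def test_two_flavor_keywords_excluded(self, health_tax, flavor_tax):
        posts = [make_post("strawberry and menthol with a cough")]
        assert extract_entries(posts, health_tax, flavor_tax) == []

    def test_no_health_keyword_excluded(self, health_tax, flavor_tax):
        posts = [make_post("strawberry flavor is lovely")]
        assert extract_entries(posts, health_tax, flavor_tax) == []

    def test_repeated_flavor_keyword_still_single_type(self, health_tax, flavor_tax):
        posts = [make_post("mango mango mango and a cough")]
        entries = extract_entries(posts, health_tax, flavor_tax)
        assert [(e.flavor_category, e.health_category) for e in entries] == [
            ("Fruit", "Respiratory")
        ]


def _df(entries, health_category, levels=None):
    df = pd.DataFrame(
        {
            "user": [e.user_id for e in entries],
            "flavor": [e.flavor_category for e in entries],
            "y": [1.0 if e.health_category == health_category else 0.0
                  for e in entries],
        }
    )
    X = pd.get_dummies(df["flavor"]).astype(float)
    return df, X[sorted(X.columns) if levels is None else levels]


@pytest.fixture(scope="module")
def clustered_entries():
    config = simulate.SimulationConfig(n_users=600, user_effect_sd=1.0, seed=8)
    return simulate.generate_entries(config)


class TestFitGee:
    def test_reduces_to_empirical_proportions_without_clustering(self):
        rng = random.Random(0)
        entries = [
            entry(f"u{i}", rng.choice(["A", "B"]),
                  rng.choice(["H1", "H2", "H3"]), pid=f"p{i}")
            for i in range(400)
        ]
        fit = fit_gee(entries, "H1")
        probs = estimate_probabilities(fit)
        df = pd.DataFrame(
            [(e.flavor_category, e.health_category == "H1") for e in entries],
            columns=["f", "y"],
        )
        for level, grp in df.groupby("f"):
            assert probs[level].probability == pytest.approx(
                grp["y"].mean(), abs=1e-8
            )

    def test_independence_limit_matches_glm(self, clustered_entries):
        fit = fit_gee(clustered_entries, "Respiratory", corstr="independence")
        df, X = _df(clustered_entries, "Respiratory", fit.flavor_levels)
        glm = sm.GLM(df["y"], X, family=sm.families.Binomial()).fit()
        assert np.abs(fit.beta - glm.params.to_numpy()).max() < 1e-6

    def test_matches_statsmodels_gee(self, clustered_entries):
        fit = fit_gee(clustered_entries, "Throat")
        df, X = _df(clustered_entries, "Throat", fit.flavor_levels)
        smfit = sm.GEE(
            df["y"], X, groups=df["user"], family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        ).fit()
        assert np.abs(fit.beta - smfit.params.to_numpy()).max() < 1e-6
        assert np.abs(fit.se() - smfit.bse.to_numpy()).max() < 1e-6
        assert fit.alpha_hat == pytest.approx(
            smfit.cov_struct.dep_params, abs=1e-6
        )

    def test_sandwich_equals_hc0_with_one_entry_per_user(self):
        config = simulate.SimulationConfig(
            n_users=1500, entries_per_user=1, user_effect_sd=0.8, seed=4
        )
        entries = simulate.generate_entries(config)
        fit = fit_gee(entries, "Throat")
        df, X = _df(entries, "Throat", fit.flavor_levels)
        glm = sm.GLM(df["y"], X, family=sm.families.Binomial()).fit(cov_type="HC0")
        assert np.abs(fit.robust_cov - glm.cov_params().to_numpy()).max() < 1e-6

    def test_clustering_invariance_within_user(self, clustered_entries):
        fit_a = fit_gee(clustered_entries, "Respiratory")
        shuffled = clustered_entries[:]
        random.Random(3).shuffle(shuffled)
        fit_b = fit_gee(shuffled, "Respiratory")
        assert np.abs(fit_a.beta - fit_b.beta).max() < 1e-10
        assert fit_a.alpha_hat == pytest.approx(fit_b.alpha_hat, abs=1e-12)

    def test_boundary_level_flagged(self):
        entries = [entry(f"u{i}", "A", "H1", f"p{i}") for i in range(20)] + [
            entry(f"v{i}", "B", "H2", f"q{i}") for i in range(20)
        ]
        fit = fit_gee(entries, "H1")
        assert fit.boundary == {"A": 1, "B": 0}
        probs = estimate_probabilities(fit)
        assert probs["A"].probability == 1.0 and probs["A"].boundary
        assert probs["B"].probability == 0.0 and probs["B"].se is None

    def test_undersized_level_dropped_with_warning(self, clustered_entries):
        few = [entry("u1", "Rare", "Respiratory", "x1"),
               entry("u2", "Rare", "Throat", "x2")]
        with pytest.warns(UserWarning):
            fit = fit_gee(clustered_entries + few, "Respiratory", min_entries=10)
        assert "Rare" in fit.dropped_levels
        assert "Rare" not in fit.flavor_levels

    def test_positive_user_effect_yields_positive_alpha(self):
        config = simulate.SimulationConfig(n_users=2000, user_effect_sd=1.5, seed=9)
        entries = simulate.generate_entries(config)
        fit = fit_gee(entries, "Throat")
        assert fit.alpha_hat > 0.05
        assert fit.converged


class TestEstimateProbabilities:
    def _fit(self, beta, cov=None, levels=None):
        beta = np.asarray(beta, dtype=float)
        k = beta.size
        cov = np.eye(k) * 0.04 if cov is None else np.asarray(cov)
        return GEEFit(
            health_category="H",
            flavor_levels=levels or [f"F{i}" for i in range(k)],
            beta=beta,
            robust_cov=cov,
            alpha_hat=0.1,
            phi_hat=1.0,
            n_entries=100,
            n_users=50,
            converged=True,
            n_iter=3,
        )

    def test_zero_log_odds_is_half(self):
        probs = estimate_probabilities(self._fit([0.0]))
        assert probs["F0"].probability == pytest.approx(0.5)

    def test_logit_inverse_pair(self):
        probs = estimate_probabilities(self._fit([math.log(0.2 / 0.8)]))
        assert probs["F0"].probability == pytest.approx(0.2, abs=1e-12)

    def test_delta_method_se(self):
        fit = self._fit([0.0])
        probs = estimate_probabilities(fit)
        assert probs["F0"].se == pytest.approx(0.25 * 0.2)  # p(1-p)*se_beta

    def test_rows_sum_to_one_under_independence(self):
        """Cell means under the independence working model are empirical
        proportions, so probabilities across exhaustive health categories
        sum to 1 per flavor."""
        config = simulate.SimulationConfig(n_users=800, user_effect_sd=0.7, seed=12)
        entries = simulate.generate_entries(config)
        cats = sorted({e.health_category for e in entries})
        fits = [fit_gee(entries, c, corstr="independence") for c in cats]
        table = heatmap_table(fits)
        sums = table.sum(axis=1, skipna=False)
        assert np.allclose(sums.to_numpy(dtype=float), 1.0, atol=1e-8)


class TestPairwiseTukey:
    def _fit(self, beta, cov, levels=None):
        beta = np.asarray(beta, dtype=float)
        return GEEFit(
            health_category="H",
            flavor_levels=levels or [f"F{i}" for i in range(beta.size)],
            beta=beta,
            robust_cov=np.asarray(cov, dtype=float),
            alpha_hat=0.0,
            phi_hat=1.0,
            n_entries=100,
            n_users=100,
            converged=True,
            n_iter=2,
        )

    def test_equal_coefficients_give_p_one(self):
        fit = self._fit([0.3, 0.3], np.eye(2) * 0.01)
        (c,) = pairwise_tukey(fit)
        assert c.z == pytest.approx(0.0) and c.p_adj == pytest.approx(1.0)

    def test_k2_reduces_to_unadjusted_normal(self):
        fit = self._fit([0.9, 0.3], np.eye(2) * 0.02)
        (c,) = pairwise_tukey(fit)
        p_normal = 2 * stats.norm.sf(abs(c.z))
        assert c.p_adj == pytest.approx(p_normal, abs=1e-6)

    def test_k6_adjustment_exceeds_unadjusted(self):
        beta = np.array([3.5 * 0.1, 0, 0, 0, 0, 0])
        fit = self._fit(beta, np.eye(6) * 0.005)  # se of contrast = 0.1
        contrasts = pairwise_tukey(fit)
        big = next(c for c in contrasts if abs(c.z) > 3.4)
        assert big.p_adj > 2 * stats.norm.sf(abs(big.z))

    def test_tukey_bounds(self, clustered_entries):
        fit = fit_gee(clustered_entries, "Respiratory")
        k = len(fit.flavor_levels)
        m = k * (k - 1) / 2
        for c in pairwise_tukey(fit):
            p_unadj = 2 * stats.norm.sf(abs(c.z))
            assert p_unadj - 1e-12 <= c.p_adj <= min(1.0, m * p_unadj) + 1e-12

    def test_number_of_contrasts(self, clustered_entries):
        fit = fit_gee(clustered_entries, "Respiratory")
        k = len(fit.flavor_levels)
        assert len(pairwise_tukey(fit)) == k * (k - 1) // 2

    def test_degenerate_se_flagged(self):
        fit = self._fit([0.5, 0.1], np.zeros((2, 2)))
        (c,) = pairwise_tukey(fit)
        assert c.degenerate and c.p_adj == 1.0 and not c.significant

    def test_significance_flag_matches_threshold(self, clustered_entries):
        fit = fit_gee(clustered_entries, "Throat")
        for c in pairwise_tukey(fit):
            assert c.significant == (c.p_adj < 0.05)


class TestHeatmapTable:
    def test_shape_and_orientation(self, clustered_entries):
        cats = sorted({e.health_category for e in clustered_entries})
        fits = [fit_gee(clustered_entries, c) for c in cats]
        table = heatmap_table(fits)
        assert table.shape == (6, len(cats))
        assert table.index.name == "flavor"

    def test_excluded_cell_is_missing(self):
        fits = [
            fit_gee(
                [entry(f"u{i}", "A", ["H1", "H2"][i % 2], f"p{i}")
                 for i in range(40)],
                "H1",
            )
        ]
        table = heatmap_table(fits, flavor_order=["A", "Z"], health_order=["H1"])
        assert np.isnan(table.loc["Z", "H1"])
        assert table.loc["A", "H1"] == pytest.approx(0.5, abs=0.2)
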