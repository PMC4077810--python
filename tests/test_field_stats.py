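import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from floodsel import field_stats, simulate


class TestBiomassFormulas:
    @pytest.mark.parametrize(
        "x, expected", [(1.0, 158.0), (4.0, 1949.0), (0.0, -1633.0)]
    )
    def test_dpm_calibration_values(self, x, expected):
        assert field_stats.dpm_biomass(x) == pytest.approx(expected)

    def test_negative_height_rejected(self):
        with pytest.raises(ValueError):
            field_stats.dpm_biomass(-0.1)

    @settings(derandomize=True, max_examples=50)
    @given(x=st.floats(0.0, 100.0), dx=st.floats(0.01, 10.0))
    def test_dpm_strictly_increasing(self, x, dx):
        assert field_stats.dpm_biomass(x + dx) > field_stats.dpm_biomass(x)

    @pytest.mark.parametrize(
        "weights, expected",
        [((30, 20, 40, 30), 1200.0), ((0, 0, 0, 0), 0.0),
         ((25, 25, 25, 25), 1000.0)],
    )
    def test_quadrat_conversion(self, weights, expected):
        assert field_stats.quadrat_biomass(weights) == expected

    def test_quadrat_count_enforced(self):
        with pytest.raises(ValueError):
            field_stats.quadrat_biomass([10, 20, 30])

    def test_below_calibration_flagged_not_clamped(self, field_records):
        tab = field_stats.biomass_table(field_records)
        assert (tab.loc[tab["below_calibration"], "biomass_kg_ha"] < 0).all()


class TestBiomassYearModel:
    @staticmethod
    def samples(rng, effect=0.0, n=30):
        rows = []
        for year in (2008, 2009):
            for hab in (1, 2, 3, 4):
                mu = np.log(2000.0)
                if year == 2009 and hab in (1, 2):
                    mu += effect
                rows.extend(
                    {"habitat": hab, "year": year,
                     "biomass_kg_ha": float(np.exp(rng.normal(mu, 0.3)))}
                    for _ in range(n)
                )
        return pd.DataFrame(rows)

    def test_no_effect_gives_tiny_interaction(self, rng):
        res = field_stats.biomass_year_model(self.samples(rng, effect=0.0))
        assert res["interaction_p"] > 0.01

    def test_coefficients_match_normal_equations(self, rng):
        df = self.samples(rng, effect=-0.5, n=10)
        res = field_stats.biomass_year_model(df)
        y = np.log(df["biomass_kg_ha"].to_numpy())
        X = [np.ones(len(df))]
        X.append((df["year"] == 2009).to_numpy(float))
        for h in (2, 3, 4):
            X.append((df["habitat"] == h).to_numpy(float))
        for h in (2, 3, 4):
            X.append(((df["habitat"] == h) & (df["year"] == 2009)).to_numpy(float))
        X = np.column_stack(X)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res["model"].params, beta, atol=1e-10)

    def test_floodplain_reduction_detected(self, rng):
        """Power: a halving of floodplain biomass in year 2 yields a
        significant year x habitat interaction in >= 90% of replicates."""
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            res = field_stats.biomass_year_model(
                self.samples(rng, effect=np.log(0.5), n=30)
            )
            hits += res["interaction_p"] < 0.05
        assert hits / n_rep >= 0.90


class TestDemography:
    def test_simple_ratios(self):
        herds = pd.DataFrame(
            [{"herd_id": "H1", "year": 2008, "adult_male": 4, "adult_female": 10,
              "subadult": 3, "young": 5, "calf": 0}]
        )
        per_herd, _ = field_stats.demographic_ratios(herds)
        assert per_herd["young_per_adult_female"].iloc[0] == 0.5
        assert per_herd["calf_per_adult_female"].iloc[0] == 0.0

    def test_zero_adult_females_excluded_with_warning(self):
        herds = pd.DataFrame(
            [
                {"herd_id": "H1", "year": 2008, "adult_male": 1,
                 "adult_female": 0, "subadult": 0, "young": 0, "calf": 0},
                {"herd_id": "H2", "year": 2008, "adult_male": 2,
                 "adult_female": 10, "subadult": 1, "young": 4, "calf": 2},
            ]
        )
        with pytest.warns(UserWarning, match="zero adult females"):
            per_herd, summary = field_stats.demographic_ratios(herds)
        assert len(per_herd) == 1

    def test_summary_matches_brute_force(self, field_records):
        per_herd, summary = field_stats.demographic_ratios(field_records.herds)
        row = summary.set_index(["ratio", "year"]).loc[
            ("calf_per_adult_female", 2008)
        ]
        vals = per_herd.loc[per_herd["year"] == 2008, "calf_per_adult_female"]
        assert row["mean"] == pytest.approx(vals.mean())
        assert row["sd"] == pytest.approx(vals.std(ddof=1))
        assert row["n_herds"] == len(vals)


def newton_binomial_logit(successes, totals, x, tol=1e-12):
    """Independent Newton solve of the binomial logistic likelihood."""
    X = np.column_stack([np.ones_like(x, dtype=float), x])
    beta = np.zeros(2)
    for _ in range(100):
        p = 1 / (1 + np.exp(-(X @ beta)))
        grad = X.T @ (successes - totals * p)
        W = totals * p * (1 - p)
        H = X.T @ (X * W[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


class TestRatioYearTest:
    def test_equal_proportions_give_null_result(self, rng):
        totals = rng.integers(20, 40, size=40)
        successes = rng.binomial(totals, 0.2)
        year = np.repeat([2008, 2009], 20)
        # force identical pooled proportions across years
        res = field_stats.ratio_year_test(successes, totals, year,
                                          family="binomial")
        assert abs(res["effect"]) < 0.5
        assert res["p"] > 0.05

    def test_matches_independent_newton_solve(self, rng):
        totals = rng.integers(15, 45, size=30)
        year = np.repeat([2008, 2009], 15)
        successes = rng.binomial(totals, np.where(year == 2008, 0.25, 0.15))
        res = field_stats.ratio_year_test(successes, totals, year,
                                          family="binomial")
        beta = newton_binomial_logit(successes.astype(float),
                                     totals.astype(float),
                                     (year == 2009).astype(float))
        assert res["effect"] == pytest.approx(beta[1], abs=1e-8)

    def test_quasibinomial_scales_se_and_uses_t(self, rng):
        totals = rng.integers(15, 45, size=30)
        year = np.repeat([2008, 2009], 15)
        successes = rng.binomial(totals, np.where(year == 2008, 0.25, 0.15))
        b = field_stats.ratio_year_test(successes, totals, year, "binomial")
        q = field_stats.ratio_year_test(successes, totals, year, "quasibinomial")
        assert q["df"] == 28
        assert q["effect"] == pytest.approx(b["effect"])
        assert q["stat"] == pytest.approx(b["stat"] / np.sqrt(q["dispersion"]))

    def test_year_effect_power(self, rng):
        """p=0.20 vs 0.15 with 200 herds/year is detected in >= 80% of runs."""
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            totals = rng.integers(20, 45, size=400)
            year = np.repeat([2008, 2009], 200)
            successes = rng.binomial(totals, np.where(year == 2008, 0.20, 0.15))
            res = field_stats.ratio_year_test(successes, totals, year,
                                              family="binomial")
            hits += (res["p"] < 0.05) and (res["effect"] < 0)
        assert hits / n_rep >= 0.80


class TestBCSOrdinal:
    def test_fit_matches_independent_optimiser(self, field_records):
        from scipy.optimize import minimize

        model = field_stats.bcs_ordinal_fit(field_records.bcs)
        df = field_stats._expand_bcs(field_records.bcs)
        X, cols = field_stats._design(df)
        scores = df["score"].to_numpy()
        n_cut = df["score"].nunique() - 1

        def neg(params):
            return -field_stats.bcs_loglik(params, scores, X, n_cut)

        start = np.r_[np.linspace(-2, 2, n_cut), np.zeros(X.shape[1])]
        res = minimize(neg, start, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-8,
                                "fatol": 1e-10})
        assert model.llf == pytest.approx(-res.fun, abs=1e-4)

    def test_cutpoints_increase_and_probs_sum_to_one(self, field_records):
        model = field_stats.bcs_ordinal_fit(field_records.bcs)
        assert (np.diff(model.cutpoints) > 0).all()
        for eta in (-1.0, 0.0, 2.0):
            assert model.category_probs(eta).sum() == pytest.approx(1.0)

    def test_positive_year_shift_raises_mean_bcs(self, landscape):
        params = simulate.BCSParams(year_effect=0.8, herd_sd=0.0)
        rec = simulate.simulate_field_records(
            landscape, {2008: 0.3, 2009: 0.8}, bcs_params=params,
            n_herds=40, n_sites_per_habitat=0, seed=21,
        )
        model = field_stats.bcs_ordinal_fit(rec.bcs)
        assert model.coefficients["year[2009]"] > 0
        df = field_stats._expand_bcs(rec.bcs)
        assert (df.loc[df.year == 2009, "score"].mean()
                > df.loc[df.year == 2008, "score"].mean())

    def test_laplace_random_intercept_recovers_herd_sd(self, landscape):
        params = simulate.BCSParams(year_effect=0.5, herd_sd=0.5)
        rec = simulate.simulate_field_records(
            landscape, {2008: 0.3, 2009: 0.8}, bcs_params=params,
            n_herds=25, n_sites_per_habitat=0, seed=2,
        )
        model = field_stats.bcs_ordinal_fit(rec.bcs, random_herd=True)
        assert 0.2 < model.herd_sd < 1.0
        assert model.coefficients["year[2009]"] > 0
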