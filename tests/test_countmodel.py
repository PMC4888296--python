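"""Hierarchical count model: structure, R-hat, recovery, adjusted counts."""

import numpy as np
import pandas as pd
import pytest

from exurban.countmodel import CountModelResults, HierarchicalCountModel, gelman_rubin

from conftest import simulate_count_table


@pytest.fixture(scope="module")
def small_fit():
    df, truth = simulate_count_table(0, n_stops=12, n_routes=3)
    model = HierarchicalCountModel(df)
    return model, model.fit(draws=600, warmup=600, chains=2, seed=1), truth


class TestBuildValidation:
    def base_df(self):
        df, _ = simulate_count_table(1, n_stops=4, n_routes=2)
        return df

    def test_single_observer_rejected(self):
        df = self.base_df()
        df["observer_id"] = "O1"
        with pytest.raises(ValueError, match="observer"):
            HierarchicalCountModel(df)

    def test_single_year_rejected(self):
        df = self.base_df()
        df = df[df.year == df.year.iloc[0]]
        with pytest.raises(ValueError, match="year"):
            HierarchicalCountModel(df)

    def test_duplicate_stop_year_rejected(self):
        df = self.base_df()
        with pytest.raises(ValueError, match="unique"):
            HierarchicalCountModel(pd.concat([df, df.iloc[:1]]))

    def test_negative_count_rejected(self):
        df = self.base_df()
        df.loc[df.index[0], "count"] = -1
        with pytest.raises(ValueError):
            HierarchicalCountModel(df)

    def test_structure_sizes(self):
        df = self.base_df()
        m = HierarchicalCountModel(df)
        assert len(m.stops) == 4
        assert len(m.route_levels) == 2 * df.year.nunique()  # route x year
        m2 = HierarchicalCountModel(df, route_by_year=False)
        assert len(m2.route_levels) == 2

    def test_linear_predictor_arithmetic(self):
        df = self.base_df()
        m = HierarchicalCountModel(df)
        th = {
            "b0": np.full(len(m.stops), np.log(5.0)),
            "b1": np.zeros(len(m.stops)),
            "b2": 0.0,
            "u_route": np.zeros(len(m.route_levels)),
            "u_obs": np.zeros(len(m.observers)),
            "u_err": np.zeros(m.n_records),
        }
        assert np.exp(m._linpred(th)) == pytest.approx(np.full(m.n_records, 5.0))


class TestGelmanRubin:
    def test_identical_chains_give_one(self, rng):
        # split R-hat of duplicated chains is 1 up to the O(1/n) split bias
        x = rng.normal(size=500)
        assert gelman_rubin(np.stack([x, x])) == pytest.approx(1.0, abs=5e-3)

    def test_separated_chains_flagged(self, rng):
        a = rng.normal(0, 1, 1000)
        b = rng.normal(10, 1, 1000)
        assert gelman_rubin(np.stack([a, b])) > 1.1

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=(2, 400))
        # independent split-R-hat computation straight from the formula
        halves = np.concatenate([x[:, :200], x[:, 200:]], axis=0)
        n = 200
        w = halves.var(axis=1, ddof=1).mean()
        b = n * halves.mean(axis=1).var(ddof=1)
        want = np.sqrt(((n - 1) / n * w + b / n) / w)
        assert gelman_rubin(x) == pytest.approx(want, abs=1e-10)

    def test_matches_arviz_split_rhat(self, rng):
        az = pytest.importorskip("arviz")
        x = rng.normal(size=(2, 500))
        want = float(az.rhat(x, method="split"))
        assert gelman_rubin(x) == pytest.approx(want, rel=1e-9)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestFit:
    def test_seed_reproducible(self):
        df, _ = simulate_count_table(2, n_stops=6, n_routes=2)
        m = HierarchicalCountModel(df)
        r1 = m.fit(draws=80, warmup=80, chains=2, seed=5)
        r2 = m.fit(draws=80, warmup=80, chains=2, seed=5)
        for k in r1.draws:
            assert np.array_equal(r1.draws[k], r2.draws[k])

    def test_different_seeds_differ(self):
        df, _ = simulate_count_table(2, n_stops=6, n_routes=2)
        m = HierarchicalCountModel(df)
        r1 = m.fit(draws=80, warmup=80, chains=2, seed=5)
        r2 = m.fit(draws=80, warmup=80, chains=2, seed=6)
        assert not np.array_equal(r1.draws["b2"], r2.draws["b2"])

    def test_single_chain_rejected(self):
        df, _ = simulate_count_table(2, n_stops=6, n_routes=2)
        with pytest.raises(ValueError):
            HierarchicalCountModel(df).fit(chains=1)

    def test_posterior_recovers_b2_interval(self, small_fit):
        _, res, truth = small_fit
        s = res.summary()
        assert s.loc["b2", "q2.5"] <= truth["b2"] <= s.loc["b2", "q97.5"]

    def test_zero_overdispersion_scale_concentrates(self):
        df, _ = simulate_count_table(3, n_stops=20, s_err=0.0)
        res = HierarchicalCountModel(df).fit(draws=1200, warmup=1200, chains=2, seed=2)
        s = res.summary()
        assert s.loc["s_err", "median"] < 0.25

    def test_fixed_effects_limit_matches_poisson_glm(self):
        """With all random-effect scales pinned near zero, the posterior mean
        approaches the fixed-effects Poisson regression fit (IRLS oracle)."""
        import statsmodels.api as sm

        df, _ = simulate_count_table(
            4, n_stops=10, n_routes=2, s_route=0.0, s_obs=0.0, s_err=0.0, b2=-0.4
        )
        m = HierarchicalCountModel(df)
        res = m.fit(
            draws=1500,
            warmup=1500,
            chains=2,
            seed=3,
            fixed_scales={"route": 1e-4, "observer": 1e-4, "error": 1e-4},
        )
        # oracle: Poisson GLM with stop intercepts, stop trends, first-year
        stop_d = pd.get_dummies(df["stop_id"]).to_numpy(float)
        x_year = ((df["year"] - np.unique(df["year"]).mean()) / 10).to_numpy()
        X = np.column_stack([stop_d, stop_d * x_year[:, None], df["first_year"]])
        glm = sm.GLM(df["count"].to_numpy(), X, family=sm.families.Poisson()).fit()
        got_b2 = res.summary().loc["b2", "mean"]
        assert got_b2 == pytest.approx(glm.params[-1], abs=0.08)
        got_b0 = res.draws["b0"].reshape(-1, 10).mean(axis=0)
        assert np.allclose(got_b0, glm.params[:10], atol=0.15)


class TestAdjustedCounts:
    def test_all_effects_zero_gives_baseline(self, small_fit):
        model, res, _ = small_fit
        frozen = CountModelResults(
            model,
            {
                "b0": np.full((2, 50, len(model.stops)), np.log(5.0)),
                "b1": np.zeros((2, 50, len(model.stops))),
                "b2": np.zeros((2, 50)),
                "u_route": np.zeros((2, 50, len(model.route_levels))),
                "u_obs": np.zeros((2, 50, len(model.observers))),
                "s_route": np.full((2, 50), 0.1),
                "s_obs": np.full((2, 50), 0.1),
                "s_err": np.full((2, 50), 0.1),
            },
        )
        adj = frozen.adjusted_counts(force=True)
        assert adj["adjusted_count"].to_numpy() == pytest.approx(5.0)
        assert (adj["q2.5"] <= adj["median"]).all()
        assert (adj["median"] <= adj["q97.5"]).all()

    def test_counts_strictly_positive(self, small_fit):
        _, res, _ = small_fit
        adj = res.adjusted_counts(force=True)
        assert (adj["adjusted_count"] > 0).all()

    def test_observer_relabelling_invariance(self):
        df, _ = simulate_count_table(5, n_stops=6, n_routes=2)
        m1 = HierarchicalCountModel(df)
        relabel = {o: f"Z{i}" for i, o in enumerate(sorted(df["observer_id"].unique()))}
        df2 = df.assign(observer_id=df["observer_id"].map(relabel))
        m2 = HierarchicalCountModel(df2)
        r1 = m1.fit(draws=100, warmup=100, chains=2, seed=9)
        r2 = m2.fit(draws=100, warmup=100, chains=2, seed=9)
        a1 = r1.adjusted_counts(force=True)["adjusted_count"]
        a2 = r2.adjusted_counts(force=True)["adjusted_count"]
        assert np.allclose(a1, a2)

    def test_nonconverged_refusal(self, small_fit):
        model, res, _ = small_fit
        bad = {k: v.copy() for k, v in res.draws.items()}
        bad["b2"] = np.stack(
            [np.zeros_like(res.draws["b2"][0]), np.ones_like(res.draws["b2"][1]) * 8]
        )
        frozen = CountModelResults(model, bad)
        with pytest.raises(RuntimeError, match="R-hat"):
            frozen.adjusted_counts()
        assert len(frozen.adjusted_counts(force=True)) == model.n_records

    def test_recovered_trend_close_to_truth(self):
        """Simulated ~3%/yr (0.35/decade) stop trend is recovered within one
        percentage point per year on the adjusted-count scale."""
        df, _ = simulate_count_table(
            6, n_stops=40, trend_mean=0.35, s_route=0.1, s_obs=0.1, s_err=0.1
        )
        res = HierarchicalCountModel(df).fit(
            draws=1500, warmup=1500, chains=2, seed=4
        )
        adj = res.adjusted_counts(force=True, include_route=False)
        mean_by_year = adj.groupby("year")["adjusted_count"].mean()
        years = mean_by_year.index.to_numpy(float)
        slope = np.polyfit(years, np.log(mean_by_year.to_numpy()), 1)[0]
        assert slope * 10 == pytest.approx(0.35, abs=0.1)
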