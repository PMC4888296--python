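"""TITAN: indicator values, change-point scan, bootstrap diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exurban.titan import (
    Titan,
    TitanConfig,
    bootstrap_diagnostics,
    change_point_scan,
    indval,
    run_titan,
)


def step_species(n=30, cp=50.0, low=0.0, high=10.0, env_max=100.0):
    env = np.linspace(0, env_max, n)
    return np.where(env >= cp, high, low), env


class TestIndval:
    def test_perfect_low_indicator(self):
        a = np.array([3.0, 3.0, 3.0, 0.0, 0.0, 0.0])
        hi = np.array([False, False, False, True, True, True])
        iv = indval(a, hi)
        assert iv["IndVal_low"] == 100.0
        assert iv["IndVal_high"] == 0.0

    def test_uniform_abundance_symmetric(self):
        a = np.full(8, 2.5)
        hi = np.arange(8) >= 4
        iv = indval(a, hi)
        assert iv["IndVal_low"] == pytest.approx(50.0)
        assert iv["IndVal_high"] == pytest.approx(50.0)

    def test_hand_computed_example(self):
        # low {2, 0}: A=0.2, B=0.5 -> 10; high {4, 4}: A=0.8, B=1 -> 80
        iv = indval(np.array([2.0, 0.0, 4.0, 4.0]), np.array([0, 0, 1, 1], bool))
        assert iv["IndVal_low"] == pytest.approx(10.0)
        assert iv["IndVal_high"] == pytest.approx(80.0)

    def test_absent_species_raises(self):
        with pytest.raises(ValueError):
            indval(np.zeros(4), np.array([0, 0, 1, 1], bool))

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            indval(np.ones(4), np.zeros(4, bool))


class TestChangePointScan:
    def test_step_species_recovered(self):
        a, env = step_species()
        res = change_point_scan(a, env, TitanConfig(n_perm=250), rng=np.random.default_rng(0))
        gap = env[1] - env[0]
        assert res["direction"] == "z+"
        assert abs(res["cp"] - 50.0) <= gap
        assert res["p"] <= 0.01

    def test_mirrored_gradient_flips_direction(self):
        a, env = step_species()
        r1 = change_point_scan(a, env, rng=np.random.default_rng(1))
        r2 = change_point_scan(a, -env, rng=np.random.default_rng(1))
        assert r1["direction"] == "z+" and r2["direction"] == "z-"
        assert r2["cp"] == pytest.approx(-r1["cp"])

    def test_z_scale_invariance(self):
        a, env = step_species(low=1.0)
        perm = np.random.default_rng(3).permuted(
            np.broadcast_to(np.arange(30), (100, 30)).copy(), axis=1
        )
        r1 = change_point_scan(a, env, perm_index=perm)
        r2 = change_point_scan(7.5 * a, env, perm_index=perm)
        assert r1["z"] == pytest.approx(r2["z"])
        assert r1["cp"] == r2["cp"]

    def test_change_point_inside_range_with_min_split(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            env = np.sort(rng.uniform(0, 100, 24))
            a = rng.poisson(3.0, 24).astype(float)
            if a.sum() == 0:
                continue
            res = change_point_scan(a, env, TitanConfig(n_perm=50), rng=rng)
            assert env[4] <= res["cp"] <= env[-5]

    def test_too_few_sites_raises(self):
        with pytest.raises(ValueError):
            change_point_scan(np.ones(8), np.arange(8.0), TitanConfig(min_split=5))

    def test_tied_env_collapse_to_single_candidate(self):
        env = np.repeat([0.0, 10.0], 6)
        a = np.where(env > 5, 4.0, 0.0)
        res = change_point_scan(a, env, TitanConfig(min_split=3, n_perm=99),
                                rng=np.random.default_rng(0))
        assert res["cp"] == pytest.approx(5.0)

    def test_exhaustive_oracle_small_case(self):
        """Independent re-computation over all candidate partitions with an
        exactly enumerated permutation set reproduces the selection."""
        rng = np.random.default_rng(5)
        n = 9
        env = np.sort(rng.uniform(0, 100, n))
        a = rng.poisson(2.0, n).astype(float) + np.where(env > 40, 3.0, 0.0)
        perms = np.array(list(itertools.permutations(range(n)))[:: 5040 // 120][:120])
        cfg = TitanConfig(min_split=3, n_perm=len(perms))
        res = change_point_scan(a, env, cfg, perm_index=perms)

        # --- oracle: direct loops over partitions, sides, permutations
        def iv(vals, split):
            lo, hi = vals[:split], vals[split:]
            A_lo = lo.mean() / (lo.mean() + hi.mean())
            A_hi = hi.mean() / (lo.mean() + hi.mean())
            return (
                100 * A_lo * (lo > 0).mean(),
                100 * A_hi * (hi > 0).mean(),
            )

        splits = [
            k
            for k in range(cfg.min_split, n - cfg.min_split + 1)
            if env[k - 1] < env[k]
        ]
        best = None
        for ci, k in enumerate(splits):
            obs = iv(a, k)
            for side in (0, 1):
                null = [iv(a[p], k)[side] for p in perms]
                mu, sd = np.mean(null), np.std(null, ddof=1)
                z = (obs[side] - mu) / sd if sd > 0 else 0.0
                if best is None or z > best[0]:
                    best = (z, (env[k - 1] + env[k]) / 2, "z+" if side else "z-")
        assert res["direction"] == best[2]
        assert res["cp"] == pytest.approx(best[1])
        assert res["z"] == pytest.approx(best[0])

    def test_null_type_i_error(self, rng):
        """Environment-independent species reach p <= 0.05 at ~5% rate."""
        n = 30
        env = np.linspace(0, 100, n)
        cfg = TitanConfig(n_perm=99)
        hits = 0
        n_rep = 150
        for _ in range(n_rep):
            a = rng.poisson(5.0, n).astype(float)
            res = change_point_scan(a, env, cfg, rng=rng, warn_zero_sd=False)
            hits += res["p"] <= 0.05
        assert 0.01 <= hits / n_rep <= 0.11


class TestBootstrap:
    def test_noiseless_step_pure_and_reliable(self):
        a, env = step_species()
        cfg = TitanConfig(n_perm=99, n_boot=99)
        rng = np.random.default_rng(0)
        obs = change_point_scan(a, env, cfg, rng=rng)
        boot = bootstrap_diagnostics(a, env, cfg, obs, rng=rng)
        assert boot["purity"] == 1.0
        assert boot["reliability"] == 1.0
        assert boot["cp_q_high"] - boot["cp_q_low"] < 15.0

    def test_single_bootstrap_quantiles_degenerate(self):
        a, env = step_species()
        cfg = TitanConfig(n_perm=50, n_boot=1)
        rng = np.random.default_rng(1)
        obs = change_point_scan(a, env, cfg, rng=rng)
        boot = bootstrap_diagnostics(a, env, cfg, obs, rng=rng)
        assert boot["cp_q_low"] == boot["cp_q_high"]

    def test_noise_species_low_quality(self, rng):
        n = 40
        env = np.linspace(0, 100, n)
        cfg = TitanConfig(n_perm=99, n_boot=60)
        weak = 0
        n_rep = 15
        for _ in range(n_rep):
            a = rng.poisson(5.0, n).astype(float)
            obs = change_point_scan(a, env, cfg, rng=rng, warn_zero_sd=False)
            boot = bootstrap_diagnostics(a, env, cfg, obs, rng=rng)
            weak += boot["reliability"] < 0.9
        assert weak >= n_rep - 2


class TestRunTitan:
    def make_community(self, rng, n_sites=60):
        env = np.sort(rng.uniform(0, 100, n_sites))
        data = {}
        truth = {}
        for i in range(4):
            cp = rng.uniform(25, 75)
            a = np.where(env >= cp, 6.0, 0.5) * rng.lognormal(0, 0.1, n_sites)
            data[f"up{i}"] = a
            truth[f"up{i}"] = "z+"
        for i in range(2):
            cp = rng.uniform(25, 75)
            data[f"down{i}"] = np.where(env < cp, 6.0, 0.5)
            truth[f"down{i}"] = "z-"
        return env, pd.DataFrame(data), truth

    def test_directions_recovered_and_rows_complete(self, rng):
        env, abund, truth = self.make_community(rng)
        cfg = TitanConfig(n_perm=99, n_boot=50)
        table = run_titan(env, abund, cfg, seed=2).set_index("species")
        assert len(table) == 6
        for sp, want in truth.items():
            assert table.loc[sp, "direction"] == want

    def test_fixed_seed_reproducible(self, rng):
        env, abund, _ = self.make_community(rng, n_sites=30)
        cfg = TitanConfig(n_perm=50, n_boot=30)
        t1 = run_titan(env, abund, cfg, seed=9)
        t2 = run_titan(env, abund, cfg, seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_species_table(self):
        table = run_titan(np.arange(12.0), pd.DataFrame(index=range(12)), seed=0)
        assert table.empty

    def test_column_permutation_permutes_rows_only(self, rng):
        env, abund, _ = self.make_community(rng, n_sites=30)
        cfg = TitanConfig(n_perm=50, n_boot=30)
        t1 = run_titan(env, abund, cfg, seed=5).set_index("species").sort_index()
        cols = list(abund.columns)[::-1]
        t2 = run_titan(env, abund[cols], cfg, seed=5).set_index("species").sort_index()
        pd.testing.assert_frame_equal(t1, t2)

    def test_all_zero_species_dropped(self, rng):
        env = np.linspace(0, 100, 20)
        abund = pd.DataFrame({"a": np.ones(20), "zero": np.zeros(20)})
        model = Titan(env, abund, TitanConfig(n_perm=20, n_boot=10))
        assert model.dropped_species == ["zero"]

    def test_undefined_env_sites_excluded(self, rng):
        env = np.linspace(0, 100, 20)
        env[3] = np.nan
        abund = pd.DataFrame({"a": rng.poisson(3.0, 20).astype(float) + 1})
        model = Titan(env, abund, TitanConfig(n_perm=20, n_boot=10))
        assert model.n_dropped_sites == 1
        assert len(model.env) == 19

    def test_row_level_error_status(self):
        env = np.repeat(5.0, 12)  # constant env: no valid candidate
        abund = pd.DataFrame({"a": np.ones(12)})
        table = run_titan(env, abund, TitanConfig(n_perm=20, n_boot=10), seed=0)
        assert table.iloc[0]["status"].startswith("error")


@given(scale=st.floats(0.1, 50.0))
@settings(max_examples=15, deadline=None, derandomize=True)
def test_property_z_invariant_to_abundance_scaling(scale):
    rng = np.random.default_rng(0)
    env = np.linspace(0, 100, 25)
    a = rng.poisson(4.0, 25).astype(float) + 1
    perm = rng.permuted(np.broadcast_to(np.arange(25), (60, 25)).copy(), axis=1)
    r1 = change_point_scan(a, env, perm_index=perm)
    r2 = change_point_scan(scale * a, env, perm_index=perm)
    assert r1["z"] == pytest.approx(r2["z"], rel=1e-9)
    assert r1["cp"] == r2["cp"]


def test_step_recovery_median_error_small(rng):
    """Simulated step responses: median |cp error| within one candidate gap."""
    n = 60
    errors = []
    for _ in range(30):
        env = np.sort(rng.uniform(0, 100, n))
        cp_true = rng.uniform(20, 80)
        a = np.where(env >= cp_true, 8.0, 0.0) * rng.lognormal(0, 0.2, n)
        res = change_point_scan(a, env, TitanConfig(n_perm=99), rng=rng)
        gaps = np.diff(np.unique(env))
        errors.append(abs(res["cp"] - cp_true) / gaps.mean())
    assert np.median(errors) <= 1.0
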