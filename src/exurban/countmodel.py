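"""Hierarchical over-dispersed Poisson adjustment of roadside bird counts.

The observed count of a species at stop *i* in year *t* is modelled as

    C_it ~ Poisson(mu_it)
    log(mu_it) = b0_stop + b1_stop * Year_t + b2 * FirstYear_it
                 + Route_it + Observer_it + Error_it

with a separate intercept and time trend per stop, a first-year-observer
effect, and zero-mean Normal random effects for route conditions (by default
varying by route x year), observer identity, and record-level over-dispersion.
``Year_t`` is centred on the mid-study year and scaled to decades so the
trend coefficients stay O(1).

Priors are weakly informative: Normal(0, 10^2) on b0, b1, b2 and
half-Normal(0, 2) on the three random-effect scales.  The posterior is
sampled by an adaptive Metropolis-within-Gibbs scheme: each block of
conditionally independent parameters (stop intercepts, stop trends, each
random-effect vector) is updated jointly with element-wise accept/reject,
which is valid because the Poisson likelihood factorises over records and
each record touches exactly one element of each block.  Proposal scales are
tuned towards 44% acceptance during warm-up and frozen afterwards.

Convergence is checked with the classical split Gelman–Rubin statistic over
(at least) two chains.  "Adjusted counts" are posterior summaries of the
expected count with observer, first-year and over-dispersion effects set to
zero; the route effect is retained by default as part of the stop's habitat
context (set ``include_route=False`` for the stricter alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_REQUIRED = ("stop_id", "year", "count", "observer_id", "route_id", "first_year")


@dataclass(frozen=True)
class Priors:
    beta_sd: float = 10.0  # Normal(0, beta_sd^2) on b0, b1, b2
    scale_sd: float = 2.0  # half-Normal(0, scale_sd) on effect scales


def gelman_rubin(chains: np.ndarray) -> float:
    """Classical split potential-scale-reduction factor for one parameter.

    Parameters
    ----------
    chains : array, shape (n_chains, n_draws)
        Post-warm-up draws; requires >= 2 chains and >= 10 draws each.

    Each chain is split in half; R-hat is ``sqrt(((n-1)/n * W + B/n) / W)``
    with W the mean within-half variance and B the between-half variance of
    the half means.  >= 1 up to floating-point error.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need draws from at least 2 chains")
    if x.shape[1] < 10:
        raise ValueError("need at least 10 draws per chain")
    n_half = x.shape[1] // 2
    halves = np.concatenate([x[:, :n_half], x[:, x.shape[1] - n_half :]], axis=0)
    m, n = halves.shape
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


class HierarchicalCountModel:
    """Per-species hierarchical count model built from a BBS-like count table.

    Parameters
    ----------
    data : DataFrame
        Columns ``stop_id, year, count, observer_id, route_id, first_year``
        (plus ``species`` if the table holds several species).  One row per
        stop x year; (stop, year) must be unique within a species.
    species : str, optional
        Select one species from a multi-species table.  The model is fitted
        per species (no cross-species pooling).
    route_by_year : bool
        If True (default) the route effect varies by route x year, capturing
        route conditions that change among years; if False it is a static
        per-route effect.
    priors : Priors, optional

    Examples
    --------
    >>> model = HierarchicalCountModel.from_dataframe(counts, species="WOTH")
    >>> res = model.fit(chains=2, draws=1000, warmup=1000, seed=1)
    >>> adj = res.adjusted_counts()
    """

    def __init__(
        self,
        data: pd.DataFrame,
        species: str | None = None,
        route_by_year: bool = True,
        priors: Priors | None = None,
    ) -> None:
        df = pd.DataFrame(data).copy()
        if species is not None:
            if "species" not in df.columns:
                raise ValueError("species requested but no 'species' column")
            df = df[df["species"] == species]
            if df.empty:
                raise ValueError(f"no records for species {species!r}")
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if df[["stop_id", "year"]].duplicated().any():
            raise ValueError("(stop, year) records are not unique")
        if (df["count"] < 0).any() or not np.allclose(df["count"] % 1, 0):
            raise ValueError("counts must be non-negative integers")
        if df["stop_id"].nunique() < 2:
            raise ValueError("need at least 2 stops")
        if df["year"].nunique() < 2:
            raise ValueError("need at least 2 years (trend unidentifiable)")
        if df["observer_id"].nunique() < 2:
            raise ValueError(
                "need at least 2 observers (observer effect unidentifiable)"
            )

        self.data = df.reset_index(drop=True)
        self.species = species
        self.route_by_year = route_by_year
        self.priors = priors or Priors()

        df = self.data
        self.stops, self._stop_idx = np.unique(df["stop_id"], return_inverse=True)
        self.observers, self._obs_idx = np.unique(
            df["observer_id"], return_inverse=True
        )
        years = df["year"].to_numpy(dtype=float)
        self.mid_year = float(np.mean(np.unique(years)))
        self._x_year = (years - self.mid_year) / 10.0  # decades from mid-study
        if route_by_year:
            keys = df["route_id"].astype(str) + "@" + df["year"].astype(str)
        else:
            keys = df["route_id"].astype(str)
        self.route_levels, self._route_idx = np.unique(keys, return_inverse=True)
        self._first = df["first_year"].to_numpy(dtype=float)
        self._y = df["count"].to_numpy(dtype=float)
        self.n_records = len(df)

        # maps used by the likelihood-invariant translation moves
        route_of = df["route_id"].astype(str).to_numpy()
        self._route_map = {}
        for r in np.unique(route_of):
            sel = route_of == r
            cells = np.unique(self._route_idx[sel])
            # year covariate of each cell (well defined when route effects
            # vary by year; the trend translation move is skipped otherwise)
            x_cells = np.array(
                [self._x_year[self._route_idx == c][0] for c in cells]
            )
            self._route_map[r] = (cells, np.unique(self._stop_idx[sel]), x_cells)
        self._obs_map = {}
        for o in range(len(self.observers)):
            sel = self._obs_idx == o
            cells = np.unique(self._route_idx[sel])
            exclusive = bool(
                (self._obs_idx[np.isin(self._route_idx, cells)] == o).all()
            )
            self._obs_map[o] = (cells, exclusive)
        # observers whose every record is a first-year record: their effect is
        # additively confounded with b2 (resolved only by the priors)
        self._allfirst_obs = np.array(
            [
                o
                for o in range(len(self.observers))
                if self._first[self._obs_idx == o].all()
            ],
            dtype=int,
        )
        # route-year cells in which every record is first-year (a new observer
        # surveying the whole route): confounded with b2 the same way
        self._allfirst_cells = np.array(
            [
                c
                for c in range(len(self.route_levels))
                if self._first[self._route_idx == c].all()
            ],
            dtype=int,
        )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, species: str | None = None, **kw):
        return cls(data, species=species, **kw)

    # ------------------------------------------------------------------ MCMC
    def _linpred(self, th: dict) -> np.ndarray:
        return (
            th["b0"][self._stop_idx]
            + th["b1"][self._stop_idx] * self._x_year
            + th["b2"] * self._first
            + th["u_route"][self._route_idx]
            + th["u_obs"][self._obs_idx]
            + th["u_err"]
        )

    def fit(
        self,
        draws: int = 1000,
        warmup: int = 1000,
        chains: int = 2,
        seed: int | None = None,
        thin: int = 1,
        fixed_scales: dict | None = None,
    ) -> "CountModelResults":
        """Sample the posterior; reproducible under a fixed seed.

        ``fixed_scales`` may pin any of ``{"route", "observer", "error"}`` to
        a constant (used e.g. to study the fixed-effects Poisson limit).
        """
        if chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        ss = np.random.SeedSequence(seed)
        out = [
            self._run_chain(draws, warmup, thin, np.random.default_rng(s), fixed_scales)
            for s in ss.spawn(chains)
        ]
        store = {k: np.stack([chain[k] for chain in out]) for k in out[0]}
        return CountModelResults(self, store)

    def _run_chain(self, draws, warmup, thin, rng, fixed_scales):
        n = self.n_records
        n_stop = len(self.stops)
        fixed_scales = fixed_scales or {}

        y = self._y
        stop_sum = np.bincount(self._stop_idx, weights=y, minlength=n_stop)
        stop_cnt = np.bincount(self._stop_idx, minlength=n_stop)
        th = {
            "b0": np.log((stop_sum + 0.5) / np.maximum(stop_cnt, 1)),
            "b1": np.zeros(n_stop),
            "b2": 0.0,
            "u_route": np.zeros(len(self.route_levels)),
            "u_obs": np.zeros(len(self.observers)),
            "u_err": np.zeros(n),
            "s_route": fixed_scales.get("route", 0.5),
            "s_obs": fixed_scales.get("observer", 0.5),
            "s_err": fixed_scales.get("error", 0.5),
        }
        eta = self._linpred(th)

        def loglik_terms(eta_):
            return y * eta_ - np.exp(eta_)

        blocks = [
            ("b0", self._stop_idx, None, n_stop),
            ("b1", self._stop_idx, None, n_stop),
            ("u_route", self._route_idx, "s_route", len(self.route_levels)),
            ("u_obs", self._obs_idx, "s_obs", len(self.observers)),
            ("u_err", np.arange(n), "s_err", n),
        ]
        steps = {name: np.full(size, 0.2) for name, _, _, size in blocks}
        step_b2 = 0.2
        steps_sigma = {"s_route": 0.5, "s_obs": 0.5, "s_err": 0.5}
        steps_rescale = {"s_route": 0.3, "s_obs": 0.3, "s_err": 0.3}
        adapt = 0.05
        beta_sd = self.priors.beta_sd
        scale_sd = self.priors.scale_sd

        n_keep = draws // thin
        store = {
            "b0": np.empty((n_keep, n_stop)),
            "b1": np.empty((n_keep, n_stop)),
            "b2": np.empty(n_keep),
            "u_route": np.empty((n_keep, len(self.route_levels))),
            "u_obs": np.empty((n_keep, len(self.observers))),
            "s_route": np.empty(n_keep),
            "s_obs": np.empty(n_keep),
            "s_err": np.empty(n_keep),
        }
        kept = 0
        ll = loglik_terms(eta)

        for it in range(warmup + draws):
            warm = it < warmup
            for name, gidx, sig_name, size in blocks:
                cur = th[name]
                prop = cur + steps[name] * rng.standard_normal(size)
                delta = prop - cur
                mult = self._x_year if name == "b1" else 1.0
                eta_new = eta + delta[gidx] * mult
                ll_new = loglik_terms(eta_new)
                dll = np.bincount(gidx, weights=ll_new - ll, minlength=size)
                psd = beta_sd if sig_name is None else th[sig_name]
                dprior = (cur**2 - prop**2) / (2.0 * psd**2)
                acc = np.log(rng.random(size)) < dll + dprior
                if acc.any():
                    th[name] = np.where(acc, prop, cur)
                    eta = eta + np.where(acc, delta, 0.0)[gidx] * mult
                    ll = loglik_terms(eta)
                if warm:
                    steps[name] = steps[name] * np.exp(adapt * (acc - 0.44))

            # scalar first-year observer effect
            prop = th["b2"] + step_b2 * rng.standard_normal()
            eta_new = eta + (prop - th["b2"]) * self._first
            ll_new = loglik_terms(eta_new)
            dpost = (ll_new - ll).sum() + (th["b2"] ** 2 - prop**2) / (2 * beta_sd**2)
            acc_b2 = np.log(rng.random()) < dpost
            if acc_b2:
                th["b2"] = prop
                eta, ll = eta_new, ll_new
            if warm:
                step_b2 *= np.exp(adapt * (acc_b2 - 0.44))

            # random-effect scales: Metropolis on log sigma (Jacobian included)
            for sig_name, vec_name, key in (
                ("s_route", "u_route", "route"),
                ("s_obs", "u_obs", "observer"),
                ("s_err", "u_err", "error"),
            ):
                if key in fixed_scales:
                    continue
                u = th[vec_name]
                m = u.size
                s2sum = float(u @ u)
                cur = th[sig_name]
                prop = cur * np.exp(steps_sigma[sig_name] * rng.standard_normal())

                def lp(s):
                    return (
                        -m * np.log(s)
                        - s2sum / (2 * s**2)
                        - s**2 / (2 * scale_sd**2)
                        + np.log(s)
                    )

                acc_s = np.log(rng.random()) < lp(prop) - lp(cur)
                if acc_s:
                    th[sig_name] = prop
                if warm:
                    steps_sigma[sig_name] *= np.exp(adapt * (acc_s - 0.44))

                # group rescale (u, s) -> (c u, c s): leaves the standardised
                # effects fixed; breaks the scale/effect funnel.  The effect
                # prior changes by -m log c, the Jacobian adds (m+1) log c.
                c = np.exp(steps_rescale[sig_name] * rng.standard_normal())
                u = th[vec_name]
                u_new = c * u
                s_new = c * th[sig_name]
                if vec_name == "u_route":
                    eta_new = eta + (u_new - u)[self._route_idx]
                elif vec_name == "u_obs":
                    eta_new = eta + (u_new - u)[self._obs_idx]
                else:
                    eta_new = eta + (u_new - u)
                ll_new = loglik_terms(eta_new)
                dpost = (
                    (ll_new - ll).sum()
                    + np.log(c)
                    + (th[sig_name] ** 2 - s_new**2) / (2 * scale_sd**2)
                )
                acc_c = np.log(rng.random()) < dpost
                if acc_c:
                    th[vec_name] = u_new
                    th[sig_name] = s_new
                    eta, ll = eta_new, ll_new
                if warm:
                    steps_rescale[sig_name] *= np.exp(adapt * (acc_c - 0.44))

            # translation moves along likelihood-invariant directions: the
            # additive confounding between intercepts and effect families is
            # resolved only by the priors, so shift along each confounded
            # direction explicitly.  Each move leaves eta unchanged; only the
            # priors enter the accept ratio.  The battery is repeated with a
            # mixture of proposal scales: these directions are nearly flat, so
            # cheap large jumps pay for themselves.
            for tscale in (0.15, 0.45, 0.15):
                b0 = th["b0"]
                for vec_name, sig_name in (
                    ("u_route", "s_route"),
                    ("u_obs", "s_obs"),
                    ("u_err", "s_err"),
                ):
                    # global shift: whole family +delta, all intercepts -delta
                    u = th[vec_name]
                    s = th[sig_name]
                    delta = 0.2 * rng.standard_normal()
                    dpost = (
                        -((u + delta) ** 2 - u**2).sum() / (2 * s**2)
                        - (((b0 - delta) ** 2 - b0**2).sum()) / (2 * beta_sd**2)
                    )
                    if np.log(rng.random()) < dpost:
                        th[vec_name] = u + delta
                        th["b0"] = b0 = b0 - delta

                # per-stop: b0_s + delta_s, over-dispersion errors of stop s
                # - delta_s (element-wise accept; stops touch disjoint records)
                u = th["u_err"]
                s_err = th["s_err"]
                delta = tscale * rng.standard_normal(n_stop)
                d_err = delta[self._stop_idx]
                dp = -np.bincount(
                    self._stop_idx,
                    weights=((u - d_err) ** 2 - u**2) / (2 * s_err**2),
                    minlength=n_stop,
                ) - (((b0 + delta) ** 2 - b0**2)) / (2 * beta_sd**2)
                acc = np.log(rng.random(n_stop)) < dp
                if acc.any():
                    th["b0"] = b0 = np.where(acc, b0 + delta, b0)
                    th["u_err"] = u - np.where(acc[self._stop_idx], d_err, 0.0)

                # per-stop trend direction: b1_s + delta_s, errors of stop s
                # - delta_s * Year_t (likelihood invariant)
                u = th["u_err"]
                b1 = th["b1"]
                delta = tscale * rng.standard_normal(n_stop)
                d_err = delta[self._stop_idx] * self._x_year
                dp = -np.bincount(
                    self._stop_idx,
                    weights=((u - d_err) ** 2 - u**2) / (2 * s_err**2),
                    minlength=n_stop,
                ) - (((b1 + delta) ** 2 - b1**2)) / (2 * beta_sd**2)
                acc = np.log(rng.random(n_stop)) < dp
                if acc.any():
                    th["b1"] = np.where(acc, b1 + delta, b1)
                    th["u_err"] = u - np.where(acc[self._stop_idx], d_err, 0.0)

                # per-route: all route-year cells of route r + delta, intercepts
                # of the stops on route r - delta; and the same for the trend
                # direction (cells + delta * x_t, stop trends - delta)
                u = th["u_route"]
                s_route = th["s_route"]
                b1 = th["b1"]
                for r, (cells, stops_r, x_cells) in self._route_map.items():
                    delta = tscale * rng.standard_normal()
                    dp = -(((u[cells] + delta) ** 2 - u[cells] ** 2).sum()) / (
                        2 * s_route**2
                    ) - (((b0[stops_r] - delta) ** 2 - b0[stops_r] ** 2).sum()) / (
                        2 * beta_sd**2
                    )
                    if np.log(rng.random()) < dp:
                        u[cells] += delta
                        b0[stops_r] -= delta
                    if not self.route_by_year:
                        continue
                    delta = tscale * rng.standard_normal()
                    d_cells = delta * x_cells
                    dp = -(((u[cells] + d_cells) ** 2 - u[cells] ** 2).sum()) / (
                        2 * s_route**2
                    ) - (((b1[stops_r] - delta) ** 2 - b1[stops_r] ** 2).sum()) / (
                        2 * beta_sd**2
                    )
                    if np.log(rng.random()) < dp:
                        u[cells] += d_cells
                        b1[stops_r] -= delta
                th["u_route"], th["b0"], th["b1"] = u, b0, b1

                # per-observer: observer effect + delta, the route-year cells that
                # observer covered - delta (exact likelihood delta computed in
                # case a cell was shared between observers)
                uo = th["u_obs"]
                s_obs = th["s_obs"]
                for o, (cells, exclusive) in self._obs_map.items():
                    delta = tscale * rng.standard_normal()
                    dp = -((uo[o] + delta) ** 2 - uo[o] ** 2) / (2 * s_obs**2) - (
                        ((u[cells] - delta) ** 2 - u[cells] ** 2).sum()
                    ) / (2 * s_route**2)
                    if not exclusive:
                        deta = delta * (
                            (self._obs_idx == o).astype(float)
                            - np.isin(self._route_idx, cells).astype(float)
                        )
                        ll_new = loglik_terms(eta + deta)
                        dp += (ll_new - ll).sum()
                    if np.log(rng.random()) < dp:
                        uo[o] += delta
                        u[cells] -= delta
                        if not exclusive:
                            eta = eta + deta
                            ll = loglik_terms(eta)
                th["u_obs"], th["u_route"] = uo, u

                # b2 <-> effects of observers seen only in their first year
                fo = self._allfirst_obs
                if fo.size:
                    delta = tscale * rng.standard_normal()
                    b2c = th["b2"]
                    dp = -((b2c + delta) ** 2 - b2c**2) / (2 * beta_sd**2) - (
                        ((uo[fo] - delta) ** 2 - uo[fo] ** 2).sum()
                    ) / (2 * th["s_obs"] ** 2)
                    if np.log(rng.random()) < dp:
                        th["b2"] = b2c + delta
                        uo[fo] -= delta
                        th["u_obs"] = uo
                fc = self._allfirst_cells
                if fc.size:
                    u = th["u_route"]
                    delta = tscale * rng.standard_normal()
                    b2c = th["b2"]
                    dp = -((b2c + delta) ** 2 - b2c**2) / (2 * beta_sd**2) - (
                        ((u[fc] - delta) ** 2 - u[fc] ** 2).sum()
                    ) / (2 * th["s_route"] ** 2)
                    if np.log(rng.random()) < dp:
                        th["b2"] = b2c + delta
                        u[fc] -= delta
                        th["u_route"] = u

            if not warm and (it - warmup) % thin == 0 and kept < n_keep:
                for k in ("b0", "b1", "u_route", "u_obs"):
                    store[k][kept] = th[k]
                for k in ("b2", "s_route", "s_obs", "s_err"):
                    store[k][kept] = th[k]
                kept += 1
        return store


class CountModelResults:
    """Posterior draws and summaries of a fitted hierarchical count model."""

    def __init__(self, model: HierarchicalCountModel, draws: dict) -> None:
        self.model = model
        self.draws = draws  # each (chains, n_draws[, dim])
        self.n_chains = draws["b2"].shape[0]
        self.n_draws = draws["b2"].shape[1]

    def _iter_scalars(self):
        for name, arr in self.draws.items():
            if arr.ndim == 2:
                yield name, arr
            else:
                for j in range(arr.shape[2]):
                    yield f"{name}[{j}]", arr[:, :, j]

    def gelman_rubin(self) -> pd.Series:
        """Split R-hat per scalar parameter."""
        return pd.Series({name: gelman_rubin(a) for name, a in self._iter_scalars()})

    def max_rhat(self) -> float:
        return float(self.gelman_rubin().max())

    def summary(self) -> pd.DataFrame:
        """Posterior mean, s.d., median, 95% interval and R-hat per parameter."""
        rows = []
        for name, a in self._iter_scalars():
            flat = a.reshape(-1)
            lo, med, hi = np.quantile(flat, (0.025, 0.5, 0.975))
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "q2.5": lo,
                    "median": med,
                    "q97.5": hi,
                    "rhat": gelman_rubin(a),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def convergence_report(self) -> dict:
        rh = self.gelman_rubin()
        return {
            "max_rhat": float(rh.max()),
            "n_parameters": int(len(rh)),
            "n_chains": self.n_chains,
            "n_draws_per_chain": self.n_draws,
            "worst_parameter": str(rh.idxmax()),
        }

    def adjusted_counts(
        self,
        statistic: str = "mean",
        include_route: bool = True,
        rhat_threshold: float = 1.1,
        force: bool = False,
    ) -> pd.DataFrame:
        """Observer-standardised expected counts per stop x year.

        Posterior summaries of ``exp(b0_stop + b1_stop * Year_t [+ Route])``
        — the expected count with observer, first-year and over-dispersion
        effects set to zero.  Refuses on a non-converged fit (max R-hat at or
        above ``rhat_threshold``) unless ``force=True``.
        """
        mr = self.max_rhat()
        if mr >= rhat_threshold and not force:
            raise RuntimeError(
                f"fit not converged (max R-hat {mr:.3f} >= {rhat_threshold}); "
                "pass force=True to override"
            )
        if statistic not in ("mean", "median"):
            raise ValueError("statistic must be 'mean' or 'median'")
        m = self.model
        b0 = self.draws["b0"].reshape(-1, len(m.stops))
        b1 = self.draws["b1"].reshape(-1, len(m.stops))
        eta = b0[:, m._stop_idx] + b1[:, m._stop_idx] * m._x_year[None, :]
        if include_route:
            ur = self.draws["u_route"].reshape(-1, len(m.route_levels))
            eta = eta + ur[:, m._route_idx]
        mu = np.exp(eta)  # (total draws, records)
        lo, med, hi = np.quantile(mu, (0.025, 0.5, 0.975), axis=0)
        out = m.data[["stop_id", "year"]].copy()
        if m.species is not None:
            out["species"] = m.species
        elif "species" in m.data.columns:
            out["species"] = m.data["species"].to_numpy()
        out["mean"] = mu.mean(axis=0)
        out["median"] = med
        out["q2.5"] = lo
        out["q97.5"] = hi
        out["adjusted_count"] = out[statistic if statistic == "median" else "mean"]
        return out
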