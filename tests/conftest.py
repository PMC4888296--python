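import numpy as np
import pandas as pd
import pytest

from exurban.raster import BinaryLandscape


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def grid_landscape(grid, pixel_size=30.0):
    """BinaryLandscape from a nested list / array of 0-1."""
    return BinaryLandscape(np.asarray(grid, dtype=bool), pixel_size=pixel_size)


def simulate_count_table(
    seed,
    n_stops=40,
    n_years=4,
    n_routes=4,
    b2=-0.3,
    s_route=0.2,
    s_obs=0.2,
    s_err=0.15,
    baseline=np.log(5),
    trend_mean=0.1,
    turnover=0.5,
):
    """Single-species count table drawn from the hierarchical model itself.

    Observers have staggered tenures (those active in the first study year
    are experienced), matching how first-year observer flags arise in the
    roadside survey.  Used by the model-recovery tests.
    """
    rng = np.random.default_rng(seed)
    years = np.array([1986, 1993, 2000, 2009])[:n_years]
    x = (years - years.mean()) / 10
    routes = [f"R{k}" for k in range(n_routes)]
    stop_route = {f"S{i:02d}": routes[i % n_routes] for i in range(n_stops)}
    counter = [0]

    def new_obs():
        counter[0] += 1
        return f"O{counter[0]:03d}"

    cur = {r: new_obs() for r in routes}
    started = {o: 0 for o in cur.values()}
    assign = {}
    for t in range(n_years):
        for r in routes:
            if t > 0 and rng.random() < turnover:
                o = new_obs()
                started[o] = t
                cur[r] = o
            assign[(r, t)] = cur[r]
    b0 = rng.normal(baseline, 0.4, n_stops)
    b1 = rng.normal(trend_mean, 0.2, n_stops)
    u_r = {(r, t): rng.normal(0, s_route) for r in routes for t in range(n_years)}
    u_o = {o: rng.normal(0, s_obs) for o in started}
    rows = []
    for t, yr in enumerate(years):
        for i, (sid, rid) in enumerate(stop_route.items()):
            o = assign[(rid, t)]
            fy = 1 if (started[o] == t and t > 0) else 0
            eta = (
                b0[i]
                + b1[i] * x[t]
                + b2 * fy
                + u_r[(rid, t)]
                + u_o[o]
                + rng.normal(0, s_err)
            )
            rows.append(
                dict(
                    stop_id=sid,
                    year=yr,
                    count=int(rng.poisson(np.exp(eta))),
                    observer_id=o,
                    route_id=rid,
                    first_year=fy,
                )
            )
    truth = dict(b2=b2, s_route=s_route, s_obs=s_obs, s_err=s_err)
    return pd.DataFrame(rows), truth
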