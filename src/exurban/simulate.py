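"""Synthetic landscapes, survey stops and bird counts with known ground truth.

The generator emulates the study system end to end so every pipeline stage
can be tested against a planted truth:

* **Landscapes** — each survey stop is surrounded by its own development
  neighbourhood (stops are spaced so 1-km buffers never overlap a
  neighbour's development).  Development consists of isolated single-pixel
  "islets" (scattered houses) and solid 3x3 blocks (clustered housing with
  a morphological core), placed on a spacing lattice that guarantees islets
  stay islets under 8-connectivity.  Across the four survey periods a
  fraction of islets is converted to blocks ("infill") and new units are
  added, reproducing the observed trajectory of scattered development
  becoming contiguous and clumped; the per-stop islet/block mix therefore
  *is* the compactness ground truth.  Forest is generated as per-stop patch
  mosaics that are progressively cleared around new development.

* **Counts** — drawn from the hierarchical over-dispersed Poisson model run
  forward: per-stop log intercepts and trends, first-year observer effect,
  route x year and observer random effects, log-normal over-dispersion, plus
  a per-species response to the stop's compactness (step or sigmoid at a
  known change point, or none).  Observers have staggered tenures (observers
  active in the first study year count as experienced), so the first-year
  effect is identifiable.

Every generated dataset carries a machine-readable ground-truth dictionary;
recovery tests read truth only from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import SurveyStop
from .raster import BinaryLandscape

YEARS = (1986, 1993, 2000, 2009)


@dataclass(frozen=True)
class LandscapeScenario:
    """Controls the synthetic landscape trajectory.

    Defaults are calibrated so the pooled compactness trajectory rises from
    roughly 10% to roughly 45% across the four periods with large
    between-stop spread, development roughly doubles, and forest declines —
    the qualitative study conditions.
    """

    n_stops: int = 125
    n_routes: int = 10
    protected_fraction: float = 0.21
    pixel_size: float = 30.0
    stop_spacing_m: float = 2300.0
    jitter_m: float = 250.0
    disc_radius_m: float = 900.0  # development neighbourhood around a stop
    site_spacing_px: int = 4  # unit-centre lattice spacing (keeps islets islets)
    initial_units_mean: float = 130.0
    initial_islet_frac: float = 0.986
    islet_frac_concentration: float = 60.0
    # a minority of stops has block-dominated ("clustered") development,
    # giving the gradient its high-compactness tail
    clustered_fraction: float = 0.18
    clustered_islet_frac: float = 0.85
    clustered_concentration: float = 20.0
    intensity_sd_log: float = 0.35
    no_dev_fraction: float = 0.06  # unprotected stops that still lack development
    conversion_rates: tuple[float, ...] = (0.004, 0.015, 0.05)
    new_units_per_period: float = 16.0
    new_unit_islet_prob: float = 0.92
    forest_base_mean: float = 0.45
    forest_patches: int = 9
    forest_patch_px: tuple[int, int] = (8, 34)
    clearings_per_period: int = 3
    clearing_px: tuple[int, int] = (6, 14)
    years: tuple[int, ...] = YEARS


@dataclass(frozen=True)
class SpeciesProfile:
    """Ground-truth response of one species to the compactness gradient."""

    name: str
    baseline_log: float  # log expected count at an average stop
    response: str = "none"  # "step", "sigmoid" or "none"
    change_point: float = 50.0  # compactness %, in (0, 100)
    direction: int = 1  # +1: increases past the change point; -1: decreases
    effect: float = 0.0  # log-scale effect size
    guild: str = "forest"

    def response_term(self, compactness: np.ndarray) -> np.ndarray:
        c = np.nan_to_num(np.asarray(compactness, dtype=float), nan=0.0)
        if self.response == "none" or self.effect == 0.0:
            return np.zeros_like(c)
        if self.response == "step":
            f = (c >= self.change_point).astype(float)
        elif self.response == "sigmoid":
            f = 1.0 / (1.0 + np.exp(-(c - self.change_point) / 8.0))
        else:
            raise ValueError(f"unknown response type {self.response!r}")
        return self.direction * self.effect * f


def default_community(seed: int | None = None) -> "CommunityScenario":
    """The 11-species community: 6 forest species with step-up responses and
    5 forest-edge species with mixed responses."""
    forest = [
        SpeciesProfile("OVEN", np.log(3.0), "step", 52.0, +1, 0.9, "forest"),
        SpeciesProfile("REVI", np.log(5.0), "step", 41.0, +1, 0.9, "forest"),
        SpeciesProfile("AMRE", np.log(1.5), "step", 62.0, +1, 1.0, "forest"),
        SpeciesProfile("WOTH", np.log(4.0), "step", 21.0, +1, 0.8, "forest"),
        SpeciesProfile("SCTA", np.log(2.0), "step", 54.0, +1, 0.9, "forest"),
        SpeciesProfile("EAWP", np.log(2.5), "step", 21.0, +1, 0.8, "forest"),
    ]
    edge = [
        SpeciesProfile("EAPH", np.log(2.0), "step", 7.0, +1, 0.8, "edge"),
        SpeciesProfile("EATO", np.log(3.0), "step", 67.0, -1, 0.7, "edge"),
        SpeciesProfile("GRCA", np.log(3.5), "sigmoid", 29.0, +1, 0.8, "edge"),
        SpeciesProfile("INBU", np.log(4.0), "step", 42.0, +1, 0.6, "edge"),
        SpeciesProfile("NOCA", np.log(4.5), "none", 50.0, +1, 0.0, "edge"),
    ]
    return CommunityScenario(species=tuple(forest + edge))


@dataclass(frozen=True)
class CommunityScenario:
    """Species profiles plus the nuisance structure of the count process."""

    species: tuple[SpeciesProfile, ...] = ()
    stop_intercept_sd: float = 0.35
    stop_trend_mean: float = 0.1  # per decade, log scale
    stop_trend_sd: float = 0.15
    first_year_effect: float = -0.3
    observer_turnover: float = 0.5  # per route per period
    route_sd: float = 0.2
    observer_sd: float = 0.2
    overdispersion_sd: float = 0.15


# ------------------------------------------------------------------ landscape
def _stop_layout(scn: LandscapeScenario, rng: np.random.Generator):
    """Jittered-grid stop locations, route blocks, protected flags."""
    n_cols = int(np.ceil(np.sqrt(scn.n_stops)))
    n_rows = int(np.ceil(scn.n_stops / n_cols))
    margin = scn.disc_radius_m + 2 * scn.pixel_size + 1100.0
    stops = []
    k = 0
    for i in range(n_rows):
        for j in range(n_cols):
            if k >= scn.n_stops:
                break
            x = margin + j * scn.stop_spacing_m + rng.uniform(-scn.jitter_m, scn.jitter_m)
            y = margin + i * scn.stop_spacing_m + rng.uniform(-scn.jitter_m, scn.jitter_m)
            stops.append((f"S{k:03d}", x, y))
            k += 1
    width = margin + (n_cols - 1) * scn.stop_spacing_m + margin
    height = margin + (n_rows - 1) * scn.stop_spacing_m + margin
    shape = (int(np.ceil(height / scn.pixel_size)), int(np.ceil(width / scn.pixel_size)))
    per_route = int(np.ceil(scn.n_stops / scn.n_routes))
    n_protected = int(round(scn.protected_fraction * scn.n_stops))
    protected_ids = set(rng.choice(scn.n_stops, size=n_protected, replace=False))
    out = []
    for k, (sid, x, y) in enumerate(stops):
        out.append(
            SurveyStop(
                stop_id=sid,
                x=x,
                y=y,
                route_id=f"R{k // per_route:02d}",
                protected=k in protected_ids,
            )
        )
    return out, shape


def _disc_sites(scn: LandscapeScenario, rng: np.random.Generator) -> np.ndarray:
    """Candidate unit-centre offsets (row, col) on a spacing lattice within
    the development disc, shuffled once per stop."""
    r_px = int(scn.disc_radius_m / scn.pixel_size)
    s = scn.site_spacing_px
    offs = [
        (dr, dc)
        for dr in range(-r_px, r_px + 1, s)
        for dc in range(-r_px, r_px + 1, s)
        if dr * dr + dc * dc <= r_px * r_px
    ]
    offs = np.array(offs)
    return offs[rng.permutation(len(offs))]


class _StopDevelopment:
    """Evolving islet/block unit list for one stop."""

    def __init__(self, scn: LandscapeScenario, rng: np.random.Generator, developed: bool):
        self.sites = _disc_sites(scn, rng) if developed else np.empty((0, 2), int)
        self.n_used = 0
        self.unit_kind: list[str] = []  # parallel to used sites
        self.scn = scn
        if not developed:
            return
        mean = scn.initial_units_mean * rng.lognormal(0.0, scn.intensity_sd_log)
        n0 = min(rng.poisson(mean), len(self.sites))
        if rng.random() < scn.clustered_fraction:
            f = rng.beta(
                scn.clustered_islet_frac * scn.clustered_concentration,
                (1 - scn.clustered_islet_frac) * scn.clustered_concentration,
            )
        else:
            f = rng.beta(
                scn.initial_islet_frac * scn.islet_frac_concentration,
                (1 - scn.initial_islet_frac) * scn.islet_frac_concentration,
            )
        for _ in range(n0):
            self.unit_kind.append("islet" if rng.random() < f else "block")
        self.n_used = n0

    def advance(self, period: int, rng: np.random.Generator) -> None:
        """Apply one period of infill conversion and growth."""
        scn = self.scn
        if self.n_used == 0 and len(self.sites) == 0:
            return
        rate = scn.conversion_rates[min(period - 1, len(scn.conversion_rates) - 1)]
        for i, kind in enumerate(self.unit_kind):
            if kind == "islet" and rng.random() < rate:
                self.unit_kind[i] = "block"
        n_new = min(
            rng.poisson(scn.new_units_per_period), len(self.sites) - self.n_used
        )
        for _ in range(n_new):
            self.unit_kind.append(
                "islet" if rng.random() < scn.new_unit_islet_prob else "block"
            )
        self.n_used += n_new

    def render(self, grid: np.ndarray, centre_rc: tuple[int, int]) -> None:
        r0, c0 = centre_rc
        for (dr, dc), kind in zip(self.sites[: self.n_used], self.unit_kind):
            r, c = r0 + int(dr), c0 + int(dc)
            if kind == "islet":
                grid[r, c] = True
            else:
                grid[r - 1 : r + 2, c - 1 : c + 2] = True


def _simulate_scene(scenario: LandscapeScenario, seed: int) -> dict:
    """Generate stops and the full 4-period exurban/forest raster stack."""
    rng = np.random.default_rng(seed)
    stops, shape = _stop_layout(scenario, rng)
    px = scenario.pixel_size
    origin = (0.0, shape[0] * px)

    def to_rc(stop):
        row = int((origin[1] - stop.y) / px)
        col = int(stop.x / px)
        return row, col

    dev_rng = np.random.default_rng(rng.integers(2**31))
    devs = {}
    for stop in stops:
        developed = (not stop.protected) and dev_rng.random() >= scenario.no_dev_fraction
        devs[stop.stop_id] = _StopDevelopment(scenario, dev_rng, developed)

    # forest mosaic at period 0: per-stop rectangles, protected stops solid
    forest0 = np.zeros(shape, dtype=bool)
    f_rng = np.random.default_rng(rng.integers(2**31))
    r_buf = int(1050 / px)
    for stop in stops:
        r0, c0 = to_rc(stop)
        if stop.protected:
            forest0[r0 - r_buf : r0 + r_buf + 1, c0 - r_buf : c0 + r_buf + 1] = True
            continue
        target = np.clip(f_rng.beta(4, 4) * 2 * scenario.forest_base_mean, 0.02, 0.95)
        n_patch = f_rng.poisson(scenario.forest_patches) + 1
        for _ in range(n_patch):
            h = f_rng.integers(*scenario.forest_patch_px)
            w = f_rng.integers(*scenario.forest_patch_px)
            if f_rng.random() > target:
                continue
            dr = f_rng.integers(-r_buf, r_buf - h + 1)
            dc = f_rng.integers(-r_buf, r_buf - w + 1)
            forest0[r0 + dr : r0 + dr + h, c0 + dc : c0 + dc + w] = True

    exurban, forest = {}, {}
    clear_rng = np.random.default_rng(rng.integers(2**31))
    cleared = np.zeros(shape, dtype=bool)
    for p, year in enumerate(scenario.years):
        if p > 0:
            for stop in stops:
                devs[stop.stop_id].advance(p, dev_rng)
            # additional forest clearing around each developed stop
            for stop in stops:
                if stop.protected:
                    continue
                r0, c0 = to_rc(stop)
                for _ in range(scenario.clearings_per_period):
                    h = clear_rng.integers(*scenario.clearing_px)
                    w = clear_rng.integers(*scenario.clearing_px)
                    dr = clear_rng.integers(-r_buf, r_buf - h + 1)
                    dc = clear_rng.integers(-r_buf, r_buf - w + 1)
                    cleared[r0 + dr : r0 + dr + h, c0 + dc : c0 + dc + w] = True
        ex = np.zeros(shape, dtype=bool)
        for stop in stops:
            devs[stop.stop_id].render(ex, to_rc(stop))
        fo = forest0 & ~cleared & ~ex
        exurban[year] = BinaryLandscape(ex, px, origin)
        forest[year] = BinaryLandscape(fo, px, origin)

    truth = {
        "seed": seed,
        "scenario": asdict(scenario),
        "n_stops": len(stops),
        "protected_stops": [s.stop_id for s in stops if s.protected],
        "undeveloped_stops": [
            s.stop_id for s in stops if devs[s.stop_id].n_used == 0
        ],
    }
    return {
        "stops": stops,
        "exurban": exurban,
        "forest": forest,
        "truth": truth,
    }


def simulate_landscape(
    scenario: LandscapeScenario, year: int, seed: int
) -> dict[str, BinaryLandscape]:
    """Exurban and forest rasters for one survey year.

    The full multi-period trajectory is regenerated deterministically from
    the seed, so calls for different years of the same (scenario, seed) are
    mutually consistent.
    """
    if year not in scenario.years:
        raise ValueError(f"year {year} not in scenario years {scenario.years}")
    scene = _simulate_scene(scenario, seed)
    return {"exurban": scene["exurban"][year], "forest": scene["forest"][year]}


# -------------------------------------------------------------------- counts
def simulate_counts(
    stops: list[SurveyStop],
    years: tuple[int, ...],
    compactness: pd.DataFrame,
    community: CommunityScenario,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Draw a multi-species count table from the hierarchical model.

    Parameters
    ----------
    compactness : DataFrame
        Long table with columns ``stop_id, year, compactness`` (the 1-km
        gradient driving the species responses; NaN = no development, which
        contributes no response term).

    Returns
    -------
    (counts, truth) : the BBS-like count table (one row per stop x year x
    species) and the ground-truth parameter dictionary.
    """
    rng = np.random.default_rng(seed)
    years = tuple(years)
    mid = np.mean(np.unique([float(y) for y in years]))
    comp = compactness.set_index(["stop_id", "year"])["compactness"]

    routes = sorted({s.route_id for s in stops})
    # staggered observer tenures; observers active at the start are experienced
    obs_counter = 0
    cur_obs, started = {}, {}
    for r in routes:
        cur_obs[r] = f"O{obs_counter:03d}"
        started[cur_obs[r]] = 0
        obs_counter += 1
    assign = {}
    for t in range(len(years)):
        for r in routes:
            if t > 0 and rng.random() < community.observer_turnover:
                o = f"O{obs_counter:03d}"
                obs_counter += 1
                started[o] = t
                cur_obs[r] = o
            assign[(r, t)] = cur_obs[r]

    u_obs = {o: rng.normal(0, community.observer_sd) for o in started}
    u_route = {
        (r, t): rng.normal(0, community.route_sd)
        for r in routes
        for t in range(len(years))
    }
    stop_dev = {
        s.stop_id: (
            rng.normal(0, community.stop_intercept_sd),
            rng.normal(community.stop_trend_mean, community.stop_trend_sd),
        )
        for s in stops
    }

    rows = []
    for sp in community.species:
        for t, year in enumerate(years):
            x_t = (year - mid) / 10.0
            for s in stops:
                o = assign[(s.route_id, t)]
                fy = 1 if (started[o] == t and t > 0) else 0
                c = comp.get((s.stop_id, year), np.nan)
                d0, d1 = stop_dev[s.stop_id]
                eta = (
                    sp.baseline_log
                    + d0
                    + d1 * x_t
                    + community.first_year_effect * fy
                    + u_route[(s.route_id, t)]
                    + u_obs[o]
                    + rng.normal(0, community.overdispersion_sd)
                    + float(sp.response_term(np.array([c]))[0])
                )
                rows.append(
                    {
                        "stop_id": s.stop_id,
                        "year": year,
                        "species": sp.name,
                        "count": int(rng.poisson(np.exp(eta))),
                        "observer_id": o,
                        "route_id": s.route_id,
                        "first_year": fy,
                    }
                )
    counts = pd.DataFrame(rows)
    truth = {
        "seed": seed,
        "species": [asdict(sp) for sp in community.species],
        "first_year_effect": community.first_year_effect,
        "route_sd": community.route_sd,
        "observer_sd": community.observer_sd,
        "overdispersion_sd": community.overdispersion_sd,
        "stop_intercept_sd": community.stop_intercept_sd,
        "stop_trend_mean": community.stop_trend_mean,
        "stop_trend_sd": community.stop_trend_sd,
    }
    return counts, truth


# ------------------------------------------------------------- study scale
def study_scale_scenario(
    seed: int,
    out_dir: str | Path | None = None,
    scenario: LandscapeScenario | None = None,
    community: CommunityScenario | None = None,
) -> dict:
    """Full study-scale input bundle: ~125 stops (about a fifth protected),
    4 survey periods, 11 species, rasters + stop/count tables + ground truth.

    Compactness is computed downstream by the analysis modules; the species
    responses here are driven by the *generative* compactness implied by the
    planted islet/block mix in each stop's 1-km buffer, recorded in the
    ground truth.

    If ``out_dir`` is given, rasters are written as TIFF (+ georeference
    sidecars), tables as CSV and the truth as ``ground_truth.json``.
    """
    from .mspa import MSPAConfig, classify_mspa
    from .metrics import BufferSpec, compactness_index, extract_buffer

    scenario = scenario or LandscapeScenario()
    community = community or default_community()
    root = np.random.default_rng(seed)
    scene = _simulate_scene(scenario, int(root.integers(2**31)))
    stops = scene["stops"]

    # generative compactness gradient at the 1-km scale
    cfg = MSPAConfig(connectivity=8, edge_width=1)
    spec1km = BufferSpec(1000.0)
    rows = []
    for year in scenario.years:
        cm = classify_mspa(scene["exurban"][year], cfg)
        for stop in stops:
            buf = extract_buffer(scene["exurban"][year], stop, spec1km)
            rows.append(
                {
                    "stop_id": stop.stop_id,
                    "year": year,
                    "compactness": compactness_index(cm, buf),
                }
            )
    comp = pd.DataFrame(rows)

    counts, count_truth = simulate_counts(
        stops, scenario.years, comp, community, int(root.integers(2**31))
    )
    truth = dict(scene["truth"])
    truth["counts"] = count_truth
    truth["generative_compactness"] = "mspa_1km"

    bundle = {
        "stops": stops,
        "exurban": scene["exurban"],
        "forest": scene["forest"],
        "counts": counts,
        "compactness_1km": comp,
        "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for year in scenario.years:
            scene["exurban"][year].write(out / f"exurban_{year}.tif")
            scene["forest"][year].write(out / f"forest_{year}.tif")
        pd.DataFrame(
            [
                {
                    "stop_id": s.stop_id,
                    "x": s.x,
                    "y": s.y,
                    "route_id": s.route_id,
                    "protected": s.protected,
                }
                for s in stops
            ]
        ).to_csv(out / "stops.csv", index=False)
        counts.to_csv(out / "counts.csv", index=False)
        comp.to_csv(out / "compactness_1km.csv", index=False)
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return bundle
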