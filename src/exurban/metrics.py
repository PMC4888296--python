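"""Landscape predictors around survey stops.

Circular "zone of influence" buffers (pixel-centre-in-circle membership) are
extracted around each roadside survey stop, and the landscape predictors used
in the bird analyses are computed within them:

* proportion of forest / exurban development (%);
* the compactness index of exurban development,
  ``100 * (1 - islet pixels / all exurban pixels)`` — 0% when development is
  fully dispersed (all MSPA islets), 100% when fully clumped (no islets),
  undefined (NaN) where the buffer contains no exurban development;
* number of forest patches larger than 0.45 ha;
* forest edge length (m), measured as interior forest/non-forest 4-adjacency
  within the buffer (the buffer clip line itself is not edge);
* Moran's I with a permutation test, used to screen stop-level spatial
  autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .mspa import ISLET, MSPAClassMap
from .raster import BinaryLandscape


@dataclass(frozen=True)
class SurveyStop:
    """A survey stop located in the raster's projected CRS (metres)."""

    stop_id: str
    x: float
    y: float
    route_id: str = ""
    protected: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"stop {self.stop_id}: non-finite coordinates")


@dataclass(frozen=True)
class BufferSpec:
    """Circular buffer; a cell belongs iff its centre lies within ``radius``."""

    radius: float  # metres; 400 (local) and 1000 (landscape) are typical

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def extract_buffer(
    landscape: BinaryLandscape, stop: SurveyStop, spec: BufferSpec
) -> np.ndarray:
    """Boolean mask of raster cells whose centres fall within the buffer.

    Raises
    ------
    ValueError
        If the circle extends beyond the raster extent (the caller may pad
        the raster or drop the stop).
    """
    x_min, y_min, x_max, y_max = landscape.extent
    r = spec.radius
    if (
        stop.x - r < x_min
        or stop.x + r > x_max
        or stop.y - r < y_min
        or stop.y + r > y_max
    ):
        raise ValueError(
            f"buffer of radius {r} m around stop {stop.stop_id!r} leaves the raster"
        )
    xs, ys = landscape.cell_centres()
    mask = (xs - stop.x) ** 2 + (ys - stop.y) ** 2 <= r**2
    if not mask.any():
        raise ValueError(f"buffer around stop {stop.stop_id!r} contains no cell")
    return mask


def proportion_cover(buffer_mask: np.ndarray, class_mask: BinaryLandscape) -> float:
    """Percent of buffer cells covered by the class; nodata cells excluded."""
    if buffer_mask.shape != class_mask.shape:
        raise ValueError("buffer and class raster grids differ")
    valid = buffer_mask
    if class_mask.nodata is not None:
        valid = buffer_mask & ~class_mask.nodata
    n = valid.sum()
    if n == 0:
        raise ValueError("empty buffer (no valid cells)")
    return 100.0 * class_mask.grid[valid].sum() / n


def compactness_index(class_map: MSPAClassMap, buffer_mask: np.ndarray) -> float:
    """Compactness of exurban development within a buffer.

    ``100 * (1 - islets / all exurban pixels)`` over the buffer; ranges from
    0% (all islets, fully dispersed) to 100% (no islets, maximally clumped).
    Returns NaN when the buffer contains no exurban pixel — such stops are
    excluded from the compactness gradient downstream.
    """
    if buffer_mask.shape != class_map.shape:
        raise ValueError("buffer and class map grids differ")
    fg = class_map.foreground & buffer_mask
    n_all = int(fg.sum())
    if n_all == 0:
        return float("nan")
    n_islet = int((class_map.labels[buffer_mask] == ISLET).sum())
    return 100.0 * (1.0 - n_islet / n_all)


def count_forest_patches(
    forest: BinaryLandscape,
    buffer_mask: np.ndarray,
    min_area_ha: float = 0.45,
    connectivity: int = 8,
) -> int:
    """Number of forest patches whose buffer-clipped area strictly exceeds
    ``min_area_ha`` (at 30 m pixels and 0.45 ha: more than 5 pixels)."""
    structure = (
        np.ones((3, 3), bool)
        if connectivity == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    clipped = forest.grid & buffer_mask
    comp, n = ndimage.label(clipped, structure=structure)
    if n == 0:
        return 0
    sizes = np.bincount(comp.ravel())[1:]
    areas = sizes * forest.pixel_size**2 / 1e4
    return int((areas > min_area_ha).sum())


def forest_edge_length(forest: BinaryLandscape, buffer_mask: np.ndarray) -> float:
    """Forest edge (m): 4-adjacent cell pairs inside the buffer with exactly
    one forest cell, times pixel size.  The buffer clip line is not edge."""
    f = forest.grid
    b = buffer_mask
    pairs = 0
    # vertical neighbours
    sel = b[:-1, :] & b[1:, :]
    pairs += int((sel & (f[:-1, :] != f[1:, :])).sum())
    # horizontal neighbours
    sel = b[:, :-1] & b[:, 1:]
    pairs += int((sel & (f[:, :-1] != f[:, 1:])).sum())
    return pairs * forest.pixel_size


def _inverse_distance_weights(coords: np.ndarray) -> np.ndarray:
    """Row-standardised inverse-distance weight matrix (zero diagonal)."""
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    rs = w.sum(axis=1, keepdims=True)
    if (rs == 0).any():
        raise ValueError("a location has zero total weight (duplicate coordinates?)")
    return w / rs


def morans_i(
    values: np.ndarray,
    coords: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Classical Moran's I with a two-sided permutation test.

    Parameters
    ----------
    values : array, shape (n,)
        Variable observed at each location; must not be constant.
    coords : array, shape (n, 2), optional
        Locations; used to build row-standardised inverse-distance weights
        when ``weights`` is not given.
    weights : array, shape (n, n), optional
        Spatial weight matrix (zero diagonal); overrides ``coords``.
    n_perm : int
        Number of random permutations for the p-value (+1 corrected).

    Returns
    -------
    dict with keys ``I`` and ``p``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 locations")
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0:
        raise ValueError("Moran's I undefined for constant values")
    if weights is None:
        if coords is None:
            raise ValueError("either coords or weights is required")
        weights = _inverse_distance_weights(np.asarray(coords, dtype=float))
    w = np.asarray(weights, dtype=float)
    s0 = w.sum()

    def stat(zv: np.ndarray) -> float:
        return n / s0 * float(zv @ w @ zv) / float((zv**2).sum())

    i_obs = stat(z)
    rng = np.random.default_rng(seed)
    exceed = 0
    e_i = -1.0 / (n - 1)
    for _ in range(n_perm):
        zp = rng.permutation(z)
        if abs(stat(zp) - e_i) >= abs(i_obs - e_i) - 1e-12:
            exceed += 1
    return {"I": i_obs, "p": (1 + exceed) / (n_perm + 1)}


def composition_table(
    records: pd.DataFrame,
    variables: tuple[str, ...] = (
        "pct_forest",
        "pct_exurban",
        "compactness",
    ),
) -> pd.DataFrame:
    """Mean ± s.d. of landscape variables per radius × year, overall and for
    protected-area stops.

    ``records`` is a long table of per-stop landscape records with at least
    ``stop_id, year, radius, protected`` and the requested variable columns.
    Stops with undefined (NaN) compactness are excluded from the compactness
    statistics; the number excluded is reported in the ``n_excluded`` column.

    Returns a table with one row per (group, radius, variable) and one
    ``mean ± sd`` string column per year, mirroring the structure of a
    landscape-composition summary table.
    """
    rows = []
    years = sorted(records["year"].unique())
    groups = [("all", records)]
    if "protected" in records.columns and records["protected"].any():
        groups.append(("protected", records[records["protected"]]))
    for gname, sub in groups:
        for radius in sorted(sub["radius"].unique()):
            at_r = sub[sub["radius"] == radius]
            for var in variables:
                if var not in at_r.columns:
                    raise KeyError(f"missing variable column {var!r}")
                row = {"group": gname, "radius": radius, "variable": var}
                n_excl = 0
                for yr in years:
                    vals = at_r.loc[at_r["year"] == yr, var].astype(float)
                    n_excl = max(n_excl, int(vals.isna().sum()))
                    vals = vals.dropna()
                    if len(vals) == 0:
                        row[str(yr)] = "—"
                    else:
                        row[str(yr)] = f"{vals.mean():.1f} ± {vals.std(ddof=1) if len(vals) > 1 else 0.0:.1f}"
                row["n_excluded"] = n_excl
                rows.append(row)
    return pd.DataFrame(rows)


def stop_landscape_records(
    stops: list[SurveyStop],
    exurban_maps: dict[int, MSPAClassMap],
    exurban_rasters: dict[int, BinaryLandscape],
    forest_rasters: dict[int, BinaryLandscape],
    radii: tuple[float, ...] = (400.0, 1000.0),
) -> pd.DataFrame:
    """Compute the full per-stop × year × radius landscape record table.

    Stops whose buffer leaves the raster raise; the pipeline pads rasters so
    this does not occur for generated scenes.
    """
    years = sorted(exurban_rasters)
    for yr in years:
        if yr not in forest_rasters:
            raise KeyError(f"missing forest raster for year {yr}")
        if yr not in exurban_maps:
            raise KeyError(f"missing MSPA class map for year {yr}")
    rows = []
    for radius in radii:
        spec = BufferSpec(radius)
        for stop in stops:
            buf = extract_buffer(exurban_rasters[years[0]], stop, spec)
            for yr in years:
                ex = exurban_rasters[yr]
                cm = exurban_maps[yr]
                fo = forest_rasters[yr]
                rows.append(
                    {
                        "stop_id": stop.stop_id,
                        "route_id": stop.route_id,
                        "protected": stop.protected,
                        "year": yr,
                        "radius": radius,
                        "pct_forest": proportion_cover(buf, fo),
                        "pct_exurban": proportion_cover(buf, ex),
                        "compactness": compactness_index(cm, buf),
                        "n_forest_patches": count_forest_patches(fo, buf),
                        "forest_edge_m": forest_edge_length(fo, buf),
                        "n_exurban_pixels": int((ex.grid & buf).sum()),
                    }
                )
    return pd.DataFrame(rows)
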