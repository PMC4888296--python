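"""Buffers, landscape predictors, compactness, and Moran's I."""

import numpy as np
import pandas as pd
import pytest

from exurban.metrics import (
    BufferSpec,
    SurveyStop,
    compactness_index,
    composition_table,
    count_forest_patches,
    extract_buffer,
    forest_edge_length,
    morans_i,
    proportion_cover,
)
from exurban.mspa import MSPAConfig, classify_mspa
from exurban.raster import BinaryLandscape

from conftest import grid_landscape


def blank_scene(n=60, pixel=30.0):
    """Empty landscape with a stop at the exact centre of the central pixel."""
    land = BinaryLandscape(np.zeros((n, n), bool), pixel_size=pixel)
    centre = n // 2
    x = (centre + 0.5) * pixel
    y = land.origin[1] - (centre + 0.5) * pixel
    return land, SurveyStop("S1", x, y), centre


class TestExtractBuffer:
    def test_cell_count_matches_circle_area(self):
        land, stop, _ = blank_scene(60)
        mask = extract_buffer(land, stop, BufferSpec(400.0))
        expect = np.pi * 400**2 / 900
        assert abs(mask.sum() - expect) / expect < 0.02

    def test_tiny_radius_single_cell(self):
        land, stop, c = blank_scene(20)
        mask = extract_buffer(land, stop, BufferSpec(10.0))
        assert mask.sum() == 1
        assert mask[c, c]

    def test_rotational_symmetry(self):
        # odd grid so the stop pixel is the exact array centre
        land, stop, _ = blank_scene(41)
        mask = extract_buffer(land, stop, BufferSpec(300.0))
        assert (mask == np.rot90(mask)).all()

    def test_stop_near_edge_raises(self):
        land, _, _ = blank_scene(20)
        near = SurveyStop("edge-stop", 45.0, 45.0)
        with pytest.raises(ValueError, match="edge-stop"):
            extract_buffer(land, near, BufferSpec(400.0))


class TestProportionCover:
    def test_full_and_empty(self):
        land, stop, _ = blank_scene(30)
        mask = extract_buffer(land, stop, BufferSpec(200.0))
        full = BinaryLandscape(np.ones((30, 30), bool))
        assert proportion_cover(mask, full) == 100.0
        assert proportion_cover(mask, land) == 0.0

    def test_half_cover(self):
        mask = np.ones((10, 10), bool)
        grid = np.zeros((10, 10), bool)
        grid[:5] = True
        assert proportion_cover(mask, BinaryLandscape(grid)) == 50.0

    def test_nodata_excluded_both_sides(self):
        mask = np.ones((4, 4), bool)
        grid = np.zeros((4, 4), bool)
        grid[0] = True  # 4 forest cells of 16
        nod = np.zeros((4, 4), bool)
        nod[3] = True  # 4 nodata cells
        cl = BinaryLandscape(grid, nodata=nod)
        assert proportion_cover(mask, cl) == pytest.approx(100 * 4 / 12)

    def test_empty_buffer_raises(self):
        with pytest.raises(ValueError):
            proportion_cover(np.zeros((3, 3), bool), grid_landscape(np.zeros((3, 3))))


class TestCompactness:
    def test_all_islets_zero_percent(self, rng):
        g = np.zeros((40, 40), bool)
        cells = [(r, c) for r in range(2, 38, 3) for c in range(2, 38, 3)]
        for r, c in [cells[i] for i in rng.choice(len(cells), 20, replace=False)]:
            g[r, c] = True
        cm = classify_mspa(BinaryLandscape(g), MSPAConfig(8, 1))
        assert compactness_index(cm, np.ones((40, 40), bool)) == 0.0

    def test_single_solid_block_hundred_percent(self):
        g = np.zeros((40, 40), bool)
        g[10:19, 10:19] = True
        cm = classify_mspa(BinaryLandscape(g), MSPAConfig(8, 1))
        assert compactness_index(cm, np.ones((40, 40), bool)) == 100.0

    def test_mixed_block_and_islets_fifty(self):
        # one 3x3 block (9 non-islet px) + 9 isolated pixels -> 100*(1-9/18)
        g = np.zeros((30, 30), bool)
        g[2:5, 2:5] = True
        for i, (r, c) in enumerate(
            [(10, 10), (10, 14), (10, 18), (14, 10), (14, 14), (14, 18),
             (18, 10), (18, 14), (18, 18)]
        ):
            g[r, c] = True
        cm = classify_mspa(BinaryLandscape(g), MSPAConfig(8, 1))
        assert compactness_index(cm, np.ones((30, 30), bool)) == pytest.approx(50.0)

    def test_no_exurban_undefined(self):
        cm = classify_mspa(grid_landscape(np.zeros((10, 10))))
        assert np.isnan(compactness_index(cm, np.ones((10, 10), bool)))

    def test_islet_infill_never_decreases_compactness(self, rng):
        # converting islets to a core-bearing block raises the index
        g = np.zeros((40, 40), bool)
        sites = [(r, c) for r in range(2, 38, 4) for c in range(2, 38, 4)]
        for r, c in sites[:30]:
            g[r, c] = True
        buf = np.ones((40, 40), bool)
        base = compactness_index(
            classify_mspa(BinaryLandscape(g), MSPAConfig()), buf
        )
        g2 = g.copy()
        r, c = sites[0]
        g2[r - 1 : r + 2, c - 1 : c + 2] = True  # islet -> 3x3 block
        after = compactness_index(
            classify_mspa(BinaryLandscape(g2), MSPAConfig()), buf
        )
        assert after > base


class TestForestPatchesAndEdge:
    def test_two_blocks_counted(self):
        g = np.zeros((30, 30), bool)
        g[2:5, 2:5] = True
        g[10:13, 10:13] = True
        assert count_forest_patches(BinaryLandscape(g), np.ones((30, 30), bool)) == 2

    def test_small_patches_below_threshold(self):
        g = np.zeros((20, 20), bool)
        for r, c in [(2, 2), (2, 8), (8, 2), (8, 8), (14, 14)]:
            g[r, c] = True
        assert count_forest_patches(BinaryLandscape(g), np.ones((20, 20), bool)) == 0

    def test_exactly_at_threshold_excluded(self):
        # 5 px = 0.45 ha at 30 m: not strictly greater
        g = np.zeros((10, 10), bool)
        g[2, 2:7] = True
        assert count_forest_patches(BinaryLandscape(g), np.ones((10, 10), bool)) == 0
        g[2, 7] = True  # 6 px = 0.54 ha
        assert count_forest_patches(BinaryLandscape(g), np.ones((10, 10), bool)) == 1

    def test_edge_of_interior_block(self):
        g = np.zeros((10, 10), bool)
        g[4:7, 4:7] = True
        assert forest_edge_length(BinaryLandscape(g), np.ones((10, 10), bool)) == 360.0

    def test_edge_all_forest_zero(self):
        g = np.ones((8, 8), bool)
        assert forest_edge_length(BinaryLandscape(g), np.ones((8, 8), bool)) == 0.0

    def test_edge_single_pixel(self):
        g = np.zeros((9, 9), bool)
        g[4, 4] = True
        assert forest_edge_length(BinaryLandscape(g), np.ones((9, 9), bool)) == 120.0

    def test_buffer_clip_line_not_edge(self):
        g = np.ones((10, 10), bool)  # all forest
        buf = np.zeros((10, 10), bool)
        buf[3:7, 3:7] = True
        assert forest_edge_length(BinaryLandscape(g), buf) == 0.0


class TestMoransI:
    def test_checkerboard_rook_is_minus_one(self):
        vals = np.fromfunction(lambda r, c: (-1.0) ** (r + c), (4, 4))
        coords = [(r, c) for r in range(4) for c in range(4)]
        w = np.zeros((16, 16))
        for i, (r1, c1) in enumerate(coords):
            for j, (r2, c2) in enumerate(coords):
                if abs(r1 - r2) + abs(c1 - c2) == 1:
                    w[i, j] = 1.0
        w = w / w.sum(axis=1, keepdims=True)
        out = morans_i(vals.ravel(), weights=w, n_perm=99, seed=0)
        assert out["I"] == pytest.approx(-1.0, abs=1e-12)

    def test_agrees_with_bruteforce_formula(self, rng):
        n = 12
        x = rng.normal(size=n)
        coords = rng.uniform(0, 100, (n, 2))
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0)
        w = w / w.sum(axis=1, keepdims=True)
        out = morans_i(x, coords=coords, n_perm=9, seed=0)
        z = x - x.mean()
        brute = (n / w.sum()) * sum(
            w[i, j] * z[i] * z[j] for i in range(n) for j in range(n)
        ) / (z**2).sum()
        assert out["I"] == pytest.approx(brute, abs=1e-12)

    def test_type_i_error_rate_near_alpha(self, rng):
        coords = rng.uniform(0, 100, (20, 2))
        hits = 0
        n_rep = 120
        for _ in range(n_rep):
            x = rng.normal(size=20)
            out = morans_i(x, coords=coords, n_perm=99, seed=int(rng.integers(2**31)))
            hits += out["p"] <= 0.05
        assert 0.005 <= hits / n_rep <= 0.12

    def test_constant_values_error(self):
        with pytest.raises(ValueError):
            morans_i(np.ones(5), coords=np.random.default_rng(0).uniform(0, 1, (5, 2)))


class TestCompositionTable:
    def make_records(self):
        rows = []
        for year in (1986, 1993):
            for sid, prot, comp in (("a", False, 40.0), ("b", False, np.nan), ("c", True, 10.0)):
                rows.append(
                    dict(stop_id=sid, year=year, radius=400.0, protected=prot,
                         pct_forest=50.0, pct_exurban=10.0, compactness=comp)
                )
        return pd.DataFrame(rows)

    def test_structure_and_exclusions(self):
        t = composition_table(self.make_records())
        assert set(t["group"]) == {"all", "protected"}
        comp_row = t[(t.group == "all") & (t.variable == "compactness")].iloc[0]
        assert comp_row["n_excluded"] == 1  # the NaN stop
        assert comp_row["1986"].startswith("25.0")  # mean of 40 and 10

    def test_single_stop_zero_sd(self):
        df = self.make_records()
        df = df[df.stop_id == "a"]
        t = composition_table(df)
        assert t.iloc[0]["1986"].endswith("± 0.0")

    def test_means_match_direct_average(self, rng):
        df = self.make_records()
        t = composition_table(df)
        for var in ("pct_forest", "pct_exurban"):
            row = t[(t.group == "all") & (t.variable == var)].iloc[0]
            want = df[df.year == 1986][var].mean()
            assert float(row["1986"].split(" ± ")[0]) == pytest.approx(want, abs=0.05)

    def test_missing_variable_raises(self):
        with pytest.raises(KeyError):
            composition_table(self.make_records(), variables=("nope",))


def test_translation_invariance(rng):
    """All buffer metrics are unchanged when scene and stop shift together."""
    g = rng.random((50, 50)) < 0.3
    f = rng.random((50, 50)) < 0.4
    for shift in (0.0, 1200.0):
        land = BinaryLandscape(g, origin=(shift, 1500.0 + shift))
        forest = BinaryLandscape(f, origin=(shift, 1500.0 + shift))
        stop = SurveyStop("s", 750.0 + shift, 750.0 + shift)
        buf = extract_buffer(land, stop, BufferSpec(400.0))
        vals = (
            proportion_cover(buf, land),
            count_forest_patches(forest, buf),
            forest_edge_length(forest, buf),
        )
        if shift == 0.0:
            base = vals
    assert vals == base
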