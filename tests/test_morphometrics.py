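import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rootanat import compute_tissue_stats, cheesewheel, fit_ellipse, write_stats
from rootanat.detection import RootModel
from rootanat.morphometrics import TissueStats


def ellipse_points(a, b, n=80, theta=0.0, centre=(0.0, 0.0), noise=0.0, seed=0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    y = b * np.sin(t)
    x = a * np.cos(t)
    rows = centre[0] + y * np.cos(theta) + x * np.sin(theta)
    cols = centre[1] + x * np.cos(theta) - y * np.sin(theta)
    pts = np.stack([rows, cols], axis=1)
    if noise:
        rng = np.random.default_rng(seed)
        pts = pts + rng.uniform(-noise, noise, pts.shape)
    return pts


class TestFitEllipse:
    def test_circle_has_near_zero_eccentricity(self):
        fit = fit_ellipse(ellipse_points(20, 20))
        assert fit.E < 0.02
        assert fit.a == pytest.approx(20, rel=1e-6)

    def test_exact_5_by_3_ellipse_gives_closed_form_value(self):
        fit = fit_ellipse(ellipse_points(5, 3, theta=0.4, centre=(7, -2)))
        assert fit.E == pytest.approx(0.8, abs=1e-9)  # sqrt(1 - 9/25)
        assert (fit.a, fit.b) == (pytest.approx(5, rel=1e-9), pytest.approx(3, rel=1e-9))

    def test_noisy_axes_recovered_within_one_percent(self):
        fit = fit_ellipse(ellipse_points(100, 60, n=200, theta=1.1, noise=1.0, seed=3))
        assert fit.a == pytest.approx(100, rel=0.01)
        assert fit.b == pytest.approx(60, rel=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipse(ellipse_points(5, 3)[:4])

    def test_collinear_points_rejected(self):
        pts = np.stack([np.arange(10.0), 2 * np.arange(10.0)], axis=1)
        with pytest.raises(ValueError):
            fit_ellipse(pts)

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.05, 50.0))
    def test_eccentricity_is_scale_invariant(self, scale):
        base = ellipse_points(8, 5, theta=0.7)
        e0 = fit_ellipse(base).E
        assert fit_ellipse(base * scale).E == pytest.approx(e0, abs=1e-6)


class TestTissueStats:
    def test_counts_partition_non_noise_cells(self, wheat_case):
        stats, model = wheat_case["stats"], wheat_case["model"]
        total = sum(stats.regions[r]["cell_count"] for r in stats.regions)
        total += sum(1 for c in model.cells if c.tissue == "epidermis")
        assert total == sum(1 for c in model.cells if c.size_class != "noise")

    def test_micron_conversion_scales_areas_quadratically(self, wheat_case, wheat_params):
        model = wheat_case["model"]
        s1 = compute_tissue_stats(model, scale=1.0)
        s2 = compute_tissue_stats(model, scale=2.0)
        assert s2.root_area == pytest.approx(4.0 * s1.root_area)
        for region in s1.regions:
            if s1.regions[region]["cell_count"]:
                assert s2.regions[region]["mean_cell_area_um2"] == pytest.approx(
                    4.0 * s1.regions[region]["mean_cell_area_um2"])

    def test_single_metaxylem_stats_are_that_cell(self, wheat_case):
        stats, model = wheat_case["stats"], wheat_case["model"]
        mx = [c for c in model.cells if c.tissue == "metaxylem"]
        assert stats.regions["metaxylem"]["cell_count"] == 1
        assert stats.regions["metaxylem"]["mean_cell_area_um2"] == pytest.approx(mx[0].area)
        assert stats.regions["metaxylem"]["mean_cell_eccentricity"] == pytest.approx(
            mx[0].eccentricity)

    def test_planted_metaxylem_area_recovered(self, wheat_case):
        truth = wheat_case["truth"]
        planted = truth.true_stats["metaxylem"]["total_area"]
        got = wheat_case["stats"].regions["metaxylem"]["total_area_um2"]
        assert got == pytest.approx(planted, rel=0.10)

    def test_region_area_ordering(self, wheat_case):
        stats = wheat_case["stats"]
        assert stats.root_area >= stats.regions["stele"]["total_area_um2"]
        assert (stats.regions["stele"]["total_area_um2"]
                >= stats.regions["metaxylem"]["total_area_um2"])

    def test_stats_invariant_to_cell_order(self, wheat_case):
        model = wheat_case["model"]
        shuffled = RootModel(**{f: getattr(model, f) for f in (
            "cells", "gamma_ini", "gamma_final", "gamma_ini_mask",
            "gamma_final_mask", "mask", "stele_centre")},
            endodermis_contour=model.endodermis_contour,
            endodermis_mask=model.endodermis_mask)
        shuffled.cells = list(reversed(model.cells))
        a = compute_tissue_stats(model, scale=1.0).to_frame()
        b = compute_tissue_stats(shuffled, scale=1.0).to_frame()
        assert a.equals(b)


class TestCheesewheel:
    def test_each_zone_has_exactly_36_regions(self, wheat_case):
        for wheel in wheat_case["wheels"]:
            t = wheel.table
            assert len(t) == 36
            assert set(t.annulus) == set(range(1, 7))
            assert set(t.wedge) == set(range(1, 7))

    def test_zone_cells_partition_into_regions(self, wheat_case):
        model = wheat_case["model"]
        zones = {w.zone: w.table.cell_count.sum() for w in wheat_case["wheels"]}
        n_stele = sum(1 for c in model.cells
                      if c.tissue in ("stele", "endodermis", "metaxylem"))
        n_cortex = sum(1 for c in model.cells if c.tissue == "cortex")
        assert zones["stele-zone"] == n_stele
        assert zones["cortex-zone"] == n_cortex

    def test_radial_eccentricity_trend_in_stele_zone(self, wheat_case):
        # endodermal cells are flatter than inner stele cells, so the
        # outermost annulus must show higher mean eccentricity
        t = [w for w in wheat_case["wheels"] if w.zone == "stele-zone"][0].table
        inner = t[t.annulus == 1].mean_eccentricity.dropna().mean()
        outer = t[t.annulus == 6].mean_eccentricity.dropna().mean()
        assert outer > inner


class TestWriteStats:
    def test_csv_outputs_have_documented_schema(self, wheat_case, tmp_path):
        paths = write_stats(wheat_case["stats"], wheat_case["wheels"],
                            wheat_case["model"], tmp_path, prefix="w")
        summary = paths["summary"].read_text().splitlines()
        assert summary[0] == "region,feature,value"
        assert any(line.startswith("metaxylem,cell_count") for line in summary)
        cells = paths["cells"].read_text().splitlines()
        assert cells[0] == ("cell_id,tissue,area_um2,eccentricity,"
                            "centroid_row,centroid_col,on_perimeter")
        assert len(cells) == len(wheat_case["model"].cells) + 1
        wheel = paths["cheesewheel"].read_text().splitlines()
        assert wheel[0] == "zone,annulus,wedge,cell_count,mean_area_px2,mean_eccentricity"
        assert len(wheel) == 73  # two zones x 36 regions + header

    def test_maize_summary_adds_protoxylem_and_aerenchyma_rows(self, maize_case, tmp_path):
        paths = write_stats(maize_case["stats"], maize_case["wheels"],
                            maize_case["model"], tmp_path, prefix="m")
        text = paths["summary"].read_text()
        assert "protoxylem" in text and "aerenchyma" in text

    def test_empty_model_writes_headers_only(self, tmp_path):
        region = np.zeros((10, 10), bool)
        region[2:8, 2:8] = True
        gamma = np.array([[2, 2], [2, 7], [7, 7], [7, 2], [2, 2]], float)
        model = RootModel(cells=[], gamma_ini=gamma, gamma_final=gamma,
                          gamma_ini_mask=region, gamma_final_mask=region,
                          mask=np.zeros((10, 10), bool))
        stats = compute_tissue_stats(model, scale=1.0)
        paths = write_stats(stats, [], model, tmp_path, prefix="empty")
        cells = paths["cells"].read_text().splitlines()
        assert len(cells) == 1  # header only
        wheel = paths["cheesewheel"].read_text().splitlines()
        assert len(wheel) == 1
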