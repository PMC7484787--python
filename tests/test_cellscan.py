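"""Bright-spot detection, cell morphometry and the MC search cascade."""

import numpy as np
import pytest

from mcflim import synthetic
from mcflim.cellscan import (
    ACTIVATED_MC,
    AMBIGUOUS_MC,
    NOT_MC,
    RESTING_MC,
    CellRecord,
    SearchCriteria,
    detect_bright_spots,
    mc_search,
    measure_cell,
    scan_image,
)
from mcflim.decay import DecayCube, FitConfig, FitMaps, N_CHANNELS, bin_decays, delta_irf

PITCH = 150.0 / 512.0


def _disc(shape, center, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r**2


def _uniform_fit_maps(shape, **values):
    defaults = dict(tau1=400.0, tau2=2200.0, a1=1.5, a2=1.0, tau_m=1100.0,
                    ratio=1.5, asym=0.2, chi2=1.0, intensity=300.0)
    defaults.update(values)
    return FitMaps(
        **{k: np.full(shape, v) for k, v in defaults.items()},
        valid=np.ones(shape, dtype=bool),
    )


class TestDetect:
    def test_flat_background_yields_no_candidates(self):
        """A cells-free rendered elastin field produces zero candidates at k=4."""
        cfg = synthetic.SceneConfig(image_size=(48, 48), field_of_view_um=(14.06, 14.06))
        cube, _ = synthetic.render_scene(cfg, np.random.default_rng(12))
        intensity = bin_decays(cube.counts, 3).sum(axis=2) / cube.power_mw
        masks = detect_bright_spots(intensity, cube.pixel_pitch_um)
        assert masks == []

    def test_planted_mcs_recovered_within_2um(self):
        """Three planted in vivo MCs are detected with centroids near truth."""
        placements = [
            synthetic.CellPlacement("resting_mc/in_vivo/healthy", (9.0, 9.0)),
            synthetic.CellPlacement("activated_mc/in_vivo/healthy", (28.0, 10.0)),
            synthetic.CellPlacement("resting_mc/in_vivo/healthy", (18.0, 28.0)),
        ]
        cfg = synthetic.SceneConfig(image_size=(128, 128), field_of_view_um=(37.5, 37.5),
                                    elastin_intensity=100.0, cells=placements)
        cube, truth = synthetic.render_scene(cfg, np.random.default_rng(5))
        intensity = bin_decays(cube.counts, 3).sum(axis=2) / cube.power_mw
        masks = detect_bright_spots(intensity, cube.pixel_pitch_um)
        assert len(masks) == 3
        found = []
        for m in masks:
            ys, xs = np.nonzero(m)
            found.append((xs.mean() * cube.pixel_pitch_um, ys.mean() * cube.pixel_pitch_um))
        for _, row in truth.table.iterrows():
            d = min(np.hypot(fx - row.center_x_um, fy - row.center_y_um)
                    for fx, fy in found)
            assert d < 2.0

    def test_oversized_blob_rejected(self, rng):
        img = rng.normal(100.0, 5.0, (128, 128))
        img[_disc(img.shape, (64, 64), 15.0 / PITCH)] += 500.0  # 30 um diameter
        masks = detect_bright_spots(img, PITCH)  # exceeds the 25 um size cap
        assert masks == []

    def test_empty_image(self):
        assert detect_bright_spots(np.zeros((10, 10)), PITCH) == []


class TestMeasure:
    def _cube(self, shape):
        counts = np.ones((*shape, N_CHANNELS))
        return DecayCube(counts, irf=delta_irf(), pixel_pitch_um=PITCH, depth_um=90.0)

    def test_disc_circularity_and_flag(self):
        shape = (64, 64)
        mask = _disc(shape, (32, 32), 17.0)
        rec = measure_cell(mask, _uniform_fit_maps(shape), self._cube(shape))
        assert 0.85 <= rec.circularity <= 1.0
        assert rec.shape_flag == 1

    def test_elongated_ellipse_flagged_noncircular(self):
        shape = (64, 64)
        yy, xx = np.ogrid[:64, :64]
        mask = ((yy - 32) / 8.0) ** 2 + ((xx - 32) / 24.0) ** 2 <= 1.0  # 3:1
        rec = measure_cell(mask, _uniform_fit_maps(shape), self._cube(shape))
        assert rec.circularity < 0.8
        assert rec.shape_flag == 0

    def test_uniform_parameters_average_exactly(self):
        shape = (32, 32)
        mask = _disc(shape, (16, 16), 8.0)
        maps = _uniform_fit_maps(shape, tau_m=987.0, ratio=2.5)
        rec = measure_cell(mask, maps, self._cube(shape))
        assert rec.fit_summary["tau_m"] == pytest.approx(987.0)
        assert rec.fit_summary["ratio"] == pytest.approx(2.5)
        assert rec.mean_intensity == pytest.approx(300.0)

    @pytest.mark.parametrize("diameter_um", [6.0, 8.0, 10.0, 12.0, 14.0])
    def test_diameter_estimator_within_one_pitch(self, diameter_um):
        shape = (96, 96)
        r_px = diameter_um / 2.0 / PITCH
        mask = _disc(shape, (48, 48), r_px)
        rec = measure_cell(mask, _uniform_fit_maps(shape), self._cube(shape))
        assert abs(rec.equivalent_diameter_um - diameter_um) < PITCH

    def test_border_mask_flagged_partial(self):
        shape = (32, 32)
        mask = _disc(shape, (0, 16), 6.0)
        rec = measure_cell(mask, _uniform_fit_maps(shape), self._cube(shape))
        assert rec.partial

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            measure_cell(np.zeros((8, 8), dtype=bool), _uniform_fit_maps((8, 8)),
                         self._cube((8, 8)))

    def test_decay_curve_peak_normalized(self):
        shape = (16, 16)
        mask = _disc(shape, (8, 8), 4.0)
        rec = measure_cell(mask, _uniform_fit_maps(shape), self._cube(shape))
        assert rec.decay_curve.max() == pytest.approx(1.0)
        assert rec.decay_curve.size == N_CHANNELS


def _record(depth=90.0, diameter=10.0, circ=0.9, intensity=300.0, tau_m=1171.0):
    return CellRecord(
        mask=np.ones((3, 3), dtype=bool), equivalent_diameter_um=diameter,
        circularity=circ, shape_flag=int(circ >= 0.8), mean_intensity=intensity,
        fit_summary={"tau_m": tau_m}, decay_curve=np.ones(N_CHANNELS),
        depth_um=depth)


class TestSearchCascade:
    def test_resting_mc_rule(self):
        # healthy in vivo longer-tau_m population: tau_m 1,171 ps, ~300 photons/mW
        assert mc_search(_record(depth=90, diameter=10, tau_m=1171.0,
                                 intensity=300.0)) == RESTING_MC

    def test_activated_mc_rule(self):
        # shorter-tau_m population: 678 ps, ~800 photons/mW, elongated
        assert mc_search(_record(depth=90, diameter=9, circ=0.6, tau_m=678.0,
                                 intensity=800.0)) == ACTIVATED_MC

    def test_too_shallow_is_not_mc(self):
        assert mc_search(_record(depth=50.0)) == NOT_MC

    def test_fibroblast_size_excluded(self):
        assert mc_search(_record(diameter=22.0)) == NOT_MC

    def test_gap_between_gates_is_ambiguous(self):
        assert mc_search(_record(tau_m=900.0)) == AMBIGUOUS_MC

    def test_intensity_floor(self):
        assert mc_search(_record(intensity=50.0)) == NOT_MC

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            SearchCriteria(resting_tau_m_min=700.0, activated_tau_m_max=800.0)

    def test_cascade_on_cohort_draws(self, default_cohort):
        """Rule recall over MC parameter draws >= 0.8; no fibroblast passes."""
        mc = default_cohort[default_cohort["label2"] == synthetic.LABEL_MC]
        labels = [
            mc_search(_record(depth=90.0, diameter=row.diameter,
                              circ=0.9 if row.shape_flag else 0.6,
                              intensity=row.intensity, tau_m=row.tau_m))
            for row in mc.itertuples()
        ]
        recall = np.mean([lab != NOT_MC for lab in labels])
        assert recall >= 0.8
        fib = default_cohort[default_cohort["class_name"] == "fibroblast"]
        fib_labels = [
            mc_search(_record(depth=90.0, diameter=row.diameter,
                              intensity=row.intensity, tau_m=row.tau_m))
            for row in fib.itertuples()
        ]
        assert all(lab == NOT_MC for lab in fib_labels)


class TestScanImage:
    def test_end_to_end_labels_planted_cells(self):
        """Full scan of a rendered scene recovers both planted MCs with
        rule labels consistent with their drawn tau_m."""
        placements = [
            synthetic.CellPlacement("resting_mc/in_vivo/healthy", (9.0, 9.0),
                                    params=(344.0, 2301.0, 1.5, 300.0, 10.0, 1)),
            synthetic.CellPlacement("activated_mc/in_vivo/healthy", (26.0, 26.0),
                                    params=(241.0, 1947.0, 3.0, 800.0, 9.0, 0)),
        ]
        cfg = synthetic.SceneConfig(image_size=(120, 120), field_of_view_um=(35.2, 35.2),
                                    elastin_intensity=100.0, cells=placements,
                                    depth_um=90.0)
        cube, _ = synthetic.render_scene(cfg, np.random.default_rng(9))
        records = scan_image(cube, fit_config=FitConfig(intensity_threshold=200.0))
        labels = sorted(r.search_label for r in records)
        assert len(records) == 2
        assert labels == [ACTIVATED_MC, RESTING_MC]
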