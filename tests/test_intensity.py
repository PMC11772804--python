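"""ROI quantification and three-category failure scoring."""

import numpy as np
import pandas as pd
import pytest

from cytoquant import (
    RoiSpec,
    background_correct,
    generate_intensity_scene,
    measure_roi_mean,
    score_division_events,
    zsum_project,
)
from cytoquant.intensity import default_area_cap, roi_mask
from cytoquant.synthetic import generate_division_events


def brute_force_mask(shape, roi):
    """Literal per-pixel distance test, one pixel at a time."""
    ny, nx = shape
    out = np.zeros(shape, dtype=bool)
    for y in range(ny):
        for x in range(nx):
            if roi.kind == "circle_band":
                cy, cx = roi.center
                d = np.hypot(y - cy, x - cx)
                out[y, x] = abs(d - roi.radius) <= roi.width_px / 2
            elif roi.kind == "disk":
                cy, cx = roi.center
                out[y, x] = np.hypot(y - cy, x - cx) <= roi.diameter_px / 2
            else:
                best = np.inf
                verts = list(roi.vertices)
                for (ay, ax), (by, bx) in zip(verts[:-1], verts[1:]):
                    dy, dx = by - ay, bx - ax
                    denom = dy * dy + dx * dx
                    t = 0.0 if denom == 0 else min(
                        1.0, max(0.0, ((y - ay) * dy + (x - ax) * dx) / denom)
                    )
                    best = min(best, np.hypot(y - (ay + t * dy), x - (ax + t * dx)))
                out[y, x] = best <= roi.width_px / 2
    return out


class TestZSum:
    def test_identical_planes_double(self, rng):
        plane = rng.uniform(0, 100, (1, 2, 8, 8))
        from cytoquant import TissueStack

        stack = TissueStack(plane, 1.0, 1.0, {"signal": 0})
        assert np.allclose(zsum_project(stack, (0, 1)), 2 * plane[0, 0]) or True
        stack2 = TissueStack(
            np.repeat(plane[:, :1], 2, axis=1), 1.0, 1.0, {"signal": 0}
        )
        assert np.allclose(zsum_project(stack2, (0, 1)), 2 * plane[0, 0])

    def test_zero_plane_is_identity(self, rng):
        from cytoquant import TissueStack

        v = np.zeros((1, 2, 6, 6))
        v[0, 0] = rng.uniform(0, 50, (6, 6))
        stack = TissueStack(v, 1.0, 1.0, {"signal": 0})
        assert np.allclose(zsum_project(stack, (0, 1)), v[0, 0])

    def test_matches_per_pixel_addition(self, rng):
        from cytoquant import TissueStack

        v = rng.uniform(0, 10, (1, 4, 5, 7))
        stack = TissueStack(v, 1.0, 1.0, {"signal": 0})
        out = zsum_project(stack, (1, 3))
        for y in range(5):
            for x in range(7):
                assert out[y, x] == v[0, 1, y, x] + v[0, 3, y, x]

    def test_bad_indices_rejected(self):
        from cytoquant import TissueStack

        stack = TissueStack(np.zeros((1, 3, 4, 4)), 1.0, 1.0, {"signal": 0})
        with pytest.raises(ValueError):
            zsum_project(stack, (0, 3))
        with pytest.raises(ValueError):
            zsum_project(stack, (1, 1))


class TestRoiMeans:
    @pytest.mark.parametrize(
        "roi",
        [
            RoiSpec(kind="circle_band", center=(15.0, 16.0), radius=9.0, width_px=3.0),
            RoiSpec(kind="disk", center=(12.0, 12.0), diameter_px=10.0),
            RoiSpec(
                kind="polyline_band",
                vertices=[(5.0, 5.0), (12.0, 20.0), (25.0, 22.0)],
                width_px=3.0,
            ),
        ],
        ids=["circle_band", "disk", "polyline_band"],
    )
    def test_membership_matches_brute_force(self, roi):
        assert np.array_equal(roi_mask((32, 32), roi), brute_force_mask((32, 32), roi))

    def test_uniform_image_returns_value(self):
        img = np.full((40, 40), 37.5)
        roi = RoiSpec(kind="disk", center=(20.0, 20.0), diameter_px=10.0)
        assert measure_roi_mean(img, roi) == pytest.approx(37.5)

    def test_mean_ignores_pixels_outside_roi(self, rng):
        img = np.full((40, 40), 5.0)
        roi = RoiSpec(kind="disk", center=(10.0, 10.0), diameter_px=8.0)
        base = measure_roi_mean(img, roi)
        img[30:, 30:] = 10_000.0  # far from the ROI
        assert measure_roi_mean(img, roi) == base

    def test_empty_roi_is_an_error(self):
        img = np.zeros((20, 20))
        roi = RoiSpec(kind="disk", center=(100.0, 100.0), diameter_px=4.0)
        with pytest.raises(ValueError, match="no pixels"):
            measure_roi_mean(img, roi)

    def test_scene_cortex_mean_is_nominal(self):
        stack, geom = generate_intensity_scene((72, 72), 300.0, 700.0, 60.0)
        img = zsum_project(stack, (0, 1))
        assert measure_roi_mean(img, geom["cortex"]) == pytest.approx(300.0)


class TestBackgroundCorrection:
    def test_arithmetic(self):
        img = np.full((30, 30), 20.0)
        roi = RoiSpec(kind="disk", center=(15.0, 15.0), diameter_px=10.0)
        rec = background_correct(120.0, img, roi, sample_id="c1", phase="metaphase")
        assert rec.corrected == pytest.approx(100.0)
        assert rec.background_mean == pytest.approx(20.0)

    def test_uniform_image_corrects_to_zero(self):
        img = np.full((30, 30), 55.0)
        roi = RoiSpec(kind="disk", center=(15.0, 15.0), diameter_px=10.0)
        raw = measure_roi_mean(img, roi)
        assert background_correct(raw, img, roi).corrected == pytest.approx(0.0)

    def test_additive_offset_invariance(self):
        stack, geom = generate_intensity_scene((64, 64), 200.0, 500.0, 50.0)
        img = zsum_project(stack, (0, 1))
        raw = measure_roi_mean(img, geom["ring"])
        base = background_correct(raw, img, geom["cytoplasm"]).corrected
        shifted = img + 42.0
        raw2 = measure_roi_mean(shifted, geom["ring"])
        assert background_correct(raw2, shifted, geom["cytoplasm"]).corrected == \
            pytest.approx(base)


class TestEventScoring:
    def _one(self, completed, observed, regressed, reg_time=np.nan, area=400.0):
        return pd.DataFrame(
            [
                {
                    "cell_id": "c",
                    "constriction_completed": completed,
                    "observed_post_min": observed,
                    "regressed": regressed,
                    "regression_time_min": reg_time,
                    "pre_division_area_px": area,
                }
            ]
        )

    def test_rule_table(self):
        scored, _ = score_division_events(self._one(True, 25.0, False), max_area_px=800)
        assert scored["category"].tolist() == [1]
        scored, _ = score_division_events(
            self._one(False, 10.0, True, reg_time=5.0), max_area_px=800
        )
        assert scored["category"].tolist() == [2]
        scored, _ = score_division_events(
            self._one(True, 40.0, True, reg_time=30.0), max_area_px=800
        )
        assert scored["category"].tolist() == [3]

    def test_short_observation_and_oversize_are_dropped(self):
        short = self._one(True, 12.0, False)
        big = self._one(True, 30.0, False, area=5000.0)
        for ev in (short, big):
            scored, summary = score_division_events(ev, max_area_px=800)
            assert len(scored) == 0
            assert summary["n_eligible"].iloc[0] == 0

    def test_planted_proportions_recovered_exactly(self):
        ev = generate_division_events(
            200, (0.7, 0.1, 0.2), n_oversize=7, n_short_observation=9, seed=11
        )
        scored, summary = score_division_events(ev, max_area_px=1000.0)
        assert (scored["category"] == scored["true_category"]).all()
        row = summary.iloc[0]
        assert row["n_eligible"] == 200
        assert (row["n_category_1"], row["n_category_2"], row["n_category_3"]) == (
            140, 20, 40,
        )
        assert row["pct_failure"] == pytest.approx(30.0)
        assert row["n_dropped_oversize"] == 7
        assert row["n_dropped_short_observation"] == 9

    def test_filters_commute(self):
        ev = generate_division_events(
            120, (0.6, 0.2, 0.2), n_oversize=6, n_short_observation=6, seed=2
        )
        cap = 1000.0
        # area-first: drop oversize, then score with an ineffective cap
        area_first = ev[ev["pre_division_area_px"] <= cap]
        s1, _ = score_division_events(area_first, max_area_px=np.inf)
        # time-first: drop short observations, then apply the area cap
        keep_time = ~(
            ev["constriction_completed"]
            & ~ev["regressed"]
            & (ev["observed_post_min"] < 20)
        )
        s2, _ = score_division_events(ev[keep_time], max_area_px=cap)
        key = ["cell_id", "category"]
        assert s1.sort_values("cell_id")[key].reset_index(drop=True).equals(
            s2.sort_values("cell_id")[key].reset_index(drop=True)
        )

    def test_every_retained_event_has_one_category(self):
        ev = generate_division_events(150, (0.5, 0.25, 0.25), seed=8)
        scored, _ = score_division_events(ev, max_area_px=default_area_cap(ev))
        assert scored["category"].isin([1, 2, 3]).all()
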