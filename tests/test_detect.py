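"""Detection contracts: outlines, Hough voting against the brute-force
oracle, partial-arc scores, area sizing, artifact exclusion and
distribution statistics."""

import math

import numpy as np
import pytest

from cryoev._raster import draw_arc, draw_ring
from cryoev.detect import (area_to_diameter, component_records, exclude_artifacts,
                           hough_accumulate, hough_circles, mask_to_outlines,
                           size_distribution)
from cryoev.types import HoughConfig, ParticleRecord

from .oracles import brute_force_hough


def disc_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestOutlines:
    def test_disc_edge_at_boundary_radius(self):
        mask = disc_mask((64, 64), 32, 32, 20)
        edge = mask_to_outlines(mask, mode="edge")
        ys, xs = np.nonzero(edge)
        radii = np.hypot(ys - 32, xs - 32)
        assert radii.min() >= 18.5 and radii.max() <= 20.5
        # closed boundary: every edge pixel has edge neighbours
        assert edge.sum() > 2 * math.pi * 18

    def test_annulus_skeleton_at_mean_radius(self):
        outer = disc_mask((80, 80), 40, 40, 32)
        inner = disc_mask((80, 80), 40, 40, 27)
        skel = mask_to_outlines(outer & ~inner, mode="skeleton")
        ys, xs = np.nonzero(skel)
        radii = np.hypot(ys - 40, xs - 40)
        assert np.median(radii) == pytest.approx(29.5, abs=1.0)
        from scipy import ndimage
        n_components, _ = ndimage.label(skel, structure=np.ones((3, 3))), None
        assert n_components[1] == 1  # one closed ring

    def test_empty_mask_empty_outline(self):
        assert mask_to_outlines(np.zeros((32, 32), dtype=bool)).sum() == 0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            mask_to_outlines(np.arange(16.0).reshape(4, 4))


class TestHough:
    def test_perfect_ring_detected_with_unit_score(self):
        outline = draw_ring((101, 101), 50, 50, 30)
        cfg = HoughConfig(r_min=20, r_max=40)
        records = hough_circles(outline, cfg, pixel_size=2.2, mode="circles")
        assert len(records) == 1
        rec = records[0]
        assert rec.radius_px == 30
        assert (rec.y, rec.x) == (50, 50)
        assert rec.score >= 0.95
        assert rec.diameter_nm == pytest.approx(2 * 30 * 2.2)

    def test_partial_arc_score_tracks_fraction(self):
        outline = draw_arc((101, 101), 50, 50, 30, fraction=0.6)
        cfg = HoughConfig(r_min=20, r_max=40)
        rings = hough_circles(outline, cfg, pixel_size=2.2, mode="rings")
        best = max(rings, key=lambda r: r.score)
        assert best.radius_px == 30
        assert best.score == pytest.approx(0.6, abs=0.05)
        circles = hough_circles(outline, cfg, pixel_size=2.2, mode="circles")
        assert all(not (r.y == 50 and r.x == 50 and r.radius_px == 30)
                   for r in circles)

    def test_accumulator_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            outline = np.zeros((64, 64), dtype=bool)
            for _ in range(2):
                draw_ring((64, 64), int(rng.integers(16, 48)),
                          int(rng.integers(16, 48)), int(rng.integers(8, 14)),
                          out=outline)
            outline |= rng.random((64, 64)) < 0.01
            fast = hough_accumulate(outline, 6, 14)
            slow = brute_force_hough(outline, 6, 14)
            np.testing.assert_array_equal(fast, slow)

    def test_concentric_rings_survive_nms(self):
        # multilamellar vesicle: two concentric bilayer rings
        outline = draw_ring((121, 121), 60, 60, 25)
        draw_ring((121, 121), 60, 60, 50, out=outline)
        cfg = HoughConfig(r_min=20, r_max=55)
        records = hough_circles(outline, cfg, pixel_size=2.2, mode="rings")
        radii = sorted(r.radius_px for r in records if r.score >= 0.9)
        assert radii == [25, 50]

    def test_r_max_too_large_rejected(self):
        with pytest.raises(ValueError):
            hough_circles(np.zeros((64, 64), dtype=bool),
                          HoughConfig(r_min=6, r_max=40), 2.2)

    def test_translation_equivariance(self):
        outline = draw_arc((128, 128), 50, 44, 20, fraction=0.7, theta0=0.8)
        shifted = np.roll(np.roll(outline, 9, axis=0), -5, axis=1)
        cfg = HoughConfig(r_min=10, r_max=30)
        rec = hough_circles(outline, cfg, 2.2, mode="rings")
        rec_s = hough_circles(shifted, cfg, 2.2, mode="rings")
        a = sorted((r.y + 9, r.x - 5, r.radius_px, round(r.score, 9)) for r in rec)
        b = sorted((r.y, r.x, r.radius_px, round(r.score, 9)) for r in rec_s)
        assert a == b

    def test_rotation_permutes_detections(self):
        outline = np.zeros((128, 128), dtype=bool)
        draw_ring((128, 128), 40, 44, 16, out=outline)
        draw_arc((128, 128), 90, 80, 22, fraction=0.65, theta0=1.2, out=outline)
        rotated = np.rot90(outline).copy()
        cfg = HoughConfig(r_min=10, r_max=30)
        rec = hough_circles(outline, cfg, 2.2, mode="rings")
        rec_r = hough_circles(rotated, cfg, 2.2, mode="rings")
        h = 128
        # (y, x) -> (h-1-x, y) under np.rot90
        a = sorted((h - 1 - r.x, r.y, r.radius_px, round(r.score, 9)) for r in rec)
        b = sorted((r.y, r.x, r.radius_px, round(r.score, 9)) for r in rec_r)
        assert a == b


class TestAreaSizing:
    def test_unit_circle(self):
        assert area_to_diameter(math.pi) == pytest.approx(2.0)

    def test_disc_closed_form(self):
        assert area_to_diameter(math.pi * 30**2) == pytest.approx(60.0)

    def test_ellipse_area_equivalent(self):
        # 2:1 ellipse, semi-axes 40/20 nm: A = 800*pi
        assert area_to_diameter(800 * math.pi) == pytest.approx(56.5685, abs=1e-3)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            area_to_diameter(0.0)

    @pytest.mark.parametrize("d", [0.5, 2.0, 45.3, 440.0])
    def test_round_trip(self, d):
        assert area_to_diameter(math.pi * (d / 2) ** 2) == pytest.approx(d)

    def test_component_records_from_counted_pixels(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:20, 10:20] = True  # 100 px component
        recs = component_records(mask, pixel_size=2.2)
        assert len(recs) == 1
        assert recs[0].diameter_nm == pytest.approx(2 * math.sqrt(100 * 2.2**2 / math.pi))
        assert recs[0].source == "area"

    def test_touching_discs_merge(self):
        mask = disc_mask((64, 64), 32, 20, 10) | disc_mask((64, 64), 32, 38, 10)
        recs = component_records(mask, pixel_size=1.0)
        assert len(recs) == 1  # documented limitation

    def test_min_area_filter(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[5, 5:8] = True  # 3 px
        assert component_records(mask, 1.0, min_area=5) == []


class TestExclusion:
    def rec(self, y, x, r, **kw):
        return ParticleRecord(class_name="EV_bilayer", y=y, x=x, radius_px=r,
                              diameter_nm=2 * r * 2.2, score=0.9,
                              source="hough_ring", **kw)

    def test_concentric_with_hole_excluded(self):
        out = exclude_artifacts([self.rec(100, 100, 450)], (256, 256),
                                hole_center=(102, 99), hole_radius_px=455)
        assert out[0].excluded and out[0].exclusion_reason == "hole_rim"

    def test_osculating_rim_arc_excluded(self):
        # small circle fitted to a stretch of rim: centre at R_rim - r
        hole = (-200, -50)
        r_rim = 450.0
        r = 20
        d = r_rim - r
        ang = 0.7
        y = hole[0] + d * math.sin(ang)
        x = hole[1] + d * math.cos(ang)
        out = exclude_artifacts([self.rec(y, x, r)], (256, 256),
                                hole_center=hole, hole_radius_px=r_rim)
        assert out[0].excluded and out[0].exclusion_reason == "hole_rim"

    def test_interior_particle_kept(self):
        out = exclude_artifacts([self.rec(128, 128, 15)], (256, 256),
                                hole_center=(-200, -50), hole_radius_px=450)
        assert not out[0].excluded

    def test_border_truncated_flagged(self):
        out = exclude_artifacts([self.rec(5, 128, 15, border_truncated=True)],
                                (256, 256))
        assert out[0].excluded and out[0].exclusion_reason == "border_truncated"

    def test_ice_overlap_flagged(self):
        ice = np.zeros((64, 64), dtype=bool)
        ice[20:50, 20:50] = True
        out = exclude_artifacts([self.rec(32, 32, 8)], (64, 64), ice_mask=ice)
        assert out[0].excluded and out[0].exclusion_reason == "ice_overlap"

    def test_nothing_deleted(self):
        recs = [self.rec(30, 30, 10), self.rec(5, 5, 12, border_truncated=True)]
        out = exclude_artifacts(recs, (64, 64))
        assert len(out) == len(recs)


class TestSizeDistribution:
    def rec(self, d, excluded=False):
        return ParticleRecord(class_name="EV_bilayer", y=0, x=0, radius_px=d / 4.4,
                              diameter_nm=d, score=1.0, source="hough_ring",
                              excluded=excluded)

    def test_median_and_count(self):
        dist = size_distribution([self.rec(40), self.rec(50), self.rec(60)])
        assert dist.median == 50
        assert dist.count == 3
        assert dist.sd == pytest.approx(10.0)

    def test_single_record_sd_flagged(self):
        dist = size_distribution([self.rec(45)])
        assert dist.sd == 0.0 and not dist.sd_defined

    def test_empty_flagged_not_nan_propagated(self):
        dist = size_distribution([])
        assert dist.count == 0 and not dist.median_defined
        assert dist.as_dict()["median_nm"] is None

    def test_excluded_records_ignored(self):
        dist = size_distribution([self.rec(40), self.rec(400, excluded=True)])
        assert dist.count == 1

    def test_histogram_half_open_bins(self):
        dist = size_distribution([self.rec(40), self.rec(49.999), self.rec(50)],
                                 bin_width_nm=10)
        assert dist.bin_edges[0] == 40
        assert dist.bin_counts[0] == 2 and dist.bin_counts[1] == 1
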