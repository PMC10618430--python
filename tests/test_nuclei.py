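import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pnpmetrics.core_io import Annotation
from pnpmetrics.nuclei import (
    filter_particles,
    measure_nuclei,
    measure_particles,
    nuc_cyt_ratio,
    ratio_gradient,
    segment_nuclei,
)
from pnpmetrics import synth


def _disk_image(centers, radius_px, n=256, value=200.0, background=10.0):
    img = np.full((n, n), background)
    yy, xx = np.mgrid[0:n, 0:n]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2] = value
    return img


def _annotation(h=128.0, w=128.0):
    return Annotation(
        midline=np.array([[0.0, w / 2], [h, w / 2]]),
        zp_position=np.array([h, w / 2]),
    )


class TestSegmentNuclei:
    def test_well_separated_disks(self):
        centers = [(y, x) for y in range(20, 282, 38) for x in range(20, 282, 38)][:50]
        img = _disk_image(centers, radius_px=6, n=300)
        labels = segment_nuclei(img, pixel_size_um=0.5)
        assert labels.max() == len(centers)
        # centroids within 1 px of truth
        from skimage.measure import regionprops

        found = sorted(tuple(np.round(p.centroid, 1)) for p in regionprops(labels))
        for (fy, fx), (ty, tx) in zip(found, sorted(centers)):
            assert abs(fy - ty) <= 1.0 and abs(fx - tx) <= 1.0

    def test_touching_disks_split(self):
        # two disks overlapping by ~20% of the radius
        r = 8
        img = _disk_image([(40, 40), (40, 40 + int(1.8 * r))], radius_px=r, n=96)
        labels = segment_nuclei(img, pixel_size_um=0.5)
        assert labels.max() == 2

    def test_blank_image(self):
        assert segment_nuclei(np.zeros((64, 64)), 0.5).max() == 0


class TestParticleFilter:
    def test_closed_bounds_fixture(self):
        """Particles straddling the area and circularity cuts classify exactly.

        Shapes are designed around the 2-100 um^2 / 0.6-1 circularity window;
        expected labels are derived from the same calibrated measures the
        filter uses, so the check isolates the selection logic.
        """
        px = 0.5
        shapes = []
        # disks of increasing radius: area = pi r^2 um^2
        for r_um in (0.5, 0.9, 2.0, 4.0, 5.6, 6.5):
            shapes.append(("disk", r_um))
        # bars of fixed width, increasing length: circularity decays
        for L_um in (4.0, 8.0, 14.0, 20.0, 30.0, 40.0):
            shapes.append(("bar", L_um))
        n = 160
        img = np.zeros((n * len(shapes) // 4, 4 * n))  # generous canvas
        labels = np.zeros_like(img, dtype=np.int32)
        yy0 = 0
        for i, (kind, size_um) in enumerate(shapes):
            cy, cx = 60 + 110 * (i // 4), 60 + (i % 4) * n
            yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
            if kind == "disk":
                mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= (size_um / px) ** 2
            else:
                half = size_um / px / 2
                mask = (np.abs(yy - cy) <= 2) & (np.abs(xx - cx) <= half)
            labels[mask] = i + 1
        measures = measure_particles(labels, px).set_index("label")
        kept = filter_particles(labels, px)
        kept_ids = set(np.unique(kept[kept > 0]).tolist())
        for lab, row in measures.iterrows():
            in_area = 2.0 <= row.area_um2 <= 100.0
            in_circ = 0.6 <= min(row.circularity, 1.0) <= 1.0
            assert (lab in kept_ids) == (in_area and in_circ), (lab, dict(row))
        # the fixture must actually straddle both cuts
        assert measures.area_um2.min() < 2.0 and measures.area_um2.max() > 100.0
        assert measures.circularity.min() < 0.6

    def test_filter_is_subset_and_idempotent(self):
        img = _disk_image([(30, 30), (30, 70), (70, 50)], radius_px=5, n=100)
        labels = segment_nuclei(img, 0.5)
        once = filter_particles(labels, 0.5)
        assert set(np.unique(once)) <= set(np.unique(labels))
        np.testing.assert_array_equal(once, filter_particles(once, 0.5))

    def test_circularity_near_one_for_large_disks(self):
        img = _disk_image([(60, 60)], radius_px=40, n=120)
        labels = (img > 100).astype(np.int32)
        circ = measure_particles(labels, 1.0).circularity[0]
        assert circ == pytest.approx(1.0, abs=0.03)

    def test_circularity_decreases_with_elongation(self):
        circs = []
        for aspect in (1.0, 1.5, 2.5, 4.0):
            yy, xx = np.mgrid[0:200, 0:200] - 100.0
            mask = ((yy / (12 * aspect)) ** 2 + (xx / 12) ** 2 <= 1).astype(np.int32)
            circs.append(measure_particles(mask, 1.0).circularity[0])
        assert all(a > b for a, b in zip(circs, circs[1:]))


class TestMeasureNuclei:
    def test_uniform_intensities_give_exact_ratio(self):
        labels = _disk_image([(64, 64)], radius_px=8, n=128, value=1, background=0).astype(np.int32)
        yap = np.full((128, 128), 200.0)
        dapi = np.full((128, 128), 100.0)
        recs = measure_nuclei(labels, yap, dapi, _annotation(), 0.5)
        assert len(recs) == 1
        assert recs[0].yap_dapi_ratio == pytest.approx(2.0)

    def test_ratio_linear_in_yap_scaling(self):
        rng = np.random.default_rng(2)
        labels = _disk_image([(40, 40), (80, 90)], radius_px=6, n=128, value=1, background=0).astype(np.int32)
        from skimage.measure import label as cc

        labels = cc(labels)
        yap = rng.uniform(50, 150, (128, 128))
        dapi = rng.uniform(80, 120, (128, 128))
        r1 = measure_nuclei(labels, yap, dapi, _annotation(), 0.5)
        r3 = measure_nuclei(labels, 3.0 * yap, dapi, _annotation(), 0.5)
        for a, b in zip(r1, r3):
            assert b.yap_dapi_ratio == pytest.approx(3.0 * a.yap_dapi_ratio, rel=1e-12)

    def test_zero_dapi_flagged(self):
        labels = _disk_image([(64, 64)], radius_px=8, n=128, value=1, background=0).astype(np.int32)
        recs = measure_nuclei(labels, np.full((128, 128), 10.0), np.zeros((128, 128)), _annotation(), 0.5)
        assert recs[0].flags == "zero_dapi"
        assert np.isnan(recs[0].yap_dapi_ratio)

    def test_end_to_end_ratios_track_generator_truth(self, sheet_scene):
        """Measured per-nucleus ratios stay within the noise envelope of truth."""
        params, stack, truth = sheet_scene
        from pnpmetrics.surface import extract_surface, project_band

        depth = extract_surface(stack, "membrane", intensity_floor=1.0)
        proj = project_band(stack, depth, 10.0)
        labels = filter_particles(
            segment_nuclei(proj.channel("dapi"), proj.pixel_size_um), proj.pixel_size_um
        )
        recs = measure_nuclei(
            labels, proj.channel("yap"), proj.channel("dapi"), truth.annotation, proj.pixel_size_um
        )
        tt = truth.nucleus_table
        matched = 0
        for rec in recs:
            d = np.hypot(tt.centroid_y_um - rec.centroid_y_um, tt.centroid_x_um - rec.centroid_x_um)
            row = tt.iloc[int(d.idxmin())]
            if d.min() < 3.0:
                matched += 1
                assert rec.yap_dapi_ratio == pytest.approx(row.ratio_noiseless, rel=0.30)
        assert matched >= 0.8 * len(tt)


class TestRatioGradient:
    def test_matches_brute_force_oracle(self):
        params = synth.SceneParams(seed=7, ratio_slope_per_um=-0.01)
        recs, truth = synth.make_nucleus_table(params, n_nuclei=1000)
        grad = ratio_gradient(recs, "mediolateral")
        ml = np.array([r.mediolateral_um for r in recs])
        rat = np.array([r.yap_dapi_ratio for r in recs])
        num = np.sum((ml - ml.mean()) * (rat - rat.mean()))
        den = np.sqrt(np.sum((ml - ml.mean()) ** 2) * np.sum((rat - rat.mean()) ** 2))
        assert grad.r == pytest.approx(num / den, abs=1e-9)

    def test_constant_ratio_within_null_band(self):
        params = synth.SceneParams(seed=8, ratio_slope_per_um=0.0)
        recs, _ = synth.make_nucleus_table(params, n_nuclei=1000)
        grad = ratio_gradient(recs)
        assert abs(grad.r) < 1.96 / np.sqrt(grad.n - 3)  # 95% null band (Fisher)

    def test_noiseless_linear_gradient_is_exact(self):
        params = synth.SceneParams(seed=9, ratio_slope_per_um=-0.01, ratio_noise_sd=0.0)
        recs, _ = synth.make_nucleus_table(params, n_nuclei=200)
        assert ratio_gradient(recs).r == pytest.approx(-1.0, abs=1e-12)

    def test_underpowered_rejected(self):
        params = synth.SceneParams(seed=10)
        recs, _ = synth.make_nucleus_table(params, n_nuclei=5)
        with pytest.raises(ValueError):
            ratio_gradient(recs)


class TestNucCytRatio:
    def test_programmed_ring_contrast(self):
        labels = _disk_image([(64, 64)], radius_px=8, n=128, value=1, background=0).astype(np.int32)
        yap = np.full((128, 128), 100.0)
        yap[labels > 0] = 300.0
        recs = measure_nuclei(labels, yap, np.full((128, 128), 50.0), _annotation(), 0.5)
        recs = nuc_cyt_ratio(recs, yap, labels, 0.5, ring_um=2.0)
        assert recs[0].nuc_cyt_ratio == pytest.approx(3.0, rel=0.02)

    def test_uniform_yap_gives_unity(self):
        labels = _disk_image([(64, 64)], radius_px=8, n=128, value=1, background=0).astype(np.int32)
        yap = np.full((128, 128), 120.0)
        recs = measure_nuclei(labels, yap, yap, _annotation(), 0.5)
        recs = nuc_cyt_ratio(recs, yap, labels, 0.5, ring_um=2.0)
        assert recs[0].nuc_cyt_ratio == pytest.approx(1.0)

    def test_group_difference_recovered(self):
        """Control (enrichment 2.0) vs Rock-inhibited (1.2) separate by t-test."""
        rng = np.random.default_rng(11)
        ratios = {"control": [], "rocki": []}
        for group, enrich in (("control", 2.0), ("rocki", 1.2)):
            for _ in range(12):
                labels = _disk_image([(32, 32)], radius_px=6, n=64, value=1, background=0).astype(np.int32)
                yap = np.full((64, 64), 100.0) + rng.normal(0, 5, (64, 64))
                yap[labels > 0] *= enrich
                recs = measure_nuclei(labels, yap, np.full((64, 64), 50.0), _annotation(64, 64), 0.5)
                recs = nuc_cyt_ratio(recs, yap, labels, 0.5)
                ratios[group].append(recs[0].nuc_cyt_ratio)
        t, p = sps.ttest_ind(ratios["control"], ratios["rocki"])
        assert p < 0.05 and t > 0

    def test_crowded_ring_flagged(self):
        labels = np.ones((32, 32), dtype=np.int32)  # no cytoplasm anywhere
        recs = measure_nuclei(labels, np.full((32, 32), 10.0), np.full((32, 32), 10.0), _annotation(32, 32), 0.5)
        recs = nuc_cyt_ratio(recs, np.full((32, 32), 10.0), labels, 0.5)
        assert "empty_ring" in recs[0].flags

    def test_invalid_ring_rejected(self):
        with pytest.raises(ValueError):
            nuc_cyt_ratio([], np.zeros((8, 8)), np.zeros((8, 8), dtype=np.int32), 0.5, ring_um=0.0)
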