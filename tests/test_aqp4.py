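"""Vessel segmentation, polarization index, radial CV, stereology."""

import numpy as np
import pandas as pd
import pytest

from glymphkit.aqp4 import (SegmentationParams, segment_vessels, classify_objects,
                            polarization_index, radial_cv, measure_vessels,
                            area_fraction, summarize_by_animal)
from glymphkit.micrograph import MicrographSpec, VesselSpec, make_vessel_micrograph

PX = 0.325


def grid_spec(n_vessels=12, noise_sd=0.3, seed=2):
    """Vessels on a lattice spaced well beyond the background expansion."""
    vessels = []
    diam = [6.0, 8.0, 20.0]
    for k in range(n_vessels):
        row, col = divmod(k, 4)
        vessels.append(VesselSpec((70.0 + 80.0 * col, 70.0 + 80.0 * row),
                                  diam[k % 3],
                                  wall_thickness_um=2.0 if diam[k % 3] > 10 else 1.5,
                                  pi_true=8.0 + (k % 5), radial_cv_true=0.05 * (k % 4)))
    return MicrographSpec(image_shape_px=(1100, 1100), vessels=tuple(vessels),
                          noise_sd=noise_sd, seed=seed)


class TestSegmentation:
    def test_recovers_all_generated_vessels(self):
        img, truth = make_vessel_micrograph(grid_spec())
        labels = segment_vessels(img, PX)
        assert labels.max() == len(truth)

    def test_all_zero_image_yields_no_objects(self):
        with pytest.warns(UserWarning, match="zero objects"):
            labels = segment_vessels(np.zeros((64, 64)), PX)
        assert labels.max() == 0

    def test_invariant_to_additive_offset(self):
        img, _ = make_vessel_micrograph(grid_spec(noise_sd=0.0))
        a = segment_vessels(img, PX)
        b = segment_vessels(img + 37.0, PX)
        assert np.array_equal(a, b)


class TestClassification:
    def _frame(self, diam, aspect=1.0, area=50.0):
        return pd.DataFrame([{"equiv_diameter_um": diam, "aspect_ratio": aspect,
                              "area_um2": area}])

    @pytest.mark.parametrize("diam,expected", [
        (6.0, "capillary"), (20.0, "small_vessel"), (10.0, "small_vessel"),
    ])
    def test_diameter_rule(self, diam, expected):
        assert classify_objects(self._frame(diam), PX).iloc[0] == expected

    def test_elongated_object_rejected(self):
        assert classify_objects(self._frame(6.0, aspect=5.0), PX).iloc[0] == "reject"

    def test_subfloor_area_rejected(self):
        assert classify_objects(self._frame(1.0, area=1.0), PX).iloc[0] == "reject"

    def test_order_permutation_invariance(self):
        df = pd.concat([self._frame(6.0), self._frame(20.0), self._frame(3.0, 5.0)],
                       ignore_index=True)
        fwd = classify_objects(df, PX)
        rev = classify_objects(df.iloc[::-1], PX)
        assert list(fwd) == list(rev[::-1])


class TestPolarizationIndex:
    def test_uniform_image_gives_unity(self):
        img = np.full((120, 120), 7.0)
        obj = np.zeros((120, 120), bool)
        obj[55:65, 55:65] = True
        assert polarization_index(obj, img, PX) == 1.0

    def test_scale_invariance_and_offset_shift(self):
        img, _ = make_vessel_micrograph(MicrographSpec(
            image_shape_px=(256, 256),
            vessels=(VesselSpec((40.0, 40.0), 8.0, pi_true=10.0),)))
        labels = segment_vessels(img, PX)
        obj = labels == 1
        pi = polarization_index(obj, img, PX, all_objects_mask=labels > 0)
        assert pi == pytest.approx(10.0, abs=1e-12)
        assert polarization_index(obj, 3.0 * img, PX, all_objects_mask=labels > 0) \
            == pytest.approx(pi, rel=1e-12)
        # additive offset c maps PI -> (max + c) / (bg + c)
        c = 20.0
        shifted = polarization_index(obj, img + c, PX, all_objects_mask=labels > 0)
        assert shifted == pytest.approx((100.0 + c) / (10.0 + c), rel=1e-12)

    def test_zero_background_is_flagged(self):
        img = np.zeros((64, 64))
        obj = np.zeros((64, 64), bool)
        obj[30:34, 30:34] = True
        img[obj] = 5.0
        assert np.isnan(polarization_index(obj, img, PX))

    def test_neighbor_exclusion_changes_background(self):
        img, _ = make_vessel_micrograph(MicrographSpec(
            image_shape_px=(512, 512),
            vessels=(VesselSpec((60.0, 60.0), 8.0, pi_true=10.0),
                     VesselSpec((110.0, 60.0), 8.0, pi_true=10.0))))
        labels = segment_vessels(img, PX)
        obj = labels == 1
        with_excl = polarization_index(obj, img, PX, all_objects_mask=labels > 0)
        without = polarization_index(obj, img, PX, all_objects_mask=None)
        assert with_excl == pytest.approx(10.0, abs=1e-9)
        assert without <= with_excl  # bright neighbour can only raise the bg

    def test_empty_object_flagged(self):
        assert np.isnan(polarization_index(np.zeros((8, 8), bool),
                                           np.ones((8, 8)), PX))


class TestRadialCV:
    def test_scale_invariance(self):
        img, _ = make_vessel_micrograph(MicrographSpec(
            image_shape_px=(256, 256),
            vessels=(VesselSpec((40.0, 40.0), 8.0, radial_cv_true=0.2),)))
        labels = segment_vessels(img, PX)
        obj = labels == 1
        assert radial_cv(obj, 2.0 * img) == pytest.approx(radial_cv(obj, img),
                                                          rel=1e-12)

    def test_too_few_pixels_rejected(self):
        obj = np.zeros((8, 8), bool)
        obj[0, :4] = True
        with pytest.raises(ValueError, match="n_wedges"):
            radial_cv(obj, np.ones((8, 8)), n_wedges=8)


class TestMeasureVessels:
    def test_recovery_on_noiseless_image(self, three_vessel_spec):
        img, truth = make_vessel_micrograph(three_vessel_spec)
        df = measure_vessels(img, three_vessel_spec.pixel_size_um)
        assert len(df) == len(truth)
        df = df.sort_values("equiv_diameter_um").reset_index(drop=True)
        truth = truth.sort_values("diameter_um").reset_index(drop=True)
        assert list(df["class"]) == list(truth["class"])
        np.testing.assert_allclose(df["pi"], truth["pi_true"], rtol=1e-9)
        np.testing.assert_allclose(df["radial_cv"], truth["radial_cv_true"],
                                   atol=5e-3)

    def test_empty_image_yields_empty_frame(self):
        with pytest.warns(UserWarning):
            df = measure_vessels(np.zeros((64, 64)), PX)
        assert len(df) == 0 and "class" in df.columns


class TestAreaFraction:
    def test_full_and_empty_masks(self):
        full = np.ones((400, 400), bool)
        for seed in (0, 1, 2):
            assert area_fraction(full, PX, seed=seed).fraction == 1.0
        assert area_fraction(np.zeros((400, 400), bool), PX, seed=0).fraction == 0.0

    def test_reproducible_by_seed(self, speckle_mask):
        a = area_fraction(speckle_mask, PX, seed=5)
        b = area_fraction(speckle_mask, PX, seed=5)
        assert (a.fraction, a.hits, a.total_markers) == \
            (b.fraction, b.hits, b.total_markers)

    def test_small_roi_falls_back_to_lattice(self):
        mask = np.ones((60, 60), bool)
        roi = np.zeros((60, 60), bool)
        roi[10:40, 10:40] = True   # ~10 um, far below the 100 um frame
        with pytest.warns(UserWarning, match="full-ROI"):
            res = area_fraction(mask, PX, roi_mask=roi, seed=0)
        assert res.fraction == 1.0 and res.total_markers > 0


class TestSummaries:
    def _objects(self):
        rows = []
        for animal, genotype, pis in [("a1", "wt", [10.0, 12.0, 14.0]),
                                      ("a2", "ko", [15.0, 17.0])]:
            for p in pis:
                rows.append({"animal": animal, "genotype": genotype,
                             "class": "capillary", "pi": p, "radial_cv": 0.1,
                             "pi_valid": True})
        return pd.DataFrame(rows)

    def test_per_animal_means(self):
        s = summarize_by_animal(self._objects()).set_index(["animal", "vessel_class"])
        assert s.loc[("a1", "capillary"), "mean_pi"] == pytest.approx(12.0)
        assert s.loc[("a2", "capillary"), "mean_pi"] == pytest.approx(16.0)
        assert s.loc[("a1", "small_vessel"), "n_objects"] == 0
        assert np.isnan(s.loc[("a1", "small_vessel"), "mean_pi"])

    def test_flagged_objects_excluded(self):
        df = self._objects()
        df.loc[0, "pi_valid"] = False
        s = summarize_by_animal(df).set_index(["animal", "vessel_class"])
        assert s.loc[("a1", "capillary"), "mean_pi"] == pytest.approx(13.0)

    def test_group_shift_recovered_from_synthetic_cohort(self):
        """4 vs 4 animals whose capillaries differ by +2.5 in true PI."""
        rows = []
        rng = np.random.default_rng(9)
        for g, (genotype, shift) in enumerate([("wt", 0.0), ("ko", 2.5)]):
            for a in range(4):
                spec = MicrographSpec(
                    image_shape_px=(700, 700), noise_sd=0.2,
                    seed=100 * g + a,
                    vessels=tuple(
                        VesselSpec((60.0 + 100.0 * c, 60.0 + 100.0 * r), 7.0,
                                   pi_true=10.0 + shift + rng.normal(0, 0.2))
                        for r in range(2) for c in range(2)))
                img, _ = make_vessel_micrograph(spec)
                df = measure_vessels(img, spec.pixel_size_um)
                df["animal"] = f"{genotype}{a}"
                df["genotype"] = genotype
                rows.append(df)
        summary = summarize_by_animal(pd.concat(rows, ignore_index=True))
        caps = summary[summary.vessel_class == "capillary"]
        diff = caps[caps.genotype == "ko"].mean_pi.mean() - \
            caps[caps.genotype == "wt"].mean_pi.mean()
        assert diff == pytest.approx(2.5, abs=0.3)
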