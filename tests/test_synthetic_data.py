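"""Generators: determinism, ground-truth consistency, calibration."""

import numpy as np
import pytest
from scipy import stats

from explantkit.records import TURNS
from explantkit.synthetic_data import (
    BodySpec,
    DirectionSpec,
    ExplantImageSpec,
    SectionImageSpec,
    StudyGroup,
    StudySpec,
    dissect_ear,
    generate_explant_image,
    generate_outgrowth_geometry,
    generate_section_image,
    generate_study_table,
)


SMALL = dict(
    image_shape=(512, 512),
    body=BodySpec(area_um2=6_000.0),
    n_start_points=5,
    neurites_per_start=(1, 2),
    length_median_um=60.0,
)


class TestExplantImage:
    def test_empty_outgrowth(self):
        img, gt = generate_explant_image(ExplantImageSpec(**{**SMALL, "n_start_points": 0}))
        assert gt.n_endings == 0
        assert gt.total_length_um == 0.0
        assert img.shape == (2, 512, 512) and img.dtype == np.uint16

    def test_seed_determinism(self):
        spec = ExplantImageSpec(**SMALL, seed=11)
        img1, gt1 = generate_explant_image(spec)
        img2, gt2 = generate_explant_image(spec)
        assert np.array_equal(img1, img2)
        assert np.array_equal(gt1.lengths_um, gt2.lengths_um)
        assert np.array_equal(gt1.endings, gt2.endings)

    def test_channels(self):
        spec = ExplantImageSpec(**SMALL, seed=2)
        img, gt = generate_explant_image(spec)
        # neuronal channel covers body + neurites, nuclear channel only body
        assert img[1][gt.neurite_mask].mean() > 3 * img[1][~(gt.neurite_mask | gt.body_mask)].mean()
        outside = ~gt.body_mask
        assert img[0][outside].mean() < 0.2 * spec.signal_level

    def test_body_exceeding_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            generate_outgrowth_geometry(
                ExplantImageSpec(image_shape=(256, 256), body=BodySpec(area_um2=1e6))
            )

    def test_length_distribution_calibration(self):
        # oracle: the stated log-normal sampled directly
        spec = ExplantImageSpec(
            image_shape=(4096, 4096),
            n_start_points=125,
            neurites_per_start=(4, 4),
            branch_probability=0.0,
            length_median_um=316.0,
            seed=42,
        )
        gt = generate_outgrowth_geometry(spec)
        assert gt.n_endings == 500
        med = np.median(gt.lengths_um)
        assert abs(med - 316.0) / 316.0 < 0.10
        oracle = np.exp(np.random.default_rng(1).normal(np.log(316.0), spec.length_sigma, 500))
        assert abs(np.median(oracle) - med) / 316.0 < 0.15

    def test_ground_truth_consistency(self):
        spec = ExplantImageSpec(**SMALL, branch_probability=0.3, seed=5)
        gt = generate_outgrowth_geometry(spec)
        # total length equals the polyline-length oracle over unique paths
        oracle = sum(
            np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)) * spec.pixel_size_um
            for p in gt.neurite_paths
        )
        assert gt.total_length_um == pytest.approx(oracle, abs=1e-6)
        assert gt.n_endings >= len(gt.start_points)
        # every ending is the terminus of exactly one polyline
        tips = {tuple(np.round(p[-1], 6)) for p in gt.neurite_paths}
        assert all(tuple(np.round(e, 6)) in tips for e in gt.endings)


class TestSectionImage:
    def test_zero_fraction(self):
        rgb, mask, realized = generate_section_image(SectionImageSpec(positive_fraction=0.0))
        assert not mask.any()
        assert realized is None

    def test_saturation_endpoint(self):
        spec = SectionImageSpec(target_ir=255.0, stain_shade_jitter=0.0, seed=3)
        rgb, mask, realized = generate_section_image(spec)
        assert mask.any()
        assert np.all(rgb[mask] == 0)
        assert realized == pytest.approx(255.0)

    def test_target_ir_recovered(self):
        spec = SectionImageSpec(target_ir=148.0, positive_fraction=0.3, seed=9)
        rgb, mask, realized = generate_section_image(spec)
        assert realized == pytest.approx(148.0, abs=2.0)

    def test_mask_fraction(self):
        from skimage.draw import polygon2mask

        spec = SectionImageSpec(positive_fraction=0.3, seed=9)
        _, mask, _ = generate_section_image(spec)
        roi = polygon2mask(spec.image_shape, spec.roi())
        assert mask.sum() / roi.sum() == pytest.approx(0.3, abs=0.02 * 0.3 + 1e-3)

    def test_empty_roi_rejected(self):
        square = np.array([[10.0, 10.0], [10.0, 50.0], [50.0, 50.0], [50.0, 10.0]])
        with pytest.raises(ValueError, match="ROI"):
            generate_section_image(
                SectionImageSpec(
                    roi_polygon=square, exclusion_polygons=(square,), positive_fraction=0.5
                )
            )


def _single_group_spec(n, seed=42, median_endings=107.0, median_length=316.0):
    return StudySpec(
        groups=(StudyGroup("NT CTRL", "apical", n, median_endings, median_length, is_control=True),),
        seed=seed,
    )


class TestStudyTable:
    def test_row_count(self):
        groups = tuple(
            StudyGroup(f"g{i}", turn, 1, 100.0, 300.0) for i, turn in enumerate(TURNS)
        )
        assert len(generate_study_table(StudySpec(groups=groups))) == 3

    def test_median_calibration(self):
        tab = generate_study_table(_single_group_spec(500))
        assert abs(tab["n_endings"].median() - 107.0) / 107.0 < 0.10
        assert abs(tab["median_length_um"].median() - 316.0) / 316.0 < 0.10

    def test_zero_litter_sd_no_litter_component(self):
        spec = StudySpec(
            groups=(StudyGroup("NT CTRL", "apical", 360, 107.0, 316.0, is_control=True),),
            litter_sd=0.0,
            explants_per_litter=36,
            seed=3,
        )
        tab = generate_study_table(spec)
        groups = [np.log(g["n_endings"].to_numpy()) for _, g in tab.groupby("litter")]
        _, p = stats.f_oneway(*groups)
        assert p > 0.01  # between-litter variance indistinguishable from within

    def test_duplicate_groups_rejected(self):
        g = StudyGroup("A", "apical", 5, 10.0, 100.0)
        with pytest.raises(ValueError, match="duplicate"):
            StudySpec(groups=(g, g))

    def test_covariates_zero_effect(self):
        tab = generate_study_table(_single_group_spec(400, seed=8))
        a = tab.loc[tab.sex == "female", "n_endings"]
        b = tab.loc[tab.sex == "male", "n_endings"]
        _, p = stats.mannwhitneyu(a, b)
        assert p > 0.01

    def test_es_design_plates_mixed(self):
        groups = (
            StudyGroup("ES CTRL", "apical", 12, 385.0, 520.0, is_control=True),
            StudyGroup("ES 1000", "apical", 12, 240.0, 450.0),
        )
        tab = generate_study_table(StudySpec(groups=groups, design="es", wells_per_plate=8))
        per_plate = tab.groupby("plate")["is_control"].agg(["sum", "count"])
        assert (per_plate["sum"] * 2 == per_plate["count"]).all()


class TestDissection:
    def test_six_per_ear(self):
        recs = dissect_ear(seed=0)
        assert len(recs) == 6

    def test_turn_split(self):
        recs = dissect_ear(seed=123)
        counts = {t: sum(r.turn == t for r in recs) for t in TURNS}
        assert counts == {"apical": 2, "middle": 2, "basal": 2}

    def test_two_ears(self):
        recs = dissect_ear(side="left") + dissect_ear(side="right")
        assert len(recs) == 12
        assert {r.side for r in recs} == {"left", "right"}
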