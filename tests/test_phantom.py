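import numpy as np
import pytest

from ctca_audit.evaluation import dice
from ctca_audit.io import BRANCH_CODES, Mask
from ctca_audit.phantom import (Lesion, PhantomSpec, default_tree, degrade_segmentation,
                                generate_cohort, generate_phantom, pseudo_segment,
                                threshold_segment)
from ctca_audit.quality import (artery_contrast_enhancement, contrast_to_noise_ratio,
                                edge_sharpness)
from conftest import make_mask
import _oracles

SMALL = dict(shape=(64, 64, 64), spacing=(0.75, 0.75, 0.75))


class TestGeneratePhantom:
    def test_same_spec_same_seed_bit_identical(self):
        s1 = PhantomSpec(**SMALL, noise_sd=15.0, blur_sigma=0.8, seed=5)
        s2 = PhantomSpec(**SMALL, noise_sd=15.0, blur_sigma=0.8, seed=5)
        a, b = generate_phantom(s1), generate_phantom(s2)
        np.testing.assert_array_equal(a.volume.values, b.volume.values)
        np.testing.assert_array_equal(a.labelled_mask.labels, b.labelled_mask.labels)

    def test_distinct_seeds_distinct_noise(self):
        a = generate_phantom(PhantomSpec(**SMALL, noise_sd=15.0, seed=1))
        b = generate_phantom(PhantomSpec(**SMALL, noise_sd=15.0, seed=2))
        assert not np.array_equal(a.volume.values, b.volume.values)

    def test_no_lesions_zero_calcium(self):
        case = generate_phantom(PhantomSpec(**SMALL))
        assert case.calcium_score == 0.0
        from ctca_audit.stats import stratify_calcium

        assert stratify_calcium(case.calcium_score).value == "none"

    def test_noiseless_contrast_exact(self, noiseless_phantom):
        # closed loop against brute-force means over the enumerated voxel sets
        ace = artery_contrast_enhancement(noiseless_phantom.volume, noiseless_phantom.tree_mask)
        assert ace == pytest.approx(350.0, abs=1e-9)
        brute = _oracles.brute_ace(noiseless_phantom.volume.values,
                                   noiseless_phantom.tree_mask.foreground(), 3)
        assert ace == pytest.approx(brute, abs=1e-9)

    def test_all_branches_present_and_aligned(self, noiseless_phantom):
        labels = set(np.unique(noiseless_phantom.labelled_mask.labels)) - {0}
        assert labels == set(BRANCH_CODES.values())
        from ctca_audit.io import check_aligned

        check_aligned(noiseless_phantom.volume, noiseless_phantom.labelled_mask)

    def test_curve_exiting_volume_rejected(self):
        with pytest.raises(ValueError, match="exits"):
            generate_phantom(PhantomSpec(shape=(32, 32, 32), spacing=(0.75,) * 3))

    def test_lesion_floor_enforced(self):
        with pytest.raises(ValueError, match="130"):
            Lesion("LAD", 0.5, 1.0, 100.0)

    def test_agatston_style_score(self):
        lesions = [Lesion("LAD", 0.4, 1.0, 150.0), Lesion("RCA", 0.5, 1.0, 450.0)]
        case = generate_phantom(PhantomSpec(**SMALL, lesions=lesions))
        vol = 4.0 / 3.0 * np.pi
        assert case.calcium_score == pytest.approx(vol * 1 + vol * 4)


class TestBlooming:
    def test_lesion_shell_brighter_than_lesion_free_twin(self):
        lesion = Lesion("LAD", 0.5, 1.5, 700.0)
        with_les = generate_phantom(PhantomSpec(**SMALL, blur_sigma=1.0, lesions=[lesion]))
        without = generate_phantom(PhantomSpec(**SMALL, blur_sigma=1.0))
        # 1-voxel shell around the lesion sphere
        curve = default_tree()["LAD"]
        centre_axis = curve.point(0.5)[0]
        sp = np.array(SMALL["spacing"])
        idx = np.indices(SMALL["shape"]).astype(float)
        world = np.stack([idx[i] * sp[i] for i in range(3)], -1)
        d = np.linalg.norm(world - centre_axis, axis=-1)
        shell = (d > lesion.radius + curve.radius(0.5)[0]) & (d <= lesion.radius + curve.radius(0.5)[0] + 2 * sp[0])
        assert with_les.volume.values[shell].mean() > without.volume.values[shell].mean()


class TestMonotoneResponses:
    def test_contrast_enhancement_rises_with_lumen_hu(self):
        vals = []
        for lumen in (250.0, 400.0, 550.0):
            means = []
            for seed in range(3):
                c = generate_phantom(PhantomSpec(**SMALL, lumen_hu=lumen, noise_sd=10.0,
                                                 blur_sigma=0.6, seed=seed))
                means.append(artery_contrast_enhancement(c.volume, c.tree_mask))
            vals.append(np.mean(means))
        assert vals[0] < vals[1] < vals[2]

    def test_cnr_falls_with_noise(self):
        vals = []
        for noise in (5.0, 15.0, 30.0):
            means = []
            for seed in range(3):
                c = generate_phantom(PhantomSpec(**SMALL, noise_sd=noise, blur_sigma=0.6, seed=seed))
                means.append(contrast_to_noise_ratio(c.volume, c.tree_mask))
            vals.append(np.mean(means))
        assert vals[0] > vals[1] > vals[2]

    def test_edge_sharpness_falls_with_blur(self):
        vals = []
        for blur in (0.3, 0.8, 1.5):
            c = generate_phantom(PhantomSpec(**SMALL, blur_sigma=blur))
            vals.append(edge_sharpness(c.volume, c.tree_mask))
        assert vals[0] > vals[1] > vals[2]


class TestThresholdSegment:
    def test_noiseless_high_contrast_recovers_tree(self):
        case = generate_phantom(PhantomSpec(**SMALL))
        preds = pseudo_segment(case, windows=((200.0, 700.0),))
        assert dice(preds[0], case.tree_mask) >= 0.95

    def test_window_excluding_lumen_errors(self):
        case = generate_phantom(PhantomSpec(**SMALL))
        seed_vox = tuple(np.rint(case.volume.world_to_voxel(
            case.centreline.branches["LM"][0])[0]).astype(int))
        with pytest.raises(ValueError, match="outside window"):
            threshold_segment(case.volume, seed_vox, -200.0, 100.0)

    def test_dsc_nonincreasing_with_noise(self):
        # low-contrast, blurred conditions where boundary noise matters
        means = []
        for noise in (0.0, 10.0, 20.0, 40.0):
            ds = []
            for seed in range(10):
                case = generate_phantom(PhantomSpec(**SMALL, lumen_hu=360.0, noise_sd=noise,
                                                    blur_sigma=1.0, seed=seed))
                pred = pseudo_segment(case, windows=((200.0, 3000.0),))[0]
                ds.append(dice(pred, case.tree_mask))
            means.append(np.mean(ds))
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestDegradeSegmentation:
    def test_zero_jitter_identity(self, noiseless_phantom):
        out = degrade_segmentation(noiseless_phantom.tree_mask, 0, None, seed=0)
        assert dice(out, noiseless_phantom.tree_mask) == 1.0

    def test_drop_one_of_two_equal_branches(self):
        # two disjoint equal cubes labelled as LM / LAD
        lab = np.zeros((16, 16, 16), np.uint8)
        lab[2:6, 2:6, 2:6] = BRANCH_CODES["LM"]
        lab[10:14, 10:14, 10:14] = BRANCH_CODES["LAD"]
        labels = make_mask(lab, kind="labelled")
        ref = make_mask((lab > 0).astype(np.uint8))
        out = degrade_segmentation(ref, 0, ["LAD"], seed=0, labels=labels)
        assert dice(out, ref) == pytest.approx(2.0 / 3.0)

    def test_dropout_without_labels_rejected(self, noiseless_phantom):
        with pytest.raises(ValueError, match="labelled"):
            degrade_segmentation(noiseless_phantom.tree_mask, 0, ["LAD"], seed=0)

    def test_jitter_degrades_more_with_amplitude(self, noiseless_phantom):
        ref = noiseless_phantom.tree_mask
        d1 = np.mean([dice(degrade_segmentation(ref, 1, None, seed=s), ref) for s in range(20)])
        d2 = np.mean([dice(degrade_segmentation(ref, 2, None, seed=s), ref) for s in range(20)])
        assert d2 < d1 < 1.0

    def test_negative_jitter_rejected(self, noiseless_phantom):
        with pytest.raises(ValueError):
            degrade_segmentation(noiseless_phantom.tree_mask, -1, None, seed=0)


class TestGenerateCohort:
    def test_reproducible_with_both_sexes(self):
        kw = dict(n=8, seed=12, shape=(64, 64, 64), spacing=(0.75, 0.75, 0.75))
        c1 = generate_cohort(**kw)
        c2 = generate_cohort(**kw)
        assert len(c1) == 8
        assert {cc.case.meta.sex for cc in c1} == {"male", "female"}
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.case.volume.values, b.case.volume.values)
            np.testing.assert_array_equal(a.predictions[0].labels, b.predictions[0].labels)

    def test_lesion_free_range_all_none_stratum(self):
        from ctca_audit.stats import stratify_calcium

        cases = generate_cohort(n=6, seed=4, shape=(64, 64, 64), spacing=(0.75,) * 3,
                                factor_ranges={"n_lesions": (0, 0)})
        assert all(stratify_calcium(cc.case.calcium_score).value == "none" for cc in cases)

    def test_contrast_parameter_tracks_measured_enhancement(self):
        cases = generate_cohort(n=10, seed=9, shape=(64, 64, 64), spacing=(0.75,) * 3,
                                factor_ranges={"lumen_hu": (150.0, 500.0)})
        gen, meas = [], []
        for cc in cases:
            meas.append(artery_contrast_enhancement(cc.case.volume, cc.case.tree_mask))
            gen.append(cc.case.volume.values.max())  # proxy: brighter lumen
        assert np.corrcoef(gen, meas)[0, 1] > 0.5

    def test_female_radii_smaller_by_construction(self):
        cases = generate_cohort(n=12, seed=3, shape=(64, 64, 64), spacing=(0.75,) * 3)
        mean_r = {"male": [], "female": []}
        for cc in cases:
            r = np.concatenate(list(cc.case.centreline.radius.values()))
            mean_r[cc.case.meta.sex].append(float(r.mean()))
        assert np.mean(mean_r["female"]) < np.mean(mean_r["male"])

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(n=4, seed=0)
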