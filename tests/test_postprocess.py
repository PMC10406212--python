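import numpy as np
import pytest
from scipy import ndimage

from patchbleed.errors import DataError
from patchbleed.inference import label_components
from patchbleed.metrics import lesion_metrics, match_lesions
from patchbleed.postprocess import (
    PruningParams,
    apply_size_cutoff,
    categorize_region,
    correct_tissue_labels,
    dilate_shell,
    postprocess_map,
    prune_lesion,
)
from patchbleed.volume_io import ContrastVolume, Tissue

SHAPE = (20, 20, 12)


def t2star_with(background=100.0, dark=None):
    """Uniform T2* volume with optional dark voxel set."""
    data = np.full(SHAPE, background, dtype=np.float32)
    if dark is not None:
        coords, value = dark
        data[tuple(np.asarray(coords).T)] = value
    return ContrastVolume(data=data, spacing=(1, 1, 3), modality="T2star")


def cube(center, half):
    c = np.asarray(center)
    ranges = [np.arange(c[i] - half, c[i] + half + 1) for i in range(3)]
    return np.array(np.meshgrid(*ranges, indexing="ij")).reshape(3, -1).T


class TestCorrectTissueLabels:
    def test_quoted_relabeling_rules(self):
        tissue = np.array([[Tissue.CORTICAL_GM, Tissue.DEEP_GM,
                            Tissue.CEREBELLAR_GM, Tissue.WM]], dtype=np.int16)[None]
        wmh = np.ones_like(tissue, dtype=bool)
        out = correct_tissue_labels(tissue, wmh)
        assert out[0, 0, 0] == Tissue.WM
        assert out[0, 0, 1] == Tissue.WM
        assert out[0, 0, 2] == Tissue.CEREBELLAR_WM
        assert out[0, 0, 3] == Tissue.WM

    def test_untouched_outside_wmh(self):
        rng = np.random.default_rng(0)
        tissue = rng.integers(0, 7, size=(6, 6, 3)).astype(np.int16)
        wmh = np.zeros(tissue.shape, dtype=bool)
        np.testing.assert_array_equal(correct_tissue_labels(tissue, wmh), tissue)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            correct_tissue_labels(np.zeros((3, 3, 3)), np.zeros((4, 4, 4), dtype=bool))


class TestDilateShell:
    def test_shell_disjoint_from_lesion(self):
        lesion = cube((10, 10, 6), 1)
        shell = dilate_shell(lesion, SHAPE, 2)
        assert not set(map(tuple, shell)) & set(map(tuple, lesion))

    def test_interior_voxel_two_dilations_gives_124(self):
        # 26-connected unit dilation twice around one voxel spans a 5^3 cube
        shell = dilate_shell(np.array([[10, 10, 6]]), SHAPE, 2)
        assert len(shell) == 5**3 - 1
        assert np.abs(shell - [10, 10, 6]).max(axis=1).max() == 2

    def test_corner_lesion_clipped(self):
        shell = dilate_shell(np.array([[0, 0, 0]]), SHAPE, 2)
        assert len(shell) == 3**3 - 1  # only the in-bounds octant remains

    def test_empty_lesion_rejected(self):
        with pytest.raises(DataError):
            dilate_shell(np.empty((0, 3), dtype=int), SHAPE, 2)


class TestPruneLesion:
    def test_dark_lesion_in_bright_surround_unchanged(self):
        lesion = cube((10, 10, 6), 1)
        vol = t2star_with(background=100.0, dark=(lesion, 30.0))
        kept = prune_lesion(lesion, vol, PruningParams(ratio_threshold=1.2))
        assert set(map(tuple, kept)) == set(map(tuple, lesion))

    def test_uniform_intensity_lesion_fully_removed(self):
        lesion = cube((10, 10, 6), 1)
        vol = t2star_with(background=100.0)  # lesion == surround
        kept = prune_lesion(lesion, vol, PruningParams(ratio_threshold=1.2))
        assert len(kept) == 0

    def test_idempotent_fixed_point(self):
        rng = np.random.default_rng(1)
        lesion = cube((10, 10, 6), 2)
        data = rng.uniform(20, 100, SHAPE).astype(np.float32)
        vol = ContrastVolume(data=data, spacing=(1, 1, 3), modality="T2star")
        once = prune_lesion(lesion, vol, PruningParams(ratio_threshold=1.3))
        twice = prune_lesion(once, vol, PruningParams(ratio_threshold=1.3))
        assert set(map(tuple, once)) == set(map(tuple, twice))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        lesion = cube((10, 10, 6), 2)
        data = rng.uniform(30, 100, SHAPE).astype(np.float32)
        vol = ContrastVolume(data=data, spacing=(1, 1, 3), modality="T2star")
        kept = [
            set(map(tuple, prune_lesion(lesion, vol, PruningParams(ratio_threshold=t))))
            for t in (1.0, 1.2, 1.5, 2.0)
        ]
        for smaller_t, larger_t in zip(kept, kept[1:]):
            assert larger_t <= smaller_t

    def test_literal_ratio_removes_hypointense_lesion(self):
        # audit mode reproduces the printed formula: dark voxels have
        # voxel/shell < 1.2 and are removed
        lesion = cube((10, 10, 6), 1)
        vol = t2star_with(background=100.0, dark=(lesion, 30.0))
        kept = prune_lesion(lesion, vol,
                            PruningParams(ratio_threshold=1.2, literal_ratio=True))
        assert len(kept) == 0


class TestSizeCutoff:
    def test_12mm_lesion_discarded(self):
        line = np.array([[x, 5, 5] for x in range(2, 14)])  # 12 voxels at 1 mm
        assert not apply_size_cutoff(line, (1, 1, 3), 10.0)

    def test_single_voxel_always_kept(self):
        assert apply_size_cutoff(np.array([[5, 5, 5]]), (1, 1, 3), 10.0)

    def test_exactly_at_cutoff_kept(self):
        line = np.array([[x, 5, 5] for x in range(2, 12)])  # 10 voxels: 9 mm + 1 mm extent
        assert apply_size_cutoff(line, (1, 1, 3), 10.0)

    def test_through_plane_extent_uses_slice_spacing(self):
        column = np.array([[5, 5, z] for z in range(4)])  # 9 mm span + 3 mm extent
        assert not apply_size_cutoff(column, (1, 1, 3), 10.0)


class TestCategorizeRegion:
    def _tissue(self):
        return np.zeros(SHAPE, dtype=np.int16)

    def test_pure_deep_gm(self):
        tissue = self._tissue()
        lesion = cube((10, 10, 6), 1)
        tissue[tuple(lesion.T)] = Tissue.DEEP_GM
        assert categorize_region(lesion, tissue) == Tissue.DEEP_GM

    def test_majority_wins(self):
        tissue = self._tissue()
        lesion = np.array([[x, 5, 5] for x in range(10)])
        tissue[tuple(lesion[:6].T)] = Tissue.WM
        tissue[tuple(lesion[6:].T)] = Tissue.CORTICAL_GM
        assert categorize_region(lesion, tissue) == Tissue.WM

    def test_tie_broken_by_priority(self):
        tissue = self._tissue()
        lesion = np.array([[x, 5, 5] for x in range(10)])
        tissue[tuple(lesion[:5].T)] = Tissue.WM
        tissue[tuple(lesion[5:].T)] = Tissue.DEEP_GM
        assert categorize_region(lesion, tissue) == Tissue.DEEP_GM

    def test_csf_only_lesion_uncategorized(self):
        tissue = self._tissue()
        lesion = cube((10, 10, 6), 1)
        tissue[tuple(lesion.T)] = Tissue.CSF
        assert categorize_region(lesion, tissue) == -1


class TestPostprocessMap:
    def test_ground_truth_survives_with_correct_regions(self, case):
        out = postprocess_map(case.microbleed_gt, case, PruningParams(ratio_threshold=1.2))
        manual = label_components(case.microbleed_gt)
        assert out.n_lesions == manual.n_lesions
        sens, prec, dice = lesion_metrics(match_lesions(out, manual))
        assert (sens, prec, dice) == (1.0, 1.0, 1.0)
        region_values = set(out.regions.values())
        assert region_values <= {int(t) for t in (
            Tissue.CORTICAL_GM, Tissue.DEEP_GM, Tissue.WM,
            Tissue.CEREBELLAR_GM, Tissue.CEREBELLAR_WM)}

    def test_vessel_false_positives_removed_lesions_kept(self, case):
        seg = case.microbleed_gt | case.vessel_mask
        manual = label_components(case.microbleed_gt)
        before = match_lesions(label_components(seg), manual)
        out = postprocess_map(seg, case, PruningParams(ratio_threshold=1.2))
        after = match_lesions(out, manual)
        assert after.FP < before.FP
        assert after.TP == before.TP

    def test_never_adds_voxels(self, case):
        seg = case.microbleed_gt | case.vessel_mask
        out = postprocess_map(seg, case, PruningParams(ratio_threshold=1.2))
        assert not np.any(out.binary() & ~seg)

    def test_empty_segmentation(self, case):
        out = postprocess_map(np.zeros(case.shape, dtype=bool), case)
        assert out.n_lesions == 0

    def test_per_region_threshold_used_for_deep_gm(self, case):
        # an absurdly strict deep-GM threshold wipes deep-GM lesions only
        strict = {int(Tissue.DEEP_GM): 1e9}
        out = postprocess_map(case.microbleed_gt, case,
                              PruningParams(ratio_threshold=1.2),
                              per_region_thresholds=strict)
        assert int(Tissue.DEEP_GM) not in set(out.regions.values())
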