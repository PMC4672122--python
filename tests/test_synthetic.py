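"""Synthetic scene and spine-library generator tests."""

import numpy as np
import pytest

from spinewave.synthetic import (
    CLASS_NAMES,
    SceneSpec,
    SpineSpec,
    demo_scene,
    make_dendrite_image,
    make_dendrite_stack,
    make_spine_library,
    max_intensity_projection,
    render_spine_subimage,
)


def simple_spec(**kw):
    base = dict(
        height=96,
        width=96,
        control_points=np.array([[10.0, 10.0], [48.0, 50.0], [86.0, 86.0]]),
        width_profile=7.0,
        spines=[],
        gaussian_sigma=0.0,
        poisson_scale=0.0,
        blur_sigma=0.0,
        seed=1,
    )
    base.update(kw)
    return SceneSpec(**base)


class TestSceneSpecValidation:
    def test_width_floor(self):
        with pytest.raises(ValueError, match="width_profile"):
            simple_spec(width_profile=1.0)

    def test_levels_ordered(self):
        with pytest.raises(ValueError, match="foreground_level"):
            simple_spec(foreground_level=0.1, background_level=0.5)

    @pytest.mark.parametrize(
        "label,kw",
        [
            ("mushroom", dict(neck_length=0.0)),  # mushroom needs a neck
            ("mushroom", dict(neck_width=8.0, head_radius=3.0)),  # neck thicker than head
            ("stubby", dict(neck_length=3.0)),  # stubby has no neck
            ("thin", dict(head_radius=3.0, neck_width=1.5)),  # thin head too big
            ("thin", dict(neck_length=19.0)),  # exceeds the 20 px envelope
        ],
    )
    def test_spine_invariants(self, label, kw):
        with pytest.raises(ValueError):
            SpineSpec(class_label=label, **kw)

    def test_off_canvas_spine_rejected(self):
        spec = simple_spec(spines=[SpineSpec(class_label="mushroom", base_t=0.02, side=-1)])
        spec.control_points = np.array([[3.0, 3.0], [48.0, 50.0], [86.0, 86.0]])
        with pytest.raises(ValueError, match="outside"):
            make_dendrite_image(spec)


class TestSceneRendering:
    def test_no_spines_foreground_equals_tube(self):
        image, truth = make_dendrite_image(simple_spec())
        assert truth.spine_records == []
        fg = image > (0.85 + 0.05) / 2
        assert np.array_equal(fg, truth.dendrite_mask)

    def test_determinism(self):
        img1, _ = make_dendrite_image(simple_spec(gaussian_sigma=0.02, poisson_scale=200))
        img2, _ = make_dendrite_image(simple_spec(gaussian_sigma=0.02, poisson_scale=200))
        assert np.array_equal(img1, img2)

    def test_one_spine_per_class(self):
        spines = [
            SpineSpec(class_label="mushroom", base_t=0.25),
            SpineSpec(class_label="stubby", base_t=0.5, side=-1),
            SpineSpec(class_label="thin", base_t=0.75),
        ]
        _, truth = make_dendrite_image(simple_spec(spines=spines))
        assert len(truth.spine_records) == 3
        assert sorted(r.class_label for r in truth.spine_records) == sorted(CLASS_NAMES)
        # spine pixel sets are disjoint from the trunk
        for rec in truth.spine_records:
            assert not (rec.mask & truth.dendrite_mask).any()
            assert rec.area > 0

    def test_backbone_inside_mask(self):
        _, truth = make_dendrite_image(simple_spec())
        rr = np.clip(np.rint(truth.backbone_points[:, 0]).astype(int), 0, 95)
        cc = np.clip(np.rint(truth.backbone_points[:, 1]).astype(int), 0, 95)
        assert truth.dendrite_mask[rr, cc].all()

    def test_demo_scene_composition(self):
        image, truth = make_dendrite_image(demo_scene(seed=3))
        labels = [r.class_label for r in truth.spine_records]
        assert labels.count("mushroom") == 8
        assert labels.count("stubby") == 8
        assert labels.count("thin") == 4


class TestSpineLibrary:
    def test_counts(self):
        images, labels = make_spine_library(3, seed=0)
        assert images.shape == (9, 20, 20)
        assert [int((labels == c).sum()) for c in range(3)] == [3, 3, 3]

    def test_determinism(self):
        i1, l1 = make_spine_library(4, seed=9)
        i2, l2 = make_spine_library(4, seed=9)
        assert np.array_equal(i1, i2) and np.array_equal(l1, l2)

    def test_canonical_templates_without_jitter(self):
        i1, _ = make_spine_library(1, seed=0, jitter=False, noise=False)
        i2, _ = make_spine_library(1, seed=77, jitter=False, noise=False)
        assert np.array_equal(i1, i2)  # seed-independent canonical templates

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            make_spine_library(0)

    def test_geometric_oracle_agrees_with_labels(self):
        """A head-blob/neck oracle on the noiseless spine masks must agree
        with the generated labels: mushroom and stubby carry a thick head
        (large inscribed disk), thin does not; stubby is short, mushroom
        long."""
        from scipy.ndimage import distance_transform_edt

        images, labels, masks = make_spine_library(
            25, seed=5, noise=False, return_truth=True
        )
        for lab, mask in zip(labels, masks):
            assert mask.any()
            rr, cc = np.nonzero(mask)
            inscribed = distance_transform_edt(mask).max()
            extent = np.hypot(rr.max() - rr.min(), cc.max() - cc.min())
            if inscribed < 1.7:
                guess = 2  # no head blob: thin
            elif extent > 3.35 * inscribed:
                guess = 0  # head plus long neck: mushroom
            else:
                guess = 1  # head only: stubby
            assert guess == lab

    def test_subimage_fits_envelope(self):
        # thin spines must fit a ~5x20 box, others 20x20
        _, mask = render_spine_subimage("thin", return_truth=True)
        rr, cc = np.nonzero(mask)
        assert (rr.max() - rr.min() + 1) <= 6  # width of the thin envelope


class TestMaxIntensityProjection:
    def test_single_slice_identity(self, rng):
        stack = rng.uniform(size=(1, 8, 8))
        assert np.array_equal(max_intensity_projection(stack), stack[0])

    def test_zero_slice_ignored(self, rng):
        a = rng.uniform(size=(8, 8))
        stack = np.stack([np.zeros((8, 8)), a])
        assert np.array_equal(max_intensity_projection(stack), a)

    def test_matches_bruteforce(self, rng):
        stack = rng.uniform(size=(3, 4, 4))
        out = max_intensity_projection(stack)
        for i in range(4):
            for j in range(4):
                assert out[i, j] == max(stack[z, i, j] for z in range(3))

    def test_idempotent(self, rng):
        stack = rng.uniform(size=(5, 6, 6))
        once = max_intensity_projection(stack)
        assert np.array_equal(max_intensity_projection(once[None]), once)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_intensity_projection(np.zeros((0, 4, 4)))

    def test_stack_generator_projects_back(self):
        spec = SceneSpec(
            height=64,
            width=64,
            control_points=np.array([[8.0, 8.0], [32.0, 30.0], [56.0, 56.0]]),
            width_profile=6.0,
            spines=[],
            gaussian_sigma=0.0,
            poisson_scale=0.0,
            seed=4,
        )
        stack, _ = make_dendrite_stack(spec, n_slices=5)
        image, _ = make_dendrite_image(spec)
        mip = max_intensity_projection(stack)
        # axial spreading keeps the in-focus value within ~15% of the scene
        assert np.abs(mip - image).max() < 0.15
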