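"""Search-space construction rules and the stochastic executor's laws."""

import dataclasses

import numpy as np
import pytest
from collections import Counter

from lca.augment import (
    ALL_OPS,
    COLOR_OPS,
    GEOMETRIC_OPS,
    AugmentationStrategy,
    SearchSpace,
    Subpolicy,
    TransformOp,
    apply_op,
    apply_strategy,
    build_default_space,
    enumerate_candidates,
    load_space_yaml,
    sample_subpolicy,
)


class TestSpaceConstruction:
    def test_default_space_shape(self, default_space):
        assert len(default_space.subpolicies) == 12
        assert default_space.ladder_probabilities == (0.1, 0.3, 0.5, 0.7, 0.9)
        assert default_space.combinatorial_size == 60

    def test_color_ops_distinct_geometric_ops_twice(self, default_space):
        color = [sp.color_op.name for sp in default_space.subpolicies]
        assert len(set(color)) == 12
        geo = Counter(sp.geometric_op.name for sp in default_space.subpolicies)
        assert set(geo) == set(GEOMETRIC_OPS)
        assert all(v == 2 for v in geo.values())

    def test_enumerate_candidates(self, default_space):
        cands = enumerate_candidates(default_space)
        assert [c.probability for c in cands] == [0.1, 0.3, 0.5, 0.7, 0.9]
        assert all(c.space is default_space for c in cands)

    def test_enumerate_singleton_and_product_rule(self, default_space):
        one = dataclasses.replace(default_space, ladder_probabilities=(0.5,))
        assert len(enumerate_candidates(one)) == 1
        three = dataclasses.replace(default_space, ladder_probabilities=(0.1, 0.5, 0.9))
        assert three.combinatorial_size == 36

    def test_empty_ladder_rejected(self, default_space):
        with pytest.raises(ValueError):
            enumerate_candidates(dataclasses.replace(default_space, ladder_probabilities=()))

    def test_mismatched_categories_rejected(self):
        with pytest.raises(ValueError):
            Subpolicy(GEOMETRIC_OPS["rotate"], GEOMETRIC_OPS["shear"], 1)

    def test_invalid_probability_rejected(self, default_space):
        with pytest.raises(ValueError):
            AugmentationStrategy(default_space, 1.5)


class TestSampling:
    def test_single_subpolicy_degenerate(self, default_space, rng):
        space = SearchSpace((default_space.subpolicies[3],), (0.5,))
        assert all(sample_subpolicy(space, rng).id == 4 for _ in range(20))

    def test_same_seed_same_sequence(self, default_space):
        a = [sample_subpolicy(default_space, np.random.default_rng(9)).id for _ in range(50)]
        b = [sample_subpolicy(default_space, np.random.default_rng(9)).id for _ in range(50)]
        assert a == b

    def test_empty_space_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_subpolicy(SearchSpace((), (0.5,)), rng)


class TestApplyOp:
    def test_flip_involution(self, lesion_image, rng):
        hf = GEOMETRIC_OPS["horizontal_flip"]
        once = apply_op(lesion_image, hf, 0.5, rng)
        twice = apply_op(once, hf, 0.5, rng)
        assert np.array_equal(twice, lesion_image)

    @pytest.mark.parametrize(
        "name,neutral",
        [("rotate", 0.0), ("translate", 0.0), ("shear", 0.0), ("scale", 1.0),
         ("brightness", 1.0), ("gamma", 1.0), ("gaussian_noise", 0.0),
         ("equalize", 0.0), ("sharpness", 0.0)],
    )
    def test_neutral_magnitude_is_identity(self, lesion_image, rng, name, neutral):
        out = apply_op(lesion_image, ALL_OPS[name], neutral, rng)
        assert np.array_equal(out, lesion_image)

    def test_gaussian_noise_std(self, rng):
        # on a constant mid-gray image the output residual std estimates sigma
        img = np.full((96, 96, 3), 0.5, dtype=np.float64)
        sigma = 10.0 / 255.0
        out = apply_op(img, COLOR_OPS["gaussian_noise"], sigma, rng)
        resid = (out - img).std()
        assert abs(resid - sigma) < 0.5 / 255.0

    def test_out_of_range_magnitude_rejected(self, lesion_image, rng):
        with pytest.raises(ValueError):
            apply_op(lesion_image, GEOMETRIC_OPS["rotate"], 90.0, rng)

    @pytest.mark.parametrize("name", sorted(ALL_OPS))
    def test_range_shape_dtype_preserved(self, lesion_image, rng, name):
        """Every op, at both ends and the middle of its magnitude range,
        keeps shape, dtype and the valid 8-bit intensity range."""
        op = ALL_OPS[name]
        lo, hi = op.magnitude_range
        for mag in (lo, (lo + hi) / 2, hi):
            out = apply_op(lesion_image, op, mag, rng)
            assert out.shape == lesion_image.shape
            assert out.dtype == lesion_image.dtype
            assert out.min() >= 0 and out.max() <= 255


class TestApplyStrategy:
    def test_p_zero_is_identity(self, default_space, lesion_image, rng):
        strategy = AugmentationStrategy(default_space, 0.0)
        out = apply_strategy(lesion_image, strategy, rng)
        assert np.array_equal(out, lesion_image)

    def test_same_seed_bitwise_identical(self, default_space, lesion_image):
        strategy = AugmentationStrategy(default_space, 0.7)
        a = apply_strategy(lesion_image, strategy, np.random.default_rng(3))
        b = apply_strategy(lesion_image, strategy, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_unchanged_fraction_matches_independence_law(self, rng):
        """With ops guaranteed to alter pixels, the fraction of images left
        untouched at P=0.5 is (1-P)^2 = 0.25 (independent execution)."""
        bump = TransformOp("bump", "color", (0.1, 0.1),
                           lambda img, m, r: np.clip(img + m, 0, 1))
        space = SearchSpace((Subpolicy(bump, GEOMETRIC_OPS["horizontal_flip"], 1),), (0.5,))
        strategy = AugmentationStrategy(space, 0.5)
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[:, :4] = 60  # asymmetric so the flip always changes pixels
        n = 40_000
        unchanged = sum(
            np.array_equal(apply_strategy(img, strategy, rng), img) for _ in range(n)
        )
        assert abs(unchanged / n - 0.25) < 0.01

    def test_forced_flip_roundtrip(self, lesion_image, rng):
        # a no-op color op paired with horizontal flip, executed twice at P=1
        noop = dataclasses.replace(COLOR_OPS["brightness"], magnitude_range=(1.0, 1.0))
        space = SearchSpace((Subpolicy(noop, GEOMETRIC_OPS["horizontal_flip"], 1),), (0.5,))
        strategy = AugmentationStrategy(space, 1.0)
        out = apply_strategy(
            apply_strategy(lesion_image, strategy, rng), strategy, rng
        )
        assert np.array_equal(out, lesion_image)


def test_yaml_space_roundtrip(tmp_path):
    doc = """
ladder: [0.2, 0.8]
subpolicies:
  - {color_op: brightness, geometric_op: rotate, color_range: [0.9, 1.1]}
  - {color_op: gamma, geometric_op: horizontal_flip}
"""
    path = tmp_path / "space.yaml"
    path.write_text(doc)
    space = load_space_yaml(path)
    assert len(space.subpolicies) == 2
    assert space.ladder_probabilities == (0.2, 0.8)
    assert space.subpolicies[0].color_op.magnitude_range == (0.9, 1.1)


def test_yaml_space_unknown_op(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("subpolicies:\n  - {color_op: nope, geometric_op: rotate}\n")
    with pytest.raises(ValueError, match="unknown op"):
        load_space_yaml(path)
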