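import math
from collections import Counter

import numpy as np
import pytest

from spermseg.fitness import (
    FitnessConfig,
    fitness_error,
    joint_entropy,
    marginal_entropy,
    mi_target_from_truth,
    mutual_information,
    quantise,
)


def mi_bruteforce(x, y, bins):
    """Contingency-table MI oracle built from Python dict counting."""
    n = x.size
    xb = [min(int(v * bins), bins - 1) for v in x.ravel()]
    yb = [int(v) for v in y.ravel()]
    cx, cy, cxy = Counter(xb), Counter(yb), Counter(zip(xb, yb))

    def H(counter):
        return -sum((c / n) * math.log2(c / n) for c in counter.values())

    return H(cx) + H(cy) - H(cxy)


class TestMarginalEntropy:
    @pytest.mark.parametrize(
        "probs,expected",
        [
            ([0.5, 0.5], 1.0),
            ([1.0, 0.0], 0.0),
            ([0.25, 0.75], -(0.25 * math.log2(0.25) + 0.75 * math.log2(0.75))),
        ],
    )
    def test_known_values(self, probs, expected):
        assert marginal_entropy(np.array(probs)) == pytest.approx(expected)

    def test_bounded_by_log_bin_count(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(8))
            h = marginal_entropy(p)
            assert 0 <= h <= math.log2(8) + 1e-12

    def test_rejects_unnormalised(self):
        with pytest.raises(ValueError):
            marginal_entropy(np.array([0.5, 0.4]))


class TestJointEntropy:
    def test_constant_mask_collapses_to_marginal(self, rng):
        x = rng.uniform(0, 1, (16, 16))
        xi = quantise(x, 8)
        y = np.zeros((16, 16), dtype=np.uint8)
        hx = marginal_entropy(np.bincount(xi.ravel(), minlength=8) / xi.size)
        assert joint_entropy(xi, y, 8) == pytest.approx(hx)

    def test_independent_uniform_binaries_give_two_bits(self):
        # checkerboard x vs horizontal stripes y: independent, each uniform
        x = np.indices((8, 8)).sum(axis=0) % 2
        y = (np.indices((8, 8))[0] // 1) % 2
        y = np.repeat(np.arange(8) % 2, 8).reshape(8, 8)
        xi = quantise(x.astype(float) * 0.99, 2)
        assert joint_entropy(xi, y.astype(np.uint8), 2) == pytest.approx(2.0)

    def test_sandwich_bounds(self, rng):
        for _ in range(10):
            x = rng.uniform(0, 1, (12, 12))
            y = (rng.uniform(0, 1, (12, 12)) > 0.7).astype(np.uint8)
            xi = quantise(x, 16)
            hx = marginal_entropy(np.bincount(xi.ravel(), minlength=16) / xi.size)
            hy = marginal_entropy(np.bincount(y.ravel(), minlength=2) / y.size)
            hxy = joint_entropy(xi, y, 16)
            assert max(hx, hy) - 1e-9 <= hxy <= hx + hy + 1e-9


class TestMutualInformation:
    def test_constant_mask_gives_zero(self, rng):
        x = rng.uniform(0, 1, (20, 20))
        assert mutual_information(x, np.ones((20, 20), dtype=np.uint8)) == 0.0
        assert mutual_information(x, np.zeros((20, 20), dtype=np.uint8)) == 0.0

    def test_binarisation_of_x_attains_mask_entropy(self, rng):
        # mask = indicator of the dark bins: deterministic given the x-bin,
        # so MI = H(Y) when the threshold aligns with a bin edge
        cfg = FitnessConfig(intensity_bins=4)
        x = rng.uniform(0, 1, (32, 32))
        y = (x < 0.25).astype(np.uint8)
        hy = marginal_entropy(np.bincount(y.ravel(), minlength=2) / y.size)
        assert mutual_information(x, y, cfg) == pytest.approx(hy, abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_pairs(self, rng):
        cfg = FitnessConfig(intensity_bins=16)
        for _ in range(100):
            x = rng.uniform(0, 1, (32, 32))
            y = (rng.uniform(0, 1, (32, 32)) > rng.uniform(0.2, 0.9)).astype(np.uint8)
            assert mutual_information(x, y, cfg) == pytest.approx(
                mi_bruteforce(x, y, 16), abs=1e-9
            )

    def test_bounded_by_min_marginal(self, rng):
        cfg = FitnessConfig(intensity_bins=8)
        for _ in range(50):
            x = rng.uniform(0, 1, (16, 16))
            y = (rng.uniform(0, 1, (16, 16)) > 0.5).astype(np.uint8)
            xi = quantise(x, 8)
            hx = marginal_entropy(np.bincount(xi.ravel(), minlength=8) / xi.size)
            hy = marginal_entropy(np.bincount(y.ravel(), minlength=2) / y.size)
            mi = mutual_information(x, y, cfg)
            assert -1e-9 <= mi <= min(hx, hy) + 1e-9

    def test_symmetric_for_binary_pair(self, rng):
        cfg = FitnessConfig(intensity_bins=2)
        x = (rng.uniform(0, 1, (16, 16)) > 0.4).astype(float) * 0.99
        y = (rng.uniform(0, 1, (16, 16)) > 0.6).astype(np.uint8)
        forward = mutual_information(x, y, cfg)
        backward = mutual_information(y.astype(float) * 0.99, (x > 0.5).astype(np.uint8), cfg)
        assert forward == pytest.approx(backward, abs=1e-12)

    def test_degenerate_mask_sweep_decreases_mi(self, rng):
        # as the binarisation threshold slides toward an all-zero mask the
        # mask carries less and less information about the frame
        x = rng.uniform(0, 1, (48, 48))
        mis = []
        for thr in (0.5, 0.2, 0.05, 0.01, 0.0):
            y = (x < thr).astype(np.uint8)
            mis.append(mutual_information(x, y))
        assert all(a >= b - 1e-12 for a, b in zip(mis, mis[1:]))
        assert mis[-1] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros((4, 4)), np.zeros((5, 4), dtype=np.uint8))


class TestFitnessError:
    @pytest.mark.parametrize("mi,expected", [(0.07, 0.0), (0.0, 0.07), (0.12, 0.05)])
    def test_absolute_difference_from_target(self, mi, expected):
        assert fitness_error(mi) == pytest.approx(expected)

    def test_negative_mi_rejected(self):
        with pytest.raises(ValueError):
            fitness_error(-0.01)


def test_truth_mask_mi_sits_near_target(small_scene):
    """The 0.07-bit target matches MI(frame, exact head mask) on a scene."""
    mi = mi_target_from_truth(small_scene.image, small_scene.truth_mask)
    assert 0.03 < mi < 0.15
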