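import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from deepfat.evaluate import (
    bland_altman,
    dice,
    dice_report,
    iou,
    origin_fit,
    paired_t,
    percent_error,
    percent_error_summary,
    quartile_groups,
)
from deepfat.volume_io import MaskVolume


def _set_counts(a, b):
    """Exhaustive set-based oracle: coordinates as python sets."""
    A = {tuple(idx) for idx in np.argwhere(np.asarray(a))}
    B = {tuple(idx) for idx in np.argwhere(np.asarray(b))}
    return len(A & B), len(A), len(B)


binary_grids = hnp.arrays(
    dtype=np.uint8,
    shape=st.tuples(st.integers(2, 6), st.integers(2, 6)),
    elements=st.integers(0, 1),
)


class TestOverlapScores:
    def test_identical_nonempty(self):
        a = np.ones((3, 3), dtype=np.uint8)
        assert dice(a, a) == 1.0
        assert iou(a, a) == 1.0

    def test_disjoint(self):
        a = np.zeros((2, 2), np.uint8)
        b = np.zeros((2, 2), np.uint8)
        a[0, 0] = 1
        b[1, 1] = 1
        assert dice(a, b) == 0.0
        assert iou(a, b) == 0.0

    def test_half_overlap(self):
        a = np.array([[1, 1, 0, 0]], np.uint8)
        b = np.array([[0, 1, 1, 0]], np.uint8)
        assert dice(a, b) == pytest.approx(0.5)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), np.uint8)
        assert dice(z, z) == 1.0
        assert iou(z, z) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2)), np.zeros((3, 3)))

    @given(a=binary_grids)
    @settings(deadline=None, derandomize=True)
    def test_matches_set_oracle_and_identity(self, a):
        b = np.roll(a, 1, axis=0)  # a correlated second grid
        inter, na, nb = _set_counts(a, b)
        expect_dice = 1.0 if na + nb == 0 else 2 * inter / (na + nb)
        union = na + nb - inter
        expect_iou = 1.0 if union == 0 else inter / union
        d, j = dice(a, b), iou(a, b)
        assert d == pytest.approx(expect_dice, abs=1e-12)
        assert j == pytest.approx(expect_iou, abs=1e-12)
        assert j == pytest.approx(d / (2.0 - d), abs=1e-12)

    def test_symmetry(self, rng):
        a = (rng.random((5, 5)) > 0.5).astype(np.uint8)
        b = (rng.random((5, 5)) > 0.5).astype(np.uint8)
        assert dice(a, b) == dice(b, a)


class TestDiceReport:
    def test_perfect_prediction(self, rng):
        vox = (rng.random((3, 6, 6)) > 0.5).astype(np.uint8)
        m = MaskVolume(vox, (1, 1, 1))
        report = dice_report(m, m)
        assert report.volume_dice == 1.0
        assert all(d == 1.0 for d in report.per_slice_dice)

    def test_empty_prediction_against_nonempty_truth(self):
        truth = MaskVolume(np.ones((2, 4, 4), np.uint8), (1, 1, 1))
        pred = MaskVolume(np.zeros((2, 4, 4), np.uint8), (1, 1, 1))
        report = dice_report(pred, truth)
        assert report.volume_dice == 0.0
        assert report.slice_mean == 0.0

    def test_matches_per_slice_brute_force(self, rng):
        p = MaskVolume((rng.random((3, 5, 5)) > 0.4).astype(np.uint8), (1, 1, 1))
        t = MaskVolume((rng.random((3, 5, 5)) > 0.6).astype(np.uint8), (1, 1, 1))
        report = dice_report(p, t)
        for z in range(3):
            inter, na, nb = _set_counts(p.voxels[z], t.voxels[z])
            expect = 1.0 if na + nb == 0 else 2 * inter / (na + nb)
            assert report.per_slice_dice[z] == pytest.approx(expect)
        inter, na, nb = _set_counts(p.voxels, t.voxels)
        assert report.volume_dice == pytest.approx(2 * inter / (na + nb))


class TestQuartileGroups:
    @pytest.mark.parametrize(
        "n,sizes",
        [(8, [2, 2, 2, 2]), (10, [3, 3, 2, 2]), (4, [1, 1, 1, 1]), (7, [2, 2, 2, 1])],
    )
    def test_sizes_and_contiguity(self, n, sizes):
        groups = quartile_groups(n)
        assert [len(g) for g in groups] == sizes
        flat = [i for g in groups for i in g]
        assert flat == list(range(n))

    def test_too_few_slices(self):
        with pytest.raises(ValueError):
            quartile_groups(3)


class TestBlandAltman:
    def test_identical_pairs(self):
        s = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.bias == 0.0 and s.sd == 0.0 and s.loa_low == s.loa_high == 0.0

    def test_constant_offset(self):
        s = bland_altman([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        assert s.bias == pytest.approx(2.0)
        assert s.sd == pytest.approx(0.0)

    def test_hand_oracle_pm2(self):
        """d = {+2, -2}: bias 0, sd (n-1) = 2.8284, LOA = ±1.96 sd."""
        s = bland_altman([0.0, 0.0], [2.0, -2.0])
        assert s.bias == pytest.approx(0.0)
        assert s.sd == pytest.approx(2.8284, abs=1e-4)
        assert s.loa_high == pytest.approx(5.5437, abs=1e-3)
        assert s.loa_low == pytest.approx(-5.5437, abs=1e-3)

    def test_recovers_injected_gaussian_sd(self, rng):
        ref = rng.uniform(50, 150, 500)
        test = ref + rng.normal(1.5, 4.0, 500)
        s = bland_altman(ref, test)
        assert s.bias == pytest.approx(1.5, abs=0.5)
        assert s.sd == pytest.approx(4.0, abs=0.5)

    def test_length_errors(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


class TestOriginFit:
    def test_exact_lines(self):
        x = np.array([1.0, 2.0, 3.0])
        fit = origin_fit(x, 2 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r == pytest.approx(1.0)
        fit = origin_fit(x, -x)
        assert fit.slope == pytest.approx(-1.0)
        assert fit.r == pytest.approx(-1.0)

    def test_hand_arithmetic(self):
        """x=(1,2,3), y=(2,3,7): m = sum(xy)/sum(x^2) = 29/14; r by the
        explicit product-moment formula."""
        x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 7.0]
        fit = origin_fit(x, y)
        assert fit.slope == pytest.approx(29 / 14)
        xm, ym = np.mean(x), np.mean(y)
        r_oracle = np.sum((x - xm) * (y - ym)) / np.sqrt(
            np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2)
        )
        assert fit.r == pytest.approx(r_oracle)

    def test_recovers_generating_slope_within_sampling_error(self, rng):
        x = rng.uniform(20, 200, 200)
        y = 0.97 * x + rng.normal(0, 5, 200)
        fit = origin_fit(x, y)
        se = 5.0 / np.sqrt(np.sum(x**2))
        assert abs(fit.slope - 0.97) < 2 * se + 1e-3

    def test_degenerate_x(self):
        with pytest.raises(ValueError):
            origin_fit([0.0, 0.0], [1.0, 2.0])


class TestPercentError:
    @pytest.mark.parametrize(
        "auto,manual,expected", [(100.0, 100.0, 0.0), (110.0, 100.0, 10.0), (95.0, 100.0, -5.0)]
    )
    def test_values(self, auto, manual, expected):
        assert percent_error(auto, manual) == pytest.approx(expected)

    def test_summary(self):
        mean, sd = percent_error_summary([110.0, 95.0], [100.0, 100.0])
        assert mean == pytest.approx(2.5)
        assert sd == pytest.approx(np.std([10.0, -5.0], ddof=1))

    def test_nonpositive_reference(self):
        with pytest.raises(ValueError):
            percent_error(10.0, 0.0)


class TestPairedT:
    def test_identical(self):
        t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_nonzero_mean_flagged(self):
        with pytest.raises(ValueError):
            paired_t([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])

    def test_hand_formula_oracle(self):
        """d = (2,-2,2,-2,2): t = mean(d) / (sd(d)/sqrt(n))."""
        x = np.array([2.0, -2.0, 2.0, -2.0, 2.0])
        y = np.zeros(5)
        t, p = paired_t(x, y)
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(t_oracle)
        p_oracle = 2 * stats.t.sf(abs(t_oracle), df=4)
        assert p == pytest.approx(p_oracle)
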