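"""Label fusion and smoothing: averaging, SVLS, majority vote, STAPLE,
GLS, sharpening."""

import numpy as np
import pytest

import raterseg as rs
from raterseg.fusion import FusionConfig, SVLSKernel, fuse, one_hot, staple_parameters
from raterseg.synthetic import RaterStack


def stack_from(labels, num_classes=2):
    return RaterStack(labels=np.asarray(labels), num_classes=num_classes)


class TestAverageFusion:
    def test_vote_fractions(self):
        # 3 of 5 raters mark the single pixel as foreground
        labels = np.array([[[1]], [[1]], [[1]], [[0]], [[0]]])
        soft = rs.average_fusion(stack_from(labels))
        assert soft.probs[0, 0, 1] == pytest.approx(0.6)

    def test_identical_raters_one_hot(self, panel_stack):
        lab = panel_stack.labels[0]
        soft = rs.average_fusion(stack_from(np.stack([lab] * 4)))
        assert set(np.unique(soft.probs)) <= {0.0, 1.0}

    def test_two_rater_disagreement_half(self):
        soft = rs.average_fusion(stack_from([[[0]], [[1]]]))
        np.testing.assert_allclose(soft.probs[0, 0], [0.5, 0.5])


class TestSVLSKernel:
    def test_sigma1_normalizer_and_center_weight(self):
        """For sigma=1 the 3x3 Gaussian weights are {1, e^-1/2, e^-1} and
        the normalised centre weight is 1/(1 + 4e^-1/2 + 4e^-1)."""
        k = SVLSKernel(sigma=1.0, size=3)
        expected_norm = 1 + 4 * np.exp(-0.5) + 4 * np.exp(-1.0)
        assert k.normalizer == pytest.approx(expected_norm, abs=1e-12)
        assert k.weights[1, 1] / k.normalizer == pytest.approx(0.2042, abs=5e-4)
        assert k.weights[0, 1] == pytest.approx(np.exp(-0.5))
        assert k.weights[0, 0] == pytest.approx(np.exp(-1.0))

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            SVLSKernel(size=4)


def brute_force_svls(labels, num_classes, weights):
    """Independent 9-term neighbourhood sum with replicate borders."""
    r, h, w = labels.shape
    oh = one_hot(labels, num_classes)
    out = np.zeros((h, w, num_classes))
    half = weights.shape[0] // 2
    for i in range(h):
        for j in range(w):
            for rr in range(r):
                acc = np.zeros(num_classes)
                for a in range(-half, half + 1):
                    for b in range(-half, half + 1):
                        ii = min(max(i + a, 0), h - 1)
                        jj = min(max(j + b, 0), w - 1)
                        acc += weights[a + half, b + half] * oh[rr, ii, jj]
                out[i, j] += acc / weights.sum()
    return out / r


class TestSVLSSmooth:
    def test_uniform_neighbourhood_stays_one_hot(self, panel_stack):
        soft = rs.svls_smooth(panel_stack)
        interior = panel_stack.labels[0] > 0
        # pick a pixel whose full 3x3 neighbourhood is foreground for all raters
        from scipy.ndimage import binary_erosion

        core = binary_erosion((panel_stack.labels[:4] > 0).all(axis=0), iterations=2)
        if core.any():
            i, j = np.argwhere(core)[0]
            # 4 of 5 raters fully agree there; the all-background rater caps it at 0.8
            assert soft.probs[i, j, 1] == pytest.approx(0.8, abs=1e-9)

    def test_straight_edge_matches_hand_convolution(self):
        """Single rater, vertical binary edge: interior edge pixels must match
        the 9-term Gaussian sum computed independently."""
        lab = np.zeros((6, 6), dtype=int)
        lab[:, 3:] = 1
        stack = stack_from(lab[None])
        k = SVLSKernel(sigma=1.0, size=3)
        soft = rs.svls_smooth(stack, k)
        oracle = brute_force_svls(stack.labels, 2, k.weights)
        np.testing.assert_allclose(soft.probs, oracle, atol=1e-9)
        # closed form for the first foreground column next to the edge:
        # fg weight = (centre + 2 edge) + right column (1 edge + 2 corner)
        w_fg = (1 + 2 * np.exp(-0.5)) + (np.exp(-0.5) + 2 * np.exp(-1.0))
        assert soft.probs[3, 3, 1] == pytest.approx(w_fg / k.normalizer, abs=1e-9)

    def test_multirater_matches_brute_force(self, panel_stack):
        sub = RaterStack(labels=panel_stack.labels[:, :12, :12], num_classes=2)
        k = SVLSKernel()
        np.testing.assert_allclose(
            rs.svls_smooth(sub, k).probs,
            brute_force_svls(sub.labels, 2, k.weights),
            atol=1e-9,
        )

    def test_commutes_with_flips(self, panel_stack):
        soft = rs.svls_smooth(panel_stack)
        for axis in (1, 2):
            flipped = RaterStack(labels=np.flip(panel_stack.labels, axis=axis), num_classes=2)
            np.testing.assert_allclose(
                rs.svls_smooth(flipped).probs, np.flip(soft.probs, axis=axis - 1), atol=1e-12
            )

    def test_delta_kernel_equals_average(self, panel_stack):
        np.testing.assert_allclose(
            rs.svls_smooth(panel_stack, SVLSKernel.delta()).probs,
            rs.average_fusion(panel_stack).probs,
            atol=1e-12,
        )


class TestMajorityVote:
    def test_strict_majority(self):
        labels = np.array([[[1]], [[1]], [[1]], [[0]], [[0]]])
        assert rs.majority_vote(stack_from(labels))[0, 0] == 1

    def test_matches_argmax_of_average_without_ties(self, panel_stack):
        counts = one_hot(panel_stack.labels, 2).sum(axis=0)
        no_tie = counts[..., 0] != counts[..., 1]
        mv = rs.majority_vote(panel_stack)
        avg_arg = rs.average_fusion(panel_stack).argmax()
        np.testing.assert_array_equal(mv[no_tie], avg_arg[no_tie])

    def test_tie_breaks_to_lowest_class(self):
        labels = np.array([[[0]], [[0]], [[1]], [[1]], [[2]]])
        assert rs.majority_vote(stack_from(labels, num_classes=3))[0, 0] == 0


def brute_force_staple(d, max_iter=100, tol=1e-7):
    """Independently coded scalar-loop EM over rater sensitivity/specificity."""
    r, npix = d.shape
    sens = [0.99999] * r
    spec = [0.99999] * r
    prior = min(max(d.mean(), 1e-6), 1 - 1e-6)
    w = [0.0] * npix
    for _ in range(max_iter):
        for i in range(npix):
            a = prior
            b = 1 - prior
            for j in range(r):
                if d[j, i] == 1:
                    a *= sens[j]
                    b *= 1 - spec[j]
                else:
                    a *= 1 - sens[j]
                    b *= spec[j]
            w[i] = a / (a + b)
        delta = 0.0
        for j in range(r):
            num_s = sum(w[i] for i in range(npix) if d[j, i] == 1)
            num_p = sum(1 - w[i] for i in range(npix) if d[j, i] == 0)
            sw = sum(w)
            new_s = min(max(num_s / max(sw, 1e-12), 1e-12), 1 - 1e-12)
            new_p = min(max(num_p / max(npix - sw, 1e-12), 1e-12), 1 - 1e-12)
            delta = max(delta, abs(new_s - sens[j]), abs(new_p - spec[j]))
            sens[j], spec[j] = new_s, new_p
        if delta < tol:
            break
    return np.array(w), np.array(sens), np.array(spec)


class TestStaple:
    def test_consensus_fixed_point(self, panel_stack):
        lab = (panel_stack.labels[0] > 0).astype(int)
        stack = stack_from(np.stack([lab] * 3))
        soft = rs.staple_fusion(stack)
        assert (soft.probs[lab == 1, 1] >= 0.99).all()

    def test_toy_matches_brute_force_em(self):
        """3 raters, 6 pixels: posterior must match an independently coded
        EM loop to 1e-6."""
        d = np.array(
            [
                [1, 1, 0, 0, 1, 0],
                [1, 0, 0, 1, 1, 0],
                [1, 1, 1, 0, 1, 0],
            ]
        )
        stack = stack_from(d.reshape(3, 1, 6))
        soft = rs.staple_fusion(stack)
        w_oracle, _, _ = brute_force_staple(d)
        np.testing.assert_allclose(soft.probs[0, :, 1], w_oracle, atol=1e-6)

    def test_all_background_rater_gets_low_sensitivity(self, one_sample):
        lab = (one_sample.gt_mask > 0).astype(int)
        stack = stack_from(np.stack([lab, lab, lab, lab, np.zeros_like(lab)]))
        sens, _ = staple_parameters(stack)
        assert sens[-1] < 0.1
        assert (sens[:4] > 0.9).all()

    def test_threshold_equals_majority_on_symmetric_panels(self):
        """With exactly equally reliable raters (same error counts on
        foreground and background) the STAPLE posterior at 0.5 reproduces
        the majority vote."""
        for seed in range(5):
            g = np.random.default_rng(seed)
            truth = np.arange(64).reshape(8, 8) % 2 == 0  # balanced prior
            fg_idx = np.argwhere(truth)
            bg_idx = np.argwhere(~truth)
            labels = []
            for _ in range(5):
                lab = truth.copy()
                for pool in (fg_idx, bg_idx):  # flip exactly 4 of each
                    for i, j in pool[g.choice(len(pool), size=4, replace=False)]:
                        lab[i, j] = ~lab[i, j]
                labels.append(lab.astype(int))
            stack = stack_from(np.stack(labels))
            post = rs.staple_fusion(stack).probs[..., 1]
            mv = rs.majority_vote(stack)
            np.testing.assert_array_equal((post > 0.5).astype(int), mv)

    def test_multiclass_rejected(self):
        with pytest.raises(ValueError):
            rs.staple_fusion(stack_from(np.zeros((2, 4, 4), dtype=int), num_classes=3))


class TestSmoothers:
    def test_gls_one_hot_closed_form(self):
        soft = rs.gls_smooth(stack_from([[[1]], [[1]]]), epsilon=0.1)
        np.testing.assert_allclose(soft.probs[0, 0], [0.05, 0.95])

    def test_sharpen_t1_identity(self, panel_stack):
        soft = rs.average_fusion(panel_stack)
        np.testing.assert_allclose(rs.sharpen(soft, 1.0).probs, soft.probs, atol=1e-12)

    def test_sharpen_small_t_approaches_argmax(self):
        soft = rs.SoftLabel(np.array([[[0.6, 0.4]]]))
        out = rs.sharpen(soft, 1e-3)
        np.testing.assert_allclose(out.probs[0, 0], [1.0, 0.0], atol=1e-9)

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            rs.sharpen(rs.SoftLabel(np.ones((1, 1, 1))), 0.0)


@pytest.mark.parametrize("method", ["average", "svls", "majority_vote", "staple", "gls", "sharpen"])
def test_every_fusion_output_normalized(method, panel_stack):
    soft = fuse(panel_stack, FusionConfig(method=method))
    assert soft.probs.min() >= 0 and soft.probs.max() <= 1
    np.testing.assert_allclose(soft.probs.sum(axis=-1), 1.0, atol=1e-6)
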