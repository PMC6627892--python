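import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crmap.errors import ContractViolationError, InvalidInputError
from crmap.mapping import (
    ActivationMap,
    average_crm,
    brute_force_crm,
    compute_cam,
    compute_crm,
    compute_gradcam,
    gradcam_weights,
)
from crmap.model_core import DenseHead, FeatureMapStack, compute_class_scores


def _random_instance(rng):
    u, v = rng.integers(1, 9, size=2)
    K = rng.integers(1, 17)
    N = rng.integers(1, 8)
    fm = FeatureMapStack(rng.normal(size=(u, v, K)))
    head = DenseHead(rng.normal(size=(K, N)), rng.normal(size=N))
    return fm, head


class TestCam:
    def test_worked_example(self, toy_fm, toy_head):
        cam = compute_cam(toy_fm, toy_head, 0)
        np.testing.assert_array_equal(cam.values, [[1, 0], [0, 1]])

    def test_zero_weights(self, toy_fm):
        head = DenseHead(np.zeros((2, 2)), np.zeros(2))
        np.testing.assert_array_equal(compute_cam(toy_fm, head, 1).values, np.zeros((2, 2)))

    def test_negative_values_preserved(self, toy_fm):
        head = DenseHead(np.array([[1.0, 0.0], [-1.0, 0.0]]), np.zeros(2))
        np.testing.assert_array_equal(
            compute_cam(toy_fm, head, 0).values, [[1, -2], [0, 1]]
        )

    def test_invalid_class(self, toy_fm, toy_head):
        with pytest.raises(IndexError):
            compute_cam(toy_fm, toy_head, 2)


class TestGradcamWeights:
    def test_analytic_equals_weight_column(self, toy_fm, toy_head):
        gw = gradcam_weights(toy_fm, 0, head=toy_head)
        np.testing.assert_array_equal(gw.alpha, [1.0, 0.0])

    def test_gradient_path_matches_analytic(self):
        # finite-difference oracle for dS_c/df summed spatially
        rng = np.random.default_rng(2)
        fm, head = _random_instance(rng)
        c = 0
        eps = 1e-6
        grads = np.zeros_like(fm.values)
        base = compute_class_scores(fm, head).scores[c]
        for idx in np.ndindex(fm.values.shape):
            bumped = fm.values.copy()
            bumped[idx] += eps
            grads[idx] = (
                compute_class_scores(FeatureMapStack(bumped), head).scores[c] - base
            ) / eps
        gw_grad = gradcam_weights(fm, c, gradients=grads)
        gw_analytic = gradcam_weights(fm, c, head=head)
        np.testing.assert_allclose(gw_grad.alpha, gw_analytic.alpha, atol=1e-5)

    def test_zero_weights(self, toy_fm):
        head = DenseHead(np.zeros((2, 3)), np.zeros(3))
        assert not gradcam_weights(toy_fm, 1, head=head).alpha.any()

    def test_needs_a_source(self, toy_fm):
        with pytest.raises(ContractViolationError):
            gradcam_weights(toy_fm, 0)


class TestGradcam:
    def test_relu_worked_example(self, toy_fm):
        gw = gradcam_weights(
            toy_fm, 0, head=DenseHead(np.array([[1.0, 0.0], [-1.0, 0.0]]), np.zeros(2))
        )
        np.testing.assert_array_equal(
            compute_gradcam(toy_fm, gw).values, [[1, 0], [0, 1]]
        )

    def test_equals_cam_when_nonnegative(self):
        rng = np.random.default_rng(3)
        fm = FeatureMapStack(rng.uniform(size=(5, 6, 4)))  # activations >= 0
        head = DenseHead(rng.uniform(size=(4, 3)), rng.normal(size=3))  # weights >= 0
        for c in range(3):
            cam = compute_cam(fm, head, c)
            gc = compute_gradcam(fm, gradcam_weights(fm, c, head=head))
            np.testing.assert_array_equal(cam.values, gc.values)

    def test_zero_stack(self):
        fm = FeatureMapStack(np.zeros((3, 3, 2)))
        gw = gradcam_weights(fm, 0, head=DenseHead(np.ones((2, 2)), np.zeros(2)))
        assert not compute_gradcam(fm, gw).values.any()

    def test_length_mismatch(self, toy_fm):
        gw = gradcam_weights(
            FeatureMapStack(np.zeros((2, 2, 3))), 0,
            head=DenseHead(np.zeros((3, 2)), np.zeros(2)),
        )
        with pytest.raises(ContractViolationError):
            compute_gradcam(toy_fm, gw)


class TestCrm:
    def test_worked_example(self, toy_fm, toy_head):
        crm = compute_crm(toy_fm, toy_head)
        np.testing.assert_allclose(crm.values, [[0.0625, 0.25], [0.0, 0.0625]])
        assert crm.target_class == "all"

    def test_brute_force_worked_example(self, toy_fm, toy_head):
        bf = brute_force_crm(toy_fm, toy_head)
        np.testing.assert_allclose(bf.values, [[0.0625, 0.25], [0.0, 0.0625]])

    def test_single_output_head_is_scaled_cam_squared(self):
        rng = np.random.default_rng(4)
        fm = FeatureMapStack(rng.normal(size=(4, 5, 3)))
        head = DenseHead(rng.normal(size=(3, 1)), rng.normal(size=1))
        cam = compute_cam(fm, head, 0).values
        crm = compute_crm(fm, head).values
        uv = fm.u * fm.v
        np.testing.assert_allclose(crm, cam**2 / uv**2)

    def test_zero_stack(self):
        fm = FeatureMapStack(np.zeros((3, 3, 2)))
        head = DenseHead(np.ones((2, 4)), np.ones(4))
        assert not compute_crm(fm, head).values.any()

    def test_locality_single_nonzero_element(self):
        vals = np.zeros((5, 6, 3))
        vals[2, 4, :] = [1.0, -2.0, 0.5]
        fm = FeatureMapStack(vals)
        head = DenseHead(np.random.default_rng(5).normal(size=(3, 4)), np.zeros(4))
        crm = compute_crm(fm, head).values
        nonzero = np.nonzero(crm)
        assert list(zip(*nonzero)) == [(2, 4)]

    def test_oracle_equivalence_randomized(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            fm, head = _random_instance(rng)
            fast = compute_crm(fm, head).values
            slow = brute_force_crm(fm, head).values
            np.testing.assert_allclose(fast, slow, rtol=1e-6, atol=1e-12)

    def test_biases_do_not_matter(self):
        rng = np.random.default_rng(6)
        fm, head = _random_instance(rng)
        shifted = DenseHead(head.weights, head.biases + rng.normal(size=head.num_classes))
        np.testing.assert_array_equal(
            compute_crm(fm, head).values, compute_crm(fm, shifted).values
        )

    def test_dimension_mismatch(self, toy_fm):
        with pytest.raises(ContractViolationError):
            compute_crm(toy_fm, DenseHead(np.eye(3), np.zeros(3)))


class TestScaleAndPermutationEquivariance:
    @given(alpha=st.floats(min_value=0.1, max_value=10.0), seed=st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, alpha, seed):
        rng = np.random.default_rng(seed)
        fm, head = _random_instance(rng)
        scaled = FeatureMapStack(alpha * fm.values)
        c = rng.integers(head.num_classes)
        np.testing.assert_allclose(
            compute_cam(scaled, head, c).values,
            alpha * compute_cam(fm, head, c).values, rtol=1e-9,
        )
        np.testing.assert_allclose(
            compute_crm(scaled, head).values,
            alpha**2 * compute_crm(fm, head).values, rtol=1e-9,
        )

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None)
    def test_spatial_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        fm, head = _random_instance(rng)
        perm = rng.permutation(fm.u * fm.v)
        flat = fm.values.reshape(fm.u * fm.v, -1)[perm]
        permuted = FeatureMapStack(flat.reshape(fm.values.shape))
        for maker in (lambda f: compute_crm(f, head).values,
                      lambda f: compute_cam(f, head, 0).values):
            orig = maker(fm).reshape(-1)[perm].reshape(fm.u, fm.v)
            np.testing.assert_allclose(maker(permuted), orig, rtol=1e-9)


class TestAverageCrm:
    def _mk(self, arr):
        return ActivationMap(np.asarray(arr, dtype=float), method="CRM", target_class="all")

    def test_idempotent_on_identical_maps(self):
        m = self._mk([[0.0, 2.0], [0.0, 0.0]])
        avg = average_crm([m, m], class_label=3)
        np.testing.assert_array_equal(avg.values, m.values)
        assert avg.n_images == 2 and avg.class_label == 3

    def test_mean(self):
        avg = average_crm([self._mk([[0, 2], [0, 0]]), self._mk([[2, 0], [0, 0]])], 0)
        np.testing.assert_array_equal(avg.values, [[1, 1], [0, 0]])

    def test_single_map_unchanged(self):
        m = self._mk([[1.0, 0.5], [0.0, 2.0]])
        np.testing.assert_array_equal(average_crm([m], 0).values, m.values)

    def test_permutation_invariance_and_scaling(self):
        rng = np.random.default_rng(7)
        maps = [self._mk(rng.uniform(size=(3, 3))) for _ in range(5)]
        a = average_crm(maps, 0).values
        b = average_crm(maps[::-1], 0).values
        np.testing.assert_allclose(a, b)
        scaled = [self._mk(3.0 * m.values) for m in maps]
        np.testing.assert_allclose(average_crm(scaled, 0).values, 3.0 * a)

    def test_normalize_each_option(self):
        maps = [self._mk([[0, 4], [0, 0]]), self._mk([[1, 0], [0, 0]])]
        avg = average_crm(maps, 0, normalize_each=True)
        np.testing.assert_array_equal(avg.values, [[0.5, 0.5], [0, 0]])

    def test_empty_list(self):
        with pytest.raises(InvalidInputError):
            average_crm([], 0)

    def test_mixed_sizes(self):
        with pytest.raises(ContractViolationError):
            average_crm([self._mk(np.zeros((2, 2))), self._mk(np.zeros((3, 3)))], 0)

    def test_rejects_non_crm(self):
        cam = ActivationMap(np.zeros((2, 2)), method="CAM", target_class=0)
        with pytest.raises(ContractViolationError):
            average_crm([cam], 0)
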