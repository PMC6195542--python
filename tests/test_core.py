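"""Unit and property tests for the standardize -> rotate -> whiten pipeline."""

import numpy as np
import pytest

import normindex as ni
from normindex.core import fit_pc_basis, project

from conftest import random_reference


def make_ref(values, labels=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ni.ReferenceMatrix(
        values,
        subject_ids=tuple(f"s{i}" for i in range(n)),
        feature_labels=tuple(labels) if labels else tuple(f"f{j}" for j in range(p)),
    )


class TestStandardization:
    @pytest.mark.parametrize(
        "column, mu, sigma",
        [
            ([1.0, 2.0, 3.0], 2.0, 1.0),
            ([0.0, 2.0], 1.0, np.sqrt(2.0)),
        ],
    )
    def test_column_moments_use_nminus1_denominator(self, column, mu, sigma):
        ref = make_ref(np.array(column)[:, None])
        params = ni.compute_standardization_params(ref)
        assert params.mu[0] == pytest.approx(mu, abs=1e-12)
        assert params.sigma[0] == pytest.approx(sigma, abs=1e-12)

    def test_constant_feature_is_rejected_by_name(self):
        ref = make_ref([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]], labels=["flat", "ok"])
        with pytest.raises(ValueError, match="zero variance.*flat"):
            ni.compute_standardization_params(ref)

    def test_subject_at_reference_mean_maps_to_origin(self):
        ref = make_ref([[1.0, 10.0], [3.0, 30.0], [2.0, 20.0]])
        params = ni.compute_standardization_params(ref)
        subj = ni.SubjectVector(params.mu, ref.feature_labels)
        z = ni.standardize(subj, params)
        assert np.allclose(z.values, 0.0, atol=1e-12)

    def test_scalar_arithmetic(self):
        params = ni.StandardizationParams(mu=[1.0], sigma=[2.0], feature_labels=("f0",))
        subj = ni.SubjectVector([3.0], ("f0",))
        assert ni.standardize(subj, params).values[0] == pytest.approx(1.0)

    def test_reference_standardized_by_own_params_has_unit_moments(self):
        ref = random_reference(40, 6, seed=3)
        params = ni.compute_standardization_params(ref)
        z = ni.standardize(ref, params).values
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_label_mismatch_raises(self):
        ref = make_ref([[1.0, 2.0], [3.0, 4.0]], labels=["a", "b"])
        params = ni.compute_standardization_params(ref)
        subj = ni.SubjectVector([1.0, 2.0], ("b", "a"))
        with pytest.raises(ValueError, match="order mismatch"):
            ni.standardize(subj, params)

    def test_missing_values_rejected_at_construction(self):
        with pytest.raises(ValueError, match="missing|non-finite"):
            make_ref([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing|non-finite"):
            ni.SubjectVector([1.0, np.inf], ("a", "b"))


class TestPCBasis:
    def test_two_feature_closed_form(self, corr83_reference):
        params = ni.compute_standardization_params(corr83_reference)
        basis = fit_pc_basis(ni.standardize(corr83_reference, params))
        assert basis.eigenvalues == pytest.approx([1.83, 0.17], abs=1e-10)
        # eigenvectors of an equicorrelation 2x2 are the diagonals
        assert np.abs(basis.eigenvectors[:, 0]) == pytest.approx([1, 1] / np.sqrt(2), abs=1e-10)

    def test_orthonormal_columns_and_descending_eigenvalues(self, gait_reference):
        params = ni.compute_standardization_params(gait_reference)
        basis = fit_pc_basis(ni.standardize(gait_reference, params))
        gram = basis.eigenvectors.T @ basis.eigenvectors
        assert np.max(np.abs(gram - np.eye(basis.m))) < 1e-8
        assert np.all(np.diff(basis.eigenvalues) <= 0)

    def test_rank_and_trace_identities_when_p_exceeds_n(self, gait_reference):
        """A centered 32-row matrix has rank <= 31 and trace p after standardization."""
        params = ni.compute_standardization_params(gait_reference)
        basis = fit_pc_basis(ni.standardize(gait_reference, params))
        assert basis.m <= 31
        assert basis.eigenvalues.sum() == pytest.approx(459.0, abs=1e-8)
        assert basis.tve[-1] == pytest.approx(1.0, abs=1e-10)

    def test_identity_covariance_gives_flat_spectrum(self):
        ref = random_reference(10000, 3, seed=11, mixing=False)
        params = ni.compute_standardization_params(ref)
        basis = fit_pc_basis(ni.standardize(ref, params))
        assert np.allclose(basis.eigenvalues, 1.0, rtol=0.05)

    def test_sign_convention_is_deterministic(self, gait_reference):
        params = ni.compute_standardization_params(gait_reference)
        z = ni.standardize(gait_reference, params)
        b1, b2 = fit_pc_basis(z), fit_pc_basis(z)
        assert np.array_equal(b1.eigenvectors, b2.eigenvectors)
        dominant = b1.eigenvectors[np.argmax(np.abs(b1.eigenvectors), axis=0), np.arange(b1.m)]
        assert np.all(dominant > 0)


class TestProjection:
    def test_origin_maps_to_origin(self, corr83_reference):
        params = ni.compute_standardization_params(corr83_reference)
        basis = fit_pc_basis(ni.standardize(corr83_reference, params))
        zero = ni.StandardizedVector(np.zeros(2), corr83_reference.feature_labels, params)
        for scaled in (True, False):
            assert np.allclose(project(zero, basis, scaled=scaled).values, 0.0)

    @pytest.mark.parametrize(
        "subject, expected_norm",
        [((1.0, 1.0), np.sqrt(2 / 1.83)), ((1.0, -1.0), np.sqrt(2 / 0.17))],
    )
    def test_whitened_scores_match_2x2_closed_form(self, corr83_reference, subject, expected_norm):
        """(1,1) lies along the high-variance diagonal; (1,-1) along the rare one."""
        params = ni.compute_standardization_params(corr83_reference)
        basis = fit_pc_basis(ni.standardize(corr83_reference, params))
        subj = ni.SubjectVector(subject, corr83_reference.feature_labels)
        scores = project(ni.standardize(subj, params), basis, scaled=True)
        assert np.linalg.norm(scores.values) == pytest.approx(expected_norm, abs=1e-8)

    def test_reference_scaled_scores_have_unit_variance(self, gait_reference):
        params = ni.compute_standardization_params(gait_reference)
        z = ni.standardize(gait_reference, params)
        basis = fit_pc_basis(z)
        scores = project(z, basis, scaled=True)
        assert np.allclose(scores.values.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_dimension_mismatch_raises(self, corr83_reference):
        params = ni.compute_standardization_params(corr83_reference)
        basis = fit_pc_basis(ni.standardize(corr83_reference, params))
        bad = ni.StandardizedVector(np.zeros(3), ("a", "b", "c"), params)
        with pytest.raises(ValueError, match="dimension mismatch"):
            project(bad, basis)


class TestFullPipelineProperties:
    def test_subject_equal_to_mean_scores_zero_for_every_measure(self):
        ref = random_reference(30, 4, seed=5)
        subj = ni.SubjectVector(ref.values.mean(axis=0), ref.feature_labels)
        for measure in ("euclidean", "squared_euclidean", "manhattan", "rms", "mad"):
            assert ni.measure_abnormality(subj, ref, "all", measure).value == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_full_pc_distance_equals_mahalanobis(self, seed):
        """With all components kept, the whitened Euclidean norm is the
        Mahalanobis distance from the inverse correlation matrix."""
        rng = np.random.default_rng(seed)
        ref = random_reference(200, 5, seed=seed)
        subj = ni.SubjectVector(rng.standard_normal(5) * 3, ref.feature_labels)
        d = ni.measure_abnormality(subj, ref, "all", "euclidean").value
        params = ni.compute_standardization_params(ref)
        z = (subj.values - params.mu) / params.sigma
        zr = (ref.values - params.mu) / params.sigma
        corr = (zr.T @ zr) / (ref.n - 1)
        oracle = np.sqrt(z @ np.linalg.solve(corr, z))
        assert d == pytest.approx(oracle, abs=1e-8)

    def test_rotation_invariance_of_full_pc_distance(self):
        """A fixed orthogonal rotation of the standardized data must not change
        any full-PC whitened distance (the metric is basis independent)."""
        rng = np.random.default_rng(17)
        ref = random_reference(60, 6, seed=23)
        params = ni.compute_standardization_params(ref)
        zr = ni.standardize(ref, params).values
        z = rng.standard_normal(6)
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))

        def full_pc_dist(zmat, zvec):
            p = ni.StandardizationParams(np.zeros(6), np.ones(6), ref.feature_labels)
            basis = fit_pc_basis(ni.StandardizedMatrix(zmat, ref.subject_ids, ref.feature_labels, p))
            scores = project(ni.StandardizedVector(zvec, ref.feature_labels, p), basis, scaled=True)
            return np.linalg.norm(scores.values)

        # rotating standardized data changes column SDs; whiten the rotated frame directly
        assert full_pc_dist(zr @ q, z @ q) == pytest.approx(full_pc_dist(zr, z), abs=1e-8)

    def test_reference_self_consistency(self, gait_reference):
        """Mean squared whitened distance over the reference = m(n-1)/n."""
        params = ni.compute_standardization_params(gait_reference)
        z = ni.standardize(gait_reference, params)
        basis = fit_pc_basis(z)
        scores = project(z, basis, scaled=True).values
        msd = np.mean(np.sum(scores**2, axis=1))
        n = gait_reference.n
        assert msd == pytest.approx(basis.m * (n - 1) / n, abs=1e-8)

    def test_retention_specifications(self, corr83_reference):
        subj = ni.SubjectVector([1.0, -1.0], corr83_reference.feature_labels)
        d_all = ni.measure_abnormality(subj, corr83_reference, "all", "euclidean")
        d_k1 = ni.measure_abnormality(subj, corr83_reference, 1, "euclidean")
        d_kg = ni.measure_abnormality(
            subj, corr83_reference, ni.RetentionRule(method="kaiser_guttman"), "euclidean"
        )
        assert d_all.k == 2 and d_k1.k == 1 and d_kg.k == 1
        assert d_k1.value == pytest.approx(d_kg.value)
        assert d_all.value > d_k1.value
        with pytest.raises(ValueError, match="fixed k"):
            ni.measure_abnormality(subj, corr83_reference, 5, "euclidean")
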