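"""Core transform: standardize against a reference cohort, rotate into its
principal-component basis, and whiten by the eigenvalue square roots.

The pipeline measures how far a subject sits from the centroid of a
reference population once the dependency structure of the features has been
removed.  Standardizing each feature by the reference mean and SD puts the
reference centroid at the origin; rotating into the orthonormal eigenvector
basis of the reference correlation matrix decorrelates the features; and
dividing each component score by sqrt(lambda_j) gives every retained
component unit variance in the reference.  The Euclidean norm of the
resulting score vector is then a Mahalanobis-type distance that remains
well defined when the feature count p exceeds the cohort size n, because
only the (at most n-1) components with non-zero eigenvalues are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "ReferenceMatrix",
    "SubjectVector",
    "StandardizationParams",
    "StandardizedMatrix",
    "StandardizedVector",
    "PCBasis",
    "PCScores",
    "compute_standardization_params",
    "standardize",
    "fit_pc_basis",
    "project",
    "measure_abnormality",
]


def _as_labels(labels: Sequence[str], size: int, what: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(labels) != size:
        raise ValueError(f"{what}: expected {size} labels, got {len(labels)}")
    return labels


@dataclass(frozen=True)
class ReferenceMatrix:
    """An n x p reference-population matrix (rows = subjects, columns = features)."""

    values: np.ndarray
    subject_ids: tuple[str, ...]
    feature_labels: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("reference values must be a 2-D array")
        n, p = values.shape
        if n < 2:
            raise ValueError(f"reference must contain at least 2 subjects, got n={n}")
        if p < 1:
            raise ValueError("reference must contain at least 1 feature")
        if not np.all(np.isfinite(values)):
            raise ValueError("reference contains missing or non-finite values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subject_ids", _as_labels(self.subject_ids, n, "subject_ids"))
        labels = _as_labels(self.feature_labels, p, "feature_labels")
        if len(set(labels)) != p:
            raise ValueError("feature_labels must be unique")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        object.__setattr__(self, "feature_labels", labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SubjectVector:
    """A single subject's length-p feature vector, ordered like the reference."""

    values: np.ndarray
    feature_labels: tuple[str, ...]
    subject_id: str = "subject"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(values)):
            raise ValueError(f"subject {self.subject_id!r} contains missing or non-finite values")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "feature_labels", _as_labels(self.feature_labels, values.size, "feature_labels")
        )

    @property
    def p(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature reference mean and SD (n-1 denominator), in feature units."""

    mu: np.ndarray
    sigma: np.ndarray
    feature_labels: tuple[str, ...]

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float).ravel()
        sigma = np.asarray(self.sigma, dtype=float).ravel()
        if mu.size != sigma.size:
            raise ValueError("mu and sigma must have equal length")
        if np.any(sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(
            self, "feature_labels", _as_labels(self.feature_labels, mu.size, "feature_labels")
        )


@dataclass(frozen=True)
class StandardizedMatrix:
    """Reference matrix in z-units: columns have mean 0, SD 1 w.r.t. the fitting params."""

    values: np.ndarray
    subject_ids: tuple[str, ...]
    feature_labels: tuple[str, ...]
    params: StandardizationParams

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class StandardizedVector:
    """Subject vector in z-units of the reference."""

    values: np.ndarray
    feature_labels: tuple[str, ...]
    params: StandardizationParams
    subject_id: str = "subject"

    @property
    def p(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class PCBasis:
    """Orthonormal eigenvector basis of the reference correlation matrix.

    ``eigenvectors`` is p x m with orthonormal columns, ``eigenvalues`` the
    matching descending variances.  ``tve`` is the cumulative proportion of
    the FULL trace (= p for standardized data) explained by the leading
    components, so for n < p it reaches 1.0 at the numeric rank.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    n_fit: int
    total_variance: float
    tve: np.ndarray = field(init=False)

    def __post_init__(self):
        vecs = np.asarray(self.eigenvectors, dtype=float)
        vals = np.asarray(self.eigenvalues, dtype=float).ravel()
        if vecs.ndim != 2 or vecs.shape[1] != vals.size:
            raise ValueError("eigenvectors must be p x m with m matching eigenvalues")
        if np.any(np.diff(vals) > 0):
            raise ValueError("eigenvalues must be in descending order")
        object.__setattr__(self, "eigenvectors", vecs)
        object.__setattr__(self, "eigenvalues", vals)
        object.__setattr__(self, "tve", np.cumsum(vals) / float(self.total_variance))

    @property
    def p(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def m(self) -> int:
        return self.eigenvalues.size

    def truncate(self, k: int) -> "PCBasis":
        """Basis restricted to the first k components (1 <= k <= m)."""
        if not 1 <= k <= self.m:
            raise ValueError(f"k must be in [1, {self.m}], got {k}")
        return PCBasis(
            eigenvectors=self.eigenvectors[:, :k],
            eigenvalues=self.eigenvalues[:k],
            n_fit=self.n_fit,
            total_variance=self.total_variance,
        )


@dataclass(frozen=True)
class PCScores:
    """Projection of standardized data onto a PC basis (optionally whitened)."""

    values: np.ndarray  # (k,) for one subject or (n, k) for a cohort
    scaled: bool
    k: int


def compute_standardization_params(ref: ReferenceMatrix) -> StandardizationParams:
    """Column means and SDs (n-1 denominator) of the reference.

    Raises if any feature has zero variance, naming the offending label: a
    constant feature carries no normalcy information and cannot be z-scored.
    """
    mu = ref.values.mean(axis=0)
    sigma = ref.values.std(axis=0, ddof=1)
    bad = np.flatnonzero(sigma == 0)
    if bad.size:
        names = ", ".join(ref.feature_labels[j] for j in bad[:5])
        raise ValueError(f"zero variance in reference feature(s): {names}")
    return StandardizationParams(mu=mu, sigma=sigma, feature_labels=ref.feature_labels)


def _check_labels(labels: tuple[str, ...], params: StandardizationParams) -> None:
    if labels != params.feature_labels:
        if set(labels) == set(params.feature_labels):
            raise ValueError("feature order mismatch with standardization params")
        raise ValueError("feature labels do not match standardization params")


def standardize(
    x: Union[ReferenceMatrix, SubjectVector],
    params: StandardizationParams,
) -> Union[StandardizedMatrix, StandardizedVector]:
    """Elementwise (x - mu) / sigma in the reference's units."""
    if isinstance(x, ReferenceMatrix):
        _check_labels(x.feature_labels, params)
        z = (x.values - params.mu) / params.sigma
        return StandardizedMatrix(
            values=z, subject_ids=x.subject_ids, feature_labels=x.feature_labels, params=params
        )
    if isinstance(x, SubjectVector):
        _check_labels(x.feature_labels, params)
        z = (x.values - params.mu) / params.sigma
        return StandardizedVector(
            values=z, feature_labels=x.feature_labels, params=params, subject_id=x.subject_id
        )
    raise TypeError(f"cannot standardize object of type {type(x).__name__}")


def fit_pc_basis(ref_z: StandardizedMatrix, zero_tol: float = 1e-10) -> PCBasis:
    """Eigen-decompose the covariance of the standardized reference.

    Computed via SVD of ref_z / sqrt(n-1) (eigenvalues = squared singular
    values), which is numerically stable when p >> n.  Components with
    eigenvalue < zero_tol * largest are truncated before any sqrt(lambda)
    scaling can blow up; the retained count is additionally capped at
    min(n-1, p), the rank bound of a centered n x p matrix.  Eigenvector
    signs are fixed so the largest-magnitude loading of each component is
    positive, making score signs reproducible across platforms.
    """
    z = np.asarray(ref_z.values, dtype=float)
    n, p = z.shape
    if n < 2:
        raise ValueError("need at least 2 reference subjects to fit a basis")
    _, s, vt = np.linalg.svd(z / np.sqrt(n - 1), full_matrices=False)
    eigenvalues = s**2
    m_cap = min(n - 1, p)
    keep = eigenvalues >= zero_tol * eigenvalues[0]
    m = min(int(keep.sum()), m_cap)
    vecs = vt[:m].T.copy()
    vals = eigenvalues[:m].copy()
    # sign convention: dominant loading positive
    flip = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(m)])
    flip[flip == 0] = 1.0
    vecs *= flip
    return PCBasis(eigenvectors=vecs, eigenvalues=vals, n_fit=n, total_variance=float(p))


def project(
    x_z: Union[StandardizedVector, StandardizedMatrix],
    basis: PCBasis,
    scaled: bool = True,
) -> PCScores:
    """Scores = E^T z; if ``scaled``, component j is divided by sqrt(lambda_j).

    With scaling, each retained component of the fitting reference has unit
    variance, so the scores live in a whitened space where the origin is the
    reference centroid and distance is comparable across components.
    """
    z = np.asarray(x_z.values, dtype=float)
    if z.shape[-1] != basis.p:
        raise ValueError(f"dimension mismatch: data has p={z.shape[-1]}, basis expects p={basis.p}")
    scores = z @ basis.eigenvectors
    if scaled:
        scores = scores / np.sqrt(basis.eigenvalues)
    return PCScores(values=scores, scaled=scaled, k=basis.m)


def _resolve_retention(basis: PCBasis, retention, ref: ReferenceMatrix, ref_z) -> int:
    """Map a retention specification to a component count k."""
    if retention is None or (isinstance(retention, str) and retention == "all"):
        return basis.m
    if isinstance(retention, (int, np.integer)):
        k = int(retention)
        if not 1 <= k <= basis.m:
            raise ValueError(f"fixed k must be in [1, {basis.m}], got {k}")
        return k
    from . import selection  # local import: selection builds on core

    if isinstance(retention, selection.RetentionRule):
        decision = selection.apply_rule(retention, basis=basis, ref=ref, ref_z=ref_z)
        if decision.k < 1:
            raise ValueError(
                f"retention rule {retention.method!r} retained k=0 components; "
                "cannot measure abnormality with an empty basis"
            )
        return decision.k
    raise TypeError(f"unsupported retention specification: {retention!r}")


def measure_abnormality(
    subj: SubjectVector,
    ref: ReferenceMatrix,
    retention="all",
    measure: str = "euclidean",
    zero_tol: float = 1e-10,
):
    """End-to-end abnormality of one subject against a reference cohort.

    Composes standardize -> fit_pc_basis -> retain k -> project (whitened)
    -> distance from the origin.  ``retention`` may be "all", a fixed integer
    k, or a :class:`normindex.selection.RetentionRule`.  Returns an
    :class:`normindex.distances.AbnormalityResult`.
    """
    from .distances import AbnormalityResult, distance_from_origin

    params = compute_standardization_params(ref)
    ref_z = standardize(ref, params)
    subj_z = standardize(subj, params)
    basis = fit_pc_basis(ref_z, zero_tol=zero_tol)
    k = _resolve_retention(basis, retention, ref, ref_z)
    scores = project(subj_z, basis.truncate(k), scaled=True)
    value = distance_from_origin(scores, measure)
    return AbnormalityResult(
        subject_id=subj.subject_id,
        measure=measure,
        basis="principal_component",
        k=k,
        value=value,
    )
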