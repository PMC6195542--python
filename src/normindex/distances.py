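"""Distance-from-origin measures over whitened PC scores, the mu=100/sigma=10
clinical rescaling, and the standard-basis conventions of earlier gait indices.

Once a subject is expressed in the whitened principal-component space of the
reference, any distance from the origin is an abnormality score.  Different
published gait indices differ only in the metric and the basis they use:
a squared Euclidean distance over all whitened components; a log-Euclidean
distance taken in the *standard* standardized basis (no decorrelation); and
an RMS difference from the reference mean in raw units.  Those conventions
are reproduced here as baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .core import (
    PCScores,
    ReferenceMatrix,
    StandardizedVector,
    SubjectVector,
    compute_standardization_params,
    measure_abnormality,
    standardize,
)

__all__ = [
    "AbnormalityResult",
    "MEASURES",
    "distance_from_origin",
    "scale_to_clinical",
    "baseline_index",
]

MEASURES = ("euclidean", "squared_euclidean", "manhattan", "rms", "mad", "ln_euclidean")


@dataclass(frozen=True)
class AbnormalityResult:
    subject_id: str
    measure: str
    basis: str  # "standard" or "principal_component"
    k: int
    value: float
    scaled_value: Optional[float] = None

    def __post_init__(self):
        if self.basis not in ("standard", "principal_component", "raw"):
            raise ValueError(f"unknown basis {self.basis!r}")


def _score_vector(scores: Union[PCScores, StandardizedVector, np.ndarray]) -> np.ndarray:
    if isinstance(scores, PCScores):
        v = scores.values
    elif isinstance(scores, StandardizedVector):
        v = scores.values
    else:
        v = np.asarray(scores, dtype=float)
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if v.ndim != 1:
        raise ValueError("distance_from_origin expects a single score vector")
    if v.size == 0:
        raise ValueError("empty score vector")
    return v


def distance_from_origin(scores, measure: str = "euclidean") -> float:
    """Distance of a score vector from the origin (the reference centroid).

    euclidean = l2 norm; squared_euclidean = its square; manhattan = l1;
    rms = l2 / sqrt(k); mad = l1 / k; ln_euclidean = ln(l2 norm).  The
    denominators for rms/mad use the number of components actually present
    in the score vector.
    """
    v = _score_vector(scores)
    k = v.size
    l2 = float(np.linalg.norm(v))
    if measure == "euclidean":
        return l2
    if measure == "squared_euclidean":
        return l2**2
    if measure == "manhattan":
        return float(np.abs(v).sum())
    if measure == "rms":
        return l2 / np.sqrt(k)
    if measure == "mad":
        return float(np.abs(v).sum()) / k
    if measure == "ln_euclidean":
        if l2 == 0.0:
            raise ValueError("ln_euclidean undefined: subject identical to reference mean")
        return float(np.log(l2))
    raise ValueError(f"unknown distance measure {measure!r}; choose one of {MEASURES}")


def scale_to_clinical(
    raw_ref: np.ndarray,
    raw_subj: Union[float, np.ndarray],
    target_mu: float = 100.0,
    target_sigma: float = 10.0,
    higher_is_normal: bool = True,
) -> Union[float, np.ndarray]:
    """Rescale raw abnormality scores to a clinical mu=100, sigma=10 scale.

    The subject's raw score is z-scored against the reference cohort's raw
    scores; with the default direction a subject at the reference mean maps
    to 100 and each reference SD of extra abnormality subtracts 10 points
    (larger = more normal, the convention of the established clinical index).
    """
    raw_ref = np.asarray(raw_ref, dtype=float)
    sd = raw_ref.std(ddof=1)
    if sd == 0:
        raise ValueError("reference raw scores have zero SD; cannot build clinical scale")
    z = (np.asarray(raw_subj, dtype=float) - raw_ref.mean()) / sd
    sign = -1.0 if higher_is_normal else 1.0
    out = target_mu + sign * target_sigma * z
    return float(out) if np.ndim(out) == 0 else out


def baseline_index(
    subj: SubjectVector,
    ref: ReferenceMatrix,
    convention: str,
) -> AbnormalityResult:
    """Abnormality under one of the prior gait-index distance conventions.

    schutte: squared Euclidean over all whitened PC scores (full retention).
    schwartz_rozumalski: natural log of the Euclidean norm of the subject's
        z-scores in the STANDARD basis — no decorrelation, which is exactly
        why it is a baseline rather than the recommended measure.
    baker: RMS difference between subject and reference mean in raw feature
        units (no standardization at all).
    """
    if convention == "schutte":
        res = measure_abnormality(subj, ref, retention="all", measure="squared_euclidean")
        return AbnormalityResult(
            subject_id=subj.subject_id,
            measure="squared_euclidean",
            basis="principal_component",
            k=res.k,
            value=res.value,
        )
    if convention == "schwartz_rozumalski":
        params = compute_standardization_params(ref)
        z = standardize(subj, params)
        value = distance_from_origin(z, "ln_euclidean")
        return AbnormalityResult(
            subject_id=subj.subject_id,
            measure="ln_euclidean",
            basis="standard",
            k=subj.p,
            value=value,
        )
    if convention == "baker":
        params = compute_standardization_params(ref)
        diff = subj.values - params.mu
        value = float(np.sqrt(np.mean(diff**2)))
        return AbnormalityResult(
            subject_id=subj.subject_id,
            measure="rms",
            basis="raw",
            k=subj.p,
            value=value,
        )
    raise ValueError(
        f"unknown baseline convention {convention!r}; "
        "choose schutte, schwartz_rozumalski or baker"
    )


def standard_basis_abnormality(
    subj: SubjectVector,
    ref: ReferenceMatrix,
    measure: str = "euclidean",
) -> AbnormalityResult:
    """Distance from the origin in the standardized (but un-rotated) basis."""
    params = compute_standardization_params(ref)
    z = standardize(subj, params)
    return AbnormalityResult(
        subject_id=subj.subject_id,
        measure=measure,
        basis="standard",
        k=subj.p,
        value=distance_from_origin(z, measure),
    )
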