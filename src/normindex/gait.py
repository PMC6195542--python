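"""Synthetic gait kinematics with the statistical structure of a real
able-bodied reference: 9 joint-angle curves sampled at 51 points of the gait
cycle (459 features), smooth, strongly inter-correlated, and of low rank
relative to the feature count.

The generative model is a smooth low-rank factor model: each subject's curve
set is the population mean plus a handful of shared smooth basis functions
weighted by subject-specific factor scores, plus a small smooth residual.
Inter-subject kinematic variability in real cohorts is dominated by
offset-like modes (e.g. overall pelvic tilt or crouch), so about half of the
default factors are near-constant over the cycle and the rest are low-order
sinusoids; this yields the strongly positive within-angle correlations and
rank <= n-1 spectra that real 32 x 459 gait matrices exhibit.  No
biomechanical fidelity is claimed beyond those statistical properties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ReferenceMatrix, SubjectVector

__all__ = [
    "ANGLE_NAMES",
    "N_CYCLE_POINTS",
    "GaitPopulationModel",
    "default_gait_model",
    "generate_reference_cohort",
    "generate_abnormal_subject",
    "feature_labels",
]

ANGLE_NAMES = (
    "pelvic_tilt",
    "pelvic_obliquity",
    "pelvic_rotation",
    "hip_flexion",
    "hip_abduction",
    "hip_rotation",
    "knee_flexion",
    "ankle_dorsiflexion",
    "foot_progression",
)
N_CYCLE_POINTS = 51  # 0..100% of the gait cycle at 2% increments
CYCLE_PCT = np.arange(0, 101, 2)


def feature_labels() -> tuple[str, ...]:
    """Angle-major labels: angle 1 points 0..100%, then angle 2, ... (459 total)."""
    return tuple(f"{a}_{c:03d}" for a in ANGLE_NAMES for c in CYCLE_PCT)


@dataclass(frozen=True)
class GaitPopulationModel:
    """Smooth low-rank population model for 9 x 51 joint-angle curves.

    mean_curves: (9, 51) population means in degrees.
    basis_functions: (q, 9, 51) smooth factor loadings (q < 32 keeps a 32-row
        cohort at rank <= 31 even before the rank bound of centering).
    score_sds: (q,) SDs of the subject factor scores, in degrees.
    noise_sd: SD of the smooth per-curve residual, degrees.
    """

    mean_curves: np.ndarray
    basis_functions: np.ndarray
    score_sds: np.ndarray
    noise_sd: float

    def __post_init__(self):
        mc = np.asarray(self.mean_curves, dtype=float)
        bf = np.asarray(self.basis_functions, dtype=float)
        sds = np.asarray(self.score_sds, dtype=float)
        if mc.shape != (len(ANGLE_NAMES), N_CYCLE_POINTS):
            raise ValueError(f"mean_curves must be {(len(ANGLE_NAMES), N_CYCLE_POINTS)}")
        if bf.ndim != 3 or bf.shape[1:] != mc.shape:
            raise ValueError("basis_functions must be (q, 9, 51)")
        if sds.shape != (bf.shape[0],):
            raise ValueError("score_sds must have length q")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "mean_curves", mc)
        object.__setattr__(self, "basis_functions", bf)
        object.__setattr__(self, "score_sds", sds)

    @property
    def q(self) -> int:
        return self.basis_functions.shape[0]


def _default_means() -> np.ndarray:
    """Smooth curves loosely shaped like able-bodied kinematic means (degrees)."""
    t = np.linspace(0.0, 1.0, N_CYCLE_POINTS)
    two_pi = 2 * np.pi
    return np.vstack(
        [
            12 + 2.0 * np.sin(two_pi * 2 * t),                      # pelvic tilt
            4.0 * np.sin(two_pi * t + 0.4),                         # pelvic obliquity
            5.0 * np.sin(two_pi * t),                               # pelvic rotation
            17 + 22.0 * np.cos(two_pi * (t + 0.05)),                # hip flexion
            3 + 4.0 * np.sin(two_pi * t + 1.0),                     # hip abduction
            -2 + 3.0 * np.sin(two_pi * t + 2.0),                    # hip rotation
            30 - 27.0 * np.cos(two_pi * (t - 0.18)) + 6 * np.sin(two_pi * 2 * t),  # knee flexion
            2 + 8.0 * np.sin(two_pi * t + 0.8) + 3 * np.sin(two_pi * 2 * t),       # ankle
            -10 + 3.0 * np.sin(two_pi * t + 0.2),                   # foot progression
        ]
    )


def default_gait_model(q: int = 12, noise_sd: float = 0.6, model_seed: int = 12345) -> GaitPopulationModel:
    """The package's default population model.

    The first ceil(q/2)-ish factors are near-constant "offset" modes and the
    rest low-order sinusoids; each factor loads on all angles with fixed
    pseudo-random weights (drawn once from ``model_seed``, so the model itself
    is deterministic).  Factor-score SDs decay geometrically from 4 degrees.
    """
    if not 1 <= q < 32:
        raise ValueError(f"q must be in [1, 31] to keep a 32-row cohort rank-deficient, got {q}")
    t = np.linspace(0.0, 1.0, N_CYCLE_POINTS)
    rng = np.random.default_rng(model_seed)
    n_offset = (q + 1) // 2
    basis = np.zeros((q, len(ANGLE_NAMES), N_CYCLE_POINTS))
    for f in range(q):
        if f < n_offset:
            shape = 1.0 + 0.25 * np.sin(2 * np.pi * t + rng.uniform(0, 2 * np.pi))
        else:
            harmonic = 1 + (f - n_offset) % 3
            shape = np.sin(2 * np.pi * harmonic * t + rng.uniform(0, 2 * np.pi))
        # per-angle weights, biased positive so within-angle correlations are
        # predominantly positive (joints co-vary in the same direction)
        weights = rng.uniform(0.2, 1.0, size=len(ANGLE_NAMES)) * rng.choice(
            [1.0, 1.0, 1.0, -1.0], size=len(ANGLE_NAMES)
        )
        basis[f] = np.outer(weights, shape)
    score_sds = 4.0 * 0.8 ** np.arange(q)
    return GaitPopulationModel(
        mean_curves=_default_means(),
        basis_functions=basis,
        score_sds=score_sds,
        noise_sd=noise_sd,
    )


def _smooth_noise(rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    """Smooth residual curves: a few random low-order harmonics per angle."""
    if noise_sd == 0:
        return np.zeros((len(ANGLE_NAMES), N_CYCLE_POINTS))
    t = np.linspace(0.0, 1.0, N_CYCLE_POINTS)
    out = np.zeros((len(ANGLE_NAMES), N_CYCLE_POINTS))
    for a in range(len(ANGLE_NAMES)):
        for harmonic in (1, 2, 3, 4):
            amp = rng.normal(0, 1.0)
            phase = rng.uniform(0, 2 * np.pi)
            out[a] += amp * np.sin(2 * np.pi * harmonic * t + phase)
    # normalize the harmonic mix to the requested SD (per-angle, in degrees)
    out *= noise_sd / np.sqrt(2.0)  # each of 4 unit-amp harmonics has var 1/2
    return out


def _draw_curves(model: GaitPopulationModel, rng: np.random.Generator) -> np.ndarray:
    scores = rng.normal(0.0, model.score_sds)
    curves = model.mean_curves + np.tensordot(scores, model.basis_functions, axes=1)
    curves = curves + _smooth_noise(rng, model.noise_sd)
    return curves


def generate_reference_cohort(
    model: GaitPopulationModel, n: int = 32, seed: int = 0
) -> ReferenceMatrix:
    """Draw an n-subject reference cohort, flattened angle-major to n x 459."""
    if n < 2:
        raise ValueError("reference cohort needs n >= 2")
    rng = np.random.default_rng(seed)
    values = np.vstack([_draw_curves(model, rng).ravel() for _ in range(n)])
    return ReferenceMatrix(
        values=values,
        subject_ids=tuple(f"able{i + 1:03d}" for i in range(n)),
        feature_labels=feature_labels(),
    )


_PERTURB_MODES = ("amplitude", "offset", "phase")
# fixed per-angle directions for the offset and phase perturbations; the
# alternating signs desynchronize joints rather than shifting gait as a whole
_ANGLE_SIGNS = np.array([1, -1, 1, -1, 1, -1, 1, -1, 1], dtype=float)


def generate_abnormal_subject(
    model: GaitPopulationModel,
    severity: float,
    mode: str = "offset",
    seed: int = 0,
) -> SubjectVector:
    """Draw one subject whose expected abnormality grows with ``severity``.

    severity 0 is an ordinary draw from the reference model.  Modes:

    - ``amplitude``: the subject's deviation from the mean curves is inflated
      by (1 + 0.5*severity) — exaggerated but well-coordinated gait.
    - ``offset``: a constant severity * 2 degrees (alternating sign across
      angles) is added to each curve — static malalignment.
    - ``phase``: each angle's curve is circularly shifted in time by
      severity * 2 cycle points with alternating sign across angles — the
      joints stay individually plausible but lose their mutual timing, the
      kind of abnormality only a dependency-aware measure sees clearly.
    """
    if severity < 0:
        raise ValueError("severity must be >= 0")
    if mode not in _PERTURB_MODES:
        raise ValueError(f"unknown perturbation mode {mode!r}; choose one of {_PERTURB_MODES}")
    rng = np.random.default_rng(seed)
    curves = _draw_curves(model, rng)
    if severity > 0:
        if mode == "amplitude":
            curves = model.mean_curves + (1.0 + 0.5 * severity) * (curves - model.mean_curves)
        elif mode == "offset":
            curves = curves + severity * 2.0 * _ANGLE_SIGNS[:, None]
        else:  # phase
            idx = np.arange(N_CYCLE_POINTS, dtype=float)
            for a in range(len(ANGLE_NAMES)):
                shift = severity * 2.0 * _ANGLE_SIGNS[a]
                src = np.mod(idx + shift, N_CYCLE_POINTS)
                curves[a] = np.interp(src, idx, curves[a], period=N_CYCLE_POINTS)
    return SubjectVector(
        values=curves.ravel(),
        feature_labels=feature_labels(),
        subject_id=f"subj_{mode}_s{severity:g}",
    )
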