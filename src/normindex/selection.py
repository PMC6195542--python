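"""Principal-component retention rules.

How many components to keep trades information loss (too few) against noise
amplification (too many — small-eigenvalue components are divided by tiny
sqrt(lambda) during whitening).  This module implements the common criteria:
cumulative total variance explained (TVE) at a cutoff, Kaiser-Guttman
(eigenvalue > 1), the broken-stick null, parallel analysis against
uncorrelated data of the same shape, and bootstrap confidence-interval
versions of the Kaiser-Guttman and TVE tests for the p >> n regime where
sample eigenvalues are not consistent estimators of population eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import (
    PCBasis,
    ReferenceMatrix,
    StandardizedMatrix,
    compute_standardization_params,
    fit_pc_basis,
    standardize,
)

__all__ = [
    "RetentionRule",
    "RetentionDecision",
    "select_tve",
    "select_kaiser_guttman",
    "select_broken_stick",
    "select_parallel",
    "bootstrap_retention",
    "broken_stick_proportions",
    "apply_rule",
]

_METHODS = (
    "all",
    "tve",
    "kaiser_guttman",
    "broken_stick",
    "parallel",
    "bootstrap_kg",
    "bootstrap_tve",
    "fixed_k",
)


@dataclass(frozen=True)
class RetentionRule:
    """A declarative retention specification, resolvable against any basis."""

    method: str = "all"
    cutoff: float = 0.90
    quantile: float = 0.95
    n_reps: int = 100
    n_boot: int = 500
    conf_level: float = 0.95
    k: int = 1  # for fixed_k
    seed: int = 0

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"unknown retention method {self.method!r}; choose one of {_METHODS}")
        for name in ("cutoff", "quantile", "conf_level"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_reps < 1 or self.n_boot < 1:
            raise ValueError("n_reps and n_boot must be >= 1")


@dataclass(frozen=True)
class RetentionDecision:
    method: str
    k: int
    diagnostics: pd.DataFrame = field(repr=False, default=None)
    warning: Optional[str] = None


def _eigenvalues_of(basis: Union[PCBasis, np.ndarray], total_variance: Optional[float]):
    """Accept a fitted PCBasis or a bare eigenvalue array (e.g. a published spectrum)."""
    if isinstance(basis, PCBasis):
        return basis.eigenvalues, float(basis.total_variance)
    vals = np.asarray(basis, dtype=float).ravel()
    if np.any(np.diff(vals) > 0):
        raise ValueError("eigenvalues must be in descending order")
    tv = float(total_variance) if total_variance is not None else float(vals.sum())
    return vals, tv


def select_tve(
    basis: Union[PCBasis, np.ndarray],
    cutoff: float,
    total_variance: Optional[float] = None,
) -> RetentionDecision:
    """Smallest k whose cumulative variance proportion reaches ``cutoff``.

    TVE is computed against the full trace (p for standardized data), so with
    a rank-truncated basis a high cutoff may be unattainable; in that case all
    m components are retained and the decision carries a warning.
    """
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    vals, tv = _eigenvalues_of(basis, total_variance)
    cum = np.cumsum(vals) / tv
    reached = np.flatnonzero(cum >= cutoff)
    warning = None
    if reached.size:
        k = int(reached[0]) + 1
    else:
        k = vals.size
        warning = f"cutoff {cutoff} unattainable with truncated basis (max TVE {cum[-1]:.4f})"
    diag = pd.DataFrame(
        {
            "component": np.arange(1, vals.size + 1),
            "eigenvalue": vals,
            "cumulative_tve": cum,
            "retained": np.arange(1, vals.size + 1) <= k,
        }
    )
    return RetentionDecision(method="tve", k=k, diagnostics=diag, warning=warning)


def select_kaiser_guttman(
    basis: Union[PCBasis, np.ndarray],
    total_variance: Optional[float] = None,
) -> RetentionDecision:
    """Retain components with eigenvalue strictly greater than 1.

    Meaningful for standardized data (trace = p), where eigenvalue 1 is the
    variance of a single original variable; a component above 1 carries more
    information than any one input feature.
    """
    vals, tv = _eigenvalues_of(basis, total_variance)
    k = int(np.sum(vals > 1.0))
    warning = None
    if k == 0:
        warning = "degenerate: no eigenvalue exceeds 1"
    diag = pd.DataFrame(
        {
            "component": np.arange(1, vals.size + 1),
            "eigenvalue": vals,
            "threshold": 1.0,
            "retained": vals > 1.0,
        }
    )
    return RetentionDecision(method="kaiser_guttman", k=k, diagnostics=diag, warning=warning)


def broken_stick_proportions(p: int) -> np.ndarray:
    """Expected variance proportions b_k = (1/p) * sum_{i=k..p} 1/i.

    The lengths of a unit stick broken at p-1 uniform random points, sorted
    descending — the null model for ordered variance proportions.
    """
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def select_broken_stick(
    basis: Union[PCBasis, np.ndarray],
    total_variance: Optional[float] = None,
    n_features: Optional[int] = None,
) -> RetentionDecision:
    """Retain the leading run of components whose observed variance proportion
    strictly exceeds the broken-stick expectation (proportions of the full
    trace, with the stick broken into the ambient number of features p)."""
    vals, tv = _eigenvalues_of(basis, total_variance)
    if isinstance(basis, PCBasis):
        p_ambient = basis.p
    else:
        p_ambient = int(n_features) if n_features is not None else vals.size
    props = vals / tv
    b = broken_stick_proportions(p_ambient)[: vals.size]
    passing = props > b
    k = int(np.argmin(passing)) if not passing.all() else vals.size
    if passing.size and not passing[0]:
        k = 0
    diag = pd.DataFrame(
        {
            "component": np.arange(1, vals.size + 1),
            "eigenvalue": vals,
            "proportion": props,
            "threshold": b,
            "retained": np.arange(1, vals.size + 1) <= k,
        }
    )
    return RetentionDecision(method="broken_stick", k=k, diagnostics=diag)


def select_parallel(
    ref_z: StandardizedMatrix,
    n_reps: int = 100,
    quantile: float = 0.95,
    seed: int = 0,
) -> RetentionDecision:
    """Parallel analysis: compare observed eigenvalues to those of uncorrelated
    standard-normal data of the same n x p shape.

    ``n_reps`` null datasets are simulated, each standardized by its own
    sample moments and decomposed exactly like the observed data; a component
    is retained while its observed eigenvalue exceeds the per-component null
    ``quantile``.  Retention stops at the first failure (leading-run rule).
    """
    if n_reps < 10:
        raise ValueError("parallel analysis needs n_reps >= 10")
    basis = fit_pc_basis(ref_z)
    n, p = ref_z.values.shape
    rng = np.random.default_rng(seed)
    m = basis.m
    null_vals = np.zeros((n_reps, m))
    for r in range(n_reps):
        x = rng.standard_normal((n, p))
        xz = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        s = np.linalg.svd(xz / np.sqrt(n - 1), compute_uv=False)
        ev = s**2
        null_vals[r] = ev[:m] if ev.size >= m else np.pad(ev, (0, m - ev.size))
    thresholds = np.quantile(null_vals, quantile, axis=0)
    passing = basis.eigenvalues > thresholds
    k = int(np.argmin(passing)) if not passing.all() else m
    if passing.size and not passing[0]:
        k = 0
    diag = pd.DataFrame(
        {
            "component": np.arange(1, m + 1),
            "eigenvalue": basis.eigenvalues,
            "threshold": thresholds,
            "retained": np.arange(1, m + 1) <= k,
        }
    )
    return RetentionDecision(method="parallel", k=k, diagnostics=diag)


def bootstrap_retention(
    ref: ReferenceMatrix,
    mode: str = "eigenvalue_lt1",
    n_boot: int = 500,
    conf_level: float = 0.95,
    cutoff: float = 0.90,
    seed: int = 0,
) -> RetentionDecision:
    """Bootstrap CI-based retention for the p >> n regime.

    Reference rows are resampled with replacement; the standardization and
    decomposition are refit per replicate, giving a bootstrap distribution of
    each ordered eigenvalue (and of cumulative TVE).  One-sided percentile
    bounds at ``conf_level`` drive the tests:

    - ``eigenvalue_lt1``: the first component whose upper bound falls below 1
      marks the cutoff; everything before it is retained (a CI version of
      Kaiser-Guttman).
    - ``tve_ge_cutoff``: retain k = the first component whose cumulative-TVE
      lower bound reaches ``cutoff`` (that component is included, since the
      test certifies the target variance has been explained).

    Replicates where a resampled column is constant are redrawn and counted.
    Deterministic given ``seed``.
    """
    if mode not in ("eigenvalue_lt1", "tve_ge_cutoff"):
        raise ValueError(f"unknown bootstrap mode {mode!r}")
    rng = np.random.default_rng(seed)
    n, p = ref.values.shape
    m_full = min(n - 1, p)
    boot_vals = np.zeros((n_boot, m_full))
    redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            x = ref.values[idx]
            sd = x.std(axis=0, ddof=1)
            if np.all(sd > 0):
                break
            redrawn += 1
        xz = (x - x.mean(axis=0)) / sd
        s = np.linalg.svd(xz / np.sqrt(n - 1), compute_uv=False)
        ev = s**2
        boot_vals[b] = ev[:m_full] if ev.size >= m_full else np.pad(ev, (0, m_full - ev.size))

    params = compute_standardization_params(ref)
    basis = fit_pc_basis(standardize(ref, params))
    m = basis.m
    boot_vals = boot_vals[:, :m]
    warning = None
    if n_boot == 1:
        warning = "degenerate: n_boot=1 gives zero-width intervals"
    if redrawn:
        warning = ((warning + "; ") if warning else "") + f"{redrawn} replicate(s) redrawn for zero-variance columns"

    comp = np.arange(1, m + 1)
    if mode == "eigenvalue_lt1":
        upper = np.quantile(boot_vals, conf_level, axis=0)
        lower = np.quantile(boot_vals, 1 - conf_level, axis=0)
        below = np.flatnonzero(upper < 1.0)
        k = int(below[0]) if below.size else m  # retain everything before the cutoff component
        diag = pd.DataFrame(
            {
                "component": comp,
                "eigenvalue": basis.eigenvalues,
                "ci_lower": lower,
                "ci_upper": upper,
                "retained": comp <= k,
            }
        )
        return RetentionDecision(method="bootstrap_kg", k=k, diagnostics=diag, warning=warning)

    boot_tve = np.cumsum(boot_vals, axis=1) / p
    lower = np.quantile(boot_tve, 1 - conf_level, axis=0)
    upper = np.quantile(boot_tve, conf_level, axis=0)
    reached = np.flatnonzero(lower >= cutoff)
    if reached.size:
        k = int(reached[0]) + 1
    else:
        k = m
        warning = ((warning + "; ") if warning else "") + (
            f"TVE cutoff {cutoff} not certified by any component; retaining all {m}"
        )
    diag = pd.DataFrame(
        {
            "component": comp,
            "eigenvalue": basis.eigenvalues,
            "cumulative_tve": basis.tve,
            "ci_lower": lower,
            "ci_upper": upper,
            "retained": comp <= k,
        }
    )
    return RetentionDecision(method="bootstrap_tve", k=k, diagnostics=diag, warning=warning)


def bootstrap_eigenvalue_intervals(
    ref: ReferenceMatrix,
    n_boot: int = 500,
    conf_level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-sided percentile CIs for the ordered eigenvalues (diagnostic helper)."""
    rng = np.random.default_rng(seed)
    n, p = ref.values.shape
    m = min(n - 1, p)
    boot_vals = np.zeros((n_boot, m))
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            x = ref.values[idx]
            sd = x.std(axis=0, ddof=1)
            if np.all(sd > 0):
                break
        xz = (x - x.mean(axis=0)) / sd
        s = np.linalg.svd(xz / np.sqrt(n - 1), compute_uv=False)
        ev = s**2
        boot_vals[b] = ev[:m] if ev.size >= m else np.pad(ev, (0, m - ev.size))
    alpha = 1 - conf_level
    return pd.DataFrame(
        {
            "component": np.arange(1, m + 1),
            "ci_lower": np.quantile(boot_vals, alpha / 2, axis=0),
            "ci_upper": np.quantile(boot_vals, 1 - alpha / 2, axis=0),
        }
    )


def apply_rule(
    rule: RetentionRule,
    basis: PCBasis,
    ref: Optional[ReferenceMatrix] = None,
    ref_z: Optional[StandardizedMatrix] = None,
) -> RetentionDecision:
    """Resolve a RetentionRule against a fitted basis (and, where the rule
    needs raw data — parallel, bootstrap — the reference itself)."""
    if rule.method == "all":
        return RetentionDecision(method="all", k=basis.m)
    if rule.method == "fixed_k":
        if not 1 <= rule.k <= basis.m:
            raise ValueError(f"fixed k must be in [1, {basis.m}], got {rule.k}")
        return RetentionDecision(method="fixed_k", k=rule.k)
    if rule.method == "tve":
        return select_tve(basis, rule.cutoff)
    if rule.method == "kaiser_guttman":
        return select_kaiser_guttman(basis)
    if rule.method == "broken_stick":
        return select_broken_stick(basis)
    if rule.method == "parallel":
        if ref_z is None:
            raise ValueError("parallel analysis needs the standardized reference")
        return select_parallel(ref_z, n_reps=rule.n_reps, quantile=rule.quantile, seed=rule.seed)
    if rule.method in ("bootstrap_kg", "bootstrap_tve"):
        if ref is None:
            raise ValueError("bootstrap retention needs the raw reference")
        mode = "eigenvalue_lt1" if rule.method == "bootstrap_kg" else "tve_ge_cutoff"
        return bootstrap_retention(
            ref,
            mode=mode,
            n_boot=rule.n_boot,
            conf_level=rule.conf_level,
            cutoff=rule.cutoff,
            seed=rule.seed,
        )
    raise ValueError(f"unknown retention method {rule.method!r}")
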