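"""Published eigenvalue spectrum used as a retention-rule fixture.

``GAIT_REFERENCE_EIGENVALUES`` is the eigenvalue spectrum reported for the
correlation matrix of an able-bodied gait reference cohort (32 subjects x
459 kinematic features: 9 joint angles at 51 gait-cycle points).  Only the
first 32 components are listed because a centered 32-row matrix has rank at
most 31 — the 32nd eigenvalue is already 0 to the printed precision and the
remaining 427 are exactly zero.  Values are as printed (2 decimal places);
they sum to 458.99, i.e. the full trace of 459 up to rounding.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GAIT_REFERENCE_EIGENVALUES", "GAIT_REFERENCE_TOTAL_VARIANCE"]

GAIT_REFERENCE_EIGENVALUES = np.array(
    [
        129.96, 67.59, 52.57, 36.59, 34.56, 30.43, 23.10, 15.77,
        12.05, 9.35, 7.50, 6.88, 4.87, 4.43, 4.14, 3.39,
        2.47, 2.40, 2.05, 1.47, 1.46, 1.32, 0.89, 0.89,
        0.72, 0.61, 0.42, 0.37, 0.33, 0.25, 0.16, 0.00,
    ]
)

GAIT_REFERENCE_TOTAL_VARIANCE = 459.0
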