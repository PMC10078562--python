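"""Sway path length metrics of a centre-of-pressure trial.

Path lengths are the cumulative absolute increments of the COP position
over the trial: per axis

    ML path = sum_i |X_{i+1} - X_i|,   AP path = sum_i |Y_{i+1} - Y_i|,

and the total planar path

    total path = sum_i sqrt((X_{i+1}-X_i)^2 + (Y_{i+1}-Y_i)^2),

summed over n = N - 1 increments.  Longer paths indicate less controlled
posture.  COP series are used unfiltered: filtering removes genuine
high-frequency sway content and deflates the path length.
"""

from __future__ import annotations

import numpy as np

from .core import CopTrial, DataError, SwayMetrics


def compute_sway_paths(trial: CopTrial) -> SwayMetrics:
    """Compute ML, AP and total sway path lengths (mm) of one trial."""
    if trial.n_samples < 2:
        raise DataError("sway paths need at least 2 samples")
    dx = np.diff(trial.x)
    dy = np.diff(trial.y)
    return SwayMetrics(
        ml_path=float(np.sum(np.abs(dx))),
        ap_path=float(np.sum(np.abs(dy))),
        total_path=float(np.sum(np.hypot(dx, dy))),
        n_increments=len(dx),
    )
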