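"""The gamma-scaling line and the position-on-line biomarker.

Quasicritical systems keep their effective exponent pairs (tau_S, tau_T)
near the line tau_T - 1 = gamma (tau_S - 1).  Over a cohort the line is
estimated by ordinary least squares of tau_T on tau_S; each subject's
"position on the line" is the scalar projection of their (vertically
shifted) exponent pair onto the line direction, normalised by the largest
projection in the cohort, giving a value in [0, 1].  Positions are
cohort-relative: values are only comparable within one jointly normalised
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateCohortError, FitFailureError

__all__ = ["ScalingLine", "fit_scaling_line", "position_on_line"]


@dataclass
class ScalingLine:
    """Least-squares line tau_T = slope * tau_S + intercept over a cohort."""

    slope: float
    intercept: float
    slope_stderr: float
    n_pairs: int


def fit_scaling_line(pairs) -> ScalingLine:
    """OLS fit of tau_T on tau_S; the slope is the cohort gamma_lsf."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise FitFailureError("need >= 3 (tau_S, tau_T) pairs")
    tau_s, tau_t = arr[:, 0], arr[:, 1]
    if np.ptp(tau_s) == 0:
        raise FitFailureError("degenerate abscissa: all tau_S equal")
    res = stats.linregress(tau_s, tau_t)
    return ScalingLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_stderr=float(res.stderr),
        n_pairs=arr.shape[0],
    )


def position_on_line(pairs, line: ScalingLine) -> np.ndarray:
    """Normalised scalar projections of exponent pairs onto the scaling line.

    Every tau_T is first shifted by the line's intercept so the line passes
    through the origin; each shifted vector (tau_S, tau_T - c) is then
    projected onto the unit vector along the line, and all projections are
    divided by the cohort maximum.  Returns values in [0, 1] with the
    maximum exactly 1.
    """
    arr = np.atleast_2d(np.asarray(pairs, dtype=float))
    direction = np.array([1.0, line.slope])
    direction = direction / np.linalg.norm(direction)
    shifted = arr - np.array([0.0, line.intercept])
    proj = shifted @ direction
    max_proj = proj.max()
    if max_proj <= 0:
        raise DegenerateCohortError("non-positive maximum projection")
    return proj / max_proj
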