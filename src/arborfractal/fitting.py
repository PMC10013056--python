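"""Log-log regression shared by the dimension estimators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError


@dataclass
class DimensionEstimate:
    """A fractal dimension from a log-log fit.

    ``D`` is the dimension on the method's convention (-slope for ruler and
    box counts, 1/(1-S) for tortuosity); ``slope`` is the raw fitted slope;
    ``stderr`` is the standard error of D; ``fit_range`` the (min, max)
    scale in µm actually used; ``method`` one of D_BC, D_BCN, D_BT, D_A.
    """

    D: float
    stderr: float
    slope: float
    fit_range: tuple[float, float]
    n_points_fit: int
    method: str


def loglog_ols(x, y, fit_range=None, min_points: int = 3):
    """OLS on (log10 x, log10 y) restricted to ``fit_range`` on x.

    Returns (slope, stderr_slope, n_used, (xmin, xmax)). Base-10 logs are
    used throughout. Raises InsufficientDataError with fewer than
    ``min_points`` rows in range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if fit_range is not None:
        lo, hi = fit_range
        mask = (x >= lo - 1e-12) & (x <= hi + 1e-12)
    else:
        mask = np.ones_like(x, dtype=bool)
    xs, ys = x[mask], y[mask]
    if len(xs) < min_points:
        raise InsufficientDataError(
            f"only {len(xs)} points inside fit range {fit_range} "
            f"(need >= {min_points})"
        )
    res = stats.linregress(np.log10(xs), np.log10(ys))
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return float(res.slope), stderr, int(len(xs)), (float(xs.min()), float(xs.max()))
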