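"""Tortuosity scaling analysis of branches.

Tortuosity T = L_P / L_D is the ratio of a sub-path's curvilinear length to
the Euclidean distance between its endpoints; T = 1 for a straight path.
Measuring T across all vertex-to-vertex sub-paths of every branch, binning
mean T against L_P on a log-log scale and fitting a slope S yields the
tortuosity fractal dimension

    D_BT = 1 / (1 - S),

which equals 1 for straight branches (S = 0) and increases with the
branches' fractal weave. Sub-paths inside sections shared between sibling
branches are deduplicated by their endpoint node pair before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    DivergentDimensionError,
    InsufficientDataError,
)
from .fitting import DimensionEstimate, loglog_ols
from .morphology import Branch

DEFAULT_FIT_RANGE = (4.0, 40.0)  # µm, matches the coastline analysis
DEFAULT_N_BINS = 12


@dataclass
class TortuosityTable:
    """Path records (start, end, L_P, L_D, T) over branch sub-paths.

    ``start``/``end`` are node ids; the dedup key is the unordered node
    pair, so identical sub-paths contributed by sibling branches that share
    a proximal section collapse to a single record.
    """

    start: np.ndarray
    end: np.ndarray
    L_P: np.ndarray
    L_D: np.ndarray
    arbor_id: str = ""

    @property
    def T(self) -> np.ndarray:
        return self.L_P / self.L_D

    @property
    def n_records(self) -> int:
        return len(self.L_P)

    def dedup_keys(self) -> np.ndarray:
        lo = np.minimum(self.start, self.end)
        hi = np.maximum(self.start, self.end)
        return lo.astype(np.int64) * (hi.max() + 1) + hi

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arbor_id": self.arbor_id,
                "start_node": self.start,
                "end_node": self.end,
                "L_P": self.L_P,
                "L_D": self.L_D,
                "T": self.T,
            }
        )


def tortuosity_table(branch: Branch, arbor_id: str = "") -> TortuosityTable:
    """All-sub-paths tortuosity of one branch.

    One record per ordered vertex pair (i < j): L_P from the cumulative arc
    length, L_D from the endpoint coordinates. Endpoints are polyline
    vertices only (no interpolation inside segments).
    """
    if len(branch) < 3:
        raise DegenerateGeometryError("tortuosity needs a branch with >= 3 points")
    n = len(branch)
    i, j = np.triu_indices(n, k=1)
    L_P = branch.cum_len[j] - branch.cum_len[i]
    diffs = branch.points[j] - branch.points[i]
    L_D = np.linalg.norm(diffs, axis=1)
    if np.any(L_D <= 0):
        k = int(np.argmin(L_D))
        raise DegenerateGeometryError(
            f"coincident sub-path endpoints (nodes {branch.node_ids[i[k]]}, "
            f"{branch.node_ids[j[k]]}): closed loop"
        )
    ids = np.asarray(branch.node_ids, dtype=np.int64)
    return TortuosityTable(
        start=ids[i], end=ids[j], L_P=L_P, L_D=L_D, arbor_id=arbor_id
    )


def deduplicate_paths(tables: list[TortuosityTable]) -> TortuosityTable:
    """Merge tables, keeping one record per unordered endpoint node pair.

    Sibling branches share proximal sections, so sub-paths lying entirely
    within a shared section appear in several per-branch tables; they are
    duplicated data and must be removed before fitting. Node pairs only
    deduplicate within the same arbor (tables from different arbors live in
    different id spaces).
    """
    start = np.concatenate([t.start for t in tables])
    end = np.concatenate([t.end for t in tables])
    L_P = np.concatenate([t.L_P for t in tables])
    L_D = np.concatenate([t.L_D for t in tables])
    arbors = np.concatenate(
        [np.full(t.n_records, t.arbor_id, dtype=object) for t in tables]
    )
    lo = np.minimum(start, end)
    hi = np.maximum(start, end)
    df = pd.DataFrame({"arbor": arbors, "lo": lo, "hi": hi})
    first = np.sort(df.drop_duplicates(["arbor", "lo", "hi"]).index.to_numpy())
    return TortuosityTable(
        start=start[first], end=end[first], L_P=L_P[first], L_D=L_D[first],
        arbor_id=tables[0].arbor_id if tables else "",
    )


def bin_table(table: TortuosityTable, fit_range=DEFAULT_FIT_RANGE,
              n_bins: int = DEFAULT_N_BINS) -> pd.DataFrame:
    """Log-spaced bins of L_P over the fit range; arithmetic mean T per bin.

    Bin centres are the geometric means of the bin edges.
    """
    edges = np.geomspace(fit_range[0], fit_range[1], n_bins + 1)
    centres = np.sqrt(edges[:-1] * edges[1:])
    idx = np.digitize(table.L_P, edges) - 1
    in_range = (idx >= 0) & (idx < n_bins) & (table.L_P <= edges[-1] + 1e-12)
    T = table.T
    rows = []
    for b in range(n_bins):
        mask = in_range & (idx == b)
        if mask.any():
            rows.append(
                {"bin_centre": centres[b], "mean_T": float(T[mask].mean()),
                 "n_paths": int(mask.sum())}
            )
    return pd.DataFrame(rows)


def dimension_from_slope(S: float) -> float:
    """Map the tortuosity scaling slope S to the dimension D_BT = 1/(1-S).

    Strictly increasing in S; S = 0 gives the Euclidean limit D_BT = 1.
    """
    if S >= 1:
        raise DivergentDimensionError(
            f"slope S = {S} >= 1 maps to a divergent dimension"
        )
    return 1.0 / (1.0 - S)


def binned_fit(table: TortuosityTable, fit_range=DEFAULT_FIT_RANGE,
               n_bins: int = DEFAULT_N_BINS) -> DimensionEstimate:
    """Fit log10 mean T against log10 L_P over binned data; return D_BT.

    The standard error of D_BT is propagated from the slope by the delta
    method: stderr(D_BT) = D_BT^2 * stderr(S).
    """
    binned = bin_table(table, fit_range, n_bins)
    if len(binned) < 3:
        raise InsufficientDataError(
            f"only {len(binned)} non-empty bins in {fit_range} (need >= 3)"
        )
    S, stderr_S, n, used = loglog_ols(binned["bin_centre"], binned["mean_T"])
    D = dimension_from_slope(S)
    return DimensionEstimate(
        D=D, stderr=D * D * stderr_S, slope=S,
        fit_range=used, n_points_fit=n, method="D_BT",
    )
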