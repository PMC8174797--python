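"""Sliding-window extraction and per-window connectivity estimation.

Windows are defined in seconds (default 30-s width, 15-s step) and converted
to TR units per scan.  Because the step may be a non-integer number of TRs
(15 s at TR 2.0 s is 7.5 TR), window starts are computed in exact fractional
TR units and rounded half-up to integer volume indices, which realizes a
7.5-TR step as alternating 8,7,8,7,... increments.  This convention
simultaneously yields 79 windows for a 804-volume TR-1.5 scan and 39 windows
for a 300-volume TR-2.0 scan.

Within each window the Pearson correlation of every ROI pair is computed and
Fisher z-transformed (atanh), giving one symmetric 10x10 z-matrix per window.
Windows are rectangular (no detrending or tapering) and never span scan
boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import RoiTimeSeries, vectorize_upper_triangle

#: correlations are clipped at this magnitude before atanh so features stay finite
R_MAX = 1.0 - 1e-7
Z_MAX = math.atanh(R_MAX)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds."""

    width_seconds: float = 30.0
    step_seconds: float = 15.0

    def __post_init__(self) -> None:
        if not (self.width_seconds >= self.step_seconds > 0):
            raise ValueError("require width_seconds >= step_seconds > 0")


@dataclass
class WindowedFC:
    """Ordered per-window Fisher-z connectivity matrices for one scan."""

    windows: list[np.ndarray]
    starts_tr: list[int]
    width_tr: int
    subject_id: str
    condition: str

    def __post_init__(self) -> None:
        if len(self.windows) != len(self.starts_tr):
            raise ValueError("windows and starts_tr must have equal length")
        if any(b <= a for a, b in zip(self.starts_tr, self.starts_tr[1:])):
            raise ValueError("window starts must be strictly increasing")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def feature_matrix(self) -> np.ndarray:
        """n_windows x 45 array of upper-triangle feature vectors."""
        return np.array([vectorize_upper_triangle(w) for w in self.windows])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def compute_window_starts(
    n_volumes: int, tr_seconds: float, spec: WindowSpec = WindowSpec()
) -> tuple[list[int], int]:
    """Window start indices (TR units) and integer window width for one scan.

    The window count is ``floor((n_volumes - width_tr) / step_tr) + 1`` with
    the step kept as an exact fraction of TRs; start of window i is
    ``round_half_up(i * step_tr)``.  No window extends past the series.
    """
    width_tr = _round_half_up(spec.width_seconds / tr_seconds)
    if n_volumes < width_tr:
        raise ValueError(
            f"series shorter than one window ({n_volumes} volumes < {width_tr} TR width)"
        )
    step_tr = spec.step_seconds / tr_seconds  # exact fractional TRs
    n_windows = int(math.floor((n_volumes - width_tr) / step_tr)) + 1
    starts = []
    for i in range(n_windows):
        s = _round_half_up(i * step_tr)
        if s + width_tr > n_volumes:  # rounding pushed past the end
            break
        starts.append(s)
    return starts, width_tr


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher z-transform atanh(r), clipped at ``Z_MAX`` for |r| -> 1.

    Strictly increasing and odd; |r| > 1 is rejected.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1):
        raise ValueError("correlation magnitude exceeds 1")
    z = np.arctanh(np.clip(arr, -R_MAX, R_MAX))
    if np.ndim(r) == 0:
        return float(z)
    return z


def window_correlation(ts: RoiTimeSeries, start_tr: int, width_tr: int) -> np.ndarray:
    """Fisher-z pairwise Pearson correlation over one window slice.

    The diagonal is set to 0 by convention; it carries no information and is
    excluded from every downstream computation.
    """
    if width_tr < 3:
        raise ValueError("window must contain at least 3 timepoints")
    if start_tr < 0 or start_tr + width_tr > ts.n_volumes:
        raise ValueError("window exceeds series bounds")
    sl = ts.data[start_tr : start_tr + width_tr]
    stds = sl.std(axis=0)
    if np.any(stds == 0):
        bad = [ts.roi_set.roi_names[i] for i in np.flatnonzero(stds == 0)]
        raise ValueError(
            f"constant ROI column(s) {bad} in window starting at TR {start_tr} "
            f"({ts.subject_id}/{ts.condition})"
        )
    r = np.corrcoef(sl, rowvar=False)
    z = np.arctanh(np.clip(r, -R_MAX, R_MAX))
    np.fill_diagonal(z, 0.0)
    return (z + z.T) / 2.0  # enforce exact symmetry against float noise


def sliding_window_fc(ts: RoiTimeSeries, spec: WindowSpec = WindowSpec()) -> WindowedFC:
    """All windowed z-matrices of a scan, in temporal order."""
    starts, width_tr = compute_window_starts(ts.n_volumes, ts.tr_seconds, spec)
    mats = [window_correlation(ts, s, width_tr) for s in starts]
    return WindowedFC(mats, starts, width_tr, ts.subject_id, ts.condition)
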