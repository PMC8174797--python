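"""Domain types and I/O for ROI time series, connectivity matrices, and cohort manifests.

The pipeline operates on 10 regions of interest (ROIs) spanning three
cognitive-control networks — dorsal attention (DAN), default mode (DMN) and
frontoparietal (FPN).  Time series are stored as tab-separated text with an
ROI-name header row; a JSON manifest lists the scans of a cohort (subject,
condition, TR, path).  Connectivity is carried as symmetric 10x10 Fisher-z
matrices whose diagonal is undefined and never enters any downstream
computation; the clustering feature representation is the upper triangle
(i < j, row-major), a length-45 vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("pre_rest", "task", "post_rest")

#: Default 10-ROI set: 2 DAN, 4 DMN, 4 FPN regions.
DEFAULT_ROI_NETWORKS: dict[str, str] = {
    "IPSl": "DAN",
    "IPSr": "DAN",
    "MPFC": "DMN",
    "PCC": "DMN",
    "LPl": "DMN",
    "LPr": "DMN",
    "LPFCl": "FPN",
    "LPFCr": "FPN",
    "pPCl": "FPN",
    "pPCr": "FPN",
}

N_ROIS = 10
N_PAIRS = N_ROIS * (N_ROIS - 1) // 2  # 45 off-diagonal pairs


class SchemaError(ValueError):
    """A table or manifest does not conform to the expected layout."""


@dataclass(frozen=True)
class RoiSet:
    """Ordered ROI names with their network membership.

    Exactly 10 unique ROIs: 2 in DAN, 4 in DMN, 4 in FPN.
    """

    roi_names: tuple[str, ...]
    network_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.roi_names) != N_ROIS:
            raise ValueError(f"expected {N_ROIS} ROIs, got {len(self.roi_names)}")
        if len(set(self.roi_names)) != N_ROIS:
            raise ValueError("ROI names must be unique")
        counts = {"DAN": 0, "DMN": 0, "FPN": 0}
        for name in self.roi_names:
            net = self.network_of.get(name)
            if net not in counts:
                raise ValueError(f"ROI {name!r} has unknown network {net!r}")
            counts[net] += 1
        if counts != {"DAN": 2, "DMN": 4, "FPN": 4}:
            raise ValueError(f"network sizes must be DAN=2, DMN=4, FPN=4; got {counts}")

    def members(self, network: str) -> tuple[str, ...]:
        return tuple(r for r in self.roi_names if self.network_of[r] == network)

    def index(self, roi: str) -> int:
        return self.roi_names.index(roi)


def default_roi_set() -> RoiSet:
    """The default 10-ROI / 3-network parcellation."""
    return RoiSet(tuple(DEFAULT_ROI_NETWORKS), dict(DEFAULT_ROI_NETWORKS))


@dataclass
class RoiTimeSeries:
    """One scan's ROI signal matrix (T timepoints x 10 ROIs) with metadata."""

    subject_id: str
    condition: str
    tr_seconds: float
    data: np.ndarray
    roi_set: RoiSet = field(default_factory=default_roi_set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.data.ndim != 2 or self.data.shape[1] != len(self.roi_set.roi_names):
            raise ValueError(f"data must be T x {len(self.roi_set.roi_names)}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        stds = self.data.std(axis=0)
        if np.any(stds == 0):
            bad = [self.roi_set.roi_names[i] for i in np.flatnonzero(stds == 0)]
            raise SchemaError(f"constant ROI column(s): {bad}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# Connectivity matrices and feature vectors
# ---------------------------------------------------------------------------

def _check_symmetric(m: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=atol, equal_nan=True):
        raise ValueError("matrix is not symmetric")
    off = m[~np.eye(m.shape[0], dtype=bool)]
    if not np.all(np.isfinite(off)):
        raise ValueError("off-diagonal entries must be finite")
    return m


def vectorize_upper_triangle(m: np.ndarray) -> np.ndarray:
    """Upper triangle (i < j, row-major) of a symmetric matrix as a vector.

    The diagonal is excluded: self-correlation is uninformative and its
    Fisher z is infinite.  Ordering is fixed so centroids are comparable
    across runs: (0,1), (0,2), ..., (0,9), (1,2), ...
    """
    m = _check_symmetric(m)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def devectorize_upper_triangle(z: np.ndarray, n: int = N_ROIS, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper_triangle`; diagonal filled with `diagonal`."""
    z = np.asarray(z, dtype=float)
    expected = n * (n - 1) // 2
    if z.shape != (expected,):
        raise ValueError(f"expected length-{expected} vector, got shape {z.shape}")
    m = np.full((n, n), float(diagonal))
    iu = np.triu_indices(n, k=1)
    m[iu] = z
    m[(iu[1], iu[0])] = z
    return m


def pair_labels(roi_set: RoiSet | None = None) -> list[tuple[str, str]]:
    """ROI-name pairs in feature order (i < j, row-major)."""
    rs = roi_set or default_roi_set()
    names = rs.roi_names
    return [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_roi_timeseries(
    path: str | Path,
    subject_id: str,
    condition: str,
    tr_seconds: float,
    roi_set: RoiSet | None = None,
) -> RoiTimeSeries:
    """Read a TSV time-series table (header = ROI names, one row per timepoint).

    Columns are reordered to the RoiSet order.  Missing ROI columns,
    non-numeric cells and constant columns are rejected with SchemaError.
    """
    rs = roi_set or default_roi_set()
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [r for r in rs.roi_names if r not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing ROI column(s) {missing}")
    df = df[list(rs.roi_names)]
    try:
        data = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.all(np.isfinite(data)):
        raise SchemaError(f"{path}: non-finite value in table")
    try:
        return RoiTimeSeries(subject_id, condition, tr_seconds, data, rs)
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_roi_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    """Write a time series as TSV; round-trips values to full double precision."""
    df = pd.DataFrame(ts.data, columns=list(ts.roi_set.roi_names))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_fc_matrix(m: np.ndarray, path: str | Path, roi_set: RoiSet | None = None) -> None:
    """Write an ROI-labelled 10x10 z-matrix as TSV."""
    rs = roi_set or default_roi_set()
    df = pd.DataFrame(_check_symmetric(m), index=list(rs.roi_names), columns=list(rs.roi_names))
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_fc_matrix(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return _check_symmetric(df.to_numpy(dtype=float))


@dataclass
class ScanEntry:
    subject_id: str
    condition: str
    tr_seconds: float
    path: str


def write_manifest(entries: Sequence[ScanEntry], path: str | Path) -> None:
    """Write the cohort manifest: one JSON record per scan."""
    records = [
        {
            "subject_id": e.subject_id,
            "condition": e.condition,
            "tr_seconds": e.tr_seconds,
            "path": e.path,
        }
        for e in entries
    ]
    Path(path).write_text(json.dumps({"scans": records}, indent=2))


def read_manifest(path: str | Path) -> list[ScanEntry]:
    payload = json.loads(Path(path).read_text())
    try:
        return [ScanEntry(**rec) for rec in payload["scans"]]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed manifest ({exc})") from exc


def load_cohort(manifest_path: str | Path, roi_set: RoiSet | None = None) -> list[RoiTimeSeries]:
    """Load every scan listed in a manifest (paths relative to the manifest)."""
    base = Path(manifest_path).parent
    scans = []
    for entry in read_manifest(manifest_path):
        p = Path(entry.path)
        if not p.is_absolute():
            p = base / p
        scans.append(
            read_roi_timeseries(p, entry.subject_id, entry.condition, entry.tr_seconds, roi_set)
        )
    return scans
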