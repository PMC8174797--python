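"""Synthetic multi-subject ROI time series with hidden connectivity states.

The generator emulates a three-condition, 15-subject fMRI study: a 300-volume
pre-task rest scan (TR 2.0 s), an 804-volume task scan (TR 1.5 s) and a
300-volume post-task rest scan (TR 2.0 s), with one subject missing the
post-task scan.  Each scan hides a per-TR Markov state sequence over five
planted connectivity patterns; observations are zero-mean Gaussians with the
active state's covariance, optionally smoothed per ROI with an AR(1) filter.

The five state blueprints realize a qualitative connectivity structure over
DAN / DMN / FPN:

1. globally high inter- and intra-network coupling, except a decoupled MPFC;
2. high DMN-FPN coupling, DAN anticorrelated with both, DAN intact inside;
3. the low-connectivity pattern — all inter-network coupling near zero,
   intra-network coupling preserved;
4. hemispherically split FPN: right FPN couples to DMN, left FPN to DAN,
   left and right FPN decoupled from each other;
5. high DAN-FPN coupling with the DMN anticorrelated and internally tight.

Blueprint z-levels (high 0.6, low 0.05, anticorrelation -0.3) are design
parameters chosen for separability, not estimates of real connectivity.  The
implied correlation matrices (tanh of z) are repaired to the nearest
positive-definite correlation matrix before sampling.  Default per-condition
occupancy profiles place most rest time in the low-connectivity state and
shift mass toward the split-FPN state during the task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from statsmodels.stats.correlation_tools import corr_nearest
from statsmodels.tools.sm_exceptions import IterationLimitWarning

from .io import (
    CONDITIONS,
    RoiSet,
    RoiTimeSeries,
    default_roi_set,
    vectorize_upper_triangle,
)

N_STATES = 5

#: planted per-condition state-probability profiles (study-design defaults)
DEFAULT_OCCUPANCY_PROFILES: dict[str, tuple[float, ...]] = {
    "pre_rest": (0.172, 0.140, 0.381, 0.138, 0.169),
    "task": (0.172, 0.188, 0.251, 0.221, 0.168),
    "post_rest": (0.168, 0.188, 0.294, 0.153, 0.197),
}

#: (n_volumes, tr_seconds) per condition
DEFAULT_CONDITION_GEOMETRY: dict[str, tuple[int, float]] = {
    "pre_rest": (300, 2.0),
    "task": (804, 1.5),
    "post_rest": (300, 2.0),
}

Z_HIGH = 0.6
Z_LOW = 0.05
Z_ANTI = -0.3


@dataclass
class StateBlueprint:
    """Target Fisher-z level per ROI pair for one planted state."""

    name: int
    z_matrix: np.ndarray  # 10x10 symmetric, diagonal 0
    description: str
    roi_set: RoiSet = field(default_factory=default_roi_set)

    def correlation(self) -> np.ndarray:
        """Implied correlation matrix, repaired to the nearest PD correlation.

        The repair solves the alternating-projections nearest-correlation
        problem with smallest eigenvalue clipped at 1e-6; the result is
        cached on the blueprint.
        """
        if getattr(self, "_correlation_cache", None) is None:
            r = np.tanh(self.z_matrix)
            np.fill_diagonal(r, 1.0)
            with warnings.catch_warnings():
                # the solver reports its iteration cap even when the iterate
                # has long converged; the spectrum is checked below instead
                warnings.simplefilter("ignore", IterationLimitWarning)
                fixed = corr_nearest(r, threshold=1e-6, n_fact=100)
            fixed = (fixed + fixed.T) / 2
            if np.linalg.eigvalsh(fixed).min() <= 0:
                raise ValueError(f"state {self.name}: covariance not PD after repair")
            self._correlation_cache = fixed
        return self._correlation_cache

    def feature_vector(self) -> np.ndarray:
        return vectorize_upper_triangle(self.z_matrix)


@dataclass
class CohortDesign:
    """Study-design parameters for cohort simulation."""

    n_subjects: int = 15
    condition_geometry: dict[str, tuple[int, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_GEOMETRY)
    )
    missing_cells: list[tuple[str, str]] | None = None  # default: last subject lacks post_rest
    occupancy_profiles: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_OCCUPANCY_PROFILES)
    )
    dwell_mean_windows: float = 4.0
    ar_coefficient: float = 0.3
    seed: int = 20210528

    def subjects(self) -> list[str]:
        return [f"sub-{i + 1:02d}" for i in range(self.n_subjects)]

    def __post_init__(self) -> None:
        if self.missing_cells is None:
            self.missing_cells = (
                [(self.subjects()[-1], "post_rest")]
                if "post_rest" in self.condition_geometry
                else []
            )
        for cond, prof in self.occupancy_profiles.items():
            prof = np.asarray(prof, dtype=float)
            if np.any(prof < 0) or not np.isclose(prof.sum(), 1.0, atol=1e-6):
                raise ValueError(f"occupancy profile for {cond} is not a probability vector")
        grid = {(s, c) for s in self.subjects() for c in self.condition_geometry}
        bad = [cell for cell in self.missing_cells if tuple(cell) not in grid]
        if bad:
            raise ValueError(f"missing_cells outside the design grid: {bad}")


@dataclass
class ScanGroundTruth:
    subject_id: str
    condition: str
    state_sequence: np.ndarray  # hidden state per TR, 1..5
    planted_occupancy: np.ndarray  # empirical per-TR state frequencies

    def __post_init__(self) -> None:
        counts = np.bincount(self.state_sequence, minlength=N_STATES + 1)[1:]
        emp = counts / counts.sum()
        if not np.allclose(emp, self.planted_occupancy):
            raise ValueError("planted occupancy inconsistent with sequence")


# ---------------------------------------------------------------------------
# blueprints
# ---------------------------------------------------------------------------

def _blueprint_matrix(fill, roi_set: RoiSet) -> np.ndarray:
    names = roi_set.roi_names
    n = len(names)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = fill(names[i], names[j])
    return m


def default_blueprints(roi_set: RoiSet | None = None) -> list[StateBlueprint]:
    """The five planted connectivity-state blueprints."""
    rs = roi_set or default_roi_set()
    net = rs.network_of
    left_fpn = {"LPFCl", "pPCl"}
    right_fpn = {"LPFCr", "pPCr"}

    def intra(a: str, b: str) -> bool:
        return net[a] == net[b]

    def s1(a: str, b: str) -> float:
        if "MPFC" in (a, b):
            other = b if a == "MPFC" else a
            return Z_HIGH if net[other] == "DMN" else Z_LOW
        return Z_HIGH

    def s2(a: str, b: str) -> float:
        if intra(a, b):
            return Z_HIGH
        nets = {net[a], net[b]}
        return Z_ANTI if "DAN" in nets else Z_HIGH  # DMN-FPN high, DAN segregated

    def s3(a: str, b: str) -> float:
        return Z_HIGH if intra(a, b) else Z_LOW

    def s4(a: str, b: str) -> float:
        pair = {a, b}
        if pair <= left_fpn or pair <= right_fpn:
            return Z_HIGH
        if (a in left_fpn and b in right_fpn) or (a in right_fpn and b in left_fpn):
            return 0.0  # hemispheric FPN decoupling
        if intra(a, b):
            return Z_HIGH
        nets = {net[a], net[b]}
        if nets == {"FPN", "DMN"} and (pair & right_fpn):
            return Z_HIGH
        if nets == {"FPN", "DAN"} and (pair & left_fpn):
            return Z_HIGH
        return Z_LOW

    def s5(a: str, b: str) -> float:
        if intra(a, b):
            return Z_HIGH
        nets = {net[a], net[b]}
        if nets == {"DAN", "FPN"}:
            return Z_HIGH
        return Z_ANTI  # DMN anticorrelated with both task-positive networks

    specs = [
        (1, s1, "global coupling, decoupled MPFC"),
        (2, s2, "DMN-FPN coupled, DAN segregated"),
        (3, s3, "low inter-network connectivity"),
        (4, s4, "split FPN: right-FPN-DMN, left-FPN-DAN"),
        (5, s5, "DAN-FPN coupled, DMN anticorrelated"),
    ]
    return [StateBlueprint(n, _blueprint_matrix(f, rs), d, rs) for n, f, d in specs]


# ---------------------------------------------------------------------------
# scan / cohort simulation
# ---------------------------------------------------------------------------

def _markov_transition(profile: np.ndarray, dwell_mean_tr: float) -> np.ndarray:
    """Transition matrix with stationary distribution ``profile`` and target mean dwell.

    P = (1 - lam) I + lam 1 pi': with probability lam the chain redraws from
    the stationary distribution.  Expected dwell in state i is
    1 / (lam (1 - pi_i)) TRs; lam is set so the stationary-weighted mean
    dwell equals ``dwell_mean_tr``.
    """
    pi = np.asarray(profile, dtype=float)
    lam = float(np.sum(pi / (1.0 - pi))) / dwell_mean_tr
    lam = min(lam, 1.0)
    k = len(pi)
    return (1 - lam) * np.eye(k) + lam * np.tile(pi, (k, 1))


def simulate_scan(
    blueprints: list[StateBlueprint],
    subject_id: str,
    condition: str,
    n_volumes: int,
    tr_seconds: float,
    occupancy_profile: np.ndarray,
    dwell_mean_windows: float = 4.0,
    ar_coefficient: float = 0.3,
    seed: int = 0,
    step_seconds: float = 15.0,
) -> tuple[RoiTimeSeries, ScanGroundTruth]:
    """Simulate one scan: hidden Markov state sequence + state-conditional Gaussians.

    The mean dwell target is given in window-equivalents and converted to TRs
    via the window step.  AR(1) smoothing (variance-preserving) is applied
    per ROI over the state-conditional innovations.
    """
    rng = np.random.default_rng(seed)
    profile = np.asarray(occupancy_profile, dtype=float)
    if np.any(profile < 0) or not np.isclose(profile.sum(), 1.0, atol=1e-6):
        raise ValueError("occupancy_profile is not a probability vector")
    k = len(blueprints)
    if len(profile) != k:
        raise ValueError("profile length must match number of blueprints")

    dwell_mean_tr = dwell_mean_windows * (step_seconds / tr_seconds)
    # degenerate profiles (single state) need no switching dynamics
    if np.any(profile >= 1.0 - 1e-12):
        seq = np.full(n_volumes, int(np.argmax(profile)) + 1)
    else:
        trans = _markov_transition(profile, dwell_mean_tr)
        seq = np.empty(n_volumes, dtype=int)
        state = int(rng.choice(k, p=profile))
        for t in range(n_volumes):
            seq[t] = state + 1
            state = int(rng.choice(k, p=trans[state]))

    covs = [bp.correlation() for bp in blueprints]
    chols = [np.linalg.cholesky(c) for c in covs]
    n_rois = covs[0].shape[0]
    innov = np.empty((n_volumes, n_rois))
    normals = rng.standard_normal((n_volumes, n_rois))
    for t in range(n_volumes):
        innov[t] = chols[seq[t] - 1] @ normals[t]
    if ar_coefficient:
        phi = float(ar_coefficient)
        data = np.empty_like(innov)
        data[0] = innov[0]
        scale = np.sqrt(1 - phi**2)  # keep marginal variance when state is constant
        for t in range(1, n_volumes):
            data[t] = phi * data[t - 1] + scale * innov[t]
    else:
        data = innov

    ts = RoiTimeSeries(subject_id, condition, tr_seconds, data, blueprints[0].roi_set)
    counts = np.bincount(seq, minlength=k + 1)[1:]
    gt = ScanGroundTruth(subject_id, condition, seq, counts / counts.sum())
    return ts, gt


def simulate_cohort(
    design: CohortDesign | None = None,
    blueprints: list[StateBlueprint] | None = None,
) -> tuple[list[RoiTimeSeries], list[ScanGroundTruth]]:
    """Simulate the full cohort: 15 pre_rest + 15 task + 14 post_rest scans by default."""
    design = design or CohortDesign()
    blueprints = blueprints or default_blueprints()
    missing = {tuple(c) for c in design.missing_cells}
    root = np.random.default_rng(design.seed)
    scans, truths = [], []
    for subject in design.subjects():
        for condition in CONDITIONS:
            if condition not in design.condition_geometry:
                continue
            scan_seed = int(root.integers(2**31))
            if (subject, condition) in missing:
                continue
            n_vol, tr = design.condition_geometry[condition]
            ts, gt = simulate_scan(
                blueprints,
                subject,
                condition,
                n_vol,
                tr,
                np.asarray(design.occupancy_profiles[condition]),
                dwell_mean_windows=design.dwell_mean_windows,
                ar_coefficient=design.ar_coefficient,
                seed=scan_seed,
            )
            scans.append(ts)
            truths.append(gt)
    return scans, truths


def sample_gaussian_occupancy(
    mean_profiles: dict[str, np.ndarray],
    noise_sd: float,
    n_subjects: int,
    rng: np.random.Generator,
    missing_cells: set[tuple[str, str]] | None = None,
    scan_intercept_sd: float = 0.0,
    n_windows: dict[str, int] | None = None,
) -> "pd.DataFrame":
    """Occupancy rows drawn as cell mean + optional scan intercept + iid noise.

    A model-conforming generator for calibration studies of the mixed-model
    test: responses are Gaussian around the planted profile, with an optional
    random intercept per (subject, condition) scan.  Unlike the multinomial
    sampler below, rows are not constrained to sum to one within a scan.
    """
    import pandas as pd

    missing_cells = missing_cells or set()
    rows = []
    for i in range(n_subjects):
        subject = f"sub-{i + 1:02d}"
        for condition, profile in mean_profiles.items():
            if (subject, condition) in missing_cells:
                continue
            profile = np.asarray(profile, dtype=float)
            u = rng.normal(0.0, scan_intercept_sd) if scan_intercept_sd > 0 else 0.0
            nw = (n_windows or {}).get(condition, 0)
            for s, p in enumerate(profile, start=1):
                rows.append(
                    {
                        "subject_id": subject,
                        "condition": condition,
                        "state": s,
                        "proportion": p + u + rng.normal(0.0, noise_sd),
                        "n_windows": nw,
                    }
                )
    return pd.DataFrame(rows)


def sample_occupancy_counts(
    profiles: dict[str, np.ndarray],
    n_windows: dict[str, int],
    n_subjects: int,
    rng: np.random.Generator,
    missing_cells: set[tuple[str, str]] | None = None,
) -> list[tuple[str, str, np.ndarray]]:
    """Multinomial window-label draws per (subject, condition), for statistical
    simulation at the occupancy level (sampling noise matched to window counts)."""
    missing_cells = missing_cells or set()
    out = []
    for i in range(n_subjects):
        subject = f"sub-{i + 1:02d}"
        for condition, profile in profiles.items():
            if (subject, condition) in missing_cells:
                continue
            n = n_windows[condition]
            counts = rng.multinomial(n, np.asarray(profile, dtype=float))
            labels = np.repeat(np.arange(1, len(profile) + 1), counts)
            out.append((subject, condition, labels))
    return out
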