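"""Model/Results facade and end-to-end pipeline orchestration.

`DynamicStatesModel` is built from a cohort of ROI time series (in memory or
via a manifest) plus a run configuration; `fit()` runs the sliding-window,
cluster-number-selection and k-means stages and returns a
`DynamicStatesResults` carrying the state solution, window assignments,
fractional-occupancy and transition tables, and diagnostics.  Statistical
testing (`test_interaction`), behaviour correlation, state matching against
another fit (`match_with`), plotting and artifact export hang off the
results object.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import occupancy as _occupancy
from .io import RoiTimeSeries, load_cohort, write_fc_matrix
from .windows import WindowSpec, WindowedFC, sliding_window_fc


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; YAML-serializable.

    Defaults mirror the method's stated settings where they exist: 30-s
    windows with 15-s steps, Euclidean k-means with 25 iterations (plus 25
    restarts for stability), Bonferroni family of 5.
    """

    width_seconds: float = 30.0
    step_seconds: float = 15.0
    k: int | str = "auto"  # "auto" -> majority rule
    k_range: tuple[int, ...] = _cluster.DEFAULT_K_RANGE
    index_set: tuple[str, ...] = _cluster.DEFAULT_INDEX_SET
    seed: int = _cluster.DEFAULT_SEED
    n_init: int = 25
    max_iter: int = 25
    selection_n_init: int = 25
    family_size: int = 5
    ci_level: float = 0.95
    verbosity: int = 1

    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.width_seconds, self.step_seconds)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        d["index_set"] = list(self.index_set)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**payload)
        return RunConfig(
            **{
                **cfg.to_dict(),
                "k_range": tuple(cfg.k_range),
                "index_set": tuple(cfg.index_set),
            }
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


class DynamicStatesModel:
    """Dynamic connectivity-state model over a multi-scan cohort.

    Parameters
    ----------
    scans
        The cohort's ROI time series (one per subject x condition scan).
    config
        Pipeline settings; ``RunConfig()`` reproduces the default protocol.
    """

    def __init__(self, scans: list[RoiTimeSeries], config: RunConfig | None = None):
        if not scans:
            raise ValueError("cohort is empty")
        self.scans = scans
        self.config = config or RunConfig()
        self._log: list[dict] = []

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, config: RunConfig | None = None):
        return cls(load_cohort(manifest_path), config)

    def _logline(self, stage: str, **fields) -> None:
        entry = {"stage": stage, **fields}
        self._log.append(entry)
        if self.config.verbosity:
            print(json.dumps(entry))

    def fit(self, k: int | str | None = None, seed: int | None = None) -> "DynamicStatesResults":
        """Run windowing, optional majority-rule k selection, and k-means.

        Deterministic given (data, config, seed).
        """
        cfg = self.config
        k = cfg.k if k is None else k
        seed = cfg.seed if seed is None else seed
        t0 = time.time()

        spec = cfg.window_spec()
        windowed = [sliding_window_fc(ts, spec) for ts in self.scans]
        per_condition: dict[str, int] = {}
        for w in windowed:
            per_condition[w.condition] = per_condition.get(w.condition, 0) + w.n_windows
        features = np.vstack([w.feature_matrix() for w in windowed])
        self._logline(
            "windows",
            scans=len(windowed),
            windows_per_condition=per_condition,
            windows_total=int(features.shape[0]),
        )

        k_report = None
        if k == "auto":
            k_report = _cluster.select_k_majority(
                features,
                k_range=tuple(cfg.k_range),
                index_set=tuple(cfg.index_set),
                seed=seed,
                n_init=cfg.selection_n_init,
            )
            k = k_report.chosen_k
            self._logline("select_k", chosen_k=k, votes=dict(k_report.votes))
        k = int(k)

        solution = _cluster.kmeans_states(
            features, k, seed=seed, n_init=cfg.n_init, max_iter=cfg.max_iter
        )
        self._logline("cluster", k=k, inertia=solution.inertia)

        scan_labels = []
        offset = 0
        for w in windowed:
            scan_labels.append(
                (w.subject_id, w.condition, solution.labels[offset : offset + w.n_windows])
            )
            offset += w.n_windows

        occ = _occupancy.occupancy_table(scan_labels, k)
        transitions = {
            (s, c): _occupancy.transition_counts(labels, k)
            for s, c, labels in scan_labels
            if len(labels) >= 2
        }
        self._logline("occupancy", rows=len(occ))
        self._logline("done", seconds=round(time.time() - t0, 2))
        return DynamicStatesResults(
            model=self,
            windowed=windowed,
            k_report=k_report,
            solution=solution,
            scan_labels=scan_labels,
            occupancy=occ,
            transitions=transitions,
            seed=seed,
        )


@dataclass
class DynamicStatesResults:
    """Fitted connectivity states with occupancy tables and diagnostics."""

    model: DynamicStatesModel
    windowed: list[WindowedFC]
    k_report: _cluster.KSelectionReport | None
    solution: _cluster.StateSolution
    scan_labels: list[tuple[str, str, np.ndarray]]
    occupancy: pd.DataFrame
    transitions: dict[tuple[str, str], tuple[np.ndarray, list[int]]]
    seed: int

    @property
    def k(self) -> int:
        return self.solution.k

    def test_interaction(
        self, family_size: int | None = None, contrast_pairs=None
    ) -> _occupancy.LmeResult:
        """Mixed-model condition x state interaction test on occupancy."""
        cfg = self.model.config
        return _occupancy.fit_occupancy_lme(
            self.occupancy,
            family_size=cfg.family_size if family_size is None else family_size,
            ci_level=cfg.ci_level,
            contrast_pairs=contrast_pairs,
        )

    def response_correlation(self, responses: dict[str, float], condition: str = "task"):
        return _occupancy.response_occupancy_correlation(responses, self.occupancy, condition)

    def match_with(self, other: "DynamicStatesResults") -> _cluster.StateMatching:
        """Optimal state-to-state matching against another fitted solution."""
        return _cluster.match_states(self.solution, other.solution)

    def occupancy_means(self) -> pd.DataFrame:
        """Mean fractional occupancy per condition x state."""
        return (
            self.occupancy.groupby(["condition", "state"])["proportion"]
            .mean()
            .unstack("state")
        )

    def summary(self, lme: _occupancy.LmeResult | None = None) -> str:
        """Human-readable report: design counts, states, occupancy, and the
        interaction test if requested (or already computed and passed in)."""
        lines = []
        lines.append("Dynamic connectivity-state model")
        lines.append("=" * 64)
        per_cond = {}
        for w in self.windowed:
            per_cond[w.condition] = per_cond.get(w.condition, 0) + w.n_windows
        lines.append(f"scans: {len(self.windowed)}   windows: {sum(per_cond.values())} {per_cond}")
        if self.k_report is not None:
            lines.append(
                f"majority-rule k: {self.k_report.chosen_k} (votes {dict(self.k_report.votes)})"
            )
        lines.append(
            f"states: k={self.k}, inertia={self.solution.inertia:.2f}, seed={self.seed}"
        )
        lines.append("")
        lines.append("mean occupancy (condition x state):")
        lines.append(self.occupancy_means().round(3).to_string())
        if lme is not None:
            lines.append("")
            lines.append(
                f"condition x state interaction: F({lme.df_num},{lme.df_den}) = "
                f"{lme.interaction_F:.4f}, p = {lme.interaction_p:.4f} [{lme.method}]"
            )
            lines.append(lme.summary_frame().round(4).to_string(index=False))
        return "\n".join(lines)

    # -- artifacts ---------------------------------------------------------

    def save(self, run_dir: str | Path, lme: _occupancy.LmeResult | None = None) -> Path:
        """Write the run directory: config, centroids, assignments, occupancy,
        transitions, statistical report and the structured stage log."""
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        cfg = self.model.config
        cfg.to_yaml(run_dir / "config.yaml")
        (run_dir / "config_hash.txt").write_text(cfg.config_hash() + "\n")

        for i, cm in enumerate(self.solution.centroid_matrices(), start=1):
            write_fc_matrix(cm, run_dir / f"centroid_state{i}.tsv")
        assign_rows = []
        for subject, condition, labels in self.scan_labels:
            for w_i, lab in enumerate(labels):
                assign_rows.append(
                    {"subject_id": subject, "condition": condition, "window": w_i, "state": int(lab)}
                )
        pd.DataFrame(assign_rows).to_csv(run_dir / "assignments.tsv", sep="\t", index=False)
        self.occupancy.to_csv(
            run_dir / "occupancy.tsv", sep="\t", index=False, float_format="%.10g"
        )
        trans_rows = []
        for (subject, condition), (counts, runs) in self.transitions.items():
            for i in range(self.k):
                for j in range(self.k):
                    trans_rows.append(
                        {
                            "subject_id": subject,
                            "condition": condition,
                            "from_state": i + 1,
                            "to_state": j + 1,
                            "count": int(counts[i, j]),
                        }
                    )
        pd.DataFrame(trans_rows).to_csv(run_dir / "transitions.tsv", sep="\t", index=False)

        report: dict = {
            "k": self.k,
            "seed": self.seed,
            "inertia": self.solution.inertia,
            "config_hash": cfg.config_hash(),
        }
        if self.k_report is not None:
            report["k_selection"] = {
                "chosen_k": self.k_report.chosen_k,
                "votes": {str(k): v for k, v in self.k_report.votes.items()},
                "per_index_choice": self.k_report.per_index_choice,
            }
        if lme is not None:
            report["interaction"] = {
                "F": lme.interaction_F,
                "df_num": lme.df_num,
                "df_den": lme.df_den,
                "p": lme.interaction_p,
                "method": lme.method,
            }
            report["contrasts"] = [
                {
                    "label": c.label,
                    "estimate": c.estimate,
                    "t": c.t,
                    "df": c.df,
                    "p_raw": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                    "cohen_d": c.cohen_d,
                    "ci": list(c.ci),
                    "ci_level": c.ci_level,
                }
                for c in lme.contrasts
            ]
        (run_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (run_dir / "run_log.jsonl").write_text(
            "\n".join(json.dumps(e) for e in self.model._log) + "\n"
        )
        return run_dir

    # -- plotting ----------------------------------------------------------

    def plot_states(self, path: str | Path | None = None):
        """Heatmaps of the k centroid z-matrices."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        mats = self.solution.centroid_matrices()
        names = self.model.scans[0].roi_set.roi_names
        fig, axes = plt.subplots(1, self.k, figsize=(3.2 * self.k, 3.2))
        axes = np.atleast_1d(axes)
        vmax = max(np.abs(m).max() for m in mats)
        for i, (ax, m) in enumerate(zip(axes, mats), start=1):
            im = ax.imshow(m, vmin=-vmax, vmax=vmax, cmap="RdBu_r")
            ax.set_title(f"state {i}")
            ax.set_xticks(range(len(names)))
            ax.set_xticklabels(names, rotation=90, fontsize=6)
            ax.set_yticks(range(len(names)))
            ax.set_yticklabels(names, fontsize=6)
        fig.colorbar(im, ax=axes.tolist(), shrink=0.7, label="Fisher z")
        if path:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return fig

    def plot_occupancy(self, path: str | Path | None = None):
        """Boxplots of fractional occupancy per state, grouped by condition."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        conditions = list(dict.fromkeys(self.occupancy["condition"]))
        fig, ax = plt.subplots(figsize=(2.0 * self.k, 4))
        width = 0.8 / len(conditions)
        for ci, cond in enumerate(conditions):
            sub = self.occupancy[self.occupancy["condition"] == cond]
            data = [
                sub[sub["state"] == s]["proportion"].to_numpy()
                for s in range(1, self.k + 1)
            ]
            pos = [s + (ci - (len(conditions) - 1) / 2) * width for s in range(1, self.k + 1)]
            ax.boxplot(data, positions=pos, widths=width * 0.9)
        ax.set_xticks(range(1, self.k + 1))
        ax.set_xticklabels([f"state {s}" for s in range(1, self.k + 1)])
        ax.set_ylabel("fractional occupancy")
        if path:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return fig


def run_pipeline(
    manifest_path: str | Path, out_dir: str | Path, config: RunConfig | None = None
) -> DynamicStatesResults:
    """End-to-end run from a cohort manifest to a report directory."""
    config = config or RunConfig()
    model = DynamicStatesModel.from_manifest(manifest_path, config)
    results = model.fit()
    lme = results.test_interaction()
    results.save(out_dir, lme=lme)
    return results


def compare_runs(a: DynamicStatesResults, b: DynamicStatesResults) -> pd.DataFrame:
    """State-matching report between two fitted solutions (equal k required)."""
    matching = a.match_with(b)
    rows = [
        {
            "state_a": sa,
            "state_b": matching.permutation[sa],
            "r": matching.per_pair_r[sa],
            "p": matching.per_pair_p[sa],
            "ci_low": matching.per_pair_ci[sa][0],
            "ci_high": matching.per_pair_ci[sa][1],
        }
        for sa in sorted(matching.permutation)
    ]
    return pd.DataFrame(rows)
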