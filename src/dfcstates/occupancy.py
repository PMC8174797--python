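"""Fractional occupancy, transitions, and condition-by-state statistics.

Fractional occupancy (time proportion) is the fraction of a scan's windows
assigned to each state; per scan the proportions over states sum to one.
Condition effects are tested with a linear mixed model: proportion as the
response, the full condition x state cell structure as fixed effects, and a
random intercept per subject-within-condition cell.  The interaction is
tested with a Wald F whose denominator degrees of freedom follow the
containment method, df = N - n_subjects - (p - 1); post hoc estimated
marginal mean (EMM) contrasts compare conditions within each state, with
Bonferroni adjustment and Cohen's d = EMM difference / residual SD.

A structural note on occupancy data: because each scan's proportions sum to
exactly one, the mean of every subject-condition group is exactly 1/k, so
the between-group variance of a random intercept on those groups is
identically zero and REML estimates sit on the boundary.  The fit therefore
detects (near-)zero random-effect variance and evaluates the Wald test on
the exact zero-variance limit (the fixed-effects fit with residual scale
RSS/(N - p)); with genuine between-group variance the REML mixed model is
used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .io import CONDITIONS

OCCUPANCY_COLUMNS = ["subject_id", "condition", "state", "proportion", "n_windows"]


@dataclass
class Contrast:
    label: str
    state: int
    estimate: float
    t: float
    df: float
    p_raw: float
    p_adjusted: float
    cohen_d: float
    ci: tuple[float, float]
    ci_level: float


@dataclass
class LmeResult:
    interaction_F: float
    df_num: int
    df_den: int
    interaction_p: float
    contrasts: list[Contrast]
    scale: float
    random_intercept_var: float
    method: str  # "reml" or "zero-variance-limit"

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "contrast": c.label,
                "state": c.state,
                "estimate": c.estimate,
                "t": c.t,
                "df": c.df,
                "p": c.p_raw,
                "p_bonferroni": c.p_adjusted,
                "cohen_d": c.cohen_d,
                "ci_low": c.ci[0],
                "ci_high": c.ci[1],
            }
            for c in self.contrasts
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# occupancy and transitions
# ---------------------------------------------------------------------------

def occupancy_table(
    scan_labels: list[tuple[str, str, np.ndarray]], k: int
) -> pd.DataFrame:
    """Fractional occupancy per (subject, condition, state).

    ``scan_labels`` holds one (subject_id, condition, window-label sequence)
    per scan, labels in 1..k.  States absent from a scan get proportion 0.
    """
    rows = []
    for subject_id, condition, labels in scan_labels:
        labels = np.asarray(labels, dtype=int)
        n = len(labels)
        if n == 0:
            raise ValueError(f"scan {subject_id}/{condition} has no labelled windows")
        if labels.min() < 1 or labels.max() > k:
            raise ValueError(f"labels outside 1..{k} in scan {subject_id}/{condition}")
        counts = np.bincount(labels, minlength=k + 1)[1:]
        for s in range(1, k + 1):
            rows.append(
                {
                    "subject_id": subject_id,
                    "condition": condition,
                    "state": s,
                    "proportion": counts[s - 1] / n,
                    "n_windows": n,
                }
            )
    return pd.DataFrame(rows, columns=OCCUPANCY_COLUMNS)


def transition_counts(labels: np.ndarray, k: int) -> tuple[np.ndarray, list[int]]:
    """k x k consecutive-pair transition counts (incl. self) and dwell-run lengths.

    counts[i-1, j-1] is the number of consecutive window pairs labelled
    (i -> j); dwell runs are the lengths of maximal constant-label stretches.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) < 2:
        raise ValueError("need at least 2 windows to count transitions")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (labels[:-1] - 1, labels[1:] - 1), 1)
    runs = []
    run = 1
    for a, b in zip(labels[:-1], labels[1:]):
        if a == b:
            run += 1
        else:
            runs.append(run)
            run = 1
    runs.append(run)
    return counts, runs


# ---------------------------------------------------------------------------
# mixed-model condition x state testing
# ---------------------------------------------------------------------------

def _cell_design(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]], pd.DataFrame]:
    """Cell-means design matrix (one column per condition x state cell)."""
    df = table.copy()
    conditions = [c for c in CONDITIONS if c in set(df["condition"])]
    extra = sorted(set(df["condition"]) - set(conditions))
    conditions += extra
    states = sorted(df["state"].unique())
    cells = [(c, s) for c in conditions for s in states]
    cell_index = {cs: i for i, cs in enumerate(cells)}
    x = np.zeros((len(df), len(cells)))
    for row_i, (c, s) in enumerate(zip(df["condition"], df["state"])):
        x[row_i, cell_index[(c, int(s))]] = 1.0
    counts = x.sum(axis=0)
    if np.any(counts == 0):
        empty = cells[int(np.argmin(counts))]
        raise ValueError(f"rank-deficient design: empty cell {empty}")
    return x, df["proportion"].to_numpy(dtype=float), cells, df


def fit_occupancy_lme(
    table: pd.DataFrame,
    family_size: int = 5,
    ci_level: float = 0.95,
    contrast_pairs: list[tuple[str, str]] | None = None,
) -> LmeResult:
    """Mixed-model test of the condition x state interaction on occupancy.

    Parameters
    ----------
    table
        OccupancyTable rows (subject_id, condition, state, proportion, ...).
        Unbalanced designs (missing subject-condition cells) are allowed.
    family_size
        Bonferroni multiplier applied to each contrast's raw p
        (p_adjusted = min(1, p_raw * family_size)).
    contrast_pairs
        Condition pairs to contrast within each state; default all pairs in
        condition order.
    """
    x, y, cells, df = _cell_design(table)
    conditions = list(dict.fromkeys(c for c, _ in cells))
    states = list(dict.fromkeys(s for _, s in cells))
    n_cond, n_state = len(conditions), len(states)
    if n_cond < 2 or n_state < 2:
        raise ValueError("need at least 2 conditions and 2 states")
    per_cond_subjects = df.groupby("condition")["subject_id"].nunique()
    if (per_cond_subjects < 2).any():
        bad = per_cond_subjects[per_cond_subjects < 2].index.tolist()
        raise ValueError(f"condition(s) with a single subject: {bad}")

    n_obs, p = x.shape
    n_subjects = df["subject_id"].nunique()
    df_den = n_obs - n_subjects - (p - 1)  # containment
    if df_den <= 0:
        raise ValueError("no residual degrees of freedom under containment")

    groups = (df["subject_id"].astype(str) + ":" + df["condition"].astype(str)).to_numpy()
    group_means = pd.Series(y).groupby(pd.Series(groups)).mean()
    degenerate = float(group_means.var(ddof=0)) < 1e-12

    method = "zero-variance-limit"
    re_var = 0.0
    if not degenerate:
        fit = None
        try:
            with warnings.catch_warnings():
                # boundary fits (true variance ~0) emit singular-covariance
                # and convergence warnings; they are resolved by the
                # zero-variance fallback below
                warnings.simplefilter("ignore")
                fit = sm.MixedLM(y, x, groups=groups).fit(reml=True)
            re_var = float(np.asarray(fit.cov_re).squeeze())
        except np.linalg.LinAlgError:
            re_var = 0.0
        if fit is not None and re_var / max(float(fit.scale), 1e-300) > 1e-8:
            method = "reml"
            beta = np.asarray(fit.fe_params, dtype=float)
            vbeta = np.asarray(fit.cov_params())[:p, :p]
            scale = float(fit.scale)
        else:
            re_var = 0.0
    if method == "zero-variance-limit":
        ols = sm.OLS(y, x).fit()
        beta = np.asarray(ols.params, dtype=float)
        vbeta = np.asarray(ols.cov_params())
        scale = float(ols.scale)  # RSS / (N - p): the exact zero-variance REML limit

    # interaction contrasts: mu_cs - mu_c0,s - mu_c,s0 + mu_c0,s0
    cell_index = {cs: i for i, cs in enumerate(cells)}
    q = (n_cond - 1) * (n_state - 1)
    L = np.zeros((q, p))
    r = 0
    c0, s0 = conditions[0], states[0]
    for c in conditions[1:]:
        for s in states[1:]:
            L[r, cell_index[(c, s)]] += 1
            L[r, cell_index[(c0, s)]] -= 1
            L[r, cell_index[(c, s0)]] -= 1
            L[r, cell_index[(c0, s0)]] += 1
            r += 1
    lb = L @ beta
    lvl = L @ vbeta @ L.T
    f_value = float(lb @ np.linalg.solve(lvl, lb)) / q
    p_inter = float(stats.f.sf(f_value, q, df_den))

    pairs = contrast_pairs or [
        (a, b) for i, a in enumerate(conditions) for b in conditions[i + 1 :]
    ]
    tcrit = stats.t.ppf(0.5 + ci_level / 2, df_den)
    contrasts = []
    for a, b in pairs:
        for s in states:
            lrow = np.zeros(p)
            lrow[cell_index[(a, s)]] = 1.0
            lrow[cell_index[(b, s)]] = -1.0
            est = float(lrow @ beta)
            se = float(np.sqrt(lrow @ vbeta @ lrow))
            tval = est / se
            praw = 2 * float(stats.t.sf(abs(tval), df_den))
            contrasts.append(
                Contrast(
                    label=f"state {s}: {a} - {b}",
                    state=int(s),
                    estimate=est,
                    t=tval,
                    df=df_den,
                    p_raw=praw,
                    p_adjusted=min(1.0, praw * family_size),
                    cohen_d=est / np.sqrt(scale),
                    ci=(est - tcrit * se, est + tcrit * se),
                    ci_level=ci_level,
                )
            )
    return LmeResult(
        interaction_F=f_value,
        df_num=q,
        df_den=int(df_den),
        interaction_p=p_inter,
        contrasts=contrasts,
        scale=scale,
        random_intercept_var=re_var,
        method=method,
    )


def response_occupancy_correlation(
    responses: dict[str, float], table: pd.DataFrame, condition: str = "task"
) -> pd.DataFrame:
    """Pearson correlation between per-subject response counts and occupancy.

    Returns one row per state with r and the two-sided p across subjects
    having both measures in the given condition.
    """
    sub = table[table["condition"] == condition]
    subjects = sorted(set(sub["subject_id"]) & set(responses))
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects with both measures")
    resp = np.array([responses[s] for s in subjects], dtype=float)
    if np.ptp(resp) == 0:
        raise ValueError("responses are constant across subjects")
    rows = []
    for s in sorted(sub["state"].unique()):
        occ = (
            sub[sub["state"] == s]
            .set_index("subject_id")["proportion"]
            .reindex(subjects)
            .to_numpy(dtype=float)
        )
        res = stats.pearsonr(resp, occ)
        rows.append({"state": int(s), "r": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows)
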