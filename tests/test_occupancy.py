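"""Fractional occupancy, transitions, the mixed-model test, and behaviour correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dfcstates as d
from dfcstates.simulate import (
    DEFAULT_OCCUPANCY_PROFILES,
    sample_gaussian_occupancy,
    sample_occupancy_counts,
)

STUDY_WINDOWS = {"pre_rest": 39, "task": 79, "post_rest": 39}
MISSING = {("sub-15", "post_rest")}


class TestOccupancyTable:
    def test_direct_counts(self):
        tab = d.occupancy_table([("s1", "task", np.array([3, 3, 3, 1, 2]))], k=5)
        by_state = tab.set_index("state")["proportion"]
        assert by_state[3] == pytest.approx(0.6)
        assert by_state[1] == pytest.approx(0.2)
        assert by_state[4] == 0.0 and by_state[5] == 0.0
        assert (tab["n_windows"] == 5).all()

    def test_single_state_scan(self):
        tab = d.occupancy_table([("s1", "pre_rest", np.full(39, 2))], k=5)
        props = tab.set_index("state")["proportion"]
        assert props[2] == 1.0 and props.drop(2).eq(0).all()

    def test_proportions_sum_to_one_and_counts_integral(self):
        rng = np.random.default_rng(0)
        scans = [
            ("s1", "pre_rest", rng.integers(1, 6, 39)),
            ("s1", "task", rng.integers(1, 6, 79)),
        ]
        tab = d.occupancy_table(scans, 5)
        sums = tab.groupby(["subject_id", "condition"])["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)
        counts = tab["proportion"] * tab["n_windows"]
        assert np.allclose(counts, np.round(counts))

    def test_law_of_large_numbers(self):
        rng = np.random.default_rng(1)
        probs = np.array([0.1, 0.2, 0.4, 0.25, 0.05])
        labels = rng.choice(np.arange(1, 6), size=10_000, p=probs)
        tab = d.occupancy_table([("s", "task", labels)], 5)
        est = tab.sort_values("state")["proportion"].to_numpy()
        assert np.abs(est - probs).max() < 0.02

    def test_invariant_under_state_permutation(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(1, 6, 100)
        perm = np.array([0, 3, 1, 4, 5, 2])  # 1->3, 2->1, 3->4, 4->5, 5->2
        tab_a = d.occupancy_table([("s", "task", labels)], 5)
        tab_b = d.occupancy_table([("s", "task", perm[labels])], 5)
        for s in range(1, 6):
            assert (
                tab_a.set_index("state")["proportion"][s]
                == tab_b.set_index("state")["proportion"][perm[s]]
            )


class TestTransitions:
    def test_enumerable_example(self):
        counts, runs = d.transition_counts(np.array([1, 1, 2]), k=3)
        assert counts[0, 0] == 1 and counts[0, 1] == 1
        assert counts.sum() == 2
        assert runs == [2, 1]

    def test_constant_sequence_only_self_transitions(self):
        counts, runs = d.transition_counts(np.full(25, 4), k=5)
        assert counts[3, 3] == 24 and counts.sum() == 24
        assert runs == [25]

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(1, 6, 500)
        counts, runs = d.transition_counts(labels, 5)
        brute = np.zeros((5, 5), dtype=int)
        for a, b in zip(labels[:-1], labels[1:]):
            brute[a - 1, b - 1] += 1
        np.testing.assert_array_equal(counts, brute)
        assert counts.sum() == len(labels) - 1
        assert sum(runs) == len(labels)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            d.transition_counts(np.array([1]), 5)


def _balanced_table(rng, n_sub=12, effects=None, noise=0.03, center_groups=False):
    rows = []
    effects = effects or {}
    for c in ("pre_rest", "task"):
        for i in range(n_sub):
            e = rng.normal(0, noise, 5)
            if center_groups:
                e -= e.mean()
            for s in range(1, 6):
                rows.append(
                    {
                        "subject_id": f"sub-{i + 1:02d}",
                        "condition": c,
                        "state": s,
                        "proportion": 0.2 + effects.get((c, s), 0.0) + e[s - 1],
                        "n_windows": 39,
                    }
                )
    return pd.DataFrame(rows)


class TestOccupancyLme:
    def test_containment_df_matches_design_arithmetic(self):
        rng = np.random.default_rng(4)
        sl = sample_occupancy_counts(
            {c: np.array(DEFAULT_OCCUPANCY_PROFILES[c]) for c in STUDY_WINDOWS},
            STUDY_WINDOWS,
            15,
            rng,
            MISSING,
        )
        res = d.fit_occupancy_lme(d.occupancy_table(sl, 5))
        # 220 observations, 15 subjects, 15 cell-mean parameters
        assert res.df_num == 8
        assert res.df_den == 220 - 15 - 14

    def test_fixed_effects_limit_reproduces_two_way_anova(self):
        # residuals centred within each scan force the random-intercept
        # variance to the boundary; the Wald F must then equal the ordinary
        # two-way interaction F
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(5)
        tab = _balanced_table(rng, center_groups=True)
        res = d.fit_occupancy_lme(tab)
        assert res.method == "zero-variance-limit"
        ols = smf.ols(
            "proportion ~ C(condition) * C(state)", data=tab.assign(state=tab.state.astype(str))
        ).fit()
        f_anova = anova_lm(ols, typ=2).loc["C(condition):C(state)", "F"]
        assert res.interaction_F == pytest.approx(f_anova, rel=1e-6)

    def test_reml_path_engages_with_real_scan_variance(self):
        rng = np.random.default_rng(6)
        tab = sample_gaussian_occupancy(
            {c: np.full(5, 0.2) for c in ("pre_rest", "task")},
            noise_sd=0.04,
            n_subjects=12,
            rng=rng,
            scan_intercept_sd=0.06,
        )
        res = d.fit_occupancy_lme(tab)
        assert res.method == "reml"
        assert res.random_intercept_var > 0

    def test_emm_estimates_invariant_under_balanced_duplication(self):
        rng = np.random.default_rng(7)
        tab = _balanced_table(rng)
        doubled = pd.concat(
            [tab, tab.assign(subject_id=tab.subject_id + "_copy")], ignore_index=True
        )
        res_a = d.fit_occupancy_lme(tab)
        res_b = d.fit_occupancy_lme(doubled)
        for ca, cb in zip(res_a.contrasts, res_b.contrasts):
            assert ca.estimate == pytest.approx(cb.estimate, abs=1e-10)

    def test_bonferroni_adjustment(self):
        rng = np.random.default_rng(8)
        res = d.fit_occupancy_lme(_balanced_table(rng), family_size=5)
        for c in res.contrasts:
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 5))

    def test_single_subject_condition_rejected(self):
        rng = np.random.default_rng(9)
        tab = _balanced_table(rng)
        tab = tab[(tab.condition != "task") | (tab.subject_id == "sub-01")]
        with pytest.raises(ValueError, match="single subject"):
            d.fit_occupancy_lme(tab)

    def test_empty_cell_named_in_error(self):
        rng = np.random.default_rng(10)
        tab = _balanced_table(rng)
        tab = tab[(tab.condition != "task") | (tab.state != 3)]
        with pytest.raises(ValueError, match="task"):
            d.fit_occupancy_lme(tab)

    def test_type_one_error_calibrated_under_model_null(self):
        # zero condition effect, iid noise: rejection rate near nominal 5%
        rng = np.random.default_rng(11)
        profiles = {c: np.full(5, 0.2) for c in STUDY_WINDOWS}
        rej = 0
        n_rep = 200
        for _ in range(n_rep):
            tab = sample_gaussian_occupancy(
                profiles, 0.05, 15, rng, MISSING, scan_intercept_sd=0.0
            )
            rej += d.fit_occupancy_lme(tab).interaction_p < 0.05
        assert 0.01 <= rej / n_rep <= 0.10

    def test_compositional_null_is_anticonservative(self):
        # the sum-to-one constraint induces negative within-scan correlation
        # the random intercept cannot absorb; the F test inflates by about
        # (1 - 1/k)^-1 — a documented limitation of the model on pure
        # sampling noise
        rng = np.random.default_rng(12)
        profiles = {c: np.array(DEFAULT_OCCUPANCY_PROFILES["pre_rest"]) for c in STUDY_WINDOWS}
        rej = 0
        n_rep = 300
        for _ in range(n_rep):
            sl = sample_occupancy_counts(profiles, STUDY_WINDOWS, 15, rng, MISSING)
            rej += d.fit_occupancy_lme(d.occupancy_table(sl, 5)).interaction_p < 0.05
        assert 0.07 <= rej / n_rep <= 0.25


class TestResponseCorrelation:
    def test_perfect_linear_relation(self):
        rng = np.random.default_rng(13)
        sl = sample_occupancy_counts(
            {"task": np.array(DEFAULT_OCCUPANCY_PROFILES["task"])},
            {"task": 79},
            10,
            rng,
        )
        tab = d.occupancy_table(sl, 5)
        occ3 = tab[(tab.state == 3)].set_index("subject_id")["proportion"]
        responses = {s: 100 * v for s, v in occ3.items()}
        out = d.response_occupancy_correlation(responses, tab, "task")
        assert out.set_index("state")["r"][3] == pytest.approx(1.0)

    def test_p_matches_t_distribution_formula(self):
        rng = np.random.default_rng(14)
        sl = sample_occupancy_counts(
            {"task": np.full(5, 0.2)}, {"task": 79}, 15, rng
        )
        tab = d.occupancy_table(sl, 5)
        responses = {f"sub-{i + 1:02d}": float(rng.normal(20, 8)) for i in range(15)}
        out = d.response_occupancy_correlation(responses, tab, "task")
        n = 15
        for _, row in out.iterrows():
            r = row["r"]
            t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert row["p"] == pytest.approx(p, rel=1e-9)

    def test_constant_responses_rejected(self):
        rng = np.random.default_rng(15)
        sl = sample_occupancy_counts({"task": np.full(5, 0.2)}, {"task": 79}, 5, rng)
        tab = d.occupancy_table(sl, 5)
        with pytest.raises(ValueError, match="constant"):
            d.response_occupancy_correlation(
                {f"sub-{i + 1:02d}": 3.0 for i in range(5)}, tab, "task"
            )

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(16)
        sl = sample_occupancy_counts({"task": np.full(5, 0.2)}, {"task": 79}, 5, rng)
        tab = d.occupancy_table(sl, 5)
        with pytest.raises(ValueError, match="3 subjects"):
            d.response_occupancy_correlation({"sub-01": 1.0, "sub-02": 2.0}, tab, "task")
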