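"""SRT statistics: medians, mixed ANOVA, GG epsilon, trends, Bayes factors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from milotask.analysis import (
    bic_bayes_factor,
    classify_evidence,
    compute_srt,
    gg_epsilon,
    median_curves,
    mixed_anova,
    polynomial_trends,
    posterior_prob,
    variability_summary,
)
from milotask.engine import run_trial

from conftest import build_spec
from test_engine import events_for


class TestComputeSrt:
    def test_srt_arithmetic(self, rng):
        spec = build_spec(rng, n=3)
        evs = events_for(spec, start=1200, gap=500)
        res = run_trial(spec, evs)
        srt = compute_srt(res).srt
        assert srt[0] == evs[0].t_ms
        assert srt[1] == evs[1].t_ms - evs[0].t_ms
        assert srt[2] == evs[2].t_ms - evs[1].t_ms

    def test_srts_telescope_to_total(self, rng):
        spec = build_spec(rng)
        res = run_trial(spec, events_for(spec))
        assert sum(compute_srt(res).srt) == res.total_ms

    def test_error_trial_yields_short_series(self, rng):
        spec = build_spec(rng)
        order = list(spec.required_order())
        res = run_trial(spec, events_for(spec, order=order[:2] + [order[5]]))
        assert res.status == "error"
        assert len(compute_srt(res).srt) == 2

    def test_preview_onset_shifts_t1(self, rng):
        spec = build_spec(rng, preview_ms=2000)
        evs = events_for(spec, start=900)
        res = run_trial(spec, evs)
        assert compute_srt(res).srt[0] == 900


def tidy_frame(values):
    """values[participant][condition][target] -> tidy rows, one per trial obs."""
    rows = []
    for pid, conds in values.items():
        for cond, obs in conds.items():
            for tgt, vals in obs.items():
                for i, v in enumerate(vals):
                    rows.append(
                        {
                            "participant": pid,
                            "condition": cond,
                            "target_index": tgt,
                            "trial": i,
                            "srt_ms": v,
                        }
                    )
    return pd.DataFrame(rows)


class TestMedianCurves:
    def test_outlier_robust_cell(self):
        df = tidy_frame({"P1": {"vanish": {1: [300, 400, 10000]}}})
        med, _ = median_curves(df)
        assert med["median_srt_ms"].iloc[0] == 400

    def test_even_count_averages_central_pair(self):
        df = tidy_frame({"P1": {"vanish": {1: [100, 200, 300, 400]}}})
        med, _ = median_curves(df)
        assert med["median_srt_ms"].iloc[0] == 250

    def test_matches_sort_based_oracle(self, rng):
        cells = {
            f"P{i}": {
                c: {t: list(rng.integers(100, 2000, rng.integers(1, 9)))
                    for t in range(1, 9)}
                for c in ("vanish", "remain")
            }
            for i in range(4)
        }
        med, _ = median_curves(tidy_frame(cells))
        for _, row in med.iterrows():
            vals = sorted(cells[row.participant][row.condition][row.target_index])
            k = len(vals)
            oracle = (
                vals[k // 2] if k % 2 else (vals[k // 2 - 1] + vals[k // 2]) / 2
            )
            assert row["median_srt_ms"] == oracle

    def test_summary_collapses_participants(self):
        df = tidy_frame(
            {
                "P1": {"vanish": {1: [100], 2: [200]}},
                "P2": {"vanish": {1: [300], 2: [400]}},
            }
        )
        _, summary = median_curves(df)
        row = summary[summary.target_index == 1].iloc[0]
        assert row["mean"] == 200 and row["n"] == 2


class TestGGEpsilon:
    def test_compound_symmetry_gives_one(self):
        k, rho = 6, 0.4
        cov = (1 - rho) * np.eye(k) + rho * np.ones((k, k))
        assert gg_epsilon(cov) == pytest.approx(1.0)

    @given(st.integers(3, 8), st.integers(0, 5000))
    def test_bounds_for_random_psd_matrices(self, k, seed):
        r = np.random.default_rng(seed)
        a = r.standard_normal((k, k + 2))
        cov = a @ a.T
        eps = gg_epsilon(cov)
        assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    @given(st.integers(3, 8), st.integers(0, 5000))
    def test_agrees_with_double_centring_formula(self, k, seed):
        # textbook Box epsilon: double-centre S, then tr(S*)^2/((k-1) sum s*_ij^2)
        r = np.random.default_rng(seed)
        a = r.standard_normal((k, k + 3))
        cov = a @ a.T
        j = np.eye(k) - np.ones((k, k)) / k
        s = j @ cov @ j
        oracle = np.trace(s) ** 2 / ((k - 1) * (s * s).sum())
        assert gg_epsilon(cov) == pytest.approx(oracle, abs=1e-10)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            gg_epsilon(np.ones((3, 4)))


def simulated_median_table(rng, n_per_group=6, targets=8, effect=0.0, offset=0.0):
    """Participant-level median SRT table straight from the latency model."""
    profile = np.full(targets, 450.0)
    profile[0] = 1100.0
    rows = []
    for g, seq in enumerate(["digit", "letter"]):
        for s in range(n_per_group):
            pid = f"{seq}-{s}"
            speed = np.exp(0.05 * rng.standard_normal())
            for ci, cond in enumerate(["vanish", "remain"]):
                for t in range(targets):
                    mu = (profile[t] + effect * t + (offset if ci else 0.0)) * speed
                    draws = mu * np.exp(0.15 * rng.standard_normal(20))
                    rows.append(
                        {
                            "participant": pid,
                            "sequence_type": seq,
                            "condition": cond,
                            "target_index": t + 1,
                            "median_srt_ms": np.median(draws),
                        }
                    )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_injected_target_effect_detected(self, rng):
        data = simulated_median_table(rng, n_per_group=12, effect=50.0)
        tab = mixed_anova(data, dv="median_srt_ms").set_index("effect")
        assert tab.loc["target_index", "p"] < 0.001

    def test_two_level_within_gets_no_epsilon(self, rng):
        data = simulated_median_table(rng)
        tab = mixed_anova(data, dv="median_srt_ms").set_index("effect")
        assert np.isnan(tab.loc["condition", "gg_epsilon"])
        assert 1 / 7 <= tab.loc["target_index", "gg_epsilon"] <= 1

    def test_unbalanced_data_rejected(self, rng):
        data = simulated_median_table(rng)
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(data.iloc[:-1], dv="median_srt_ms")

    def test_matches_pingouin_on_one_between_one_within(self, rng):
        pg = pytest.importorskip("pingouin")
        data = simulated_median_table(rng, n_per_group=8)
        t1 = data[data.target_index == 1]
        ours = mixed_anova(
            t1, dv="median_srt_ms", within=("condition",), between="sequence_type"
        ).set_index("effect")
        theirs = pg.mixed_anova(
            t1.assign(median_srt_s=t1.median_srt_ms / 1000),
            dv="median_srt_s",
            within="condition",
            between="sequence_type",
            subject="participant",
        ).set_index("Source")
        assert ours.loc["condition", "F"] == pytest.approx(
            theirs.loc["condition", "F"], rel=1e-8
        )
        assert ours.loc["sequence_type", "F"] == pytest.approx(
            theirs.loc["sequence_type", "F"], rel=1e-8
        )
        assert ours.loc["sequence_type * condition", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-8
        )

    def test_matches_anova_rm_on_two_within(self, rng):
        from statsmodels.stats.anova import AnovaRM

        data = simulated_median_table(rng, n_per_group=5)
        ours = mixed_anova(
            data, dv="median_srt_ms", within=("condition", "target_index"),
            between=None,
        ).set_index("effect")
        res = AnovaRM(
            data, depvar="median_srt_ms", subject="participant",
            within=["condition", "target_index"],
        ).fit().anova_table
        assert ours.loc["condition", "F"] == pytest.approx(
            res.loc["condition", "F Value"], rel=1e-8
        )
        assert ours.loc["target_index", "F"] == pytest.approx(
            res.loc["target_index", "F Value"], rel=1e-8
        )
        assert ours.loc["condition * target_index", "F"] == pytest.approx(
            res.loc["condition:target_index", "F Value"], rel=1e-8
        )

    def test_mse_reported_in_seconds_squared(self, rng):
        # ms inputs are rescaled so error mean squares land on the s^2 scale
        data = simulated_median_table(rng, n_per_group=12)
        tab = mixed_anova(data, dv="median_srt_ms").set_index("effect")
        assert 1e-4 < tab.loc["condition", "MSE"] < 1.0


class TestPolynomialTrends:
    def test_linear_means_kill_higher_orders(self):
        m = np.tile(np.arange(8.0), (6, 1)) * 10 + 100
        tab = polynomial_trends(m).set_index("trend")
        assert tab.loc["quadratic", "F"] == 0
        assert tab.loc["cubic", "F"] == 0

    def test_symmetric_u_shape_is_pure_quadratic(self):
        x = np.arange(7.0) - 3
        m = np.tile(x**2, (6, 1)) + np.random.default_rng(0).normal(0, 1e-9, (6, 7))
        tab = polynomial_trends(m).set_index("trend")
        assert tab.loc["linear", "F"] < 1e-6
        assert tab.loc["quadratic", "F"] > 1e6

    def test_default_srt_profile_has_all_three_trends(self, rng):
        # T2-T8 means of the default virtual participant across a cohort
        from milotask.simulate import DEFAULT_SRT_PROFILE

        prof = np.array(DEFAULT_SRT_PROFILE)
        m = prof * np.exp(0.05 * rng.standard_normal((24, 7)))
        tab = polynomial_trends(m).set_index("trend")
        assert (tab["p"] < 0.01).all()

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            polynomial_trends(np.ones((5, 3)), max_order=3)


class TestBayes:
    def test_zero_f_is_pure_complexity_penalty(self):
        br = bic_bayes_factor(0.0, 1, 22, 24)
        assert br.bf01 == pytest.approx(24**0.5)

    def test_reciprocal_identity_and_posteriors(self):
        br = bic_bayes_factor(3.7, 2, 40, 20)
        assert br.bf10 * br.bf01 == pytest.approx(1.0)
        assert br.posterior_h0 + br.posterior_h1 == pytest.approx(1.0)
        assert br.posterior_h1 == pytest.approx(br.bf10 / (1 + br.bf10))

    @pytest.mark.parametrize(
        "F,printed_bf10",
        [(6.8, 5.0), (10.4, 21.1)],
    )
    def test_printed_condition_effects_recovered(self, F, printed_bf10):
        # from rounded printed F values; agreement only to ~10%
        br = bic_bayes_factor(F, 1, 22, 24)
        assert br.bf10 == pytest.approx(printed_bf10, rel=0.10)

    def test_posterior_transform_values(self):
        assert posterior_prob(1.0) == 0.5
        assert posterior_prob(3.0) == 0.75
        assert posterior_prob(100.0) > 0.99

    @given(st.floats(0.01, 100.0))
    def test_posterior_symmetry_and_monotonicity(self, bf):
        assert posterior_prob(bf) + posterior_prob(1 / bf) == pytest.approx(1.0)
        assert posterior_prob(bf * 1.1) > posterior_prob(bf)

    def test_posterior_requires_positive_bf(self):
        with pytest.raises(ValueError):
            posterior_prob(0.0)

    @pytest.mark.parametrize(
        "bf,posterior,label",
        [
            (2.1, 0.67, "weak"),
            (21.1, None, "substantial"),
            (3.0, None, "substantial"),  # boundary is strict
            (2.9, 0.76, "substantial"),  # both conditions must hold
        ],
    )
    def test_evidence_classification(self, bf, posterior, label):
        assert classify_evidence(bf, posterior) == label


class TestVariability:
    def make_table(self, rng, n_trials=10):
        rows = []
        for pid in ("P1", "P2"):
            for cond in ("vanish", "remain"):
                for tr in range(n_trials):
                    for tgt in range(1, 9):
                        rows.append(
                            {
                                "participant": pid,
                                "condition": cond,
                                "trial": tr,
                                "target_index": tgt,
                                "srt_ms": float(rng.integers(200, 1500)),
                            }
                        )
        return pd.DataFrame(rows)

    def test_constant_srts_have_zero_sd(self):
        df = pd.DataFrame(
            {
                "participant": ["P1"] * 4,
                "condition": ["vanish"] * 4,
                "target_index": [1, 2, 1, 2],
                "srt_ms": [500.0, 300.0, 500.0, 300.0],
            }
        )
        out = variability_summary(df)
        assert out.t1_sd.iloc[0] == 0 and out.later_sd.iloc[0] == 0

    def test_scale_equivariance(self, rng):
        df = self.make_table(rng)
        a = variability_summary(df)
        b = variability_summary(df.assign(srt_ms=df.srt_ms * 2))
        assert np.allclose(b.t1_sd, 2 * a.t1_sd)
        assert np.allclose(b.later_iqr, 2 * a.later_iqr)

    def test_matches_two_pass_sd_oracle(self, rng):
        df = self.make_table(rng)
        out = variability_summary(df).set_index(["participant", "condition"])
        for (pid, cond), grp in df.groupby(["participant", "condition"]):
            v = grp.loc[grp.target_index == 1, "srt_ms"].to_numpy()
            mean = v.sum() / len(v)
            oracle = np.sqrt(((v - mean) ** 2).sum() / (len(v) - 1))
            assert out.loc[(pid, cond), "t1_sd"] == pytest.approx(oracle)

    def test_single_trial_flagged_missing(self):
        df = pd.DataFrame(
            {
                "participant": ["P1"],
                "condition": ["vanish"],
                "target_index": [1],
                "srt_ms": [500.0],
            }
        )
        out = variability_summary(df)
        assert np.isnan(out.t1_sd.iloc[0])
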