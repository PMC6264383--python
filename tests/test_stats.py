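"""Group statistics: aggregation, t/ANOVA/Bayes, physio correlations, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gradnf import (
    aggregate_median_psc,
    cohens_d_from_t,
    derive_prior_scale,
    fdr_adjust,
    informed_bayes_t,
    one_sample_t,
    paired_t,
    physio_task_analysis,
    rm_anova_2x2,
    run_difference_trend,
)
from gradnf.errors import AggregationError, DegenerateDataError, DesignError
from gradnf.glm import PscEstimate
from gradnf.simulate import simulate_physio


def make_psc_rows(values):
    """Rows from dict {(subject, region, condition, level): [per-run psc]}."""
    rows = []
    for (subject, region, condition, level), pscs in values.items():
        for i, psc in enumerate(pscs):
            rows.append(
                PscEstimate(region=region, condition=condition, level=level,
                            psc=psc, run_id=f"r{i}", subject=subject)
            )
    return rows


class TestAggregation:
    def test_median_is_robust_to_outlier_run(self):
        rows = {}
        for subject, pscs in (("s1", [1, 2, 3, 4, 100]), ("s2", [5])):
            for region in ("SMA", "M1"):
                for condition in ("active", "passive"):
                    for level in ("low", "high"):
                        rows[(subject, region, condition, level)] = pscs
        table = aggregate_median_psc(make_psc_rows(rows))
        assert (table.loc[table.subject == "s1", "median_psc"] == 3).all()
        assert (table.loc[table.subject == "s2", "median_psc"] == 5).all()

    def test_balanced_cohort_row_count(self, mini_cohort):
        from gradnf.pipeline import analyze_cohort

        psc, _, _ = analyze_cohort(mini_cohort)
        table = aggregate_median_psc(psc)
        assert len(table) == 3 * 2 * 2 * 2

    def test_missing_cell_rejected(self):
        rows = make_psc_rows({("s1", "SMA", "active", "low"): [1.0]})
        with pytest.raises(AggregationError, match="missing cell"):
            aggregate_median_psc(rows)


class TestPairedT:
    def test_one_sided_p_at_printed_t(self, rng):
        """Data constructed to give t = -2.196 yields one-sided p ~ 0.022."""
        n = 17
        base = rng.standard_normal(n)
        x = base - base.mean()  # mean 0
        # scale so that t = mean/sem hits the target after shifting
        x = x / (x.std(ddof=1) / np.sqrt(n))  # now sem = 1
        shift = -2.196
        res = one_sample_t(x + shift, side="less")
        assert res.t == pytest.approx(-2.196, abs=1e-9)
        assert res.df == 16
        assert res.p == pytest.approx(0.022, abs=5e-4)

    def test_d_equals_t_over_sqrt_n(self, rng):
        x, y = rng.standard_normal(17), rng.standard_normal(17)
        res = paired_t(x, y, side="two")
        assert res.d == pytest.approx(res.t / np.sqrt(17), abs=1e-12)

    def test_agrees_with_scipy(self, rng):
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        res = paired_t(x, y, side="two")
        ref = sps.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_constant_shift_degenerate(self):
        x = np.arange(10, dtype=float)
        with pytest.raises(DegenerateDataError):
            paired_t(x + 1.0, x, side="greater")


class TestCohensD:
    @pytest.mark.parametrize(
        "t, n, expected",
        [(-2.196, 17, -0.533), (3.006, 17, 0.729), (-3.552, 17, -0.862), (0.0, 17, 0.0)],
    )
    def test_printed_values(self, t, n, expected):
        assert cohens_d_from_t(t, n) == pytest.approx(expected, abs=1e-3)


class TestRmAnova:
    @staticmethod
    def table_from_cells(cells, n=10, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n):
            subj_off = rng.normal(0, 1) if noise else 0.0
            for (condition, level), mu in cells.items():
                rows.append(
                    {"subject": f"s{s}", "region": "SMA", "condition": condition,
                     "level": level,
                     "median_psc": mu + subj_off + (rng.normal(0, noise) if noise else 0)}
                )
        return pd.DataFrame(rows)

    def test_additive_noiseless_interaction_zero(self):
        cells = {("active", "low"): 0.1, ("active", "high"): 0.3,
                 ("passive", "low"): 0.2, ("passive", "high"): 0.4}
        exact = self.table_from_cells(cells, noise=0.0)
        effects = {e.effect: e for e in rm_anova_2x2(exact, "SMA")}
        assert effects["interaction"].F == 0.0
        # the additive level/condition effects are real and noiseless
        assert np.isinf(effects["level"].F)

    def test_level_F_equals_paired_t_squared(self):
        rng = np.random.default_rng(3)
        cells = {("active", "low"): 0.1, ("active", "high"): 0.3,
                 ("passive", "low"): 0.15, ("passive", "high"): 0.35}
        table = self.table_from_cells(cells, noise=0.2, seed=3)
        effects = {e.effect: e for e in rm_anova_2x2(table, "SMA")}
        wide = table.pivot_table(index="subject", columns=["condition", "level"],
                                 values="median_psc")
        high = wide[[("active", "high"), ("passive", "high")]].mean(axis=1)
        low = wide[[("active", "low"), ("passive", "low")]].mean(axis=1)
        t = paired_t(high.to_numpy(), low.to_numpy(), side="two")
        assert effects["level"].F == pytest.approx(t.t**2, abs=1e-8)
        assert effects["level"].p == pytest.approx(t.p, abs=1e-10)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        table = self.table_from_cells(
            {("active", "low"): 0.1, ("active", "high"): 0.35,
             ("passive", "low"): 0.2, ("passive", "high"): 0.3},
            n=14, noise=0.25, seed=7,
        )
        ours = {e.effect: e for e in rm_anova_2x2(table, "SMA")}
        ref = pingouin.rm_anova(
            data=table, dv="median_psc", within=["level", "condition"],
            subject="subject", detailed=True,
        )
        ref_f = dict(zip(ref["Source"], ref["F"]))
        assert ours["level"].F == pytest.approx(ref_f["level"], rel=1e-6)
        assert ours["condition"].F == pytest.approx(ref_f["condition"], rel=1e-6)
        assert ours["interaction"].F == pytest.approx(ref_f["level * condition"], rel=1e-6)

    def test_unbalanced_rejected(self):
        table = self.table_from_cells(
            {("active", "low"): 0.1, ("active", "high"): 0.3,
             ("passive", "low"): 0.2, ("passive", "high"): 0.4},
            n=5, noise=0.1,
        )
        with pytest.raises(DesignError):
            rm_anova_2x2(table.iloc[:-1], "SMA")


class TestRunTrend:
    @staticmethod
    def rows_with_diffs(diffs_by_run, n_subjects=8, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subjects):
            for r, diff in enumerate(diffs_by_run):
                eps = rng.normal(0, noise) if noise else 0.0
                low = 0.2 + rng.normal(0, noise)
                rows.append(PscEstimate("SMA", "active", "low", low, f"r{r}", f"s{s}"))
                rows.append(
                    PscEstimate("SMA", "active", "high", low + diff + eps, f"r{r}", f"s{s}")
                )
        return rows

    def test_constant_differences_give_zero_F(self):
        rows = self.rows_with_diffs([0.1] * 5, noise=0.0)
        res = run_difference_trend(rows, "SMA")
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.df_num == 4

    def test_F_grows_with_trend_amplitude(self):
        f_values = []
        for amp in (0.0, 0.1, 0.3):
            diffs = [0.1 + amp * r for r in range(5)]
            res = run_difference_trend(self.rows_with_diffs(diffs, noise=0.05, seed=5), "SMA")
            f_values.append(res.F)
        assert f_values[0] < f_values[1] < f_values[2]


class TestInformedBayes:
    def test_bf_increases_in_t_for_directed_positive(self):
        bfs = [informed_bayes_t(t, 17, 0.55, "greater").bf for t in (-1, 0, 1, 2, 3)]
        assert all(b < a for b, a in zip(bfs, bfs[1:]))

    def test_bf_at_zero_t_below_one(self):
        assert informed_bayes_t(0.0, 17, 0.55, "greater").bf < 1
        assert informed_bayes_t(0.0, 17, 1.11, "less").bf < 1

    def test_small_prior_scale_collapses_to_null(self):
        assert informed_bayes_t(2.5, 17, 1e-4, "greater").bf == pytest.approx(1.0, abs=5e-3)

    def test_direction_symmetry(self):
        a = informed_bayes_t(2.3, 17, 0.8, "greater").bf
        b = informed_bayes_t(-2.3, 17, 0.8, "less").bf
        assert a == pytest.approx(b, rel=1e-9)

    @pytest.mark.parametrize("t, scale, side", [(3.006, 0.55, "greater"),
                                                (-3.552, 1.11, "less"),
                                                (-2.196, 1.11, "less"),
                                                (1.2, 0.4, "two")])
    def test_quadrature_matches_riemann_oracle(self, t, scale, side):
        """Adaptive quadrature agrees with a brute-force fine Riemann sum."""
        n = 17
        res = informed_bayes_t(t, n, scale, side)
        # oracle: fixed fine grid over the truncated prior support
        u = np.linspace(0, scale * 12, 200_001)
        du = u[1] - u[0]
        t_eff = -t if side == "less" else t
        like = sps.nct.pdf(t_eff, n - 1, u * np.sqrt(n))
        if side == "two":
            like = 0.5 * (like + sps.nct.pdf(t_eff, n - 1, -u * np.sqrt(n)))
        prior = 2.0 * sps.norm.pdf(u, 0, scale)
        bf_oracle = np.trapezoid(like * prior, dx=du) / sps.t.pdf(t_eff, n - 1)
        assert res.bf == pytest.approx(bf_oracle, rel=1e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DesignError):
            informed_bayes_t(1.0, 17, -0.5)
        with pytest.raises(DesignError):
            informed_bayes_t(1.0, 1, 0.5)


class TestPriorScale:
    @pytest.mark.parametrize(
        "psc, fraction, expected", [(1.48, 0.75, 1.11), (1.10, 0.50, 0.55), (0.8, 1.0, 0.8)]
    )
    def test_products(self, psc, fraction, expected):
        assert derive_prior_scale(psc, fraction) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(DesignError):
            derive_prior_scale(-1.0, 0.5)


class TestFdr:
    def test_largest_p_unchanged(self):
        adj = fdr_adjust([0.037, 0.207, 0.744, 0.077])
        assert adj.max() == pytest.approx(0.744)
        assert (adj >= np.array([0.037, 0.207, 0.744, 0.077])).all()

    def test_equal_ps_unchanged(self):
        assert fdr_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_step_up_arithmetic(self):
        # adjusted_i = min over j>=i of p_j * m / j = 0.04 for all four
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=8)
        perm = rng.permutation(8)
        assert fdr_adjust(p)[perm] == pytest.approx(fdr_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(DesignError):
            fdr_adjust([0.5, 1.2])


class TestPhysioAnalysis:
    def test_null_coupling_recovers_zero(self, nf_design, hrf):
        records = pd.DataFrame(
            [
                {
                    "subject": f"s{s}",
                    "region": "SMA",
                    "kind": "petco2",
                    "values": simulate_physio(nf_design, "petco2", 0.0, seed=1000 + s).values,
                }
                for s in range(60)
            ]
        )
        (res,) = physio_task_analysis(records, nf_design, hrf)
        se = res.z_sem
        assert abs(res.z_mean) < 3 * se
        assert res.p_fdr >= res.p

    def test_fisher_z_zero_fixed_point(self):
        assert np.arctanh(0.0) == 0.0

    def test_negative_coupling_negative_group_z(self, nf_design, hrf):
        records = pd.DataFrame(
            [
                {
                    "subject": f"s{s}",
                    "region": region,
                    "kind": "petco2",
                    "values": simulate_physio(
                        nf_design, "petco2", -1.0, seed=2000 + s
                    ).values,
                }
                for s in range(20)
                for region in ("SMA", "M1")
            ]
        )
        results = physio_task_analysis(records, nf_design, hrf)
        assert all(r.z_mean < 0 for r in results)

    def test_constant_trace_warns_and_skips(self, nf_design, hrf):
        records = pd.DataFrame(
            [
                {"subject": "s0", "region": "SMA", "kind": "petco2",
                 "values": np.full(180, 40.0)},
            ]
            + [
                {"subject": f"s{s}", "region": "SMA", "kind": "petco2",
                 "values": simulate_physio(nf_design, "petco2", 0.0, seed=s).values}
                for s in range(1, 6)
            ]
        )
        with pytest.warns(UserWarning, match="constant"):
            (res,) = physio_task_analysis(records, nf_design, hrf)
        assert res.n == 5  # constant-trace subject contributes no z


def test_bonferroni_adjustment_caps_at_one():
    from gradnf import bonferroni_adjust

    adj = bonferroni_adjust([0.01, 0.4, 0.9])
    assert adj == pytest.approx([0.03, 1.0, 1.0])
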