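import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dentage as d
from dentage.errors import (
    ConstantInput,
    CoverageError,
    LengthMismatch,
    PerfectExpectedAgreement,
    SubjectMismatch,
)
from dentage.tables import ConversionGrid, grid_ages


class TestBiasReport:
    def test_identity_pairs(self):
        ca = [6.5, 9.1, 12.0, 15.2]
        rep = d.bias_report(ca, ca, seed=0)
        assert rep.mean_diff == 0 and rep.median_abs_dev == 0
        assert rep.pct_within_1yr == 100.0 and rep.pct_beyond_2yr == 0.0
        assert rep.degenerate_variance

    def test_one_sample_t_closed_form(self):
        # diffs {1,2,3}: mean 2, sd 1, t = 2 / (1/sqrt(3)) = 3.464
        rep = d.bias_report([1.0, 2.0, 3.0], [0.0, 0.0, 0.0], seed=0)
        assert rep.t_statistic == pytest.approx(3.464, abs=5e-4)
        assert rep.ci95[0] < rep.mean_diff < rep.ci95[1]

    def test_degenerate_variance_histogram(self):
        rep = d.bias_report([1.0, 2.0, 3.0], [0.5, 1.5, 2.5], seed=0)
        assert rep.degenerate_variance and np.isnan(rep.p_one_sample)
        # all |diffs| = 0.5 land in the [0.5, 1.0) bin
        assert rep.abs_dev_histogram[-1] == (0.5, 1.0, 3)
        assert sum(c for _, _, c in rep.abs_dev_histogram) == rep.n

    def test_histogram_counts_sum_to_n(self):
        rng = np.random.default_rng(1)
        da = rng.normal(10, 2, 100)
        ca = rng.normal(10, 2, 100)
        rep = d.bias_report(da, ca, seed=1)
        assert sum(c for _, _, c in rep.abs_dev_histogram) == 100

    def test_bootstrap_brackets_analytic_ci(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(0.2, 1.0, 400)
        rep = d.bias_report(diffs, np.zeros(400), seed=11)
        lo_a, hi_a = rep.ci95
        lo_b, hi_b = rep.bootstrap_ci95
        # percentile bootstrap at 2000 resamples tracks the t interval
        assert abs(lo_b - lo_a) < 0.05 and abs(hi_b - hi_a) < 0.05

    def test_bootstrap_reproducible_under_seed(self):
        da, ca = [1.0, 2.2, 2.9, 4.5], [1.1, 2.0, 3.3, 4.0]
        r1 = d.bias_report(da, ca, seed=42)
        r2 = d.bias_report(da, ca, seed=42)
        assert r1.bootstrap_ci95 == r2.bootstrap_ci95

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatch):
            d.bias_report([1.0, 2.0], [1.0], seed=0)


class TestCorrelationReport:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        rep = d.correlation_report(x, 2 * x + 1)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.spearman_rho == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.arange(10.0)
        rep = d.correlation_report(x, np.exp(x))
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.pearson_r < 1.0

    def test_spearman_closed_form(self):
        # d^2 = {0,1,1,0}: rho = 1 - 6*2 / (4*15) = 0.8
        rep = d.correlation_report([1, 2, 3, 4], [1, 3, 2, 4])
        assert rep.spearman_rho == pytest.approx(0.8)

    def test_constant_input(self):
        with pytest.raises(ConstantInput):
            d.correlation_report([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCohenKappa:
    def test_identical_ratings(self):
        assert d.cohen_kappa(list("ABCDEFGH"), list("ABCDEFGH")) == pytest.approx(1.0)

    def test_fully_crossed_two_categories(self):
        # p_o = 0, p_e = 0.5 -> kappa = -1
        assert d.cohen_kappa(list("AABB"), list("BBAA")) == pytest.approx(-1.0)

    def test_altman_band_for_good_agreement(self):
        assert d.agreement_label(0.7) == "good"
        assert d.agreement_label(0.62) == "good"
        assert d.agreement_label(0.85) == "very good"
        assert d.agreement_label(0.1) == "poor"

    def test_perfect_expected_agreement(self):
        with pytest.raises(PerfectExpectedAgreement):
            d.cohen_kappa(["H", "H", "H"], ["H", "H", "H"])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.sampled_from("ABCD"), min_size=5, max_size=30))
    def test_relabel_invariance(self, r1):
        rng = np.random.default_rng(len(r1))
        r2 = ["".join(rng.permutation(list("ABCD")))[0] for _ in r1]
        relabel = dict(zip("ABCD", "WXYZ"))
        try:
            k1 = d.cohen_kappa(r1, r2)
        except PerfectExpectedAgreement:
            return
        k2 = d.cohen_kappa([relabel[a] for a in r1], [relabel[b] for b in r2])
        assert k1 == pytest.approx(k2)
        assert -1.0 - 1e-9 <= k1 <= 1.0 + 1e-9


class TestRaterComparison:
    def test_identical_chart_sets(self, all_h_chart):
        charts = {f"s{i}": d.DentalChart.from_sequence(list("DEFGHHH")) for i in range(5)}
        charts["x"] = all_h_chart
        out = d.rater_comparison(charts, dict(charts))
        assert out.mean_kappa == pytest.approx(1.0)
        assert all(k == pytest.approx(1.0) for k in out.per_tooth_kappa.values())

    def test_perturbed_charts_give_intermediate_kappa(self, kosovo):
        cfg = d.SimulationConfig(seed=99, n_per_bin=5)
        cohort = d.generate_cohort(cfg)
        subjects = cohort.subjects[:50]
        rng = np.random.default_rng(17)
        charts1, charts2 = {}, {}
        for s in subjects:
            charts1[s.id] = s.chart
            stages = dict(s.chart.stages)
            for fdi in d.FDI_TEETH:
                if rng.random() < 0.10:
                    cur = d.STAGES.index(stages[fdi])
                    stages[fdi] = d.STAGES[min(7, max(0, cur + rng.choice([-1, 1])))]
            charts2[s.id] = d.DentalChart(stages)
        out = d.rater_comparison(charts1, charts2)
        assert 0.0 < out.mean_kappa < 1.0
        # deterministic under the fixed seed
        again = d.rater_comparison(charts1, charts2)
        assert again.mean_kappa == out.mean_kappa

    def test_disjoint_subjects_rejected(self, all_h_chart):
        with pytest.raises(SubjectMismatch):
            d.rater_comparison({"a": all_h_chart}, {"b": all_h_chart})


class TestMethodComparison:
    def test_self_comparison_all_zero(self, small_cohort, kosovo):
        out = d.method_comparison(small_cohort, kosovo, kosovo, seed=5)
        assert out.bias.mean_diff == 0.0
        assert np.array_equal(out.da_a, out.da_b)

    def test_shifted_grid_shifts_dental_age(self, small_cohort, kosovo):
        """A clone whose grid maps each score to age+0.2 lowers DA(a)-DA(b) by 0.2."""
        ages = grid_ages()
        shifted_grids = {}
        for sex in ("F", "M"):
            g = kosovo.grid(sex)
            # score at (age - 0.2), linearly extended below the 6.0 edge
            slope = (g.scores[1] - g.scores[0]) / 0.1
            src = np.where(ages - 0.2 >= 6.0, ages - 0.2, 6.0)
            scores = np.interp(src, g.ages, g.scores)
            scores[ages - 0.2 < 6.0] -= slope * (6.0 - (ages - 0.2))[ages - 0.2 < 6.0]
            shifted_grids[sex] = ConversionGrid(sex=sex, ages=ages, scores=np.round(scores, 4))
        clone = d.ReferenceTables(score_table=kosovo.score_table, grids=shifted_grids)
        interior = small_cohort.filter(lambda s: 8.0 < s.chronological_age < 14.0)
        out = d.method_comparison(interior, kosovo, clone, seed=5)
        assert out.bias.mean_diff == pytest.approx(-0.2, abs=0.02)
        assert out.correlation.spearman_rho > 0.99

    def test_coverage_error_names_population(self, small_cohort, kosovo):
        # a table starting at stage H cannot score everything
        poor = d.MaturityScoreTable(
            population="sparse", scores={(sex, t, "H"): 10.0 for sex in "FM" for t in d.FDI_TEETH}
        )
        sparse = d.ReferenceTables(score_table=poor, grids=dict(kosovo.grids))
        with pytest.raises(CoverageError, match="sparse"):
            d.method_comparison(small_cohort, kosovo, sparse, seed=5)
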