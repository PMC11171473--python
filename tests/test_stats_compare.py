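"""Regression fits, ANCOVA line comparison, extra-sum-of-squares curve
comparison, and the study-level comparison report."""

import numpy as np
import pytest

from aortavisc.protocol import FENTANYL_STAGES
from aortavisc.stats_compare import (
    compare_curves,
    compare_lines,
    default_contrast_plan,
    fit_exponential,
    fit_linear,
    run_comparisons,
)
from aortavisc.synthetic_data import default_study_config, generate_points

P_LEVELS = np.repeat(np.linspace(77.2, 157.4, 4), 4)  # 4 animals x 4 loads


def xy(p, y):
    return np.column_stack([p, y])


class TestLinearFit:
    def test_exact_line(self):
        pts = xy(P_LEVELS, 0.05 * P_LEVELS + 8.0)
        fit = fit_linear(pts)
        assert fit.slope == pytest.approx(0.05, rel=1e-12)
        assert fit.intercept == pytest.approx(8.0, rel=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.df == fit.n - 2

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="n >= 3"):
            fit_linear(xy(np.array([1.0, 2.0]), np.array([1.0, 2.0])))

    def test_rank_deficient(self):
        with pytest.raises(ValueError, match="rank deficient"):
            fit_linear(xy(np.full(5, 100.0), np.arange(5.0)))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(50, 200, 12)
            y = rng.normal(0, 1, 12) + 0.1 * p
            fit = fit_linear(xy(p, y))
            # independent oracle: explicit normal equations
            X = np.column_stack([np.ones(12), p])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            s2 = resid @ resid / (12 - 2)
            cov = s2 * np.linalg.inv(X.T @ X)
            assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
            assert fit.slope == pytest.approx(beta[1], rel=1e-10)
            assert fit.intercept_se == pytest.approx(np.sqrt(cov[0, 0]), rel=1e-10)
            assert fit.slope_se == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-10)

    def test_slope_within_3se_of_truth(self):
        """Monte-Carlo: the slope estimate falls within 3 SE of the
        generating slope in >= 99% of replicates."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            y = 8.0 + 0.05 * P_LEVELS + rng.normal(0, 0.2, P_LEVELS.size)
            fit = fit_linear(xy(P_LEVELS, y))
            hits += abs(fit.slope - 0.05) <= 3.0 * fit.slope_se
        assert hits / n_rep >= 0.99


class TestExponentialFit:
    def test_exact_curve(self):
        y = 0.1 * np.exp(0.012 * P_LEVELS)
        fit = fit_exponential(xy(P_LEVELS, y))
        assert fit.converged
        assert fit.a == pytest.approx(0.1, rel=1e-6)
        assert fit.b == pytest.approx(0.012, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_flat_data(self):
        rng = np.random.default_rng(0)
        y = 5.0 + rng.normal(0, 1e-6, P_LEVELS.size)
        fit = fit_exponential(xy(P_LEVELS, y))
        assert fit.a == pytest.approx(5.0, rel=1e-4)
        assert abs(fit.b) < 1e-6

    def test_requires_positive_values(self):
        with pytest.raises(ValueError, match="y > 0"):
            fit_exponential(xy(P_LEVELS, np.linspace(-1, 10, P_LEVELS.size)))

    def test_parameters_within_3se_of_truth(self):
        rng = np.random.default_rng(11)
        a, b = 0.3e6, 0.012
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            y = a * np.exp(b * P_LEVELS) + rng.normal(0, 0.08e6, P_LEVELS.size)
            fit = fit_exponential(xy(P_LEVELS, y))
            hits += (fit.converged and abs(fit.a - a) <= 3 * fit.a_se
                     and abs(fit.b - b) <= 3 * fit.b_se)
        assert hits / n_rep >= 0.99


class TestLineComparison:
    def test_identical_datasets(self):
        rng = np.random.default_rng(5)
        y = 8.0 + 0.05 * P_LEVELS + rng.normal(0, 0.2, P_LEVELS.size)
        results = compare_lines(xy(P_LEVELS, y), xy(P_LEVELS, y))
        by_test = {r.test: r for r in results}
        assert by_test["slopes"].p_value == pytest.approx(1.0)
        assert by_test["elevations"].p_value == pytest.approx(1.0)
        assert not by_test["slopes"].significant

    def test_elevations_only_when_slopes_agree(self):
        rng = np.random.default_rng(6)
        ya = 8.0 + 0.02 * P_LEVELS + rng.normal(0, 0.1, P_LEVELS.size)
        yb = 8.0 + 0.30 * P_LEVELS + rng.normal(0, 0.1, P_LEVELS.size)
        results = compare_lines(xy(P_LEVELS, ya), xy(P_LEVELS, yb))
        assert [r.test for r in results] == ["slopes"]
        assert results[0].significant

    def test_power_for_strong_slope_difference(self):
        """Slopes differing by 5 noise-SDs per pressure span are detected
        in > 90% of replicates at n = 16 per line."""
        rng = np.random.default_rng(8)
        sd = 0.2
        delta = 5.0 * sd / (P_LEVELS.max() - P_LEVELS.min())
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            ya = 8.0 + 0.05 * P_LEVELS + rng.normal(0, sd, P_LEVELS.size)
            yb = 8.0 + (0.05 + delta) * P_LEVELS + rng.normal(0, sd, P_LEVELS.size)
            hits += compare_lines(xy(P_LEVELS, ya), xy(P_LEVELS, yb))[0].p_value < 0.05
        assert hits / n_rep > 0.9


class TestCurveComparison:
    def test_identical_datasets(self):
        rng = np.random.default_rng(9)
        y = 0.3e6 * np.exp(0.012 * P_LEVELS) + rng.normal(0, 0.05e6, P_LEVELS.size)
        res = compare_curves(xy(P_LEVELS, y), xy(P_LEVELS, y))
        assert res.F == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0)
        assert res.df1 == 2 and res.df2 == 2 * P_LEVELS.size - 4

    def test_nested_model_consistency(self):
        """Separate fits never fit worse than the shared fit: F >= 0."""
        rng = np.random.default_rng(10)
        for _ in range(30):
            ya = 0.3e6 * np.exp(rng.uniform(0.005, 0.02) * P_LEVELS) \
                + rng.normal(0, 0.1e6, P_LEVELS.size)
            yb = 0.3e6 * np.exp(rng.uniform(0.005, 0.02) * P_LEVELS) \
                + rng.normal(0, 0.1e6, P_LEVELS.size)
            res = compare_curves(xy(P_LEVELS, ya), xy(P_LEVELS, yb))
            assert res.F >= 0.0
            assert 0.0 <= res.p_value <= 1.0

    def test_power_for_threefold_rate_difference(self):
        rng = np.random.default_rng(12)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            ya = 0.3e6 * np.exp(0.004 * P_LEVELS) + rng.normal(0, 0.05e6, P_LEVELS.size)
            yb = 0.3e6 * np.exp(0.012 * P_LEVELS) + rng.normal(0, 0.05e6, P_LEVELS.size)
            hits += compare_curves(xy(P_LEVELS, ya), xy(P_LEVELS, yb)).p_value < 0.05
        assert hits / n_rep > 0.9


class TestReport:
    def test_single_group_skips_between_group_contrasts(self):
        cfg = default_study_config(n_sham=0, stages=["control", "Fe-9"], seed=4)
        pts = generate_points(cfg)
        plan = default_contrast_plan(stages=["control", "Fe-9"])
        report, _ = run_comparisons(pts, plan)
        skipped = report[report.test == "skipped"]
        between = report[report.contrast.str.contains("sham-vs-pin")]
        assert (between.test == "skipped").all()  # no sham cells exist
        assert skipped.note.str.contains("unusable").all()
        ran = report[report.test != "skipped"]
        assert not ran.empty  # within-pin contrasts still run
        assert ran.contrast.str.contains("pin:").all()

    def test_identical_cells_never_significant(self):
        cfg = default_study_config(stages=["control"], n_sham=2, n_pin=0,
                                   between_animal_sigma=0.0,
                                   f0_noise_sigma=0.0, seed=1)
        pts = generate_points(cfg)
        plan = [{"id": "f0:self", "measure": "f0",
                 "cell_a": {"group": "sham", "stage": "control"},
                 "cell_b": {"group": "sham", "stage": "control"}},
                {"id": "E:self", "measure": "Eprime",
                 "cell_a": {"group": "sham", "stage": "control"},
                 "cell_b": {"group": "sham", "stage": "control"}}]
        report, _ = run_comparisons(pts, plan)
        assert not report.significant.any()

    def test_recovers_generated_effect_pattern_single_study(self):
        """The melatonin-deficiency signature shows up where generated: the
        pin group's E' is flagged against sham only at the lowest fentanyl
        concentration, while fentanyl depresses sham E' at every dose."""
        stages = ["control"] + list(FENTANYL_STAGES)
        cfg = default_study_config(stages=stages, seed=20240)
        pts = generate_points(cfg)
        plan = []
        for st in FENTANYL_STAGES:
            plan.append({"id": f"E:between@{st}", "measure": "Eprime",
                         "cell_a": {"group": "sham", "stage": st},
                         "cell_b": {"group": "pin", "stage": st}})
            plan.append({"id": f"E:sham@{st}", "measure": "Eprime",
                         "cell_a": {"group": "sham", "stage": st},
                         "cell_b": {"group": "sham", "stage": "control"}})
        report, fits = run_comparisons(pts, plan)
        calls = dict(zip(report.contrast, report.significant))
        assert calls["E:between@Fe-9"]
        for st in ("Fe-8", "Fe-7", "Fe-6"):
            assert not calls[f"E:between@{st}"]
        for st in FENTANYL_STAGES:
            assert calls[f"E:sham@{st}"]
        assert fits.converged.all()

    def test_holm_is_no_less_conservative(self):
        cfg = default_study_config(stages=["control", "Fe-9"], seed=30)
        pts = generate_points(cfg)
        plan = default_contrast_plan(stages=["control", "Fe-9"])
        plain, _ = run_comparisons(pts, plan, holm=False)
        holm, _ = run_comparisons(pts, plan, holm=True)
        assert holm.significant.sum() <= plain.significant.sum()
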