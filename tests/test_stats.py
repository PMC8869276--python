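import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from thermofatigue.features import FEATURE_COLUMNS
from thermofatigue.stats import (
    boxplot_summary,
    build_report,
    correlate_with_rpe,
    greenhouse_geisser_epsilon,
    lsd_posthoc,
    rm_anova,
    shapiro_wilk,
)

ROIS = ("Exercised Leg", "Nonexercised Leg", "Nose Tip", "Corrugator")


def tidy_table(scores, rpe=None, feature="delta_t", rois=ROIS):
    """n x k score matrix -> tidy feature table."""
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    rpe = rpe if rpe is not None else np.full(n, 7)
    rows = []
    for i in range(n):
        for j in range(k):
            row = {"subject_id": f"S{i + 1:02d}", "roi": rois[j],
                   "rpe": int(rpe[i])}
            for feat in FEATURE_COLUMNS:
                row[feat] = 0.0
            row[feature] = scores[i, j]
            rows.append(row)
    return pd.DataFrame(rows)


def oracle_rm_anova(scores):
    """Brute-force sums-of-squares + covariance-eigenvalue epsilon oracle.

    Independent of the implementation: explicit cell-by-cell SS loops and
    the sphericity factor from the eigenvalues of the double-centred
    condition covariance matrix.
    """
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    grand = scores.mean()
    ss_cond = sum(n * (scores[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (scores[i, :].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum(
        (scores[i, j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    ss_err = ss_tot - ss_cond - ss_subj
    f = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    S = np.cov(scores, rowvar=False, ddof=1)
    C = np.eye(k) - np.ones((k, k)) / k
    lam = np.linalg.eigvalsh(C @ S @ C)
    lam = lam[lam > 1e-12 * lam.max()] if lam.max() > 0 else lam
    eps = lam.sum() ** 2 / ((k - 1) * np.sum(lam**2))
    return f, min(1.0, eps)


class TestShapiroWilk:
    # frozen oracle: R 4.3.3 shapiro.test on these exact values gives
    # W = 0.9130389455, p = 0.3759608099
    R_INPUT = [0.8817121595265062, -0.7430977686063489, -0.860742941112305,
               -0.48940732589470637, 1.2716670110955381, -0.5353284486809142,
               1.4196942109131803, -2.1390144874931454]

    def test_matches_reference_implementation(self):
        w, p = shapiro_wilk(self.R_INPUT)
        assert w == pytest.approx(0.9130389455, abs=1e-6)
        assert p == pytest.approx(0.3759608099, abs=1e-6)

    def test_perfect_normal_quantiles_score_high(self):
        n = 8
        i = np.arange(1, n + 1)
        q = sst.norm.ppf((i - 0.375) / (n + 0.25))
        w, p = shapiro_wilk(q)
        assert w > 0.99
        assert p > 0.5

    def test_constant_input_is_a_degeneracy_error(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk(np.full(8, 3.0))


class TestRmAnova:
    def test_identical_conditions_give_zero_f(self, rng):
        subj = rng.normal(0, 1, 8)
        scores = np.tile(subj[:, None], (1, 4))
        res = rm_anova(tidy_table(scores), "delta_t")
        assert res.f == 0.0
        assert res.p == 1.0

    def test_two_conditions_reduce_to_paired_t(self, rng):
        # algebraic identity: k = 2 RM-ANOVA F equals the squared paired t
        for _ in range(20):
            scores = rng.normal(0, 1, (8, 2))
            res = rm_anova(tidy_table(scores, rois=ROIS[:2]), "delta_t")
            t = sst.ttest_rel(scores[:, 0], scores[:, 1]).statistic
            assert res.epsilon == pytest.approx(1.0, abs=1e-12)
            assert res.f == pytest.approx(t**2, abs=1e-10 * max(1, t**2))

    def test_matches_brute_force_oracle_on_random_tables(self, rng):
        for _ in range(50):
            scores = rng.normal(0, 1, (8, 4)) + rng.normal(0, 1, (8, 1))
            res = rm_anova(tidy_table(scores), "delta_t")
            f_o, eps_o = oracle_rm_anova(scores)
            assert res.f == pytest.approx(f_o, rel=1e-8)
            assert res.epsilon == pytest.approx(eps_o, rel=1e-8)
            assert res.df1 == pytest.approx(res.epsilon * 3, rel=1e-12)
            assert res.df2 == pytest.approx(res.epsilon * 21, rel=1e-12)
            assert 1.0 / 3 <= res.epsilon <= 1.0

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        scores = rng.normal(0, 1, (8, 4))
        table = tidy_table(scores)
        res = rm_anova(table, "delta_t")
        pg = pingouin.rm_anova(
            data=table, dv="delta_t", within="roi", subject="subject_id",
            correction=True, detailed=False,
        )
        assert res.f == pytest.approx(float(pg["F"].iloc[0]), rel=1e-6)
        assert res.epsilon == pytest.approx(float(pg["eps"].iloc[0]), rel=1e-6)
        assert res.p == pytest.approx(float(pg["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_invariant_to_per_subject_constant_and_relabelling(self, rng):
        scores = rng.normal(0, 1, (8, 4))
        res0 = rm_anova(tidy_table(scores), "delta_t")
        shifted = scores + rng.normal(0, 5, (8, 1))
        res1 = rm_anova(tidy_table(shifted), "delta_t")
        assert res1.f == pytest.approx(res0.f, rel=1e-9)
        assert res1.epsilon == pytest.approx(res0.epsilon, rel=1e-9)
        perm = rng.permutation(8)
        res2 = rm_anova(tidy_table(scores[perm]), "delta_t")
        assert res2.f == pytest.approx(res0.f, rel=1e-9)

    def test_incomplete_crossing_lists_missing_cells(self, rng):
        table = tidy_table(rng.normal(0, 1, (4, 4)))
        table = table[~((table.subject_id == "S02") & (table.roi == "Nose Tip"))]
        with pytest.raises(ValueError, match="S02"):
            rm_anova(table, "delta_t")


class TestLsdPosthoc:
    def test_six_pairs_for_four_rois(self, rng):
        res = lsd_posthoc(tidy_table(rng.normal(0, 1, (8, 4))), "delta_t")
        assert len(res) == 6

    def test_identical_pair_gives_zero_t_unit_p(self, rng):
        scores = rng.normal(0, 1, (8, 4))
        scores[:, 1] = scores[:, 0]
        res = lsd_posthoc(tidy_table(scores), "delta_t")
        pair = next(r for r in res if {r.roi_a, r.roi_b} == set(ROIS[:2]))
        assert pair.t == 0.0 and pair.p == 1.0 and pair.mean_diff == 0.0

    def test_mean_differences_antisymmetric(self, rng):
        scores = rng.normal(0, 1, (8, 4))
        res = lsd_posthoc(tidy_table(scores), "delta_t")
        wide = {(r.roi_a, r.roi_b): r.mean_diff for r in res}
        for (a, b), d in wide.items():
            assert d == pytest.approx(
                scores[:, ROIS.index(a)].mean() - scores[:, ROIS.index(b)].mean()
            )

    def test_large_injected_effect_flags_only_its_pairs(self, rng):
        scores = rng.normal(0, 0.05, (8, 4))
        scores[:, 0] += 1.5  # exercised leg warms, others do not
        res = lsd_posthoc(tidy_table(scores), "delta_t")
        for r in res:
            involved = "Exercised Leg" in (r.roi_a, r.roi_b)
            assert (r.p < 0.001) == involved


class TestCorrelateWithRpe:
    def test_exact_linear_feature_gives_unit_correlation(self):
        rpe = np.array([3, 5, 6, 7, 8, 9, 4, 6])
        up = tidy_table(np.tile(1.0 + 2.0 * rpe[:, None], (1, 4)), rpe=rpe)
        cells = correlate_with_rpe(up, features=("delta_t",))
        assert all(c.r == pytest.approx(1.0) for c in cells)
        down = tidy_table(np.tile(1.0 - 2.0 * rpe[:, None], (1, 4)), rpe=rpe)
        cells = correlate_with_rpe(down, features=("delta_t",))
        assert all(c.r == pytest.approx(-1.0) for c in cells)

    def test_hand_computed_pearson_example(self):
        # x = 1..5 vs y = (2,1,4,3,5): r = 8 / sqrt(10*10) = 0.8
        rpe = np.array([2, 1, 4, 3, 5])
        table = tidy_table(np.tile(np.arange(1.0, 6.0)[:, None], (1, 4)), rpe=rpe)
        cells = correlate_with_rpe(table, features=("delta_t",))
        assert all(c.r == pytest.approx(0.8) for c in cells)
        assert all(c.n == 5 for c in cells)

    def test_matrix_covers_features_by_rois(self, rng):
        table = tidy_table(rng.normal(0, 1, (8, 4)),
                           rpe=rng.integers(1, 11, 8))
        cells = correlate_with_rpe(table)
        assert len(cells) == len(FEATURE_COLUMNS) * 4

    def test_zero_variance_feature_flagged_not_crashed(self):
        rpe = np.array([3, 5, 6, 7, 8, 9, 4, 6])
        table = tidy_table(np.zeros((8, 4)), rpe=rpe)
        cells = correlate_with_rpe(table, features=("delta_t",))
        assert all(c.degenerate and np.isnan(c.r) for c in cells)


class TestBuildReport:
    @pytest.fixture(scope="class")
    @staticmethod
    def report():
        rng = np.random.default_rng(5)
        scores = rng.normal(0, 1, (8, 4))
        table = tidy_table(scores, rpe=rng.integers(1, 11, 8))
        for feat in FEATURE_COLUMNS:
            table[feat] = rng.normal(0, 1, len(table))
        return build_report(table)

    def test_one_anova_row_per_feature(self, report):
        assert len(report.anova) == 6
        assert {a.feature for a in report.anova} == set(FEATURE_COLUMNS)
        assert len(report.correlations) == 24

    def test_boxplot_summary_matches_order_statistics(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        s = boxplot_summary(vals)
        assert s == {"min": 1.0, "q1": 2.0, "median": 3.0, "q3": 4.0,
                     "max": 100.0}

    def test_json_round_trips(self, report):
        d = json.loads(report.to_json())
        assert d["alpha"] == 0.05
        assert len(d["anova"]) == 6
        assert json.loads(json.dumps(d)) == d

    def test_markdown_contains_all_sections(self, report):
        md = report.to_markdown()
        assert "ANOVA" in md and "Pairwise" in md and "correlations" in md
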