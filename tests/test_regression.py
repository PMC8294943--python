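"""Ridge CV harness and the ANOVA / Tukey / t-test comparisons."""

import numpy as np
import pandas as pd
import pytest

import braincae as bc
from braincae.regression import RegressionReport


def make_features(n=60, p=20, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    ids = [f"s{i:03d}" for i in range(n)]
    return bc.FeatureMatrix(matrix=X, subject_ids=ids, kind="latent",
                            provenance={})


def report_from_scores(scores, target="t"):
    recs = pd.DataFrame({"repeat": np.arange(len(scores)), "fold": 0,
                         "score": np.asarray(scores, dtype=float)})
    return RegressionReport(target=target, provenance={}, records=recs,
                            metric="rmse", n_subjects=0, folds=1,
                            repeats=len(scores), ridge_penalty=1.0, seed=0)


class TestRidgeCV:
    def test_realizable_target_near_zero_rmse(self):
        fm = make_features(seed=1)
        y = 2.0 * fm.matrix[:, 3] - 1.0
        rep = bc.ridge_cv(fm, y, ridge_penalty=1e-8, seed=0)
        assert rep.metric == "rmse"
        assert rep.mean < 1e-6
        assert len(rep.records) == 50

    def test_permuted_target_rmse_near_population_sd(self):
        """Null features: CV RMSE approaches the target's population SD."""
        rng = np.random.default_rng(2)
        fm = make_features(n=200, p=10, seed=2)
        y = rng.standard_normal(200) * 3.0 + 5.0
        y_perm = rng.permutation(y)
        rep = bc.ridge_cv(fm, y_perm, ridge_penalty=1.0, seed=1)
        assert abs(rep.mean - y.std()) / y.std() < 0.15

    def test_deterministic_given_seed(self):
        fm = make_features(seed=3)
        y = fm.matrix[:, 0] + np.random.default_rng(4).standard_normal(60)
        a = bc.ridge_cv(fm, y, seed=7)
        b = bc.ridge_cv(fm, y, seed=7)
        assert a.records.equals(b.records)
        c = bc.ridge_cv(fm, y, seed=8)
        assert not a.records.equals(c.records)

    def test_binary_target_gives_accuracy(self):
        rng = np.random.default_rng(5)
        fm = make_features(n=80, seed=5)
        y = (fm.matrix[:, 0] > 0).astype(float)
        rep = bc.ridge_cv(fm, y, seed=0)
        assert rep.metric == "accuracy"
        assert 0.5 < rep.mean <= 1.0

    def test_errors(self):
        fm = make_features(n=4)
        with pytest.raises(ValueError):
            bc.ridge_cv(fm, np.ones(4))           # constant target
        with pytest.raises(ValueError):
            bc.ridge_cv(fm, np.arange(4.0), folds=5)  # fewer subjects than folds
        fm2 = make_features(n=10)
        y = np.arange(10.0); y[3] = np.nan
        with pytest.raises(ValueError):
            bc.ridge_cv(fm2, y)

    def test_inner_cv_penalty_selection(self):
        """With a penalty grid, heavy regularization is dropped when the
        target is exactly realizable (the inner CV picks the small alpha)."""
        fm = make_features(n=60, p=10, seed=6)
        y = fm.matrix[:, 2] * 3.0
        fixed = bc.ridge_cv(fm, y, ridge_penalty=100.0, repeats=2, seed=0)
        tuned = bc.ridge_cv(fm, y, ridge_penalty=100.0, repeats=2, seed=0,
                            penalty_grid=(1e-8, 100.0))
        assert tuned.mean < fixed.mean * 0.1

    def test_fold_standardization_uses_training_folds_only(self):
        """A pipeline that standardizes on the full matrix before splitting
        leaks; the harness must not reproduce that leaky score on a
        planted overfit case."""
        rng = np.random.default_rng(9)
        n = 20
        X = rng.standard_normal((n, 300))
        y = rng.standard_normal(n)
        fm = bc.FeatureMatrix(X, [f"s{i}" for i in range(n)], "latent", {})
        clean = bc.ridge_cv(fm, y, ridge_penalty=1e-6, repeats=2, seed=0)

        # deliberately leaky reimplementation: global standardization
        from sklearn.linear_model import Ridge
        from sklearn.model_selection import KFold
        Xg = (X - X.mean(0)) / np.where(X.std(0) == 0, 1, X.std(0))
        base = np.random.default_rng(0)
        fold_seeds = base.integers(0, 2**31 - 1, size=2)
        leaky = []
        for rep in range(2):
            kf = KFold(5, shuffle=True, random_state=int(fold_seeds[rep]))
            for tr, te in kf.split(Xg):
                m = Ridge(alpha=1e-6).fit(Xg[tr], y[tr])
                leaky.append(np.sqrt(np.mean((m.predict(Xg[te]) - y[te]) ** 2)))
        assert not np.allclose(clean.records["score"].to_numpy(),
                               np.array(leaky), atol=1e-12)


class BruteForceTwoWay:
    """Sums-of-squares two-way balanced ANOVA, written out longhand."""

    def __init__(self, df):
        self.df = df

    def f_and_p(self):
        from scipy.stats import f as fdist
        df = self.df
        a_levels = sorted(df["blocks"].unique())
        b_levels = sorted(df["channels"].unique())
        n = len(df[(df.blocks == a_levels[0]) & (df.channels == b_levels[0])])
        grand = df["score"].mean()
        ss_a = sum(len(df[df.blocks == a]) * (df[df.blocks == a]["score"].mean() - grand) ** 2
                   for a in a_levels)
        ss_b = sum(len(df[df.channels == b]) * (df[df.channels == b]["score"].mean() - grand) ** 2
                   for b in b_levels)
        ss_ab, ss_e = 0.0, 0.0
        for a in a_levels:
            for b in b_levels:
                cell = df[(df.blocks == a) & (df.channels == b)]["score"]
                ss_ab += n * (cell.mean() - df[df.blocks == a]["score"].mean()
                              - df[df.channels == b]["score"].mean() + grand) ** 2
                ss_e += ((cell - cell.mean()) ** 2).sum()
        df_a, df_b = len(a_levels) - 1, len(b_levels) - 1
        df_ab = df_a * df_b
        df_e = len(df) - len(a_levels) * len(b_levels)
        ms = lambda ss, d: ss / d
        out = {}
        for name, ss, d in [("blocks", ss_a, df_a), ("channels", ss_b, df_b),
                            ("interaction", ss_ab, df_ab)]:
            F = ms(ss, d) / ms(ss_e, df_e)
            out[name] = (F, float(fdist.sf(F, d, df_e)))
        return out


class TestAnova:
    def grid_from(self, fn):
        return {(b, c): fn(b, c) for b in (1, 2, 3, 4) for c in (1, 4, 16, 32)}

    def test_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(0)
        grid = self.grid_from(lambda b, c: rng.normal(1.0 + 0.1 * b, 0.2, 10))
        table = bc.compare_models_anova(grid)
        rows = [{"blocks": b, "channels": c, "score": s}
                for (b, c), scores in grid.items() for s in scores]
        brute = BruteForceTwoWay(pd.DataFrame(rows)).f_and_p()
        assert table.f_value("blocks") == pytest.approx(brute["blocks"][0], abs=1e-10)
        assert table.f_value("channels") == pytest.approx(brute["channels"][0], abs=1e-10)
        assert table.p_value("blocks") == pytest.approx(brute["blocks"][1], abs=1e-10)
        assert table.p_value("channels") == pytest.approx(brute["channels"][1], abs=1e-10)

    def test_two_by_two_textbook_case(self):
        # hand-checkable 2x2 balanced design with 3 replicates per cell
        grid = {(1, 1): [3.0, 4.0, 5.0], (1, 4): [6.0, 7.0, 8.0],
                (2, 1): [5.0, 6.0, 7.0], (2, 4): [9.0, 10.0, 11.0]}
        table = bc.compare_models_anova(grid)
        rows = [{"blocks": b, "channels": c, "score": s}
                for (b, c), scores in grid.items() for s in scores]
        brute = BruteForceTwoWay(pd.DataFrame(rows)).f_and_p()
        for factor in ("blocks", "channels"):
            assert table.f_value(factor) == pytest.approx(brute[factor][0], abs=1e-10)

    def test_null_grids_keep_type_I_rate(self):
        """All cells from one normal: main effects exceed 0.05 rarely."""
        rng = np.random.default_rng(42)
        ok = 0
        for _ in range(100):
            grid = self.grid_from(lambda b, c: rng.normal(0.0, 1.0, 10))
            table = bc.compare_models_anova(grid)
            if table.p_value("blocks") > 0.05 and table.p_value("channels") > 0.05:
                ok += 1
        assert ok >= 90

    def test_planted_block_effect_detected(self):
        rng = np.random.default_rng(1)
        grid = self.grid_from(
            lambda b, c: rng.normal(1.0 + (0.5 if b == 3 else 0.0), 0.05, 10))
        table = bc.compare_models_anova(grid)
        assert table.p_value("blocks") < 0.001
        res = pd.DataFrame(data=table.tukey_blocks.summary().data[1:],
                           columns=table.tukey_blocks.summary().data[0])
        with3 = res[(res.group1 == 3) | (res.group2 == 3)]
        assert with3["reject"].all()

    def test_missing_cell_raises(self):
        grid = self.grid_from(lambda b, c: np.zeros(10) + b + c)
        del grid[(3, 16)]
        with pytest.raises(ValueError, match="missing"):
            bc.compare_models_anova(grid)


class TestRoiTTest:
    def test_identical_reports(self):
        a = report_from_scores([1.0, 1.1, 0.9, 1.0, 1.05])
        t, p, sig = bc.compare_to_roi_ttest(a, report_from_scores(a.repeat_means))
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert not sig

    def test_separated_samples(self):
        rng = np.random.default_rng(3)
        a = report_from_scores(rng.normal(1.0, 0.01, 10))
        b = report_from_scores(rng.normal(2.0, 0.01, 10))
        t, p, sig = bc.compare_to_roi_ttest(a, b)
        assert p < 0.001 and sig

    def test_matches_pooled_variance_formula(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 10), rng.normal(0.3, 1.2, 10)
        t, p, _ = bc.compare_to_roi_ttest(report_from_scores(x),
                                          report_from_scores(y))
        n = 10
        sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (2 * n - 2)
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (2 / n))
        assert t == pytest.approx(t_hand, abs=1e-10)

    def test_unequal_repeats_raise(self):
        with pytest.raises(ValueError):
            bc.compare_to_roi_ttest(report_from_scores([1, 2, 3]),
                                    report_from_scores([1, 2]))
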