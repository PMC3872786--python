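"""RT analyses: trimming, residual partitioning, grids, ceiling arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import imgcalc as ic


def _trials(rts, subject="s0", correct=True, is_word=True):
    n = len(rts)
    return pd.DataFrame({
        "subject": [subject] * n,
        "word": [f"w{i}" for i in range(n)],
        "is_word": [is_word] * n,
        "correct": [correct] * n,
        "rt": rts,
    })


class TestPreprocessTrials:
    def test_absolute_filters(self):
        t = _trials([350.0, 500.0, 4200.0, 600.0])
        cleaned, report = ic.preprocess_trials(t)
        assert sorted(cleaned["rt"]) == [500.0, 600.0]
        steps = {s["step"]: s["removed"] for s in report.steps}
        assert steps["too_fast"] == 1 and steps["too_slow"] == 1

    def test_z_trim_removes_planted_extremes(self):
        rts = [500.0] * 98 + [2000.0] * 2
        rng = np.random.default_rng(0)
        rts = [r + rng.normal(0, 5) for r in rts]  # avoid zero sd
        cleaned, report = ic.preprocess_trials(_trials(rts))
        assert len(cleaned) == 98
        assert report.steps[-1]["removed"] == 2
        # direct z oracle on the pre-trim distribution
        arr = np.array(rts)
        z = (arr - arr.mean()) / arr.std(ddof=1)
        assert int((np.abs(z) > 2.5).sum()) == 2

    def test_error_and_nonword_trials_dropped(self):
        t = pd.concat([
            _trials([500.0, 600.0]),
            _trials([550.0], correct=False),
            _trials([560.0], is_word=False),
        ], ignore_index=True)
        cleaned, report = ic.preprocess_trials(t)
        assert len(cleaned) == 2
        steps = {s["step"]: s["removed"] for s in report.steps}
        assert steps["errors_and_nonwords"] == 2

    def test_low_accuracy_subject_dropped_first(self):
        frames = []
        rng = np.random.default_rng(1)
        for s in range(10):
            f = _trials(list(rng.normal(600, 30, 40)), subject=f"s{s}")
            if s == 0:  # one subject far below the rest in accuracy
                f["correct"] = [True] * 10 + [False] * 30
            frames.append(f)
        t = pd.concat(frames, ignore_index=True)
        cleaned, report = ic.preprocess_trials(t)
        assert "s0" not in set(cleaned["subject"])
        assert report.steps[0]["step"] == "subject_accuracy"
        assert report.steps[0]["removed"] == 40

    def test_planted_outlier_counts_recovered(self):
        rng = np.random.default_rng(5)
        items = pd.DataFrame({"x": rng.random(40)},
                             index=[f"w{i}" for i in range(40)])
        trials, truth = ic.generate_trials(items, ic.RTSpec(
            n_subjects=20, outlier_rate=0.03, error_rate=0.0,
            residual_sd=30.0, subject_sd=20.0, seed=5))
        cleaned, report = ic.preprocess_trials(
            trials.drop(columns="planted_outlier"))
        absolute_removed = sum(s["removed"] for s in report.steps
                               if s["step"] in ("too_fast", "too_slow"))
        # planted outliers are far outside 400-4000 ms, so the absolute
        # filters must catch exactly the planted set
        assert absolute_removed == truth["n_planted_outliers"]

    def test_empty_after_filtering_errors(self):
        with pytest.raises(ValueError):
            ic.preprocess_trials(_trials([100.0, 50.0]))


class TestResidualize:
    def test_identical_covariate_gives_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        resid = ic.residualize(y, pd.DataFrame({"c": y}))
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_orthogonal_covariate_centers_y(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        c = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to y, mean 0
        resid = ic.residualize(y, pd.DataFrame({"c": c}))
        assert np.allclose(resid, y - y.mean())

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(2)
        C = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = rng.normal(size=50)
        resid = ic.residualize(y, C)
        for c in "abc":
            assert abs(resid @ C[c].to_numpy()) < 1e-8


class TestVariancePartition:
    def _items(self, img_effect=0.0, seed=0, n=400):
        rng = np.random.default_rng(seed)
        cov = pd.DataFrame({
            "on": rng.integers(0, 10, n).astype(float),
            "length": rng.integers(3, 10, n).astype(float),
            "lnfrequency": rng.normal(5, 1.5, n),
        })
        ctx = rng.normal(size=n)
        emo = rng.normal(size=n)
        # imageability correlated with the composites but causally inert
        # unless img_effect > 0
        img = 0.7 * ctx + 0.7 * emo + rng.normal(0, 0.4, n)
        rt = (650 - 20 * ctx - 25 * emo + 5 * cov["length"]
              - 10 * cov["lnfrequency"] + rng.normal(0, 10, n)
              - img_effect * img)
        return rt, cov, img, ctx, emo

    def test_composites_fully_explain_imageability(self):
        rt, cov, img, ctx, emo = self._items(img_effect=0.0, seed=1)
        report = ic.variance_partition(rt, cov, img, ctx, emo)
        assert report.before > 0.3  # imageability looks predictive...
        assert report.after < 0.005  # ...but is fully absorbed
        assert report.ratio < 0.02

    def test_independent_imageability_effect_survives(self):
        rt, cov, img, ctx, emo = self._items(img_effect=30.0, seed=2)
        report = ic.variance_partition(rt, cov, img, ctx, emo)
        assert report.after > 0.05

    def test_orthogonal_imageability_explains_nothing(self):
        rng = np.random.default_rng(3)
        rt, cov, _, ctx, emo = self._items(seed=3)
        img = rng.normal(size=len(rt))  # unrelated to everything
        report = ic.variance_partition(rt, cov, img, ctx, emo)
        assert report.before < 0.02

    def test_after_never_exceeds_before(self):
        for seed in range(5):
            rt, cov, img, ctx, emo = self._items(img_effect=10.0, seed=seed)
            report = ic.variance_partition(rt, cov, img, ctx, emo)
            assert report.after <= report.before + 1e-6


class TestZCategorize:
    def test_tail_proportions_near_normal(self):
        rng = np.random.default_rng(0)
        labels = ic.zcategorize(rng.normal(size=100_000))
        p_low = (labels == "low").mean()
        p_high = (labels == "high").mean()
        assert p_low == pytest.approx(0.159, abs=0.01)
        assert p_high == pytest.approx(0.159, abs=0.01)
        assert (labels == "mid").mean() == pytest.approx(0.683, abs=0.01)

    def test_boundary_value_is_mid(self):
        # construct data whose max sits exactly at +1z: n values with
        # one-of-each extreme symmetric around 0
        x = np.array([-1.0, 0.0, 1.0])  # z of extremes = ±1 exactly
        labels = ic.zcategorize(x)
        assert list(labels) == ["mid", "mid", "mid"]

    @given(st.floats(-1000, 1000))
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance(self, shift):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        assert (ic.zcategorize(x) == ic.zcategorize(x + shift)).all()

    def test_zero_spread_errors(self):
        with pytest.raises(ValueError):
            ic.zcategorize([2.0, 2.0, 2.0])


class TestCategoryGrid:
    def test_hand_built_grid(self):
        ctx = np.array(["high"] * 4 + ["low"] * 4 + ["mid"] * 4)
        emo = np.array(["high", "high", "low", "low"] * 3)
        rts = np.arange(12, dtype=float) * 10 + 600
        grid = ic.category_grid(ctx, emo, rts)
        cell = grid[(grid["context"] == "high") & (grid["emotionality"] == "high")]
        assert cell["count"].iloc[0] == 2
        assert cell["mean_rt"].iloc[0] == pytest.approx((600 + 610) / 2)
        sd = np.std([600.0, 610.0], ddof=1)
        assert cell["se"].iloc[0] == pytest.approx(sd / math.sqrt(2))

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(4)
        n = 200
        ctx = rng.choice(["low", "mid", "high"], n)
        emo = rng.choice(["low", "mid", "high"], n)
        rts = rng.normal(650, 40, n)
        member = rng.random(n) < 0.3
        grid = ic.category_grid(ctx, emo, rts, member=member)
        assert grid["proportion"].sum() == pytest.approx(1.0, abs=1e-9)
        assert grid["count"].sum() == member.sum()

    def test_single_populated_cell(self):
        ctx = np.array(["high", "high"])
        emo = np.array(["low", "low"])
        grid = ic.category_grid(ctx, emo, np.array([600.0, 700.0]))
        pop = grid[grid["count"] > 0]
        assert len(pop) == 1 and pop["proportion"].iloc[0] == 1.0

    def test_empty_cells_flagged_not_fabricated(self):
        ctx = np.array(["high"])
        emo = np.array(["high"])
        grid = ic.category_grid(ctx, emo, np.array([650.0]))
        empty = grid[grid["count"] == 0]
        assert empty["mean_rt"].isna().all()


class TestNullEffect:
    def test_identical_proportions_zero(self):
        m = np.array([600.0, 650, 700])
        p = np.array([0.2, 0.5, 0.3])
        assert ic.null_effect(m, p, p) == pytest.approx(0.0)

    def test_two_cell_hand_arithmetic(self):
        assert ic.null_effect(np.array([600.0, 700.0]),
                              np.array([0.75, 0.25]),
                              np.array([0.25, 0.75])) == pytest.approx(50.0)

    def test_matches_weighted_average_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            m = rng.normal(650, 40, 9)
            ph = rng.dirichlet(np.ones(9))
            pl = rng.dirichlet(np.ones(9))
            expected = float(np.sum(pl * m) - np.sum(ph * m))
            assert ic.null_effect(m, ph, pl) == pytest.approx(expected)

    def test_constant_shift_invariant(self):
        rng = np.random.default_rng(7)
        m = rng.normal(650, 40, 9)
        ph = rng.dirichlet(np.ones(9))
        pl = rng.dirichlet(np.ones(9))
        assert ic.null_effect(m + 123.0, ph, pl) == pytest.approx(
            ic.null_effect(m, ph, pl))

    def test_bad_proportions_error(self):
        with pytest.raises(ValueError):
            ic.null_effect(np.array([600.0, 700.0]),
                           np.array([0.6, 0.6]), np.array([0.5, 0.5]))


class TestCeilingArithmetic:
    def test_published_reliability_transfer(self):
        assert ic.equivalent_correlation(0.81, 1608, 1849) == pytest.approx(
            0.79, abs=0.005)

    def test_identity_at_equal_n(self):
        assert ic.equivalent_correlation(0.5, 100, 100) == pytest.approx(0.5)

    def test_numeric_t_equality_check(self):
        # independent check: solve for r2 such that t(r2, n2) = t(r1, n1)
        import scipy.optimize
        r1, n1, n2 = 0.5, 10, 10000

        def t_of(r, n):
            return r * math.sqrt(n - 2) / math.sqrt(1 - r * r)

        target = t_of(r1, n1)
        r2 = scipy.optimize.brentq(lambda r: t_of(r, n2) - target, 0, 0.999)
        assert ic.equivalent_correlation(r1, n1, n2) == pytest.approx(r2)
        assert r2 == pytest.approx(0.016, abs=0.002)

    def test_strictly_decreasing_in_n2(self):
        vals = [ic.equivalent_correlation(0.6, 500, n2)
                for n2 in (100, 500, 2000, 10000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            ic.equivalent_correlation(1.0, 100, 100)
        with pytest.raises(ValueError):
            ic.equivalent_correlation(0.5, 2, 100)

    @pytest.mark.parametrize("model,ceiling,expected", [
        (36.5, 62.0, 58.87),
        (40.0, 40.0, 100.0),
        (0.0, 50.0, 0.0),
    ])
    def test_variance_ratio(self, model, ceiling, expected):
        assert ic.variance_ratio(model, ceiling) == pytest.approx(
            expected, abs=0.01)

    def test_zero_ceiling_errors(self):
        with pytest.raises(ValueError):
            ic.variance_ratio(10.0, 0.0)
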