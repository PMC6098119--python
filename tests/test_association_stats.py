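import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from endfootnet.association_stats import (
    AssociationRecord,
    PathologyStateRule,
    adjust_pvalues,
    demographics_test,
    dementia_logistic,
    dichotomize_pathology,
    interaction_contrast,
    model_diagnostics,
    pathology_ols,
    validation_logistic,
)

# --------------------------------------------------------------------------
# oracles


def reference_bh(p):
    """Benjamini-Hochberg adjusted p straight from the step-up definition."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def reference_holm_sidak(p):
    """Step-down Holm-Sidak: p_adj(i) = max_{j<=i} [1 - (1-p_j)^(m-j+1)]."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_max = 0.0
    for j, i in enumerate(order, start=1):
        running_max = max(running_max, 1 - (1 - p[i]) ** (m - j + 1))
        adj[i] = min(running_max, 1.0)
    return adj


def _subjects(n, rng, dementia=None):
    frame = pd.DataFrame(
        {
            "age_increment": rng.integers(0, 5, n).astype(float),
            "apoe4": (rng.random(n) < 0.2).astype(float),
            "tbi": (rng.random(n) < 0.5).astype(float),
        },
        index=[f"S{i}" for i in range(n)],
    )
    frame["dementia"] = (
        dementia.astype(float) if dementia is not None else (rng.random(n) < 0.5).astype(float)
    )
    return frame


# --------------------------------------------------------------------------
# logistic


class TestDementiaLogistic:
    def test_null_calibration(self, rng):
        n, hits = 200, 0
        trials = 100
        for _ in range(trials):
            subjects = _subjects(n, rng)
            x = pd.Series(rng.normal(size=n), index=subjects.index)
            rec = dementia_logistic(x, subjects)
            if abs(rec.statistic) >= 3:
                hits += 1
        assert hits <= max(2, 0.01 * trials + 2)

    def test_perfect_separation_is_flagged_not_raised(self, rng):
        n = 60
        dem = np.arange(n) < 30
        subjects = _subjects(n, rng, dementia=dem)
        x = pd.Series(np.where(dem, 10.0, -10.0), index=subjects.index)
        rec = dementia_logistic(x, subjects)
        assert rec.flag == "separation"
        assert np.isnan(rec.p_raw)

    def test_slope_recovery(self, rng):
        slopes = []
        for _ in range(50):
            n = 100
            x = rng.normal(size=n)
            p = 1 / (1 + np.exp(-(0.0 + 1.0 * x)))
            dem = rng.random(n) < p
            subjects = _subjects(n, rng, dementia=dem)
            rec = dementia_logistic(pd.Series(x, index=subjects.index), subjects)
            if not rec.flag:
                slopes.append(rec.coefficient)
        assert abs(np.mean(slopes) - 1.0) <= 0.15

    def test_one_outcome_class_is_error(self, rng):
        subjects = _subjects(20, rng, dementia=np.ones(20, dtype=bool))
        with pytest.raises(ValueError):
            dementia_logistic(pd.Series(rng.normal(size=20), index=subjects.index), subjects)

    def test_wald_statistic_invariant_to_covariate_rescaling(self, rng):
        n = 150
        subjects = _subjects(n, rng)
        x = pd.Series(rng.normal(size=n), index=subjects.index)
        rec1 = dementia_logistic(x, subjects)
        scaled = subjects.copy()
        scaled["age_increment"] = scaled["age_increment"] * 5 + 77  # years instead of class
        rec2 = dementia_logistic(x, scaled)
        assert rec1.statistic == pytest.approx(rec2.statistic, abs=1e-6)


# --------------------------------------------------------------------------
# OLS


class TestPathologyOLS:
    def test_exact_linear_relationship_recovered(self, rng):
        n = 50
        subjects = _subjects(n, rng)
        x = pd.Series(rng.normal(size=n) + 5, index=subjects.index)
        y = pd.Series(2.5 * x.to_numpy() + 1.0, index=subjects.index, name="ptau_ng_mg")
        rec = pathology_ols(x, y, subjects, transform="never")
        assert rec.coefficient == pytest.approx(2.5, abs=1e-8)
        assert rec.p_raw < 1e-20

    def test_t_statistic_matches_normal_equations(self, rng):
        # closed-form (X'X)^-1 computation on a fixed 30 x 4 design
        n = 30
        subjects = _subjects(n, rng)
        x = pd.Series(rng.normal(size=n), index=subjects.index)
        y = pd.Series(rng.normal(size=n) + 0.4 * x.to_numpy(), index=subjects.index, name="y")
        rec = pathology_ols(x, y, subjects, transform="never")
        X = np.column_stack(
            [np.ones(n), x, subjects["age_increment"], subjects["apoe4"], subjects["tbi"]]
        )
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ y.to_numpy()
        resid = y.to_numpy() - X @ beta
        s2 = resid @ resid / (n - X.shape[1])
        t = beta[1] / np.sqrt(s2 * xtx_inv[1, 1])
        assert rec.statistic == pytest.approx(t, abs=1e-10)

    def test_skewed_outcome_triggers_log_transform(self, rng):
        n = 80
        subjects = _subjects(n, rng)
        x = pd.Series(rng.normal(size=n), index=subjects.index)
        y = pd.Series(np.exp(rng.normal(size=n) * 1.5), index=subjects.index, name="ab40")
        rec = pathology_ols(x, y, subjects, transform="auto")
        assert rec.log_transformed

    def test_symmetric_outcome_not_transformed(self, rng):
        n = 80
        subjects = _subjects(n, rng)
        x = pd.Series(rng.normal(size=n), index=subjects.index)
        y = pd.Series(rng.normal(size=n) + 10, index=subjects.index, name="y")
        rec = pathology_ols(x, y, subjects, transform="auto")
        assert not rec.log_transformed

    def test_too_few_observations_is_error(self, rng):
        subjects = _subjects(4, rng)
        x = pd.Series(rng.normal(size=4), index=subjects.index)
        y = pd.Series(rng.normal(size=4), index=subjects.index, name="y")
        with pytest.raises(ValueError):
            pathology_ols(x, y, subjects)

    def test_null_pvalues_uniform(self, rng):
        n = 60
        subjects = _subjects(n, rng)
        pvals = []
        for _ in range(200):
            x = pd.Series(rng.normal(size=n), index=subjects.index)
            y = pd.Series(rng.normal(size=n), index=subjects.index, name="y")
            pvals.append(pathology_ols(x, y, subjects, transform="never").p_raw)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestInteractionContrast:
    def test_equal_slopes_give_small_t(self, rng):
        for _ in range(20):
            n = 100
            dem = rng.random(n) < 0.5
            subjects = _subjects(n, rng, dementia=dem)
            x = pd.Series(rng.normal(size=n), index=subjects.index)
            y = pd.Series(1.0 * x.to_numpy() + rng.normal(size=n), index=subjects.index, name="y")
            rec = interaction_contrast(x, y, subjects, transform="never")
            assert abs(rec.statistic) < 4.5  # null interaction, generous guard

    def test_slope_difference_detected(self, rng):
        hits = 0
        for _ in range(50):
            n = 100
            dem = rng.random(n) < 0.5
            subjects = _subjects(n, rng, dementia=dem)
            x = rng.normal(size=n)
            slope = np.where(dem, 1.0, 0.0)
            y = pd.Series(slope * x + rng.normal(size=n), index=subjects.index, name="y")
            rec = interaction_contrast(
                pd.Series(x, index=subjects.index), y, subjects, transform="never"
            )
            hits += rec.p_raw < 0.05
        assert hits >= 40  # >= 80% power

    def test_label_swap_flips_sign(self, rng):
        n = 80
        dem = rng.random(n) < 0.5
        subjects = _subjects(n, rng, dementia=dem)
        x = pd.Series(rng.normal(size=n), index=subjects.index)
        y = pd.Series(
            np.where(dem, 1.5, 0.2) * x.to_numpy() + rng.normal(size=n),
            index=subjects.index,
            name="y",
        )
        rec1 = interaction_contrast(x, y, subjects, transform="never")
        flipped = subjects.copy()
        flipped["dementia"] = 1.0 - flipped["dementia"]
        rec2 = interaction_contrast(x, y, flipped, transform="never")
        assert np.sign(rec1.statistic) == -np.sign(rec2.statistic)

    def test_single_group_is_error(self, rng):
        subjects = _subjects(30, rng, dementia=np.zeros(30, dtype=bool))
        x = pd.Series(rng.normal(size=30), index=subjects.index)
        y = pd.Series(rng.normal(size=30), index=subjects.index, name="y")
        with pytest.raises(ValueError):
            interaction_contrast(x, y, subjects)


# --------------------------------------------------------------------------
# multiple testing


def _records(pvals, regions=None):
    regions = regions or ["TCX"] * len(pvals)
    return [
        AssociationRecord(
            gene_id=f"g{i}",
            region=regions[i],
            outcome="o",
            model="ols",
            statistic=1.0,
            coefficient=1.0,
            p_raw=p,
            n=50,
        )
        for i, p in enumerate(pvals)
    ]


class TestAdjustPvalues:
    def test_single_record_identity(self):
        (rec,) = adjust_pvalues(_records([0.03]))
        assert rec.p_fdr == pytest.approx(0.03)
        assert rec.p_adj == pytest.approx(0.03)

    def test_three_p_example_matches_oracle(self):
        p = [0.01, 0.02, 0.04]
        out = adjust_pvalues(_records(p))
        bh = reference_bh(np.array(p))
        assert [r.p_fdr for r in out] == pytest.approx(list(bh))
        hs = reference_holm_sidak(np.array(p))  # all selected at q < 0.05
        assert [r.p_adj for r in out] == pytest.approx(list(hs))

    def test_all_ones_stay_one(self):
        out = adjust_pvalues(_records([1.0, 1.0, 1.0]))
        assert all(r.p_fdr == 1.0 for r in out)
        assert all(np.isnan(r.p_adj) for r in out)  # nothing selected

    def test_random_vectors_match_enumeration_oracle(self, rng):
        for _ in range(50):
            m = int(rng.integers(2, 25))
            p = rng.random(m) ** 2
            regions = [["TCX", "HIP", "PCX"][i] for i in rng.integers(0, 3, m)]
            out = adjust_pvalues(_records(list(p), regions))
            bh = reference_bh(p)
            assert [r.p_fdr for r in out] == pytest.approx(list(bh), abs=1e-12)
            selected = bh < 0.05
            for region in set(regions):
                idx = [i for i in range(m) if regions[i] == region and selected[i]]
                if not idx:
                    continue
                hs = reference_holm_sidak(p[idx])
                assert [out[i].p_adj for i in idx] == pytest.approx(list(hs), abs=1e-12)
            for i in range(m):
                if not selected[i]:
                    assert np.isnan(out[i].p_adj)

    def test_p_adj_not_below_p_raw(self, rng):
        out = adjust_pvalues(_records(list(rng.random(30) * 0.05)))
        for r in out:
            if np.isfinite(r.p_adj):
                assert r.p_adj >= r.p_raw - 1e-12

    def test_flagged_records_pass_through(self):
        recs = _records([0.01, 0.02])
        recs[1].p_raw = np.nan
        out = adjust_pvalues(recs)
        assert np.isnan(out[1].p_fdr)
        assert np.isfinite(out[0].p_fdr)

    def test_empty_input(self):
        assert adjust_pvalues([]) == []


# --------------------------------------------------------------------------
# dichotomization / validation / demographics / diagnostics


class TestDichotomize:
    @pytest.mark.parametrize(
        "braak,expected", [(5, 1.0), (6, 1.0), (4, 0.0), (0, 0.0)]
    )
    def test_braak_threshold(self, braak, expected):
        frame = pd.DataFrame({"braak": [braak], "neuritic_plaque_score": [0], "caa_score": [0]})
        assert dichotomize_pathology(frame)["braak_state"].iloc[0] == expected

    def test_caa_and_plaques_at_three(self):
        frame = pd.DataFrame(
            {"braak": [0, 0], "neuritic_plaque_score": [3, 2], "caa_score": [3, 2]}
        )
        flags = dichotomize_pathology(frame)
        assert list(flags["plaque_state"]) == [1.0, 0.0]
        assert list(flags["caa_state"]) == [1.0, 0.0]

    def test_missing_score_gives_missing_flag(self):
        frame = pd.DataFrame({"braak": [np.nan], "neuritic_plaque_score": [1], "caa_score": [1]})
        assert np.isnan(dichotomize_pathology(frame)["braak_state"].iloc[0])

    def test_custom_rule(self):
        frame = pd.DataFrame({"braak": [4], "neuritic_plaque_score": [0], "caa_score": [0]})
        flags = dichotomize_pathology(frame, PathologyStateRule(braak=4))
        assert flags["braak_state"].iloc[0] == 1.0


class TestValidationLogistic:
    def test_label_swap_flips_z(self, rng):
        n = 40
        y = rng.random(n) < 0.5
        x = pd.Series(rng.normal(size=n) + y, index=[f"S{i}" for i in range(n)])
        yb = pd.Series(y.astype(float), index=x.index)
        z1 = validation_logistic(x, yb).statistic
        z2 = validation_logistic(x, 1.0 - yb).statistic
        assert np.sign(z1) == -np.sign(z2)

    def test_constant_measure_degenerate(self, rng):
        n = 30
        y = pd.Series((rng.random(n) < 0.5).astype(float), index=[f"S{i}" for i in range(n)])
        rec = validation_logistic(pd.Series(np.ones(n), index=y.index), y)
        assert rec.flag == "degenerate"

    def test_known_effect_directionally_correct(self, rng):
        correct = 0
        for _ in range(30):
            n = 30
            y = rng.random(n) < 0.5
            x = pd.Series(rng.normal(size=n) + 1.5 * y, index=[f"S{i}" for i in range(n)])
            rec = validation_logistic(x, pd.Series(y.astype(float), index=x.index))
            correct += (not rec.flag) and rec.statistic > 0
        assert correct >= 27  # >= 90%


class TestDemographics:
    def test_identical_groups(self):
        a = [1, 2, 3, 4, 5, 6, 7, 8]
        res = demographics_test(a, a)
        assert res.u_statistic == len(a) ** 2 / 2
        assert res.p_value > 0.9

    def test_fully_separated_groups(self):
        res = demographics_test([1, 2, 3], [10, 11, 12])
        assert res.u_statistic in (0.0, 9.0)
        assert res.p_value < 0.2

    def test_u_matches_exhaustive_enumeration(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        res = demographics_test(a, b)
        u = sum(
            1.0 if ai > bj else (0.5 if ai == bj else 0.0) for ai in a for bj in b
        )
        assert res.u_statistic == pytest.approx(u)

    def test_quartiles_reported(self, rng):
        a = np.arange(1, 9, dtype=float)
        res = demographics_test(a, a + 1)
        assert res.median_a == 4.5
        assert res.quartiles_a == (pytest.approx(2.75), pytest.approx(6.25))


class TestModelDiagnostics:
    def _fit(self, x, y):
        import statsmodels.api as sm

        X = sm.add_constant(x)
        return sm.OLS(y, X).fit()

    def test_duplicated_balanced_design_no_flags(self):
        # every point has an exact twin and deviations are bounded, so no
        # observation can dominate the fit
        x = np.repeat(np.tile(np.array([1.0, 2.0, 3.0, 4.0]), 5), 2)
        wiggle = np.tile([0.01, -0.01], 20)
        y = 2 * x + wiggle
        res = model_diagnostics(self._fit(x, y))
        assert not res.flagged.any()

    def test_gross_outlier_has_max_cooks_d(self, rng):
        x = rng.normal(size=30)
        y = x + 0.1 * rng.normal(size=30)
        y[7] += 20.0
        res = model_diagnostics(self._fit(x, y))
        assert res.cooks_distance.argmax() == 7
        assert res.flagged[7]

    def test_cooks_d_matches_leave_one_out_refit(self, rng):
        import statsmodels.api as sm

        n = 25
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)
        fit = self._fit(x, y)
        res = model_diagnostics(fit)
        X = sm.add_constant(x)
        p = X.shape[1]
        s2 = fit.mse_resid
        yhat = fit.fittedvalues
        for i in range(n):  # refit-without-i oracle
            mask = np.arange(n) != i
            fit_i = sm.OLS(y[mask], X[mask]).fit()
            yhat_i = X @ fit_i.params
            d_i = np.sum((yhat - yhat_i) ** 2) / (p * s2)
            assert res.cooks_distance[i] == pytest.approx(d_i, abs=1e-10)
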