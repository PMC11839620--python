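"""Survival coding, Cox partial-likelihood fitting and model comparison."""
import numpy as np
import pandas as pd
import pytest

from seedfit.io import PhenotypeTable
from seedfit.simulate import SimConfig, simulate_all
from seedfit.survival import (code_survival, fit_cox, fit_model_set,
                              km_by_group, model_table)


def _phen(status_rows):
    """PhenotypeTable from {sid: [status per census]}."""
    surv = [(sid, t + 1, 30 * (t + 1), s)
            for sid, statuses in status_rows.items()
            for t, s in enumerate(statuses)]
    ids = list(status_rows)
    return PhenotypeTable(
        seedlings=pd.DataFrame({"seedling_id": ids, "mother_id": "M",
                                "seed_weight": 1.0}),
        survival=pd.DataFrame(surv, columns=["seedling_id", "census", "day",
                                             "status"]),
        heights=pd.DataFrame(columns=["seedling_id", "day", "height_cm"]))


class TestCoding:
    def test_death_at_first_dead_census(self):
        rec = code_survival(_phen({"s1": [0, 0, 1, 1]}))
        assert rec.iloc[0]["time"] == 3 and rec.iloc[0]["event"] == 1

    def test_alive_throughout_is_censored(self):
        rec = code_survival(_phen({"s1": [0, 0, 0, 0, 0]}))
        assert rec.iloc[0]["time"] == 5 and rec.iloc[0]["event"] == 0

    def test_resurrection_rejected(self):
        with pytest.raises(ValueError, match="s1"):
            code_survival(_phen({"s1": [0, 1, 0, 1]}))


def _toy_data():
    """5 observations, distinct event times, one informative covariate."""
    records = pd.DataFrame({
        "seedling_id": list("abcde"),
        "time": [2, 3, 5, 7, 9],
        "event": [1, 1, 0, 1, 1]})
    cov = pd.DataFrame({"seedling_id": list("abcde"),
                        "qdis": [0.9, 0.1, 0.5, 0.3, 0.05],
                        "w": [1.0, 1.2, 0.8, 1.1, 0.9],
                        "r": [0.0, 0.5, 0.0, 0.25, 0.0]})
    return records, cov


def _toy_data10():
    """10 observations; large enough for stable two-covariate fits."""
    n = 10
    records = pd.DataFrame({
        "seedling_id": [f"s{i}" for i in range(n)],
        "time": [2, 3, 5, 7, 9, 4, 6, 8, 10, 11],
        "event": [1, 1, 0, 1, 1, 1, 0, 1, 1, 0]})
    cov = pd.DataFrame({
        "seedling_id": [f"s{i}" for i in range(n)],
        "qdis": [0.9, 0.1, 0.5, 0.3, 0.05, 0.6, 0.2, 0.4, 0.7, 0.15],
        "w": [1.0, 1.2, 0.8, 1.1, 0.9, 1.3, 0.95, 1.05, 0.85, 1.15],
        "r": [0.0, 0.5, 0.0, 0.25, 0.0, 0.1, 0.0, 0.3, 0.05, 0.2]})
    return records, cov


def _oracle_partial_loglik(beta, times, events, x):
    """Independent textbook implementation (no ties in the toy data)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * np.array(x)[risk])))
    return ll


class TestCoxFit:
    def test_null_model_is_pure_deviance(self):
        records, cov = _toy_data()
        fit = fit_cox(records, cov, ())
        assert fit.df == 0
        assert fit.aic == pytest.approx(fit.deviance)
        assert fit.deviance == pytest.approx(-2 * fit.log_partial_lik)

    def test_matches_grid_search_oracle(self):
        records, cov = _toy_data()
        fit = fit_cox(records, cov, ("qdis",))
        grid = np.linspace(-10, 10, 200001)
        lls = [_oracle_partial_loglik(b, records["time"].to_numpy(),
                                      records["event"].to_numpy(),
                                      cov["qdis"].to_numpy()) for b in grid]
        b_star = grid[int(np.argmax(lls))]
        assert fit.coef[0] == pytest.approx(b_star, abs=1e-4)

    def test_gradient_vanishes_at_optimum(self):
        from seedfit.survival import _pl_grad_hess

        records, cov = _toy_data10()
        fit = fit_cox(records, cov, ("qdis", "w"))
        df = records.merge(cov, on="seedling_id")
        _, grad, _ = _pl_grad_hess(fit.coef, df[["qdis", "w"]].to_numpy(float),
                                   df["time"].to_numpy(float),
                                   df["event"].to_numpy(int), "efron")
        assert np.abs(grad).max() < 1e-6

    def test_tie_methods_agree_without_ties(self):
        records, cov = _toy_data()
        fe = fit_cox(records, cov, ("qdis",), ties="efron")
        fb = fit_cox(records, cov, ("qdis",), ties="breslow")
        assert fe.coef[0] == pytest.approx(fb.coef[0], abs=1e-8)
        assert fe.se[0] == pytest.approx(fb.se[0], abs=1e-8)

    def test_covariate_order_does_not_leak(self):
        records, cov = _toy_data10()
        f1 = fit_cox(records, cov, ("qdis", "w"))
        f2 = fit_cox(records, cov, ("w", "qdis"))
        assert f1.coef[0] == pytest.approx(f2.coef[1], abs=1e-10)
        assert f1.coef[1] == pytest.approx(f2.coef[0], abs=1e-10)

    def test_qdis_and_fdis_are_mutually_exclusive(self):
        records, cov = _toy_data()
        cov = cov.assign(fdis=cov["qdis"] / 10)
        with pytest.raises(ValueError, match="separately"):
            fit_cox(records, cov, ("qdis", "fdis"))

    def test_matches_lifelines_on_synthetic_cohort(self, small_study):
        """Independent cross-check against lifelines (Efron ties)."""
        from lifelines import CoxPHFitter

        phen = small_study["phen"]
        cov = small_study["truth"].covariates
        records = code_survival(phen)
        fit = fit_cox(records, cov, ("qdis", "w"))
        df = records.merge(cov, on="seedling_id")[["time", "event",
                                                   "qdis", "w"]]
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        assert fit.coef[0] == pytest.approx(cph.params_["qdis"], abs=1e-4)
        assert fit.coef[1] == pytest.approx(cph.params_["w"], abs=1e-4)
        assert fit.se[0] == pytest.approx(
            cph.standard_errors_["qdis"], abs=1e-4)
        assert fit.log_partial_lik == pytest.approx(
            cph.log_likelihood_, abs=1e-6)

    def test_effect_recovery_single_replicate(self):
        cfg = SimConfig(rng_seed=31)
        _, _, phen, truth = simulate_all(cfg)
        records = code_survival(phen)
        fit = fit_cox(records, truth.covariates, ("qdis",))
        assert fit.coef[0] < 0
        assert abs(fit.coef[0] - (-3.4)) <= 2 * fit.se[0]


class TestModelTable:
    def test_nested_models_never_fit_worse(self):
        records, cov = _toy_data10()
        small = fit_cox(records, cov, ("qdis",))
        large = fit_cox(records, cov, ("qdis", "w"))
        assert large.deviance <= small.deviance + 1e-9
        tab = model_table([small, large])
        assert tab["best"].sum() == 1

    def test_single_fit_flagged_minimal(self):
        records, cov = _toy_data()
        tab = model_table([fit_cox(records, cov, ("w",))])
        assert len(tab) == 1 and bool(tab["best"].iloc[0])

    def test_mismatched_records_rejected(self):
        records, cov = _toy_data()
        other = records.copy()
        other.loc[0, "time"] = 4
        f1 = fit_cox(records, cov, ("w",))
        f2 = fit_cox(other, cov, ("w",))
        with pytest.raises(ValueError):
            model_table([f1, f2])

    def test_model_family_prefers_true_covariate(self):
        cfg = SimConfig(rng_seed=33)
        _, _, phen, truth = simulate_all(cfg)
        records = code_survival(phen)
        fits, tab = fit_model_set(records, truth.covariates,
                                  statistic="qdis")
        aic_w = tab.loc[tab["model"].eq(2), "AIC"].iloc[0]   # {w}
        best_row = tab.loc[tab["best"]]
        assert "qdis" in str(best_row.drop(columns=["model"]).notna()
                             .idxmax(axis=1).iloc[0]) or \
            best_row["qdis"].notna().all()
        aic_wq = tab.loc[tab["qdis"].notna() & tab["w"].notna(), "AIC"].min()
        assert aic_wq < aic_w


class TestKaplanMeier:
    def test_distinct_events_drop_one_over_n(self):
        records = pd.DataFrame({"seedling_id": list("abcd"),
                                "time": [1, 2, 3, 4],
                                "event": [1, 1, 1, 1]})
        cov = pd.DataFrame({"seedling_id": list("abcd"),
                            "qdis": [0.5] * 4})
        curves = km_by_group(records, cov, "qdis", cuts=(0.1, 0.9))
        assert list(curves) == ["2"]
        surv = curves["2"]["survival"].to_numpy()
        assert np.allclose(surv, [1.0, 0.75, 0.5, 0.25, 0.0])

    def test_no_events_flat_at_one(self):
        records = pd.DataFrame({"seedling_id": list("ab"),
                                "time": [5, 5], "event": [0, 0]})
        cov = pd.DataFrame({"seedling_id": list("ab"), "qdis": [0.2, 0.2]})
        with pytest.warns(UserWarning):
            curves = km_by_group(records, cov, "qdis")
        assert (curves["2"]["survival"] == 1.0).all()

    def test_protective_effect_orders_groups(self, default_study):
        phen = default_study["phen"]
        cov = default_study["truth"].covariates
        records = code_survival(phen)
        curves = km_by_group(records, cov, "qdis")
        finals = {g: sf["survival"].iloc[-1] for g, sf in curves.items()}
        assert finals["3"] > finals["2"] > finals["1"]
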