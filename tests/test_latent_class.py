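"""Latent-class survival model: EM correctness, oracles, invariants."""

import numpy as np
import pytest
from scipy.optimize import minimize

from flimlca.latent_class import (_class_loglik, _event_time_cuts, _exposure,
                                  class_proportion, ClassAssignment,
                                  fit_latent_class_model, hazard_ratios,
                                  select_model)
from flimlca.preprocess import build_design
from flimlca.synthetic import coin_os_spec, simulate_cohort

from conftest import COVARIATES, single_class_spec


def _direct_k1_loglik(cohort, covariates, n_bins):
    """Independent oracle: direct quasi-Newton maximization of the K=1
    piecewise-exponential PH likelihood."""
    X, _ = build_design(cohort.table, covariates)
    cuts = _event_time_cuts(cohort.time, cohort.event, n_bins)
    expo, ev = _exposure(cohort.time, cohort.event, cuts)
    B, p = cuts.size, X.shape[1]

    def neg(theta):
        return -_class_loglik(expo, ev, X, theta[:B], theta[B:]).sum()

    th0 = np.concatenate([np.full(B, np.log(cohort.event.mean()
                                            / cohort.time.mean())), np.zeros(p)])
    res = minimize(neg, th0, method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-10})
    return -res.fun


@pytest.mark.parametrize("seed", [11, 12])
def test_k1_fit_matches_direct_maximization(seed):
    cohort = simulate_cohort(coin_os_spec(n_patients=400, seed=seed))
    model, _ = fit_latent_class_model(cohort, COVARIATES, k=1, n_bins=4,
                                      seed=0, tol=1e-12, max_iter=5000,
                                      compute_se=False)
    oracle = _direct_k1_loglik(cohort, COVARIATES, 4)
    assert model.log_likelihood == pytest.approx(oracle, abs=1e-6)


def test_k1_no_covariates_baseline_is_events_over_persontime():
    cohort = simulate_cohort(single_class_spec(500, seed=3, p_covariates=4))
    model, _ = fit_latent_class_model(cohort, [], k=1, n_bins=4, seed=0,
                                      tol=1e-12, compute_se=False)
    cuts = model.cut_points
    expo, ev = _exposure(cohort.time, cohort.event, cuts)
    closed_form = ev.sum(axis=0) / expo.sum(axis=0)
    np.testing.assert_allclose(model.baseline_rates[0], closed_form, rtol=1e-10)


def test_loglik_monotone_and_membership_rows_sum_to_one(coin_cohort):
    model, assignment = fit_latent_class_model(coin_cohort, COVARIATES, k=2,
                                               n_bins=4, n_restarts=2, seed=3,
                                               compute_se=False)
    hist = np.array(model.metadata["loglik_history"])
    assert (np.diff(hist) >= -1e-7 * (np.abs(hist[:-1]) + 1)).all()
    np.testing.assert_allclose(assignment.membership.sum(axis=1), 1.0,
                               atol=1e-10)
    np.testing.assert_array_equal(
        assignment.map_label, np.argmax(assignment.membership, axis=1) + 1)


def test_class_one_is_best_prognosis(recovery_cohort):
    model, _ = fit_latent_class_model(recovery_cohort, COVARIATES, k=2,
                                      n_bins=4, n_restarts=3, seed=1,
                                      compute_se=False)
    med = model.metadata["model_implied_medians"]
    assert med[0] >= med[1]


def test_recovery_on_inflated_separation_preset(recovery_cohort):
    model, assignment = fit_latent_class_model(recovery_cohort, COVARIATES,
                                               k=2, n_bins=4, n_restarts=4,
                                               seed=2, compute_se=False)
    truth = recovery_cohort.true_class
    acc = (assignment.map_label == truth).mean()
    assert acc >= 0.85
    assert model.mixing_weights[0] == pytest.approx(0.156, abs=0.06)


def test_missing_covariates_imputed_with_indicator(coin_cohort):
    table = coin_cohort.table.copy()
    table.loc[table.index[:40], "fret"] = np.nan
    from flimlca.cohort import Cohort
    cohort = Cohort(table)
    model, _ = fit_latent_class_model(cohort, COVARIATES, k=1, n_bins=3,
                                      seed=0, compute_se=False)
    assert "fret_missing" in model.design_names


def test_zero_events_rejected(coin_cohort):
    from flimlca.cohort import Cohort
    table = coin_cohort.table.copy()
    table["event"] = 0
    with pytest.raises(ValueError, match="events"):
        fit_latent_class_model(Cohort(table), COVARIATES, k=1)


def test_hazard_ratio_report_invariants(recovery_cohort):
    model, _ = fit_latent_class_model(recovery_cohort, COVARIATES, k=2,
                                      n_bins=4, n_restarts=3, seed=1)
    report = hazard_ratios(model)
    ok = report[report["flags"] == ""]
    assert (ok["hr"] > 0).all()
    assert ((ok["ci_low"] <= ok["hr"]) & (ok["hr"] <= ok["ci_high"])).all()


def test_class_proportion_percentages():
    # the trial's printed splits: 62/398 -> 15.6%, 44/398 -> 11.1%
    for count, pct in ((62, 15.6), (44, 11.1)):
        member = np.zeros((398, 2))
        member[:count, 0] = 1.0
        member[count:, 1] = 1.0
        assign = ClassAssignment(membership=member,
                                 map_label=np.argmax(member, axis=1) + 1)
        table = class_proportion(assign)
        assert round(table.loc[0, "percent"], 1) == pct

    single = ClassAssignment(membership=np.ones((5, 1)),
                             map_label=np.ones(5, dtype=int))
    assert class_proportion(single).loc[0, "percent"] == 100.0


def test_select_model_grid_metadata(coin_cohort):
    model = select_model(coin_cohort, COVARIATES, k_candidates=(1, 2),
                         bins_candidates=(3,), seed=0, n_restarts=2,
                         compute_se=False)
    grid = model.metadata["selection_grid"]
    assert len(grid) == 2
    bics = [g["bic"] for g in grid if not g["failed"]]
    assert model.bic == pytest.approx(min(bics))
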