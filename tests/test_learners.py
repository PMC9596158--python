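import numpy as np
import pandas as pd
import pytest

from consurv.cohorts import standardize
from consurv.coxph import fit_cox
from consurv.evaluation import harrell_cindex
from consurv.learners import (ENET_ALPHAS, AlgorithmSpec, CVPlan,
                              FittedLearner, LearnerError, SelectorEmptyError,
                              fit_learner, load_learner, predict_scores,
                              save_learner, select_features, spec_from_label)
from conftest import make_cohort

CV = CVPlan(folds=10, seed=7)

FAST_GRIDS = {
    "LASSO": {"n_lambda": 20},
    "Ridge": {"n_lambda": 10},
    "Enet": {"n_lambda": 10},
    "CoxBoost": {"steps": list(range(0, 51, 10))},
    "GBM": {"n_estimators": [50]},
    "RSF": {"n_estimators": [80]},
    "SuperPC": {"threshold_quantiles": [0.0, 0.5]},
    "SurvSVM": {},
    "plsRcox": {},
    "StepCox": {},
}


def _fit(label, cohort, cv=CV):
    spec = spec_from_label(label)
    spec = AlgorithmSpec(spec.family, spec.params, FAST_GRIDS[spec.family])
    return fit_learner(spec, cohort, cv)


def test_spec_validation():
    with pytest.raises(LearnerError):
        AlgorithmSpec("Enet", {"alpha": 1.5})
    with pytest.raises(LearnerError):
        AlgorithmSpec("StepCox", {"direction": "sideways"})
    with pytest.raises(LearnerError):
        AlgorithmSpec("NotAFamily")
    assert AlgorithmSpec("RSF").can_select
    assert not AlgorithmSpec("GBM").can_select
    assert len(ENET_ALPHAS) == 9


def test_lasso_huge_lambda_empty_selection(medium_train_cohort):
    train, _, _ = medium_train_cohort
    spec = AlgorithmSpec("LASSO", grid={"n_lambda": 1})
    # a single-lambda grid at lambda_max zeroes everything
    fl = fit_learner(spec, train, CV)
    assert all(b == 0 for b in fl.state["fitted"]["beta"])
    with pytest.raises(SelectorEmptyError):
        select_features(fl)


def test_lasso_lambda_zero_matches_newton(medium_train_cohort):
    """Coordinate descent at lambda = 0 is the unpenalized MLE."""
    train, _, _ = medium_train_cohort
    sub = train.subset_genes(["g00000", "g00001", "g00002"])
    from consurv._solvers import fit_coxnet

    x = sub.expr.T.to_numpy()
    t = sub.surv["time"].to_numpy()
    e = sub.surv["event"].to_numpy()
    beta = fit_coxnet(x, t, e, lam=0.0, alpha=1.0)
    mle = fit_cox(x, sub.surv, ties="breslow")
    assert np.max(np.abs(beta - mle.beta)) < 1e-4


def test_coxboost_step_structure(medium_train_cohort):
    train, _, _ = medium_train_cohort
    from consurv._solvers import fit_coxboost

    x = train.expr.T.to_numpy()
    t = train.surv["time"].to_numpy()
    e = train.surv["event"].to_numpy()
    assert np.count_nonzero(fit_coxboost(x, t, e, 0)) == 0
    assert np.count_nonzero(fit_coxboost(x, t, e, 1)) == 1


def test_coxboost_unpenalized_converges_to_mle(medium_train_cohort):
    train, _, _ = medium_train_cohort
    sub = train.subset_genes(["g00000", "g00003"])
    from consurv._solvers import fit_coxboost

    x = sub.expr.T.to_numpy()
    t = sub.surv["time"].to_numpy()
    e = sub.surv["event"].to_numpy()
    beta = fit_coxboost(x, t, e, n_steps=3000, penalty=0.0)
    mle = fit_cox(x, sub.surv, ties="breslow")
    assert np.max(np.abs(beta - mle.beta)) < 1e-2


def test_survsvm_perfect_gene_gives_cindex_one():
    """One gene perfectly orders uncensored survival times."""
    n = 100
    rng = np.random.default_rng(2)
    time = np.sort(rng.exponential(5, n)) + 0.01
    g = np.linspace(-1, 1, n)  # higher value -> longer survival
    expr = pd.DataFrame({f"s{i}": [g[i]] for i in range(n)}, index=["gA"])
    surv = pd.DataFrame({"time": time, "event": np.ones(n, dtype=int)},
                        index=expr.columns)
    from consurv.cohorts import Cohort

    cohort = standardize(Cohort(name="p", role="training", expr=expr, surv=surv))
    fl = _fit("SurvSVM", cohort)
    s = predict_scores(fl, cohort.expr)
    risk = -s if fl.orientation == "higher_is_protective" else s
    c, _ = harrell_cindex(risk.to_numpy(), cohort.surv)
    assert c == pytest.approx(1.0)


def test_rsf_on_pure_noise_selects_few_genes():
    cohort = standardize(make_cohort(n=150, genes=tuple(f"g{i:02d}" for i in range(50)),
                                     seed=3, censor=0.3))
    spec = AlgorithmSpec("RSF", grid={"n_estimators": [150]})
    fl = fit_learner(spec, cohort, CVPlan(folds=10, seed=3))
    assert len(fl.selected_genes) < 10  # < 20% of 50


def test_stepcox_recovers_signal_gene():
    cohort = standardize(make_cohort(
        n=300, genes=("gene1", "gene2", "gene3", "gene4"), seed=5,
        beta={"gene1": 1.0}, censor=0.2, name="sc"))
    fl = _fit("StepCox[both]", cohort)
    assert "gene1" in select_features(fl)
    null_aic = -2.0 * fit_cox(np.zeros((cohort.n_samples, 1)), cohort.surv).null_loglik
    assert fl.state["fitted"]["aic"] < null_aic


def test_predict_linear_is_dot_product(medium_train_cohort):
    train, test, _ = medium_train_cohort
    fl = _fit("Ridge", train)
    beta = fl.state["fitted"]["beta"]
    s = predict_scores(fl, test.expr)
    manual = beta @ test.expr.loc[list(fl.genes_used)].to_numpy()
    assert np.allclose(s.to_numpy(), manual, atol=1e-12)


def test_predict_training_duplicate_and_missing_gene(medium_train_cohort):
    train, _, _ = medium_train_cohort
    fl = _fit("CoxBoost", train)
    s1 = predict_scores(fl, train.expr)
    s2 = predict_scores(fl, train.expr[train.samples[:3]])
    assert np.allclose(s1.to_numpy()[:3], s2.to_numpy())
    with pytest.raises(LearnerError, match="g00000"):
        predict_scores(fl, train.expr.drop(index="g00000"))


def test_select_features_order_and_errors(medium_train_cohort):
    train, _, _ = medium_train_cohort
    fl = _fit("LASSO", train)
    sel = select_features(fl)
    beta = dict(zip(fl.genes_used, fl.state["fitted"]["beta"]))
    mags = [abs(beta[g]) for g in sel]
    assert mags == sorted(mags, reverse=True)
    gbm = _fit("GBM", train)
    with pytest.raises(LearnerError, match="not a selector"):
        select_features(gbm)


def test_selection_tie_breaks_lexicographically():
    from consurv.learners import _order_genes

    assert _order_genes(["gB", "gA"], np.array([0.5, 0.5])) == ("gA", "gB")


@pytest.mark.parametrize("label", [
    "RSF", "LASSO", "Ridge", "Enet[a=0.5]", "GBM", "SurvSVM", "SuperPC",
    "plsRcox", "CoxBoost", "StepCox[both]"])
def test_orientation_and_determinism_all_families(label, medium_train_cohort):
    """Oriented scores beat chance on planted-signal data, and refitting with
    the same CV plan reproduces identical scores."""
    train, test, _ = medium_train_cohort
    fl = _fit(label, train)
    s = predict_scores(fl, test.expr)
    risk = -s if fl.orientation == "higher_is_protective" else s
    c, _ = harrell_cindex(risk.to_numpy(), test.surv)
    assert c > 0.5
    fl2 = _fit(label, train)
    s2 = predict_scores(fl2, test.expr)
    assert np.array_equal(s.to_numpy(), s2.to_numpy())


def test_lasso_path_nonzeros_monotone(medium_train_cohort):
    train, _, _ = medium_train_cohort
    from consurv._solvers import fit_coxnet_path

    x = train.expr.T.to_numpy()
    lams, betas = fit_coxnet_path(x, train.surv["time"].to_numpy(),
                                  train.surv["event"].to_numpy(), alpha=1.0,
                                  n_lambda=50)
    nz = (np.abs(betas) > 0).sum(axis=1)
    assert np.all(np.diff(nz) >= 0)  # lambda descending -> support grows


def test_cv_folds_partition(medium_train_cohort):
    train, _, _ = medium_train_cohort
    from consurv.learners import _cv_folds

    folds = _cv_folds(train.n_samples, train.surv["event"].to_numpy(),
                      CVPlan(folds=10, seed=1))
    all_val = np.concatenate([va for _, va in folds])
    assert sorted(all_val) == list(range(train.n_samples))
    for tr, va in folds:
        assert set(tr).isdisjoint(va)


@pytest.mark.parametrize("label", ["LASSO", "RSF", "SuperPC", "plsRcox"])
def test_save_load_round_trip(label, medium_train_cohort, tmp_path):
    train, test, _ = medium_train_cohort
    fl = _fit(label, train)
    save_learner(fl, tmp_path / "m")
    fl2 = load_learner(tmp_path / "m")
    assert np.array_equal(predict_scores(fl, test.expr).to_numpy(),
                          predict_scores(fl2, test.expr).to_numpy())
    assert fl2.selected_genes == fl.selected_genes
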