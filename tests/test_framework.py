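import numpy as np
import pandas as pd
import pytest

from consurv.cohorts import MultiCohort, standardize, standardize_all
from consurv.framework import (CombinationSpec, FrameworkError, LeaderboardRow,
                               build_leaderboard, enumerate_combinations,
                               run_combination, run_sweep, score_and_stratify)
from consurv.learners import AlgorithmSpec, CVPlan, spec_from_label
from consurv.simulate import SimConfig, simulate_multicohort

CV = CVPlan(folds=10, seed=13)

FAST = {"LASSO": {"n_lambda": 15}, "Ridge": {"n_lambda": 10}}


@pytest.fixture(scope="module")
def small_sweep_data():
    planted = {f"g{i:05d}": b for i, b in
               zip(range(5), [0.6, -0.5, 0.5, -0.45, 0.4])}
    cfg = SimConfig(K=4, n_per_cohort=150, G=30, planted=planted,
                    block_corr=0.0, censor_target=0.25, seed=23)
    mc, _ = simulate_multicohort(cfg)
    mcs = standardize_all(mc)
    return mcs.cohorts[0], mcs.cohorts[1:], list(mc.shared_genes)


def test_default_roster_has_76_combinations():
    combos = enumerate_combinations("default")
    assert len(combos) == 76
    labels = [c.label for c in combos]
    assert len(set(labels)) == 76
    assert "CoxBoost + SurvSVM" in labels  # the published winning combination
    assert "LASSO + Ridge" in labels


def test_remodel_roster_has_18_single_models():
    combos = enumerate_combinations("remodel")
    assert len(combos) == 18
    assert all(c.selector is None for c in combos)
    assert sum(c.modeler.family == "Enet" for c in combos) == 9


def test_single_pair_roster():
    roster = {"version": 1, "name": "tiny", "combinations": ["LASSO + Ridge"]}
    combos = enumerate_combinations(roster)
    assert len(combos) == 1
    assert combos[0].label == "LASSO + Ridge"


def test_non_selector_cannot_lead_a_pair():
    with pytest.raises(FrameworkError):
        CombinationSpec(selector=AlgorithmSpec("GBM"),
                        modeler=AlgorithmSpec("Ridge"))


def test_build_leaderboard_order_ties_and_errors():
    def row(label, mean, genes, status="ok"):
        return LeaderboardRow(label=label, cindex={}, mean_testing_cindex=mean,
                              n_selected_genes=genes, status=status)

    board, winner = build_leaderboard(
        [row("a", 0.70, 9), row("b", 0.68, 5), row("c", 0.66, 3)])
    assert list(board["label"][:3]) == ["a", "b", "c"] and winner == "a"
    board, winner = build_leaderboard([row("big", 0.70, 9), row("small", 0.70, 5)])
    assert winner == "small"  # tie -> fewer genes
    board, winner = build_leaderboard([row("b", 0.70, 5), row("a", 0.70, 5)])
    assert winner == "a"  # tie -> label
    with pytest.raises(FrameworkError):
        build_leaderboard([row("x", np.nan, 0, status="skipped")])


def test_run_combination_signal_and_null(small_sweep_data):
    train, testing, genes = small_sweep_data
    spec = CombinationSpec(selector=spec_from_label("LASSO", FAST["LASSO"]),
                           modeler=spec_from_label("Ridge", FAST["Ridge"]))
    row, sig = run_combination(spec, train, testing, CV, genes)
    assert row.status == "ok"
    assert row.mean_testing_cindex > 0.65
    assert row.mean_testing_cindex == pytest.approx(
        np.mean([row.cindex[c.name] for c in testing]))

    from consurv.benchmarks import permute_outcomes

    null_mc = permute_outcomes(MultiCohort(cohorts=(train, *testing),
                                           shared_genes=tuple(train.genes)), 99)
    row0, _ = run_combination(spec, null_mc.cohorts[0], null_mc.cohorts[1:],
                              CV, genes)
    assert row0.status == "ok"
    assert 0.40 <= row0.mean_testing_cindex <= 0.60


def test_empty_selection_yields_skipped_row(small_sweep_data):
    train, testing, genes = small_sweep_data
    spec = CombinationSpec(
        selector=AlgorithmSpec("LASSO", grid={"n_lambda": 1}),  # lambda_max only
        modeler=AlgorithmSpec("Ridge", grid={"n_lambda": 5}))
    row, sig = run_combination(spec, train, testing, CV, genes)
    assert row.status == "skipped"
    assert row.reason == "selector returned no genes"
    assert sig is None


def test_anti_leakage_testing_outcomes_never_touch_fitting(small_sweep_data):
    """Poisoning testing-cohort outcomes leaves the fitted signature
    (selected genes and coefficients) bit-identical."""
    train, testing, genes = small_sweep_data
    spec = CombinationSpec(selector=spec_from_label("LASSO", FAST["LASSO"]),
                           modeler=spec_from_label("Ridge", FAST["Ridge"]))
    _, sig1 = run_combination(spec, train, testing, CV, genes)
    poisoned = []
    rng = np.random.default_rng(1)
    for c in testing:
        surv = c.surv.copy()
        surv["time"] = rng.exponential(5, len(surv)) + 0.01
        surv["event"] = rng.integers(0, 2, len(surv))
        if surv["event"].sum() == 0:
            surv.iloc[0, surv.columns.get_loc("event")] = 1
        poisoned.append(type(c)(name=c.name, role=c.role, expr=c.expr,
                                surv=surv, standardized=c.standardized))
    _, sig2 = run_combination(spec, train, poisoned, CV, genes)
    assert sig1.genes == sig2.genes
    assert np.array_equal(sig1.modeler.state["fitted"]["beta"],
                          sig2.modeler.state["fitted"]["beta"])


def test_sweep_determinism_and_order_independence(small_sweep_data):
    train, testing, genes = small_sweep_data
    roster = {"version": 1, "name": "mini", "combinations":
              ["Ridge", "LASSO + Ridge", "CoxBoost"]}
    combos = enumerate_combinations(roster, grids={
        "Ridge": {"n_lambda": 8}, "LASSO": {"n_lambda": 10},
        "CoxBoost": {"steps": [0, 10, 20]}})
    rows1, _ = run_sweep(combos, train, testing, CV, genes)
    rows2, _ = run_sweep(list(reversed(combos)), train, testing, CV, genes)
    m1 = {r.label: r.mean_testing_cindex for r in rows1}
    m2 = {r.label: r.mean_testing_cindex for r in rows2}
    assert m1 == m2


def test_winner_is_argmax(small_sweep_data):
    train, testing, genes = small_sweep_data
    roster = {"version": 1, "name": "mini", "combinations":
              ["Ridge", "SurvSVM", "plsRcox", "LASSO + Ridge"]}
    combos = enumerate_combinations(roster, grids={"Ridge": {"n_lambda": 8},
                                                   "LASSO": {"n_lambda": 10}})
    rows, _ = run_sweep(combos, train, testing, CV, genes)
    board, winner = build_leaderboard(rows)
    ok = [r for r in rows if r.status == "ok"]
    assert board.iloc[0]["mean_testing_cindex"] == max(
        r.mean_testing_cindex for r in ok)


def test_score_and_stratify_median_convention(small_sweep_data):
    train, testing, genes = small_sweep_data
    spec = CombinationSpec(selector=None,
                           modeler=spec_from_label("Ridge", FAST["Ridge"]))
    _, sig = run_combination(spec, train, testing, CV, genes)

    scores, groups = score_and_stratify(sig, testing[0])
    med = np.median(scores)
    assert set(groups[scores >= med]) == {"high"}
    assert set(groups[scores < med]) == {"low"}
    n = len(scores)
    assert (groups == "high").sum() >= n // 2  # median element goes high

    from consurv.evaluation import km_logrank

    _, _, p = km_logrank(groups.to_numpy(), testing[0].surv)
    assert p < 0.05  # planted signal separates the median split


def test_stratify_constant_scores_all_high(small_sweep_data, caplog):
    train, testing, genes = small_sweep_data
    spec = CombinationSpec(selector=None,
                           modeler=spec_from_label("Ridge", FAST["Ridge"]))
    _, sig = run_combination(spec, train, testing, CV, genes)
    const = testing[0]
    expr = const.expr.copy()
    expr.loc[:, :] = 0.0
    const = type(const)(name=const.name, role=const.role, expr=expr,
                        surv=const.surv, standardized=True)
    with caplog.at_level("WARNING"):
        scores, groups = score_and_stratify(sig, const)
    assert set(groups) == {"high"}
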