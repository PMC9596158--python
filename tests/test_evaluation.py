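import numpy as np
import pandas as pd
import pytest

from consurv.cohorts import Cohort
from consurv.evaluation import (EvaluationError, ExternalSignature,
                                apply_signature, calibration_curve,
                                compare_cindex, evaluate_signature_scores,
                                harrell_cindex, km_curve, km_logrank,
                                score_to_survival_probs, time_auc)
from conftest import make_cohort


def _surv(time, event):
    return pd.DataFrame({"time": time, "event": event})


def _cindex_oracle(scores, time, event):
    """Independent O(n^2) pair enumeration (Harrell's convention)."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            usable = (time[i] < time[j] and event[i] == 1) or \
                     (time[i] == time[j] and event[i] == 1 and event[j] == 0)
            if not usable:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


def test_cindex_hand_example():
    c, se = harrell_cindex([5, 4, 3, 6], _surv([2, 4, 6, 8], [1, 1, 0, 1]))
    assert c == pytest.approx(0.6)  # 3 of 5 usable pairs concordant
    assert se == pytest.approx(np.sqrt(0.6 * 0.4 / 5))


def test_cindex_perfect_ordering():
    t = np.arange(1.0, 11.0)
    c, _ = harrell_cindex(-t, _surv(t, np.ones(10, int)))
    assert c == 1.0


def test_cindex_matches_oracle_on_200_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(4, 31))
        t = np.round(rng.exponential(5, n), 1) + 0.1
        e = rng.integers(0, 2, n)
        e[rng.integers(0, n)] = 1
        s = np.round(rng.normal(size=n), 1)
        try:
            c, _ = harrell_cindex(s, _surv(t, e))
        except EvaluationError:
            continue
        assert c == pytest.approx(_cindex_oracle(s, t, e), abs=1e-12)


def test_cindex_negation_symmetry():
    rng = np.random.default_rng(7)
    t = rng.exponential(5, 40) + 0.01
    e = rng.integers(0, 2, 40)
    e[0] = 1
    s = rng.normal(size=40)  # continuous: no ties
    c1, _ = harrell_cindex(s, _surv(t, e))
    c2, _ = harrell_cindex(-s, _surv(t, e))
    assert c1 + c2 == pytest.approx(1.0, abs=1e-12)


def test_cindex_all_censored_errors():
    with pytest.raises(EvaluationError):
        harrell_cindex([1, 2, 3], _surv([1, 2, 3.0], [0, 0, 0]))


def test_compare_cindex_identity_and_signal():
    rng = np.random.default_rng(11)
    n = 300
    x = rng.normal(size=n)
    t = rng.exponential(10 * np.exp(-1.2 * x)) + 0.01
    e = np.ones(n, int)
    surv = _surv(t, e)
    d, z, p = compare_cindex(x, x, surv)
    assert d == 0.0 and p == 1.0
    perm = rng.permutation(n)
    d, z, p = compare_cindex(x, x[perm], surv)
    assert d > 0 and p < 0.01


def test_compare_cindex_jackknife_close_to_bootstrap():
    rng = np.random.default_rng(3)
    n = 100
    x = rng.normal(size=n)
    t = rng.exponential(8 * np.exp(-0.8 * x)) + 0.01
    e = rng.integers(0, 2, n)
    e[:10] = 1
    y = x + rng.normal(scale=1.0, size=n)
    surv = _surv(t, e)
    d, z, p = compare_cindex(x, y, surv)
    se_jack = abs(d / z)
    boots = []
    for _ in range(2000):
        idx = rng.integers(0, n, n)
        sb = _surv(t[idx], e[idx])
        try:
            ca, _ = harrell_cindex(x[idx], sb)
            cb, _ = harrell_cindex(y[idx], sb)
        except EvaluationError:
            continue
        boots.append(ca - cb)
    se_boot = np.std(boots, ddof=1)
    assert se_jack / se_boot < 1.5 and se_boot / se_jack < 1.5


def test_time_auc_equals_roc_auc_without_censoring():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(5)
    for _ in range(10):
        n = 150
        t = rng.exponential(5, n) + 0.01
        s = rng.normal(size=n)
        surv = _surv(t, np.ones(n, int))
        for h in np.quantile(t, [0.3, 0.6]):
            auc = time_auc(s, surv, [h])[h]
            assert auc == pytest.approx(roc_auc_score((t <= h).astype(int), s),
                                        abs=1e-12)


def test_time_auc_monotone_transform_invariance():
    rng = np.random.default_rng(6)
    n = 200
    t = rng.exponential(5, n) + 0.01
    e = rng.integers(0, 2, n)
    e[:10] = 1
    s = rng.normal(size=n)
    surv = _surv(t, e)
    h = float(np.quantile(t, 0.5))
    a1 = time_auc(s, surv, [h])[h]
    a2 = time_auc(np.exp(s), surv, [h])[h]
    a3 = time_auc(np.log(s - s.min() + 1.0), surv, [h])[h]
    assert a1 == pytest.approx(a2, abs=1e-12)
    assert a1 == pytest.approx(a3, abs=1e-12)


def test_time_auc_signal_and_permutation():
    rng = np.random.default_rng(8)
    n = 1000
    lp = rng.normal(size=n) * 1.5
    t = 20 * (-np.log(rng.uniform(size=n)) * np.exp(-lp)) ** (1 / 1.2)
    surv = _surv(t + 1e-6, np.ones(n, int))
    hs = list(np.quantile(t, [0.25, 0.5, 0.75]))
    aucs = time_auc(lp, surv, hs)
    assert all(a > 0.80 for a in aucs.values())
    perm = time_auc(lp[rng.permutation(n)], surv, hs)
    assert all(0.45 <= a <= 0.55 for a in perm.values())


def test_time_auc_horizon_above_follow_up_errors():
    surv = _surv([1, 2, 3.0], [1, 1, 1])
    with pytest.raises(EvaluationError):
        time_auc([1, 2, 3], surv, [5.0])


def test_km_logrank_identical_groups_is_null():
    t = np.array([1, 2, 3, 4, 5.0, 6])
    e = np.array([1, 0, 1, 1, 0, 1])
    surv = _surv(np.r_[t, t], np.r_[e, e])
    g = np.array(["a"] * 6 + ["b"] * 6)
    curves, chi2, p = km_logrank(g, surv)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_km_logrank_single_event_hand_computation():
    """One event at t=1 in group A, group B censored later: O-E = 0.5 and
    chi-square = (0.5)^2 / 0.25 = 1 from the hand-enumerated 2x2 table."""
    surv = _surv([1.0, 2.0], [1, 0])
    curves, chi2, p = km_logrank(np.array(["A", "B"]), surv)
    assert chi2 == pytest.approx(1.0)


def test_km_curve_starts_at_one_non_increasing():
    c = make_cohort(n=60, seed=2)
    k = km_curve(c.surv["time"], c.surv["event"])
    assert np.all(np.diff(k.survival) <= 1e-15)
    assert k.at(-1.0) == 1.0 and k.survival[0] <= 1.0


def test_calibration_true_model_is_calibrated():
    rng = np.random.default_rng(10)
    n = 1000
    lp = 0.8 * rng.normal(size=n)
    shape, scale = 1.2, 20.0
    t = scale * (-np.log(rng.uniform(size=n)) * np.exp(-lp)) ** (1 / shape)
    cmax = np.quantile(t, 0.9) * 2
    cens = rng.uniform(0, cmax, n)
    time = np.minimum(t, cens) + 1e-9
    event = (t <= cens).astype(int)
    h = float(np.quantile(time, 0.4))
    true_p = np.exp(-((h / scale) ** shape) * np.exp(lp))
    curve = calibration_curve(true_p, _surv(time, event), h, n_bins=4)
    assert curve["defined"].all()
    assert np.mean(np.abs(curve["predicted"] - curve["observed"])) <= 0.05


def test_calibration_constant_predictions_single_bin():
    c = make_cohort(n=80, seed=4)
    h = float(np.quantile(c.surv["time"], 0.4))
    curve = calibration_curve(np.full(80, 0.5), c.surv, h)
    assert len(curve) == 1
    overall = km_curve(c.surv["time"], c.surv["event"]).at(h)
    assert curve["observed"].iloc[0] == pytest.approx(overall)


def test_calibration_anti_calibrated_predictions_deviate():
    rng = np.random.default_rng(12)
    n = 800
    lp = 1.0 * rng.normal(size=n)
    t = 20 * (-np.log(rng.uniform(size=n)) * np.exp(-lp)) ** (1 / 1.2) + 1e-9
    h = float(np.quantile(t, 0.4))
    true_p = np.exp(-((h / 20.0) ** 1.2) * np.exp(lp))
    curve = calibration_curve(1.0 - true_p, _surv(t, np.ones(n, int)), h)
    assert np.mean(np.abs(curve["predicted"] - curve["observed"])) > 0.2


def test_apply_signature_exact_and_coverage():
    expr = pd.DataFrame([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
                        index=["g1", "g2", "g3"], columns=["s1", "s2"])
    surv = pd.DataFrame({"time": [5.0, 7.0], "event": [1, 1]},
                        index=["s1", "s2"])
    cohort = Cohort(name="t", role="testing", expr=expr, surv=surv)
    sig = ExternalSignature("sig", {"g1": 2.0, "g2": -1.0, "g3": 0.5})
    scores, cov = apply_signature(sig, cohort)
    assert np.allclose(scores, [2 * 1 - 3 + 0.5 * 5, 2 * 2 - 4 + 0.5 * 6])
    sig2 = ExternalSignature("sig2", {"g1": 2.0, "g2": -1.0, "gX": 9.0})
    scores2, cov2 = apply_signature(sig2, cohort)
    assert cov2["fraction"] == pytest.approx(2 / 3)
    assert np.allclose(scores2, [2 * 1 - 3, 2 * 2 - 4])
    with pytest.raises(EvaluationError, match="gX"):
        apply_signature(sig2, cohort, missing_policy="error")
    with pytest.raises(EvaluationError):
        apply_signature(ExternalSignature("s", {"zz": 1.0}), cohort)


def test_evaluate_signature_scores_report():
    c = make_cohort(n=200, seed=14, beta={"gA": 0.9}, censor=0.25)
    risk = pd.Series(c.expr.loc["gA"].to_numpy(), index=c.samples)
    h = float(np.quantile(c.surv["time"], 0.4))
    cov = pd.DataFrame({"age": np.random.default_rng(0).normal(60, 8, 200)},
                       index=c.samples)
    rep = evaluate_signature_scores(risk, c, horizons=[h], covariates=cov,
                                    calibration_t=h)
    assert rep.cindex > 0.6
    assert rep.logrank_p < 0.05
    assert rep.auc[h] > 0.6
    assert rep.adjusted_hr > 1.0 and rep.adjusted_hr_p < 0.05
    assert rep.calibration is not None
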