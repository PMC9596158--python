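"""Survival evaluation suite.

Harrell's concordance index (with the usable-pair convention), a paired
z-comparison of two C-indexes with jackknife variance, IPCW time-dependent
cumulative/dynamic AUC with Kaplan–Meier censoring weights, Kaplan–Meier
curves with Greenwood intervals and the k-group log-rank test, calibration
curves against binned KM estimates, and application of external gene
signatures (gene -> coefficient tables) to a cohort.

Scores handed to the concordance and AUC estimators are in *risk*
orientation (higher score = worse outcome); protective scores must be
negated by the caller (the framework does this automatically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import Cohort
from .coxph import baseline_survival, fit_cox

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# concordance


def _pair_matrices(scores: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Usable-pair mask and per-pair concordance contribution (n x n).

    Pair (i, j) is usable iff the smaller time is an event; pairs with equal
    times and both events are unusable (Harrell's convention).  Contribution
    is 1 for concordant, 0.5 for score ties, 0 for discordant.
    """
    t = time[:, None]
    e = event[:, None]
    s = scores[:, None]
    earlier = (t < t.T) & (e == 1)          # i strictly earlier and event
    tied_time = (t == t.T)
    one_event = tied_time & (e == 1) & (e.T == 0)  # equal times, only i has event
    usable = earlier | one_event
    conc = np.where(s > s.T, 1.0, np.where(s == s.T, 0.5, 0.0))
    return usable, conc


def harrell_cindex(scores, surv: pd.DataFrame) -> tuple[float, float]:
    """Harrell's C with a pair-count standard error.

    Returns ``(C, SE)`` where ``C = (concordant + 0.5 * ties) / usable`` and
    ``SE = sqrt(C * (1 - C) / n_usable)``.
    """
    s = np.asarray(scores, dtype=float)
    t = surv["time"].to_numpy(dtype=float)
    e = surv["event"].to_numpy(dtype=int)
    usable, conc = _pair_matrices(s, t, e)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise EvaluationError("no usable pairs (all censored?)")
    c = float((conc * usable).sum() / n_usable)
    se = float(np.sqrt(max(c * (1.0 - c), 0.0) / n_usable))
    return c, se


def compare_cindex(scores_a, scores_b, surv: pd.DataFrame) -> tuple[float, float, float]:
    """Paired C-index difference with jackknife variance.

    Returns ``(delta_c, z, p)``; ``delta_c = C(A) - C(B)``.  The jackknife
    leaves one subject out at a time, removing its row and column from the
    pair sums, which makes the variance deterministic.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    t = surv["time"].to_numpy(dtype=float)
    e = surv["event"].to_numpy(dtype=int)
    n = len(t)
    if len(sa) != n or len(sb) != n:
        raise EvaluationError("score vectors must align with the survival table")

    ua, ca = _pair_matrices(sa, t, e)
    ub, cb = _pair_matrices(sb, t, e)
    usable = ua  # usability depends only on (time, event), identical for A and B
    num_a, num_b = ca * usable, cb * usable
    tot_u = usable.sum()
    tot_a, tot_b = num_a.sum(), num_b.sum()
    delta = tot_a / tot_u - tot_b / tot_u

    # leave-one-out: subtract row i and column i (diagonal is never usable)
    u_i = usable.sum(axis=0) + usable.sum(axis=1)
    a_i = num_a.sum(axis=0) + num_a.sum(axis=1)
    b_i = num_b.sum(axis=0) + num_b.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        delta_loo = (tot_a - a_i) / (tot_u - u_i) - (tot_b - b_i) / (tot_u - u_i)
    ok = np.isfinite(delta_loo)
    if ok.sum() < 2:
        logger.warning("compare_cindex: degenerate jackknife; p = 1")
        return float(delta), 0.0, 1.0
    d = delta_loo[ok]
    var = (len(d) - 1) / len(d) * np.sum((d - d.mean()) ** 2)
    if var <= 0:
        logger.warning("compare_cindex: zero jackknife variance; p = 1")
        return float(delta), 0.0, 1.0
    z = float(delta / np.sqrt(var))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(delta), z, p


# ---------------------------------------------------------------------------
# Kaplan–Meier, log-rank


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray          # distinct event times
    survival: np.ndarray
    at_risk: np.ndarray
    greenwood_var: np.ndarray  # variance of S(t) (Greenwood)

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float, level: float = 0.95) -> tuple[float, float]:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0, 1.0
        s = self.survival[idx]
        se = np.sqrt(self.greenwood_var[idx])
        zq = stats.norm.ppf(0.5 + level / 2.0)
        return float(max(s - zq * se, 0.0)), float(min(s + zq * se, 1.0))


def km_curve(time, event, group: str = "all") -> KMCurve:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t[e == 1])
    n = len(t)
    surv, var_terms, at_risk = [], [], []
    s = 1.0
    gw = 0.0
    for u in uniq:
        r = int((t >= u).sum())
        d = int(((t == u) & (e == 1)).sum())
        s *= 1.0 - d / r
        if r > d:
            gw += d / (r * (r - d))
        at_risk.append(r)
        surv.append(s)
        var_terms.append(s**2 * gw if s > 0 else 0.0)
    return KMCurve(group=group, times=uniq, survival=np.array(surv),
                   at_risk=np.array(at_risk), greenwood_var=np.array(var_terms))


def km_logrank(groups, surv: pd.DataFrame) -> tuple[list[KMCurve], float, float]:
    """KM curve per group plus the k-group log-rank chi-square test."""
    g = np.asarray(groups)
    t = surv["time"].to_numpy(dtype=float)
    e = surv["event"].to_numpy(dtype=int)
    labels = list(pd.unique(g))
    if len(labels) < 2:
        raise EvaluationError("log-rank requires >= 2 groups")
    for lab in labels:
        if (g == lab).sum() == 0:
            raise EvaluationError(f"group {lab!r} has zero subjects")
    curves = [km_curve(t[g == lab], e[g == lab], group=str(lab)) for lab in labels]

    k = len(labels)
    event_times = np.unique(t[e == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for u in event_times:
        at_risk = np.array([((t >= u) & (g == lab)).sum() for lab in labels], dtype=float)
        deaths = np.array([((t == u) & (e == 1) & (g == lab)).sum() for lab in labels],
                          dtype=float)
        n_u = at_risk.sum()
        d_u = deaths.sum()
        if n_u == 0 or d_u == 0:
            continue
        observed += deaths
        expected += d_u * at_risk / n_u
        if n_u > 1:
            f = d_u * (n_u - d_u) / (n_u - 1)
            p_r = at_risk / n_u
            var += f * (np.diag(p_r) - np.outer(p_r, p_r))
    o_e = (observed - expected)[:-1]
    v = var[:-1, :-1]
    try:
        chi2 = float(o_e @ np.linalg.solve(v, o_e))
    except np.linalg.LinAlgError:
        chi2 = float(o_e @ np.linalg.pinv(v) @ o_e)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return curves, chi2, p


# ---------------------------------------------------------------------------
# time-dependent AUC (IPCW, cumulative cases / dynamic controls)


def _censoring_km(time: np.ndarray, event: np.ndarray) -> KMCurve:
    return km_curve(time, 1 - event, group="censoring")


def time_auc(scores, surv: pd.DataFrame, horizons: Sequence[float]) -> dict[float, float]:
    """IPCW cumulative/dynamic AUC(t) with KM censoring weights.

    Cases at horizon t are subjects with an event at or before t (weighted by
    the inverse KM censoring survival just before their event time); controls
    are subjects still under observation beyond t.  Horizons with no cases or
    no controls are reported as NaN.
    """
    s = np.asarray(scores, dtype=float)
    t = surv["time"].to_numpy(dtype=float)
    e = surv["event"].to_numpy(dtype=int)
    t_max = t.max()
    g_km = _censoring_km(t, e)

    def g_at_minus(times: np.ndarray) -> np.ndarray:
        return np.array([g_km.at(u - 1e-12) for u in times])

    out: dict[float, float] = {}
    for h in horizons:
        if h >= t_max:
            raise EvaluationError(f"horizon {h} is not below the largest observed time")
        case = (t <= h) & (e == 1)
        ctrl = t > h
        if case.sum() == 0 or ctrl.sum() == 0:
            logger.warning("time_auc: horizon %s has no cases or no controls", h)
            out[float(h)] = float("nan")
            continue
        w = np.zeros_like(s)
        gvals = g_at_minus(t[case])
        gvals = np.clip(gvals, 1e-12, None)
        w[case] = 1.0 / gvals
        sc, scs = s[case], s[ctrl]
        wc = w[case]
        gt = (sc[:, None] > scs[None, :]).astype(float)
        gt += 0.5 * (sc[:, None] == scs[None, :])
        num = (wc[:, None] * gt).sum()
        den = wc.sum() * len(scs)
        out[float(h)] = float(num / den)
    return out


# ---------------------------------------------------------------------------
# calibration


def calibration_curve(
    sig_probs, surv: pd.DataFrame, t: float, n_bins: int = 4
) -> pd.DataFrame:
    """Predicted vs observed survival at horizon ``t`` in quantile bins.

    Returns a table with one row per bin: mean predicted probability, the KM
    observed survival at ``t`` within the bin, its Greenwood CI, and the bin
    size.  Bins with no information at ``t`` are flagged undefined.
    """
    p = np.asarray(sig_probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise EvaluationError("predicted probabilities must lie in [0, 1]")
    tt = surv["time"].to_numpy(dtype=float)
    ee = surv["event"].to_numpy(dtype=int)
    if t >= tt.max():
        raise EvaluationError("horizon t must be below the maximum follow-up")
    if np.unique(p).size == 1:
        bins = np.zeros(len(p), dtype=int)
        n_eff = 1
        logger.warning("calibration_curve: constant predictions; single bin")
    else:
        q = np.quantile(p, np.linspace(0, 1, n_bins + 1))
        q[0], q[-1] = -np.inf, np.inf
        bins = np.searchsorted(q, p, side="right") - 1
        n_eff = n_bins
    rows = []
    for b in range(n_eff):
        m = bins == b
        if m.sum() == 0:
            continue
        at_risk_t = int(((tt >= t) & m).sum())
        events_t = int(((tt <= t) & (ee == 1) & m).sum())
        if at_risk_t == 0 and events_t == 0:
            rows.append({"bin": b, "n": int(m.sum()), "predicted": float(p[m].mean()),
                         "observed": float("nan"), "ci_low": float("nan"),
                         "ci_high": float("nan"), "defined": False})
            continue
        kmc = km_curve(tt[m], ee[m], group=f"bin{b}")
        lo, hi = kmc.ci_at(t)
        rows.append({"bin": b, "n": int(m.sum()), "predicted": float(p[m].mean()),
                     "observed": kmc.at(t), "ci_low": lo, "ci_high": hi,
                     "defined": True})
    return pd.DataFrame(rows)


def score_to_survival_probs(
    scores, cohort: Cohort, t: float
) -> np.ndarray:
    """Absolute survival probabilities from a score via a one-covariate Cox.

    Most learners emit only relative scores; this refits a univariate Cox of
    the outcome on the score and applies the Breslow baseline, as recorded in
    report metadata so curves are not misread as learner-native probabilities.
    """
    s = np.asarray(scores, dtype=float)[:, None]
    fit = fit_cox(s, cohort.surv)
    s0 = baseline_survival(fit, s, cohort.surv)
    return np.asarray(s0(t)) ** np.exp(s[:, 0] * fit.beta[0])


# ---------------------------------------------------------------------------
# external signatures


@dataclass(frozen=True)
class ExternalSignature:
    """A published gene signature: name, gene -> coefficient, orientation."""

    name: str
    coefficients: Mapping[str, float]
    orientation: Literal["higher_is_risk", "higher_is_protective"] = "higher_is_risk"

    def __post_init__(self) -> None:
        if len(self.coefficients) < 1:
            raise ValueError("signature needs at least one gene")
        if not all(np.isfinite(list(self.coefficients.values()))):
            raise ValueError("signature coefficients must be finite")


def read_signature(path, name: str | None = None) -> ExternalSignature:
    """Read a TSV with columns ``gene`` and ``coefficient``."""
    df = pd.read_csv(path, sep="\t")
    return ExternalSignature(
        name=name or str(path),
        coefficients=dict(zip(df["gene"].astype(str), df["coefficient"].astype(float))),
    )


def apply_signature(
    sig: ExternalSignature, cohort: Cohort,
    missing_policy: Literal["drop", "error"] = "drop",
) -> tuple[pd.Series, dict]:
    """Risk score per sample: sum of coef * expression over covered genes."""
    present = [g for g in sig.coefficients if g in cohort.expr.index]
    missing = [g for g in sig.coefficients if g not in cohort.expr.index]
    if missing and missing_policy == "error":
        raise EvaluationError(f"signature {sig.name!r}: missing genes {missing}")
    if not present:
        raise EvaluationError(f"signature {sig.name!r}: no genes present in cohort")
    coefs = np.array([sig.coefficients[g] for g in present])
    scores = pd.Series(coefs @ cohort.expr.loc[present].to_numpy(dtype=float),
                       index=cohort.expr.columns, name=sig.name)
    coverage = {"n_present": len(present), "n_total": len(sig.coefficients),
                "fraction": len(present) / len(sig.coefficients), "missing": missing}
    return scores, coverage


# ---------------------------------------------------------------------------
# report


@dataclass(frozen=True)
class EvaluationReport:
    """Per-cohort summary of a signature's performance."""

    cohort: str
    cindex: float
    cindex_se: float
    auc: dict[float, float]
    logrank_chi2: float
    logrank_p: float
    calibration: pd.DataFrame | None
    adjusted_hr: float | None          # multivariate-adjusted HR of the score
    adjusted_hr_p: float | None
    notes: tuple[str, ...] = ()


def evaluate_signature_scores(
    risk_scores: pd.Series,
    cohort: Cohort,
    horizons: Sequence[float] = (),
    groups: pd.Series | None = None,
    covariates: pd.DataFrame | None = None,
    calibration_t: float | None = None,
) -> EvaluationReport:
    """Full evaluation of risk-oriented scores on one cohort.

    ``covariates`` (optional) enter a multivariate Cox alongside the score;
    categorical columns are one-hot encoded against a first-level reference.
    """
    scores = risk_scores.loc[cohort.samples]
    c, se = harrell_cindex(scores.to_numpy(), cohort.surv)
    auc = time_auc(scores.to_numpy(), cohort.surv, horizons) if len(horizons) else {}
    notes: list[str] = []
    if groups is None:
        med = float(np.median(scores))
        groups = pd.Series(np.where(scores.to_numpy() <= med, "low_risk", "high_risk"),
                           index=scores.index)
    if groups.nunique() >= 2:
        _, chi2, p = km_logrank(groups.loc[cohort.samples].to_numpy(), cohort.surv)
    else:
        chi2, p = 0.0, 1.0
        notes.append("single risk group; log-rank skipped")
    calib = None
    if calibration_t is not None:
        probs = score_to_survival_probs(scores.to_numpy(), cohort, calibration_t)
        calib = calibration_curve(probs, cohort.surv, calibration_t)
        notes.append("calibration probabilities from univariate Cox on the score "
                     "(Breslow baseline), not learner-native")
    adj_hr = adj_p = None
    if covariates is not None:
        design = pd.get_dummies(covariates.loc[cohort.samples], drop_first=True)
        design = design.astype(float)
        design.insert(0, "score", scores.to_numpy())
        fit = fit_cox(design, cohort.surv)
        adj_hr = float(np.exp(fit.beta[0]))
        adj_p = float(fit.wald_p[0])
    return EvaluationReport(cohort=cohort.name, cindex=c, cindex_se=se, auc=auc,
                            logrank_chi2=chi2, logrank_p=p, calibration=calib,
                            adjusted_hr=adj_hr, adjusted_hr_p=adj_p, notes=tuple(notes))
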