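"""Cox proportional-hazards machinery.

Implements Newton–Raphson maximization of the Cox partial likelihood with
Efron (default) or Breslow tie handling, the cross-cohort consensus
prognostic-gene screen, and the Breslow baseline survival estimator needed
to turn model scores into absolute survival probabilities.

The likelihood, gradient and Hessian are vectorized over tied-event groups
so that the univariate screen (one fit per gene per cohort, tens of
thousands of fits) stays fast in pure NumPy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import Cohort, MultiCohort

logger = logging.getLogger(__name__)

TiesMethod = Literal["efron", "breslow"]

_MAX_ABS_BETA = 20.0
_GTOL = 1e-8
_MAX_ITER = 50


class CoxError(ValueError):
    pass


@dataclass(frozen=True)
class _SurvPrep:
    """Sorted survival layout shared by all likelihood evaluations."""

    order: np.ndarray          # argsort of time (ascending)
    time_s: np.ndarray
    event_s: np.ndarray
    starts: np.ndarray         # first sorted index of each tied-time group
    group_of: np.ndarray       # group index of each sorted sample
    ev_rows: np.ndarray        # sorted row indices of events
    ev_group: np.ndarray       # group index per event
    ev_starts: np.ndarray      # reduceat boundaries of events grouped by group
    ev_groups_u: np.ndarray    # group indices that contain >= 1 event
    d_per_group: np.ndarray    # number of events in each group (all groups)
    frac_efron: np.ndarray     # l/d per event within its group (Efron weights)


def _prepare(time: np.ndarray, event: np.ndarray) -> _SurvPrep:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    n = len(t_s)
    new_group = np.ones(n, dtype=bool)
    new_group[1:] = t_s[1:] != t_s[:-1]
    starts = np.flatnonzero(new_group)
    group_of = np.cumsum(new_group) - 1
    d_per_group = np.bincount(group_of, weights=e_s, minlength=len(starts)).astype(int)

    ev_rows = np.flatnonzero(e_s == 1)
    ev_group = group_of[ev_rows]
    ev_new = np.ones(len(ev_rows), dtype=bool)
    ev_new[1:] = ev_group[1:] != ev_group[:-1]
    ev_starts = np.flatnonzero(ev_new)
    ev_groups_u = ev_group[ev_starts] if len(ev_rows) else np.empty(0, dtype=int)
    # within-group event rank l = 0..d-1, Efron fraction l/d
    rank = np.arange(len(ev_rows)) - np.repeat(ev_starts, np.diff(np.r_[ev_starts, len(ev_rows)]))
    d_of_ev = d_per_group[ev_group]
    frac = rank / np.maximum(d_of_ev, 1)
    return _SurvPrep(order, t_s, e_s, starts, group_of, ev_rows, ev_group,
                     ev_starts, ev_groups_u, d_per_group, frac)


def _suffix_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _loglik_grad_hess(
    x_s: np.ndarray, eta: np.ndarray, prep: _SurvPrep, ties: TiesMethod,
    want_hess: bool = True,
):
    """Partial log-likelihood with gradient and (optionally) Hessian.

    ``x_s`` and ``eta`` are already in sorted-time order.
    """
    n, p = x_s.shape
    w = np.exp(np.clip(eta, -500, 500))
    s0_suf = _suffix_cumsum(w)
    s0r = s0_suf[prep.starts]
    wx = w[:, None] * x_s
    s1r = _suffix_cumsum(wx)[prep.starts]
    if want_hess:
        wxx = wx[:, :, None] * x_s[:, None, :]
        s2r = _suffix_cumsum(wxx)[prep.starts]

    ev = prep.ev_rows
    if len(ev) == 0:
        raise CoxError("no events")
    we, xe = w[ev], x_s[ev]
    s0d_u = np.add.reduceat(we, prep.ev_starts)
    s1d_u = np.add.reduceat(we[:, None] * xe, prep.ev_starts, axis=0)
    # scatter tied-event sums to full group indexing
    s0d = np.zeros(len(prep.starts))
    s0d[prep.ev_groups_u] = s0d_u
    s1d = np.zeros((len(prep.starts), p))
    s1d[prep.ev_groups_u] = s1d_u

    frac = prep.frac_efron if ties == "efron" else np.zeros(len(ev))
    g = prep.ev_group
    phi = s0r[g] - frac * s0d[g]
    psi = (s1r[g] - frac[:, None] * s1d[g]) / phi[:, None]
    loglik = float(eta[ev].sum() - np.log(phi).sum())
    grad = xe.sum(axis=0) - psi.sum(axis=0)
    if not want_hess:
        return loglik, grad, None
    s2d_u = np.add.reduceat(we[:, None, None] * xe[:, :, None] * xe[:, None, :],
                            prep.ev_starts, axis=0)
    s2d = np.zeros((len(prep.starts), p, p))
    s2d[prep.ev_groups_u] = s2d_u
    term = (s2r[g] - frac[:, None, None] * s2d[g]) / phi[:, None, None]
    hess = -(term.sum(axis=0) - np.einsum("ij,ik->jk", psi, psi))
    return loglik, grad, hess


@dataclass(frozen=True)
class CoxFit:
    """A fitted Cox model (per-covariate log-hazard units)."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    null_loglik: float
    ties_method: TiesMethod
    converged: bool
    n: int
    n_events: int
    names: tuple[str, ...]

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se > 0, self.beta / self.se, 0.0)

    @property
    def wald_p(self) -> np.ndarray:
        return stats.chi2.sf(self.z**2, df=1)

    @property
    def aic(self) -> float:
        return 2.0 * len(self.beta) - 2.0 * self.loglik


def _as_xy(covariates, surv: pd.DataFrame):
    if isinstance(covariates, pd.DataFrame):
        names = tuple(str(c) for c in covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = tuple(f"x{j}" for j in range(x.shape[1]))
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    if x.shape[0] != len(time):
        raise CoxError("covariate rows must match survival table")
    if not np.isfinite(x).all():
        raise CoxError("covariates contain non-finite values")
    return x, names, time, event


def fit_cox(covariates, surv: pd.DataFrame, ties: TiesMethod = "efron") -> CoxFit:
    """Newton–Raphson Cox fit with step-halving.

    Converged when the gradient max-norm drops below 1e-8 (or 50 iterations).
    Monotone likelihood (separation) is caught by capping |beta| at 20 and
    flagging the fit as not converged.
    """
    x, names, time, event = _as_xy(covariates, surv)
    if event.sum() < 1:
        raise CoxError("no events in survival table")
    prep = _prepare(time, event)
    x_s = x[prep.order]
    n, p = x_s.shape

    beta = np.zeros(p)
    null_ll, _, _ = _loglik_grad_hess(x_s, np.zeros(n), prep, ties, want_hess=False)
    ll, grad, hess = _loglik_grad_hess(x_s, x_s @ beta, prep, ties)
    converged = False
    for _ in range(_MAX_ITER):
        if np.max(np.abs(grad)) < _GTOL:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _loglik_grad_hess(x_s, x_s @ cand, prep, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                break
            scale *= 0.5
        else:
            break
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > _MAX_ABS_BETA:
            logger.warning("fit_cox: |beta| exceeded %.0f (separation?); capped", _MAX_ABS_BETA)
            beta = np.clip(beta, -_MAX_ABS_BETA, _MAX_ABS_BETA)
            ll, grad, hess = _loglik_grad_hess(x_s, x_s @ beta, prep, ties)
            converged = False
            break
    else:
        converged = np.max(np.abs(grad)) < _GTOL
    if converged and np.max(np.abs(beta)) > 0.9 * _MAX_ABS_BETA:
        # flat likelihood with a diverging coefficient: monotone likelihood
        logger.warning("fit_cox: coefficient near cap; likely separation")
        converged = False

    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return CoxFit(beta=beta, se=se, loglik=ll, null_loglik=null_ll,
                  ties_method=ties, converged=converged, n=n,
                  n_events=int(event.sum()), names=names)


# ---------------------------------------------------------------------------
# per-sample derivative machinery (Breslow) shared with penalized solvers


def martingale_weights(eta: np.ndarray, prep: _SurvPrep):
    """Per-sample score residual g_i and diagonal Fisher weight w_i (Breslow).

    g_i = delta_i - exp(eta_i) * A(T_i)   (martingale residual)
    w_i = exp(eta_i) * A(T_i) - exp(2 eta_i) * B(T_i)
    with A/B the cumulative sums of d/S0 and d/S0^2 over event times <= T_i.
    Returned in original (unsorted) order of ``prep.order``'s inverse.
    """
    w = np.exp(np.clip(eta, -500, 500))
    s0r = _suffix_cumsum(w)[prep.starts]
    d = prep.d_per_group
    with np.errstate(divide="ignore"):
        inc_a = np.where(d > 0, d / s0r, 0.0)
        inc_b = np.where(d > 0, d / s0r**2, 0.0)
    cum_a = np.cumsum(inc_a)[prep.group_of]
    cum_b = np.cumsum(inc_b)[prep.group_of]
    g_s = prep.event_s - w * cum_a
    w_s = np.clip(w * cum_a - w**2 * cum_b, 1e-10, None)
    inv = np.empty_like(prep.order)
    inv[prep.order] = np.arange(len(prep.order))
    return g_s[inv], w_s[inv]


def breslow_cumhaz(eta: np.ndarray, prep: _SurvPrep):
    """Breslow cumulative baseline hazard at each distinct event time."""
    w = np.exp(np.clip(eta, -500, 500))
    s0r = _suffix_cumsum(w)[prep.starts]
    d = prep.d_per_group
    keep = d > 0
    times = prep.time_s[prep.starts][keep]
    h0 = np.cumsum(d[keep] / s0r[keep])
    return times, h0


class StepSurvival:
    """Right-continuous step function S0(t); S0(t) = 1 before the first event."""

    def __init__(self, times: np.ndarray, surv: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.surv = np.asarray(surv, dtype=float)

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.atleast_1d(np.asarray(t, dtype=float)),
                              side="right") - 1
        out = np.where(idx >= 0, self.surv[np.clip(idx, 0, None)], 1.0)
        return out if np.ndim(t) else float(out[0])


def baseline_survival(fit: CoxFit, covariates, surv: pd.DataFrame) -> StepSurvival:
    """Breslow baseline survival S0(t) = exp(-H0(t)) at covariates = 0.

    S(t | x) = S0(t) ** exp(lp(x)) for a linear predictor lp in the fit's
    covariate coding.
    """
    if not fit.converged:
        raise CoxError("baseline_survival requires a converged fit")
    x, _, time, event = _as_xy(covariates, surv)
    prep = _prepare(time, event)
    eta = (x @ fit.beta)[prep.order]
    times, h0 = breslow_cumhaz(eta, prep)
    return StepSurvival(times, np.exp(-h0))


def predict_survival(
    fit: CoxFit, s0: StepSurvival, covariates, t
) -> np.ndarray:
    """S(t | x) = S0(t) ** exp(x beta) for each row of ``covariates``."""
    x = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) \
        else np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    lp = x @ fit.beta
    return np.asarray(s0(t)) ** np.exp(lp)


# ---------------------------------------------------------------------------
# consensus prognostic-gene screen


@dataclass(frozen=True)
class ConsensusRule:
    """Cross-cohort selection rule for consensus prognostic genes.

    A gene is selected when its univariate Cox association is significant
    (Wald p below ``p_threshold``) in at least ``min_cohorts`` of the K
    cohorts and, when ``require_direction``, the hazard direction agrees
    (all HR > 1 or all HR < 1) across those qualifying cohorts.
    """

    p_threshold: float = 0.05
    min_cohorts: int = 8
    require_direction: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_cohorts < 1:
            raise ValueError("min_cohorts must be >= 1")


@dataclass(frozen=True)
class ScreenRecord:
    """Per-gene cross-cohort univariate-Cox evidence."""

    gene: str
    hr: dict[str, float]        # cohort -> hazard ratio (NaN on fit failure)
    wald_p: dict[str, float]
    n_qualifying: int
    direction_consistent: bool
    selected: bool


def consensus_screen(mc: MultiCohort, rule: ConsensusRule | None = None) -> list[ScreenRecord]:
    """Univariate Cox screen of every shared gene across every cohort.

    Each cohort contributes one fit per gene (gene as sole covariate); a
    failed or non-converged fit marks that cohort non-qualifying for that
    gene without aborting the screen.
    """
    rule = rule or ConsensusRule()
    if rule.min_cohorts > len(mc):
        raise ValueError("min_cohorts exceeds the number of cohorts")
    per_cohort: list[tuple[str, _SurvPrep, np.ndarray]] = []
    for c in mc:
        time = c.surv["time"].to_numpy(dtype=float)
        event = c.surv["event"].to_numpy(dtype=int)
        prep = _prepare(time, event)
        per_cohort.append((c.name, prep, c.expr.to_numpy(dtype=float)))

    records: list[ScreenRecord] = []
    for gi, gene in enumerate(mc.shared_genes):
        hrs: dict[str, float] = {}
        ps: dict[str, float] = {}
        for name, prep, xmat in per_cohort:
            try:
                fit = _fit_univariate(xmat[gi], prep)
            except (CoxError, np.linalg.LinAlgError):
                fit = None
            if fit is None or not fit[2]:
                logger.debug("screen: fit failed for gene %s in cohort %s", gene, name)
                hrs[name] = float("nan")
                ps[name] = float("nan")
            else:
                beta, se, _ = fit
                hrs[name] = float(np.exp(beta))
                z2 = (beta / se) ** 2 if se > 0 else 0.0
                ps[name] = float(stats.chi2.sf(z2, df=1))
        qual = [name for name in hrs
                if np.isfinite(ps[name]) and ps[name] < rule.p_threshold]
        if qual:
            signs = {hrs[name] > 1.0 for name in qual}
            consistent = len(signs) == 1
        else:
            consistent = False
        selected = len(qual) >= rule.min_cohorts and (
            consistent or not rule.require_direction
        )
        records.append(ScreenRecord(gene=gene, hr=hrs, wald_p=ps,
                                    n_qualifying=len(qual),
                                    direction_consistent=consistent,
                                    selected=selected))
    return records


def _fit_univariate(x: np.ndarray, prep: _SurvPrep):
    """Scalar Newton fit (Efron ties) reusing a prepared survival layout."""
    x_s = x[prep.order][:, None]
    beta = np.zeros(1)
    ll, grad, hess = _loglik_grad_hess(x_s, x_s @ beta, prep, "efron")
    converged = False
    for _ in range(_MAX_ITER):
        if abs(grad[0]) < _GTOL:
            converged = True
            break
        h = hess[0, 0]
        if h >= 0 or not np.isfinite(h):
            break
        step = -grad[0] / h
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * np.array([step])
            ll_new, grad_new, hess_new = _loglik_grad_hess(x_s, x_s @ cand, prep, "efron")
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                break
            scale *= 0.5
        else:
            break
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if abs(beta[0]) > _MAX_ABS_BETA:
            return float(np.clip(beta[0], -_MAX_ABS_BETA, _MAX_ABS_BETA)), float("inf"), False
    se = float(np.sqrt(-1.0 / hess[0, 0])) if hess[0, 0] < 0 else float("inf")
    return float(beta[0]), se, converged


def screen_to_frame(records: Sequence[ScreenRecord]) -> pd.DataFrame:
    """Flatten screen records to a table (one row per gene)."""
    rows = []
    for r in records:
        row: dict[str, object] = {"gene": r.gene}
        for name in r.hr:
            row[f"hr_{name}"] = r.hr[name]
            row[f"p_{name}"] = r.wald_p[name]
        row["n_qualifying"] = r.n_qualifying
        row["direction_consistent"] = r.direction_consistent
        row["selected"] = r.selected
        rows.append(row)
    return pd.DataFrame(rows)
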