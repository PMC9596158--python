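"""Ten survival-learning algorithm families behind one fit/score/select contract.

Families
--------
===========  ========================================================  ===========
family       backend                                                   selector?
===========  ========================================================  ===========
RSF          scikit-survival RandomSurvivalForest                      yes
LASSO        in-package coordinate-descent penalized Cox (l1)          yes
Ridge        in-package coordinate-descent penalized Cox (l2)          no
Enet         in-package coordinate-descent penalized Cox (l1+l2)       no
GBM          scikit-survival GradientBoostingSurvivalAnalysis          no
SurvSVM      scikit-survival FastSurvivalSVM (linear)                  no
SuperPC      univariate-z screening + PCA + Cox on components          no
plsRcox      sequential PLS components on martingale residuals + Cox   no
CoxBoost     in-package componentwise likelihood boosting              yes
StepCox      AIC-guided stepwise multivariate Cox                      yes
===========  ========================================================  ===========

Hyperparameters are tuned by K-fold cross-validation (default 10 folds)
maximizing the mean out-of-fold Harrell C-index; grid ties break toward the
smallest-complexity entry (grids are ordered accordingly).  All learners
consume cohort-standardized expression, so linear coefficients are per-SD.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sksurv.ensemble import GradientBoostingSurvivalAnalysis, RandomSurvivalForest
from sksurv.svm import FastSurvivalSVM
from sksurv.util import Surv

from ._solvers import fit_coxboost, fit_coxnet, fit_coxnet_path, lambda_path
from .cohorts import Cohort
from .coxph import CoxError, fit_cox
from .evaluation import EvaluationError, harrell_cindex

logger = logging.getLogger(__name__)

Orientation = Literal["higher_is_risk", "higher_is_protective"]

FAMILIES = ("RSF", "LASSO", "Ridge", "Enet", "GBM", "SurvSVM", "SuperPC",
            "plsRcox", "CoxBoost", "StepCox")
SELECTOR_FAMILIES = ("RSF", "LASSO", "CoxBoost", "StepCox")
STEPCOX_DIRECTIONS = ("both", "backward", "forward")
ENET_ALPHAS = tuple(round(0.1 * i, 1) for i in range(1, 10))


class LearnerError(ValueError):
    pass


class SelectorEmptyError(LearnerError):
    """A selector returned no genes."""


@dataclass(frozen=True)
class AlgorithmSpec:
    """One algorithm family plus its variant parameters.

    ``params`` holds variant identity (Enet: ``alpha``; StepCox:
    ``direction``); ``grid`` optionally overrides the default hyper-grid.
    """

    family: str
    params: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise LearnerError(f"unknown algorithm family {self.family!r}")
        if self.family == "Enet":
            a = self.params.get("alpha")
            if a is None or not (0.0 < float(a) < 1.0):
                raise LearnerError("Enet requires alpha in (0, 1)")
        if self.family == "StepCox":
            d = self.params.get("direction", "both")
            if d not in STEPCOX_DIRECTIONS:
                raise LearnerError(f"StepCox direction must be one of {STEPCOX_DIRECTIONS}")

    @property
    def can_select(self) -> bool:
        return self.family in SELECTOR_FAMILIES

    @property
    def can_model(self) -> bool:
        return True

    @property
    def label(self) -> str:
        if self.family == "Enet":
            return f"Enet[a={self.params['alpha']}]"
        if self.family == "StepCox":
            return f"StepCox[{self.params.get('direction', 'both')}]"
        return self.family


def spec_from_label(label: str, grid: dict | None = None) -> AlgorithmSpec:
    """Parse labels like ``Enet[a=0.3]`` / ``StepCox[backward]`` / ``RSF``."""
    grid = grid or {}
    if label.startswith("Enet[a="):
        return AlgorithmSpec("Enet", {"alpha": float(label[7:-1])}, grid)
    if label.startswith("StepCox["):
        return AlgorithmSpec("StepCox", {"direction": label[8:-1]}, grid)
    return AlgorithmSpec(label, {}, grid)


@dataclass(frozen=True)
class CVPlan:
    """Cross-validation plan: fold count, seed, metric fixed to Harrell's C."""

    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise LearnerError("folds must be >= 2")

    def effective_folds(self, n_events: int) -> int:
        if self.folds > n_events:
            logger.warning("CVPlan: folds reduced from %d to %d (events)",
                           self.folds, max(n_events, 2))
            return max(n_events, 2)
        return self.folds


@dataclass(frozen=True)
class FittedLearner:
    """A fitted model: opaque state plus the gene and orientation contract."""

    spec: AlgorithmSpec
    genes_used: tuple[str, ...]
    selected_genes: tuple[str, ...] | None
    orientation: Orientation
    cv_record: dict
    state: dict

    def predict(self, expr: pd.DataFrame) -> pd.Series:
        return predict_scores(self, expr)


def _rng_seed(seed: int, tag: str) -> int:
    return (seed + zlib.crc32(tag.encode())) % (2**31 - 1)


def _order_genes(genes: Sequence[str], weight: np.ndarray) -> tuple[str, ...]:
    """Stable order: descending |weight|, ties by gene id."""
    idx = sorted(range(len(genes)), key=lambda i: (-abs(weight[i]), genes[i]))
    return tuple(genes[i] for i in idx)


# ---------------------------------------------------------------------------
# family backends: each provides grid(), fit(), predict(), orientation


def _surv_y(t: np.ndarray, e: np.ndarray):
    return Surv.from_arrays(event=e.astype(bool), time=t)


class _Backend:
    orientation: Orientation = "higher_is_risk"
    #: grids ordered smallest-complexity first (tie -> simplest wins)

    def __init__(self, spec: AlgorithmSpec, seed: int):
        self.spec = spec
        self.seed = seed

    def grid(self, x, t, e) -> list[dict]:
        raise NotImplementedError

    def fit(self, x, t, e, hp: dict) -> dict:
        raise NotImplementedError

    def predict(self, state: dict, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def selected(self, state: dict, genes: Sequence[str]):
        return None


class _PenalizedCox(_Backend):
    """LASSO (alpha=1), Ridge (alpha=0), Enet (0<alpha<1)."""

    @property
    def alpha(self) -> float:
        if self.spec.family == "LASSO":
            return 1.0
        if self.spec.family == "Ridge":
            return 0.0
        return float(self.spec.params["alpha"])

    def grid(self, x, t, e) -> list[dict]:
        n_lam = int(self.spec.grid.get("n_lambda", 100))
        if self.alpha == 0.0:
            lams = np.geomspace(10.0, 1e-4, n_lam)
        else:
            lams = lambda_path(x, t, e, self.alpha, n_lam)
        return [{"lam": float(l)} for l in lams]  # descending: sparsest first

    def fit(self, x, t, e, hp: dict) -> dict:
        beta = fit_coxnet(x, t, e, hp["lam"], self.alpha)
        return {"beta": beta, "lam": hp["lam"]}

    def cv_path(self, x, t, e, grid, folds):
        """Warm-started path evaluation shared across the lambda grid."""
        lams = np.array([hp["lam"] for hp in grid])
        scores = np.full((len(folds), len(lams)), np.nan)
        for fi, (tr, va) in enumerate(folds):
            _, betas = fit_coxnet_path(x[tr], t[tr], e[tr], self.alpha, lambdas=lams)
            for li in range(len(lams)):
                s = x[va] @ betas[li]
                scores[fi, li] = _safe_c(s, t[va], e[va])
        return scores

    def predict(self, state, x):
        return x @ state["beta"]

    def selected(self, state, genes):
        nz = np.flatnonzero(state["beta"])
        return _order_genes([genes[i] for i in nz], state["beta"][nz])


class _CoxBoost(_Backend):
    def grid(self, x, t, e) -> list[dict]:
        steps = self.spec.grid.get("steps")
        if steps is None:
            steps = list(range(0, 101, 5))
        return [{"M": int(m)} for m in steps]  # ascending: fewest steps first

    def _penalty(self, e) -> float:
        return float(self.spec.grid.get("penalty", 9.0 * int(e.sum())))

    def fit(self, x, t, e, hp: dict) -> dict:
        beta = fit_coxboost(x, t, e, hp["M"], penalty=self._penalty(e))
        return {"beta": beta, "M": hp["M"]}

    def cv_path(self, x, t, e, grid, folds):
        """Boosting is incremental: one pass per fold records every M."""
        steps = [hp["M"] for hp in grid]
        m_max = max(steps)
        scores = np.full((len(folds), len(steps)), np.nan)
        for fi, (tr, va) in enumerate(folds):
            pen = self._penalty(e[tr])
            betas = _coxboost_checkpoints(x[tr], t[tr], e[tr], m_max, steps, pen)
            for si in range(len(steps)):
                s = x[va] @ betas[si]
                scores[fi, si] = _safe_c(s, t[va], e[va])
        return scores

    def predict(self, state, x):
        return x @ state["beta"]

    def selected(self, state, genes):
        nz = np.flatnonzero(state["beta"])
        return _order_genes([genes[i] for i in nz], state["beta"][nz])


def _coxboost_checkpoints(x, t, e, m_max, steps, penalty):
    from ._solvers import _prep_sorted, martingale_weights

    n, p = x.shape
    prep = _prep_sorted(t, e)
    beta = np.zeros(p)
    eta = np.zeros(n)
    out = {}
    if 0 in steps:
        out[0] = beta.copy()
    for m in range(1, m_max + 1):
        g, w = martingale_weights(eta[prep.order], prep)
        u = x.T @ g
        denom = (w[:, None] * x**2).sum(axis=0) + penalty
        j = int(np.argmax(u**2 / denom))
        nu = u[j] / denom[j]
        beta[j] += nu
        eta = eta + x[:, j] * nu
        if m in steps:
            out[m] = beta.copy()
    return [out[m] for m in steps]


class _StepCox(_Backend):
    def grid(self, x, t, e):
        return [{}]

    def fit(self, x, t, e, hp):
        direction = self.spec.params.get("direction", "both")
        surv = pd.DataFrame({"time": t, "event": e})
        p = x.shape[1]
        current = set() if direction == "forward" else set(range(p))
        max_terms = int(self.spec.grid.get("max_terms", p))

        def aic_of(cols: set[int]) -> float:
            if not cols:
                null = fit_cox(np.zeros((len(t), 1)), surv)
                return -2.0 * null.null_loglik
            f = fit_cox(x[:, sorted(cols)], surv)
            return f.aic

        best_aic = aic_of(current)
        for _ in range(2 * p + 5):
            moves = []
            if direction in ("forward", "both") and len(current) < max_terms:
                moves += [("add", j) for j in range(p) if j not in current]
            if direction in ("backward", "both"):
                moves += [("drop", j) for j in sorted(current)]
            best_move, best_move_aic = None, best_aic
            for kind, j in moves:
                cols = current | {j} if kind == "add" else current - {j}
                try:
                    a = aic_of(cols)
                except (CoxError, np.linalg.LinAlgError):
                    continue
                if a < best_move_aic - 1e-10:
                    best_move, best_move_aic = (kind, j), a
            if best_move is None:
                break
            kind, j = best_move
            current = current | {j} if kind == "add" else current - {j}
            best_aic = best_move_aic
        cols = sorted(current)
        if cols:
            f = fit_cox(x[:, cols], surv)
            beta = np.zeros(p)
            beta[cols] = f.beta
        else:
            beta = np.zeros(p)
        return {"beta": beta, "aic": best_aic, "terms": cols}

    def predict(self, state, x):
        return x @ state["beta"]

    def selected(self, state, genes):
        cols = state["terms"]
        return _order_genes([genes[i] for i in cols], state["beta"][cols])


class _RSF(_Backend):
    def grid(self, x, t, e):
        n_trees = self.spec.grid.get("n_estimators", [500])
        if np.isscalar(n_trees):
            n_trees = [n_trees]
        leaf = int(self.spec.grid.get("min_samples_leaf", 15))
        return [{"n_estimators": int(k), "min_samples_leaf": leaf} for k in n_trees]

    def fit(self, x, t, e, hp):
        model = RandomSurvivalForest(
            n_estimators=hp["n_estimators"], min_samples_leaf=hp["min_samples_leaf"],
            random_state=self.seed, n_jobs=1)
        model.fit(x, _surv_y(t, e))
        return {"model": model, "x": x, "t": t, "e": e, "hp": hp}

    def predict(self, state, x):
        return state["model"].predict(x)  # expected cumulative hazard: risk

    def selected(self, state, genes):
        """Positive permutation importance on a seeded internal holdout.

        The forest is refit on 75% of the training samples and each gene's
        column is permuted on the held-out 25%; importance is the drop in
        held-out C-index (mean over repeats).  This avoids the inflated
        training-set importance of deep trees.
        """
        x, t, e, hp = state["x"], state["t"], state["e"], state["hp"]
        rng = np.random.default_rng(self.seed)
        n = len(t)
        perm = rng.permutation(n)
        n_hold = max(n // 4, 10)
        hold, tr = perm[:n_hold], perm[n_hold:]
        if e[tr].sum() < 2 or e[hold].sum() < 1:
            tr, hold = perm, perm  # tiny data: fall back to in-sample
        model = RandomSurvivalForest(
            n_estimators=hp["n_estimators"], min_samples_leaf=hp["min_samples_leaf"],
            random_state=self.seed, n_jobs=1)
        model.fit(x[tr], _surv_y(t[tr], e[tr]))
        base = _safe_c(model.predict(x[hold]), t[hold], e[hold])
        imp = np.zeros(x.shape[1])
        n_rep = int(self.spec.grid.get("importance_repeats", 5))
        for j in range(x.shape[1]):
            drops = []
            for r in range(n_rep):
                xp = x[hold].copy()
                xp[:, j] = xp[rng.permutation(len(hold)), j]
                drops.append(base - _safe_c(model.predict(xp), t[hold], e[hold]))
            imp[j] = np.mean(drops)
        pos = np.flatnonzero(imp > 0)
        return _order_genes([genes[i] for i in pos], imp[pos])


class _GBM(_Backend):
    def grid(self, x, t, e):
        trees = self.spec.grid.get("n_estimators", [50, 100, 200])
        if np.isscalar(trees):
            trees = [trees]
        return [{"n_estimators": int(k)} for k in trees]

    def fit(self, x, t, e, hp):
        model = GradientBoostingSurvivalAnalysis(
            loss="coxph", n_estimators=hp["n_estimators"], learning_rate=0.1,
            max_depth=3, random_state=self.seed)
        model.fit(x, _surv_y(t, e))
        return {"model": model}

    def predict(self, state, x):
        return state["model"].predict(x)


class _SurvSVM(_Backend):
    orientation: Orientation = "higher_is_protective"

    def grid(self, x, t, e):
        return [{"alpha": float(self.spec.grid.get("alpha", 1.0))}]

    def fit(self, x, t, e, hp):
        model = FastSurvivalSVM(alpha=hp["alpha"], rank_ratio=0.0,
                                fit_intercept=True, max_iter=100,
                                random_state=self.seed)
        model.fit(x, _surv_y(t, e))
        return {"model": model}

    def predict(self, state, x):
        return state["model"].predict(x)  # time-like: higher = longer survival


class _SuperPC(_Backend):
    def grid(self, x, t, e):
        qs = self.spec.grid.get("threshold_quantiles",
                                [round(0.1 * i, 1) for i in range(10)])
        ks = self.spec.grid.get("n_components", [1, 2, 3])
        # simplest first: fewest components, then fewest genes (high threshold)
        return [{"k": int(k), "q": float(q)} for k in ks for q in sorted(qs, reverse=True)]

    def fit(self, x, t, e, hp):
        surv = pd.DataFrame({"time": t, "event": e})
        z = _univariate_z(x, t, e)
        thr = np.quantile(np.abs(z), hp["q"])
        keep = np.flatnonzero(np.abs(z) >= thr)
        if len(keep) == 0:
            keep = np.array([int(np.argmax(np.abs(z)))])
        k = min(hp["k"], len(keep), x.shape[0] - 1)
        xs = x[:, keep]
        mu = xs.mean(axis=0)
        _, _, vt = np.linalg.svd(xs - mu, full_matrices=False)
        v = _sign_fixed(vt[:k].T)
        pcs = (xs - mu) @ v
        f = fit_cox(pcs, surv)
        return {"keep": keep, "mu": mu, "v": v, "gamma": f.beta}

    def predict(self, state, x):
        pcs = (x[:, state["keep"]] - state["mu"]) @ state["v"]
        return pcs @ state["gamma"]


class _PLSCox(_Backend):
    """Sequential PLS components for Cox regression.

    Each component weights genes by covariance with the current model's
    martingale residuals, the design is deflated against the component, and
    a Cox model on the components provides residuals for the next one.
    """

    def grid(self, x, t, e):
        ks = self.spec.grid.get("n_components", [1, 2, 3])
        return [{"k": int(k)} for k in ks]

    def fit(self, x, t, e, hp):
        from ._solvers import _prep_sorted, martingale_weights

        surv = pd.DataFrame({"time": t, "event": e})
        prep = _prep_sorted(t, e)
        xd = x.copy()
        ws, ps, comps = [], [], []
        eta = np.zeros(len(t))
        gamma = np.zeros(0)
        for _ in range(hp["k"]):
            r, _ = martingale_weights(eta[prep.order], prep)
            w = xd.T @ r
            norm = np.linalg.norm(w)
            if norm < 1e-12:
                break
            w = w / norm
            comp = xd @ w
            denom = comp @ comp
            if denom < 1e-12:
                break
            p_load = xd.T @ comp / denom
            xd = xd - np.outer(comp, p_load)
            ws.append(w)
            ps.append(p_load)
            comps.append(comp)
            tmat = np.column_stack(comps)
            f = fit_cox(tmat, surv)
            gamma = f.beta
            eta = tmat @ gamma
        return {"w": ws, "p": ps, "gamma": gamma}

    def predict(self, state, x):
        s = x.copy().astype(float)
        scores = np.zeros(x.shape[0])
        for c, (w, p_load) in enumerate(zip(state["w"], state["p"])):
            comp = s @ w
            s = s - np.outer(comp, p_load)
            if c < len(state["gamma"]):
                scores += state["gamma"][c] * comp
        return scores


def _sign_fixed(v: np.ndarray) -> np.ndarray:
    """Fix the sign of each loading column (largest |entry| positive)."""
    v = v.copy()
    for j in range(v.shape[1]):
        i = int(np.argmax(np.abs(v[:, j])))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    return v


def _univariate_z(x: np.ndarray, t: np.ndarray, e: np.ndarray) -> np.ndarray:
    from .coxph import _fit_univariate, _prepare

    prep = _prepare(t, e)
    z = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        try:
            beta, se, conv = _fit_univariate(x[:, j], prep)
            z[j] = beta / se if (conv and np.isfinite(se) and se > 0) else 0.0
        except (CoxError, np.linalg.LinAlgError):
            z[j] = 0.0
    return z


_BACKENDS = {
    "RSF": _RSF, "LASSO": _PenalizedCox, "Ridge": _PenalizedCox,
    "Enet": _PenalizedCox, "GBM": _GBM, "SurvSVM": _SurvSVM,
    "SuperPC": _SuperPC, "plsRcox": _PLSCox, "CoxBoost": _CoxBoost,
    "StepCox": _StepCox,
}


def _safe_c(scores, t, e) -> float:
    try:
        c, _ = harrell_cindex(scores, pd.DataFrame({"time": t, "event": e}))
        return c
    except EvaluationError:
        return np.nan


def _cv_folds(n: int, events: np.ndarray, plan: CVPlan):
    k = plan.effective_folds(int(events.sum()))
    kf = KFold(n_splits=k, shuffle=True, random_state=plan.seed % (2**31 - 1))
    folds = []
    for tr, va in kf.split(np.arange(n)):
        if events[tr].sum() >= 1:
            folds.append((tr, va))
    if not folds:
        raise LearnerError("no usable CV folds (too few events)")
    return folds


def fit_learner(spec: AlgorithmSpec, train: Cohort, cv: CVPlan) -> FittedLearner:
    """Tune by CV on the training cohort, then refit on all of it.

    The out-of-fold C-index is computed on risk-oriented validation scores;
    grid ties go to the smallest-complexity entry.
    """
    if not train.standardized:
        logger.warning("fit_learner: training cohort is not standardized")
    genes = tuple(train.genes)
    x = train.expr.to_numpy(dtype=float).T  # samples x genes
    t = train.surv["time"].to_numpy(dtype=float)
    e = train.surv["event"].to_numpy(dtype=int)
    seed = _rng_seed(cv.seed, spec.label)
    backend = _BACKENDS[spec.family](spec, seed)
    grid = backend.grid(x, t, e)

    if len(grid) == 1:
        best_hp, cv_scores = grid[0], None
    else:
        folds = _cv_folds(len(t), e, cv)
        if hasattr(backend, "cv_path"):
            score_mat = backend.cv_path(x, t, e, grid, folds)
        else:
            score_mat = np.full((len(folds), len(grid)), np.nan)
            for gi, hp in enumerate(grid):
                for fi, (tr, va) in enumerate(folds):
                    try:
                        state = backend.fit(x[tr], t[tr], e[tr], hp)
                        s = backend.predict(state, x[va])
                    except (LearnerError, CoxError, np.linalg.LinAlgError, ValueError):
                        continue
                    if backend.orientation == "higher_is_protective":
                        s = -s
                    score_mat[fi, gi] = _safe_c(s, t[va], e[va])
        mean_c = np.nanmean(score_mat, axis=0)
        if np.all(np.isnan(mean_c)):
            raise LearnerError(f"{spec.label}: grid exhausted without a valid fit")
        best_idx = int(np.nanargmax(mean_c))  # first max = simplest on ties
        best_hp = grid[best_idx]
        cv_scores = {"mean_c": mean_c.tolist(), "chosen_index": best_idx}

    state = backend.fit(x, t, e, best_hp)
    sel = backend.selected(state, genes) if spec.can_select else None
    return FittedLearner(
        spec=spec, genes_used=genes, selected_genes=sel,
        orientation=backend.orientation,
        cv_record={"chosen": best_hp, "folds": cv.folds, "seed": cv.seed,
                   "scores": cv_scores},
        state={"backend": backend, "fitted": state},
    )


def predict_scores(fl: FittedLearner, expr: pd.DataFrame) -> pd.Series:
    """Score samples (columns of a genes x samples frame); no imputation."""
    missing = [g for g in fl.genes_used if g not in expr.index]
    if missing:
        raise LearnerError(f"expression lacks required genes: {missing}")
    x = expr.loc[list(fl.genes_used)].to_numpy(dtype=float).T
    scores = fl.state["backend"].predict(fl.state["fitted"], x)
    return pd.Series(np.asarray(scores, dtype=float), index=expr.columns)


def select_features(fl: FittedLearner) -> tuple[str, ...]:
    if not fl.spec.can_select:
        raise LearnerError(f"{fl.spec.label} is not a selector")
    if fl.selected_genes is None or len(fl.selected_genes) == 0:
        raise SelectorEmptyError(f"{fl.spec.label}: selector returned no genes")
    return fl.selected_genes


# ---------------------------------------------------------------------------
# serialization (versioned archive; linear families as TSV coefficients)

_ARCHIVE_VERSION = 1
_LINEAR_FAMILIES = ("LASSO", "Ridge", "Enet", "CoxBoost", "StepCox")


def save_learner(fl: FittedLearner, path) -> None:
    """Write a versioned archive directory; linear families store a TSV
    coefficient table, other families a joblib state blob."""
    import joblib

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": _ARCHIVE_VERSION,
        "family": fl.spec.family,
        "params": fl.spec.params,
        "grid": fl.spec.grid,
        "genes_used": list(fl.genes_used),
        "selected_genes": list(fl.selected_genes) if fl.selected_genes is not None else None,
        "orientation": fl.orientation,
        "cv_record": {k: v for k, v in fl.cv_record.items() if k != "scores"},
        "seed": fl.state["backend"].seed,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    fitted = fl.state["fitted"]
    if fl.spec.family in _LINEAR_FAMILIES:
        pd.DataFrame({"gene": list(fl.genes_used), "coefficient": fitted["beta"]}) \
            .to_csv(path / "coefficients.tsv", sep="\t", index=False,
                    float_format="%.17g")  # exact float64 round trip
        extra = {k: v for k, v in fitted.items() if k != "beta"}
        if fl.spec.family == "StepCox":
            extra["terms"] = [int(i) for i in fitted["terms"]]
        (path / "extra.json").write_text(json.dumps(extra, default=float))
    else:
        joblib.dump(fitted, path / "state.joblib")


def load_learner(path) -> FittedLearner:
    import joblib

    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta["version"] != _ARCHIVE_VERSION:
        raise LearnerError(f"unsupported archive version {meta['version']}")
    spec = AlgorithmSpec(meta["family"], meta["params"], meta["grid"])
    backend = _BACKENDS[spec.family](spec, meta["seed"])
    if spec.family in _LINEAR_FAMILIES:
        coefs = pd.read_csv(path / "coefficients.tsv", sep="\t",
                            float_precision="round_trip")
        fitted = {"beta": coefs["coefficient"].to_numpy(dtype=float)}
        fitted.update(json.loads((path / "extra.json").read_text()))
    else:
        fitted = joblib.load(path / "state.joblib")
    sel = meta["selected_genes"]
    return FittedLearner(
        spec=spec, genes_used=tuple(meta["genes_used"]),
        selected_genes=tuple(sel) if sel is not None else None,
        orientation=meta["orientation"], cv_record=meta["cv_record"],
        state={"backend": backend, "fitted": fitted},
    )
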