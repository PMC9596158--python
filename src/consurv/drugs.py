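"""Drug-repurposing screen: cell-line-to-patient sensitivity transfer plus a
thresholded decile differential / correlation screen.

Per compound, a ridge regression of cell-line AUC (area under the
dose-response curve; lower = more sensitive) on cell-line expression is
tuned by 10-fold CV and applied to patient expression (standardized with
the cell-line panel's parameters).  Estimated patient AUCs are then screened
two ways against the signature score (protective orientation):

(a) differential — compare the top and bottom score deciles with a two-sided
    Wilcoxon rank-sum test; log2FC = log2(mean AUC low group / mean AUC high
    group), so log2FC > threshold selects compounds with *lower* AUC (more
    sensitivity) in the high-score group;
(b) correlation — Spearman r between estimated AUC and score over all
    patients, requiring r below a negative threshold.

Hits are the intersection of (a) and (b), sorted by r ascending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)


class DrugScreenError(ValueError):
    pass


@dataclass(frozen=True)
class DrugScreenConfig:
    decile_fraction: float = 0.10
    log2fc_threshold: float = 0.2
    spearman_threshold: float = -0.4
    wilcoxon_alpha: float = 0.05
    max_missing_fraction: float = 0.2
    min_lines_per_compound: int = 10
    min_gene_overlap: int = 100
    ridge_lambda_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.decile_fraction <= 0.5):
            raise ValueError("decile_fraction must be in (0, 0.5]")
        if self.spearman_threshold >= 0:
            raise ValueError("spearman_threshold must be negative")


@dataclass(frozen=True)
class DrugHit:
    compound: str
    log2fc: float
    wilcoxon_p: float
    spearman_r: float
    passed_differential: bool
    passed_correlation: bool

    @property
    def is_hit(self) -> bool:
        return self.passed_differential and self.passed_correlation


def _kfold_ridge_cv(x: np.ndarray, y: np.ndarray, lambdas, folds: int, seed: int) -> float:
    """Pick ridge lambda by K-fold CV MSE; one SVD per fold shared across
    the lambda grid."""
    n = len(y)
    k = min(folds, n)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed % (2**31 - 1))
    lambdas = np.asarray(lambdas, dtype=float)
    sse = np.zeros(len(lambdas))
    for tr, va in kf.split(np.arange(n)):
        xtr, ytr = x[tr], y[tr]
        ybar = ytr.mean()
        u, s, vt = np.linalg.svd(xtr, full_matrices=False)
        uty = u.T @ (ytr - ybar)
        for li, lam in enumerate(lambdas):
            d = s / (s**2 + lam)
            beta = vt.T @ (d * uty)
            pred = x[va] @ beta + ybar
            sse[li] += np.sum((y[va] - pred) ** 2)
    return float(lambdas[int(np.argmin(sse))])


def _ridge_fit(x: np.ndarray, y: np.ndarray, lam: float):
    ybar = y.mean()
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    beta = vt.T @ ((s / (s**2 + lam)) * (u.T @ (y - ybar)))
    return beta, ybar


def estimate_patient_auc(
    ccl_expr: pd.DataFrame,
    drm: pd.DataFrame,
    patient_expr: pd.DataFrame,
    cfg: DrugScreenConfig | None = None,
) -> pd.DataFrame:
    """Estimated AUC per patient x compound via ridge transfer.

    ``ccl_expr``: genes x cell lines; ``drm``: cell lines x compounds (NaN =
    missing); ``patient_expr``: genes x patients.  Genes are standardized on
    the cell-line panel; patient expression reuses the panel's mean/SD.
    """
    cfg = cfg or DrugScreenConfig()
    genes = [g for g in ccl_expr.index if g in patient_expr.index]
    if len(genes) == 0:
        raise DrugScreenError("zero gene overlap between cell lines and patients")
    if len(genes) < cfg.min_gene_overlap:
        logger.warning("gene overlap %d below configured minimum %d",
                       len(genes), cfg.min_gene_overlap)
    xc = ccl_expr.loc[genes].to_numpy(dtype=float)
    mu = xc.mean(axis=1, keepdims=True)
    sd = xc.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    xc = ((xc - mu) / sd).T                      # lines x genes
    xp = ((patient_expr.loc[genes].to_numpy(dtype=float) - mu) / sd).T

    lines = list(ccl_expr.columns)
    drm = drm.loc[[l for l in lines if l in drm.index]]
    preds = {}
    for comp in drm.columns:
        y_all = drm[comp]
        obs = y_all.notna()
        frac_missing = 1.0 - obs.mean()
        if frac_missing > cfg.max_missing_fraction:
            logger.info("compound %s dropped: %.0f%% missing", comp, 100 * frac_missing)
            continue
        if obs.sum() < cfg.min_lines_per_compound:
            logger.info("compound %s excluded: only %d observed lines", comp, int(obs.sum()))
            continue
        rows = [lines.index(l) for l in y_all.index[obs]]
        x = xc[rows]
        y = y_all[obs].to_numpy(dtype=float)
        lam = _kfold_ridge_cv(x, y, cfg.ridge_lambda_grid, cfg.cv_folds, cfg.seed)
        beta, ybar = _ridge_fit(x, y, lam)
        preds[comp] = xp @ beta + ybar
    if not preds:
        raise DrugScreenError("no compound passed the missingness/coverage filters")
    return pd.DataFrame(preds, index=patient_expr.columns)


def screen_drugs(
    est_auc: pd.DataFrame,
    scores: pd.Series,
    cfg: DrugScreenConfig | None = None,
) -> list[DrugHit]:
    """Decile differential + correlation screen (see module docstring).

    ``scores`` are signature scores in protective orientation aligned to the
    rows of ``est_auc``; the 'high' group is the top ``decile_fraction`` of
    scores and the 'low' group the bottom.
    """
    cfg = cfg or DrugScreenConfig()
    if not est_auc.index.equals(scores.index):
        scores = scores.loc[est_auc.index]
    n = len(scores)
    if n < 20:
        raise DrugScreenError("need at least 20 patients for the decile screen")
    n_dec = int(np.floor(n * cfg.decile_fraction))
    if n_dec < 5:
        raise DrugScreenError("cohort too small for decile screen")
    order = np.argsort(scores.to_numpy(), kind="stable")
    low_idx = order[:n_dec]
    high_idx = order[-n_dec:]

    hits: list[DrugHit] = []
    s_all = scores.to_numpy()
    for comp in est_auc.columns:
        a = est_auc[comp].to_numpy(dtype=float)
        obs = np.isfinite(a)
        lo = a[low_idx][np.isfinite(a[low_idx])]
        hi = a[high_idx][np.isfinite(a[high_idx])]
        if len(lo) == 0 or len(hi) == 0:
            continue
        mean_lo, mean_hi = lo.mean(), hi.mean()
        if mean_lo <= 0 or mean_hi <= 0:
            log2fc = float("nan")
        else:
            log2fc = float(np.log2(mean_lo / mean_hi))
        if np.all(lo[:, None] == hi[None, :]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(lo, hi, alternative="two-sided").pvalue)
        if np.ptp(a[obs]) == 0:  # flat compound: correlation undefined
            r = float("nan")
        else:
            r = float(stats.spearmanr(a[obs], s_all[obs]).statistic)
        passed_diff = bool(np.isfinite(log2fc) and log2fc > cfg.log2fc_threshold
                           and p < cfg.wilcoxon_alpha)
        passed_corr = bool(np.isfinite(r) and r < cfg.spearman_threshold)
        hits.append(DrugHit(compound=comp, log2fc=log2fc, wilcoxon_p=p,
                            spearman_r=r, passed_differential=passed_diff,
                            passed_correlation=passed_corr))
    hits.sort(key=lambda h: (not h.is_hit, h.spearman_r))
    return hits


def hits_to_frame(hits) -> pd.DataFrame:
    return pd.DataFrame([{
        "compound": h.compound, "log2fc": h.log2fc, "wilcoxon_p": h.wilcoxon_p,
        "spearman_r": h.spearman_r, "passed_differential": h.passed_differential,
        "passed_correlation": h.passed_correlation, "hit": h.is_hit,
    } for h in hits])
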