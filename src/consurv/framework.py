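"""Selector x modeler combination sweep and the consensus signature.

Enumerates algorithm combinations from a roster file, runs each on the
training cohort (selector first, if present, to reduce the gene set; then
the modeler on the reduced set), scores the training and every testing
cohort, ranks combinations by the mean held-out C-index over the *testing*
cohorts only, and emits the winning combination as a deployable
:class:`SignatureModel`.

Testing cohorts are touched only at the scoring step — never during selector
or modeler fitting or tuning — so the mean testing C-index is an honest
held-out estimate for each combination (selection bias across combinations
remains, which is why external validation matters).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohorts import Cohort, MultiCohort, standardize
from .evaluation import EvaluationError, harrell_cindex
from .learners import (AlgorithmSpec, CVPlan, FittedLearner, LearnerError,
                       SelectorEmptyError, fit_learner, predict_scores,
                       select_features, spec_from_label)

logger = logging.getLogger(__name__)

ROSTER_VERSION = 1


class FrameworkError(ValueError):
    pass


@dataclass(frozen=True)
class CombinationSpec:
    """One pipeline: optional selector (dimension reduction) + modeler."""

    selector: AlgorithmSpec | None
    modeler: AlgorithmSpec

    def __post_init__(self) -> None:
        if self.selector is not None and not self.selector.can_select:
            raise FrameworkError(
                f"{self.selector.label} cannot act as a selector")

    @property
    def label(self) -> str:
        if self.selector is None:
            return self.modeler.label
        return f"{self.selector.label} + {self.modeler.label}"


def _builtin_roster_path(name: str):
    return resources.files("consurv").joinpath(f"rosters/{name}.yaml")


def load_roster(source) -> dict:
    """Load a roster config: a path, or a shipped roster name
    (``"default"`` — the 76 combinations; ``"remodel"`` — the 18 single
    models)."""
    if isinstance(source, str) and source in ("default", "remodel"):
        text = _builtin_roster_path(source).read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    if cfg.get("version") != ROSTER_VERSION:
        raise FrameworkError(f"unsupported roster version {cfg.get('version')!r}")
    return cfg


def enumerate_combinations(roster: dict | str, grids: dict | None = None) -> list[CombinationSpec]:
    """Expand a roster config into a duplicate-free, ordered combination list.

    The roster's ``combinations`` entries are explicit labels, either a
    single algorithm (``"CoxBoost"``) or ``"Selector + Modeler"``.
    ``grids`` optionally maps family name -> hyper-grid override (applied to
    every variant of the family, e.g. reduced grids for quick sweeps).
    """
    if isinstance(roster, str) or not isinstance(roster, dict):
        roster = load_roster(roster)
    grids = grids or {}
    combos: list[CombinationSpec] = []
    seen: set[str] = set()
    for entry in roster["combinations"]:
        parts = [p.strip() for p in str(entry).split("+")]
        if len(parts) == 1:
            sel = None
            mod = spec_from_label(parts[0])
        elif len(parts) == 2:
            sel = spec_from_label(parts[0])
            mod = spec_from_label(parts[1])
        else:
            raise FrameworkError(f"bad roster entry {entry!r}")
        if sel is not None:
            sel = AlgorithmSpec(sel.family, sel.params, grids.get(sel.family, {}))
        mod = AlgorithmSpec(mod.family, mod.params, grids.get(mod.family, {}))
        spec = CombinationSpec(selector=sel, modeler=mod)
        if spec.label in seen:
            raise FrameworkError(f"duplicate combination label {spec.label!r}")
        seen.add(spec.label)
        combos.append(spec)
    return combos


@dataclass(frozen=True)
class LeaderboardRow:
    label: str
    cindex: dict[str, float]          # cohort name -> C (training + testing)
    mean_testing_cindex: float
    n_selected_genes: int
    status: str                       # "ok" | "skipped"
    reason: str = ""


@dataclass(frozen=True)
class SignatureModel:
    """The deployable winning signature.

    ``score`` returns user-facing scores in *protective* orientation
    (higher = better outcome); ``risk_score`` returns the negated
    (risk-oriented) version used for concordance.
    """

    genes: tuple[str, ...]
    modeler: FittedLearner
    label: str
    provenance: dict

    def risk_score(self, cohort: Cohort) -> pd.Series:
        c = cohort if cohort.standardized else standardize(cohort)
        s = predict_scores(self.modeler, c.expr.loc[list(self.genes)])
        return s if self.modeler.orientation == "higher_is_risk" else -s

    def score(self, cohort: Cohort) -> pd.Series:
        return -self.risk_score(cohort)


def _combo_cv(cv: CVPlan, label: str) -> CVPlan:
    """Per-combination RNG stream: master seed + label hash, order-independent."""
    return CVPlan(folds=cv.folds,
                  seed=(cv.seed + zlib.crc32(label.encode())) % (2**31 - 1))


def run_combination(
    spec: CombinationSpec,
    train: Cohort,
    testing: MultiCohort | Sequence[Cohort],
    cv: CVPlan,
    input_genes: Sequence[str],
    _selector_cache: dict | None = None,
) -> tuple[LeaderboardRow, SignatureModel | None]:
    """Fit one combination on the training cohort and score all cohorts.

    Selector or modeler failures yield a skipped row, never an exception.
    """
    testing_cohorts = list(testing)
    train_s = train if train.standardized else standardize(train)
    train_in = train_s.subset_genes(list(input_genes))
    try:
        if spec.selector is not None:
            key = spec.selector.label
            if _selector_cache is not None and key in _selector_cache:
                genes = _selector_cache[key]
            else:
                sel_fit = fit_learner(spec.selector, train_in,
                                      _combo_cv(cv, key))
                genes = select_features(sel_fit)
                if _selector_cache is not None:
                    _selector_cache[key] = genes
        else:
            genes = tuple(input_genes)
        modeler_fit = fit_learner(spec.modeler, train_s.subset_genes(list(genes)),
                                  _combo_cv(cv, spec.label))
        sig = SignatureModel(
            genes=tuple(genes), modeler=modeler_fit, label=spec.label,
            provenance={"cv_seed": cv.seed, "folds": cv.folds,
                        "input_genes": list(input_genes)})
        cidx: dict[str, float] = {}
        cidx[train.name] = harrell_cindex(
            sig.risk_score(train_s).to_numpy(), train_s.surv)[0]
        test_cs = []
        for c in testing_cohorts:
            cs = c if c.standardized else standardize(c)
            cidx[c.name] = harrell_cindex(sig.risk_score(cs).to_numpy(), cs.surv)[0]
            test_cs.append(cidx[c.name])
        row = LeaderboardRow(
            label=spec.label, cindex=cidx,
            mean_testing_cindex=float(np.mean(test_cs)),
            n_selected_genes=len(genes), status="ok")
        return row, sig
    except SelectorEmptyError:
        reason = "selector returned no genes"
    except (LearnerError, EvaluationError, np.linalg.LinAlgError, ValueError) as exc:
        reason = f"{type(exc).__name__}: {exc}"
    logger.warning("combination %s skipped: %s", spec.label, reason)
    row = LeaderboardRow(label=spec.label, cindex={},
                         mean_testing_cindex=float("nan"),
                         n_selected_genes=0, status="skipped", reason=reason)
    return row, None


def run_sweep(
    combos: Sequence[CombinationSpec],
    train: Cohort,
    testing: MultiCohort | Sequence[Cohort],
    cv: CVPlan,
    input_genes: Sequence[str],
) -> tuple[list[LeaderboardRow], dict[str, SignatureModel]]:
    """Run every combination; selector fits are cached by selector label
    (each selector's gene set is identical for all of its modelers)."""
    cache: dict = {}
    rows, sigs = [], {}
    for spec in combos:
        row, sig = run_combination(spec, train, testing, cv, input_genes,
                                   _selector_cache=cache)
        rows.append(row)
        if sig is not None:
            sigs[spec.label] = sig
    return rows, sigs


def build_leaderboard(rows: Sequence[LeaderboardRow]) -> tuple[pd.DataFrame, str]:
    """Rank rows by mean testing C-index (desc); ties by fewer genes, then
    label.  Returns the ranked table and the winning label."""
    ok = [r for r in rows if r.status == "ok"]
    if not ok:
        raise FrameworkError("all combinations were skipped")
    ranked = sorted(ok, key=lambda r: (-r.mean_testing_cindex,
                                       r.n_selected_genes, r.label))
    skipped = [r for r in rows if r.status != "ok"]
    records = []
    for r in ranked + skipped:
        rec = {"label": r.label, "mean_testing_cindex": r.mean_testing_cindex,
               "n_genes": r.n_selected_genes, "status": r.status, "reason": r.reason}
        rec.update({f"C_{k}": v for k, v in r.cindex.items()})
        records.append(rec)
    return pd.DataFrame(records), ranked[0].label


def score_and_stratify(sig: SignatureModel, cohort: Cohort) -> tuple[pd.Series, pd.Series]:
    """Protective scores plus a median split into 'high' / 'low' groups.

    Samples exactly at the median go to the high group (documented
    convention); constant scores put every sample in 'high' with a warning.
    """
    scores = sig.score(cohort)
    med = float(np.median(scores.to_numpy()))
    if np.ptp(scores.to_numpy()) == 0:
        logger.warning("score_and_stratify: constant scores; all samples 'high'")
    groups = pd.Series(np.where(scores.to_numpy() >= med, "high", "low"),
                       index=scores.index, name="group")
    return scores, groups


def leaderboard_to_tsv(board: pd.DataFrame, path) -> None:
    board.to_csv(path, sep="\t", index=False)
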