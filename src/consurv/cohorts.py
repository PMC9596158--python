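"""Multi-cohort expression + survival containers and I/O.

A :class:`Cohort` pairs a log-scale gene x sample expression matrix with a
survival table (time, event, optional covariates) for one study.  Cohorts
from several studies are aligned on their shared gene space into a
:class:`MultiCohort`, which is the substrate for cross-cohort screening and
model sweeps.  A batch-adjusted "Meta" cohort can be assembled by per-cohort
gene-wise z-scoring followed by sample concatenation.

Expression tables are TSV/CSV with the gene identifier in the first column
and one column per sample; clinical tables require ``sample_id``, ``time``
and ``event`` columns, with any extra columns preserved as covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Role = Literal["training", "testing", "external"]

REQUIRED_CLINICAL_COLUMNS = ("sample_id", "time", "event")


class CohortValidationError(ValueError):
    """Raised when expression/survival tables violate the data contract."""


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass(frozen=True)
class Cohort:
    """One study: aligned expression matrix and survival table.

    Parameters
    ----------
    name : str
        Study label, e.g. a cohort accession.
    role : {"training", "testing", "external"}
        How the cohort participates in the model sweep.
    expr : pandas.DataFrame
        Genes x samples, log-scale normalized expression.
    surv : pandas.DataFrame
        Indexed by sample id; columns ``time`` (positive, one declared unit
        per run), ``event`` (0/1) and optional covariates.
    standardized : bool
        Whether gene rows have been z-scored within this cohort.
    constant_genes : tuple of str
        Genes flagged as constant (zeroed) during standardization.
    """

    name: str
    role: Role
    expr: pd.DataFrame
    surv: pd.DataFrame
    standardized: bool = False
    constant_genes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        validate_cohort(self)

    @property
    def genes(self) -> list[str]:
        return list(self.expr.index)

    @property
    def samples(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.surv["event"].sum())

    def subset_genes(self, genes: Sequence[str]) -> "Cohort":
        missing = [g for g in genes if g not in self.expr.index]
        if missing:
            raise KeyError(f"genes not in cohort {self.name!r}: {missing[:10]}")
        return replace(self, expr=self.expr.loc[list(genes)])


def validate_cohort(c: Cohort) -> None:
    expr, surv = c.expr, c.surv
    if expr.index.duplicated().any():
        dup = expr.index[expr.index.duplicated()].unique().tolist()
        raise CohortValidationError(f"duplicate gene ids: {dup[:10]}")
    if expr.columns.duplicated().any():
        dup = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise CohortValidationError(f"duplicate sample ids: {dup[:10]}")
    if surv.index.duplicated().any():
        dup = surv.index[surv.index.duplicated()].unique().tolist()
        raise CohortValidationError(f"duplicate survival sample ids: {dup[:10]}")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise CohortValidationError(
            f"cohort {c.name!r}: expression contains missing/non-finite values; "
            "impute upstream"
        )
    for col in ("time", "event"):
        if col not in surv.columns:
            raise CohortValidationError(f"survival table lacks column {col!r}")
    bad_time = surv.index[~(surv["time"].to_numpy(dtype=float) > 0)].tolist()
    if bad_time:
        raise CohortValidationError(f"nonpositive survival time for samples: {bad_time[:10]}")
    ev = surv["event"].to_numpy(dtype=float)
    bad_ev = surv.index[~np.isin(ev, (0.0, 1.0))].tolist()
    if bad_ev:
        raise CohortValidationError(f"event not in {{0,1}} for samples: {bad_ev[:10]}")
    if set(expr.columns) != set(surv.index):
        raise CohortValidationError(
            f"cohort {c.name!r}: expression and survival sample sets differ"
        )
    if list(expr.columns) != list(surv.index):
        raise CohortValidationError(
            f"cohort {c.name!r}: expression and survival sample order differ"
        )
    if expr.shape[1] < 2:
        raise CohortValidationError(f"cohort {c.name!r}: fewer than 2 samples")
    if int(surv["event"].sum()) < 1:
        raise CohortValidationError(f"cohort {c.name!r}: no events")


@dataclass(frozen=True)
class MultiCohort:
    """Cohorts aligned to a shared, identically ordered gene space."""

    cohorts: tuple[Cohort, ...]
    shared_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        for c in self.cohorts:
            if tuple(c.genes) != self.shared_genes:
                raise CohortValidationError(
                    f"cohort {c.name!r} gene vector differs from shared_genes"
                )

    def __iter__(self):
        return iter(self.cohorts)

    def __len__(self) -> int:
        return len(self.cohorts)

    def by_role(self, role: Role) -> list[Cohort]:
        return [c for c in self.cohorts if c.role == role]

    def get(self, name: str) -> Cohort:
        for c in self.cohorts:
            if c.name == name:
                return c
        raise KeyError(name)


def read_cohort(expr_path, clin_path, name: str, role: Role = "testing") -> Cohort:
    """Read and inner-join an expression table and a clinical table.

    Samples present in only one of the two tables are dropped (count logged).
    """
    expr = pd.read_csv(expr_path, sep=_sep_for(expr_path), index_col=0)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    clin = pd.read_csv(clin_path, sep=_sep_for(clin_path))
    for col in REQUIRED_CLINICAL_COLUMNS:
        if col not in clin.columns:
            raise CohortValidationError(
                f"clinical table {clin_path} lacks required column {col!r}"
            )
    clin = clin.set_index(clin["sample_id"].astype(str)).drop(columns=["sample_id"])
    common = [s for s in expr.columns if s in clin.index]
    if not common:
        raise CohortValidationError(
            f"cohort {name!r}: zero overlapping samples between expression and clinical"
        )
    dropped = (len(expr.columns) - len(common)) + (len(clin.index) - len(common))
    if dropped:
        logger.warning("cohort %s: %d sample(s) dropped (unmatched ids)", name, dropped)
    return Cohort(name=name, role=role, expr=expr[common], surv=clin.loc[common])


def write_cohort(cohort: Cohort, expr_path, clin_path) -> None:
    """Serialize a cohort in the same TSV/CSV dialect used by :func:`read_cohort`."""
    expr = cohort.expr.copy()
    expr.index.name = "gene_id"
    expr.to_csv(expr_path, sep=_sep_for(expr_path))
    clin = cohort.surv.copy()
    clin.insert(0, "sample_id", clin.index)
    clin.to_csv(clin_path, sep=_sep_for(clin_path), index=False)


def intersect_genes(cohorts: Sequence[Cohort]) -> MultiCohort:
    """Align cohorts to their gene intersection (order from the first cohort)."""
    if len(cohorts) < 2:
        raise ValueError("intersect_genes requires at least 2 cohorts")
    shared = set(cohorts[0].genes)
    for c in cohorts[1:]:
        shared &= set(c.genes)
    if not shared:
        raise CohortValidationError("empty gene intersection across cohorts")
    ordered = tuple(g for g in cohorts[0].genes if g in shared)
    return MultiCohort(
        cohorts=tuple(c.subset_genes(ordered) for c in cohorts),
        shared_genes=ordered,
    )


def standardize(cohort: Cohort) -> Cohort:
    """Z-score each gene row within the cohort (ddof=1); constant genes zeroed."""
    x = cohort.expr.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    const = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd[const] = 1.0
    z = (x - mu) / sd
    z[const] = 0.0
    flagged = tuple(np.asarray(cohort.genes)[const])
    if flagged:
        logger.warning("cohort %s: %d constant gene(s) zeroed", cohort.name, len(flagged))
    return replace(
        cohort,
        expr=pd.DataFrame(z, index=cohort.expr.index, columns=cohort.expr.columns),
        standardized=True,
        constant_genes=flagged,
    )


def standardize_all(mc: MultiCohort) -> MultiCohort:
    return MultiCohort(
        cohorts=tuple(standardize(c) for c in mc.cohorts), shared_genes=mc.shared_genes
    )


def assemble_meta(mc: MultiCohort, name: str = "Meta") -> Cohort:
    """Pooled cohort: per-cohort gene-wise z-scoring, then sample concatenation.

    The z-scoring acts as a location/scale batch adjustment, so every cohort
    contributes mean-zero unit-variance gene rows.  Duplicate sample ids
    across cohorts ("repetitions") keep the first occurrence in cohort order.
    """
    exprs, survs = [], []
    seen: set[str] = set()
    n_dup = 0
    for c in mc.cohorts:
        cs = c if c.standardized else standardize(c)
        keep = [s for s in cs.samples if s not in seen]
        n_dup += cs.n_samples - len(keep)
        seen.update(keep)
        exprs.append(cs.expr[keep])
        survs.append(cs.surv.loc[keep, ["time", "event"]])
    if n_dup:
        logger.warning("assemble_meta: %d repetition(s) removed", n_dup)
    return Cohort(
        name=name,
        role="testing",
        expr=pd.concat(exprs, axis=1),
        surv=pd.concat(survs, axis=0),
        standardized=False,
    )
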