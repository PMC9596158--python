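"""Seeded synthetic multi-cohort survival-expression data and drug panels.

The generator plants proportional-hazards gene effects in correlated
Gaussian expression, applies cohort-level batch shift/scale perturbations,
draws event times from a Weibull baseline via the inverse-CDF under the PH
model, and calibrates an independent uniform censoring distribution by
bisection so the realized censored fraction matches a target.  Every draw is
reproducible from the config seed.

A companion generator builds a synthetic cell-line drug panel: expression,
a signature score per line, and an AUC matrix in which planted "sensitive"
compounds have AUC decreasing in the score while null compounds are
independent of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohorts import Cohort, MultiCohort


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one multi-cohort simulation.

    Parameters
    ----------
    K : int
        Number of cohorts.
    n_per_cohort : int or sequence of int
        Samples per cohort (a scalar applies to all K).
    G : int
        Number of genes.
    planted : mapping gene index/name -> log hazard ratio
        Per-standard-deviation log-HR of each planted gene; all other genes
        carry no effect.
    baseline_shape, baseline_scale : float
        Weibull baseline hazard parameters (time in months by default).
    censor_target : float in [0, 1)
        Desired censored fraction; the censoring distribution is calibrated
        by bisection to hit it in expectation.
    batch_shift_sd : float
        SD of the per-cohort, per-gene additive batch shift.
    batch_scale_range : (float, float)
        Uniform range of the per-cohort, per-gene multiplicative batch scale.
    block_corr : float in [0, 1)
        Equicorrelation within consecutive gene blocks of ``block_size``.
    """

    K: int = 10
    n_per_cohort: int | Sequence[int] = 150
    G: int = 2000
    planted: Mapping[str, float] = field(default_factory=dict)
    baseline_shape: float = 1.2
    baseline_scale: float = 30.0
    censor_target: float = 0.3
    batch_shift_sd: float = 0.5
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    block_corr: float = 0.2
    block_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.censor_target < 1.0):
            raise ValueError("censor_target must be in [0, 1)")
        if not (0.0 <= self.block_corr < 1.0):
            raise ValueError("block_corr must be in [0, 1)")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull parameters must be positive")

    def gene_names(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.G)]

    def sizes(self) -> list[int]:
        if np.isscalar(self.n_per_cohort):
            return [int(self.n_per_cohort)] * self.K
        sizes = [int(n) for n in self.n_per_cohort]
        if len(sizes) != self.K:
            raise ValueError("n_per_cohort length must equal K")
        return sizes


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulation run."""

    planted: dict[str, float]
    linear_predictor: dict[str, pd.Series]  # cohort name -> per-sample true lp
    batch_shift: dict[str, np.ndarray]
    batch_scale: dict[str, np.ndarray]

    def planted_genes(self) -> list[str]:
        return sorted(self.planted)


def _block_gaussian(rng: np.random.Generator, n: int, G: int, rho: float, block: int) -> np.ndarray:
    """Genes x samples equicorrelated-block Gaussian draws.

    Within each block of ``block`` consecutive genes, pairwise correlation is
    ``rho`` (one shared factor per block); blocks are independent.
    """
    z = rng.standard_normal((G, n))
    if rho <= 0:
        return z
    n_blocks = int(np.ceil(G / block))
    shared = rng.standard_normal((n_blocks, n))
    shared_full = np.repeat(shared, block, axis=0)[:G]
    return np.sqrt(rho) * shared_full + np.sqrt(1.0 - rho) * z


def _weibull_ph_times(
    rng: np.random.Generator, lp: np.ndarray, shape: float, scale: float
) -> np.ndarray:
    """Inverse-CDF event times: t = scale * (-log U * exp(-lp))**(1/shape)."""
    u = rng.uniform(size=lp.shape)
    return scale * (-np.log(u) * np.exp(-lp)) ** (1.0 / shape)


def _calibrate_cmax(event_times: np.ndarray, censor_target: float) -> float:
    """Bisect c so that, with C ~ U(0, c), E[censored fraction] = target.

    P(C_i < T_i) = min(T_i / c, 1); the mean of this over samples is
    decreasing in c, so plain bisection applies.
    """
    if censor_target <= 0:
        return np.inf

    def frac(c: float) -> float:
        return float(np.mean(np.minimum(event_times / c, 1.0)))

    lo, hi = 1e-9, float(event_times.max()) * 2
    while frac(hi) > censor_target:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > censor_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_multicohort(cfg: SimConfig) -> tuple[MultiCohort, SimTruth]:
    """Draw K cohorts with planted PH effects, batch perturbation and censoring."""
    genes = cfg.gene_names()
    gene_pos = {g: i for i, g in enumerate(genes)}
    beta = np.zeros(cfg.G)
    for g, b in cfg.planted.items():
        if g not in gene_pos:
            raise ValueError(f"planted gene {g!r} is not in the simulated gene set")
        beta[gene_pos[g]] = float(b)

    root = np.random.SeedSequence(cfg.seed)
    cohort_seeds = root.spawn(cfg.K)
    cohorts: list[Cohort] = []
    lp_map: dict[str, pd.Series] = {}
    shift_map: dict[str, np.ndarray] = {}
    scale_map: dict[str, np.ndarray] = {}

    for k, (n, ss) in enumerate(zip(cfg.sizes(), cohort_seeds)):
        rng = np.random.default_rng(ss)
        name = f"cohort{k:02d}"
        x = _block_gaussian(rng, n, cfg.G, cfg.block_corr, cfg.block_size)
        lp = beta @ x  # pre-batch linear predictor
        t_event = _weibull_ph_times(rng, lp, cfg.baseline_shape, cfg.baseline_scale)
        cmax = _calibrate_cmax(t_event, cfg.censor_target)
        t_cens = rng.uniform(0.0, cmax, size=n) if np.isfinite(cmax) else np.full(n, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        time = np.maximum(time, 1e-8)
        if event.sum() == 0:  # degenerate draw under extreme censoring
            event[int(np.argmax(time))] = 1

        shift = rng.normal(0.0, cfg.batch_shift_sd, size=cfg.G)
        scale = rng.uniform(*cfg.batch_scale_range, size=cfg.G)
        x_obs = x * scale[:, None] + shift[:, None]

        samples = [f"{name}_s{i:04d}" for i in range(n)]
        expr = pd.DataFrame(x_obs, index=genes, columns=samples)
        surv = pd.DataFrame({"time": time, "event": event}, index=samples)
        role: str = "training" if k == 0 else "testing"
        cohorts.append(Cohort(name=name, role=role, expr=expr, surv=surv))
        lp_map[name] = pd.Series(lp, index=samples)
        shift_map[name] = shift
        scale_map[name] = scale

    mc = MultiCohort(cohorts=tuple(cohorts), shared_genes=tuple(genes))
    truth = SimTruth(
        planted={g: float(b) for g, b in cfg.planted.items()},
        linear_predictor=lp_map,
        batch_shift=shift_map,
        batch_scale=scale_map,
    )
    return mc, truth


def true_survival_probability(
    cfg: SimConfig, lp: np.ndarray, t: float
) -> np.ndarray:
    """Model-true S(t | x) = exp(-(t/scale)^shape * exp(lp)) for the generator."""
    lam = (t / cfg.baseline_scale) ** cfg.baseline_shape
    return np.exp(-lam * np.exp(np.asarray(lp, dtype=float)))


def simulate_drug_panel(
    n_lines: int,
    n_compounds: int,
    n_sensitive: int,
    signature_weights: Mapping[str, float],
    noise_sd: float = 0.5,
    seed: int = 0,
    n_extra_genes: int = 50,
    auc_baseline: float = 10.0,
    sensitivity_slope: float = 2.0,
    missing_fraction: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Synthetic cell-line panel for the drug-repurposing screen.

    Returns ``(expression genes x lines, AUC lines x compounds, sensitive ids)``.
    Sensitive compounds follow ``AUC = a - b * score + noise`` (lower AUC at
    high signature score, i.e. more sensitive); null compounds are independent
    of the score.  About ``missing_fraction`` of AUC entries are set missing
    at random.
    """
    if n_sensitive > n_compounds:
        raise ValueError("n_sensitive must not exceed n_compounds")
    rng = np.random.default_rng(seed)
    sig_genes = list(signature_weights)
    genes = sig_genes + [f"x{i:04d}" for i in range(n_extra_genes)]
    lines = [f"CL{i:04d}" for i in range(n_lines)]
    x = rng.standard_normal((len(genes), n_lines))
    expr = pd.DataFrame(x, index=genes, columns=lines)

    w = np.array([signature_weights[g] for g in sig_genes])
    score = w @ x[: len(sig_genes)]
    score_norm = score / max(score.std(), 1e-12)

    compounds = [f"drug{j:03d}" for j in range(n_compounds)]
    sensitive = compounds[:n_sensitive]
    auc = np.empty((n_lines, n_compounds))
    for j, comp in enumerate(compounds):
        noise = rng.normal(0.0, noise_sd, size=n_lines)
        if comp in sensitive:
            auc[:, j] = auc_baseline - sensitivity_slope * score_norm + noise
        else:
            auc[:, j] = auc_baseline + noise
    drm = pd.DataFrame(auc, index=lines, columns=compounds)
    if missing_fraction > 0:
        mask = rng.uniform(size=auc.shape) < missing_fraction
        drm = drm.mask(mask)
    return expr, drm, sensitive
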