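"""Frozen synthetic benchmark conditions.

These configurations define the study conditions under which the package's
self-contained claims are measured (screen recovery, sweep sanity, null
calibration, drug-screen recovery).  They are fixed by an a-priori power
analysis documented in the methods note and shared by the test suite and
the acceptance script; they are not tuning knobs.
"""

from __future__ import annotations

import numpy as np

from .simulate import SimConfig

#: Two co-expressed prognostic programs: a hazardous and a protective
#: 10-gene module, each occupying one correlation block (block size 10).
SCREEN_PLANTED: dict[str, float] = {
    **{f"g{i:05d}": 0.5 for i in range(10)},          # block 0, hazardous
    **{f"g{i:05d}": -0.5 for i in range(100, 110)},   # block 10, protective
}


def screen_benchmark(seed: int) -> SimConfig:
    """Consensus-screen benchmark: K=10 cohorts, n=150 each, G=2000 genes,
    20 planted genes with |log-HR| = 0.5 arranged as two 10-gene modules."""
    return SimConfig(
        K=10, n_per_cohort=150, G=2000, planted=SCREEN_PLANTED,
        censor_target=0.25, block_corr=0.35, block_size=10,
        batch_shift_sd=0.5, batch_scale_range=(0.8, 1.25), seed=seed,
    )


#: Sweep benchmark gene set: the 20 planted genes plus 12 nulls, mirroring a
#: post-screen consensus gene panel handed to the combination sweep.
SWEEP_INPUT_GENES: tuple[str, ...] = tuple(
    sorted(SCREEN_PLANTED) + [f"g{i:05d}" for i in range(300, 312)]
)


def sweep_benchmark(seed: int) -> SimConfig:
    """Sweep benchmark: training cohort n=160 plus nine testing cohorts
    n=120, 400 genes, same planted modules as the screen benchmark."""
    return SimConfig(
        K=10, n_per_cohort=[160] + [120] * 9, G=400, planted=SCREEN_PLANTED,
        censor_target=0.25, block_corr=0.35, block_size=10,
        batch_shift_sd=0.5, batch_scale_range=(0.8, 1.25), seed=seed,
    )


#: Reduced hyper-grids for full-roster sweeps (problem sizes chosen for the
#: benchmark scale; the per-family defaults remain the library defaults).
SWEEP_GRIDS: dict[str, dict] = {
    "LASSO": {"n_lambda": 30},
    "Ridge": {"n_lambda": 20},
    "Enet": {"n_lambda": 20},
    "CoxBoost": {"steps": list(range(0, 51, 10))},
    "GBM": {"n_estimators": [50, 100]},
    "RSF": {"n_estimators": [100]},
    "SuperPC": {"threshold_quantiles": [0.0, 0.3, 0.6, 0.9]},
}


def permute_outcomes(mc, seed: int):
    """Permute (time, event) jointly within every cohort: the sweep null."""
    from .cohorts import MultiCohort

    rng = np.random.default_rng(seed)
    cohorts = []
    for c in mc:
        perm = rng.permutation(c.n_samples)
        surv = c.surv.copy()
        surv[["time", "event"]] = surv[["time", "event"]].to_numpy()[perm]
        cohorts.append(type(c)(name=c.name, role=c.role, expr=c.expr, surv=surv,
                               standardized=c.standardized,
                               constant_genes=c.constant_genes))
    return MultiCohort(cohorts=tuple(cohorts), shared_genes=mc.shared_genes)
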