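import numpy as np
import pandas as pd
import pytest

from consurv.cohorts import Cohort
from consurv.simulate import SimConfig, simulate_multicohort


def make_cohort(n=50, genes=("gA", "gB", "gC"), seed=0, name="toy",
                role="testing", censor=0.3, beta=None):
    """Small analytic cohort: exponential times under PH on the first gene(s)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((len(genes), n))
    lp = np.zeros(n)
    if beta:
        for g, b in beta.items():
            lp += b * x[list(genes).index(g)]
    t_event = rng.exponential(10.0 * np.exp(-lp))
    t_cens = rng.exponential(10.0 / max(censor, 1e-9)) if censor > 0 else np.full(n, np.inf)
    time = np.maximum(np.minimum(t_event, t_cens), 1e-6)
    event = (t_event <= t_cens).astype(int)
    if event.sum() == 0:
        event[np.argmax(time)] = 1
    samples = [f"{name}_s{i}" for i in range(n)]
    return Cohort(
        name=name, role=role,
        expr=pd.DataFrame(x, index=list(genes), columns=samples),
        surv=pd.DataFrame({"time": time, "event": event}, index=samples),
    )


@pytest.fixture(scope="session")
def planted_multicohort():
    """Four cohorts, 40 genes, two planted effects; no batch perturbation."""
    cfg = SimConfig(K=4, n_per_cohort=150, G=40,
                    planted={"g00000": 0.7, "g00010": -0.6},
                    batch_shift_sd=0.0, batch_scale_range=(1.0, 1.0),
                    block_corr=0.0, censor_target=0.25, seed=21)
    return simulate_multicohort(cfg)


@pytest.fixture(scope="session")
def medium_train_cohort():
    """One standardized training cohort with a 6-gene signal among 25 genes."""
    from consurv.cohorts import standardize

    planted = {f"g{i:05d}": b for i, b in
               zip(range(6), [0.6, -0.5, 0.45, 0.5, -0.4, 0.35])}
    cfg = SimConfig(K=2, n_per_cohort=180, G=25, planted=planted,
                    batch_shift_sd=0.0, batch_scale_range=(1.0, 1.0),
                    block_corr=0.0, censor_target=0.25, seed=31)
    mc, truth = simulate_multicohort(cfg)
    return standardize(mc.cohorts[0]), standardize(mc.cohorts[1]), truth
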