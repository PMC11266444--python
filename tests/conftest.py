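import numpy as np
import pandas as pd
import pytest

from adtraj.cohort import (
    CohortConfig,
    DeclineParams,
    apply_missingness,
    generate_baseline,
    generate_longitudinal,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across tests."""
    cfg = CohortConfig(n_learn=60, n_placebo=60, n_solanezumab=60, seed=11)
    baseline = generate_baseline(cfg)
    visits, truth = generate_longitudinal(baseline, cfg)
    visits = apply_missingness(visits, cfg)
    return cfg, baseline, visits, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_linear_visits(n, weeks, intercepts, slopes, noise_sd=0.0, rng=None, versions=True):
    """Long PACC table with per-participant linear trajectories."""
    rows = []
    for i in range(n):
        for k, w in enumerate(weeks):
            eps = rng.normal(0.0, noise_sd) if (rng is not None and noise_sd) else 0.0
            rows.append(
                {
                    "id": f"p{i:04d}",
                    "week": float(w),
                    "measure": "PACC",
                    "value": intercepts[i] + slopes[i] * w + eps,
                    "test_version": "ABC"[k % 3] if versions else "A",
                }
            )
    return pd.DataFrame(rows)
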