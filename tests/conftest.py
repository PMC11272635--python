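import json
from pathlib import Path

import numpy as np
import pytest

import hipimpinge as hi
from hipimpinge.lmm import IncidenceGenerator, simulate_incidence

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def mean_hip():
    """One hip at the cohort-mean anatomy (cam-type, AIIS type II)."""
    return hi.generate_hip(hi.AnatomyParams())


@pytest.fixture(scope="session")
def no_cam_hip():
    """Spherical-head hip with normal coverage and versions."""
    return hi.generate_hip(
        hi.AnatomyParams(alpha_angle=40.0, femoral_version=15.0,
                         acetabular_version=19.0, lcea=30.0, aiis_type="I")
    )


def benchmark_tables():
    """The five frozen LMM benchmark datasets (regenerated, not stored)."""
    out = {}
    out["bench_default"] = simulate_incidence(IncidenceGenerator(seed=42))
    out["bench_small"] = simulate_incidence(IncidenceGenerator(
        n_patients=30, random_intercept_sd=5.0, residual_sd=12.0, seed=7))
    out["bench_finegrid"] = simulate_incidence(IncidenceGenerator(
        n_patients=50, tilts=(-10.0, -5.0, 0.0, 5.0, 10.0), beta_tilt=-0.5, seed=11))
    out["bench_highvar"] = simulate_incidence(IncidenceGenerator(
        n_patients=20, random_intercept_sd=25.0, residual_sd=5.0, beta_lcea=1.2, seed=3))
    df = simulate_incidence(IncidenceGenerator(n_patients=40, seed=99))
    rng = np.random.default_rng(1234)
    out["bench_unbalanced"] = df[rng.random(len(df)) > 0.2].reset_index(drop=True)
    return out


@pytest.fixture(scope="session")
def lmm_reference():
    """Frozen reference fits of the benchmark datasets (lmerTest/lme4)."""
    return json.loads((DATA / "lmm_benchmarks.json").read_text())
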