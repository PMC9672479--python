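"""Shared fixtures: small phantoms and one demo-scale pipeline run.

Everything is generated programmatically and seeded; the demo pipeline
run is session-scoped because several test modules inspect its outputs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from perfrad.phantom import AcquisitionSpec, BolusModel, LesionSpec, generate_phantom
from perfrad.pipeline import PipelineConfig, run_pipeline


SMALL_ACQ = AcquisitionSpec(n_timepoints=12, n_slices=8, height=16, width=16)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(
        SMALL_ACQ, BolusModel(), LesionSpec(target_fraction=0.2, geometry_seed=7),
        noise_sd=2.0, seed=7,
    )


@pytest.fixture(scope="session")
def toy_table():
    """100-feature table with 5 planted informative features (d = 2)."""
    rng = np.random.default_rng(0)
    n = 160
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 100))
    for j in range(5):
        X[:, j] += 2.0 * y
    cols = [f"f{j:03d}" for j in range(100)]
    return pd.DataFrame(X, columns=cols), pd.Series(y)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One demo-scale end-to-end pipeline run (effect cohort)."""
    out = tmp_path_factory.mktemp("demo_run")
    cfg = PipelineConfig(out_dir=str(out), seed=1)
    report = run_pipeline(cfg)
    return cfg, report, out


@pytest.fixture(scope="session")
def demo_rerun(demo_run, tmp_path_factory):
    """The demo configuration executed a second time, for reproducibility."""
    cfg, _, _ = demo_run
    out = tmp_path_factory.mktemp("demo_rerun")
    cfg2 = PipelineConfig(**{**cfg.__dict__, "out_dir": str(out)})
    run_pipeline(cfg2)
    return out


@pytest.fixture(scope="session")
def null_run(tmp_path_factory):
    """A no-effect cohort run: lesion voxels behave exactly like tissue."""
    out = tmp_path_factory.mktemp("null_run")
    cfg = PipelineConfig(out_dir=str(out), seed=3, attenuation=1.0, delay=0.0)
    report = run_pipeline(cfg)
    return cfg, report, out
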