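import dataclasses

import numpy as np
import pytest

import factbmap as fm


@pytest.fixture(scope="session")
def baseline_cohort() -> fm.Cohort:
    """Synthetic development-sized cohort under the default study conditions."""
    return fm.generate_cohort(fm.SynthConfig(n=238, seed=5))


@pytest.fixture(scope="session")
def big_cohort() -> fm.Cohort:
    """Large synthetic cohort (n = 10^4) for recovery and distributional checks."""
    return fm.generate_cohort(fm.SynthConfig(n=10_000, seed=1))


@pytest.fixture(scope="session")
def clip_cohort(big_cohort) -> fm.Cohort:
    """The large cohort with the utility plainly top-coded at 1 (Tobit mechanism)."""
    df = big_cohort.data.assign(utility=np.minimum(big_cohort.data["latent_utility"], 1.0))
    return fm.Cohort(df, meta=big_cohort.meta)


@pytest.fixture(scope="session")
def heavy_ceiling_cohort() -> fm.Cohort:
    """Top-coded cohort with ~25% ceiling mass: default slopes, raised intercept."""
    true = dataclasses.replace(fm.published_mapping("ols", 4), intercept=0.4156)
    cfg = fm.SynthConfig(n=2000, seed=11, true_mapping=true, ceiling_rule="clip")
    return fm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def heavy_ceiling_truth() -> fm.FittedMapping:
    return dataclasses.replace(fm.published_mapping("ols", 4), intercept=0.4156)
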