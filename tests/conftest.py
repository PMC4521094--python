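import numpy as np
import pytest

from amypet import (
    CohortConfig,
    PhantomRegion,
    PhantomSpec,
    StratumConfig,
    default_cohort_config,
    default_roi_model,
    generate_phantom,
)


@pytest.fixture(scope="session")
def default_config():
    return default_cohort_config(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def single_stratum_config(diagnosis, age_group, seed=0, **overrides):
    """Cohort config holding only one stratum of the calibrated default."""
    base = default_cohort_config(seed=seed)
    s = base.strata[(diagnosis, age_group)]
    if overrides:
        from dataclasses import replace

        s = replace(s, **overrides)
    return CohortConfig(
        strata={(diagnosis, age_group): s},
        roi_model=default_roi_model(),
        seed=seed,
    )


def flat_phantom(ratios, noise_sd=0.0, fwhm=0.0, seed=0, shape=(12, 8, 8)):
    """Slab phantom: one region per entry of ``ratios`` plus reference label 1."""
    regions = [PhantomRegion(1, "reference", 1.0, "ref")]
    regions += [
        PhantomRegion(i + 2, f"r{i}", r, "GM") for i, r in enumerate(ratios)
    ]
    return generate_phantom(
        PhantomSpec(
            grid_shape=shape,
            regions=tuple(regions),
            reference_label=1,
            noise_sd=noise_sd,
            smoothing_fwhm_mm=fwhm,
            seed=seed,
        )
    )


def simulate_mixture(n, weights, means, sds, rng):
    comp = rng.choice(len(means), size=n, p=np.asarray(weights))
    return rng.normal(np.take(means, comp), np.take(sds, comp))
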