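import pytest

from ecgresp import EstimatorConfig, SyntheticConfig, WIDE_RR_BAND, generate


@pytest.fixture(scope="session")
def wide_cfg():
    """Estimator configured with the wide 5-40 bpm anticipated-RR band."""
    return EstimatorConfig(rr_band=WIDE_RR_BAND)


@pytest.fixture(scope="session")
def steady_truth():
    """Steady ventilated analog: HR 60, true RR 12 bpm, 10% modulation,
    light noise (2% of the R amplitude), slight beat jitter, 120 s."""
    return generate(
        SyntheticConfig(
            fs=1000.0,
            duration=120.0,
            hr=60.0,
            hr_jitter_sd=0.01,
            rr=12.0,
            mod_depth=0.10,
            noise_sd=0.02,
            seed=1,
        )
    )


@pytest.fixture(scope="session")
def clean_truth():
    """Noise-free, jitter-free steady record for exact-recovery checks."""
    return generate(
        SyntheticConfig(fs=1000.0, duration=90.0, hr=60.0, rr=12.0, mod_depth=0.10, seed=0)
    )
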