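import pytest
from hypothesis import HealthCheck, settings

# derandomized hypothesis: the suite is bit-reproducible run to run
settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from plfasip import community, pipeline, simulate  # noqa: E402


@pytest.fixture(scope="session")
def catalog():
    return community.load_catalog()


def _zero_noise_config(seed=1):
    cfg = simulate.default_scenario(seed=seed)
    cfg.delta_sd = 0.0
    cfg.amount_cv = 0.0
    cfg.co2_cv = 0.0
    cfg.gas_delta_sd = 0.0
    cfg.field_cv = 0.0
    return cfg


@pytest.fixture(scope="session")
def zero_noise_dataset():
    return simulate.simulate_incubation(_zero_noise_config())


@pytest.fixture(scope="session")
def noisy_dataset():
    return simulate.simulate_incubation(simulate.default_scenario(seed=1))


@pytest.fixture(scope="session")
def zero_noise_result(zero_noise_dataset):
    return pipeline.run_pipeline(
        zero_noise_dataset.measurements,
        zero_noise_dataset.gas,
        pipeline.RunConfig(),
    )


@pytest.fixture(scope="session")
def noisy_result(noisy_dataset):
    return pipeline.run_pipeline(
        noisy_dataset.measurements, noisy_dataset.gas, pipeline.RunConfig()
    )
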