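import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_profiles():
    """30 ligands x 4 poses generated from alpha=0.587, beta=0.267, no noise."""
    from cyplie.synthetic import GeneratorConfig, generate_profiles

    config = GeneratorConfig(
        n_ligands=30, poses_per_ligand=4, noise_sigma=0.0, seed=11
    )
    return generate_profiles(config)


@pytest.fixture(scope="session")
def noisy_profiles():
    """Paper-regime training set: 35 ligands, 4-7 poses, sigma=3.3 kJ/mol."""
    from cyplie.synthetic import GeneratorConfig, generate_profiles

    config = GeneratorConfig(seed=42)
    return generate_profiles(config)
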