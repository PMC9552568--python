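"""Shared fixtures: small synthetic runs reused across test modules."""
import pytest

from scdcsurv import GeneratorConfig, run_pipeline


@pytest.fixture(scope="session")
def noiseless_run():
    """Noiseless limit: full coverage, clean identifiers, no miscoding."""
    return run_pipeline(GeneratorConfig.noiseless(n_population=800, seed=11))


@pytest.fixture(scope="session")
def default_run():
    """Default study conditions: identifier noise, partial coverage, miscodes."""
    return run_pipeline(GeneratorConfig(n_population=1500, seed=7))
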