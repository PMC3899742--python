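"""Shared fixtures: scenario runs are expensive, so run each once."""

import pytest

from hscdelay import run_scenario
from hscdelay.presets import load_preset


@pytest.fixture(scope="session")
def no_cta_preset():
    return load_preset("no_cta")


@pytest.fixture(scope="session")
def with_cta_preset():
    return load_preset("with_cta")


@pytest.fixture(scope="session")
def control_result():
    return run_scenario("control")


@pytest.fixture(scope="session")
def hia_only_result():
    return run_scenario("hia_only")


@pytest.fixture(scope="session")
def cta_only_result():
    return run_scenario("cta_only")


@pytest.fixture(scope="session")
def combined_result():
    return run_scenario("combined")
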