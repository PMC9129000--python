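"""Shared fixtures: the canonical seeded validation scenarios are expensive
(each simulates and aligns a whole library), so they are session-scoped."""

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from orgrearr.pipeline import demo_config, run_pipeline
from orgrearr.scenarios import (
    crossover_asymmetry,
    isomerization_filtering,
    junction_precision_recall,
    stoichiometry_recovery,
)

SCENARIO_SEED = 1


@pytest.fixture(scope="session")
def stoich_result():
    return stoichiometry_recovery(seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def junction_result():
    return junction_precision_recall(seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def isomer_result():
    return isomerization_filtering(seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def xover_result():
    return crossover_asymmetry(seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("demo")
    manifest = run_pipeline(demo_config(out, seed=0))
    return manifest, Path(out)


@pytest.fixture(scope="session")
def demo_rerun(tmp_path_factory):
    """Second run of the demo configuration at the same seed (determinism)."""
    out = tmp_path_factory.mktemp("demo_rerun")
    return run_pipeline(demo_config(out, seed=0))
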