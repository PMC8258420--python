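import shutil

import pytest
from hypothesis import HealthCheck, settings

from bidscurator.curate import curate_store
from bidscurator.synthfix import (
    demo_heuristic_path,
    fixture_completeness,
    fixture_overview,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def _overview_master(tmp_path_factory):
    root = tmp_path_factory.mktemp("overview_master")
    fixture_overview(root, seed=0)
    return root


@pytest.fixture(scope="session")
def _completeness_master(tmp_path_factory):
    root = tmp_path_factory.mktemp("completeness_master")
    fixture_completeness(root, seed=0)
    return root


@pytest.fixture()
def overview_store(_overview_master, tmp_path):
    """Fresh copy of the 20-subject overview project (uncurated)."""
    root = tmp_path / "overview"
    shutil.copytree(_overview_master, root)
    return root


@pytest.fixture()
def completeness_store(_completeness_master, tmp_path):
    """Fresh copy of the completeness project (uncurated)."""
    root = tmp_path / "completeness"
    shutil.copytree(_completeness_master, root)
    return root


@pytest.fixture()
def heuristic_path():
    return demo_heuristic_path()


@pytest.fixture()
def curated_overview(overview_store, heuristic_path):
    """Overview project with the demo heuristic applied."""
    curate_store(overview_store, heuristic_path)
    return overview_store


@pytest.fixture()
def curated_completeness(completeness_store, heuristic_path):
    curate_store(completeness_store, heuristic_path)
    return completeness_store
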