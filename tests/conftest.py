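import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from evanno import (  # noqa: E402
    load_evidence_tables,
    load_gene_models,
)
from evanno.synthdata import (  # noqa: E402
    SimConfig,
    generate_universe,
    generate_worked_example,
)


@pytest.fixture(scope="session")
def worked(tmp_path_factory):
    """The shipped miniature scenario: 20 somatic coding SNVs, 3 drivers."""
    outdir = tmp_path_factory.mktemp("worked")
    return generate_worked_example(outdir)


@pytest.fixture(scope="session")
def universe(tmp_path_factory):
    """A default-sized universe (100 germline, 60 somatic, 3 drivers)."""
    outdir = tmp_path_factory.mktemp("universe")
    return generate_universe(SimConfig(seed=11), outdir)


@pytest.fixture(scope="session")
def universe_models(universe):
    return load_gene_models(universe.paths["genepred"])


@pytest.fixture(scope="session")
def universe_evidence(universe):
    return load_evidence_tables(universe.paths["refdir"], universe.config.mesh_term)
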