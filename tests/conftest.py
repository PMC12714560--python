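import pathlib

import pytest

from deletion_scope.scenarios import pooled_deletion_scenario


@pytest.fixture(scope="session")
def scenario():
    """Canonical pooled three-lineage deletion scenario (fixed seed)."""
    return pooled_deletion_scenario(seed=1)


@pytest.fixture(scope="session")
def scenario_sam(scenario, tmp_path_factory) -> pathlib.Path:
    path = tmp_path_factory.mktemp("pool") / "alignments.sam"
    path.write_text(scenario.pool.sam_text)
    return path


@pytest.fixture(scope="session")
def scenario_alignments(scenario_sam):
    from deletion_scope.extraction import read_alignments

    return list(read_alignments(scenario_sam))
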