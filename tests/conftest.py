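import numpy as np
import pytest

from isletpipe import (
    ExpressionMatrix,
    default_study_config,
    generate_fixture,
    run_pipeline,
)


@pytest.fixture(scope="session")
def _study_fixture_cached():
    return generate_fixture(default_study_config(seed=0))


@pytest.fixture
def study_fixture(_study_fixture_cached):
    """The default 448-cell capture at seed 0 (fresh cell records per test)."""
    import copy

    matrix, cells, truth = _study_fixture_cached
    return matrix, copy.deepcopy(cells), truth


@pytest.fixture(scope="session")
def study_run():
    """Full pipeline result on the default capture at seed 0."""
    return run_pipeline(simulate=default_study_config(seed=0))


@pytest.fixture
def toy_matrix():
    """3 transcripts (2 genes) x 2 cells; INS has two transcripts."""
    return ExpressionMatrix(
        transcript_ids=["NM_000207", "NM_001185097", "NM_002054"],
        gene_of={"NM_000207": "INS", "NM_001185097": "INS", "NM_002054": "GCG"},
        cell_ids=["C1", "C2"],
        values=np.array([[1000.0, 0.0], [100.0, 0.0], [25.0, 3000.0]]),
    )
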