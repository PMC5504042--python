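import numpy as np
import pytest

from isletpipe import (
    CellRecord,
    ConfigurationError,
    ExpressionMatrix,
    filter_bihormonal,
    filter_low_exonic,
    filter_low_reads,
    hormone_profile,
)


def _cells(reads_exonic):
    return [
        CellRecord(f"C{i}", "S1", reads, exonic)
        for i, (reads, exonic) in enumerate(reads_exonic)
    ]


def _hormone_matrix(levels):
    """One cell per row of (INS, GCG, SST)."""
    values = np.array(levels, dtype=float).T
    return ExpressionMatrix(
        ["NM_000207", "NM_002054", "NM_001048"],
        {"NM_000207": "INS", "NM_002054": "GCG", "NM_001048": "SST"},
        [f"C{i}" for i in range(len(levels))],
        values,
    )


def test_read_filter_boundary_is_strict():
    """Exactly one million reads is retained; 999,999 is excluded."""
    cells = _cells([(999_999, 0.5), (1_000_000, 0.5), (2_000_000, 0.5)])
    retained, excluded, report = filter_low_reads(cells, 1_000_000)
    assert [c.cell_id for c in excluded] == ["C0"]
    assert excluded[0].status == "excluded_low_reads"
    assert report.n_input == 3 and report.n_excluded == 1 and report.n_retained == 2


def test_exonic_filter_boundary_is_strict():
    cells = _cells([(2_000_000, 0.299), (2_000_000, 0.30), (2_000_000, 0.9)])
    retained, excluded, _ = filter_low_exonic(cells, 0.30)
    assert [c.cell_id for c in excluded] == ["C0"]
    assert [c.cell_id for c in retained] == ["C1", "C2"]


def test_exonic_filter_no_exclusions_when_all_high():
    cells = _cells([(2_000_000, 0.9)] * 4)
    retained, excluded, _ = filter_low_exonic(cells, 0.30)
    assert not excluded and len(retained) == 4


def test_hormone_profile_mono_and_ties():
    m = _hormone_matrix([(1000, 50, 0), (300, 300, 0), (0, 0, 0)])
    call = hormone_profile(m, "C0")
    assert call.primary_hormone == "INS" and call.secondary_hormone == "GCG"
    assert call.secondary_ratio == pytest.approx(0.05)
    assert call.verdict == "mono_hormonal"
    tie = hormone_profile(m, "C1")
    # tie broken to panel order (INS primary); verdict unaffected
    assert tie.primary_hormone == "INS" and tie.secondary_ratio == 1.0
    assert tie.verdict == "bihormonal_excluded"
    none = hormone_profile(m, "C2")
    assert none.verdict == "no_hormone" and none.secondary_ratio is None


def test_hormone_profile_missing_panel_gene():
    m = _hormone_matrix([(1, 1, 1)]).subset_transcripts(["NM_000207"])
    with pytest.raises(ConfigurationError, match="GCG"):
        hormone_profile(m, "C0", hormone_panel=("INS", "GCG", "SST"))


def test_hormone_profile_scale_invariance():
    rng = np.random.default_rng(5)
    base = rng.random((6, 3)) * 1000
    for c in (1e-3, 1.0, 7.3, 1e4):
        m = _hormone_matrix(base)
        scaled = _hormone_matrix(base * c)
        for cell in m.cell_ids:
            assert (
                hormone_profile(m, cell).verdict
                == hormone_profile(scaled, cell).verdict
            )


def test_bihormonal_filter_strict_inequality():
    m = _hormone_matrix([(1000, 100.0, 0), (1000, 100.0001, 0)])
    cells = _cells([(2_000_000, 0.5)] * 2)
    retained, excluded, report, calls = filter_bihormonal(m, cells, 0.10)
    assert [c.cell_id for c in retained] == ["C0"]
    assert [c.cell_id for c in excluded] == ["C1"]
    assert calls[0].verdict == "mono_hormonal"


def test_no_endocrine_cohort_passes_unfiltered():
    m = _hormone_matrix([(0, 0, 0)] * 3)
    cells = _cells([(2_000_000, 0.5)] * 3)
    retained, excluded, _, calls = filter_bihormonal(m, cells, 0.10)
    assert not excluded
    assert all(c.verdict == "no_hormone" for c in calls)


def test_partition_property_every_stage(study_fixture):
    """Each filter yields a disjoint, exhaustive partition of its input."""
    matrix, cells, _ = study_fixture
    pool = list(cells)
    retained, excluded, _ = filter_low_reads(pool, 1_000_000)
    assert len(retained) + len(excluded) == len(pool)
    assert not {c.cell_id for c in retained} & {c.cell_id for c in excluded}
    pool = retained
    retained, excluded, _ = filter_low_exonic(pool, 0.30)
    assert len(retained) + len(excluded) == len(pool)
    pool = retained
    sub = matrix.subset_cells([c.cell_id for c in pool])
    retained, excluded, _, _ = filter_bihormonal(sub, pool, 0.10)
    assert len(retained) + len(excluded) == len(pool)
    assert not {c.cell_id for c in retained} & {c.cell_id for c in excluded}


def test_fixture_exclusions_match_planted_truth(study_fixture):
    matrix, cells, truth = study_fixture
    retained, excluded, _ = filter_low_reads(list(cells), 1_000_000)
    assert {c.cell_id for c in excluded} == set(truth.cells_of_class("low_read"))
    retained, excluded, report = filter_low_exonic(retained, 0.30)
    assert {c.cell_id for c in excluded} == set(truth.cells_of_class("low_exonic"))
    assert {s: v["excluded"] for s, v in report.per_subject.items()} == {
        "S1": 22, "S2": 2, "S3": 23,
    }
    sub = matrix.subset_cells([c.cell_id for c in retained])
    _, excluded, _, _ = filter_bihormonal(sub, retained, 0.10)
    assert {c.cell_id for c in excluded} == set(truth.cells_of_class("bihormonal"))
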