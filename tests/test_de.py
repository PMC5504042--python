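import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from isletpipe import (
    PipelineConfig,
    ValidationError,
    anova_two_group,
    bonferroni_adjust,
    select_testable_transcripts,
    signed_fold_change,
    two_stage_de,
)
from isletpipe.synthetic_data import default_study_config, generate_fixture
from isletpipe import run_pipeline


# --- prevalence filter ------------------------------------------------------


def test_prevalence_boundary():
    from isletpipe import ExpressionMatrix

    values = np.zeros((2, 100))
    values[0, :25] = 51.0  # >50 in exactly 25% of cells -> kept
    values[1, :24] = 51.0  # in 24% -> dropped
    m = ExpressionMatrix(["T1", "T2"], {"T1": "A", "T2": "B"},
                         [f"C{i}" for i in range(100)], values)
    kept = select_testable_transcripts(m, m.cell_ids, 50.0, 0.25)
    assert kept == ["T1"]
    # exactly 50 does not count (strict >): T1 drops out too
    values2 = values.copy()
    values2[0, :] = 50.0
    m2 = ExpressionMatrix(["T1", "T2"], dict(m.gene_of), list(m.cell_ids), values2)
    assert select_testable_transcripts(m2, m2.cell_ids, 50.0, 0.25) == []


def test_stringent_fraction_is_monotone(study_run):
    m = study_run.normalized
    cells = [c.cell_id for c in study_run.type_calls if c.type in ("alpha", "beta")]
    loose = set(select_testable_transcripts(m, cells, 50.0, 0.25))
    strict = set(select_testable_transcripts(m, cells, 50.0, 0.42))
    assert strict <= loose


# --- ANOVA ------------------------------------------------------------------


def test_anova_hand_example():
    """A=(1,2,3) vs B=(4,5,6): F = 13.5 = t^2 with t = -3.674, p ~ 0.0214."""
    F, p = anova_two_group([1, 2, 3], [4, 5, 6])
    assert F == pytest.approx(13.5, rel=1e-12)
    assert p == pytest.approx(0.0213116, rel=1e-4)
    t = scipy.stats.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=True)
    assert F == pytest.approx(t.statistic**2, rel=1e-12)
    assert p == pytest.approx(t.pvalue, rel=1e-12)


def test_anova_degenerate_cases():
    assert anova_two_group([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
    F, p = anova_two_group([1.0, 1.0], [2.0, 2.0])
    assert math.isinf(F) and p == 0.0
    with pytest.raises(ValidationError):
        anova_two_group([1.0], [2.0, 3.0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_anova_equals_squared_pooled_t(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), rng.integers(2, 40))
    b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), rng.integers(2, 40))
    F, p = anova_two_group(a, b)
    t = scipy.stats.ttest_ind(a, b, equal_var=True)
    assert F == pytest.approx(t.statistic**2, rel=1e-10)
    assert p == pytest.approx(t.pvalue, rel=1e-10)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_group_swap_antisymmetry(seed):
    rng = np.random.default_rng(seed)
    a = rng.random(10) * 100
    b = rng.random(12) * 100
    F1, p1 = anova_two_group(a, b)
    F2, p2 = anova_two_group(b, a)
    assert p1 == pytest.approx(p2, rel=1e-10)
    fc_ab, _ = signed_fold_change(a.mean(), b.mean())
    fc_ba, _ = signed_fold_change(b.mean(), a.mean())
    assert fc_ab == pytest.approx(-fc_ba, rel=1e-12) or fc_ab == fc_ba == 1.0


# --- fold change ------------------------------------------------------------


@pytest.mark.parametrize(
    "mean_a,mean_b,expected",
    [(10, 2, 5.0), (2, 10, -5.0), (3, 3, 1.0)],
)
def test_signed_fold_change_convention(mean_a, mean_b, expected):
    fc, capped = signed_fold_change(mean_a, mean_b)
    assert fc == pytest.approx(expected) and not capped


def test_signed_fold_change_degenerate():
    fc, capped = signed_fold_change(5.0, 0.0)
    assert math.isinf(fc) and fc > 0 and capped
    fc, capped = signed_fold_change(0.0, 5.0)
    assert math.isinf(fc) and fc < 0 and capped
    assert signed_fold_change(0.0, 0.0) == (None, False)


# --- Bonferroni -------------------------------------------------------------


def test_bonferroni_values():
    assert bonferroni_adjust(0.5, 582) == 1.0
    assert bonferroni_adjust(1e-4, 582) == pytest.approx(0.0582)
    assert bonferroni_adjust(0.3, 1) == 0.3


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0, 1), st.integers(1, 10_000))
def test_bonferroni_monotone_and_capped(p, n):
    adj = bonferroni_adjust(p, n)
    assert p <= adj <= 1.0
    if n == 1:
        assert adj == p
    elif 0.0 < p and p * n < 1.0:
        assert adj > p


# --- two-stage design -------------------------------------------------------


def test_planted_de_recovered_with_correct_sign(study_run):
    truth = study_run.truth
    by_transcript = {r.transcript_id: r for r in study_run.de_results}
    for direction in ("beta_up", "alpha_up"):
        planted = truth.de_transcripts(direction)
        recovered = [
            t
            for t in planted
            if t in by_transcript
            and by_transcript[t].verdict == "replicated"
            and by_transcript[t].direction == direction
        ]
        assert len(recovered) >= 0.95 * len(planted)


def test_no_null_transcript_replicates(study_run):
    nulls = set(study_run.truth.null_transcripts())
    replicated_nulls = [
        r for r in study_run.de_results if r.transcript_id in nulls and r.verdict == "replicated"
    ]
    assert not replicated_nulls


def test_directional_partition(study_run):
    seen = {}
    for r in study_run.de_results:
        assert r.direction in ("beta_up", "alpha_up")
        assert r.transcript_id not in seen
        seen[r.transcript_id] = r.direction
        if r.discovery is not None:
            assert (r.discovery.signed_fc > 0) == (r.direction == "beta_up")


def test_validation_correction_is_per_direction(study_run):
    """Validation adjusted p = raw p x candidate count of that direction."""
    n_cand = study_run.manifest.de_summary["n_candidates"]
    for r in study_run.de_results:
        if r.validation is None:
            continue
        expected = min(1.0, r.validation.raw_p * n_cand[r.direction])
        assert r.validation.adjusted_p == pytest.approx(expected, rel=1e-12)


def test_discovery_only_verdict_when_effect_absent_in_validation():
    """A transcript DE only in discovery subjects mirrors a non-replicating hit."""
    cfg = default_study_config(seed=5)
    matrix, cells, truth = generate_fixture(cfg)
    # zero out one planted beta_up transcript in the validation subject's cells
    target = truth.de_transcripts("beta_up")[0]
    row = matrix.transcript_ids.index(target)
    base = cfg.de_base_level
    for j, cell_id in enumerate(matrix.cell_ids):
        if cell_id.startswith("S3"):
            matrix.values[row, j] = base  # same mean in both groups downstream
    result = run_pipeline(matrix=matrix, cells=cells)
    by_transcript = {r.transcript_id: r for r in result.de_results}
    assert by_transcript[target].verdict == "discovery_only"
    assert by_transcript[target].discovery.adjusted_p < 0.05


def test_empty_candidate_set_is_valid():
    """alpha=0 yields no candidates, an empty result list and a sane report."""
    result = run_pipeline(
        config=PipelineConfig(alpha=1e-300),
        simulate=default_study_config(seed=1),
    )
    assert result.de_results == []
    assert result.manifest.de_summary["n_candidates"] == {"beta_up": 0, "alpha_up": 0}


def test_stage_with_too_few_cells_errors(study_run):
    with pytest.raises(ValidationError, match="fewer than 2"):
        two_stage_de(
            study_run.normalized,
            study_run.type_calls,
            {c.cell_id: c.subject_id for c in study_run.cells},
            ["S1", "S2"],
            ["NO_SUCH_SUBJECT"],
        )
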