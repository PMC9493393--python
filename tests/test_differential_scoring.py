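"""Replicate aggregation, delta-z classification, waterfall ranking."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from snapscreen import (
    Classification,
    aggregate_replicates,
    classify_factor,
    fold_change,
    score_screen,
    waterfall_table,
)
from snapscreen.differential_scoring import FactorScore, ScreenResult
from snapscreen.exceptions import DesignError


def test_aggregate_replicates_mean_and_preservation():
    mean, reps = aggregate_replicates([4, 6])
    assert mean == pytest.approx(5.0)
    assert reps == [4.0, 6.0]
    mean, reps = aggregate_replicates([5])  # single replicate allowed
    assert mean == pytest.approx(5.0)
    with pytest.raises(DesignError):
        aggregate_replicates([])


@pytest.mark.parametrize(
    "z_a,z_b,expected",
    [
        (2.0, 6.0, Classification.TEST_SELECTIVE),  # dz = 4
        (5.5, 6.0, Classification.RECRUITED_NONSELECTIVE),  # dz = 0.5
        (4.0, 4.9, Classification.NOT_RECRUITED),  # neither reaches 5
        (2.5, 5.0, Classification.TEST_SELECTIVE),  # both thresholds inclusive
        (5.0, 2.5, Classification.REFERENCE_SELECTIVE),  # mirrored boundary
        (6.0, 2.0, Classification.REFERENCE_SELECTIVE),
        (12.0, 12.0, Classification.RECRUITED_NONSELECTIVE),
        (-3.0, 9.0, Classification.TEST_SELECTIVE),
    ],
)
def test_classification_rules(z_a, z_b, expected):
    assert classify_factor(z_a, z_b) is expected


def test_classification_rejects_nan():
    with pytest.raises(ValueError):
        classify_factor(float("nan"), 1.0)


def test_degenerate_zero_thresholds():
    # With (0, 0) every non-negative factor is recruited and the dz tie at 0
    # resolves to test-selective by the inclusive rule.
    assert classify_factor(3.0, 3.0, z_cut=0.0, dz_cut=0.0) is Classification.TEST_SELECTIVE
    assert classify_factor(3.0, 2.0, z_cut=0.0, dz_cut=0.0) is Classification.REFERENCE_SELECTIVE


@given(
    st.floats(-20, 40), st.floats(-20, 40),
    st.floats(0.1, 10), st.floats(0.1, 10),
)
def test_classification_is_a_partition_and_antisymmetric(z_a, z_b, z_cut, dz_cut):
    cls = classify_factor(z_a, z_b, z_cut, dz_cut)
    assert cls in set(Classification)
    swapped = classify_factor(z_b, z_a, z_cut, dz_cut)
    mirror = {
        Classification.TEST_SELECTIVE: Classification.REFERENCE_SELECTIVE,
        Classification.REFERENCE_SELECTIVE: Classification.TEST_SELECTIVE,
        Classification.NOT_RECRUITED: Classification.NOT_RECRUITED,
        Classification.RECRUITED_NONSELECTIVE: Classification.RECRUITED_NONSELECTIVE,
    }
    # Swapping condition labels exchanges the selective classes exactly,
    # except at a dz tie on the cutoff where the inclusive rule breaks the
    # symmetry in favour of the test condition.
    if abs(abs(z_b - z_a) - dz_cut) > 1e-12:
        assert swapped is mirror[cls]


@given(st.floats(-10, 30), st.floats(-10, 30), st.floats(0, 20))
def test_raising_test_signal_never_demotes_a_test_selective_hit(z_a, z_b, bump):
    if classify_factor(z_a, z_b) is Classification.TEST_SELECTIVE:
        assert classify_factor(z_a, z_b + bump) is Classification.TEST_SELECTIVE


@pytest.mark.parametrize(
    "mean_a,mean_b,expected",
    [(10.0, 12.0, 2.0), (12.0, 12.0, 0.0), (12.0, 10.0, -2.0)],
)
def test_fold_change_is_log2_difference(mean_a, mean_b, expected):
    assert fold_change(mean_a, mean_b) == pytest.approx(expected)
    assert 2 ** fold_change(mean_a, mean_b) == pytest.approx(2 ** expected)


# ---------------------------------------------------------------------------
# Screen-level scoring
# ---------------------------------------------------------------------------


def _mk_score(fid, z_a, z_b, log2_fc=0.0, is_control=False):
    return FactorScore(
        factor_id=fid,
        category="dna_repair",
        z_by_replicate_a=(z_a,),
        z_by_replicate_b=(z_b,),
        z_a=z_a,
        z_b=z_b,
        delta_z=z_b - z_a,
        log2_fc=log2_fc,
        classification=classify_factor(z_a, z_b),
        is_control=is_control,
    )


def test_partition_tallies_sum_to_library_size():
    rng = np.random.default_rng(7)
    scores = [
        _mk_score(f"F{i}", float(a), float(b))
        for i, (a, b) in enumerate(rng.normal(3, 4, size=(200, 2)))
    ]
    result = ScreenResult(scores, 5.0, 2.5, "duplex", "triplex")
    counts = result.counts
    assert sum(counts.values()) == result.library_size == 200
    assert result.recruited_count == 200 - counts[Classification.NOT_RECRUITED]


def test_controls_are_scored_but_excluded_from_tallies():
    scores = [_mk_score("F1", 1.0, 9.0), _mk_score("RPA2", 2.0, 10.0, is_control=True)]
    result = ScreenResult(scores, 5.0, 2.5, "duplex", "triplex")
    assert result.library_size == 1
    assert result.counts[Classification.TEST_SELECTIVE] == 1
    included = ScreenResult(scores, 5.0, 2.5, "duplex", "triplex", controls_excluded=False)
    assert included.library_size == 2


def test_score_screen_matches_scalar_classifier(paper_sim, paper_scored):
    _, _, result = paper_scored
    for s in result.scores:
        assert s.classification is classify_factor(s.z_a, s.z_b, result.z_cut, result.dz_cut)
        assert s.delta_z == pytest.approx(s.z_b - s.z_a)
        assert s.z_a == pytest.approx(np.mean(s.z_by_replicate_a))
        assert len(s.z_by_replicate_a) == len(s.z_by_replicate_b) == 2


def test_score_screen_recovers_planted_structure(paper_sim, paper_scored):
    """Recovered tallies sit at the planted 16/17/93 partition up to the
    irreducible delta-z noise of duplicate screens (see docs/methods.md)."""
    _, _, result = paper_scored
    counts = result.counts
    assert 123 <= result.recruited_count <= 126
    assert 16 <= counts[Classification.TEST_SELECTIVE] <= 24
    assert 17 <= counts[Classification.REFERENCE_SELECTIVE] <= 25
    assert 84 <= counts[Classification.RECRUITED_NONSELECTIVE] <= 93
    assert sum(counts.values()) == 520


def test_score_screen_antisymmetric_under_condition_swap(paper_sim, paper_scored):
    normalized, _, result = paper_scored
    swapped = score_screen(normalized, paper_sim.library, "triplex", "duplex")
    fwd = {s.factor_id: s for s in result.scores}
    for s in swapped.scores:
        f = fwd[s.factor_id]
        assert s.delta_z == pytest.approx(-f.delta_z)
        assert s.log2_fc == pytest.approx(-f.log2_fc)
    counts_f, counts_s = result.counts, swapped.counts
    assert counts_s[Classification.TEST_SELECTIVE] == counts_f[Classification.REFERENCE_SELECTIVE]
    assert counts_s[Classification.REFERENCE_SELECTIVE] == counts_f[Classification.TEST_SELECTIVE]
    assert counts_s[Classification.NOT_RECRUITED] == counts_f[Classification.NOT_RECRUITED]


# ---------------------------------------------------------------------------
# Waterfall table
# ---------------------------------------------------------------------------


def test_waterfall_orders_by_delta_z_then_fold_change():
    scores = [
        _mk_score("A", 0.0, 3.0),           # dz 3
        _mk_score("B", 3.0, 0.0),           # dz -3
        _mk_score("C", 0.0, 0.1),           # dz 0.1
        _mk_score("D", 0.0, 1.0, log2_fc=2.0),  # dz 1, fc 2
        _mk_score("E", 0.0, 1.0, log2_fc=1.0),  # dz 1, fc 1 (tie on dz)
    ]
    result = ScreenResult(scores, 5.0, 2.5, "duplex", "triplex")
    table = waterfall_table(result)
    assert list(table["factor_id"]) == ["A", "D", "E", "C", "B"]
    assert (table["delta_z"].diff().dropna() <= 0).all()
    assert set(table["dz_cutoff_upper"]) == {2.5}
    assert set(table["dz_cutoff_lower"]) == {-2.5}


def test_waterfall_empty_result_is_empty():
    result = ScreenResult([], 5.0, 2.5, "duplex", "triplex")
    assert waterfall_table(result).empty
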