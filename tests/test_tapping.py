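"""Tap-train cleaning rules, tap-click matching, and summary statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synchrolab import (
    TapTrain,
    average_runs,
    code_verbal_responses,
    discard_warmup,
    generate_sequence,
    match_taps,
    remove_double_taps,
    remove_iti_outliers,
    summarize,
)
from synchrolab.tapping import DOUBLE_TAP, ITI_OUTLIER, WARMUP, clean


def train(taps, cond="iso", run=1):
    return TapTrain("p1", cond, run, np.asarray(taps, float))


@pytest.fixture
def seq5():
    return generate_sequence(5, 1250, 0.0)


# ---------------------------------------------------------------------------
# warm-up discard


def test_warmup_discard_counts():
    t = discard_warmup(train(np.arange(60) * 1250.0), 10)
    assert np.sum(t.valid_mask) == 50
    assert np.sum(t.exclusions == WARMUP) == 10
    # two 60-tap runs minus 10 warm-up taps each leave 100 analysis taps
    assert 2 * np.sum(t.valid_mask) == 100


def test_warmup_discard_degenerate_short_train():
    with pytest.warns(UserWarning):
        t = discard_warmup(train(np.arange(5) * 1250.0), 10)
    assert np.sum(t.valid_mask) == 0


def test_warmup_zero_is_identity():
    t = discard_warmup(train([0, 1250, 2500]), 0)
    assert np.sum(t.valid_mask) == 3


# ---------------------------------------------------------------------------
# double-tap rule


@pytest.mark.parametrize(
    "taps, excluded",
    [
        ([1250, 1310, 2500], [1310.0]),  # gap 60 < 100
        ([1250, 1360, 2500], []),  # gap 110 >= 100
        ([], []),
    ],
)
def test_double_tap_rule(taps, excluded):
    t = remove_double_taps(train(taps), 100)
    assert t.taps[t.exclusions == DOUBLE_TAP].tolist() == excluded


def test_double_tap_chain_keeps_first():
    """In a burst the comparison continues from the retained tap."""
    t = remove_double_taps(train([1000, 1050, 1120, 1250]), 100)
    # 1050 is within 100 of 1000; 1120 within 100 of 1000? no (120), keep;
    # 1250 is 130 after 1120, keep
    assert t.taps[t.exclusions == DOUBLE_TAP].tolist() == [1050.0]


# ---------------------------------------------------------------------------
# ITI-outlier rule


@pytest.mark.parametrize(
    "taps, excluded",
    [
        ([0, 1250, 3200], [3200.0]),  # interval 1950 > 1875
        ([0, 1250, 1850], [1850.0]),  # interval 600 < 625
        ([0, 1250, 2500, 3750], []),  # taps exactly at onsets
    ],
)
def test_iti_outlier_rule(taps, excluded, seq5):
    t = remove_iti_outliers(train(taps), seq5, 0.5)
    assert t.taps[t.exclusions == ITI_OUTLIER].tolist() == excluded


def test_iti_outlier_interval_recomputed_over_retained(seq5):
    # after 1850 is dropped, 2500 is compared against 1250 (interval 1250, ok)
    t = remove_iti_outliers(train([0, 1250, 1850, 2500]), seq5, 0.5)
    assert t.taps[t.exclusions == ITI_OUTLIER].tolist() == [1850.0]
    assert np.sum(t.valid_mask) == 3


# ---------------------------------------------------------------------------
# matching


def test_match_nearest_click(seq5):
    m = match_taps(train([1200]), seq5)
    assert m.pairs.tolist() == [[1200.0, 1250.0]]
    assert m.offsets.tolist() == [-50.0]


def test_match_nearest_tap_wins_per_click(seq5):
    m = match_taps(train([1240, 1255]), seq5)
    # 1255 is nearer (|+5| < |-10|); 1240 left unmatched
    assert [1255.0, 1250.0] in m.pairs.tolist()
    assert 1240.0 in m.unmatched_taps.tolist()


def test_match_half_open_boundary(seq5):
    # tap exactly midway pairs with the earlier click at offset +ISI/2
    m = match_taps(train([625]), seq5)
    assert m.pairs.tolist() == [[625.0, 0.0]]
    assert m.offsets.tolist() == [625.0]


# ---------------------------------------------------------------------------
# summaries


def test_summary_of_perfect_taps(seq5):
    s = summarize(train(seq5.onsets.astype(float)), seq5)
    assert s.mean_se == 0 and s.sd_se == 0
    assert s.mean_iti == 1250 and s.sd_iti == 0


def test_summary_constant_anticipation(seq5):
    s = summarize(train(seq5.onsets - 50.0), seq5)
    assert s.mean_se == -50 and s.sd_se == 0


def test_summary_hand_computed_offsets():
    seq = generate_sequence(4, 1250, 0.0)
    s = summarize(train([1200, 2530, 3700]), seq)
    offsets = np.array([-50.0, 30.0, -50.0])
    assert s.mean_se == pytest.approx(offsets.mean(), abs=1e-9)
    assert s.mean_se == pytest.approx(-23.3333, abs=1e-3)
    assert s.sd_se == pytest.approx(offsets.std(ddof=1), abs=1e-9)


def test_summary_invalid_with_fewer_than_two_pairs(seq5):
    s = summarize(train([1200]), seq5)
    assert not s.valid


def test_average_runs_means_statistics(seq5):
    s1 = summarize(train(seq5.onsets - 40.0), seq5)
    s2 = summarize(train(seq5.onsets - 60.0), seq5)
    avg = average_runs([s1, s2])
    assert avg.mean_se == -50
    assert avg.n_valid_taps == s1.n_valid_taps + s2.n_valid_taps


def test_average_runs_single_run_identity(seq5):
    s1 = summarize(train(seq5.onsets - 40.0), seq5)
    avg = average_runs([s1])
    assert avg.mean_se == s1.mean_se and avg.sd_se == s1.sd_se


# ---------------------------------------------------------------------------
# verbal responses


@pytest.mark.parametrize(
    "responses, expected",
    [
        ([True, True], True),
        ([True, False], False),
        ([False, False], False),
        ([True], True),  # early-terminated session, single run
        ([], None),  # missing
    ],
)
def test_code_verbal_responses(responses, expected):
    assert code_verbal_responses(responses) is expected


# ---------------------------------------------------------------------------
# properties


def test_exclusion_counts_conserved(seq5, rng):
    seq = generate_sequence(60, 1250, 0.0)
    taps = np.sort(
        np.concatenate(
            [
                seq.onsets + rng.normal(0, 120, 60),
                seq.onsets[rng.random(60) < 0.1] + 30,  # doubles
            ]
        )
    )
    t = clean(train(taps), seq)
    counts = t.exclusion_counts()
    assert sum(counts.values()) == len(taps)


def test_cleaning_order_invariant_on_violation_free_train():
    """On a train with no rule violations the three rules commute."""
    seq = generate_sequence(30, 1250, 0.0)
    taps = seq.onsets - 50.0
    orders = [
        lambda t: remove_iti_outliers(
            remove_double_taps(discard_warmup(train(taps), 0)), seq
        ),
        lambda t: remove_double_taps(
            remove_iti_outliers(discard_warmup(train(taps), 0), seq)
        ),
    ]
    results = [f(taps) for f in orders]
    assert np.array_equal(results[0].valid_taps, results[1].valid_taps)


@given(shift=st.floats(-600, 625))
@settings(deadline=None, max_examples=30)
def test_constant_shift_recovered_exactly(shift):
    """A perfectly periodic tapper shifted by c has mean SE = c, SD = 0."""
    seq = generate_sequence(20, 1250, 0.0)
    s = summarize(train(seq.onsets + shift), seq)
    assert s.mean_se == pytest.approx(shift, abs=1e-9)
    assert s.sd_se == pytest.approx(0, abs=1e-9)


def test_long_gap_does_not_cascade(seq5):
    """One long gap excludes one tap; taps resuming the tempo afterwards
    are retained (the reference re-anchors on the excluded tap)."""
    seq = generate_sequence(10, 1250, 0.0)
    taps = [0, 1250, 3200, 4450, 5700]  # 3200 is a late outlier
    t = remove_iti_outliers(train(taps), seq, 0.5)
    assert t.taps[t.exclusions == ITI_OUTLIER].tolist() == [3200.0]
    assert np.sum(t.valid_mask) == 4
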