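import itertools
from collections import Counter

import numpy as np
import pytest

import emgseq as E
from emgseq.onset import OnsetAnnotation
from emgseq.thresholds import (DECREMENT_FRACTION, NA_VALUE, is_na,
                               _unique_preserving)
from .conftest import make_recording


def _flags(*channels):
    return tuple(c in channels for c in range(1, 7))


def _const_after(ch_levels, t0=600, n=4000):
    """Channels step from 0 to a constant level at t0."""
    sigs = {}
    for ch, level in ch_levels.items():
        s = np.zeros(n)
        s[t0:] = level
        sigs[ch] = s
    return make_recording(sigs)


class TestInitialMaxThreshold:
    def test_eighty_percent_of_single_peak(self):
        rec = _const_after({1: 2.0})
        ann = OnsetAnnotation(600.0, _flags(1), (600.0,) + (np.nan,) * 5)
        out = E.initial_max_threshold([rec], [ann])
        assert out[0] == pytest.approx(1.6)
        assert is_na(out[1])

    def test_mean_over_acquisitions(self):
        recs = [_const_after({1: 1.0}), _const_after({1: 2.0})]
        ann = OnsetAnnotation(600.0, _flags(1), (600.0,) + (np.nan,) * 5)
        out = E.initial_max_threshold(recs, [ann, ann])
        assert out[0] == pytest.approx((0.8 + 1.6) / 2)

    def test_channel_never_active_gets_sentinel(self):
        rec = _const_after({1: 2.0})
        ann = OnsetAnnotation(600.0, _flags(1), (600.0,) + (np.nan,) * 5)
        out = E.initial_max_threshold([rec], [ann])
        assert all(is_na(out[c]) for c in range(1, 6))

    def test_requires_a_detected_soa(self):
        rec = _const_after({})
        ann = OnsetAnnotation(None, _flags(), (np.nan,) * 6)
        with pytest.raises(ValueError, match="SoA"):
            E.initial_max_threshold([rec], [ann])


class TestLadder:
    def test_multiplicative_ten_percent_decrements(self):
        lad = E.build_ladder(0.8, 0.001, 3)
        assert lad.values == pytest.approx((0.8, 0.72, 0.648))

    def test_five_steps_admissible_before_half_peak_floor(self):
        assert E.max_admissible_steps() == 5
        # the 6th candidate would drop below 50% of the peak
        assert 0.8 * DECREMENT_FRACTION ** 4 > 0.5
        assert 0.8 * DECREMENT_FRACTION ** 5 < 0.5

    def test_entries_below_low_threshold_become_sentinel(self):
        lad = E.build_ladder(0.030, 0.028, 3)
        assert lad.values[0] == pytest.approx(0.030)
        assert is_na(lad.values[1]) and is_na(lad.values[2])

    def test_unreachable_start_yields_all_sentinel(self):
        assert all(is_na(v) for v in E.build_ladder(0.02, 0.05, 4).values)
        assert all(is_na(v) for v in E.build_ladder(NA_VALUE, 0.02, 4).values)

    def test_step_count_bounds(self):
        with pytest.raises(ValueError):
            E.build_ladder(1.0, 0.1, 1)
        with pytest.raises(ValueError):
            E.build_ladder(1.0, 0.1, 6)


def _toy_instance(rng, n_active=3, n_steps=3, n_acq=4):
    """Random small instance: step signals and full ladders on a few channels."""
    n = 320
    channels = sorted(rng.choice(range(1, 7), size=n_active, replace=False))
    recs, anns = [], []
    for _ in range(n_acq):
        sigs = {}
        for ch in channels:
            t_step = int(rng.integers(5, 250))
            level = float(rng.uniform(0.5, 2.0))
            s = np.zeros(n)
            s[t_step:] = level
            sigs[ch] = s
        recs.append(make_recording(sigs, n=n))
        anns.append(OnsetAnnotation(0.0, _flags(*channels), (0.0,) * 6))
    ladders = []
    for c in range(1, 7):
        if c in channels:
            top = float(rng.uniform(0.8, 1.8))
            values = tuple(top * DECREMENT_FRACTION ** i for i in range(n_steps))
        else:
            values = (NA_VALUE,) * n_steps
        ladders.append(E.ThresholdLadder(channel=c, values=values))
    return recs, anns, ladders


def _brute_force_best(recs, anns, ladders):
    """Independent enumeration over candidate products using encode_sequence."""
    cands = [_unique_preserving(l.values) for l in ladders]
    best = None
    for combo in itertools.product(*cands):
        vec = E.ThresholdVector(task=recs[0].label, values=tuple(combo), n_steps=2)
        seqs = [E.encode_sequence(r, a.soa_ms, vec).entries
                for r, a in zip(recs, anns)]
        count = Counter(seqs).most_common(1)[0][1]
        if best is None or count > best[1]:
            best = (combo, count)
    return best


class TestRepresentativeSearch:
    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_active = int(rng.integers(2, 4))  # <= 3 channels
        n_steps = int(rng.integers(2, 4))   # <= 3 steps
        recs, anns, ladders = _toy_instance(rng, n_active, n_steps)
        vec, modal, count = E.search_representative_vector(
            recs, anns, ladders, n_steps)
        oracle_combo, oracle_count = _brute_force_best(recs, anns, ladders)
        assert count == oracle_count
        # the returned vector must itself achieve the modal count
        seqs = [E.encode_sequence(r, a.soa_ms, vec).entries
                for r, a in zip(recs, anns)]
        assert Counter(seqs).most_common(1)[0][1] == count
        assert Counter(seqs)[modal] == count

    def test_combination_count_is_steps_to_the_active_channels(self):
        rng = np.random.default_rng(42)
        recs, anns, ladders = _toy_instance(rng, n_active=3, n_steps=3)
        cands = [_unique_preserving(l.values) for l in ladders]
        n_combos = int(np.prod([len(c) for c in cands]))
        assert n_combos == 3 ** 3

    def test_identical_acquisitions_tie_break_to_highest_thresholds(self):
        rng = np.random.default_rng(7)
        recs, anns, ladders = _toy_instance(rng, n_active=2, n_steps=3, n_acq=1)
        recs = recs * 3
        anns = anns * 3
        vec, _, count = E.search_representative_vector(recs, anns, ladders, 3)
        assert count == 3
        for c in range(6):
            assert vec.values[c] == pytest.approx(ladders[c].values[0])

    def test_empty_recordings_rejected(self):
        ladders = [E.ThresholdLadder(c, (NA_VALUE,) * 2) for c in range(1, 7)]
        with pytest.raises(ValueError):
            E.search_representative_vector([], [], ladders, 2)


def test_representative_matrix_is_four_by_six(fitted):
    frame = fitted.threshold_frame()
    assert frame.shape == (4, 6)
    assert list(frame.index) == list(E.TASKS)
    for task, vec in fitted.threshold_vectors.items():
        assert len(vec.values) == 6
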