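import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emgseq as E
from emgseq.thresholds import NA_VALUE
from .conftest import make_recording


def _vector(values, task="Tip"):
    return E.ThresholdVector(task=task, values=tuple(values), n_steps=4)


def _crossing_recording(latencies, n=400):
    """Channels step to 1 V at the given latency (ms from t=0); None = never."""
    sigs = {}
    for ch, lat in latencies.items():
        if lat is None:
            continue
        s = np.zeros(n)
        s[lat:] = 1.0
        sigs[ch] = s
    return make_recording(sigs, n=n)


class TestEncodeSequence:
    def test_ranks_channels_by_crossing_time(self):
        rec = _crossing_recording({4: 120, 1: 150, 3: 200, 5: 250,
                                   2: None, 6: None})
        seq = E.encode_sequence(rec, 0.0, _vector([0.5] * 6))
        assert seq.entries == (4, 1, 3, 5, 0, 0)
        assert seq.latencies_ms[4] == pytest.approx(120.0)
        assert seq.latencies_ms[5] == pytest.approx(250.0)

    def test_never_crossing_channels_are_trailing_zeros(self):
        rec = _crossing_recording({2: 50, 6: 90})
        # channels 2 and 6 get unreachable sentinels -> encoded 0 at the tail
        seq = E.encode_sequence(rec, 0.0, _vector(
            [0.5, NA_VALUE, 0.5, 0.5, 0.5, NA_VALUE]))
        assert seq.entries == (0, 0, 0, 0, 0, 0)

    def test_no_crossing_gives_all_zeros(self):
        rec = _crossing_recording({})
        seq = E.encode_sequence(rec, 0.0, _vector([0.5] * 6))
        assert seq.entries == (0,) * 6

    def test_simultaneous_crossings_tie_break_by_channel(self):
        rec = _crossing_recording({5: 100, 2: 100})
        seq = E.encode_sequence(rec, 0.0, _vector([0.5] * 6))
        assert seq.entries[:2] == (2, 5)

    def test_window_overrun_rejected(self):
        rec = _crossing_recording({1: 50}, n=200)
        with pytest.raises(ValueError, match="overrun"):
            E.encode_sequence(rec, 0.0, _vector([0.5] * 6), window_ms=300)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(lats=st.lists(st.one_of(st.none(), st.integers(0, 299)),
                         min_size=6, max_size=6))
    def test_nonzero_entries_distinct_and_zeros_trailing(self, lats):
        rec = _crossing_recording(
            {c + 1: lat for c, lat in enumerate(lats)}, n=400)
        seq = E.encode_sequence(rec, 0.0, _vector([0.5] * 6))
        nz = [e for e in seq.entries if e]
        assert len(set(nz)) == len(nz)
        assert seq.entries[len(nz):] == (0,) * (6 - len(nz))
        assert set(nz) == {c + 1 for c, lat in enumerate(lats) if lat is not None}

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_lowering_a_threshold_never_delays_that_channel(self, seed):
        rng = np.random.default_rng(seed)
        sigs = {c: np.abs(np.cumsum(rng.normal(0, 0.05, 400)))
                for c in range(1, 7)}
        rec = make_recording(sigs, n=400)
        hi = _vector([0.6] * 6)
        lo_vals = [0.6] * 6
        lo_vals[2] = 0.3
        lo = _vector(lo_vals)
        s_hi = E.encode_sequence(rec, 0.0, hi)
        s_lo = E.encode_sequence(rec, 0.0, lo)
        pos_hi = s_hi.entries.index(3) if 3 in s_hi.entries else 6
        pos_lo = s_lo.entries.index(3) if 3 in s_lo.entries else 6
        if 3 in s_hi.entries:
            assert s_lo.latencies_ms[3] <= s_hi.latencies_ms[3]
            assert pos_lo <= pos_hi


class TestEncodeFeatures:
    def test_feature_has_twelve_entries(self, fitted):
        rec = fitted.usable[0]
        ann = fitted.usable_annotations[0]
        feat = E.encode_features(rec, ann.soa_ms, fitted.threshold_vectors)
        assert feat.shape == (12,)
        assert feat.dtype == np.int64

    def test_all_sentinel_vector_gives_zero_block(self):
        rec = _crossing_recording({1: 50, 2: 100})
        vectors = {t: _vector([0.5] * 6, task=t) for t in E.TASKS}
        vectors["Point"] = _vector([NA_VALUE] * 6, task="Point")
        feat = E.encode_features(rec, 0.0, vectors)
        assert list(feat[9:]) == [0, 0, 0]
        assert list(feat[:3]) == [1, 2, 0]

    def test_rest_like_acquisition_encodes_all_zero(self):
        rec = _crossing_recording({})
        vectors = {t: _vector([0.5] * 6, task=t) for t in E.TASKS}
        assert not E.encode_features(rec, 0.0, vectors).any()

    def test_missing_task_vector_rejected(self):
        rec = _crossing_recording({1: 50})
        vectors = {t: _vector([0.5] * 6, task=t) for t in E.TASKS[:3]}
        with pytest.raises(ValueError, match="missing"):
            E.encode_features(rec, 0.0, vectors)


class TestTimingSummary:
    def test_single_acquisition_means(self):
        rec = _crossing_recording({2: 100, 4: 200, 1: 250})
        seq = E.encode_sequence(rec, 0.0, _vector([0.5] * 6))
        summary = E.activation_timing_summary([seq])
        assert summary.mean_rank_latencies_ms == pytest.approx((100, 200, 250))
        assert summary.mean_activations == pytest.approx(3.0)

    def test_recovers_generator_latency_ordering(self, fitted):
        summary = fitted.timing_summary()
        first, second, third = summary.mean_rank_latencies_ms
        assert 0 < first < second < third < 300
        assert summary.mean_activations >= 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            E.activation_timing_summary([])


def test_sequence_validation_rejects_interior_zeros():
    with pytest.raises(ValueError, match="trailing"):
        E.ActivationSequence(entries=(1, 0, 2, 0, 0, 0), latencies_ms={})
    with pytest.raises(ValueError, match="distinct"):
        E.ActivationSequence(entries=(1, 1, 0, 0, 0, 0), latencies_ms={})
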