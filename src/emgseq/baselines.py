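"""Comparison feature sets: transient envelope (ETS) and steady-state MAV (ESS).

ETS summarizes the raw envelope over the 300 ms transient window after the
SoA as per-channel bin means (10 ms bins by default, 6 x 30 = 180 features;
``bin_ms=1`` recovers the raw samples).  ESS anchors on the steady state,
approximated as the instant of the first absolute envelope peak among the
six channels, and takes the per-channel mean absolute value over a 100 ms
window from that anchor.  ``timing_comparison`` quantifies how much earlier
the sequence-based class selection (last activation of the partial
sequence) occurs than the steady-state anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synthetic import EnvelopeRecording, N_CHANNELS


@dataclass(frozen=True)
class SteadyStateAnchor:
    t_peak_ms: float
    channel_of_peak: int


@dataclass(frozen=True)
class TimingComparison:
    t_seq_ms: float
    t_ess_ms: float

    @property
    def gap_ms(self) -> float:
        return self.t_ess_ms - self.t_seq_ms


def ets_features(rec: EnvelopeRecording, soa_ms: float,
                 window_ms: float = 300.0, bin_ms: float = 10.0) -> np.ndarray:
    """Per-channel envelope bin means over the transient window, concatenated."""
    i0 = int(round(soa_ms * rec.fs / 1000.0))
    n_win = int(round(window_ms * rec.fs / 1000.0))
    n_bin = int(round(bin_ms * rec.fs / 1000.0))
    if i0 + n_win > rec.n_samples:
        raise ValueError("transient window overruns recording end")
    if n_bin < 1 or n_win % n_bin:
        raise ValueError("bin_ms must divide window_ms")
    seg = rec.samples[i0:i0 + n_win]  # (n_win, 6)
    binned = seg.reshape(n_win // n_bin, n_bin, N_CHANNELS).mean(axis=1)
    return binned.T.ravel()  # channel-major: ch1 bins, ch2 bins, ...


def ess_features(rec: EnvelopeRecording,
                 window_ms: float = 100.0) -> tuple[np.ndarray, SteadyStateAnchor]:
    """Six-channel MAV at the steady-state anchor.

    The anchor is the global maximum sample over all channels (earliest
    instant, then lowest channel, on ties); the MAV of each channel is the
    mean absolute envelope over [t_peak, t_peak + window).
    """
    flat = int(np.argmax(rec.samples))  # row-major: earliest time, lowest channel
    i_peak, c_peak = divmod(flat, N_CHANNELS)
    n_win = int(round(window_ms * rec.fs / 1000.0))
    if i_peak + n_win > rec.n_samples:
        raise ValueError("steady-state window overruns recording end")
    mav = np.abs(rec.samples[i_peak:i_peak + n_win]).mean(axis=0)
    anchor = SteadyStateAnchor(t_peak_ms=i_peak / rec.fs * 1000.0,
                               channel_of_peak=c_peak + 1)
    return mav, anchor


def timing_comparison(soa_ms: float, crossing_latencies_ms: Sequence[float],
                      anchor: SteadyStateAnchor,
                      k: int = 3) -> TimingComparison:
    """Class-selection timing of the sequence method vs the ESS anchor.

    ``t_seq`` is the latency (from SoA) of the last activation of the
    partial sequence, i.e. the min(k, n)-th crossing; ``t_ess`` is the
    latency of the steady-state anchor.
    """
    lats = sorted(crossing_latencies_ms)
    if not lats:
        raise ValueError("empty partial sequence")
    t_seq = float(lats[min(k, len(lats)) - 1])
    t_ess = float(anchor.t_peak_ms - soa_ms)
    return TimingComparison(t_seq_ms=t_seq, t_ess_ms=t_ess)
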