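"""Double-threshold onset detection.

The low threshold ``TH_Low = mu + x * sigma`` is a single dataset-level
value, with ``mu`` and ``sigma`` the mean and standard deviation of the
envelope in the rest state, pooled over all channels and acquisitions of a
dataset.  A channel is considered to have crossed only when it exceeds
TH_Low throughout a sustained window (50 ms by default); the Start of
Activation (SoA) of an acquisition is the earliest sustained crossing over
the six channels, and channels without any sustained crossing are flagged
Not Active.

``tune_x`` reproduces the multiplier-tuning experiment: for each candidate
``x`` it measures the false-activation rate, i.e. the fraction of
acquisitions with a sustained crossing starting inside the initial rest
interval (first 100 ms by default), and selects the smallest candidate
whose rate stays below 5%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synthetic import EnvelopeRecording, N_CHANNELS


@dataclass(frozen=True)
class RestModel:
    """Rest statistics and the derived low threshold.

    ``th_low`` is mu + x * sigma by construction.
    """

    mu: float
    sigma: float
    x: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def th_low(self) -> float:
        return self.mu + self.x * self.sigma


@dataclass(frozen=True)
class OnsetAnnotation:
    """Per-acquisition onset result.

    ``soa_ms`` is None when no channel sustains a crossing (a rest-like
    acquisition).  ``active_flags[c]`` tells whether channel c+1 ever
    sustained a crossing; ``first_low_crossing_ms[c]`` is the start time of
    its first sustained window (NaN when never active).
    """

    soa_ms: float | None
    active_flags: tuple[bool, ...]
    first_low_crossing_ms: tuple[float, ...]


def _first_sustained_start(above: np.ndarray, w: int) -> int | None:
    """First index i such that above[i:i+w] is all True, else None."""
    if above.size < w:
        return None
    counts = np.convolve(above.astype(np.intp), np.ones(w, dtype=np.intp), "valid")
    hits = np.flatnonzero(counts == w)
    return int(hits[0]) if hits.size else None


def estimate_rest_model(recordings: Sequence[EnvelopeRecording],
                        rest_window_ms: tuple[float, float] = (0.0, 500.0),
                        x: float = 15.0) -> RestModel:
    """Pool rest-phase samples over all channels and recordings.

    The window must lie inside every recording's guaranteed rest phase.
    """
    if not recordings:
        raise ValueError("empty recording list")
    lo, hi = rest_window_ms
    if not 0 <= lo < hi:
        raise ValueError("invalid rest window")
    chunks = []
    for rec in recordings:
        if hi > rec.rest_duration_ms:
            raise ValueError(
                f"rest window [{lo}, {hi}) ms exceeds the guaranteed rest "
                f"phase ({rec.rest_duration_ms} ms) of a recording")
        i0 = int(round(lo * rec.fs / 1000.0))
        i1 = int(round(hi * rec.fs / 1000.0))
        chunks.append(rec.samples[i0:i1].ravel())
    pooled = np.concatenate(chunks)
    sigma = float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0
    return RestModel(mu=float(np.mean(pooled)), sigma=sigma, x=float(x))


def detect_soa(rec: EnvelopeRecording, rest: RestModel,
               sustain_ms: float = 50.0,
               search_window_ms: tuple[float, float] | None = None) -> OnsetAnnotation:
    """Detect the Start of Activation with the sustained-crossing rule.

    For each channel, finds the first time t such that every sample in
    [t, t + sustain_ms) exceeds TH_Low; the sustain window may extend past
    the end of the search window but not past the recording.  SoA is the
    minimum such t over channels; it is reported at the first sample of the
    sustained window.
    """
    if sustain_ms < 1.0:
        raise ValueError("sustain_ms must be >= 1 ms")
    w = int(round(sustain_ms * rec.fs / 1000.0))
    if w > rec.n_samples:
        raise ValueError("sustain window longer than recording")
    if search_window_ms is None:
        s0, s1 = 0, rec.n_samples
    else:
        s0 = int(round(search_window_ms[0] * rec.fs / 1000.0))
        s1 = int(round(search_window_ms[1] * rec.fs / 1000.0))
        if not 0 <= s0 < s1 <= rec.n_samples:
            raise ValueError("search window outside recording")

    firsts = np.full(N_CHANNELS, np.nan)
    flags = [False] * N_CHANNELS
    for c in range(N_CHANNELS):
        above = rec.samples[s0:, c] > rest.th_low
        start = _first_sustained_start(above, w)
        if start is not None and (s0 + start) < s1:
            flags[c] = True
            firsts[c] = (s0 + start) / rec.fs * 1000.0
    soa = float(np.nanmin(firsts)) if any(flags) else None
    return OnsetAnnotation(soa_ms=soa, active_flags=tuple(flags),
                           first_low_crossing_ms=tuple(firsts))


@dataclass(frozen=True)
class XTuningResult:
    """False-activation rates per candidate multiplier and the selection."""

    rates: dict[float, float]
    selected: float | None
    mu: float
    sigma: float


def tune_x(recordings: Sequence[EnvelopeRecording],
           candidates: Sequence[float] = (2.0, 5.0, 10.0, 15.0),
           false_window_ms: tuple[float, float] = (0.0, 100.0),
           sustain_ms: float = 50.0,
           rest_window_ms: tuple[float, float] = (0.0, 500.0),
           max_rate: float = 0.05) -> XTuningResult:
    """Measure false-activation rates and select the low-threshold multiplier.

    A false activation is a sustained crossing whose window starts inside
    ``false_window_ms`` (the initial rest interval).  The selected x is the
    smallest candidate with a rate below ``max_rate``; ``selected`` is None
    when no candidate qualifies.
    """
    if not recordings:
        raise ValueError("empty recording list")
    base = estimate_rest_model(recordings, rest_window_ms, x=0.0)
    rates: dict[float, float] = {}
    for x in sorted(candidates):
        rest = RestModel(base.mu, base.sigma, float(x))
        n_false = sum(
            detect_soa(rec, rest, sustain_ms, false_window_ms).soa_ms is not None
            for rec in recordings)
        rates[float(x)] = n_false / len(recordings)
    selected = next((x for x in sorted(rates) if rates[x] < max_rate), None)
    return XTuningResult(rates=rates, selected=selected,
                         mu=base.mu, sigma=base.sigma)
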