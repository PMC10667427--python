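"""Muscular activation sequence encoding and the 12-element feature.

A muscular activation sequence ranks the six channels by the time each
first exceeds its TH_High inside the 300 ms transient window after the SoA;
the sequence entry is the channel number, channels that never cross (or
whose TH_High is the NA sentinel) contribute a 0 appended at the tail.

The classification feature encodes each acquisition under all four tasks'
representative threshold vectors, keeps the first three elements of each
of the four sequences, and concatenates them into a 1x12 integer vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .synthetic import EnvelopeRecording, N_CHANNELS
from .thresholds import ThresholdVector

#: Fixed task order of the feature blocks.
TASKS = ("Spherical", "Tip", "Platform", "Point")
PREFIX_LEN = 3
FEATURE_LEN = PREFIX_LEN * len(TASKS)


@dataclass(frozen=True)
class ActivationSequence:
    """Length-6 ordinal sequence with per-channel crossing latencies.

    ``entries`` are channel numbers in crossing order, zeros trailing;
    ``latencies_ms`` maps each crossed channel to its latency from the SoA.
    """

    entries: tuple[int, ...]
    latencies_ms: Mapping[int, float]

    def __post_init__(self) -> None:
        nz = [e for e in self.entries if e != 0]
        if len(set(nz)) != len(nz):
            raise ValueError("nonzero entries must be distinct channels")
        if tuple(e for e in self.entries if e == 0) != self.entries[len(nz):]:
            raise ValueError("zeros must occupy only trailing positions")

    @property
    def n_activations(self) -> int:
        return sum(1 for e in self.entries if e != 0)

    def prefix(self, k: int = PREFIX_LEN) -> tuple[int, ...]:
        return self.entries[:k]


def encode_sequence(rec: EnvelopeRecording, soa_ms: float,
                    th_vector: ThresholdVector,
                    window_ms: float = 300.0) -> ActivationSequence:
    """Encode one acquisition under one threshold vector.

    Channels are ranked by the first sample in [SoA, SoA + window) strictly
    exceeding their TH_High; simultaneous crossings break ties by lower
    channel number.  NA-sentinel thresholds are unreachable by construction
    and therefore encode 0.
    """
    if soa_ms is None:
        raise ValueError("soa_ms must be present to encode a sequence")
    i0 = int(round(soa_ms * rec.fs / 1000.0))
    i1 = i0 + int(round(window_ms * rec.fs / 1000.0))
    if i1 > rec.n_samples:
        raise ValueError("transient window overruns recording end")
    seg = rec.samples[i0:i1]
    crossed: list[tuple[float, int]] = []
    latencies: dict[int, float] = {}
    for c in range(N_CHANNELS):
        th = th_vector.values[c]
        idx = np.flatnonzero(seg[:, c] > th)
        if idx.size:
            lat = idx[0] / rec.fs * 1000.0
            crossed.append((lat, c + 1))
            latencies[c + 1] = float(lat)
    crossed.sort()
    entries = tuple(ch for _, ch in crossed)
    entries += (0,) * (N_CHANNELS - len(entries))
    return ActivationSequence(entries=entries, latencies_ms=latencies)


def encode_features(rec: EnvelopeRecording, soa_ms: float,
                    representative_vectors: Mapping[str, ThresholdVector],
                    window_ms: float = 300.0,
                    tasks: Sequence[str] = TASKS) -> np.ndarray:
    """Refined (1 x 12) feature: four 3-element partial sequences appended.

    The acquisition is encoded under each task's representative vector in
    the fixed task order; each sequence is truncated to its first three
    elements and the four rows are concatenated.
    """
    missing = [t for t in tasks if t not in representative_vectors]
    if missing:
        raise ValueError(f"missing representative vectors for tasks {missing}")
    blocks = []
    for task in tasks:
        seq = encode_sequence(rec, soa_ms, representative_vectors[task], window_ms)
        blocks.extend(seq.prefix(PREFIX_LEN))
    return np.asarray(blocks, dtype=np.int64)


@dataclass(frozen=True)
class TimingSummary:
    """Mean activation latencies and dataset activation statistics."""

    mean_rank_latencies_ms: tuple[float, ...]
    mean_activations: float
    mean_active_channels: float
    n_sequences: int


def activation_timing_summary(sequences: Sequence[ActivationSequence],
                              k: int = PREFIX_LEN,
                              active_counts: Sequence[int] | None = None) -> TimingSummary:
    """Mean latency of the 1st..k-th activations across acquisitions.

    ``mean_activations`` is the mean number of crossings inside the
    transient window (activation timing); ``mean_active_channels`` is the
    mean number of channels active in the acquisition (activation entity),
    taken from ``active_counts`` when provided (e.g. from onset flags) and
    otherwise equal to the crossing count.
    """
    if not sequences:
        raise ValueError("no sequences")
    ranks: list[list[float]] = [[] for _ in range(k)]
    for seq in sequences:
        lats = sorted(seq.latencies_ms.values())
        for r in range(min(k, len(lats))):
            ranks[r].append(lats[r])
    means = tuple(float(np.mean(r)) if r else float("nan") for r in ranks)
    n_act = float(np.mean([s.n_activations for s in sequences]))
    if active_counts is not None:
        entity = float(np.mean(list(active_counts)))
    else:
        entity = n_act
    return TimingSummary(mean_rank_latencies_ms=means, mean_activations=n_act,
                         mean_active_channels=entity,
                         n_sequences=len(sequences))
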