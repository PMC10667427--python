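"""Per-task TH_High ladders and the exhaustive representative-vector search.

For each task, the starting point is a 1x6 vector of 80% of the per-channel
envelope peak inside the 300 ms transient window after the SoA, averaged
over the task's acquisitions.  Each channel's candidate ladder is obtained
by multiplicative 10% decrements of that start value (80%, 72%, 64.8%, ...
of the peak), admissible while above 50% of the peak — hence at most five
steps — and while above TH_Low; inadmissible entries become the NA_Value
sentinel, a voltage above the 5 V full scale that no envelope can reach.

The representative TH_High vector for a task is found by exhaustively
enumerating every combination of one candidate per channel
(n_steps ** 6 combinations for full ladders), encoding the activation
sequence of every acquisition under each combination, and selecting the
combination whose most-repeated (modal) sequence has the highest count.
Ties prefer the earliest-enumerated, i.e. highest-threshold, combination.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .onset import OnsetAnnotation
from .synthetic import EnvelopeRecording, N_CHANNELS, FULL_SCALE_V

#: Sentinel threshold for Not Active channels: above full scale, unreachable.
NA_VALUE = 10.0

START_FRACTION = 0.8
DECREMENT_FRACTION = 0.9
FLOOR_FRACTION = 0.5

_POW7 = 7 ** np.arange(N_CHANNELS, dtype=np.int64)


def is_na(value: float) -> bool:
    return value > FULL_SCALE_V


@dataclass(frozen=True)
class ThresholdLadder:
    """Descending TH_High candidates for one channel (NA_Value sentinels)."""

    channel: int
    values: tuple[float, ...]
    start_fraction: float = START_FRACTION
    decrement_fraction: float = DECREMENT_FRACTION
    floor_fraction: float = FLOOR_FRACTION


@dataclass(frozen=True)
class ThresholdVector:
    """Per-task representative TH_High vector (entries may be NA_Value)."""

    task: str
    values: tuple[float, ...]
    n_steps: int

    def __post_init__(self) -> None:
        if len(self.values) != N_CHANNELS:
            raise ValueError("a threshold vector has one value per channel")


def max_admissible_steps(start_fraction: float = START_FRACTION,
                         decrement_fraction: float = DECREMENT_FRACTION,
                         floor_fraction: float = FLOOR_FRACTION) -> int:
    """Number of ladder steps that stay above the peak-fraction floor."""
    n = 0
    value = start_fraction
    while value > floor_fraction:
        n += 1
        value *= decrement_fraction
    return n


def initial_max_threshold(task_recordings: Sequence[EnvelopeRecording],
                          annotations: Sequence[OnsetAnnotation],
                          window_ms: float = 300.0) -> np.ndarray:
    """Starting 1x6 maximum TH_High vector for one task.

    Per channel: the mean over acquisitions of 80% of the envelope peak in
    [SoA, SoA + window).  Acquisitions where the channel is Not Active do
    not contribute (their per-acquisition TH_High is the sentinel); a
    channel Not Active in every acquisition gets NA_VALUE.
    """
    if len(task_recordings) != len(annotations):
        raise ValueError("recordings and annotations must be parallel")
    sums = np.zeros(N_CHANNELS)
    counts = np.zeros(N_CHANNELS, dtype=int)
    n_with_soa = 0
    for rec, ann in zip(task_recordings, annotations):
        if ann.soa_ms is None:
            continue
        n_with_soa += 1
        i0 = int(round(ann.soa_ms * rec.fs / 1000.0))
        i1 = min(i0 + int(round(window_ms * rec.fs / 1000.0)), rec.n_samples)
        window = rec.samples[i0:i1]
        for c in range(N_CHANNELS):
            if ann.active_flags[c]:
                sums[c] += START_FRACTION * float(window[:, c].max())
                counts[c] += 1
    if n_with_soa == 0:
        raise ValueError("no acquisition with a detected SoA")
    out = np.full(N_CHANNELS, NA_VALUE)
    mask = counts > 0
    out[mask] = sums[mask] / counts[mask]
    return out


def build_ladder(max_th: float, th_low: float, n_steps: int,
                 channel: int = 0) -> ThresholdLadder:
    """Build one channel's descending candidate ladder.

    values[i] = max_th * 0.9**i for i = 0..n_steps-1, each replaced by
    NA_VALUE when it does not exceed TH_Low; a Not Active channel (max_th
    already the sentinel) yields an all-NA ladder.
    """
    if not 2 <= n_steps <= 5:
        raise ValueError("n_steps must lie in 2..5")
    if is_na(max_th) or max_th <= th_low:
        values = (NA_VALUE,) * n_steps
    else:
        values = tuple(
            v if v > th_low else NA_VALUE
            for v in (max_th * DECREMENT_FRACTION ** i for i in range(n_steps)))
    return ThresholdLadder(channel=channel, values=values)


def _unique_preserving(values: Sequence[float]) -> np.ndarray:
    out: list[float] = []
    for v in values:
        if not any(np.isclose(v, u) for u in out):
            out.append(float(v))
    return np.asarray(out)


def sequence_to_code(entries: Sequence[int]) -> int:
    return int(np.dot(np.asarray(entries, dtype=np.int64), _POW7))

def code_to_sequence(code: int) -> tuple[int, ...]:
    return tuple(int(code // int(p)) % 7 for p in _POW7)


def search_representative_vector(
        task_recordings: Sequence[EnvelopeRecording],
        annotations: Sequence[OnsetAnnotation],
        ladders: Sequence[ThresholdLadder],
        n_steps: int,
        window_ms: float = 300.0,
) -> tuple[ThresholdVector, tuple[int, ...], int]:
    """Exhaustive search for the task's representative TH_High vector.

    Enumerates every combination of one candidate per channel (an all-NA
    channel contributes a single fixed sentinel entry), encodes every
    acquisition's activation sequence under each combination, and returns
    the combination maximizing the modal-sequence count, together with the
    modal sequence and its count.  Equal counts resolve to the earliest
    enumerated combination; since ladders are scanned highest-to-lowest,
    that is the most conservative (highest-threshold) one.
    """
    if not task_recordings:
        raise ValueError("empty recordings")
    if len(ladders) != N_CHANNELS:
        raise ValueError("need one ladder per channel")
    pairs = [(r, a) for r, a in zip(task_recordings, annotations)
             if a.soa_ms is not None]
    if not pairs:
        raise ValueError("no acquisition with a detected SoA")

    cands = [_unique_preserving(lad.values) for lad in ladders]
    sizes = [len(c) for c in cands]
    n_rec = len(pairs)

    # First-crossing sample index (inf = never) per recording/channel/candidate.
    T = np.full((n_rec, N_CHANNELS, max(sizes)), np.inf)
    for i, (rec, ann) in enumerate(pairs):
        i0 = int(round(ann.soa_ms * rec.fs / 1000.0))
        i1 = i0 + int(round(window_ms * rec.fs / 1000.0))
        if i1 > rec.n_samples:
            raise ValueError("transient window overruns recording end")
        seg = rec.samples[i0:i1]
        for c in range(N_CHANNELS):
            for j, v in enumerate(cands[c]):
                idx = np.flatnonzero(seg[:, c] > v)
                if idx.size:
                    T[i, c, j] = idx[0]

    combos = np.array(list(itertools.product(*[range(s) for s in sizes])),
                      dtype=np.intp)
    n_combo = combos.shape[0]

    # Crossing times per (recording, combination, channel).
    G = np.empty((n_rec, n_combo, N_CHANNELS))
    for c in range(N_CHANNELS):
        G[:, :, c] = T[:, c, :][:, combos[:, c]]

    order = np.argsort(G, axis=2, kind="stable")  # ties -> lower channel
    sorted_t = np.take_along_axis(G, order, axis=2)
    seq = np.where(np.isfinite(sorted_t), order + 1, 0).astype(np.int64)
    codes = seq @ _POW7  # (n_rec, n_combo)

    # Modal count per combination via run lengths over sorted codes.
    S = np.sort(codes, axis=0)
    run = np.ones(n_combo, dtype=np.int64)
    best = np.ones(n_combo, dtype=np.int64)
    best_code = S[0].copy()
    for i in range(1, n_rec):
        run = np.where(S[i] == S[i - 1], run + 1, 1)
        improved = run > best
        best = np.where(improved, run, best)
        best_code = np.where(improved, S[i], best_code)

    m = int(np.argmax(best))  # first maximizer = highest thresholds
    values = tuple(float(cands[c][combos[m, c]]) for c in range(N_CHANNELS))
    vector = ThresholdVector(task=task_recordings[0].label, values=values,
                             n_steps=n_steps)
    return vector, code_to_sequence(int(best_code[m])), int(best[m])


def fit_threshold_matrix(recordings: Sequence[EnvelopeRecording],
                         annotations: Sequence[OnsetAnnotation],
                         th_low: float, n_steps: int,
                         tasks: Sequence[str],
                         window_ms: float = 300.0):
    """Representative TH_High vector per task (the 4x6 matrix).

    Returns ``(vectors, modal)`` where ``vectors`` maps task -> ThresholdVector
    and ``modal`` maps task -> (modal sequence, modal count).
    """
    vectors: dict[str, ThresholdVector] = {}
    modal: dict[str, tuple[tuple[int, ...], int]] = {}
    for task in tasks:
        recs = [r for r in recordings if r.label == task]
        anns = [a for r, a in zip(recordings, annotations) if r.label == task]
        if not recs:
            raise ValueError(f"no recordings for task {task!r}")
        max_th = initial_max_threshold(recs, anns, window_ms)
        ladders = [build_ladder(max_th[c], th_low, n_steps, channel=c + 1)
                   for c in range(N_CHANNELS)]
        vec, mseq, mcount = search_representative_vector(
            recs, anns, ladders, n_steps, window_ms)
        vectors[task] = vec
        modal[task] = (mseq, mcount)
    return vectors, modal
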