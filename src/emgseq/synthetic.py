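"""Synthetic sEMG-envelope generator with known ground truth.

Emulates the acquisition protocol of a six-sensor forearm bracelet setup:
commercial envelope sensors (0-5 V output), 1 kHz sampling, 4 s acquisitions
that begin with at least 500 ms of rest.  Each gesture is defined by which
channels activate, in which order, with which delays and plateau amplitudes.
Because the generator knows the onset time, activation order and active set
of every recording, every downstream stage (onset detection, threshold
search, sequence encoding, classification, online simulation) can be tested
against ground truth.

Signal model
------------
Rest-phase noise is a first-order autoregressive (low-pass filtered white)
process: envelope sensors smooth the rectified EMG, so rest noise is
temporally correlated, which is what makes short sustained false crossings
possible at small threshold multipliers.  Active channels add a logistic
rise (10->90% over ``rise_time``) to a plateau whose amplitude carries a
per-acquisition scale jitter, a slow multiplicative temporal jitter and a
mid-contraction "effort overshoot" bump, so that the global envelope peak
(the steady-state anchor used by the ESS baseline) always falls well after
the transient.  The final signal is clipped to the 0-5 V sensor range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit

N_CHANNELS = 6
FULL_SCALE_V = 5.0

_LN81 = float(np.log(81.0))  # logistic 10->90% span in units of the scale k
_LN99 = float(np.log(99.0))


@dataclass(frozen=True)
class NoiseModel:
    """Rest-phase envelope noise statistics.

    Parameters
    ----------
    rest_mean, rest_sd : float
        Mean and standard deviation of the envelope at rest, in volts.
        Defaults are the average rest statistics of the six-sensor bracelet
        (0.012 V mean, 0.0007 V sd).
    correlation_time : float
        Autocorrelation time of the rest noise in ms (AR(1) time constant),
        modelling the sensor's internal envelope smoothing.
    """

    rest_mean: float = 0.012
    rest_sd: float = 0.0007
    correlation_time: float = 100.0

    def __post_init__(self) -> None:
        if self.rest_mean <= 0 or self.rest_sd < 0:
            raise ValueError("rest_mean must be > 0 and rest_sd >= 0")
        if self.correlation_time <= 0:
            raise ValueError("correlation_time must be positive (ms)")


@dataclass(frozen=True)
class GestureProfile:
    """Ground-truth description of one gesture's muscular activation pattern.

    ``order`` is the activation order (channel numbers 1..6); ``mean_delays``
    maps each active channel to its mean onset delay after movement onset in
    ms and must be consistent with ``order`` (sorting channels by delay
    reproduces the order).  ``plateau_amplitudes`` maps active channels to
    plateau voltages.  A profile with no active channels is the Rest class.
    """

    name: str
    order: tuple[int, ...] = ()
    mean_delays: Mapping[int, float] = field(default_factory=dict)
    plateau_amplitudes: Mapping[int, float] = field(default_factory=dict)
    active_channels: tuple[int, ...] = ()
    delay_jitter_sd: float = 10.0
    amplitude_jitter_cv: float = 0.05
    rise_time: float = 70.0
    effort_overshoot: float = 0.2

    def __post_init__(self) -> None:
        order = tuple(int(c) for c in self.order)
        object.__setattr__(self, "order", order)
        if not self.active_channels:
            object.__setattr__(self, "active_channels", tuple(sorted(order)))
        if set(self.active_channels) != set(order):
            raise ValueError("active_channels must equal the channels in order")
        if any(c < 1 or c > N_CHANNELS for c in order):
            raise ValueError("channels must lie in 1..6")
        if order:
            if set(self.mean_delays) != set(order):
                raise ValueError("mean_delays must cover exactly the active channels")
            if set(self.plateau_amplitudes) != set(order):
                raise ValueError("plateau_amplitudes must cover exactly the active channels")
            if any(d < 0 for d in self.mean_delays.values()):
                raise ValueError("delays must be non-negative")
            by_delay = tuple(sorted(order, key=lambda c: self.mean_delays[c]))
            if by_delay != order:
                raise ValueError("mean_delays are inconsistent with order")
        if self.rise_time <= 0:
            raise ValueError("rise_time must be positive (ms)")

    @property
    def is_rest(self) -> bool:
        return not self.order


@dataclass
class EnvelopeRecording:
    """One labeled 6-channel envelope acquisition.

    ``samples`` has shape (n_samples, 6) in volts; ``truth`` (present for
    synthetic recordings) holds the ground-truth onset time, realized
    activation order and active channel set.
    """

    samples: np.ndarray
    label: str
    fs: float = 1000.0
    subject_id: str = "S0"
    rest_duration_ms: float = 500.0
    truth: dict | None = None
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise ValueError("samples must have shape (n_samples, 6)")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs * 1000.0


def _ar1(rng: np.random.Generator, shape: tuple[int, int], tau_ms: float,
         dt_ms: float) -> np.ndarray:
    """Unit-variance stationary AR(1) noise along axis 0."""
    a = float(np.exp(-dt_ms / tau_ms))
    innov = rng.standard_normal(shape) * np.sqrt(1.0 - a * a)
    x0 = rng.standard_normal(shape[1])
    out, _ = lfilter([1.0], [1.0, -a], innov, axis=0, zi=(a * x0)[None, :])
    return out


def generate_recording(profile: GestureProfile, noise: NoiseModel, seed,
                       *, fs: float = 1000.0, duration_s: float = 4.0,
                       rest_duration_ms: float = 500.0,
                       onset_jitter_ms: float = 200.0,
                       subject_id: str = "S0") -> EnvelopeRecording:
    """Generate one synthetic envelope acquisition with ground truth.

    Movement onset is drawn uniformly in ``[rest_duration_ms,
    rest_duration_ms + onset_jitter_ms]`` so the start of activation varies
    across repetitions.  The recorded truth onset is the first active
    channel's realized activation start.

    Raises
    ------
    ValueError
        If the latest activation (rest + onset jitter + max delay +
        rise time) would not fit inside the recording, or if a plateau
        amplitude is not at least 20 rest standard deviations above the
        rest mean (the low threshold would be unreachable).
    """
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration_s))
    dt_ms = 1000.0 / fs

    samples = noise.rest_mean + noise.rest_sd * _ar1(
        rng, (n, N_CHANNELS), noise.correlation_time, dt_ms)

    truth: dict = {"onset_ms": None, "movement_onset_ms": None,
                   "order": (), "active_channels": (), "starts_ms": {}}

    if not profile.is_rest:
        total_ms = n * dt_ms
        latest = (rest_duration_ms + onset_jitter_ms
                  + max(profile.mean_delays.values()) + profile.rise_time)
        if latest >= total_ms:
            raise ValueError(
                "activation does not fit: rest + onset jitter + max delay "
                f"+ rise time = {latest:.0f} ms >= {total_ms:.0f} ms")
        floor = noise.rest_mean + 20.0 * noise.rest_sd
        low = [c for c, a in profile.plateau_amplitudes.items() if a < floor]
        if low:
            raise ValueError(f"plateau amplitude of channels {low} below "
                             f"rest_mean + 20*rest_sd = {floor:.4f} V")

        movement_onset = rest_duration_ms + rng.uniform(0.0, onset_jitter_ms)
        t = np.arange(n) * dt_ms
        k = profile.rise_time / _LN81
        starts: dict[int, float] = {}
        for c in profile.order:
            delay = max(0.0, profile.mean_delays[c]
                        + rng.normal(0.0, profile.delay_jitter_sd))
            start = movement_onset + delay
            starts[c] = start
            # logistic rise, shifted/rescaled to be exactly 0 at `start`
            shape = expit((t - (start + k * _LN99)) / k)
            shape = np.clip((shape - 0.01) / 0.99, 0.0, None)
            scale = profile.plateau_amplitudes[c] * max(
                0.1, 1.0 + rng.normal(0.0, profile.amplitude_jitter_cv))
            # slow multiplicative jitter + mid-contraction overshoot bump
            slow = 1.0 + profile.amplitude_jitter_cv * _ar1(
                rng, (n, 1), 300.0, dt_ms)[:, 0]
            slow = np.clip(slow, 0.2, None)
            frac = np.clip((t - start) / max(total_ms - start, 1.0), 0.0, 1.0)
            bump = 1.0 + profile.effort_overshoot * np.sin(np.pi * frac)
            samples[:, c - 1] += scale * shape * slow * bump

        realized = tuple(sorted(starts, key=starts.get))
        truth = {"onset_ms": float(min(starts.values())),
                 "movement_onset_ms": float(movement_onset),
                 "order": realized,
                 "active_channels": tuple(sorted(starts)),
                 "starts_ms": {c: float(s) for c, s in starts.items()}}

    np.clip(samples, 0.0, FULL_SCALE_V, out=samples)
    return EnvelopeRecording(samples=samples, label=profile.name, fs=fs,
                             subject_id=subject_id,
                             rest_duration_ms=rest_duration_ms, truth=truth)


def generate_dataset(profiles: Sequence[GestureProfile], noise: NoiseModel,
                     reps_per_gesture: int, seed, *, subject_id: str = "S0",
                     **kwargs) -> list[EnvelopeRecording]:
    """Generate ``reps_per_gesture`` recordings for each profile.

    Per-recording seeds are spawned from the master seed, so the dataset is
    bitwise reproducible and recordings are mutually independent.
    """
    if reps_per_gesture < 1:
        raise ValueError("reps_per_gesture must be >= 1")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gesture names in profiles")
    children = np.random.SeedSequence(seed).spawn(len(profiles) * reps_per_gesture)
    out: list[EnvelopeRecording] = []
    i = 0
    for profile in profiles:
        for rep in range(reps_per_gesture):
            rec = generate_recording(profile, noise, children[i],
                                     subject_id=subject_id, **kwargs)
            rec.recording_id = f"{subject_id}_{profile.name}_{rep:03d}"
            out.append(rec)
            i += 1
    return out


def default_noise() -> NoiseModel:
    return NoiseModel()


def default_profiles() -> list[GestureProfile]:
    """The four default gesture profiles.

    Activation orders are distinct between gestures; the first three
    activations of each gesture fall within ~200 ms of movement onset so
    the 300 ms transient window captures them.  "Point" recruits only two
    channels, "Spherical" five (the last two well outside the transient
    window), mirroring the qualitative activation-entity spread of real
    grasps.  Amplitudes are chosen for class separability; real per-task
    envelope amplitudes are subject-specific.
    """
    return [
        GestureProfile(
            "Spherical", order=(4, 1, 6, 2, 3),
            mean_delays={4: 30, 1: 105, 6: 185, 2: 380, 3: 450},
            plateau_amplitudes={4: 1.8, 1: 1.4, 6: 1.1, 2: 0.9, 3: 0.8}),
        GestureProfile(
            "Tip", order=(2, 5, 3),
            mean_delays={2: 35, 5: 110, 3: 190},
            plateau_amplitudes={2: 1.2, 5: 1.6, 3: 1.0}),
        GestureProfile(
            "Platform", order=(6, 3, 1, 5),
            mean_delays={6: 30, 3: 100, 1: 180, 5: 420},
            plateau_amplitudes={6: 1.5, 3: 1.3, 1: 1.7, 5: 0.9}),
        GestureProfile(
            "Point", order=(3, 1),
            mean_delays={3: 40, 1: 130},
            plateau_amplitudes={3: 1.4, 1: 1.1}),
    ]


def rest_profile() -> GestureProfile:
    return GestureProfile("Rest")
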