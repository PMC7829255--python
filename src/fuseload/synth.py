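"""Workload-modulated synthetic session simulator.

Generates multi-stream recordings with the statistical structure the rest
of the pipeline assumes: a participant solves a sequence of puzzles of
nominal difficulty 1-5 while four physiological streams are recorded at
their native rates and a marker stream logs every action.

Signal models (standard textbook forms, not biophysical forward models):

* **GSR** - tonic skin-conductance level with a slow drift plus
  Poisson-timed phasic skin-conductance responses (SCRs) with exponential
  rise/decay; both SCR rate and tonic level rise with difficulty.
* **PPG** - periodic blood-volume pulse at an instantaneous heart rate
  that rises with difficulty; pulse amplitude shrinks slightly with
  difficulty (sympathetic vasoconstriction); additive noise.
* **fNIRS** - difficulty boxcar convolved with the canonical double-gamma
  haemodynamic response function plus 1/f (pink) noise on 27 channels of
  oxyhaemoglobin; deoxyhaemoglobin is anti-correlated (-0.5 x O2Hb).
* **ET** - fixation/saccade alternation of binocular gaze coordinates,
  with fixation rate increasing and fixation scatter tightening under
  load.

Every simulated quantity of interest (SCR times, instantaneous heart
rate, fixation log, true ratings) is exposed as ground truth so tests can
use the generator's own event log as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .streams import (
    CHANNELS,
    DEFAULT_RATES,
    MODALITIES,
    MarkerEvent,
    SessionRecording,
    StreamSeries,
)

__all__ = [
    "ParticipantProfile",
    "SimConfig",
    "GroundTruth",
    "PuzzleInterval",
    "canonical_hrf",
    "simulate_modality",
    "generate_markers",
    "simulate_session",
    "default_action_rate",
]


@dataclass
class ParticipantProfile:
    """Participant-level generative parameters.

    Units: heart rate in beats/min, conductance in microsiemens, HRF gain
    in arbitrary concentration units per difficulty unit, ratings on the
    7-point scale.
    """

    baseline_hr: float = 68.0            # beats/min at rest
    hr_per_difficulty: float = 2.5       # beats/min per difficulty unit
    tonic_scl: float = 8.0               # uS tonic level at rest
    tonic_per_difficulty: float = 0.15   # uS per difficulty unit
    scr_rate_base: float = 4.0           # SCR events/min at rest
    scr_rate_per_difficulty: float = 3.0  # events/min per difficulty unit
    scr_amplitude: float = 0.4           # uS mean SCR amplitude
    hrf_gain: float = 0.12               # a.u. per difficulty unit
    ppg_amp_per_difficulty: float = 0.04  # fractional amplitude loss per unit
    fixation_rate_base: float = 2.0      # fixations/s at rest
    fixation_rate_per_difficulty: float = 0.4
    gaze_scatter_base: float = 0.06      # normalised screen units
    gaze_scatter_per_difficulty: float = 0.3  # fractional scatter tightening
    rating_bias: float = 0.0             # 7-point scale units
    rating_noise_sd: float = 0.5         # 7-point scale units


def default_action_rate(difficulty: float) -> float:
    """Puzzle-GUI action rate in actions/min as a function of difficulty.

    Chosen so a five-puzzle default session yields on the order of one to
    three hundred markers.
    """
    return 3.0 + 0.8 * float(difficulty)


@dataclass
class PuzzleInterval:
    start: float
    end: float
    puzzle_id: int
    difficulty: float


@dataclass
class SimConfig:
    """Full specification of one simulated session."""

    n_puzzles: int = 5
    puzzle_difficulties: tuple = (1, 2, 3, 4, 5)
    puzzle_duration: float = 600.0       # seconds per puzzle
    rest_duration: float = 30.0          # seconds between puzzles
    profile: ParticipantProfile = field(default_factory=ParticipantProfile)
    stream_rates: dict = field(default_factory=lambda: dict(DEFAULT_RATES))
    jitter_sd: float = 0.0               # seconds, per-sample clock jitter
    clock_drift: dict = field(default_factory=dict)  # stream -> seconds over session
    missing_gaps: list = field(default_factory=list)  # (start, duration) seconds
    participant_id: str = "sim01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_puzzles < 0:
            raise ValueError("n_puzzles must be >= 0")
        if len(self.puzzle_difficulties) != self.n_puzzles:
            raise ValueError("puzzle_difficulties length must equal n_puzzles")
        if any(r <= 0 for r in self.stream_rates.values()):
            raise ValueError("stream rates must be strictly positive")
        if self.profile.rating_noise_sd < 0:
            raise ValueError("rating noise SD must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    def schedule(self) -> list[PuzzleInterval]:
        out, t = [], self.rest_duration
        for pid, d in enumerate(self.puzzle_difficulties):
            out.append(PuzzleInterval(t, t + self.puzzle_duration, pid, float(d)))
            t += self.puzzle_duration + self.rest_duration
        return out

    @property
    def duration(self) -> float:
        n = self.n_puzzles
        return n * self.puzzle_duration + (n + 1) * self.rest_duration


@dataclass
class GroundTruth:
    """What the simulator actually did: the oracle for downstream stages."""

    difficulties: dict[int, float]        # puzzle id -> true difficulty
    ratings: dict[int, int]               # puzzle id -> simulated 7-point rating
    marker_puzzles: list[int]             # per-marker puzzle assignment
    schedule: list[PuzzleInterval]
    events: dict = field(default_factory=dict)  # per-modality event logs


# ---------------------------------------------------------------------------
# haemodynamic response


def canonical_hrf(
    time_points: np.ndarray,
    gain: float = 1.0,
    peak_delay: float = 6.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Double-gamma haemodynamic response, peak-normalised and scaled by gain.

    The response is ``gain * (g1(t) - undershoot_ratio * g2(t))`` with two
    unit-scale gamma densities peaking at ``peak_delay`` and
    ``peak_delay + 10`` seconds, each normalised to unit peak.  Starts at
    exactly zero, rises to a single positive peak (5-8 s post onset at the
    default delay) and relaxes through a shallow undershoot.  Linear in
    ``gain`` by construction.
    """
    t = np.asarray(time_points, dtype=np.float64)
    if t.size and np.any(t < 0):
        raise ValueError("time points must be non-negative")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly ascending")

    def gpeak(tt: np.ndarray, shape: float) -> np.ndarray:
        # unit-scale gamma kernel normalised to unit peak at its mode
        mode = shape - 1.0
        log_peak = mode * np.log(mode) - mode
        with np.errstate(divide="ignore"):
            logv = np.where(tt > 0, mode * np.log(np.maximum(tt, 1e-300)) - tt, -np.inf)
        return np.exp(logv - log_peak)

    a1 = peak_delay + 1.0
    a2 = peak_delay + 11.0
    return gain * (gpeak(t, a1) - undershoot_ratio * gpeak(t, a2))


# ---------------------------------------------------------------------------
# difficulty profiles


def _as_profile(difficulty_profile):
    """Accept a callable t -> difficulty or a list of (start, end, d)."""
    if callable(difficulty_profile):
        return difficulty_profile
    segments = [(float(a), float(b), float(d)) for a, b, d in difficulty_profile]

    def prof(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        out = np.zeros_like(t)
        for a, b, d in segments:
            out[(t >= a) & (t < b)] = d
        return out

    return prof


def _pink_noise(n: int, rng: np.random.Generator, sd: float) -> np.ndarray:
    """1/f-shaped Gaussian noise with standard deviation ``sd``."""
    if n == 0:
        return np.zeros(0)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


# ---------------------------------------------------------------------------
# per-modality simulators


def _simulate_gsr(t, d, profile, rng):
    rate_hz = len(t) / (t[-1] - t[0] + 1e-12) if len(t) > 1 else 1.0
    tonic = (
        profile.tonic_scl
        + profile.tonic_per_difficulty * d
        + 0.2 * np.sin(2 * np.pi * t / 300.0 + rng.uniform(0, 2 * np.pi))
    )
    # inhomogeneous Poisson SCR train by thinning
    lam = (profile.scr_rate_base + profile.scr_rate_per_difficulty * d) / 60.0
    lam_max = float(lam.max()) if len(lam) else 0.0
    signal = tonic.copy()
    scr_times: list[float] = []
    if lam_max > 0 and len(t) > 1:
        duration = t[-1] - t[0]
        n_cand = rng.poisson(lam_max * duration)
        cand = np.sort(rng.uniform(t[0], t[-1], n_cand))
        keep = rng.uniform(0, lam_max, n_cand) <= np.interp(cand, t, lam)
        scr_times = cand[keep].tolist()
        # SCR kernel: exponential rise (0.75 s) and decay (3 s)
        tk = np.arange(0, 15.0, 1.0 / rate_hz)
        kern = np.exp(-tk / 3.0) - np.exp(-tk / 0.75)
        kern /= kern.max()
        for t0 in scr_times:
            i0 = int(np.searchsorted(t, t0))
            amp = profile.scr_amplitude * rng.lognormal(0.0, 0.3)
            seg = min(len(kern), len(t) - i0)
            signal[i0 : i0 + seg] += amp * kern[:seg]
    signal += rng.normal(0, 0.02, len(t))
    return signal[:, None], {"scr_times": np.array(scr_times)}


def _simulate_ppg(t, d, profile, rng):
    n = len(t)
    # smooth heart-rate variability on top of the difficulty-driven mean
    hrv = _pink_noise(n, rng, 1.5)
    hr = profile.baseline_hr + profile.hr_per_difficulty * d + hrv
    dt = np.diff(t, prepend=t[0] if n else 0.0)
    phase = np.cumsum(hr / 60.0 * dt)
    amp = 1.0 - profile.ppg_amp_per_difficulty * d
    pulse = 0.6 * np.sin(2 * np.pi * phase) + 0.25 * np.sin(4 * np.pi * phase + 1.0)
    signal = amp * pulse + rng.normal(0, 0.05, n)
    return signal[:, None], {"instantaneous_hr": hr}


def _simulate_fnirs(t, d, profile, rng):
    n = len(t)
    rate_hz = (n - 1) / (t[-1] - t[0]) if n > 1 else 1.0
    neural = d  # boxcar at true difficulty
    tk = np.arange(0, 30.0, 1.0 / rate_hz)
    kern = canonical_hrf(tk)
    ksum = kern.sum()
    kern = kern / ksum if ksum != 0 else kern
    resp = fftconvolve(neural, kern)[:n] if n else np.zeros(0)
    # per-channel sensitivity: not every optode pair sits over responsive cortex
    sens = rng.uniform(0.3, 1.0, 27)
    o2hb = np.empty((n, 27))
    hhb = np.empty((n, 27))
    # low per-trial SNR: the evoked response is small against systemic
    # physiology (cardiac, respiratory, Mayer waves) that is SHARED across
    # optodes, so spatial averaging cannot cancel it, plus per-channel
    # instrumental 1/f noise
    systemic = _pink_noise(n, rng, 0.25)
    for c in range(27):
        o2hb[:, c] = (
            profile.hrf_gain * sens[c] * resp
            + systemic * rng.uniform(0.7, 1.3)
            + _pink_noise(n, rng, 0.15)
        )
        hhb[:, c] = -0.5 * o2hb[:, c] + _pink_noise(n, rng, 0.1)
    samples = np.concatenate([o2hb, hhb], axis=1)
    return samples, {"channel_sensitivity": sens, "response": resp}


def _simulate_et(t, d, profile, rng):
    n = len(t)
    gaze = np.empty((n, 4))
    fix_starts: list[float] = []
    if n == 0:
        return gaze, {"fixation_starts": np.array(fix_starts)}
    t0, t_end = t[0], t[-1]
    now = t0
    centre = rng.uniform(0.2, 0.8, 2)
    d_of = lambda x: float(np.interp(x, t, d)) if n > 1 else 0.0  # noqa: E731
    i = 0
    while now < t_end + 1e-9:
        diff = d_of(now)
        rate = profile.fixation_rate_base + profile.fixation_rate_per_difficulty * diff
        dur = rng.exponential(1.0 / rate)
        fix_starts.append(now)
        j = int(np.searchsorted(t, now + dur))
        scatter = profile.gaze_scatter_base / (
            1.0 + profile.gaze_scatter_per_difficulty * diff
        )
        m = max(j - i, 0)
        if m:
            pts = centre + rng.normal(0, scatter, (m, 2))
            gaze[i:j, 0:2] = pts + np.array([-0.015, 0.0])  # left eye
            gaze[i:j, 2:4] = pts + np.array([+0.015, 0.0])  # right eye
        i = j
        centre = np.clip(centre + rng.normal(0, 0.15, 2), 0.05, 0.95)
        now += dur
    if i < n:
        gaze[i:] = gaze[i - 1] if i else 0.5
    gaze += rng.normal(0, 0.003, gaze.shape)
    return gaze, {"fixation_starts": np.array(fix_starts)}


_SIMULATORS = {
    "GSR": _simulate_gsr,
    "PPG": _simulate_ppg,
    "fNIRS": _simulate_fnirs,
    "ET": _simulate_et,
}

_CHANNEL_LABELS = {
    "GSR": ["conductance"],
    "PPG": ["bvp"],
    "ET": ["left_x", "left_y", "right_x", "right_y"],
    "fNIRS": [f"CH{c + 1}_O2Hb" for c in range(27)] + [f"CH{c + 1}_HHb" for c in range(27)],
}


def simulate_modality(
    modality: str,
    duration: float,
    difficulty_profile,
    profile: ParticipantProfile | None = None,
    rate: float | None = None,
    seed: int | np.random.Generator = 0,
    return_events: bool = False,
):
    """Simulate one modality stream over ``duration`` seconds.

    ``difficulty_profile`` is either a callable ``t -> difficulty`` or a
    list of ``(start, end, difficulty)`` segments (difficulty 0 elsewhere).
    Returns a :class:`StreamSeries`; with ``return_events=True`` also the
    generator's event log (SCR times, instantaneous heart rate, ...).
    """
    if modality not in _SIMULATORS:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    profile = profile or ParticipantProfile()
    rate = float(rate if rate is not None else DEFAULT_RATES[modality])
    if rate <= 0:
        raise ValueError("rate must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n, dtype=np.float64) / rate
    d = _as_profile(difficulty_profile)(t) if n else np.zeros(0)
    samples, events = _SIMULATORS[modality](t, d, profile, rng)
    series = StreamSeries(
        name=modality,
        nominal_rate=rate,
        timestamps=t,
        samples=samples.astype(np.float64),
        channel_labels=list(_CHANNEL_LABELS[modality]),
    )
    assert series.n_channels == CHANNELS[modality]
    return (series, events) if return_events else series


# ---------------------------------------------------------------------------
# markers


_ACTION_TYPES = ("select_hint", "unselect_hint", "select_answer", "unselect_answer")


def generate_markers(
    puzzle_schedule: list[PuzzleInterval],
    action_rate_model=default_action_rate,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim01",
):
    """Poisson-timed GUI action markers within each puzzle interval.

    Each marker carries the participant id, timestamp, action type, action
    id and a status flag; the action id encodes the puzzle
    (``"p<puzzle>:<n>"``).  Returns ``(markers, puzzle_assignment)`` with
    markers in ascending time order.
    """
    sched = sorted(puzzle_schedule, key=lambda p: p.start)
    for a, b in zip(sched, sched[1:]):
        if b.start < a.end:
            raise ValueError("puzzle intervals must not overlap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    markers: list[MarkerEvent] = []
    assignment: list[int] = []
    for itv in sched:
        dur_min = (itv.end - itv.start) / 60.0
        n = rng.poisson(action_rate_model(itv.difficulty) * dur_min)
        times = np.sort(rng.uniform(itv.start, itv.end, n))
        for j, tm in enumerate(times):
            action = _ACTION_TYPES[rng.integers(len(_ACTION_TYPES))]
            status = ("correct", "incorrect", "checked")[rng.integers(3)]
            markers.append(
                MarkerEvent(
                    timestamp=float(tm),
                    participant_id=participant_id,
                    action_type=action,
                    action_id=f"p{itv.puzzle_id}:{j}",
                    status=status,
                )
            )
            assignment.append(itv.puzzle_id)
    return markers, assignment


def puzzle_of_marker(marker: MarkerEvent) -> int:
    """Recover the puzzle id encoded in a marker's action id."""
    head = marker.action_id.split(":", 1)[0]
    if not head.startswith("p"):
        raise ValueError(f"action_id {marker.action_id!r} carries no puzzle id")
    return int(head[1:])


# ---------------------------------------------------------------------------
# session assembly


def _apply_clock_effects(series: StreamSeries, drift: float, jitter_sd: float,
                         gaps: list, rng: np.random.Generator) -> StreamSeries:
    t = series.timestamps.copy()
    samples = series.samples
    if drift and len(t) > 1:
        span = t[-1] - t[0]
        t = t[0] + (t - t[0]) * (1.0 + drift / span)
    if jitter_sd > 0 and len(t) > 1:
        t = t + rng.normal(0, jitter_sd, len(t))
        # clocks never run backwards: enforce strict ascent
        t = np.maximum.accumulate(t + np.arange(len(t)) * 1e-9)
        t += np.arange(len(t)) * 1e-12
    keep = np.ones(len(t), dtype=bool)
    for start, dur in gaps:
        keep &= ~((t >= start) & (t < start + dur))
    return replace(series, timestamps=t[keep], samples=samples[keep])


def simulate_session(config: SimConfig) -> tuple[SessionRecording, GroundTruth]:
    """Simulate one full session: four signal streams, markers, ground truth.

    Deterministic: identical config (including seed) gives bit-identical
    output.  Jitter, per-stream clock drift and missing-data gaps are
    applied after clean signal generation, so ground truth refers to the
    undistorted clock.
    """
    rng = np.random.default_rng(config.seed)
    sched = config.schedule()
    segs = [(p.start, p.end, p.difficulty) for p in sched]
    streams: dict[str, StreamSeries] = {}
    events: dict[str, dict] = {}
    for modality in MODALITIES:
        child = np.random.default_rng(rng.integers(2**31))
        series, ev = simulate_modality(
            modality,
            config.duration,
            segs,
            profile=config.profile,
            rate=config.stream_rates.get(modality, DEFAULT_RATES[modality]),
            seed=child,
            return_events=True,
        )
        drift = float(config.clock_drift.get(modality, 0.0))
        series = _apply_clock_effects(
            series, drift, config.jitter_sd, config.missing_gaps,
            np.random.default_rng(rng.integers(2**31)),
        )
        streams[modality] = series
        events[modality] = ev

    markers, assignment = generate_markers(
        sched, seed=np.random.default_rng(rng.integers(2**31)),
        participant_id=config.participant_id,
    )

    # simulated 7-point ratings: linear map of difficulty 1..5 onto 1..7
    # plus participant bias and noise, rounded and clipped
    ratings: dict[int, int] = {}
    for p in sched:
        raw = (
            1.0 + (p.difficulty - 1.0) * 1.5
            + config.profile.rating_bias
            + rng.normal(0, config.profile.rating_noise_sd)
        )
        ratings[p.puzzle_id] = int(np.clip(round(raw), 1, 7))

    recording = SessionRecording(
        streams=streams,
        markers=markers,
        metadata={"participant_id": config.participant_id, "simulated": 1},
    )
    truth = GroundTruth(
        difficulties={p.puzzle_id: p.difficulty for p in sched},
        ratings=ratings,
        marker_puzzles=assignment,
        schedule=sched,
        events=events,
    )
    return recording, truth
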