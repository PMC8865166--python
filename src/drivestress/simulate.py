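"""Synthetic driving-session generator.

Emulates the kind of data a fixed-base driving-simulator study produces:
per-participant ECG (500 Hz) and speed (10 Hz) traces over two trips on the
same route, with cue/event markers for three hazard-predictability
conditions (U: unpredictable, P: predictable, PF: predictable and familiar),
plus post-hoc perceived-stress ratings on a 1-5 Likert scale.

The generator injects a known biphasic evoked cardiac response (an initial
deceleration, ECR1, followed by an acceleration, ECR2) time-locked to the
markers, so every downstream stage (R-peak detection, epoching, ANOVA,
polynomial contrasts) can be validated against ground truth.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("U", "P", "PF")
WINDOWS = ("postcue", "postevent")
#: post-baseline analysis-window end (s): 10 grid levels for U/P, 16 for PF
POSTWINDOW_END = {"U": 4.5, "P": 4.5, "PF": 7.5}


def _raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Compactly supported unit lobe on [center-width, center+width]."""
    u = (t - center) / width
    out = np.zeros_like(t, dtype=float)
    inside = np.abs(u) < 1.0
    out[inside] = np.cos(0.5 * np.pi * u[inside]) ** 2
    return out


@dataclass(frozen=True)
class EcrTemplate:
    """Biphasic evoked-cardiac-response template in bpm vs. seconds.

    Two compact raised-cosine lobes: a deceleration (ECR1, amplitude <= 0)
    peaking at ``decel_peak_time`` and an acceleration (ECR2, amplitude >= 0)
    peaking at ``accel_peak_time``. The template is continuous, identically
    zero for t <= 0 and vanishes beyond ``accel_peak_time + lobe_width``.
    """

    decel_amplitude: float = -5.0
    decel_peak_time: float = 1.0
    accel_amplitude: float = 6.0
    accel_peak_time: float = 3.0
    lobe_width: float = 1.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(dataclasses.astuple(self))):
            raise ValueError("ECR template parameters must be finite")
        if self.decel_amplitude > 0:
            raise ValueError("decel_amplitude must be <= 0 (ECR1 is a deceleration)")
        if self.accel_amplitude < 0:
            raise ValueError("accel_amplitude must be >= 0 (ECR2 is an acceleration)")
        if self.lobe_width <= 0:
            raise ValueError("lobe_width must be positive")
        if not self.decel_peak_time < self.accel_peak_time:
            raise ValueError("decel_peak_time must precede accel_peak_time")
        if self.decel_peak_time < self.lobe_width:
            raise ValueError(
                "decel lobe would extend before t=0 "
                "(need decel_peak_time >= lobe_width)"
            )

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = self.decel_amplitude * _raised_cosine(t, self.decel_peak_time, self.lobe_width)
        out += self.accel_amplitude * _raised_cosine(t, self.accel_peak_time, self.lobe_width)
        return out

    def scaled(self, factor: float) -> "EcrTemplate":
        """Template with both lobe amplitudes multiplied by ``factor`` >= 0."""
        return replace(
            self,
            decel_amplitude=self.decel_amplitude * factor,
            accel_amplitude=self.accel_amplitude * factor,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ConditionTiming:
    """Printed cue/event durations (s) plus cue-onset -> event-onset gap."""

    cue_duration_s: float
    event_duration_s: float
    cue_event_gap_s: float

    def __post_init__(self) -> None:
        if min(self.cue_duration_s, self.event_duration_s, self.cue_event_gap_s) <= 0:
            raise ValueError("all durations must be positive")


@dataclass(frozen=True)
class SpeedDecelProfile:
    """Event-locked speed deceleration: ramp down, hold, linear recovery."""

    onset_lag_s: float = 0.5
    magnitude_kmh: float = 30.0
    ramp_s: float = 2.0
    hold_s: float = 2.0
    recovery_s: float = 6.0

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float) - self.onset_lag_s
        out = np.zeros_like(t, dtype=float)
        ramp = (t >= 0) & (t < self.ramp_s)
        out[ramp] = -self.magnitude_kmh * t[ramp] / self.ramp_s
        hold = (t >= self.ramp_s) & (t < self.ramp_s + self.hold_s)
        out[hold] = -self.magnitude_kmh
        t2 = t - self.ramp_s - self.hold_s
        rec = (t2 >= 0) & (t2 < self.recovery_s)
        out[rec] = -self.magnitude_kmh * (1.0 - t2[rec] / self.recovery_s)
        return out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_condition_timings() -> dict[str, ConditionTiming]:
    # Mean stimulus durations of the emulated protocol; U's "cue" is a
    # positional marker only (the cue is invisible in that condition).
    return {
        "U": ConditionTiming(cue_duration_s=2.0, event_duration_s=1.83, cue_event_gap_s=5.0),
        "P": ConditionTiming(cue_duration_s=4.41, event_duration_s=3.01, cue_event_gap_s=5.0),
        "PF": ConditionTiming(cue_duration_s=7.24, event_duration_s=3.73, cue_event_gap_s=8.0),
    }


def default_ecr_map() -> dict[tuple[str, str], EcrTemplate | None]:
    """Injected responses for Trip 2: anticipation after visible cues,
    acceleration after every hazardous event."""
    post_event = EcrTemplate(0.0, 1.0, 8.0, 3.0, 1.0)
    return {
        ("U", "postcue"): None,  # invisible cue: nothing to anticipate
        ("U", "postevent"): post_event,
        ("P", "postcue"): EcrTemplate(-5.0, 1.0, 6.0, 3.0, 1.0),
        ("P", "postevent"): post_event,
        ("PF", "postcue"): EcrTemplate(-5.0, 2.0, 6.0, 4.5, 1.5),
        ("PF", "postevent"): post_event,
    }


DEFAULT_RATING_DISTRIBUTIONS: dict[str, dict[int, float]] = {
    "high": {3: 1 / 3, 4: 1 / 3, 5: 1 / 3},
    "low": {1: 0.5, 2: 0.5},
}


@dataclass(frozen=True)
class SessionConfig:
    """All knobs of one participant's simulated session."""

    baseline_hr: float = 70.0  # bpm
    # noise defaults calibrated so a simulated n=27 cohort's postcue
    # quadratic-trend t matches the magnitude reported for cued hazards
    # in the emulated study (|t| ~ 4.8)
    hrv_sd: float = 1.8  # beat-to-beat noise on the rate scale, bpm
    rsa_amplitude: float = 1.2  # respiratory sinus arrhythmia, bpm
    rsa_freq: float = 0.25  # Hz (~15 breaths/min)
    ecg_fs: float = 500.0  # Hz
    speed_fs: float = 10.0  # Hz
    base_speed: float = 90.0  # km/h
    speed_noise_sd: float = 0.5  # km/h
    ecg_noise_sd: float = 0.03  # in units of the R amplitude (1.0)
    trip_duration_s: float = 120.0
    condition_timings: Mapping[str, ConditionTiming] = field(
        default_factory=default_condition_timings
    )
    cue_onsets: Mapping[str, float] = field(
        default_factory=lambda: {"U": 15.0, "P": 45.0, "PF": 80.0}
    )
    ecr_by_condition: Mapping[tuple[str, str], EcrTemplate | None] = field(
        default_factory=default_ecr_map
    )
    pf_control_attenuation: float = 0.6  # Trip-1 first exposure of PF
    stress_gain: Mapping[str, float] = field(
        default_factory=lambda: {"high": 1.5, "low": 0.5}
    )  # multiplies post-event response amplitudes per stress group
    speed_decel_profile: SpeedDecelProfile = field(default_factory=SpeedDecelProfile)
    stress_group: str = "low"
    rating_distributions: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: DEFAULT_RATING_DISTRIBUTIONS
    )
    render_ecg: bool = True

    def __post_init__(self) -> None:
        if self.ecg_fs <= 80.0:
            raise ValueError("ecg_fs must exceed 80 Hz so a 2-40 Hz band is representable")
        if self.trip_duration_s <= 0:
            raise ValueError("trip_duration_s must be positive")
        if self.stress_group not in ("high", "low"):
            raise ValueError("stress_group must be 'high' or 'low'")

    def event_onset(self, condition: str) -> float:
        return self.cue_onsets[condition] + self.condition_timings[condition].cue_event_gap_s


@dataclass
class TripData:
    """One trip's raw traces: ECG (may be absent) and speed."""

    ecg_time: np.ndarray | None
    ecg: np.ndarray | None
    speed_time: np.ndarray
    speed: np.ndarray


@dataclass
class DriverSession:
    """One participant's signals, markers and ratings for both trips."""

    participant_id: str
    trips: dict[int, TripData]
    markers: pd.DataFrame  # trip, condition, marker_type, onset_s, duration_s
    ratings: dict[str, int]  # condition -> 1..5 (U and P only)


@dataclass
class GroundTruthManifest:
    """What was actually injected, for oracle-style validation."""

    participant_id: str
    stress_group: str
    exclusion_flag: str  # {none, motion_sickness, bad_ecg}
    baseline_hr: float
    true_beats: dict[int, np.ndarray]  # trip -> beat times, s
    injected: dict[str, dict]  # "trip|condition|window" -> template params
    speed_profile: dict

    def to_json(self) -> str:
        payload = {
            "participant_id": self.participant_id,
            "stress_group": self.stress_group,
            "exclusion_flag": self.exclusion_flag,
            "baseline_hr": self.baseline_hr,
            "true_beats": {str(k): v.tolist() for k, v in self.true_beats.items()},
            "injected": self.injected,
            "speed_profile": self.speed_profile,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        d = json.loads(text)
        return cls(
            participant_id=d["participant_id"],
            stress_group=d["stress_group"],
            exclusion_flag=d["exclusion_flag"],
            baseline_hr=d["baseline_hr"],
            true_beats={int(k): np.asarray(v) for k, v in d["true_beats"].items()},
            injected=d["injected"],
            speed_profile=d["speed_profile"],
        )


# ---------------------------------------------------------------------------
# core signal generators
# ---------------------------------------------------------------------------

def sample_rr_train(
    config: SessionConfig,
    ecr_deltas: Callable[[float], float] | None = None,
    duration: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Generate R-peak times by inverting the instantaneous rate.

    Starting at t=0, each next interval satisfies ``RRI = 60 / rate(t + RRI)``
    with ``rate(t) = baseline + ecr(t) + rsa(t) + noise`` (noise drawn once
    per beat on the bpm scale, SD ``hrv_sd``); the implicit equation is
    solved by a short fixed-point iteration and the result clamped to
    [0.3, 2.0] s. Evaluating the rate at the interval's *closing* time makes
    the scheme self-consistent: the instantaneous HR derived from the beats,
    HR_n = 60 / RRI_n placed at beat n, reproduces ``baseline + ecr + rsa``
    at the beat times exactly (up to noise), with no half-interval lag. It is
    exact in the noise-free constant-rate limit.
    """
    if not 30.0 <= config.baseline_hr <= 200.0:
        raise ValueError(f"baseline_hr {config.baseline_hr} outside [30, 200] bpm")
    duration = config.trip_duration_s if duration is None else float(duration)
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng)

    # breathing is not locked to the route: random RSA phase per trip
    rsa_phase = rng.uniform(0.0, 2 * np.pi) if config.rsa_amplitude else 0.0
    def rate_at(tt: float, noise: float) -> float:
        rate = config.baseline_hr + noise
        if ecr_deltas is not None:
            delta = float(ecr_deltas(tt))
            if not np.isfinite(delta):
                raise ValueError(f"ECR template returned non-finite value at t={tt:.3f}")
            rate += delta
        if config.rsa_amplitude:
            rate += config.rsa_amplitude * np.sin(
                2 * np.pi * config.rsa_freq * tt + rsa_phase
            )
        return rate

    beats = [0.0]
    t = 0.0
    while True:
        noise = rng.normal(0.0, config.hrv_sd) if config.hrv_sd else 0.0
        interval = float(np.clip(60.0 / max(rate_at(t, noise), 1e-6), 0.3, 2.0))
        for _ in range(4):  # fixed point of RRI = 60 / rate(t + RRI)
            interval = float(
                np.clip(60.0 / max(rate_at(t + interval, noise), 1e-6), 0.3, 2.0)
            )
        t += interval
        if t > duration + 1e-9:
            break
        beats.append(t)
    return np.asarray(beats)


#: P-QRS-T morphology: wave -> (offset from R, amplitude, Gaussian width), s
DEFAULT_MORPHOLOGY: dict[str, tuple[float, float, float]] = {
    "P": (-0.20, 0.12, 0.030),
    "Q": (-0.030, -0.08, 0.010),
    "R": (0.0, 1.0, 0.012),
    "S": (0.030, -0.10, 0.010),
    "T": (0.25, 0.25, 0.050),
}


def synthesize_ecg(
    beat_times: Sequence[float],
    ecg_fs: float = 500.0,
    morphology: Mapping[str, tuple[float, float, float]] | None = None,
    noise_sd: float = 0.0,
    duration: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a beat train as a uniform ECG trace (times, amplitudes).

    Each beat is a fixed sum of Gaussian P/Q/R/S/T bumps with the R apex on
    the sample nearest the beat time; the R wave dominates the others by
    at least 3x. Broadband Gaussian noise at ``noise_sd`` is added on top.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and np.any(np.diff(beat_times) < 0.3):
        raise ValueError("beat intervals below 0.3 s would overlap QRS templates")
    morphology = DEFAULT_MORPHOLOGY if morphology is None else morphology
    if duration is None:
        duration = (beat_times[-1] + 0.6) if beat_times.size else 1.0
    n = int(round(duration * ecg_fs)) + 1
    times = np.arange(n) / ecg_fs
    signal = np.zeros(n)

    half = int(round(0.45 * ecg_fs))
    local_t = np.arange(-half, half + 1) / ecg_fs
    template = np.zeros_like(local_t)
    for offset, amp, sigma in morphology.values():
        template += amp * np.exp(-0.5 * ((local_t - offset) / sigma) ** 2)

    for bt in beat_times:
        center = int(round(bt * ecg_fs))
        lo, hi = center - half, center + half + 1
        slo, shi = max(lo, 0), min(hi, n)
        signal[slo:shi] += template[slo - lo : shi - lo]

    if noise_sd:
        rng = np.random.default_rng(rng)
        signal = signal + rng.normal(0.0, noise_sd, size=n)
    return times, signal


# ---------------------------------------------------------------------------
# session and cohort assembly
# ---------------------------------------------------------------------------

def _trip_templates(
    config: SessionConfig, trip: int
) -> dict[tuple[str, str], EcrTemplate]:
    """Templates actually injected in a given trip.

    Trip 2 (experimental) carries the configured map. Trip 1 (control) is
    hazard-free for U and P; the PF cue+event also run in Trip 1 (that first
    exposure is what makes PF "familiar"), by default at attenuated amplitude.
    """
    out: dict[tuple[str, str], EcrTemplate] = {}
    gain = config.stress_gain.get(config.stress_group, 1.0)
    for (cond, window), tpl in config.ecr_by_condition.items():
        if tpl is None:
            continue
        if window == "postevent":
            tpl = tpl.scaled(gain)
        if trip == 2:
            out[(cond, window)] = tpl
        elif cond == "PF":
            out[(cond, window)] = tpl.scaled(config.pf_control_attenuation)
    return out


def _marker_onset(config: SessionConfig, condition: str, marker_type: str) -> float:
    if marker_type == "cue_onset":
        return config.cue_onsets[condition]
    return config.event_onset(condition)


def _corrupt_ecg_with_spurious_beats(
    signal: np.ndarray, beat_times: np.ndarray, ecg_fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Insert R-like spikes mid-interval in ~35% of intervals (bad electrode
    contact caricature) so the artifact-correction stage flags the record."""
    out = signal.copy()
    spike_half = int(round(0.012 * ecg_fs * 3))
    local_t = np.arange(-spike_half, spike_half + 1) / ecg_fs
    spike = 0.9 * np.exp(-0.5 * (local_t / 0.012) ** 2)
    for i in range(len(beat_times) - 1):
        if rng.random() < 0.35:
            mid = 0.5 * (beat_times[i] + beat_times[i + 1])
            c = int(round(mid * ecg_fs))
            lo, hi = c - spike_half, c + spike_half + 1
            if 0 <= lo and hi <= out.size:
                out[lo:hi] += spike
    return out


def generate_session(
    config: SessionConfig,
    seed: int | np.random.Generator | None = 0,
    participant_id: str = "p001",
    exclusion_flag: str = "none",
) -> tuple[DriverSession, GroundTruthManifest]:
    """Simulate one participant: two trips of ECG + speed, markers, ratings.

    Deterministic for a fixed (config, seed): identical inputs give
    byte-identical outputs.
    """
    if exclusion_flag not in ("none", "motion_sickness", "bad_ecg"):
        raise ValueError(f"unknown exclusion_flag {exclusion_flag!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    marker_rows = []
    for trip in (1, 2):
        for cond in CONDITIONS:
            timing = config.condition_timings[cond]
            for mtype, dur in (
                ("cue_onset", timing.cue_duration_s),
                ("event_onset", timing.event_duration_s),
            ):
                onset = _marker_onset(config, cond, mtype)
                if onset > config.trip_duration_s - 8.0:
                    raise ValueError(
                        f"{cond}/{mtype} marker at {onset:.1f}s is closer than 8 s "
                        f"to the {config.trip_duration_s:.1f}s recording end"
                    )
                marker_rows.append((trip, cond, mtype, onset, dur))
    markers = pd.DataFrame(
        marker_rows, columns=["trip", "condition", "marker_type", "onset_s", "duration_s"]
    )

    trips: dict[int, TripData] = {}
    true_beats: dict[int, np.ndarray] = {}
    injected: dict[str, dict] = {}
    for trip in (1, 2):
        templates = _trip_templates(config, trip)
        anchors = [
            (_marker_onset(config, cond, "cue_onset" if win == "postcue" else "event_onset"), tpl)
            for (cond, win), tpl in templates.items()
        ]
        for (cond, win), tpl in templates.items():
            injected[f"{trip}|{cond}|{win}"] = tpl.to_dict()

        def ecr(t: float) -> float:
            return sum(float(tpl(t - onset)) for onset, tpl in anchors)

        beats = sample_rr_train(config, ecr if anchors else None, rng=rng)
        true_beats[trip] = beats

        if config.render_ecg:
            ecg_t, ecg_v = synthesize_ecg(
                beats,
                ecg_fs=config.ecg_fs,
                noise_sd=config.ecg_noise_sd,
                duration=config.trip_duration_s,
                rng=rng,
            )
            if exclusion_flag == "bad_ecg":
                ecg_v = _corrupt_ecg_with_spurious_beats(ecg_v, beats, config.ecg_fs, rng)
        else:
            ecg_t = ecg_v = None

        n_sp = int(round(config.trip_duration_s * config.speed_fs)) + 1
        sp_t = np.arange(n_sp) / config.speed_fs
        sp_v = np.full(n_sp, config.base_speed)
        # speed responses accompany every hazardous event actually present
        for cond in CONDITIONS:
            present = trip == 2 or cond == "PF"
            if present:
                sp_v += config.speed_decel_profile(sp_t - config.event_onset(cond))
        if config.speed_noise_sd:
            sp_v = sp_v + rng.normal(0.0, config.speed_noise_sd, size=n_sp)
        trips[trip] = TripData(ecg_time=ecg_t, ecg=ecg_v, speed_time=sp_t, speed=sp_v)

    ratings: dict[str, int] = {}
    dist = config.rating_distributions[config.stress_group]
    values = sorted(dist)
    probs = np.asarray([dist[v] for v in values], dtype=float)
    probs = probs / probs.sum()
    for cond in ("U", "P"):  # PF has no matched safe condition to rate against
        ratings[cond] = int(rng.choice(values, p=probs))

    session = DriverSession(participant_id, trips, markers, ratings)
    manifest = GroundTruthManifest(
        participant_id=participant_id,
        stress_group=config.stress_group,
        exclusion_flag=exclusion_flag,
        baseline_hr=config.baseline_hr,
        true_beats=true_beats,
        injected=injected,
        speed_profile=config.speed_decel_profile.to_dict(),
    )
    return session, manifest


@dataclass
class Cohort:
    sessions: list[DriverSession]
    manifests: list[GroundTruthManifest]

    def manifest_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pid": [m.participant_id for m in self.manifests],
                "stress_group": [m.stress_group for m in self.manifests],
                "exclusion_flag": [m.exclusion_flag for m in self.manifests],
            }
        )


def generate_cohort(
    n: int,
    base_config: SessionConfig | None = None,
    exclusion_spec: Mapping[str, int] | None = None,
    stress_split: Mapping[str, int] | None = None,
    seed: int = 0,
    config_sampler: Callable[[int, np.random.Generator, SessionConfig], SessionConfig]
    | None = None,
) -> Cohort:
    """Generate ``n`` participants with per-participant jitter and exclusions.

    ``exclusion_spec`` gives counts, e.g. ``{"motion_sickness": 5, "bad_ecg": 2}``;
    flagged participants are chosen at random. ``stress_split`` gives exact
    high/low counts among the NON-excluded participants (the analyzed sample);
    default assigns high to ~41% of them. One global seed fans out to
    per-participant substreams indexed by participant number, so the cohort is
    reproducible participant by participant.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base_config = SessionConfig() if base_config is None else base_config
    exclusion_spec = dict(exclusion_spec or {})
    unknown = set(exclusion_spec) - {"motion_sickness", "bad_ecg"}
    if unknown:
        raise ValueError(f"unknown exclusion reasons: {sorted(unknown)}")
    n_excl = sum(exclusion_spec.values())
    if n_excl > n:
        raise ValueError(f"exclusion counts ({n_excl}) exceed cohort size ({n})")

    cohort_rng = np.random.default_rng([seed, 1 << 20])
    order = cohort_rng.permutation(n)
    flags = ["none"] * n
    pos = 0
    for reason in ("motion_sickness", "bad_ecg"):
        for _ in range(exclusion_spec.get(reason, 0)):
            flags[order[pos]] = reason
            pos += 1

    included = [i for i in range(n) if flags[i] == "none"]
    if stress_split is None:
        n_high = int(round(len(included) * 11 / 27))
        stress_split = {"high": n_high, "low": len(included) - n_high}
    if stress_split["high"] + stress_split["low"] != len(included):
        raise ValueError(
            "stress_split must cover exactly the non-excluded participants "
            f"({len(included)}), got {dict(stress_split)}"
        )
    labels_inc = ["high"] * stress_split["high"] + ["low"] * stress_split["low"]
    cohort_rng.shuffle(labels_inc)
    labels = ["low"] * n
    for i, lab in zip(included, labels_inc):
        labels[i] = lab
    for i in range(n):
        if flags[i] != "none":
            labels[i] = str(cohort_rng.choice(["high", "low"]))

    sessions, manifests = [], []
    for i in range(n):
        prng = np.random.default_rng([seed, i])
        cfg = replace(
            base_config,
            baseline_hr=float(np.clip(base_config.baseline_hr + prng.normal(0, 7), 50, 95)),
            base_speed=float(base_config.base_speed + prng.normal(0, 8)),
            stress_group=labels[i],
        )
        if config_sampler is not None:
            cfg = config_sampler(i, prng, cfg)
        session, manifest = generate_session(
            cfg, seed=prng, participant_id=f"p{i + 1:03d}", exclusion_flag=flags[i]
        )
        sessions.append(session)
        manifests.append(manifest)
    return Cohort(sessions, manifests)


def simulate_epoch_pair_cohort(
    n: int,
    template: EcrTemplate | None = None,
    end_rel: float = 4.5,
    onset: float = 10.0,
    duration: float = 20.0,
    base_config: SessionConfig | None = None,
    seed: int = 0,
    baseline_jitter_sd: float = 7.0,
    step: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Beat-level Monte Carlo of one analysis cell across ``n`` participants.

    For each participant, two independent beat trains stand in for the
    control and experimental trips; the experimental one carries ``template``
    time-locked to ``onset`` (None = null cohort). Instantaneous HR is
    splined and cut into a baseline-referenced epoch exactly as the full
    pipeline does, skipping only ECG rendering and R-peak detection.

    Returns ``(rel_times, exp, ctrl)`` where the matrices are
    n x len(rel_times) change values including the zero baseline column.
    """
    from scipy.interpolate import CubicSpline  # local: keeps import cost off hot path

    base_config = SessionConfig() if base_config is None else base_config
    n_grid = int(round((end_rel + 0.5) / step))
    rel = -0.5 + step * np.arange(n_grid + 1)
    exp = np.empty((n, rel.size))
    ctrl = np.empty((n, rel.size))
    for i in range(n):
        prng = np.random.default_rng([seed, i])
        cfg = replace(
            base_config,
            baseline_hr=float(
                np.clip(base_config.baseline_hr + prng.normal(0, baseline_jitter_sd), 50, 95)
            ),
        )
        for out, tpl in ((ctrl, None), (exp, template)):
            ecr = (lambda t: float(tpl(t - onset))) if tpl is not None else None
            beats = sample_rr_train(cfg, ecr, duration=duration, rng=prng)
            hr_t, hr_v = beats[1:], 60.0 / np.diff(beats)
            vals = CubicSpline(hr_t, hr_v, bc_type="natural")(onset + rel)
            out[i] = vals - vals[0]
    return rel, exp, ctrl


# ---------------------------------------------------------------------------
# on-disk bundle (tab-delimited, UTF-8, '.' decimal)
# ---------------------------------------------------------------------------

def write_session_bundle(
    outdir: str | Path, session: DriverSession, manifest: GroundTruthManifest | None = None
) -> Path:
    pdir = Path(outdir) / session.participant_id
    pdir.mkdir(parents=True, exist_ok=True)
    for trip, data in session.trips.items():
        if data.ecg is not None:
            pd.DataFrame({"time_s": data.ecg_time, "mv": data.ecg}).to_csv(
                pdir / f"trip{trip}_ecg.tsv", sep="\t", index=False, float_format="%.6f"
            )
        pd.DataFrame({"time_s": data.speed_time, "kmh": data.speed}).to_csv(
            pdir / f"trip{trip}_speed.tsv", sep="\t", index=False, float_format="%.6f"
        )
    session.markers.to_csv(pdir / "markers.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"condition": list(session.ratings), "rating": list(session.ratings.values())}
    ).to_csv(pdir / "ratings.tsv", sep="\t", index=False)
    if manifest is not None:
        (pdir / "truth.json").write_text(manifest.to_json())
    return pdir


def write_cohort(outdir: str | Path, cohort: Cohort) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for session, manifest in zip(cohort.sessions, cohort.manifests):
        write_session_bundle(outdir, session, manifest)
    cohort.manifest_frame().to_csv(outdir / "cohort_manifest.tsv", sep="\t", index=False)
    return outdir


def read_session_bundle(outdir: str | Path, pid: str) -> tuple[DriverSession, GroundTruthManifest | None]:
    pdir = Path(outdir) / pid
    trips: dict[int, TripData] = {}
    for trip in (1, 2):
        ecg_path = pdir / f"trip{trip}_ecg.tsv"
        if ecg_path.exists():
            ecg = pd.read_csv(ecg_path, sep="\t")
            ecg_t, ecg_v = ecg["time_s"].to_numpy(), ecg["mv"].to_numpy()
        else:
            ecg_t = ecg_v = None
        sp = pd.read_csv(pdir / f"trip{trip}_speed.tsv", sep="\t")
        trips[trip] = TripData(ecg_t, ecg_v, sp["time_s"].to_numpy(), sp["kmh"].to_numpy())
    markers = pd.read_csv(pdir / "markers.tsv", sep="\t")
    ratings_df = pd.read_csv(pdir / "ratings.tsv", sep="\t")
    ratings = dict(zip(ratings_df["condition"], ratings_df["rating"].astype(int)))
    truth_path = pdir / "truth.json"
    manifest = (
        GroundTruthManifest.from_json(truth_path.read_text()) if truth_path.exists() else None
    )
    return DriverSession(pid, trips, markers, ratings), manifest


def read_cohort(outdir: str | Path) -> Cohort:
    outdir = Path(outdir)
    frame = pd.read_csv(outdir / "cohort_manifest.tsv", sep="\t")
    sessions, manifests = [], []
    for pid in frame["pid"]:
        session, manifest = read_session_bundle(outdir, pid)
        sessions.append(session)
        manifests.append(manifest)
    return Cohort(sessions, manifests)
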