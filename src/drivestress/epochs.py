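"""Baseline-referenced change epochs, AUC summaries and stress grouping.

An epoch is a stimulus-locked segment sampled every 0.5 s from -0.5 s before
to 4.5 s (U, P) or 7.5 s (PF) after a marker onset. The sample at -0.5 s is
the baseline; every value is expressed as change from it,
``HRC(t) = HR(t) - HR(t0)``, so the baseline point of every epoch is exactly
zero. The same construction applies to the 10 Hz speed trace (linearly
interpolated onto the grid). A signed trapezoidal area under the change
curve over the post-baseline window summarizes each participant's response.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .simulate import CONDITIONS, POSTWINDOW_END

logger = logging.getLogger(__name__)

GRID_STEP = 0.5
BASELINE_REL = -0.5


@dataclass
class Epoch:
    participant_id: str
    condition: str  # U, P, PF
    condition_type: str  # experimental / control
    window: str  # postcue / postevent
    channel: str  # hr / speed
    rel_times: np.ndarray
    change_values: np.ndarray  # bpm or km/h, change from baseline
    baseline_value: float

    @property
    def post_mask(self) -> np.ndarray:
        return self.rel_times >= 0.0


@dataclass
class EpochMatrix:
    """participants x time grid of change values for one analysis cell."""

    condition: str
    condition_type: str
    window: str
    channel: str
    participant_ids: list[str]
    rel_times: np.ndarray  # includes the -0.5 s baseline point
    data: np.ndarray  # n x len(rel_times)

    @property
    def post_data(self) -> np.ndarray:
        """Post-baseline block (the ANOVA time levels: 10 for U/P, 16 for PF)."""
        return self.data[:, self.rel_times >= 0.0]

    @property
    def n_time_levels(self) -> int:
        return self.post_data.shape[1]


@dataclass
class AucRecord:
    participant_id: str
    condition: str
    condition_type: str
    window: str
    channel: str
    auc: float  # bpm*s or (km/h)*s


def _rel_grid(end_rel: float, step: float = GRID_STEP) -> np.ndarray:
    n = int(round((end_rel - BASELINE_REL) / step))
    return BASELINE_REL + step * np.arange(n + 1)


def extract_epoch(
    times: np.ndarray,
    values: np.ndarray,
    onset: float,
    end_rel: float,
    channel: str = "hr",
    participant_id: str = "",
    condition: str = "",
    condition_type: str = "",
    window: str = "",
    step: float = GRID_STEP,
) -> Epoch | None:
    """Cut one baseline-referenced epoch out of a series.

    ``times``/``values`` are the series' support: HR knots at beat times
    (interpolated with a natural cubic spline) or the uniform speed trace
    (interpolated linearly). Returns None — logged — when the series does not
    cover [onset - 0.5 s, onset + end_rel], which downstream drives
    complete-case dropping.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    rel = _rel_grid(end_rel, step)
    abs_times = onset + rel
    if abs_times[0] < times[0] - 1e-9 or abs_times[-1] > times[-1] + 1e-9:
        logger.warning(
            "missing epoch %s %s/%s/%s: series [%0.1f, %0.1f] does not cover "
            "[%0.1f, %0.1f]",
            participant_id, condition, condition_type, window,
            times[0], times[-1], abs_times[0], abs_times[-1],
        )
        return None
    if channel == "hr":
        if times.size < 4:
            return None
        sampled = CubicSpline(times, values, bc_type="natural")(abs_times)
    else:
        sampled = np.interp(abs_times, times, values)
    baseline = float(sampled[0])
    return Epoch(
        participant_id, condition, condition_type, window, channel,
        rel, sampled - baseline, baseline,
    )


@dataclass
class ParticipantSeries:
    """Per-participant inputs to epoching: HR knots and speed per trip."""

    participant_id: str
    hr_knots: dict[int, tuple[np.ndarray, np.ndarray]]  # trip -> (t, bpm)
    speed: dict[int, tuple[np.ndarray, np.ndarray]]  # trip -> (t, kmh)
    markers: pd.DataFrame
    ratings: dict[str, int]


TRIP_FOR_TYPE = {"control": 1, "experimental": 2}


def build_epoch_matrices(
    participants: list[ParticipantSeries],
    channels: tuple[str, ...] = ("hr", "speed"),
    window_ends: dict[str, float] | None = None,
    step: float = GRID_STEP,
) -> dict[tuple[str, str, str, str], EpochMatrix]:
    """Assemble (condition, type, window, channel) -> EpochMatrix.

    Control epochs come from Trip 1 at the matched route positions (for PF
    the Trip-1 "control" contains the first exposure to the cue and event);
    experimental epochs come from Trip 2. Rows are aligned by participant
    across the experimental/control pair; a participant missing either member
    of a pair is dropped from both and logged.
    """
    window_ends = dict(POSTWINDOW_END if window_ends is None else window_ends)
    out: dict[tuple[str, str, str, str], EpochMatrix] = {}
    for cond in CONDITIONS:
        end_rel = window_ends[cond]
        for window, mtype in (("postcue", "cue_onset"), ("postevent", "event_onset")):
            for channel in channels:
                rows: dict[str, dict[str, Epoch]] = {}
                for p in participants:
                    pair: dict[str, Epoch] = {}
                    for ctype, trip in TRIP_FOR_TYPE.items():
                        sel = p.markers[
                            (p.markers["trip"] == trip)
                            & (p.markers["condition"] == cond)
                            & (p.markers["marker_type"] == mtype)
                        ]
                        if sel.empty:
                            continue
                        onset = float(sel["onset_s"].iloc[0])
                        series = p.hr_knots[trip] if channel == "hr" else p.speed[trip]
                        ep = extract_epoch(
                            series[0], series[1], onset, end_rel, channel,
                            p.participant_id, cond, ctype, window, step,
                        )
                        if ep is not None:
                            pair[ctype] = ep
                    if len(pair) == 2:
                        rows[p.participant_id] = pair
                    else:
                        logger.warning(
                            "participant %s dropped from %s/%s/%s (incomplete pair)",
                            p.participant_id, cond, window, channel,
                        )
                if not rows:
                    continue
                rel = _rel_grid(end_rel, step)
                pids = list(rows)
                for ctype in TRIP_FOR_TYPE:
                    data = np.vstack([rows[pid][ctype].change_values for pid in pids])
                    out[(cond, ctype, window, channel)] = EpochMatrix(
                        cond, ctype, window, channel, pids, rel, data
                    )
    return out


def auc(epoch: Epoch) -> AucRecord:
    """Signed trapezoidal area of the change curve over [0, end] (the forced
    zero baseline point at -0.5 s is excluded)."""
    mask = epoch.post_mask
    value = float(np.trapezoid(epoch.change_values[mask], epoch.rel_times[mask]))
    return AucRecord(
        epoch.participant_id, epoch.condition, epoch.condition_type,
        epoch.window, epoch.channel, value,
    )


def matrix_aucs(matrix: EpochMatrix) -> pd.DataFrame:
    """AUC per participant row of an EpochMatrix."""
    mask = matrix.rel_times >= 0.0
    values = np.trapezoid(matrix.data[:, mask], matrix.rel_times[mask], axis=1)
    return pd.DataFrame(
        {
            "pid": matrix.participant_ids,
            "condition": matrix.condition,
            "type": matrix.condition_type,
            "window": matrix.window,
            "channel": matrix.channel,
            "auc": values,
        }
    )


def median_split(ratings: pd.DataFrame, threshold: float = 2.5) -> pd.DataFrame:
    """Assign high/low perceived-stress groups per condition.

    ``ratings`` has columns pid, condition, rating (1-5 Likert). A rating
    strictly above ``threshold`` (2.5 of 5) is high-perceived stress.
    """
    out = ratings.copy()
    bad = out[(out["rating"] < 1) | (out["rating"] > 5)]
    if not bad.empty:
        raise ValueError(
            f"rating outside 1-5 for participant(s) {sorted(bad['pid'].unique())}"
        )
    out["group"] = np.where(out["rating"] > threshold, "high", "low")
    return out
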