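"""Trajectory-level kinematic parameter extraction.

One recorded pointing movement (index-finger position tracked at 120 Hz in
X/Y/Z) is reduced to 20 named kinematic parameters: temporal landmarks of the
velocity/acceleration profile, their locations expressed as percentages of
movement time and of horizontal path, movement amplitudes, and a
dimensionless-jerk smoothness index.  Movement boundaries are found with the
classic velocity-threshold rule: onset (offset) is where speed rises above
(falls below) 10% of the trial's peak speed for six consecutive samples.

Trials are aggregated per participant and condition into per-parameter means
and sample standard deviations, which form the feature tables consumed by the
classification stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "PARAMETER_FIELDS",
    "PARAMETER_LABELS",
    "Trajectory",
    "KinematicVector",
    "ParticipantConditionFeatures",
    "SegmentationError",
    "lowpass_filter",
    "differentiate",
    "detect_bounds",
    "dimensionless_jerk",
    "extract_kinematics",
    "aggregate",
    "exclude_errors",
]

#: Attribute names of the 20 kinematic parameters, in canonical table order
#: (parameter numbers 1..20 used throughout the feature-index convention).
PARAMETER_FIELDS: tuple[str, ...] = (
    "duration",
    "peak_velocity",
    "time_to_peak_velocity",
    "percent_peak_velocity_location",
    "percent_time_before_peak_velocity",
    "percent_time_after_peak_velocity",
    "peak_acceleration",
    "time_to_peak_acceleration",
    "percent_time_to_peak_acceleration",
    "percent_peak_acceleration_location",
    "peak_deceleration",
    "time_to_peak_deceleration",
    "percent_time_to_peak_deceleration",
    "percent_peak_deceleration_location",
    "dimensionless_jerk",
    "horizontal_max_amplitude",
    "vertical_amplitude",
    "time_to_peak_vertical_amplitude",
    "percent_time_of_peak_vertical_amplitude",
    "percent_location_of_peak_vertical_amplitude",
)

#: Human-readable parameter names (reports, plots, index_to_label).
PARAMETER_LABELS: tuple[str, ...] = (
    "Duration",
    "Peak velocity",
    "Time to peak velocity",
    "Percent peak velocity location",
    "Percent time before peak velocity",
    "Percent time after peak velocity",
    "Peak acceleration",
    "Time to peak acceleration",
    "Percent time to peak acceleration",
    "Percent peak acceleration location",
    "Peak deceleration",
    "Time to peak deceleration",
    "Percent time to peak deceleration",
    "Percent peak deceleration location",
    "Jerk",
    "Horizontal Max amplitude",
    "Vertical amplitude",
    "Time to peak vertical amplitude",
    "Percent time of peak vertical amplitude",
    "Percent location of peak vertical amplitude",
)


class SegmentationError(ValueError):
    """Raised when no movement onset/offset satisfying the threshold rule exists."""

    def __init__(self, message: str, trial_id: object | None = None):
        super().__init__(message if trial_id is None else f"{message} (trial {trial_id})")
        self.trial_id = trial_id


@dataclass
class Trajectory:
    """One trial's uniformly sampled 3-D position series.

    Axes follow the recording convention: ``x`` is the horizontal movement
    direction (rightward positive), ``y`` vertical, ``z`` lateral.  Positions
    in mm, time in seconds, default sampling rate 120 Hz.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    rate: float = 120.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("t, x, y, z must have equal length")
        if n < 24:
            raise ValueError(f"trajectory too short: {n} samples (< 24)")
        dt = np.diff(self.t)
        if dt.size and (np.abs(dt - dt[0]) > 1e-9).any():
            raise ValueError("time base is not uniformly spaced")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate


@dataclass
class KinematicVector:
    """The 20 kinematic parameters of one trial, by name.

    Units: seconds for times, mm for amplitudes, mm/s and mm/s^2 for velocity
    and acceleration extrema, percentages in [0, 100].  ``peak_deceleration``
    is the most negative acceleration in the window (signed).
    ``dimensionless_jerk`` is -(D^3 / v_peak^2) * integral(jerk^2): more
    negative means less smooth.
    """

    duration: float
    peak_velocity: float
    time_to_peak_velocity: float
    percent_peak_velocity_location: float
    percent_time_before_peak_velocity: float
    percent_time_after_peak_velocity: float
    peak_acceleration: float
    time_to_peak_acceleration: float
    percent_time_to_peak_acceleration: float
    percent_peak_acceleration_location: float
    peak_deceleration: float
    time_to_peak_deceleration: float
    percent_time_to_peak_deceleration: float
    percent_peak_deceleration_location: float
    dimensionless_jerk: float
    horizontal_max_amplitude: float
    vertical_amplitude: float
    time_to_peak_vertical_amplitude: float
    percent_time_of_peak_vertical_amplitude: float
    percent_location_of_peak_vertical_amplitude: float

    def as_array(self) -> np.ndarray:
        """Parameters as a length-20 array in canonical table order."""
        return np.array([getattr(self, f) for f in PARAMETER_FIELDS], dtype=float)


@dataclass
class ParticipantConditionFeatures:
    """Per-parameter mean and SD over one participant's trials in one condition."""

    participant: str
    group: str
    condition: str
    mean_vector: np.ndarray
    sd_vector: np.ndarray
    n_trials_used: int


def lowpass_filter(traj: Trajectory, cutoff: float = 10.0, order: int = 2) -> Trajectory:
    """Zero-phase Butterworth low-pass filter of all three position axes.

    Forward-backward filtering (squared magnitude response, zero phase lag)
    with reflected end padding; length preserved.

    Parameters
    ----------
    cutoff : corner frequency in Hz, must be below the Nyquist rate.
    order : order of the underlying one-pass Butterworth design.
    """
    if not 0 < cutoff < traj.rate / 2:
        raise ValueError(f"cutoff must lie in (0, {traj.rate / 2}) Hz, got {cutoff}")
    sos = signal.butter(order, cutoff, btype="low", fs=traj.rate, output="sos")
    pad = min(3 * (2 * order + 1), len(traj) - 1)
    def _f(s: np.ndarray) -> np.ndarray:
        return signal.sosfiltfilt(sos, s, padlen=pad)
    return Trajectory(traj.t.copy(), _f(traj.x), _f(traj.y), _f(traj.z), traj.rate)


def differentiate(traj: Trajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Velocity, acceleration and jerk of the horizontal (movement) axis.

    Central differences in the interior, one-sided at the endpoints; series
    lengths equal the trajectory length.
    """
    if len(traj) < 5:
        raise ValueError("need at least 5 samples to differentiate")
    dt = traj.dt
    v = np.gradient(traj.x, dt)
    a = np.gradient(v, dt)
    j = np.gradient(a, dt)
    return v, a, j


def _runs_above(mask: np.ndarray, run_length: int) -> np.ndarray:
    """Start indices i such that mask[i:i+run_length] is all True."""
    if len(mask) < run_length:
        return np.array([], dtype=int)
    window = np.convolve(mask.astype(int), np.ones(run_length, dtype=int), mode="valid")
    return np.flatnonzero(window == run_length)


def detect_bounds(
    velocity: np.ndarray,
    rate: float = 120.0,
    threshold_fraction: float = 0.1,
    run_length: int = 6,
    trial_id: object | None = None,
) -> tuple[int, int]:
    """Movement onset and offset by the sustained velocity-threshold rule.

    Onset is the first sample of the earliest run of ``run_length`` consecutive
    samples with speed above ``threshold_fraction`` of the trial's peak speed
    (|velocity|); offset is the last sample before speed stays below the
    threshold for ``run_length`` consecutive samples after the peak.  At the
    default 120 Hz, 6 samples correspond to 48 ms of sustained movement,
    making the rule robust to brief threshold crossings.

    Returns ``(onset, offset)`` indices with onset < argmax(speed) <= offset.
    Raises :class:`SegmentationError` when no qualifying run exists.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    speed = np.abs(np.asarray(velocity, dtype=float))
    peak = speed.max()
    if peak <= 0:
        raise SegmentationError("velocity is identically zero", trial_id)
    thr = threshold_fraction * peak
    above = speed > thr
    onset_runs = _runs_above(above, run_length)
    if onset_runs.size == 0:
        raise SegmentationError("no sustained supra-threshold run (onset)", trial_id)
    onset = int(onset_runs[0])
    i_peak = int(np.argmax(speed))
    below_runs = _runs_above(~above, run_length)
    below_runs = below_runs[below_runs > i_peak]
    if below_runs.size == 0:
        raise SegmentationError("velocity never settles below threshold (offset)", trial_id)
    offset = int(below_runs[0]) - 1
    if offset <= onset:
        raise SegmentationError("degenerate movement window", trial_id)
    return onset, offset


def dimensionless_jerk(jerk: np.ndarray, duration: float, peak_velocity: float) -> float:
    """Dimensionless-jerk smoothness of a movement window.

    Computes ``-(D^3 / v_peak^2) * integral(j(t)^2 dt)`` by trapezoidal
    integration over the window the jerk series spans.  The minimum-jerk
    movement attains the optimum -204.8 under this normalisation; noisier,
    more fragmented movements score more negative.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if peak_velocity <= 0:
        raise ValueError("peak_velocity must be positive")
    jerk = np.asarray(jerk, dtype=float)
    if len(jerk) < 2:
        raise ValueError("jerk series needs at least 2 samples")
    dt = duration / (len(jerk) - 1)
    integral = np.trapezoid(jerk ** 2, dx=dt)
    return float(-(duration ** 3) / (peak_velocity ** 2) * integral)


def _pct_location(x: np.ndarray, idx: int, onset: int, offset: int) -> float:
    span = x[offset] - x[onset]
    if span == 0:
        return 0.0
    pct = 100.0 * (x[idx] - x[onset]) / span
    return float(np.clip(pct, 0.0, 100.0))  # absorb numerical overshoot


def extract_kinematics(
    traj: Trajectory,
    cutoff: float = 10.0,
    order: int = 2,
    threshold_fraction: float = 0.1,
    run_length: int = 6,
    prefiltered: bool = False,
    trial_id: object | None = None,
) -> KinematicVector:
    """All 20 kinematic parameters of one trial.

    The trajectory is low-pass filtered (unless ``prefiltered``), the
    horizontal axis differentiated, the movement window segmented with
    :func:`detect_bounds`, and every parameter computed on that window.
    Percent-of-time fields are relative to movement duration; percent-of-
    horizontal-movement fields are relative to the onset-to-offset
    displacement and clamped to [0, 100].
    """
    ft = traj if prefiltered else lowpass_filter(traj, cutoff, order)
    v, a, j = differentiate(ft)
    onset, offset = detect_bounds(v, ft.rate, threshold_fraction, run_length, trial_id)
    sl = slice(onset, offset + 1)
    rate = ft.rate
    duration = (offset - onset) / rate

    vw, aw = v[sl], a[sl]
    i_pv = onset + int(np.argmax(np.abs(vw)))
    peak_velocity = float(abs(v[i_pv]))
    t_pv = (i_pv - onset) / rate
    pct_before = 100.0 * t_pv / duration

    i_pa = onset + int(np.argmax(aw))
    i_pd = onset + int(np.argmin(aw))

    i_py = onset + int(np.argmax(ft.y[sl]))
    t_py = (i_py - onset) / rate

    dj = dimensionless_jerk(j[sl], duration, peak_velocity)

    x = ft.x
    return KinematicVector(
        duration=duration,
        peak_velocity=peak_velocity,
        time_to_peak_velocity=t_pv,
        percent_peak_velocity_location=_pct_location(x, i_pv, onset, offset),
        percent_time_before_peak_velocity=pct_before,
        percent_time_after_peak_velocity=100.0 - pct_before,
        peak_acceleration=float(a[i_pa]),
        time_to_peak_acceleration=(i_pa - onset) / rate,
        percent_time_to_peak_acceleration=100.0 * (i_pa - onset) / rate / duration,
        percent_peak_acceleration_location=_pct_location(x, i_pa, onset, offset),
        peak_deceleration=float(a[i_pd]),
        time_to_peak_deceleration=(i_pd - onset) / rate,
        percent_time_to_peak_deceleration=100.0 * (i_pd - onset) / rate / duration,
        percent_peak_deceleration_location=_pct_location(x, i_pd, onset, offset),
        dimensionless_jerk=dj,
        horizontal_max_amplitude=float(x[sl].max() - x[sl].min()),
        vertical_amplitude=float(ft.y[sl].max() - ft.y[onset]),
        time_to_peak_vertical_amplitude=t_py,
        percent_time_of_peak_vertical_amplitude=100.0 * t_py / duration,
        percent_location_of_peak_vertical_amplitude=_pct_location(x, i_py, onset, offset),
    )


def aggregate(
    trials: list[KinematicVector],
    participant: str = "",
    group: str = "",
    condition: str = "",
) -> ParticipantConditionFeatures:
    """Mean and sample SD (n-1 denominator) of the 20 parameters over trials."""
    if len(trials) < 2:
        raise ValueError(
            f"need >= 2 trials to aggregate, got {len(trials)} "
            f"(participant={participant!r}, condition={condition!r})"
        )
    arr = np.vstack([kv.as_array() for kv in trials])
    return ParticipantConditionFeatures(
        participant=participant,
        group=group,
        condition=condition,
        mean_vector=arr.mean(axis=0),
        sd_vector=arr.std(axis=0, ddof=1),
        n_trials_used=len(trials),
    )


def exclude_errors(trials: list, extra_failed_ids: set | None = None) -> tuple[list, dict]:
    """Drop flagged error trials (and segmentation failures) with a report.

    ``trials`` is a list of trial records exposing ``.group``, ``.error_flag``
    and an identifying tuple via ``.trial_id`` (the synthetic cohort's records
    do).  Returns the retained trials and a report with per-group exclusion
    percentages.
    """
    extra_failed_ids = extra_failed_ids or set()
    kept, report = [], {}
    groups: dict[str, list[int]] = {}
    for tr in trials:
        excluded = tr.error_flag is not None or tr.trial_id in extra_failed_ids
        groups.setdefault(tr.group, []).append(int(excluded))
        if not excluded:
            kept.append(tr)
    for g, flags in groups.items():
        report[g] = {
            "n_trials": len(flags),
            "n_excluded": int(sum(flags)),
            "percent_excluded": 100.0 * sum(flags) / len(flags),
        }
    return kept, report
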