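"""Synthetic motion-capture cohorts and feature tables.

The generator emulates the structure of a two-group imitation experiment:
each participant imitates a short pointing sequence under 8 conditions
(Target/No-Target crossed with Normal/Fast/Elevated/Short), 8 trials per
condition, hand position sampled at 120 Hz.  A trial is one rightward
point-to-point movement built from a minimum-jerk horizontal profile — the
quintic polynomial that minimises integrated squared jerk, the standard model
for reaching — plus a raised-cosine vertical lift (low bump for flat
trajectories, pronounced for the elevated/curved condition) and additive
measurement noise.

Group differences enter through :class:`GroupEffectSpec`: per-condition
multipliers on trial-to-trial variability (the clinical group is modelled as
more variable when imitating fast goal-less movements and less variable for
the unusual elevated movement, mirroring the direction reported for autistic
adults) and optional additive shifts of the nominal movement parameters.

Feature tables with planted informative columns can also be drawn directly
from group-conditional Gaussians, bypassing the trajectory level, for
selection/evaluation benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import Trajectory
from .io import FeatureKey, FeatureMatrix, STATISTICS

__all__ = [
    "CONDITION_CODES",
    "ConditionSpec",
    "GroupEffectSpec",
    "TrialRecord",
    "SyntheticCohort",
    "make_condition_spec",
    "default_group_effect",
    "simulate_trial",
    "simulate_cohort",
    "simulate_feature_table",
    "simulate_condition_table",
]

#: The 8 imitation conditions: Target / No-Target crossed with movement type.
CONDITION_CODES: tuple[str, ...] = ("TF", "TN", "TE", "TS", "NTF", "NTN", "NTE", "NTS")

#: Movement-type rows of the stimulus design: tempo (beats/min), amplitude
#: (cm), trajectory shape.  One beat per movement.
_MOVEMENT_TYPES = {
    "N": (48, 15, "flat"),
    "F": (58, 15, "flat"),
    "S": (48, 10, "flat"),
    "E": (48, 15, "curved"),
}


@dataclass(frozen=True)
class ConditionSpec:
    """Stimulus parameters of one imitation condition."""

    code: str
    tempo: int  # beats per minute; one beat per movement
    amplitude: float  # horizontal extent, cm
    trajectory_shape: str  # "flat" or "curved"
    targeted: bool  # visible targets present

    @property
    def nominal_duration(self) -> float:
        """Nominal movement duration in seconds (one beat)."""
        return 60.0 / self.tempo

    @property
    def amplitude_mm(self) -> float:
        return self.amplitude * 10.0


def make_condition_spec(code: str) -> ConditionSpec:
    """Condition specification for one of the 8 valid condition codes."""
    if code not in CONDITION_CODES:
        raise ValueError(f"unknown condition code {code!r}; valid: {CONDITION_CODES}")
    movement = code[-1]
    tempo, amplitude, shape = _MOVEMENT_TYPES[movement]
    return ConditionSpec(
        code=code,
        tempo=tempo,
        amplitude=amplitude,
        trajectory_shape=shape,
        targeted=not code.startswith("NT"),
    )


@dataclass
class GroupEffectSpec:
    """How one group's movements deviate from the nominal generative model.

    ``sd_scale_per_condition`` multiplies the trial-to-trial jitter SDs of the
    nominal movement parameters in that condition (1.0 = control level).
    ``mean_shift_per_parameter`` maps ``(condition code, parameter)`` — with
    parameter one of ``duration``, ``amplitude``, ``lift`` — to an additive
    offset on that nominal value (seconds / mm / mm respectively).
    """

    group: str = "control"
    sd_scale_per_condition: dict[str, float] = field(default_factory=dict)
    mean_shift_per_parameter: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, mult in self.sd_scale_per_condition.items():
            if mult <= 0:
                raise ValueError(f"sd scale for {code} must be > 0, got {mult}")

    def sd_scale(self, code: str) -> float:
        return self.sd_scale_per_condition.get(code, 1.0)

    def shift(self, code: str, parameter: str) -> float:
        return self.mean_shift_per_parameter.get((code, parameter), 0.0)


def default_group_effect(group: str = "ASC") -> GroupEffectSpec:
    """Default group effect used by cohort simulation.

    Controls are the reference (all multipliers 1).  The clinical group is
    modelled with doubled trial-to-trial variability in the No-Target Fast
    condition and halved variability in No-Target Elevated; all other
    conditions are at control level.  Magnitudes are generator choices — the
    direction (higher SDs for fast goal-less imitation, lower for the unusual
    elevated movement) follows what has been described for autistic adults.
    """
    if group == "control":
        return GroupEffectSpec(group="control")
    return GroupEffectSpec(
        group=group,
        sd_scale_per_condition={"NTF": 2.0, "NTE": 0.5},
    )


# Control-level trial-to-trial jitter, as fractions of the nominal values.
_JITTER_FRAC = {"duration": 0.05, "amplitude": 0.04, "lift": 0.20}
# Vertical lift of the index finger: low bump for flat trajectories,
# pronounced for the curved ("elevated") movement.  Heights in mm.
_LIFT_MM = {"flat": 8.0, "curved": 60.0}
_REST_S = 0.30  # leading/trailing rest, seconds


def _min_jerk_pos(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile on tau in [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_trial(
    spec: ConditionSpec,
    effect: GroupEffectSpec | None = None,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
    rate: float = 120.0,
    jitter_scale: float = 1.0,
) -> Trajectory:
    """Simulate one trial: rest, a single rightward movement, rest.

    The horizontal profile is minimum-jerk with nominal duration 60/tempo s
    and extent = condition amplitude; the vertical profile is a raised-cosine
    bump peaking mid-movement.  Nominal duration, extent and lift receive
    Gaussian trial-to-trial jitter whose SD is the control-level fraction of
    the nominal value times the group's per-condition multiplier, plus any
    additive group mean shift.  ``noise_sd`` (mm) is added i.i.d. to every
    sample of all three axes.  ``jitter_scale=0`` switches all
    trial-to-trial jitter off (deterministic nominal movement), which the
    closed-form tests rely on.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if jitter_scale < 0:
        raise ValueError("jitter_scale must be >= 0")
    effect = effect or GroupEffectSpec()
    rng = rng if rng is not None else np.random.default_rng()
    scale = effect.sd_scale(spec.code)

    nominal = {
        "duration": spec.nominal_duration,
        "amplitude": spec.amplitude_mm,
        "lift": _LIFT_MM[spec.trajectory_shape],
    }
    drawn = {}
    for name, base in nominal.items():
        jitter_sd = _JITTER_FRAC[name] * base * scale * jitter_scale
        drawn[name] = base + effect.shift(spec.code, name) + rng.normal(0.0, jitter_sd)
    duration = max(drawn["duration"], 0.25)
    extent = max(drawn["amplitude"], 1.0)
    lift = max(drawn["lift"], 0.0)

    n_rest = int(round(_REST_S * rate))
    n_move = max(int(round(duration * rate)), 12)
    n = 2 * n_rest + n_move + 1
    t = np.arange(n) / rate

    tau = np.clip((np.arange(n) - n_rest) / n_move, 0.0, 1.0)
    x = extent * _min_jerk_pos(tau)
    y = lift * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau))
    z = np.zeros(n)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
        y = y + rng.normal(0.0, noise_sd, n)
        z = z + rng.normal(0.0, noise_sd, n)
    return Trajectory(t, x, y, z, rate)


@dataclass
class TrialRecord:
    """One simulated trial plus its manifest metadata."""

    participant: str
    group: str
    condition: str
    trial_index: int
    trajectory: Trajectory
    error_flag: str | None = None  # None | "recording" | "imitation"

    @property
    def trial_id(self) -> tuple[str, str, int]:
        return (self.participant, self.condition, self.trial_index)


@dataclass
class SyntheticCohort:
    """All trials of a simulated two-group cohort, with ground truth."""

    trials: list[TrialRecord]
    truth: dict[str, GroupEffectSpec]
    seed: int

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": [tr.participant for tr in self.trials],
                "group": [tr.group for tr in self.trials],
                "condition": [tr.condition for tr in self.trials],
                "trial": [tr.trial_index for tr in self.trials],
                "error_flag": [tr.error_flag or "" for tr in self.trials],
            }
        )

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for tr in self.trials:
            seen.setdefault(tr.participant, None)
        return list(seen)


def _corrupt_recording(traj: Trajectory, rng: np.random.Generator) -> Trajectory:
    """Tracker dropout: a mid-trial chunk of samples freezes at one value."""
    n = len(traj)
    start = int(rng.integers(n // 4, n // 2))
    length = int(rng.integers(n // 4, n // 2))
    x, y, z = traj.x.copy(), traj.y.copy(), traj.z.copy()
    for s in (x, y, z):
        s[start : start + length] = s[start]
    return Trajectory(traj.t, x, y, z, traj.rate)


def simulate_cohort(
    n_asc: int,
    n_ctrl: int,
    effect: GroupEffectSpec | None = None,
    seed: int = 0,
    error_fraction_asc: float = 0.06,
    error_fraction_ctrl: float = 0.02,
    noise_sd: float = 1.0,
    trials_per_condition: int = 8,
) -> SyntheticCohort:
    """Simulate a full two-group cohort (8 conditions x 8 trials each).

    Each participant contributes ``trials_per_condition`` trials in each of
    the 8 conditions (64 analysable trials at the default).  A configurable
    fraction of each group's trials is flagged as error trials (recording
    dropouts or imitation errors, roughly half each); flagged recording
    trials are also corrupted so that downstream exclusion actually matters.
    Fully reproducible from ``seed``.
    """
    if n_asc < 2 or n_ctrl < 2:
        raise ValueError("need >= 2 participants per group (SD aggregation)")
    effect = effect if effect is not None else default_group_effect("ASC")
    ctrl_effect = GroupEffectSpec(group="control")
    rng = np.random.default_rng(seed)

    trials: list[TrialRecord] = []
    roster = [("ASC", i, error_fraction_asc) for i in range(n_asc)] + [
        ("control", i, error_fraction_ctrl) for i in range(n_ctrl)
    ]
    for group, idx, err_frac in roster:
        pid = f"{'A' if group == 'ASC' else 'C'}{idx + 1:02d}"
        geffect = effect if group == "ASC" else ctrl_effect
        for code in CONDITION_CODES:
            spec = make_condition_spec(code)
            for k in range(trials_per_condition):
                traj = simulate_trial(spec, geffect, noise_sd, rng)
                flag = None
                if err_frac > 0 and rng.random() < err_frac:
                    flag = "recording" if rng.random() < 0.5 else "imitation"
                    if flag == "recording":
                        traj = _corrupt_recording(traj, rng)
                trials.append(TrialRecord(pid, group, code, k, traj, flag))
    return SyntheticCohort(trials=trials, truth={"ASC": effect, "control": ctrl_effect}, seed=seed)


def _two_block_columns(conditions: tuple[str, str] = ("NTF", "NTE"), statistic: str = "sd"):
    return [FeatureKey(c, statistic, p) for c in conditions for p in range(1, 21)]


def simulate_feature_table(
    n_asc: int,
    n_ctrl: int,
    n_features: int = 40,
    informative_idx: set[int] | frozenset[int] = frozenset(),
    effect_size: float = 0.0,
    seed: int = 0,
) -> FeatureMatrix:
    """Draw a participants x features table from group-conditional Gaussians.

    Non-informative features are N(0, 1) in both groups; features whose
    1-based global index is in ``informative_idx`` have their ASC mean shifted
    by ``effect_size`` standard deviations.  With the default 40 features the
    column index map follows the two-condition SD convention (1-20 = NTF SDs,
    21-40 = NTE SDs in canonical parameter order); other widths get generic
    synthetic column keys.  Ground truth is recorded on the returned matrix.
    """
    informative_idx = frozenset(informative_idx)
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    bad = [i for i in informative_idx if not 1 <= i <= n_features]
    if bad:
        raise ValueError(f"informative indices out of range 1..{n_features}: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    n = n_asc + n_ctrl
    values = rng.normal(0.0, 1.0, size=(n, n_features))
    labels = np.array(["ASC"] * n_asc + ["control"] * n_ctrl)
    for i in informative_idx:
        values[:n_asc, i - 1] += effect_size

    if n_features == 40:
        columns = _two_block_columns()
    else:
        columns = [FeatureKey("SYN", "sd", ((p - 1) % 20) + 1) for p in range(1, n_features + 1)]
    participants = [f"A{i + 1:02d}" for i in range(n_asc)] + [f"C{i + 1:02d}" for i in range(n_ctrl)]
    fm = FeatureMatrix(values=values, labels=labels, columns=columns, participants=participants)
    fm.truth = {"informative_idx": sorted(informative_idx), "effect_size": effect_size}
    return fm


def simulate_condition_table(
    n_asc: int,
    n_ctrl: int,
    effects: dict[tuple[str, str, int], float] | None = None,
    seed: int = 0,
) -> FeatureMatrix:
    """Full 8-condition x {mean, sd} x 20-parameter table (320 columns).

    All columns are N(0, 1); ``effects`` maps ``(condition, statistic,
    parameter number)`` to a standardized ASC mean shift for that column.
    Useful for exercising the condition screen without the trajectory level.
    """
    effects = effects or {}
    rng = np.random.default_rng(seed)
    columns = [
        FeatureKey(c, s, p) for c in CONDITION_CODES for s in STATISTICS for p in range(1, 21)
    ]
    n = n_asc + n_ctrl
    values = rng.normal(0.0, 1.0, size=(n, len(columns)))
    labels = np.array(["ASC"] * n_asc + ["control"] * n_ctrl)
    key_pos = {k: i for i, k in enumerate(columns)}
    for key, shift in effects.items():
        if FeatureKey(*key) not in key_pos:
            raise KeyError(f"no such column: {key}")
        values[:n_asc, key_pos[FeatureKey(*key)]] += shift
    participants = [f"A{i + 1:02d}" for i in range(n_asc)] + [f"C{i + 1:02d}" for i in range(n_ctrl)]
    fm = FeatureMatrix(values=values, labels=labels, columns=columns, participants=participants)
    fm.truth = {"effects": dict(effects)}
    return fm
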