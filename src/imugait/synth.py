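"""Synthetic multi-IMU gait cohort generator.

Emulates an acquisition protocol in which each subject stands for 15 s,
walks a straight 7 m path, and stands again for 5 s, repeating each of
seven task variants four times: normal gait (WN), ataxic (WA) and
Parkinsonian (WP) walks, and hemiplegic (WH) and equine/foot-drop (WF)
walks mimicked once per body side.  Five IMUs (sternum, both pelvis sides,
both wrists) sample 9 channels each at 128 Hz.

The signal model is deliberately simple — a cadence-locked sinusoid stack
(fundamental plus two harmonics) per channel, a gravity/bias offset,
class-specific modifier terms, and white Gaussian noise — but it realises
every kinematic cue that distinguishes the classes clinically:

* WN: brisk cadence, symmetric arm swing, no tremor;
* WH: reduced cadence, near-absent arm swing on the paretic side, extra
  pelvis rotation on that side (leg circumduction);
* WF: asymmetric pelvis gyroscope amplitude (compensation for weak foot
  dorsiflexion on the affected side);
* WA: wide base of support (inflated lateral pelvis variance) and a low
  cadence;
* WP: short slow steps, forward-flexed trunk (quasi-static sternum
  accelerometer bias) and a 4–6 Hz hand tremor on the wrists.

Axis convention for every sensor frame: x anterior, y lateral (leftward),
z vertical (up); gravity therefore loads the accelerometer z axis while
standing and walking upright.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .io import (AXES, COMPONENT_ORDER, SENSOR_ORDER, SIDED_CLASSES,
                 GaitClass, IMURecording, Side, ValidationError,
                 write_recording)

__all__ = [
    "GaitSignature",
    "CohortConfig",
    "default_signature",
    "subject_profile",
    "simulate_repetition",
    "cohort_plan",
    "simulate_cohort",
    "TASK_VARIANTS",
]

#: the seven task variants each subject repeats (class, affected side)
TASK_VARIANTS: tuple[tuple[GaitClass, Side], ...] = (
    (GaitClass.WN, Side.NONE),
    (GaitClass.WA, Side.NONE),
    (GaitClass.WP, Side.NONE),
    (GaitClass.WH, Side.LEFT),
    (GaitClass.WH, Side.RIGHT),
    (GaitClass.WF, Side.LEFT),
    (GaitClass.WF, Side.RIGHT),
)

# class-level gait parameters: step cadence orders WN > WF > WH > WA > WP
# ("low cadence" ataxia, "short and slow steps" parkinsonism), and walking
# speed sets the class-dependent duration of the 7 m path.
_CADENCE_HZ = {GaitClass.WN: 1.8, GaitClass.WH: 1.4, GaitClass.WF: 1.6,
               GaitClass.WA: 1.1, GaitClass.WP: 1.0}
_SPEED_M_S = {GaitClass.WN: 1.25, GaitClass.WH: 0.80, GaitClass.WF: 0.95,
              GaitClass.WA: 0.65, GaitClass.WP: 0.50}

_GRAVITY = 9.81
_PATH_LENGTH_M = 7.0

# base oscillation amplitude per (sensor-site kind, component)
_BASE_AMP = {
    ("pelvis", "acc"): 2.0, ("pelvis", "gyro"): 1.5, ("pelvis", "mag"): 0.0,
    ("wrist", "acc"): 1.2, ("wrist", "gyro"): 1.0, ("wrist", "mag"): 0.08,
    ("sternum", "acc"): 1.0, ("sternum", "gyro"): 0.5, ("sternum", "mag"): 0.0,
}
_SITE_KIND = {"S": "sternum", "LP": "pelvis", "RP": "pelvis",
              "LW": "wrist", "RW": "wrist"}
# ambient magnetic field in sensor frame (arbitrary units)
_MAG_FIELD = np.array([0.4, 0.1, -0.3])


@dataclasses.dataclass
class GaitSignature:
    """Per-class kinematic fingerprint driving the signal model."""

    gait_class: GaitClass
    affected_side: Side
    cadence_hz: float
    step_amplitude_scale: dict[str, float]
    arm_swing_asymmetry: float = 0.0
    tremor_freq_hz: float = 0.0
    tremor_amplitude: float = 0.0
    trunk_lean_offset: float = 0.0
    base_width_noise: float = 0.0
    cadence_jitter: float = 0.02
    speed_m_s: float = 1.0
    pelvis_gyro_asymmetry: float = 1.0  # affected/contralateral amp ratio
    harmonic_weights: tuple[float, float, float] = (1.0, 0.45, 0.2)
    wrist_harmonic_weights: tuple[float, float, float] | None = None
    amplitude_modulation: float = 0.0  # stride-to-stride amplitude irregularity
    cadence_wobble: float = 0.0  # within-walk timing irregularity (FM depth)

    def __post_init__(self) -> None:
        if self.cadence_hz <= 0:
            raise ValidationError("cadence_hz must be positive")
        if not 0.0 <= self.arm_swing_asymmetry <= 1.0:
            raise ValidationError("arm_swing_asymmetry must lie in [0, 1]")
        if min(self.tremor_freq_hz, self.tremor_amplitude,
               self.base_width_noise, self.cadence_jitter,
               self.amplitude_modulation, self.cadence_wobble) < 0:
            raise ValidationError("signature rates/amplitudes must be >= 0")


def default_signature(gait_class: GaitClass, side: Side = Side.NONE,
                      ) -> GaitSignature:
    """Default kinematic signature for a gait class and affected side."""
    gait_class = GaitClass(gait_class)
    side = Side(side)
    sided = gait_class in SIDED_CLASSES
    if sided and side is Side.NONE:
        raise ValidationError(f"{gait_class.value} requires a side")
    if not sided and side is not Side.NONE:
        raise ValidationError(f"{gait_class.value} takes no affected side")

    sig = GaitSignature(
        gait_class=gait_class,
        affected_side=side,
        cadence_hz=_CADENCE_HZ[gait_class],
        speed_m_s=_SPEED_M_S[gait_class],
        step_amplitude_scale={s: 1.0 for s in SENSOR_ORDER},
    )
    if gait_class is GaitClass.WN:
        # vigorous symmetric arm swing, almost purely at stride frequency
        sig.wrist_harmonic_weights = (1.2, 0.08, 0.02)
    elif gait_class is GaitClass.WH:
        # spastic, stiff stride: little harmonic content; paretic arm still
        sig.arm_swing_asymmetry = 0.8
        sig.pelvis_gyro_asymmetry = 1.4
        sig.harmonic_weights = (1.0, 0.2, 0.08)
    elif gait_class is GaitClass.WF:
        # foot-drop compensation: pronounced second-harmonic swing bump
        sig.pelvis_gyro_asymmetry = 1.7
        sig.harmonic_weights = (0.75, 0.7, 0.2)
    elif gait_class is GaitClass.WA:
        # wide-based, irregular stepping; arms abducted for balance rather
        # than swinging rhythmically
        sig.base_width_noise = 1.2
        sig.cadence_jitter = 0.08
        sig.amplitude_modulation = 0.3
        sig.cadence_wobble = 0.15
        sig.harmonic_weights = (1.0, 0.45, 0.2)
        sig.wrist_harmonic_weights = (0.7, 0.45, 0.3)
    elif gait_class is GaitClass.WP:
        # short slow shuffling steps with hand tremor and trunk flexion
        sig.tremor_freq_hz = 5.0
        sig.tremor_amplitude = 0.5
        sig.trunk_lean_offset = 1.5
        sig.step_amplitude_scale = {s: 0.6 for s in SENSOR_ORDER}
        sig.harmonic_weights = (1.0, 0.35, 0.5)
    return sig


@dataclasses.dataclass
class CohortConfig:
    """Cohort-level acquisition protocol and noise settings."""

    n_subjects: int = 19
    repetitions_per_task: int = 4
    pre_stand_s: float = 15.0
    post_stand_s: float = 5.0
    sampling_rate_hz: float = 128.0
    seed: int = 0
    noise_sd: float = 0.02
    subject_variability_sd: float = 0.10
    path_length_m: float = _PATH_LENGTH_M

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.repetitions_per_task < 1:
            raise ValidationError("cohort counts must be positive")
        if min(self.pre_stand_s, self.post_stand_s) < 0:
            raise ValidationError("standing durations must be >= 0")
        if self.sampling_rate_hz <= 0 or self.path_length_m <= 0:
            raise ValidationError("rate and path length must be positive")
        if min(self.noise_sd, self.subject_variability_sd) < 0:
            raise ValidationError("noise levels must be >= 0")


def subject_profile(config: CohortConfig, subject_index: int) -> dict:
    """Per-subject random scales, shared across that subject's repetitions."""
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, 1, subject_index)))
    sd = config.subject_variability_sd
    return {
        "subject_id": f"subj{subject_index:02d}",
        "amp_scale": {s: float(np.exp(rng.normal(0.0, sd)))
                      for s in SENSOR_ORDER},
        "cadence_scale": float(np.exp(rng.normal(0.0, sd / 2))),
        "speed_scale": float(np.exp(rng.normal(0.0, sd / 2))),
        # small deviation from the shared biomechanical phase template
        "phase_jitter": rng.normal(0.0, 0.25, size=(45, 3)),
    }


def _phase_template() -> tuple[np.ndarray, np.ndarray]:
    """Shared per-channel phase and axis-gain template.

    Gait waveforms are biomechanically consistent across people (pelvis
    acceleration peaks at heel strike for everyone), so the per-harmonic
    phases and relative axis gains are global constants; subjects and
    repetitions only jitter around them.
    """
    rng = np.random.default_rng(np.random.SeedSequence(777))
    phases = rng.uniform(0.0, 2 * np.pi, size=(45, 3))
    gains = rng.uniform(0.8, 1.2, size=45)
    return phases, gains


_TEMPLATE_PHASES, _TEMPLATE_GAINS = _phase_template()


def _channel_plan(signature: GaitSignature, profile: dict):
    """Amplitude, harmonic weights, phase and bias per channel.

    Returns arrays of shapes (45,), (45, 3), (45, 3), (45,).  Class cues
    that survive per-channel normalization are encoded as waveform-shape
    changes: the affected-side pelvis gyroscope of a circumducting gait
    (WH, WF) shifts energy into the second harmonic (one extra swing bump
    per stride).
    """
    side = signature.affected_side
    affected_wrist = {"left": "LW", "right": "RW"}.get(side.value)
    affected_pelvis = {"left": "LP", "right": "RP"}.get(side.value)
    other_pelvis = {"LP": "RP", "RP": "LP"}.get(affected_pelvis)

    base_hw = np.asarray(signature.harmonic_weights, dtype=np.float64)
    amps = np.empty(45)
    biases = np.zeros(45)
    hweights = np.tile(base_hw, (45, 1))
    freq_mult = np.ones(45)
    i = 0
    for sensor in SENSOR_ORDER:
        kind = _SITE_KIND[sensor]
        for comp in COMPONENT_ORDER:
            base = _BASE_AMP[(kind, comp)]
            base *= signature.step_amplitude_scale.get(sensor, 1.0)
            base *= profile["amp_scale"][sensor]
            circumduction = False
            if comp != "mag":
                if sensor == affected_wrist:
                    base *= (1.0 - signature.arm_swing_asymmetry)
                if comp == "gyro" and sensor == affected_pelvis:
                    base *= signature.pelvis_gyro_asymmetry
                    circumduction = signature.pelvis_gyro_asymmetry > 1.0
                if comp == "gyro" and sensor == other_pelvis:
                    base *= 0.9
            for axis in AXES:
                axis_gain = {"x": 1.0, "y": 0.7, "z": 0.85}[axis]
                amps[i] = base * axis_gain * _TEMPLATE_GAINS[i]
                if kind == "wrist" and comp != "mag":
                    # arms swing once per stride, i.e. half the step rate
                    freq_mult[i] = 0.5
                    if signature.wrist_harmonic_weights is not None:
                        hweights[i] = signature.wrist_harmonic_weights
                if circumduction:
                    # compensatory circumduction: double-bump swing profile
                    strength = min(signature.pelvis_gyro_asymmetry - 1.0,
                                   1.0)
                    hweights[i] = (base_hw
                                   + strength * np.array([-0.5, 1.0, 0.1]))
                if comp == "acc" and axis == "z":
                    biases[i] = _GRAVITY
                if comp == "acc" and axis == "x" and sensor == "S":
                    biases[i] = signature.trunk_lean_offset
                if comp == "mag":
                    biases[i] = _MAG_FIELD[AXES.index(axis)]
                i += 1
    phases = _TEMPLATE_PHASES + profile["phase_jitter"]
    return amps, hweights, phases, biases, freq_mult


def _column(sensor: str, comp: str, axis: str) -> int:
    return (SENSOR_ORDER.index(sensor) * 9
            + COMPONENT_ORDER.index(comp) * 3 + AXES.index(axis))


_HARMONIC_WEIGHTS = np.array([1.0, 0.45, 0.2])


def simulate_repetition(signature: GaitSignature, profile: dict,
                        config: CohortConfig, seed: int,
                        repetition_index: int = 0) -> IMURecording:
    """Simulate one stand–walk–stand repetition for one subject.

    The same ``(signature, profile, config, seed)`` always produces a
    bit-identical recording.
    """
    fs = config.sampling_rate_hz
    rng = np.random.default_rng(np.random.SeedSequence((seed,)))

    speed = signature.speed_m_s * profile["speed_scale"]
    walk_s = config.path_length_m / speed
    n_pre = int(round(config.pre_stand_s * fs))
    n_walk = int(round(walk_s * fs))
    n_post = int(round(config.post_stand_s * fs))
    if n_walk < 2:
        raise ValidationError("walk duration too short for the sampling rate")
    n_total = n_pre + n_walk + n_post

    cadence = (signature.cadence_hz * profile["cadence_scale"]
               * (1.0 + rng.normal(0.0, signature.cadence_jitter)))
    cadence = max(cadence, 0.1)

    amps, hweights, phases, biases, freq_mult = _channel_plan(signature,
                                                               profile)
    phases = phases + rng.normal(0.0, 0.05, size=phases.shape)

    signal = np.zeros((n_total, 45))
    signal += biases  # gravity / trunk-lean / magnetic-field offsets

    t_walk = np.arange(n_walk) / fs
    if signature.cadence_wobble > 0:
        # ataxic timing irregularity: slowly varying instantaneous cadence
        wob = rng.normal(0.0, 1.0, size=n_walk)
        kernel = np.hanning(max(int(fs / cadence), 8))
        wob = np.convolve(wob, kernel / kernel.sum(), mode="same")
        wob /= max(np.abs(wob).max(), 1e-9)
        tau = np.cumsum(1.0 + signature.cadence_wobble * wob) / fs
    else:
        tau = t_walk
    walk = np.zeros((n_walk, 45))
    for h in range(3):
        # (n_walk, 1) phase argument broadcast against per-channel phases
        arg = (2 * np.pi * (h + 1) * cadence * freq_mult
               * tau[:, None] + phases[:, h])
        walk += hweights[:, h] * amps * np.sin(arg)

    # class modifiers -----------------------------------------------------
    if signature.amplitude_modulation > 0:
        # stride-to-stride irregularity: slow random amplitude envelope on
        # every accelerometer/gyroscope channel
        env = rng.normal(0.0, 1.0, size=n_walk)
        kernel = np.hanning(max(int(fs / cadence), 8))
        env = np.convolve(env, kernel / kernel.sum(), mode="same")
        env /= max(np.abs(env).max(), 1e-9)
        # irregular but never close to standstill mid-walk
        env = np.maximum(1.0 + signature.amplitude_modulation * env, 0.6)
        motion_cols = [_column(s, c, a) for s in SENSOR_ORDER
                       for c in ("acc", "gyro") for a in AXES]
        walk[:, motion_cols] *= env[:, None]
    if signature.tremor_amplitude > 0:
        freq = signature.tremor_freq_hz + rng.uniform(-0.5, 0.5)
        tremor = signature.tremor_amplitude * np.sin(
            2 * np.pi * freq * t_walk + rng.uniform(0, 2 * np.pi))
        for sensor in ("LW", "RW"):
            for comp in ("acc", "gyro"):
                for axis in AXES:
                    walk[:, _column(sensor, comp, axis)] += tremor
    if signature.base_width_noise > 0:
        # slow lateral sway of the pelvis: low-pass filtered random walk
        for sensor in ("LP", "RP"):
            sway = rng.normal(0.0, signature.base_width_noise, size=n_walk)
            kernel = np.hanning(int(fs / 2))
            sway = np.convolve(sway, kernel / kernel.sum(), mode="same")
            walk[:, _column(sensor, "acc", "y")] += sway * 8.0

    # slow heading drift on all magnetometers while walking
    heading = 0.1 * np.sin(2 * np.pi * 0.05 * t_walk
                           + rng.uniform(0, 2 * np.pi))
    for sensor in SENSOR_ORDER:
        for axis in ("x", "y"):
            walk[:, _column(sensor, "mag", axis)] += heading

    signal[n_pre:n_pre + n_walk] += walk

    # quiet standing: tiny postural sway on acc/gyro channels only
    sway_cols = [_column(s, c, a) for s in SENSOR_ORDER
                 for c in ("acc", "gyro") for a in AXES]
    for block in (slice(0, n_pre), slice(n_pre + n_walk, n_total)):
        n_block = block.stop - block.start
        if n_block == 0:
            continue
        t_block = np.arange(n_block) / fs
        sway = 0.05 * np.sin(2 * np.pi * 0.3 * t_block
                             + rng.uniform(0, 2 * np.pi))
        signal[block, sway_cols] += sway[:, None]

    signal += rng.normal(0.0, config.noise_sd, size=signal.shape)

    # trim half a second at each walk edge so the labelled segment excludes
    # the stand-to-walk and walk-to-stand transitions
    margin = int(round(0.5 * fs))
    walk_start = n_pre + min(margin, n_walk // 4)
    walk_end = n_pre + n_walk - min(margin, n_walk // 4)

    return IMURecording(
        subject_id=profile["subject_id"],
        gait_class=signature.gait_class,
        affected_side=signature.affected_side,
        repetition_index=repetition_index,
        signal=signal,
        segment_bounds=(walk_start, walk_end),
        sampling_rate_hz=fs,
    )


def cohort_plan(config: CohortConfig) -> list[dict]:
    """The full recording schedule implied by a cohort config.

    One entry per (subject, task variant, repetition); with the defaults of
    19 subjects and 4 repetitions per task this is 19 x 7 x 4 = 532 entries,
    28 per subject.
    """
    plan = []
    for subj in range(config.n_subjects):
        for task_idx, (gait_class, side) in enumerate(TASK_VARIANTS):
            for rep in range(config.repetitions_per_task):
                plan.append({
                    "subject_index": subj,
                    "subject_id": f"subj{subj:02d}",
                    "gait_class": gait_class,
                    "affected_side": side,
                    "task_index": task_idx,
                    "repetition_index": rep,
                })
    return plan


def _repetition_seed(config: CohortConfig, subj: int, task: int,
                     rep: int) -> int:
    ss = np.random.SeedSequence((config.seed, 2, subj, task, rep))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(config: CohortConfig) -> list[IMURecording]:
    """Simulate every repetition in the cohort plan.

    Deterministic in ``config`` (including its seed); each repetition has an
    independent random stream while subject-level scales are shared across a
    subject's repetitions.
    """
    profiles = {s: subject_profile(config, s)
                for s in range(config.n_subjects)}
    recordings = []
    for entry in cohort_plan(config):
        sig = default_signature(entry["gait_class"], entry["affected_side"])
        seed = _repetition_seed(config, entry["subject_index"],
                                entry["task_index"],
                                entry["repetition_index"])
        rep_in_task = entry["repetition_index"]
        # repetition_index unique within (subject, class+side)
        recordings.append(simulate_repetition(
            sig, profiles[entry["subject_index"]], config, seed,
            repetition_index=entry["task_index"] * config.repetitions_per_task
            + rep_in_task))
    return recordings


def write_cohort(recordings: list[IMURecording], out_dir) -> Path:
    """Write all recordings plus the manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists():
        manifest_path.unlink()
    for rec in recordings:
        name = (f"{rec.subject_id}_{rec.gait_class.value}"
                f"_{rec.affected_side.value}_{rec.repetition_index:02d}.csv")
        write_recording(rec, out_dir / name, manifest_path)
    return manifest_path
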