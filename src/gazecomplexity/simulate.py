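"""Synthetic gaze-recording cohorts for the three computer activities.

The generator emulates a desktop eye-tracker session in which each
participant reads a text, watches a video and types, one minute per task at
150 Hz.  The model is deliberately minimal but covers every channel the
feature pipeline consumes:

* gaze position is a piecewise-constant fixation process with Gaussian
  intra-fixation jitter; fixation centres move by saccade-amplitude draws
  following an activity-specific scan pattern (left-to-right staircase sweeps
  for reading, smooth pursuit-like drift for watching, alternation between a
  text zone and a keyboard zone for typing);
* pupil diameter is an activity-dependent baseline plus colored Gaussian
  noise whose spectral exponent (0 = white, 1 = 1/f) is the per-activity
  complexity knob, gated to zero during blinks;
* blinks arrive as a Poisson process and mark the validity flag, with extra
  i.i.d. validity dropout emulating tracker glitches.

Participant heterogeneity (pupil baseline offsets, timing multipliers, small
spectral-exponent jitter) is applied at the cohort level, so the same
participant keeps the same idiosyncrasies across their three tasks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ACTIVITIES, CHANNELS, GazeRecording

GAZE_PATTERNS = ("staircase_sweep", "pursuit_drift", "zone_alternation")

#: Degrees of visual angle spanned by the unit-width screen (sets the
#: conversion from saccade amplitude in degrees to normalized coordinates).
SCREEN_DEG = 30.0


@dataclass(frozen=True)
class ActivityProfile:
    """Generative parameters for one computer activity.

    Durations are in seconds, amplitudes in degrees of visual angle, blink
    rate in events per minute, pupil baselines in pixels and millimetres.
    ``pupil_noise_spectral_exponent`` is the exponent beta of the 1/f^beta
    noise added to the pupil and gaze-jitter channels: 0 gives white noise,
    1 gives 1/f noise; it is the knob that separates activities in
    complexity space.
    """

    activity_label: str
    fixation_duration_mean: float
    fixation_duration_sd: float
    saccade_amplitude_mean: float
    saccade_amplitude_sd: float
    blink_rate: float
    blink_duration_mean: float
    pupil_baseline_px: float
    pupil_baseline_mm: float
    pupil_noise_spectral_exponent: float
    gaze_pattern: str
    pupil_noise_sd_px: float = 1.8

    def __post_init__(self) -> None:
        if self.activity_label not in ACTIVITIES:
            raise ValueError(f"activity_label must be one of {ACTIVITIES}")
        if self.gaze_pattern not in GAZE_PATTERNS:
            raise ValueError(f"gaze_pattern must be one of {GAZE_PATTERNS}")
        for name in (
            "fixation_duration_mean", "fixation_duration_sd",
            "saccade_amplitude_mean", "saccade_amplitude_sd",
            "blink_rate", "blink_duration_mean",
            "pupil_baseline_px", "pupil_baseline_mm", "pupil_noise_sd_px",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.pupil_noise_spectral_exponent <= 2.0:
            raise ValueError("pupil_noise_spectral_exponent must lie in [0, 2]")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings.

    ``sampling_rate * task_duration`` must be an integer sample count; the
    seed fully determines every recording in the cohort.
    """

    n_participants: int = 30
    sampling_rate: float = 150.0
    task_duration: float = 60.0
    seed: int = 0
    validity_dropout_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.sampling_rate <= 0 or self.task_duration <= 0:
            raise ValueError("sampling_rate and task_duration must be positive")
        n = self.sampling_rate * self.task_duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sampling_rate * task_duration must be an integer")
        if not 0.0 <= self.validity_dropout_rate < 1.0:
            raise ValueError("validity_dropout_rate must lie in [0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.task_duration))


def default_profiles() -> dict[str, ActivityProfile]:
    """The three default activity profiles.

    Pupil baselines follow the pattern reported for these tasks — widest
    while watching (19.93 px), then typing (19.34 px), narrowest while
    reading (17.97 px).  Fixation, saccade and blink parameters are set to
    plausible oculomotor values for each task; the spectral exponent rises
    from reading (near-white pupil noise) through typing to watching
    (1/f-like), giving the three activities distinct multiscale-entropy
    signatures.
    """
    return {
        "reading": ActivityProfile(
            activity_label="reading",
            fixation_duration_mean=0.24,
            fixation_duration_sd=0.07,
            saccade_amplitude_mean=2.4,
            saccade_amplitude_sd=0.9,
            blink_rate=9.0,
            blink_duration_mean=0.15,
            pupil_baseline_px=17.97,
            pupil_baseline_mm=3.59,
            pupil_noise_spectral_exponent=0.15,
            gaze_pattern="staircase_sweep",
        ),
        "watching": ActivityProfile(
            activity_label="watching",
            fixation_duration_mean=0.30,
            fixation_duration_sd=0.11,
            saccade_amplitude_mean=3.6,
            saccade_amplitude_sd=1.4,
            blink_rate=7.0,
            blink_duration_mean=0.18,
            pupil_baseline_px=19.93,
            pupil_baseline_mm=3.99,
            pupil_noise_spectral_exponent=1.1,
            gaze_pattern="pursuit_drift",
        ),
        "typing": ActivityProfile(
            activity_label="typing",
            fixation_duration_mean=0.27,
            fixation_duration_sd=0.09,
            saccade_amplitude_mean=3.0,
            saccade_amplitude_sd=1.2,
            blink_rate=11.0,
            blink_duration_mean=0.12,
            pupil_baseline_px=19.34,
            pupil_baseline_mm=3.87,
            pupil_noise_spectral_exponent=0.6,
            gaze_pattern="zone_alternation",
        ),
    }


def identical_profiles(base_activity: str = "reading") -> dict[str, ActivityProfile]:
    """Clone one activity profile across all three labels.

    The degenerate cohort in which activities differ only by label: the
    null condition for separability checks, under which classifiers should
    score at chance.  Defaults to cloning the reading profile.
    """
    base = default_profiles()[base_activity]
    return {
        activity: dataclasses.replace(base, activity_label=activity)
        for activity in ACTIVITIES
    }


def colored_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with power spectrum ~ 1/f^exponent.

    Synthesized in the frequency domain by shaping the spectrum of white
    Gaussian noise; the DC component is zeroed so the sample mean is exactly
    zero.
    """
    if n < 2:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spectrum * shape, n)
    sd = shaped.std()
    if sd == 0:
        return shaped
    return shaped / sd


def _fixation_sequence(
    profile: ActivityProfile, n_samples: int, fs: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Lay out fixations and saccades for the whole task.

    Returns per-sample arrays: fixation centre x/y, elapsed-fixation-duration,
    magnitude and direction of the saccade that started the current fixation.
    """
    cx = np.empty(n_samples)
    cy = np.empty(n_samples)
    fpogd = np.empty(n_samples)
    sac_mag = np.empty(n_samples)
    sac_dir = np.empty(n_samples)

    deg2norm = 1.0 / SCREEN_DEG
    # pattern state
    x, y = 0.1, 0.15
    if profile.gaze_pattern == "pursuit_drift":
        x, y = 0.5, 0.5
        drift_angle = rng.uniform(0.0, 2 * np.pi)
    zone = 0  # typing: 0 = text area, 1 = keyboard
    last_mag, last_dir = 0.0, 0.0

    i = 0
    while i < n_samples:
        dur = max(rng.normal(profile.fixation_duration_mean, profile.fixation_duration_sd), 0.06)
        n_fix = max(int(round(dur * fs)), 1)
        stop = min(i + n_fix, n_samples)
        idx = np.arange(i, stop)
        if profile.gaze_pattern == "pursuit_drift":
            # smooth pursuit: the "fixation" centre glides at a slowly
            # re-oriented velocity instead of standing still
            drift_angle += rng.normal(0.0, 0.6)
            speed = abs(rng.normal(2.0, 0.8)) * deg2norm  # deg/s -> norm/s
            t_local = (idx - i) / fs
            seg_x = x + speed * np.cos(drift_angle) * t_local
            seg_y = y + speed * np.sin(drift_angle) * t_local
            cx[idx], cy[idx] = seg_x, seg_y
            x, y = float(seg_x[-1]), float(seg_y[-1])
            if not 0.1 < x < 0.9 or not 0.1 < y < 0.9:
                drift_angle = np.arctan2(0.5 - y, 0.5 - x) + rng.normal(0.0, 0.3)
                x, y = np.clip(x, 0.08, 0.92), np.clip(y, 0.08, 0.92)
        else:
            cx[idx], cy[idx] = x, y
        fpogd[idx] = (idx - i + 1) / fs
        sac_mag[idx] = last_mag
        sac_dir[idx] = last_dir
        i = stop

        amp = max(rng.normal(profile.saccade_amplitude_mean, profile.saccade_amplitude_sd), 0.3)
        step = amp * deg2norm
        if profile.gaze_pattern == "staircase_sweep":
            if x + step > 0.92:  # return sweep to the next line
                new_x = 0.1 + rng.normal(0.0, 0.01)
                new_y = y + 0.045
                if new_y > 0.88:
                    new_y = 0.15
                amp = np.hypot(x - new_x, y - new_y) * SCREEN_DEG
                x, y = new_x, new_y
                last_dir = 180.0 + rng.normal(0.0, 5.0)
            else:
                x += step
                y += rng.normal(0.0, 0.003)
                last_dir = rng.normal(0.0, 8.0) % 360.0
        elif profile.gaze_pattern == "zone_alternation":
            if rng.random() < 0.18:  # glance between text and keyboard
                zone = 1 - zone
                new_y = 0.75 if zone else 0.3
                amp = max(abs(new_y - y) * SCREEN_DEG, amp)
                y = new_y + rng.normal(0.0, 0.02)
                last_dir = (90.0 if zone else 270.0) + rng.normal(0.0, 10.0)
            else:
                direction = rng.uniform(0.0, 2 * np.pi)
                x = np.clip(x + step * np.cos(direction), 0.08, 0.92)
                y = np.clip(y + 0.3 * step * np.sin(direction), 0.05, 0.95)
                last_dir = np.degrees(direction) % 360.0
        else:  # pursuit_drift: occasional catch-up saccade
            direction = rng.uniform(0.0, 2 * np.pi)
            x = np.clip(x + step * np.cos(direction), 0.08, 0.92)
            y = np.clip(y + step * np.sin(direction), 0.08, 0.92)
            last_dir = np.degrees(direction) % 360.0
        last_mag = amp
    return cx, cy, fpogd, sac_mag, sac_dir


def _blink_train(
    profile: ActivityProfile, n_samples: int, fs: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Poisson blink process.

    Returns (blink mask, BKDUR channel, BKPMIN channel).  BKDUR is
    event-coded: nonzero only on the sample that ends a blink, carrying that
    blink's duration.  BKPMIN is a per-sample running rate: blink onsets in
    the trailing 10 s window, scaled to events per minute.
    """
    duration_s = n_samples / fs
    rate_per_s = profile.blink_rate / 60.0
    n_events = rng.poisson(rate_per_s * duration_s)
    onsets = np.sort(rng.uniform(0.0, duration_s, n_events))
    mask = np.zeros(n_samples, dtype=bool)
    bkdur = np.zeros(n_samples)
    kept_onsets = []
    last_end = -1.0
    for onset in onsets:
        if onset <= last_end:  # skip overlapping events
            continue
        dur = max(rng.normal(profile.blink_duration_mean, 0.3 * profile.blink_duration_mean), 0.04)
        i0 = int(onset * fs)
        i1 = min(int((onset + dur) * fs), n_samples - 1)
        if i0 >= n_samples:
            break
        mask[i0 : i1 + 1] = True
        bkdur[i1] = dur
        kept_onsets.append(onset)
        last_end = onset + dur
    # trailing-window rate: onsets in the last 10 s, scaled to events/min
    window_s = 10.0
    t = np.arange(1, n_samples + 1) / fs
    onset_arr = np.asarray(kept_onsets)
    in_window = (
        np.searchsorted(onset_arr, t, side="right")
        - np.searchsorted(onset_arr, t - window_s, side="right")
    )
    bkpmin = in_window * 60.0 / np.minimum(t, window_s)
    return mask, bkdur, bkpmin


def simulate_recording(
    profile: ActivityProfile,
    config: SimConfig,
    participant_id: str,
    seed: int | np.random.SeedSequence,
) -> GazeRecording:
    """Simulate one participant x activity task.

    The same (profile, config, seed) triple always produces bit-identical
    channel arrays.  During blinks the four pupil-size channels are zeroed
    and VALID is 0; extra i.i.d. dropout at ``config.validity_dropout_rate``
    clears VALID without touching the signal values.
    """
    rng = np.random.default_rng(seed)
    n = config.n_samples
    fs = config.sampling_rate
    beta = profile.pupil_noise_spectral_exponent

    cx, cy, fpogd, sac_mag, sac_dir = _fixation_sequence(profile, n, fs, rng)
    jitter_scale = 0.004
    fpogx = np.clip(cx + jitter_scale * colored_noise(n, beta, rng), 0.0, 1.0)
    fpogy = np.clip(cy + jitter_scale * colored_noise(n, beta, rng), 0.0, 1.0)

    e_left = colored_noise(n, beta, rng)
    e_right = colored_noise(n, beta, rng)
    lpd = profile.pupil_baseline_px + profile.pupil_noise_sd_px * e_left
    rpd = profile.pupil_baseline_px + profile.pupil_noise_sd_px * (
        0.8 * e_left + 0.6 * e_right
    )
    px_per_mm = profile.pupil_baseline_px / profile.pupil_baseline_mm
    lpmm = profile.pupil_baseline_mm + (lpd - profile.pupil_baseline_px) / px_per_mm \
        + 0.02 * colored_noise(n, beta, rng)
    rpmm = profile.pupil_baseline_mm + (rpd - profile.pupil_baseline_px) / px_per_mm \
        + 0.02 * colored_noise(n, beta, rng)

    lpcx = 0.42 + 0.05 * (fpogx - 0.5) + 0.012 * colored_noise(n, beta, rng)
    lpcy = 0.5 + 0.05 * (fpogy - 0.5) + 0.012 * colored_noise(n, beta, rng)

    blink_mask, bkdur, bkpmin = _blink_train(profile, n, fs, rng)
    for arr in (lpd, rpd, lpmm, rpmm):
        arr[blink_mask] = 0.0
        np.clip(arr, 0.0, None, out=arr)

    valid = np.ones(n, dtype=int)
    valid[blink_mask] = 0
    if config.validity_dropout_rate > 0:
        valid[rng.random(n) < config.validity_dropout_rate] = 0

    data = pd.DataFrame(
        {
            "FPOGX": fpogx, "FPOGY": fpogy, "FPOGD": fpogd,
            "LPD": lpd, "LPMM": lpmm, "RPD": rpd, "RPMM": rpmm,
            "LPCX": lpcx, "LPCY": lpcy,
            "BKDUR": bkdur, "BKPMIN": bkpmin,
            "SAC_MAG": sac_mag, "SAC_DIR": sac_dir,
            "VALID": valid,
        },
        columns=list(CHANNELS),
    )
    return GazeRecording(
        participant_id=participant_id,
        activity_label=profile.activity_label,
        sampling_rate=fs,
        data=data,
    )


def _participant_profile(
    base: ActivityProfile, rng: np.random.Generator
) -> ActivityProfile:
    """Apply one participant's idiosyncrasies to an activity profile.

    The draws come from a participant-specific stream, so a participant's
    pupil offset, timing multiplier and exponent jitter are identical across
    their three activities (a random participant effect).
    """
    pupil_offset = rng.normal(0.0, 1.3)
    timing = float(np.exp(rng.normal(0.0, 0.15)))
    blink_mult = float(np.exp(rng.normal(0.0, 0.3)))
    beta_jitter = rng.normal(0.0, 0.05)
    return dataclasses.replace(
        base,
        fixation_duration_mean=base.fixation_duration_mean * timing,
        saccade_amplitude_mean=base.saccade_amplitude_mean * timing,
        blink_rate=base.blink_rate * blink_mult,
        pupil_baseline_px=max(base.pupil_baseline_px + pupil_offset, 1.0),
        pupil_baseline_mm=max(base.pupil_baseline_mm + pupil_offset / 5.0, 0.5),
        pupil_noise_spectral_exponent=float(
            np.clip(base.pupil_noise_spectral_exponent + beta_jitter, 0.0, 2.0)
        ),
    )


def simulate_cohort(
    config: SimConfig,
    profiles: dict[str, ActivityProfile] | None = None,
    participant_effects: bool = True,
) -> list[GazeRecording]:
    """Simulate a full cohort: every participant performs all three tasks.

    Returns ``3 * config.n_participants`` recordings with participant ids
    ``P001`` .. ``P<n>`` shared across each participant's activities.  With
    ``participant_effects=False`` all participants use the base profiles
    unchanged (useful for isolating activity effects).
    """
    if profiles is None:
        profiles = default_profiles()
    recordings: list[GazeRecording] = []
    for p in range(config.n_participants):
        pid = f"P{p + 1:03d}"
        for a, activity in enumerate(ACTIVITIES):
            base = profiles[activity]
            if participant_effects:
                # the participant stream is re-created per activity from the
                # same seed, so one participant gets identical idiosyncrasy
                # draws in all three tasks
                profile = _participant_profile(base, np.random.default_rng(
                    np.random.SeedSequence((config.seed, p, 10_000))
                ))
            else:
                profile = base
            task_seed = np.random.SeedSequence((config.seed, p, a))
            recordings.append(simulate_recording(profile, config, pid, task_seed))
    return recordings
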