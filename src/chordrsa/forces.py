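"""Isometric force-trace simulation for chord trials.

Each trial is a 5-channel force time series sampled at ``sampling_hz``.
Instructed fingers ramp from the 0.5 N baseline to a 2.5 N plateau via a
smooth 300 ms rise and back; noninstructed fingers stay
at baseline but receive coupled force proportional to the summed
enslavement from the instructed fingers.  All channels are floored at
0 N (the sensors cannot report negative force).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .designs import ChordConfig

BASELINE_N = 0.5
TARGET_N = 2.5
RAMP_S = 0.3  # logistic rise time constant of the press


@dataclass(frozen=True)
class SkillParams:
    """Behavioural parameters of a simulated participant.

    press_gain
        fraction of the 2 N press amplitude actually produced (1 = exact).
    enslavement_gain
        coupling strength mapping instructed drive onto noninstructed
        fingers through an enslavement matrix (dimensionless).
    noise_sd
        white force noise per sample, in newtons.
    learning_rate
        per-completed-block multiplicative decay of noise_sd and
        enslavement_gain (1 = no learning).
    """

    press_gain: float = 1.0
    enslavement_gain: float = 0.0
    noise_sd: float = 0.0
    learning_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in [0, 1]")

    def after_blocks(self, n_completed: int) -> "SkillParams":
        """Skill after ``n_completed`` blocks of practice: error
        amplitude (noise and coupling) decays multiplicatively."""
        decay = self.learning_rate**n_completed
        return replace(
            self,
            noise_sd=self.noise_sd * decay,
            enslavement_gain=self.enslavement_gain * decay,
        )


@dataclass
class ForceTrial:
    """Uniformly sampled 5-channel force trace plus design metadata."""

    config: ChordConfig
    forces: np.ndarray  # (n_samples, 5), newtons
    sampling_hz: float
    run: int = 0
    block: int = 0

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.forces.shape[0]) / self.sampling_hz

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.forces, columns=[f"f{i}" for i in range(1, 6)])
        df.insert(0, "time_s", self.time_s)
        return df


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _press_profile(t: np.ndarray, t_on: float, t_off: float) -> np.ndarray:
    """Smooth 0->1->0 profile: cubic smoothstep rise over RAMP_S at
    t_on, matching fall at t_off.  Unlike a logistic, the profile
    reaches the plateau exactly, so commanded plateau forces are exact."""
    rise = _smoothstep((t - t_on) / RAMP_S)
    fall = _smoothstep((t - t_off) / RAMP_S)
    return rise - fall


def simulate_force_trial(
    config: ChordConfig,
    skill: SkillParams,
    enslavement: np.ndarray | None = None,
    sampling_hz: float = 100.0,
    duration_s: float = 2.3,
    press_onset_s: float = 0.6,
    press_offset_s: float = 1.7,
    seed: int | np.random.Generator = 0,
    run: int = 0,
    block: int = 0,
) -> ForceTrial:
    """Simulate one chord trial.

    With ``noise_sd == 0`` and ``enslavement_gain == 0`` the instructed
    channels ramp from 0.5 N to a 2.5 N plateau and back while the
    noninstructed channels hold 0.5 N.  With positive coupling,
    noninstructed finger ``f`` receives additional plateau force
    ``enslavement_gain * sum_g E[g, f]`` over the instructed fingers
    ``g``, shaped by the same press profile.

    Deterministic for a fixed integer ``seed``.
    """
    if sampling_hz <= 0:
        raise ValueError("sampling_hz must be positive")
    if not isinstance(config, ChordConfig):
        config = ChordConfig(str(config))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = int(round(duration_s * sampling_hz)) + 1
    t = np.arange(n) / sampling_hz
    profile = _press_profile(t, press_onset_s, press_offset_s)

    forces = np.full((n, 5), BASELINE_N)
    amp = skill.press_gain * (TARGET_N - BASELINE_N)
    for f in config.instructed:
        forces[:, f - 1] += amp * profile

    if skill.enslavement_gain > 0:
        if enslavement is None:
            raise ValueError("enslavement matrix required when enslavement_gain > 0")
        E = np.asarray(enslavement, dtype=float)
        if E.shape != (5, 5):
            raise ValueError("enslavement matrix must be 5x5")
        for f in config.noninstructed:
            drive = sum(E[g - 1, f - 1] for g in config.instructed)
            forces[:, f - 1] += skill.enslavement_gain * drive * profile

    if skill.noise_sd > 0:
        forces = forces + rng.normal(0.0, skill.noise_sd, size=forces.shape)

    np.clip(forces, 0.0, None, out=forces)  # physical floor
    return ForceTrial(config=config, forces=forces, sampling_hz=sampling_hz, run=run, block=block)
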