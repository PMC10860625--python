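"""Session designs for the multi-finger chord task.

A *chord* is a simultaneous isometric press of three of the five fingers
(1 thumb … 5 little finger) to a 2.5 N target while the remaining two
fingers hold a 0.5 N baseline.  Two session layouts are modelled:

* a self-paced *training* session, where each block cycles through the
  configurations with a fixed number of repetitions each, and
* a timed *scanner* session, where each configuration block consists of
  ``trials_per_block`` back-to-back trials and is repeated
  ``blocks_per_config`` times per run.  With the default parameters
  (5 configurations x 3 blocks x 3 trials, 2.3 s trials) a run contains
  45 trials arranged in 6.9 s blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FINGERS = frozenset({1, 2, 3, 4, 5})

#: configurations used in the scanner session (easy -> difficult)
SCANNER_CONFIGS = ("145", "234", "134", "125", "235")
#: configurations used in the training session
TRAINING_CONFIGS = ("345", "123", "124", "245", "135")


class DesignOverflowError(ValueError):
    """Raised when a design does not fit in the available scan time."""


@dataclass(frozen=True)
class ChordConfig:
    """A three-finger chord, e.g. ``"145"`` = thumb + ring + little."""

    label: str

    def __post_init__(self) -> None:
        if len(self.label) != 3 or len(set(self.label)) != 3:
            raise ValueError(f"chord label must be 3 distinct digits, got {self.label!r}")
        digits = {int(c) for c in self.label}
        if not digits <= FINGERS:
            raise ValueError(f"chord digits must be in 1..5, got {self.label!r}")

    @property
    def instructed(self) -> frozenset[int]:
        return frozenset(int(c) for c in self.label)

    @property
    def noninstructed(self) -> frozenset[int]:
        return FINGERS - self.instructed


@dataclass(frozen=True)
class Trial:
    run: int
    block: int
    config: ChordConfig
    onset_s: float
    instruction_s: float
    response_window_s: float


@dataclass
class SessionDesign:
    session_kind: str  # "training" | "scanner"
    configs: list[ChordConfig]
    trials: list[Trial]
    tr_s: float
    n_volumes_per_run: int
    n_runs: int = 1
    meta: dict = field(default_factory=dict)

    def trials_in_run(self, run: int) -> list[Trial]:
        return [t for t in self.trials if t.run == run]

    def to_frame(self) -> pd.DataFrame:
        """One row per trial: run, block, config label, onset, windows."""
        return pd.DataFrame(
            {
                "run": [t.run for t in self.trials],
                "block": [t.block for t in self.trials],
                "config": [t.config.label for t in self.trials],
                "onset_s": [t.onset_s for t in self.trials],
                "instruction_s": [t.instruction_s for t in self.trials],
                "response_window_s": [t.response_window_s for t in self.trials],
            }
        )


def _as_configs(configs) -> list[ChordConfig]:
    out = []
    for c in configs:
        out.append(c if isinstance(c, ChordConfig) else ChordConfig(str(c)))
    if not out:
        raise ValueError("configs must be nonempty")
    return out


def build_scanner_design(
    n_runs: int = 4,
    configs=SCANNER_CONFIGS,
    blocks_per_config: int = 3,
    trials_per_block: int = 3,
    instruction_s: float = 1.3,
    trial_s: float = 2.3,
    tr_s: float = 1.5,
    n_volumes: int = 141,
    inter_block_s: float = 6.0,
    lead_in_s: float = 6.0,
    seed: int | None = 0,
) -> SessionDesign:
    """Timed scanner design: per run, each config block repeated
    ``blocks_per_config`` times with ``trials_per_block`` back-to-back
    trials of ``trial_s`` seconds.  Block order is randomised per run
    under ``seed``.

    Raises
    ------
    DesignOverflowError
        if the blocks plus rests do not fit in ``n_volumes * tr_s``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if min(instruction_s, trial_s, tr_s) <= 0:
        raise ValueError("durations must be positive")
    cfgs = _as_configs(configs)
    rng = np.random.default_rng(seed)

    block_s = trials_per_block * trial_s
    n_blocks = len(cfgs) * blocks_per_config
    total_s = lead_in_s + n_blocks * block_s + (n_blocks - 1) * inter_block_s
    run_s = n_volumes * tr_s
    if total_s > run_s:
        raise DesignOverflowError(
            f"design needs {total_s:.1f}s but the run is {run_s:.1f}s "
            f"({n_volumes} volumes x {tr_s}s)"
        )

    trials: list[Trial] = []
    for run in range(n_runs):
        order = np.repeat(np.arange(len(cfgs)), blocks_per_config)
        rng.shuffle(order)
        t = lead_in_s
        for block_idx, cfg_idx in enumerate(order):
            for k in range(trials_per_block):
                trials.append(
                    Trial(
                        run=run,
                        block=block_idx,
                        config=cfgs[cfg_idx],
                        onset_s=t + k * trial_s,
                        instruction_s=instruction_s,
                        response_window_s=trial_s,
                    )
                )
            t += block_s + inter_block_s

    return SessionDesign(
        session_kind="scanner",
        configs=cfgs,
        trials=trials,
        tr_s=tr_s,
        n_volumes_per_run=n_volumes,
        n_runs=n_runs,
        meta={
            "blocks_per_config": blocks_per_config,
            "trials_per_block": trials_per_block,
            "block_s": block_s,
            "seed": seed,
        },
    )


def build_training_design(
    n_blocks: int = 6,
    configs=TRAINING_CONFIGS,
    reps_per_config: int = 4,
    instruction_s: float = 3.0,
    nominal_trial_s: float = 4.0,
    seed: int | None = 0,
) -> SessionDesign:
    """Self-paced training design: per block each config appears
    ``reps_per_config`` times in randomised order.  Onsets are nominal
    (the session is self-paced and untimed)."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    cfgs = _as_configs(configs)
    rng = np.random.default_rng(seed)

    trials: list[Trial] = []
    t = 0.0
    for block in range(n_blocks):
        order = np.repeat(np.arange(len(cfgs)), reps_per_config)
        rng.shuffle(order)
        for cfg_idx in order:
            trials.append(
                Trial(
                    run=0,
                    block=block,
                    config=cfgs[cfg_idx],
                    onset_s=t,
                    instruction_s=instruction_s,
                    response_window_s=nominal_trial_s,
                )
            )
            t += nominal_trial_s

    return SessionDesign(
        session_kind="training",
        configs=cfgs,
        trials=trials,
        tr_s=float("nan"),
        n_volumes_per_run=0,
        n_runs=1,
        meta={"reps_per_config": reps_per_config, "seed": seed},
    )
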