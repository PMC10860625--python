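"""Trial scoring: response onset, release, and the deviance statistic.

Deviance quantifies how far the five-finger force pattern is from the
instructed chord between response onset and release: the summed absolute
deviation of the noninstructed fingers from the 0.5 N baseline plus the
summed absolute deviation of each instructed finger from the
instructed-finger mean force, averaged over time.  Lower is better; a
perfect trial scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forces import BASELINE_N, ForceTrial

ONSET_THRESHOLD_N = 1.5
RELEASE_EPS_N = 0.1


@dataclass
class DevianceRecord:
    trial_id: int
    run: int
    block: int
    config: str
    onset_idx: int
    release_idx: int
    deviance: float
    valid: bool


def detect_response_onset(trial: ForceTrial, threshold_n: float = ONSET_THRESHOLD_N) -> int | None:
    """First sample at which any channel reaches ``threshold_n``
    (default 1.5 N); ``None`` if no channel ever crosses (no-response
    trial, to be marked invalid rather than raised)."""
    if trial.forces.shape[0] == 0:
        raise ValueError("empty trial")
    hits = np.flatnonzero((trial.forces >= threshold_n).any(axis=1))
    return int(hits[0]) if hits.size else None


def detect_release(
    trial: ForceTrial,
    onset: int,
    baseline_n: float = BASELINE_N,
    eps_n: float = RELEASE_EPS_N,
) -> int:
    """First sample after ``onset`` at which all instructed channels are
    back below ``baseline_n + eps_n``; falls back to the last sample if
    the forces are never released."""
    if onset is None or onset < 0 or onset >= trial.forces.shape[0]:
        raise ValueError("onset must be a valid sample index")
    instructed = [f - 1 for f in trial.config.instructed]
    sub = trial.forces[onset + 1 :, instructed]
    # only count release after the press has actually risen above the band
    pressed = np.flatnonzero((sub >= baseline_n + eps_n).any(axis=1))
    if pressed.size == 0:
        return trial.forces.shape[0] - 1
    start = pressed[0]
    released = np.flatnonzero((sub[start:] < baseline_n + eps_n).all(axis=1))
    if released.size == 0:
        return trial.forces.shape[0] - 1
    return int(onset + 1 + start + released[0])


def compute_deviance(
    trial: ForceTrial,
    onset: int,
    release: int,
    baseline_n: float = BASELINE_N,
    residual: str = "absolute",
) -> float:
    """Mean over samples in the inclusive window [onset, release] of

        sum_{f noninstructed} |F_f(t) - baseline|
      + sum_{f instructed}    |F_f(t) - mean_{g instructed} F_g(t)|

    ``residual="squared"`` substitutes squared deviations (selectable
    alternative; the default absolute form preserves newton units).
    """
    if onset < 0 or onset >= release:
        raise ValueError("require 0 <= onset < release")
    if release >= trial.forces.shape[0]:
        raise ValueError("release beyond trial end")
    win = trial.forces[onset : release + 1]
    instructed = sorted(f - 1 for f in trial.config.instructed)
    noninstructed = sorted(f - 1 for f in trial.config.noninstructed)
    dev_non = win[:, noninstructed] - baseline_n
    dev_ins = win[:, instructed] - win[:, instructed].mean(axis=1, keepdims=True)
    if residual == "absolute":
        per_sample = np.abs(dev_non).sum(axis=1) + np.abs(dev_ins).sum(axis=1)
    elif residual == "squared":
        per_sample = (dev_non**2).sum(axis=1) + (dev_ins**2).sum(axis=1)
    else:
        raise ValueError(f"unknown residual kind {residual!r}")
    return float(per_sample.mean())


def score_trial(trial: ForceTrial, trial_id: int = 0) -> DevianceRecord:
    """Onset detection, release detection and deviance in one pass."""
    onset = detect_response_onset(trial)
    if onset is None:
        return DevianceRecord(
            trial_id=trial_id,
            run=trial.run,
            block=trial.block,
            config=trial.config.label,
            onset_idx=-1,
            release_idx=-1,
            deviance=float("nan"),
            valid=False,
        )
    release = detect_release(trial, onset)
    if release <= onset:
        release = trial.forces.shape[0] - 1
    dev = compute_deviance(trial, onset, release)
    return DevianceRecord(
        trial_id=trial_id,
        run=trial.run,
        block=trial.block,
        config=trial.config.label,
        onset_idx=onset,
        release_idx=release,
        deviance=dev,
        valid=True,
    )


def aggregate_learning(
    records: pd.DataFrame,
    difficulty_split: dict[str, str],
    time_col: str = "block",
) -> pd.DataFrame:
    """Aggregate per-trial deviance into the learning table: one row per
    subject x ``time_col`` (block or run) x difficulty level, with the
    mean deviance over valid trials and the invalid-trial count.

    ``records`` must carry columns subject, group, ``time_col``, config,
    deviance, valid.  ``difficulty_split`` maps every config label to
    "easy" or "difficult"; a missing config raises.
    """
    records = records.copy()
    records["config"] = records["config"].astype(str)  # robust to CSV round-trip
    missing = set(records["config"]) - set(difficulty_split)
    if missing:
        raise KeyError(f"configs missing from difficulty split: {sorted(missing)}")
    if records.empty:
        return pd.DataFrame(
            columns=["subject", "group", time_col, "difficulty", "mean_deviance", "n_trials", "n_invalid"]
        )
    records["difficulty"] = records["config"].map(difficulty_split)
    grouped = records.groupby(["subject", "group", time_col, "difficulty"], observed=True)
    out = grouped.apply(
        lambda g: pd.Series(
            {
                "mean_deviance": g.loc[g["valid"], "deviance"].mean(),
                "n_trials": int(g["valid"].sum()),
                "n_invalid": int((~g["valid"]).sum()),
            }
        ),
        include_groups=False,
    ).reset_index()
    return out
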