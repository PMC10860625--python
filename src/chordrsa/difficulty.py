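"""Enslavement-based chord difficulty model.

Finger enslavement is the involuntary force a noninstructed finger
produces when another finger flexes, expressed as % of maximal voluntary
contraction.  Given a 5x5 enslavement matrix, each chord is scored by
three summed components:

* E1 — enslavement among the instructed fingers (helps: they move together),
* E2 — enslavement among the noninstructed fingers (helps: they relax together),
* E3 — enslavement between the two sets (hurts: instructed drive leaks out).

The combined score E1 + E2 - E3 ranks chords from easy (high score) to
difficult (low score).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .designs import ChordConfig


def symmetrize(E: np.ndarray) -> np.ndarray:
    """(E + E.T) / 2 with the diagonal zeroed; enslavement direction is
    not distinguished by the difficulty model."""
    E = np.asarray(E, dtype=float)
    if E.shape != (5, 5):
        raise ValueError("enslavement matrix must be 5x5")
    if (E < 0).any():
        raise ValueError("enslavement entries must be nonnegative")
    S = (E + E.T) / 2.0
    np.fill_diagonal(S, 0.0)
    return S


@dataclass(frozen=True)
class DifficultyScore:
    config: ChordConfig
    e1: float
    e2: float
    e3: float

    @property
    def score(self) -> float:
        return self.e1 + self.e2 - self.e3


def enslavement_components(E: np.ndarray, config: ChordConfig | str) -> tuple[float, float, float]:
    """(E1, E2, E3) for one chord: unordered-pair sums of the
    symmetrized matrix within instructed, within noninstructed, and
    across the two sets (each pair counted once)."""
    if not isinstance(config, ChordConfig):
        config = ChordConfig(str(config))
    S = symmetrize(E)
    ins = sorted(config.instructed)
    non = sorted(config.noninstructed)
    e1 = sum(S[a - 1, b - 1] for a, b in combinations(ins, 2))
    e2 = sum(S[a - 1, b - 1] for a, b in combinations(non, 2))
    e3 = sum(S[a - 1, b - 1] for a in ins for b in non)
    return float(e1), float(e2), float(e3)


def difficulty_score(E: np.ndarray, config: ChordConfig | str) -> DifficultyScore:
    if not isinstance(config, ChordConfig):
        config = ChordConfig(str(config))
    e1, e2, e3 = enslavement_components(E, config)
    return DifficultyScore(config=config, e1=e1, e2=e2, e3=e3)


def rank_and_split(E: np.ndarray, configs, n_easy: int) -> dict[str, str]:
    """Sort chords by score descending (ties broken lexicographically by
    label) and label the top ``n_easy`` "easy", the rest "difficult"."""
    labels = [c.label if isinstance(c, ChordConfig) else str(c) for c in configs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate config labels")
    if not 0 < n_easy < len(labels):
        raise ValueError("need 0 < n_easy < number of configs")
    scored = [(difficulty_score(E, lab).score, lab) for lab in labels]
    ordered = sorted(scored, key=lambda sl: (-sl[0], sl[1]))
    split = {}
    for rank, (_, lab) in enumerate(ordered):
        split[lab] = "easy" if rank < n_easy else "difficult"
    return split


def score_table(E: np.ndarray, configs) -> pd.DataFrame:
    """Long table of per-chord components and scores, rank 1 = easiest."""
    rows = []
    for c in configs:
        d = difficulty_score(E, c)
        rows.append({"config": d.config.label, "E1": d.e1, "E2": d.e2, "E3": d.e3, "score": d.score})
    df = pd.DataFrame(rows).sort_values(["score", "config"], ascending=[False, True], ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def synthetic_enslavement_matrix(base: float = 2.0, decay: float = 0.55, seed: int | None = None) -> np.ndarray:
    """Synthetic stand-in for a measured inter-finger enslavement matrix
    (% MVC).  Neighbouring fingers couple most strongly and coupling
    decays with anatomical distance, the dominant feature of measured
    enslavement patterns; optional multiplicative jitter under ``seed``.
    Purely synthetic — not the literature matrix, which this package
    does not ship.
    """
    idx = np.arange(5)
    dist = np.abs(idx[:, None] - idx[None, :])
    E = base * decay ** (dist - 1.0)
    np.fill_diagonal(E, 0.0)
    # the thumb is more independent than the other fingers
    E[0, :] *= 0.5
    E[:, 0] *= 0.5
    if seed is not None:
        rng = np.random.default_rng(seed)
        E = E * rng.uniform(0.8, 1.2, size=E.shape)
        E = (E + E.T) / 2.0
        np.fill_diagonal(E, 0.0)
    return E


def read_enslavement_csv(path) -> np.ndarray:
    """5x5 enslavement matrix from CSV with finger indices as header
    row and index column."""
    df = pd.read_csv(path, index_col=0)
    E = df.to_numpy(dtype=float)
    if E.shape != (5, 5):
        raise ValueError(f"expected a 5x5 matrix, got {E.shape}")
    return E


def write_enslavement_csv(E: np.ndarray, path) -> None:
    fingers = [str(i) for i in range(1, 6)]
    pd.DataFrame(np.asarray(E, dtype=float), index=fingers, columns=fingers).to_csv(path)
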