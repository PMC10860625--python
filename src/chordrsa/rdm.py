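"""Representational dissimilarity matrices (RDMs).

An RDM holds the pairwise dissimilarities among the five chord
conditions for one subject/region/hemisphere — 10 unordered pairs,
stored in scipy's condensed (``squareform``) order.  Cross-validated
distances can be negative, so no nonnegativity is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform


@dataclass
class RDM:
    labels: tuple[str, ...]
    values: np.ndarray  # condensed, length C(n, 2)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = tuple(str(c) for c in self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n * (n - 1) // 2,):
            raise ValueError(
                f"expected {n * (n - 1) // 2} condensed entries for {n} conditions, "
                f"got shape {self.values.shape}"
            )

    @property
    def n_conditions(self) -> int:
        return len(self.labels)

    def pairs(self) -> list[tuple[str, str]]:
        return list(combinations(self.labels, 2))

    def as_matrix(self) -> np.ndarray:
        """Symmetric matrix with zero diagonal."""
        return squareform(self.values, checks=False)

    def entry(self, a: str, b: str) -> float:
        a, b = str(a), str(b)
        try:
            i, j = self.labels.index(a), self.labels.index(b)
        except ValueError as exc:
            raise KeyError(f"unknown condition label in pair ({a}, {b})") from exc
        if i == j:
            return 0.0
        return float(self.as_matrix()[i, j])

    @classmethod
    def from_matrix(cls, labels, matrix, **meta) -> "RDM":
        M = np.asarray(matrix, dtype=float)
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 0.0)
        return cls(labels=tuple(labels), values=squareform(M, checks=False), meta=dict(meta))

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {"cond_i": a, "cond_j": b, "distance": v}
            for (a, b), v in zip(self.pairs(), self.values)
        ]
        df = pd.DataFrame(rows)
        for k, v in self.meta.items():
            df[k] = v
        return df

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, **meta) -> "RDM":
        labels: list[str] = []
        for a, b in zip(df["cond_i"], df["cond_j"]):
            for lab in (str(a), str(b)):
                if lab not in labels:
                    labels.append(lab)
        n = len(labels)
        M = np.zeros((n, n))
        for _, row in df.iterrows():
            i, j = labels.index(str(row["cond_i"])), labels.index(str(row["cond_j"]))
            M[i, j] = M[j, i] = row["distance"]
        return cls.from_matrix(labels, M, **meta)


def mean_rdm(rdms: list[RDM], **meta) -> RDM:
    """Entrywise mean of RDMs sharing the same condition labels."""
    if not rdms:
        raise ValueError("need at least one RDM")
    labels = rdms[0].labels
    for r in rdms[1:]:
        if r.labels != labels:
            raise ValueError("RDMs must share condition labels")
    return RDM(labels=labels, values=np.mean([r.values for r in rdms], axis=0), meta=dict(meta))
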