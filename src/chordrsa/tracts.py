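"""Interhemispheric tract microstructure summaries.

Deterministic tractography tracks a transcallosal pathway in both
directions (left->right seed and right->left seed), yielding a
streamline count and mean FA / MD per direction.  The two directions
are combined into a single streamline-count-weighted ("vertex-weighted")
mean per metric:

    vw = (N_LR * m_LR + N_RL * m_RL) / (N_LR + N_RL)

FA (fractional anisotropy) is unitless in [0, 1]; MD (mean diffusivity)
is in 1e-3 mm^2/s.  Counts may be fractional (supersampled seeding).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TractSummary:
    n_lr: float
    n_rl: float
    fa_lr: float
    fa_rl: float
    md_lr: float
    md_rl: float
    vw_fa: float | None = None
    vw_md: float | None = None
    subject: str = ""
    tract: str = ""

    def __post_init__(self) -> None:
        if self.n_lr < 0 or self.n_rl < 0:
            raise ValueError("streamline counts must be >= 0")
        if self.n_lr + self.n_rl <= 0:
            raise ValueError("at least one direction must have streamlines")
        for fa in (self.fa_lr, self.fa_rl):
            if not 0.0 <= fa <= 1.0:
                raise ValueError(f"FA must be in [0, 1], got {fa}")


def vertex_weighted_mean(n_lr: float, m_lr: float, n_rl: float, m_rl: float) -> float:
    """Streamline-count-weighted mean of a per-direction tract metric."""
    total = n_lr + n_rl
    if total <= 0:
        raise ValueError("total streamline count must be positive")
    return (n_lr * m_lr + n_rl * m_rl) / total


def summarize_tract(summary: TractSummary) -> TractSummary:
    """Fill vw_FA and vw_MD from the per-direction fields."""
    return replace(
        summary,
        vw_fa=vertex_weighted_mean(summary.n_lr, summary.fa_lr, summary.n_rl, summary.fa_rl),
        vw_md=vertex_weighted_mean(summary.n_lr, summary.md_lr, summary.n_rl, summary.md_rl),
    )


def simulate_tract_summary(
    n_lr: float,
    n_rl: float,
    fa_lr: float,
    fa_rl: float,
    md_lr: float,
    md_rl: float,
    jitter: float = 0.0,
    seed: int | np.random.Generator = 0,
    subject: str = "",
    tract: str = "",
) -> TractSummary:
    """Synthetic per-direction tract summary.  ``jitter`` applies
    multiplicative lognormal-ish noise (sd as a fraction) to every
    field under ``seed``; FA stays clipped to [0, 1] and counts to >= 0.
    Deterministic given the seed; jitter 0 stores the inputs verbatim.
    """
    if n_lr < 0 or n_rl < 0 or n_lr + n_rl <= 0:
        raise ValueError("counts must be >= 0 and not both zero")
    for fa in (fa_lr, fa_rl):
        if not 0.0 <= fa <= 1.0:
            raise ValueError(f"FA must be in [0, 1], got {fa}")
    vals = np.array([n_lr, n_rl, fa_lr, fa_rl, md_lr, md_rl], dtype=float)
    if jitter > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        vals = vals * np.exp(rng.normal(0.0, jitter, size=vals.shape))
        vals[2:4] = np.clip(vals[2:4], 0.0, 1.0)
        vals[:2] = np.maximum(vals[:2], 1e-9)
    return TractSummary(
        n_lr=float(vals[0]),
        n_rl=float(vals[1]),
        fa_lr=float(vals[2]),
        fa_rl=float(vals[3]),
        md_lr=float(vals[4]),
        md_rl=float(vals[5]),
        subject=subject,
        tract=tract,
    )


def tract_table(summaries: list[TractSummary]) -> pd.DataFrame:
    """CSV-ready table; fills vw columns where missing."""
    rows = []
    for s in summaries:
        if s.vw_fa is None:
            s = summarize_tract(s)
        rows.append(
            {
                "subject": s.subject,
                "tract": s.tract,
                "N_LR": s.n_lr,
                "N_RL": s.n_rl,
                "FA_LR": s.fa_lr,
                "FA_RL": s.fa_rl,
                "MD_LR": s.md_lr,
                "MD_RL": s.md_rl,
                "vw_FA": s.vw_fa,
                "vw_MD": s.vw_md,
            }
        )
    return pd.DataFrame(rows)
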