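"""Behavioural learning analysis.

Aggregates trial deviance into the first/last x easy/difficult learning
tables for both sessions and runs the three-way repeated-measures
ANCOVA (group x phase x difficulty, age covariate) with
Bonferroni-flagged group contrasts, mirroring how intact-hand motor
learning is compared across groups.
"""

from pathlib import Path

import pandas as pd

from chordrsa.designs import SCANNER_CONFIGS, TRAINING_CONFIGS
from chordrsa.difficulty import rank_and_split, synthetic_enslavement_matrix
from chordrsa.pipeline import learning_tables
from chordrsa.stats import adjusted_contrasts, format_effect, rm_ancova

OUT = Path("results")
trials = pd.read_csv(OUT / "trials.csv")
subjects = pd.read_csv(OUT / "subjects.csv")

split = rank_and_split(synthetic_enslavement_matrix(), TRAINING_CONFIGS + SCANNER_CONFIGS, n_easy=5)
train_table, scan_table = learning_tables(trials, subjects, split)
train_table.to_csv(OUT / "learning_training.csv", index=False)
scan_table.to_csv(OUT / "learning_scanner.csv", index=False)

for name, table in (("training", train_table), ("scanner", scan_table)):
    fit = rm_ancova(table, "mean_deviance", within=["phase", "difficulty"], covariate="age")
    print(f"--- {name} session deviance (rmANCOVA, age-adjusted) ---")
    for _, row in fit.effects.iterrows():
        print(f"  {row['effect']}: {format_effect(row)}")
    contr = adjusted_contrasts(fit)
    print("  group contrasts (Bonferroni-adjusted alpha "
          f"{contr['adjusted_alpha'].iloc[0]:.4f}):")
    for _, c in contr.iterrows():
        print(f"    {c['contrast']}: t({c['df']:.0f}) = {c['t']:.2f}; p = {c['p']:.3f}")
    contr.to_csv(OUT / f"contrasts_{name}.csv", index=False)
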