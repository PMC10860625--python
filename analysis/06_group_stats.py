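"""Group-level inference over all pipeline outputs.

Runs the covariate-adjusted repeated-measures ANCOVAs (behaviour,
mean distances, homotopy, typicality, tract metrics), one-sample t
tests against zero for information content and the RDM correlations,
and the Freedman-Lane permutation test for the group effect on
homotopy.  Writes the long-format stats tables under results/.
"""

from pathlib import Path

import pandas as pd

from chordrsa.pipeline import default_config, run_stats

OUT = Path("results")
cfg = default_config()

train_table = pd.read_csv(OUT / "learning_training.csv")
scan_table = pd.read_csv(OUT / "learning_scanner.csv")
distances = pd.read_csv(OUT / "distances.csv")
comparisons = pd.read_csv(OUT / "comparisons.csv")
tracts = pd.read_csv(OUT / "tracts.csv")

effects, t_tests, contrasts, lines = run_stats(
    train_table, scan_table, distances, comparisons, tracts,
    n_perm=int(cfg["stats"]["n_perm"]), master_seed=int(cfg["seed"]),
)
effects.to_csv(OUT / "stats_effects.csv", index=False)
t_tests.to_csv(OUT / "stats_t_tests.csv", index=False)
contrasts.to_csv(OUT / "stats_contrasts.csv", index=False)

print("\n".join(lines))
print("\none-sample t tests vs zero:")
for _, r in t_tests.iterrows():
    print(f"  {r['analysis']} | {r['group']} {r['hemisphere']}: "
          f"t({r['df']:.0f}) = {r['t']:.2f}; p = {r['p']:.4f}")
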