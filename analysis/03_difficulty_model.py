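"""Enslavement-based chord difficulty model.

Scores all C(5,3) = 10 three-finger chords from the synthetic
enslavement matrix via the E1 + E2 - E3 combination (within-instructed
plus within-noninstructed minus across-set enslavement; higher = easier)
and splits them into easy/difficult halves.
"""

from itertools import combinations
from pathlib import Path

from chordrsa.difficulty import (
    rank_and_split,
    score_table,
    synthetic_enslavement_matrix,
    write_enslavement_csv,
)

OUT = Path("results")
OUT.mkdir(exist_ok=True)

E = synthetic_enslavement_matrix()
write_enslavement_csv(E, OUT / "enslavement_matrix_synthetic.csv")

chords = ["".join(map(str, c)) for c in combinations(range(1, 6), 3)]
table = score_table(E, chords)
table.to_csv(OUT / "difficulty_scores.csv", index=False)
split = rank_and_split(E, chords, n_easy=5)

print("chord difficulty (score = E1 + E2 - E3, higher = easier):")
print(table.round(3).to_string(index=False))
easy = sorted(k for k, v in split.items() if v == "easy")
hard = sorted(k for k, v in split.items() if v == "difficult")
print(f"easy half:      {', '.join(easy)}")
print(f"difficult half: {', '.join(hard)}")
print("(split derives from the synthetic fixture matrix; supply a measured "
      "enslavement matrix CSV to reproduce a published ranking)")
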