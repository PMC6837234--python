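"""Cognate-class coding of grandfather terms.

Builds a tiny word list (Swedish farfar/morfar, Polish dziadek, English
grandfather), clusters the forms by normalized edit distance at the 0.4
threshold, and converts the resulting classes into a multistate character.
"""
import pandas as pd

import kinrates as kr

table = kr.WordFormTable(
    pd.DataFrame(
        [
            ("Swedish", "FF", "farfar"),
            ("Polish", "FF", "dziadek"),
            ("English", "FF", "grandfather"),
            ("Swedish", "MF", "morfar"),
            ("Polish", "MF", "dziadek"),
            ("English", "MF", "grandfather"),
        ],
        columns=["language", "meaning", "form"],
    )
)

print("pairwise normalized edit distances (FF+MF forms):")
dm = kr.distance_matrix(
    {"farfar": "farfar", "morfar": "morfar", "dziadek": "dziadek",
     "grandfather": "grandfather"}
)
for i, a in enumerate(dm.labels):
    for j, b in enumerate(dm.labels):
        if i < j:
            print(f"  d({a}, {b}) = {dm.values[i, j]:.3f}")

part = kr.flat_cluster(dm, 0.4)
print("\ncognate classes at threshold 0.4:")
for cls, members in part.classes().items():
    print(f"  class {cls}: {[form for _, form in members]}")

# Values below 0.4 (farfar~morfar at 0.333) merge into one ancestral class;
# everything else stays separate - three classes for the grandfather meaning.

for meaning in ("FF", "MF"):
    p = kr.partition_meaning(table, meaning)
    char = kr.build_character(p, ["English", "Polish", "Swedish"])
    print(f"\n{meaning} character (k={char.k} classes):", char.states)
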