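"""Shared domain types for the kinship-term replacement pipeline.

The study design couples three kinds of data: word-form tables (which word a
language uses for a kin category), dated phylogenies of the languages, and
corpus frequency counts. The types here are thin, validated containers around
pandas/dendropy objects; heavy computation lives in the sibling modules.
"""
from __future__ import annotations

import dataclasses
from typing import Optional

import dendropy
import pandas as pd

#: The ten consanguineal kin categories of the study. Codes read left-to-right
#: through the genealogy: B brother, D daughter, F father, M mother,
#: MB mother's brother, MZ mother's sister, MZD mother's sister's daughter,
#: MZS mother's sister's son, S son, Z sister.
KIN_TYPES: tuple[str, ...] = ("B", "D", "F", "M", "MB", "MZ", "MZD", "MZS", "S", "Z")

KIN_GLOSSES: dict[str, str] = {
    "B": "brother",
    "D": "daughter",
    "F": "father",
    "M": "mother",
    "MB": "maternal uncle",
    "MZ": "maternal aunt",
    "MZD": "maternal aunt's daughter",
    "MZS": "maternal aunt's son",
    "S": "son",
    "Z": "sister",
}

LEXICAL_CLASSES = ("kin", "swadesh")
CORPUS_TYPES = ("spoken", "written", "web")

#: State symbols used in NEXUS multistate matrices: 0-9A-Z plus eleven
#: non-reserved punctuation symbols, so up to 47 cognate classes per meaning
#: (NEXUS symbols are case-insensitive, which rules out lowercase letters).
STATE_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ!@#$%^&.|_~"
MISSING_STATE = "?"


class ValidationError(ValueError):
    """Input violates a type invariant; message carries row/line locations."""


class FormatError(ValueError):
    """Input file is structurally malformed (missing columns, bad dialect)."""


@dataclasses.dataclass(frozen=True)
class KinType:
    """One kin category: a closed-set code plus a human-readable gloss."""

    code: str
    gloss: str = ""

    def __post_init__(self) -> None:
        if self.code not in KIN_TYPES:
            raise ValidationError(
                f"kin-type code {self.code!r} not in the ten-category set {KIN_TYPES}"
            )
        if not self.gloss:
            object.__setattr__(self, "gloss", KIN_GLOSSES[self.code])


@dataclasses.dataclass
class WordFormTable:
    """Word forms keyed by language x meaning.

    ``data`` columns: language, meaning, form, transcription (optional,
    may be NA), lexical_class in {kin, swadesh}. The (language, meaning, form)
    triple is unique.
    """

    data: pd.DataFrame

    REQUIRED = ("language", "meaning", "form")

    def __post_init__(self) -> None:
        df = self.data
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"word list missing required column {col!r}")
        if "lexical_class" not in df.columns:
            df = df.assign(lexical_class="kin")
        if "transcription" not in df.columns:
            df = df.assign(transcription=pd.NA)
        df = df.reset_index(drop=True)
        bad_class = ~df["lexical_class"].isin(LEXICAL_CLASSES)
        if bad_class.any():
            rows = (df.index[bad_class] + 2).tolist()
            raise ValidationError(
                f"lexical_class must be one of {LEXICAL_CLASSES}; bad rows (line numbers): {rows}"
            )
        empty = df["form"].isna() | (df["form"].astype(str).str.strip() == "")
        if empty.any():
            rows = (df.index[empty] + 2).tolist()
            raise ValidationError(f"empty word forms at lines {rows}")
        dup = df.duplicated(subset=["language", "meaning", "form"], keep=False)
        if dup.any():
            rows = (df.index[df.duplicated(subset=["language", "meaning", "form"])] + 2).tolist()
            raise ValidationError(
                f"duplicate (language, meaning, form) triples at lines {rows}"
            )
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def languages(self) -> list[str]:
        return sorted(self.data["language"].unique())

    @property
    def meanings(self) -> list[str]:
        return sorted(self.data["meaning"].unique())

    def for_meaning(self, meaning: str) -> pd.DataFrame:
        return self.data[self.data["meaning"] == meaning]


@dataclasses.dataclass
class TreeSample:
    """An ordered sample of rooted, dated phylogenies over a shared label set.

    Branch lengths are in years throughout; unit conversion to per-10-kyr
    happens only inside rate reporting.
    """

    trees: list[dendropy.Tree]

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValidationError("tree sample is empty")
        for i, t in enumerate(self.trees):
            validate_phylogeny(t, where=f"tree {i}")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> dendropy.Tree:
        return self.trees[i]

    @property
    def label_universe(self) -> set[str]:
        out: set[str] = set()
        for t in self.trees:
            out |= {leaf.taxon.label for leaf in t.leaf_node_iter()}
        return out


def validate_phylogeny(tree: dendropy.Tree, where: str = "tree") -> None:
    """Check the rooted-dated-tree invariants: one root, unique leaf labels,
    finite non-negative branch lengths."""
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        seen, dups = set(), set()
        for lb in labels:
            (dups if lb in seen else seen).add(lb)
        raise ValidationError(f"{where}: duplicate leaf labels {sorted(dups)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        bl = edge.length
        if bl is None:
            continue  # zero-length root edge conventions vary
        if not (bl == bl) or bl == float("inf"):
            raise ValidationError(f"{where}: non-finite branch length")
        if bl < 0:
            raise ValidationError(f"{where}: negative branch length {bl}")


@dataclasses.dataclass
class MultistateCharacter:
    """One meaning's cognate-class character: taxon -> dense state index.

    ``states`` maps taxon label to an int in 0..k-1 or to None for missing
    ('?'). States are dense: every index in 0..k-1 occurs for at least one
    taxon unless k == 0.
    """

    meaning: str
    states: dict[str, Optional[int]]

    def __post_init__(self) -> None:
        bad = {s for s in self.states.values() if s is not None and s < 0}
        if bad:
            raise ValidationError(
                f"character {self.meaning!r}: negative states {sorted(bad)}"
            )

    @property
    def is_dense(self) -> bool:
        """True when the observed states are exactly 0..k-1 (as produced by
        the cognate-coding builders)."""
        observed = sorted({s for s in self.states.values() if s is not None})
        return observed == list(range(len(observed)))

    @property
    def k(self) -> int:
        vals = [s for s in self.states.values() if s is not None]
        return (max(vals) + 1) if vals else 0

    @property
    def taxa(self) -> list[str]:
        return sorted(self.states)

    @property
    def observed_taxa(self) -> list[str]:
        return sorted(t for t, s in self.states.items() if s is not None)


@dataclasses.dataclass
class CorpusCounts:
    """Per-corpus occurrence counts.

    Columns: language, form, meaning, corpus_id, corpus_type in
    {spoken, written, web}, count (non-negative int), corpus_size (positive
    int tokens), with count <= corpus_size.
    """

    data: pd.DataFrame

    REQUIRED = ("language", "form", "meaning", "corpus_id", "corpus_type", "count", "corpus_size")

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"frequency table missing required column {col!r}")
        bad_type = ~df["corpus_type"].isin(CORPUS_TYPES)
        if bad_type.any():
            rows = (df.index[bad_type] + 2).tolist()
            raise ValidationError(f"corpus_type must be in {CORPUS_TYPES}; bad lines {rows}")
        if (df["corpus_size"] <= 0).any():
            rows = (df.index[df["corpus_size"] <= 0] + 2).tolist()
            raise ValidationError(f"corpus_size must be positive; bad lines {rows}")
        if (df["count"] < 0).any():
            rows = (df.index[df["count"] < 0] + 2).tolist()
            raise ValidationError(f"count must be non-negative; bad lines {rows}")
        over = df["count"] > df["corpus_size"]
        if over.any():
            rows = (df.index[over] + 2).tolist()
            raise ValidationError(f"count exceeds corpus_size at lines {rows}")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)


@dataclasses.dataclass
class OverrideTable:
    """Expert cognate-class overrides: (meaning, language, form) -> class label."""

    data: pd.DataFrame

    REQUIRED = ("meaning", "language", "form", "cognate_class")

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"override table missing required column {col!r}")
        dup = df.duplicated(subset=["meaning", "language", "form"], keep=False)
        if dup.any():
            keys = df.loc[dup, ["meaning", "language", "form"]].drop_duplicates()
            raise ValidationError(
                "duplicate override keys: "
                + "; ".join("/".join(map(str, r)) for r in keys.itertuples(index=False))
            )
        self.data = df

    def __len__(self) -> int:
        return len(self.data)
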