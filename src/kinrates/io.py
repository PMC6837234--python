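"""Readers and writers for word lists, tree samples, frequency tables,
override files and NEXUS multistate character matrices.

All delimited inputs are UTF-8 CSV with a header row; trees are Newick or
NEXUS (translate blocks handled by dendropy). Validation failures raise
:class:`~kinrates.types.ValidationError` / :class:`~kinrates.types.FormatError`
with line locations so that bad rows can be found in the source file.
"""
from __future__ import annotations

import logging
import re
import unicodedata
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy
import pandas as pd

from .types import (
    CorpusCounts,
    FormatError,
    MISSING_STATE,
    MultistateCharacter,
    OverrideTable,
    STATE_SYMBOLS,
    TreeSample,
    ValidationError,
    WordFormTable,
    validate_phylogeny,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_wordlist(path: PathLike) -> WordFormTable:
    """Read a word-form table from CSV.

    The header must name at least ``language``, ``meaning`` and ``form``;
    optional columns ``transcription`` and ``lexical_class`` are carried
    through (``lexical_class`` defaults to ``kin``).
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file has no header row")
    return WordFormTable(df)


def write_wordlist(table: WordFormTable, path: PathLike) -> None:
    table.data.to_csv(path, index=False)


def read_frequency_table(path: PathLike) -> CorpusCounts:
    """Read corpus counts from CSV; counts and corpus sizes are integers."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    for col in ("count", "corpus_size"):
        if col in df.columns:
            try:
                df[col] = df[col].astype("int64")
            except ValueError as e:
                raise FormatError(f"{path}: non-integer {col}: {e}")
    return CorpusCounts(df)


def write_frequency_table(counts: CorpusCounts, path: PathLike) -> None:
    counts.data.to_csv(path, index=False)


def read_overrides(path: PathLike) -> OverrideTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    return OverrideTable(df)


# ---------------------------------------------------------------------------
# trees


def read_tree_sample(path: PathLike, format: str = "newick") -> TreeSample:
    """Read a sample of rooted, dated trees (branch lengths in years).

    Plain Newick carries no explicit rooting flag; trees are treated as
    rooted unless annotated ``[&U]``, which is rejected. Negative branch
    lengths are an error.
    """
    if format not in ("newick", "nexus"):
        raise FormatError(f"unknown tree format {format!r}")
    trees = dendropy.TreeList.get(
        path=str(path),
        schema=format,
        rooting="default-rooted",
        preserve_underscores=True,
    )
    if len(trees) == 0:
        raise FormatError(f"{path}: no trees found")
    out = []
    for i, t in enumerate(trees):
        if not t.is_rooted:
            raise ValidationError(f"{path}: tree {i} is explicitly unrooted")
        validate_phylogeny(t, where=f"{path}: tree {i}")
        out.append(t)
    return TreeSample(out)


def read_tree(path: PathLike, format: str = "newick") -> dendropy.Tree:
    return read_tree_sample(path, format=format)[0]


def write_tree_sample(sample: TreeSample, path: PathLike, format: str = "newick") -> None:
    tl = dendropy.TreeList(sample.trees)
    tl.write(path=str(path), schema=format, suppress_rooting=(format == "newick"))


def prune_to_taxa(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Prune a tree down to ``taxa``, preserving all path lengths among the
    retained leaves (degree-2 nodes are collapsed with edge lengths summed).
    """
    taxa = set(taxa)
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = taxa - leaf_labels
    if missing:
        raise ValidationError(f"taxa not on tree: {sorted(missing)}")
    if len(taxa) < 2:
        raise ValidationError(f"need at least 2 taxa to prune to, got {len(taxa)}")
    pruned = tree.extract_tree_with_taxa_labels(
        labels=taxa, suppress_unifurcations=True
    )
    # extract_tree may leave a stub edge above the new root; it does not
    # affect leaf-to-leaf path lengths but we zero it for tidiness.
    if pruned.seed_node.edge.length:
        pruned.seed_node.edge.length = 0.0
    return pruned


def leaf_distance_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Pairwise leaf-to-leaf path-length matrix (years), labels sorted."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in pdm.taxon_iter())
    taxa = {t.label: t for t in pdm.taxon_iter()}
    import numpy as np

    m = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d = pdm.patristic_distance(taxa[a], taxa[b])
                m[i, j] = m[j, i] = d
    return pd.DataFrame(m, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# label reconciliation


def canonical_label(label: str) -> str:
    """NFC-normalize and case-fold a language label for matching."""
    return unicodedata.normalize("NFC", label).casefold().strip()


def reconcile_labels(
    labels: Iterable[str],
    universe: Iterable[str],
    aliases: Optional[Mapping[str, str]] = None,
) -> dict[str, str]:
    """Map data labels onto tree leaf labels.

    Matching is exact string equality after NFC normalization and case
    folding; ``aliases`` (data label -> tree label) handles residual
    mismatches. Unmatched labels map to nothing and are reported by the
    caller.
    """
    aliases = dict(aliases or {})
    canon_universe: dict[str, str] = {}
    for u in universe:
        canon_universe.setdefault(canonical_label(u), u)
    out: dict[str, str] = {}
    for lb in labels:
        if lb in aliases:
            out[lb] = aliases[lb]
        elif canonical_label(lb) in canon_universe:
            out[lb] = canon_universe[canonical_label(lb)]
    return out


# ---------------------------------------------------------------------------
# NEXUS multistate character matrices

_MEANINGS_COMMENT = re.compile(r"\[meanings:\s*(.*?)\s*\]")


def write_character_matrix(
    characters: Sequence[MultistateCharacter], path: PathLike
) -> None:
    """Write per-meaning multistate characters as one NEXUS standard matrix.

    Columns follow the order of ``characters``; a ``[meanings: ...]`` comment
    records the column meanings so the file round-trips losslessly. States use
    the 47-symbol alphabet of :data:`kinrates.types.STATE_SYMBOLS`, missing
    ``?``.
    """
    characters = list(characters)
    if not characters:
        raise ValidationError("no characters to write")
    for c in characters:
        if c.k > len(STATE_SYMBOLS):
            raise ValidationError(
                f"character {c.meaning!r} has {c.k} states; NEXUS symbols allow {len(STATE_SYMBOLS)}"
            )
    taxa = sorted(set().union(*[set(c.states) for c in characters]))
    sa = dendropy.StateAlphabet(
        fundamental_states=STATE_SYMBOLS, no_data_symbol=MISSING_STATE
    )
    tn = dendropy.TaxonNamespace(taxa)
    mat = dendropy.StandardCharacterMatrix(default_state_alphabet=sa, taxon_namespace=tn)
    for taxon in tn:
        row = []
        for c in characters:
            s = c.states.get(taxon.label)
            row.append(MISSING_STATE if s is None else STATE_SYMBOLS[s])
        mat[taxon] = "".join(row)
    text = mat.as_string(schema="nexus")
    meanings = " ".join(c.meaning for c in characters)
    text = text.replace(
        "BEGIN CHARACTERS;", f"BEGIN CHARACTERS;\n[meanings: {meanings}]", 1
    )
    Path(path).write_text(text, encoding="utf-8")


def read_character_matrix(path: PathLike) -> list[MultistateCharacter]:
    """Read a NEXUS standard matrix back into per-meaning characters."""
    text = Path(path).read_text(encoding="utf-8")
    mat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    m = _MEANINGS_COMMENT.search(text)
    nchar = max(len(mat[t]) for t in mat.taxon_namespace)
    if m:
        meanings = m.group(1).split()
        if len(meanings) != nchar:
            raise FormatError(
                f"{path}: meanings comment lists {len(meanings)} names for {nchar} characters"
            )
    else:
        meanings = [f"c{i + 1}" for i in range(nchar)]
    out = []
    for j, meaning in enumerate(meanings):
        states: dict[str, Optional[int]] = {}
        for taxon in mat.taxon_namespace:
            sym = str(mat[taxon][j])
            states[taxon.label] = None if sym == MISSING_STATE else STATE_SYMBOLS.index(sym)
        out.append(MultistateCharacter(meaning=meaning, states=states))
    return out
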