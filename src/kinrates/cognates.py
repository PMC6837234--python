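"""Cognate-class assignment by normalized edit distance and flat UPGMA
clustering, with expert overrides.

For each meaning, the word forms across languages are compared pairwise by
Levenshtein distance normalized by the longer string, clustered by
average-linkage agglomeration cut at a flat threshold (default 0.4), and the
resulting classes become the states of a multistate phylogenetic character.
Expert overrides can reassign individual (language, form) occurrences.
"""
from __future__ import annotations

import dataclasses
import logging
import unicodedata
from typing import Mapping, Optional, Sequence

import edlib
import numpy as np

from .types import MultistateCharacter, OverrideTable, ValidationError, WordFormTable

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.4

LINKAGES = ("average", "single", "complete")
SYNONYM_POLICIES = ("first", "most_frequent", "error")


def normalize_form(form: str, translit: Optional[Mapping[str, str]] = None) -> str:
    """Produce a segmental string from an orthographic form.

    NFC-normalizes, case-folds and strips whitespace, then applies the
    user-supplied substitution table (e.g. digraph -> segment) longest-match
    first, scanning left to right. Substitution outputs are not re-scanned.
    """
    if not form or not form.strip():
        raise ValidationError("empty word form")
    s = unicodedata.normalize("NFC", form).casefold()
    s = "".join(s.split())
    if not translit:
        return s
    keys = sorted(translit, key=len, reverse=True)
    out = []
    i = 0
    while i < len(s):
        for k in keys:
            if k and s.startswith(k, i):
                out.append(translit[k])
                i += len(k)
                break
        else:
            out.append(s[i])
            i += 1
    return "".join(out)


def edit_distance(a: str, b: str) -> float:
    """Levenshtein distance with unit costs, divided by max(|a|, |b|).

    Returns a value in [0, 1]: 0 for identical strings, 1 when every segment
    of the longer string must change.
    """
    if not a or not b:
        raise ValidationError("edit_distance requires non-empty strings")
    if a == b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return d / max(len(a), len(b))


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric pairwise normalized edit distances with item labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal not zero")
        if np.any((v < 0) | (v > 1)):
            raise ValidationError("distances outside [0, 1]")
        self.values = v


def distance_matrix(forms: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise normalized edit distances between labelled segmental strings.

    ``forms`` maps an item label (e.g. a language name) to its segmental
    string; labels are kept in sorted order for determinism.
    """
    if not forms:
        raise ValidationError("need at least one form")
    labels = sorted(forms)
    n = len(labels)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = edit_distance(forms[labels[i]], forms[labels[j]])
    return DistanceMatrix(labels, v)


@dataclasses.dataclass
class CognatePartition:
    """Assignment of form occurrences to cognate classes for one meaning.

    ``assignment`` maps (language, form) to a dense integer class label;
    ``provenance`` records per occurrence whether the label is 'automatic'
    or an expert 'override'.
    """

    meaning: str
    assignment: dict[tuple[str, str], int]
    provenance: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        classes = sorted(set(self.assignment.values()))
        if classes and classes != list(range(len(classes))):
            raise ValidationError(f"class labels not dense: {classes}")
        if set(self.provenance) != set(self.assignment):
            raise ValidationError("provenance keys do not match assignment keys")

    @property
    def n_classes(self) -> int:
        return len(set(self.assignment.values()))

    def classes(self) -> dict[int, list[tuple[str, str]]]:
        out: dict[int, list[tuple[str, str]]] = {}
        for occ, c in sorted(self.assignment.items()):
            out.setdefault(c, []).append(occ)
        return out


def _cluster_labels(labels: Sequence[str], d: np.ndarray, theta: float, linkage: str) -> list[set[int]]:
    """Agglomerate items until the minimum inter-cluster linkage distance
    exceeds theta. Ties are broken by the lexicographically smallest member
    label of the candidate pair (then the second cluster's smallest member),
    so the result is independent of input order."""
    clusters: list[set[int]] = [{i} for i in range(len(labels))]

    def linkdist(a: set[int], b: set[int]) -> float:
        block = d[np.ix_(sorted(a), sorted(b))]
        if linkage == "average":
            return float(block.mean())
        if linkage == "single":
            return float(block.min())
        return float(block.max())

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = linkdist(clusters[i], clusters[j])
                mi = min(labels[x] for x in clusters[i])
                mj = min(labels[x] for x in clusters[j])
                key = (dist, min(mi, mj), max(mi, mj))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (dist, _, _), i, j = best
        if dist > theta:
            break
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return clusters


def flat_cluster(
    matrix: DistanceMatrix,
    theta: float = DEFAULT_THRESHOLD,
    meaning: str = "",
    linkage: str = "average",
) -> CognatePartition:
    """Flat agglomerative clustering of forms into cognate classes.

    Average linkage (UPGMA) by default; merging stops when the minimum
    inter-cluster distance exceeds ``theta``. Class labels are dense integers
    ordered by each class's lexicographically smallest member label.
    """
    if not (0 < theta < 1):
        raise ValidationError(f"threshold must be in (0, 1), got {theta}")
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}")
    labels = matrix.labels
    clusters = _cluster_labels(labels, matrix.values, theta, linkage)
    clusters.sort(key=lambda c: min(labels[i] for i in c))
    assignment: dict[tuple[str, str], int] = {}
    provenance: dict[tuple[str, str], str] = {}
    for ci, members in enumerate(clusters):
        for i in members:
            lang, form = _split_label(labels[i])
            assignment[(lang, form)] = ci
            provenance[(lang, form)] = "automatic"
    return CognatePartition(meaning, assignment, provenance)


def _join_label(language: str, form: str) -> str:
    return f"{language}␟{form}"


def _split_label(label: str) -> tuple[str, str]:
    if "␟" in label:
        lang, form = label.split("␟", 1)
        return lang, form
    return "", label


def partition_meaning(
    table: WordFormTable,
    meaning: str,
    theta: float = DEFAULT_THRESHOLD,
    translit: Optional[Mapping[str, str]] = None,
    linkage: str = "average",
    synonym_policy: str = "first",
    corpus_counts=None,
) -> CognatePartition:
    """Cluster all of one meaning's forms across languages into cognate classes.

    The ``transcription`` column is used where present; otherwise the
    orthographic form is normalized. A language with several synonymous forms
    keeps the first listed one by default; ``synonym_policy='most_frequent'``
    keeps the form with the highest total corpus count (requires
    ``corpus_counts``), and ``'error'`` raises.
    """
    if synonym_policy not in SYNONYM_POLICIES:
        raise ValidationError(f"synonym_policy must be one of {SYNONYM_POLICIES}")
    rows = table.for_meaning(meaning)
    if rows.empty:
        raise ValidationError(f"no forms for meaning {meaning!r}")
    if synonym_policy == "most_frequent":
        if corpus_counts is None:
            raise ValidationError(
                "synonym_policy='most_frequent' needs corpus_counts"
            )
        cdf = corpus_counts.data
        totals = (
            cdf[cdf["meaning"] == meaning]
            .groupby(["language", "form"])["count"]
            .sum()
        )
        # stable sort: highest total count first, ties keep listed order
        rows = rows.assign(
            _total=[
                totals.get((r.language, r.form), 0)
                for r in rows.itertuples(index=False)
            ]
        ).sort_values("_total", ascending=False, kind="stable")
    forms: dict[str, str] = {}
    kept: dict[str, str] = {}
    for row in rows.itertuples(index=False):
        if row.language in kept:
            if synonym_policy == "error":
                raise ValidationError(
                    f"language {row.language!r} has multiple forms for {meaning!r}"
                )
            log.info("meaning %s: language %s has synonyms; keeping %r",
                     meaning, row.language, kept[row.language])
            continue
        seg = (
            normalize_form(row.transcription)
            if isinstance(row.transcription, str) and row.transcription
            else normalize_form(row.form, translit)
        )
        kept[row.language] = row.form
        forms[_join_label(row.language, row.form)] = seg
    return flat_cluster(distance_matrix(forms), theta, meaning=meaning, linkage=linkage)


def apply_overrides(
    partition: CognatePartition, overrides: OverrideTable
) -> CognatePartition:
    """Apply expert class overrides to an automatic partition.

    Override class labels are free strings: occurrences sharing an override
    label form one class; an override label matching an existing class's
    smallest member merges into it. Labels are re-densified afterwards.
    Overrides naming unknown occurrences are warned about and skipped.
    """
    rows = overrides.data[overrides.data["meaning"] == partition.meaning]
    if rows.empty:
        return partition
    assignment = dict(partition.assignment)
    provenance = dict(partition.provenance)
    # group overridden occurrences by their override label
    groups: dict[str, list[tuple[str, str]]] = {}
    for row in rows.itertuples(index=False):
        occ = (row.language, row.form)
        if occ not in assignment:
            log.warning(
                "override for unknown occurrence %r / %r (meaning %s); skipped",
                row.language, row.form, partition.meaning,
            )
            continue
        groups.setdefault(str(row.cognate_class), []).append(occ)
    if not groups:
        return partition
    # existing classes keyed by an arbitrary stable name: their class index
    next_label = partition.n_classes
    for label, occs in sorted(groups.items()):
        try:
            target = int(label)
            if not (0 <= target < partition.n_classes):
                target = next_label
                next_label += 1
        except ValueError:
            target = next_label
            next_label += 1
        for occ in occs:
            assignment[occ] = target
            provenance[occ] = "override"
    # re-densify, ordering classes by smallest member
    classes: dict[int, list[tuple[str, str]]] = {}
    for occ, c in sorted(assignment.items()):
        classes.setdefault(c, []).append(occ)
    order = sorted(classes, key=lambda c: min(classes[c]))
    remap = {c: i for i, c in enumerate(order)}
    assignment = {occ: remap[c] for occ, c in assignment.items()}
    return CognatePartition(partition.meaning, assignment, provenance)


def build_character(
    partition: CognatePartition, taxa: Sequence[str]
) -> MultistateCharacter:
    """Turn a cognate partition into a multistate character over ``taxa``.

    State indices are relabelled densely by first appearance in the given
    (fixed) taxon order; taxa without a form get the missing state. A taxon
    carrying two different classes for the meaning is an error (synonyms are
    resolved upstream).
    """
    by_lang: dict[str, int] = {}
    for (lang, _form), c in sorted(partition.assignment.items()):
        if lang in by_lang and by_lang[lang] != c:
            raise ValidationError(
                f"taxon {lang!r} assigned to conflicting classes for {partition.meaning!r}"
            )
        by_lang[lang] = c
    unknown = set(by_lang) - set(taxa)
    if unknown:
        raise ValidationError(f"partition covers taxa not in the taxon set: {sorted(unknown)}")
    states: dict[str, Optional[int]] = {}
    relabel: dict[int, int] = {}
    for t in taxa:
        c = by_lang.get(t)
        if c is None:
            states[t] = None
        else:
            if c not in relabel:
                relabel[c] = len(relabel)
            states[t] = relabel[c]
    return MultistateCharacter(meaning=partition.meaning, states=states)
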