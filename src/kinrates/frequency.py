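"""Corpus counts -> aggregated centered log frequency per million (clfpm).

Each corpus contributes log(1e6 * count / corpus_size) per word; values are
centered within each corpus (so corpora of different register and size share
one scale) and then averaged, unweighted, over the corpora available for a
(language, meaning). Zero counts are treated as missing, not as 0 fpm: the
study list contains common words, and absence from a corpus almost always
means the word list and corpus language variety do not match rather than a
true zero frequency. A Laplace (+1) mode is available for sensitivity
analysis.
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .types import CorpusCounts, ValidationError, WordFormTable

log = logging.getLogger(__name__)

#: Swadesh meanings excluded from the combined analysis because they duplicate
#: kin categories: mother, father, husband, wife.
KIN_SWADESH_MEANINGS = ("mother", "father", "husband", "wife")


def fpm(count: float, corpus_size: float) -> Optional[float]:
    """Occurrences per million tokens; zero counts are missing (None)."""
    if corpus_size <= 0:
        raise ValidationError(f"corpus_size must be positive, got {corpus_size}")
    if count == 0:
        return None
    return 1e6 * count / corpus_size


def per_corpus_log_fpm(counts: CorpusCounts, laplace: bool = False) -> pd.DataFrame:
    """Per-record natural-log fpm. Zero-count rows are dropped (flagged) in
    the default mode, or smoothed to count+1 with ``laplace=True``."""
    df = counts.data.copy()
    if laplace:
        df["count"] = df["count"] + 1
    zero = df["count"] == 0
    if zero.any():
        log.info("dropping %d zero-count records (treated as missing)", int(zero.sum()))
        df = df[~zero].copy()
    df["fpm"] = 1e6 * df["count"] / df["corpus_size"]
    df["log_fpm"] = np.log(df["fpm"])
    return df


def center_within_corpus(records: pd.DataFrame) -> pd.DataFrame:
    """Center log_fpm within each corpus: subtract the corpus mean log_fpm.

    The centered values of each corpus sum to zero exactly (up to float
    tolerance); centering is idempotent."""
    if records.empty:
        raise ValidationError("no records with defined frequencies to center")
    out = records.copy()
    out["clfpm"] = out["log_fpm"] - out.groupby("corpus_id")["log_fpm"].transform("mean")
    return out


def aggregate_clfpm(
    records: pd.DataFrame, wordlist: Optional[WordFormTable] = None
) -> pd.DataFrame:
    """Average centered values over corpora per (language, meaning).

    Returns one row per (language, meaning) with columns ``clfpm`` (unweighted
    mean over contributing corpora), ``n_corpora``, and ``lexical_class``
    (joined from ``wordlist`` when given, else carried through or 'kin')."""
    if "clfpm" not in records.columns:
        raise ValidationError("records must be centered first (no clfpm column)")
    grouped = (
        records.groupby(["language", "meaning"], as_index=False)
        .agg(clfpm=("clfpm", "mean"), n_corpora=("corpus_id", "nunique"))
    )
    if wordlist is not None:
        classes = wordlist.data[["language", "meaning", "lexical_class"]].drop_duplicates()
        grouped = grouped.merge(classes, on=["language", "meaning"], how="left")
        grouped["lexical_class"] = grouped["lexical_class"].fillna("kin")
    elif "lexical_class" in records.columns:
        classes = records[["language", "meaning", "lexical_class"]].drop_duplicates(
            subset=["language", "meaning"]
        )
        grouped = grouped.merge(classes, on=["language", "meaning"], how="left")
    else:
        grouped["lexical_class"] = "kin"
    return grouped


def compute_clfpm(
    counts: CorpusCounts,
    wordlist: Optional[WordFormTable] = None,
    laplace: bool = False,
) -> pd.DataFrame:
    """Full pipeline: counts -> log fpm -> within-corpus centering -> aggregation."""
    return aggregate_clfpm(
        center_within_corpus(per_corpus_log_fpm(counts, laplace=laplace)), wordlist
    )


def exclude_kin_swadesh(table):
    """Drop Swadesh-class rows whose meanings duplicate kin categories
    (mother, father, husband, wife). Kin-class rows are always retained.

    Accepts a DataFrame with ``meaning`` and ``lexical_class`` columns or a
    WordFormTable; returns the same type."""
    if isinstance(table, WordFormTable):
        df = table.data
        out = df[~((df["lexical_class"] == "swadesh") & (df["meaning"].isin(KIN_SWADESH_MEANINGS)))]
        n = len(df) - len(out)
        if n:
            log.info("excluded %d Swadesh kin rows", n)
        return WordFormTable(out.reset_index(drop=True))
    df = table
    mask = (df["lexical_class"] == "swadesh") & (df["meaning"].isin(KIN_SWADESH_MEANINGS))
    if mask.any():
        log.info("excluded %d Swadesh kin rows", int(mask.sum()))
    return df[~mask].reset_index(drop=True)
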