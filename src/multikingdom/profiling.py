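"""Relative-abundance profiling: normalization, taxonomic rank
aggregation, and the fungal read-decontamination rule.

Profiles are ``samples x features`` DataFrames. Taxonomy is a
``features x ranks`` DataFrame using the fixed seven-rank header
``domain, phylum, class, order, family, genus, species``.
"""

from __future__ import annotations

import logging

import pandas as pd

__all__ = ["RANKS", "normalize_profile", "aggregate_rank", "decontaminate_fungal"]

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def normalize_profile(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert a ``features x samples`` count table to a ``samples x
    features`` relative-abundance profile (each row sums to 1).

    Zero counts stay zero. A sample whose column sums to zero cannot be
    normalized and raises a ``ValueError`` naming it.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.columns.duplicated().any() or counts.index.duplicated().any():
        raise ValueError("sample and feature ids must be unique")
    totals = counts.sum(axis=0)
    empty = totals.index[totals <= 0]
    if len(empty):
        raise ValueError(f"sample(s) with zero total counts: {list(empty)}")
    return (counts / totals).T


def aggregate_rank(
    profile: pd.DataFrame, taxonomy: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Sum feature abundances into taxa at the requested rank.

    Row sums are preserved exactly. A feature with a missing/empty label at
    ``rank`` is routed to an ``"unclassified"`` bucket with a warning.
    """
    if rank not in taxonomy.columns:
        raise ValueError(f"taxonomy has no rank {rank!r}; columns: {list(taxonomy.columns)}")
    labels = taxonomy.reindex(profile.columns)[rank]
    missing = labels.isna() | (labels == "")
    if missing.any():
        logger.warning(
            "%d feature(s) without a %s label routed to 'unclassified'",
            int(missing.sum()), rank,
        )
        labels = labels.where(~missing, "unclassified")
    out = profile.T.groupby(labels).sum().T
    out.columns.name = rank
    return out


def decontaminate_fungal(assignments: pd.DataFrame) -> pd.Series:
    """Tally fungal read counts after cross-kingdom decontamination.

    ``assignments`` has one row per read with columns ``read_id, species,
    fungal_match, prokaryote_match, viral_match`` (boolean flags). A
    fungal-assigned read is discarded iff it also matches any prokaryote or
    viral reference; survivors are counted per fungal species.
    """
    required = {"species", "fungal_match", "prokaryote_match", "viral_match"}
    if not required.issubset(assignments.columns):
        raise ValueError(f"assignments missing columns {required - set(assignments.columns)}")
    keep = (
        assignments["fungal_match"].astype(bool)
        & ~assignments["prokaryote_match"].astype(bool)
        & ~assignments["viral_match"].astype(bool)
    )
    counts = assignments.loc[keep].groupby("species").size()
    counts.name = "count"
    return counts
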