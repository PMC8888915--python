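"""Aggregate rarefied read counts into functional-guild responses per sample.

Each taxon carries at most one guild label (single-label model; taxa
without an annotation count as 'unassigned' and contribute to no guild).
The per-sample guild read counts are the response variables the downstream
abundance models consume; modeling itself is out of scope here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix, GuildTable, UNASSIGNED_GUILD, warn


def guild_read_counts(
    matrix: CountMatrix, guilds: GuildTable, guild_names: list[str]
) -> pd.DataFrame:
    """Sample x guild table of summed read counts.

    count(sample, guild) = sum of the sample's reads over taxa annotated
    with that guild. Unassigned taxa contribute to no column; requesting a
    guild outside the annotation vocabulary is an error.
    """
    known = guilds.known_guilds()
    unknown = [g for g in guild_names if g not in known]
    if unknown:
        raise KeyError(f"unknown guild(s) {unknown}; known guilds: {known}")
    labels = guilds.guild_of(matrix.taxon_ids).to_numpy()
    out = pd.DataFrame(
        0, index=pd.Index(matrix.sample_ids, name="sample_id"), columns=list(guild_names),
        dtype=np.int64,
    )
    any_assigned = False
    for g in guild_names:
        rows = labels == g
        if rows.any():
            any_assigned = True
            out[g] = matrix.counts[rows, :].sum(axis=0)
    if not any_assigned:
        warn("no taxa carry any of the requested guilds; all counts are zero")
    return out


def unassigned_read_counts(matrix: CountMatrix, guilds: GuildTable) -> pd.Series:
    """Per-sample reads of taxa with no guild annotation (conservation check)."""
    labels = guilds.guild_of(matrix.taxon_ids).to_numpy()
    rows = labels == UNASSIGNED_GUILD
    return pd.Series(
        matrix.counts[rows, :].sum(axis=0) if rows.any() else np.zeros(matrix.n_samples, dtype=np.int64),
        index=pd.Index(matrix.sample_ids, name="sample_id"),
        name=UNASSIGNED_GUILD,
    )


def dominant_guilds(matrix: CountMatrix, guilds: GuildTable, k: int) -> list[str]:
    """The k guilds with greatest total read count, ties lexicographic.

    If fewer than k assigned guilds exist, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    known = guilds.known_guilds()
    totals = guild_read_counts(matrix, guilds, known).sum(axis=0)
    ranked = sorted(known, key=lambda g: (-totals[g], g))
    if k > len(ranked):
        warn(f"requested k={k} dominant guilds but only {len(ranked)} are assigned")
        return ranked
    return ranked[:k]
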