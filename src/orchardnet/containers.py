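"""Core in-memory containers exchanged between pipeline stages.

The central object is :class:`CountMatrix`, a taxa x samples table of
nonnegative integer read counts (the classic OTU-table orientation).
Sample metadata, guild annotations and correlation/network results get
small dedicated containers so every stage has an explicit contract.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

LAND_USES = ("IPM", "organic", "grassland")
LOCATIONS = ("crop_row", "drive_row", "none")

#: Soil covariates carried through (never computed) when present.
COVARIATE_COLUMNS = ("water_content", "organic_matter", "pH", "NH4", "NO3", "P")

UNASSIGNED_GUILD = "unassigned"


class ValidationError(ValueError):
    """Raised when a container or input table violates its invariants."""


@dataclass
class CountMatrix:
    """Nonnegative integer abundances of taxa (rows) across samples (columns)."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_taxa, n_samples), integer dtype

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix (taxa x samples)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        n_taxa, n_samples = self.counts.shape
        if n_taxa < 1 or n_samples < 1:
            raise ValidationError("need at least 1 taxon and 1 sample")
        if len(self.taxon_ids) != n_taxa or len(self.sample_ids) != n_samples:
            raise ValidationError("identifier lists do not match counts shape")
        if len(set(self.taxon_ids)) != n_taxa:
            raise ValidationError("duplicate taxon identifiers")
        if len(set(self.sample_ids)) != n_samples:
            raise ValidationError("duplicate sample identifiers")
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.taxon_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        """Total reads per sample (library size)."""
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        cols = [idx[s] for s in sample_ids]
        return CountMatrix(self.taxon_ids, list(sample_ids), self.counts[:, cols])

    def select_taxa(self, taxon_ids: list[str]) -> "CountMatrix":
        idx = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxon_ids if t not in idx]
        if missing:
            raise KeyError(f"taxa not in matrix: {missing}")
        rows = [idx[t] for t in taxon_ids]
        return CountMatrix(list(taxon_ids), self.sample_ids, self.counts[rows, :])

    def drop_empty_taxa(self) -> "CountMatrix":
        keep = self.counts.sum(axis=1) > 0
        if keep.all():
            return self
        return CountMatrix(
            [t for t, k in zip(self.taxon_ids, keep) if k],
            self.sample_ids,
            self.counts[keep, :],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleMetadata:
    """Per-sample stratum labels and nesting; thin validated wrapper on a DataFrame.

    Strata are land-use x location classes: the four orchard classes
    (IPM/organic x crop_row/drive_row) plus grassland, whose location is
    recorded as ``none``.
    """

    table: pd.DataFrame  # columns: sample_id, land_use, location, site_id, plot_id, subplot_id [+ covariates]

    REQUIRED = ("sample_id", "land_use", "location", "site_id", "plot_id", "subplot_id")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        bad_use = set(df["land_use"]) - set(LAND_USES)
        if bad_use:
            raise ValidationError(f"unknown land_use values: {sorted(bad_use)}")
        bad_loc = set(df["location"]) - set(LOCATIONS)
        if bad_loc:
            raise ValidationError(f"unknown location values: {sorted(bad_loc)}")
        grass = df["land_use"] == "grassland"
        none_loc = df["location"] == "none"
        if (grass != none_loc).any():
            bad = df.loc[grass != none_loc, "sample_id"].iloc[0]
            raise ValidationError(
                f"sample {bad!r}: location must be 'none' iff land_use is 'grassland'"
            )
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def strata(self) -> pd.Series:
        """Stratum label per sample: 'IPM_crop_row', ..., or 'grassland'."""
        df = self.table
        labels = np.where(
            df["land_use"] == "grassland",
            "grassland",
            df["land_use"].astype(str) + "_" + df["location"].astype(str),
        )
        return pd.Series(labels, index=df["sample_id"].to_numpy(), name="stratum")

    def subset(self, sample_ids: list[str]) -> "SampleMetadata":
        df = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleMetadata(df)


@dataclass
class GuildTable:
    """Single-label functional-guild annotation per taxon."""

    table: pd.DataFrame  # columns: taxon_id, kingdom, guild

    MULTI_LABEL_SEPARATORS = ("|", ",", ";")

    def __post_init__(self) -> None:
        df = self.table
        for col in ("taxon_id", "kingdom", "guild"):
            if col not in df.columns:
                raise ValidationError(f"guild table missing column {col!r}")
        if df["taxon_id"].duplicated().any():
            dup = df.loc[df["taxon_id"].duplicated(), "taxon_id"].iloc[0]
            raise ValidationError(f"duplicate taxon_id {dup!r} in guild table")
        bad_kingdom = set(df["kingdom"]) - {"fungi", "bacteria"}
        if bad_kingdom:
            raise ValidationError(f"unknown kingdom values: {sorted(bad_kingdom)}")
        multi = df["guild"].astype(str).str.contains(
            "|".join(map(re.escape, self.MULTI_LABEL_SEPARATORS))
        )
        if multi.any():
            bad = df.loc[multi, ["taxon_id", "guild"]].iloc[0]
            raise ValidationError(
                f"taxon {bad['taxon_id']!r} carries a multi-guild label "
                f"{bad['guild']!r}; collapse annotations to a single guild per "
                "taxon before loading (single-label model)"
            )
        self.table = df.reset_index(drop=True)

    def guild_of(self, taxon_ids: list[str]) -> pd.Series:
        """Guild label per requested taxon; unannotated taxa -> 'unassigned'."""
        mapping = self.table.set_index("taxon_id")["guild"]
        return pd.Series(
            [mapping.get(t, UNASSIGNED_GUILD) for t in taxon_ids], index=taxon_ids
        )

    def known_guilds(self) -> list[str]:
        vocab = set(self.table["guild"]) - {UNASSIGNED_GUILD}
        return sorted(vocab)


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rank correlations among taxa across samples."""

    taxon_ids: list[str]
    rho: np.ndarray  # symmetric, diagonal 1
    p: np.ndarray    # symmetric, two-sided p-values in [0, 1]
    n: int           # samples used

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        k = len(self.taxon_ids)
        if self.rho.shape != (k, k) or self.p.shape != (k, k):
            raise ValidationError("rho/p shape mismatch with taxon_ids")
        if not np.allclose(self.rho, self.rho.T, equal_nan=True):
            raise ValidationError("rho not symmetric")
        if not np.allclose(self.p, self.p.T, equal_nan=True):
            raise ValidationError("p not symmetric")


@dataclass
class KeystoneCriteria:
    """Joint strict thresholds flagging highly connected, central taxa.

    A node is keystone iff degree > degree_min AND closeness > closeness_min
    AND betweenness < betweenness_max (all strict). Closeness and betweenness
    are on the unnormalized scale.
    """

    degree_min: float
    closeness_min: float
    betweenness_max: float

    def __post_init__(self) -> None:
        for name in ("degree_min", "closeness_min", "betweenness_max"):
            v = getattr(self, name)
            if v is None:
                raise ValidationError(f"keystone criteria missing field {name}")
            if v < 0:
                raise ValidationError(f"keystone criterion {name} must be >= 0")


#: Published joint thresholds for fungal networks.
FUNGAL_KEYSTONE = KeystoneCriteria(degree_min=5, closeness_min=0.005, betweenness_max=40)
#: Published joint thresholds for bacterial networks.
BACTERIAL_KEYSTONE = KeystoneCriteria(degree_min=15, closeness_min=0.03, betweenness_max=50)

KEYSTONE_PRESETS = {"fungi": FUNGAL_KEYSTONE, "bacteria": BACTERIAL_KEYSTONE}


@dataclass
class TopologySummary:
    """Whole-network topology metrics on the unweighted simple graph.

    Diameter and average path length are over connected node pairs only and
    are None for edgeless graphs; modularity is Newman Q of the detected
    partition (None when there are no edges).
    """

    n_nodes: int
    n_edges: int
    mean_degree: float
    diameter: int | None
    avg_path_length: float | None
    mean_closeness: float
    mean_betweenness: float
    modularity: float | None
    n_components: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def warn(message: str) -> None:
    """Package-level warning channel (plain UserWarning)."""
    warnings.warn(message, UserWarning, stacklevel=3)
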