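"""Typed containers and strict TSV readers/writers for all pipeline tables.

All tables are plain TSV.  Internally every community table is oriented
samples-in-rows regardless of the on-disk orientation; the sample label is
the join key across counts, metadata and downstream results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: PR2-style lineage ranks, fixed length 8.
RANKS = (
    "domain",
    "supergroup",
    "division",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: The twelve physicochemical variables carried by sample metadata.
ENV_VARS = (
    "temperature",
    "pH",
    "DO",
    "chla",
    "NO3_N",
    "NO2_N",
    "NH4_N",
    "TN",
    "TP",
    "PO4_P",
    "CODMn",
    "TOC",
)

_META_REQUIRED = ("site", "season", "depth_m", "latitude", "longitude") + ENV_VARS


class TableError(ValueError):
    """Raised on malformed or invariant-violating input tables."""


@dataclass
class CommunityTable:
    """Samples x ASVs matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame with sample ids as the index and ASV ids as columns.
        Values must be non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise TableError("duplicate sample ids")
        if df.columns.has_duplicates:
            raise TableError("duplicate ASV ids")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise TableError("non-integer cell in community table")
            df = df.astype(np.int64)
        if values.size and (df.to_numpy() < 0).any():
            raise TableError("negative cell in community table")
        self.counts = df.astype(np.int64) if values.size else df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def select_samples(self, sample_ids) -> "CommunityTable":
        return CommunityTable(self.counts.loc[list(sample_ids)])

    def select_asvs(self, asv_ids) -> "CommunityTable":
        return CommunityTable(self.counts.loc[:, list(asv_ids)])

    def relative_abundance(self) -> pd.DataFrame:
        sums = self.counts.sum(axis=1)
        if (sums == 0).any():
            raise TableError("all-zero sample row")
        return self.counts.div(sums, axis=0)

    def write(self, path, orientation: str = "samples_in_rows") -> None:
        df = self.counts
        if orientation == "samples_in_rows":
            df.rename_axis("sample_id").to_csv(path, sep="\t")
        elif orientation == "samples_in_columns":
            df.T.rename_axis("asv_id").to_csv(path, sep="\t")
        else:
            raise ValueError(f"unknown orientation {orientation!r}")


@dataclass
class TaxonomyTable:
    """ASV -> 8-rank lineage (PR2 convention); empty string = unassigned rank."""

    lineages: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.lineages
        if df.index.has_duplicates:
            raise TableError("duplicate asv_id in taxonomy")
        if tuple(df.columns) != RANKS:
            raise TableError(f"taxonomy must have exactly the ranks {RANKS}")
        self.lineages = df.fillna("").astype(str)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.lineages.index)

    def lineage(self, asv_id: str) -> tuple[str, ...]:
        return tuple(self.lineages.loc[asv_id])

    def __contains__(self, asv_id: str) -> bool:
        return asv_id in self.lineages.index

    def write(self, path, separator: str = ";") -> None:
        joined = self.lineages.apply(lambda row: separator.join(row), axis=1)
        joined.rename("lineage").rename_axis("asv_id").to_csv(path, sep="\t")


@dataclass
class SampleMetadata:
    """Per-sample design and physicochemical data.

    Required columns: site, season, depth_m, latitude, longitude and the
    twelve environment variables in :data:`ENV_VARS`.  Extra numeric columns
    are carried through as auxiliary environment variables.
    """

    table: pd.DataFrame
    aux_vars: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        df = self.table
        if df.index.has_duplicates:
            raise TableError("duplicate sample_id in metadata")
        missing = [c for c in _META_REQUIRED if c not in df.columns]
        if missing:
            raise TableError(f"metadata missing required columns: {missing}")
        lat = df["latitude"].astype(float)
        lon = df["longitude"].astype(float)
        if ((lat < -90) | (lat > 90)).any():
            raise TableError("latitude out of [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise TableError("longitude out of [-180, 180]")
        if (df["depth_m"].astype(float) <= 0).any():
            raise TableError("depth_m must be positive")
        numeric = ("depth_m", "latitude", "longitude") + ENV_VARS + tuple(self.aux_vars)
        for col in numeric:
            df[col] = pd.to_numeric(df[col], errors="raise")
            if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
                raise TableError(f"non-finite value in metadata column {col!r}")
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def env(self, variables=None) -> pd.DataFrame:
        """Environment matrix (samples x variables)."""
        cols = list(variables) if variables is not None else list(ENV_VARS) + list(self.aux_vars)
        return self.table[cols].astype(float)

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.table["latitude"].to_numpy(dtype=float),
            self.table["longitude"].to_numpy(dtype=float),
        )

    def write(self, path) -> None:
        self.table.rename_axis("sample_id").to_csv(path, sep="\t")


@dataclass
class DistanceMatrix:
    """Labelled symmetric pairwise matrix.

    ``kind`` records the semantics; similarity kinds (``*_similarity``)
    have unit diagonal and values in [0, 1], dissimilarity/distance kinds
    have zero diagonal.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "euclidean"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise TableError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-10):
            raise TableError("distance matrix not symmetric")
        if (v < -1e-12).any():
            raise TableError("negative distances")
        if self.is_similarity:
            if (v > 1 + 1e-9).any():
                raise TableError("similarity values exceed 1")
        else:
            if not np.allclose(np.diag(v), 0, atol=1e-9):
                raise TableError("nonzero diagonal")
        self.values = v
        self.labels = list(self.labels)

    @property
    def is_similarity(self) -> bool:
        return self.kind.endswith("similarity")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major (scipy condensed) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def subset(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path) -> None:
        self.to_frame().rename_axis("label").to_csv(path, sep="\t")


def read_community_table(path, orientation: str = "samples_in_rows") -> CommunityTable:
    """Read an ASV count table from TSV.

    Parameters
    ----------
    path
        TSV file with one label column (first column) and a header row.
    orientation
        ``"samples_in_rows"`` (index = sample ids, columns = ASV ids) or
        ``"samples_in_columns"`` (index = asv_id, columns = sample ids).
        The returned table is always samples-in-rows.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples_in_columns":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if df.isna().any().any():
        raise TableError("ragged or missing cells in community table")
    return CommunityTable(df)


def read_taxonomy(path, separator: str = ";") -> TaxonomyTable:
    """Read an ASV -> lineage TSV; lineages padded to 8 ranks.

    Lineage strings with more than 8 separated ranks are rejected (rank
    overflow), shorter ones are right-padded with empty strings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.shape[1] < 2:
        raise TableError("taxonomy TSV needs asv_id and lineage columns")
    asv_ids = df.iloc[:, 0]
    rows = []
    for asv, lineage in zip(asv_ids, df.iloc[:, 1]):
        parts = [p.strip() for p in str(lineage).split(separator)]
        # a trailing separator produces one empty overflow token; drop it
        while len(parts) > len(RANKS) and parts[-1] == "":
            parts.pop()
        if len(parts) > len(RANKS):
            raise TableError(
                f"lineage for {asv!r} has {len(parts)} ranks; at most {len(RANKS)} allowed"
            )
        parts += [""] * (len(RANKS) - len(parts))
        rows.append(parts)
    out = pd.DataFrame(rows, index=pd.Index(asv_ids, name="asv_id"), columns=list(RANKS))
    return TaxonomyTable(out)


def read_metadata(path) -> SampleMetadata:
    """Read the sample metadata TSV (strict column contract)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    aux = tuple(
        c
        for c in df.columns
        if c not in _META_REQUIRED and pd.api.types.is_numeric_dtype(df[c])
    )
    return SampleMetadata(df, aux_vars=aux)


def align_tables(table: CommunityTable, metadata: SampleMetadata) -> tuple[CommunityTable, SampleMetadata]:
    """Check the sample-label join and return metadata reordered to the counts.

    Fails fast on any sample present in counts but absent from metadata.
    """
    missing = [s for s in table.sample_ids if s not in metadata.table.index]
    if missing:
        raise TableError(f"samples missing from metadata: {missing}")
    meta = SampleMetadata(metadata.table.loc[table.sample_ids].copy(), metadata.aux_vars)
    return table, meta
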