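"""Readers, writers and validation for the tabular and graph formats the
pipeline touches.

Canonical on-disk dialects are plain TSV: count tables (OTUs as rows,
samples as columns), sample metadata, taxonomy (semicolon-joined or
per-rank columns), FUNGuild-style guild lookups, GraphML and edge CSV for
networks.  All readers validate rather than silently subsetting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]

SOIL_VARS = [
    "pH_H2O",
    "total_C",
    "total_N",
    "C_N",
    "total_P",
    "assimilable_P",
    "NO3",
    "NH4",
]

PLANT_TYPES = ("cultivated", "wild")


class FormatError(ValueError):
    """A file violated the documented dialect."""


class ConsistencyError(ValueError):
    """Cross-file identifiers disagree."""


@dataclass
class CountTable:
    """Integer OTU x sample abundance matrix.

    ``counts`` is a DataFrame indexed by OTU id with sample-id columns;
    every downstream stage consumes this object.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate OTU id {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (arr < 0).any():
            raise FormatError("counts must be non-negative")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.counts[list(sample_ids)].copy())

    def select_otus(self, otu_ids) -> "CountTable":
        return CountTable(self.counts.loc[list(otu_ids)].copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.counts.equals(other.counts)


@dataclass
class SampleMetadata:
    """Per-sample design factors plus the soil-chemistry vector.

    ``frame`` is indexed by sample id with columns ``site``, ``plant_type``,
    ``plot`` and any of the eight soil variables (pH unitless; C, N in %;
    P, NO3, NH4 in mg/kg).  ``plant_type`` is normalized to lowercase
    {cultivated, wild}.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("site", "plant_type", "plot"):
            if col not in df.columns:
                raise FormatError(f"metadata missing mandatory column {col!r}")
        if df.index.duplicated().any():
            raise FormatError("duplicate sample id in metadata")
        df["plant_type"] = df["plant_type"].astype(str).str.strip().str.lower()
        bad = set(df["plant_type"]) - set(PLANT_TYPES)
        if bad:
            raise FormatError(f"unknown plant_type value(s): {sorted(bad)}")
        for col in ("site", "plot"):
            df[col] = df[col].astype(str)
        for var in self.soil_columns:
            vals = df[var].to_numpy(dtype=float)
            if np.isinf(vals).any():
                raise FormatError(f"non-finite soil value in column {var!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def soil_columns(self) -> list[str]:
        return [v for v in SOIL_VARS if v in self.frame.columns]

    def soil(self) -> pd.DataFrame:
        return self.frame[self.soil_columns].astype(float)

    def select_samples(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())


@dataclass
class TaxonomyTable:
    """OTU id -> ranked lineage (kingdom..species); unassigned ranks are NA."""

    frame: pd.DataFrame  # indexed by otu_id, columns = RANKS subset

    UNASSIGNED = {"", "unidentified", "unassigned", "na", "nan", "incertae_sedis"}

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            raise FormatError("duplicate OTU id in taxonomy")
        for rank in self.frame.columns:
            if rank not in RANKS:
                raise FormatError(f"unknown taxonomy rank {rank!r}")
        # fixed rank order, explicit missing markers -> NA
        cols = [r for r in RANKS if r in self.frame.columns]
        df = self.frame[cols]
        df = df.apply(lambda s: s.astype("string").str.strip())
        df = df.mask(df.apply(lambda s: s.str.lower().isin(self.UNASSIGNED)))
        self.frame = df

    @property
    def otu_ids(self) -> list[str]:
        return list(self.frame.index)

    def lineage(self, otu_id: str) -> dict:
        row = self.frame.loc[otu_id]
        return {r: (None if pd.isna(v) else str(v)) for r, v in row.items()}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        skip = 1 if first.startswith("# Constructed from biom file") else 0
    return pd.read_csv(path, sep="\t", skiprows=skip, dtype=str, keep_default_na=False)


def read_count_table(path) -> CountTable:
    """Parse an OTU x sample TSV (first column = OTU id, header required)."""
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: need an OTU-id column plus >= 1 sample column")
    raw = raw.set_index(raw.columns[0])
    mat = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            try:
                val = int(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer count {cell!r} at OTU {raw.index[i]!r},"
                    f" sample {col!r} (line {i + 2})"
                ) from None
            if val < 0:
                raise FormatError(
                    f"{path}: negative count at OTU {raw.index[i]!r}, sample {col!r}"
                )
            mat[i, j] = val
    return CountTable(pd.DataFrame(mat, index=raw.index.rename("otu_id"), columns=raw.columns))


def write_count_table(table: CountTable, path) -> None:
    table.counts.rename_axis("otu_id").to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    raw = _read_tsv(path)
    if "sample_id" not in raw.columns:
        raise FormatError(f"{path}: metadata missing mandatory column 'sample_id'")
    raw = raw.set_index("sample_id")
    frame = raw.copy()
    for var in SOIL_VARS:
        if var in frame.columns:
            frame[var] = pd.to_numeric(frame[var].replace({"NA": np.nan, "": np.nan}))
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.rename_axis("sample_id").to_csv(path, sep="\t", na_rep="NA")


def read_taxonomy(path) -> TaxonomyTable:
    """Read taxonomy TSV; ranks either per-column or semicolon-joined in a
    single ``lineage``/``taxonomy`` column."""
    raw = _read_tsv(path)
    if "otu_id" not in raw.columns:
        raise FormatError(f"{path}: taxonomy missing mandatory column 'otu_id'")
    raw = raw.set_index("otu_id")
    joined = next((c for c in ("lineage", "taxonomy") if c in raw.columns), None)
    if joined is not None:
        parts = raw[joined].str.split(";", expand=True)
        parts.columns = RANKS[: parts.shape[1]]
        # strip rank prefixes like "g__Fusarium"
        frame = parts.apply(lambda s: s.str.strip().str.replace(r"^[a-z]__", "", regex=True))
    else:
        keep = [c for c in raw.columns if c.lower() in RANKS]
        if not keep:
            raise FormatError(f"{path}: no recognized rank columns")
        frame = raw[keep].rename(columns=str.lower)
    return TaxonomyTable(frame)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    tax.frame.rename_axis("otu_id").to_csv(path, sep="\t", na_rep="unidentified")


GUILD_DB_COLUMNS = ["taxon", "taxonomicLevel", "trophicMode", "guild", "confidenceRanking"]


def read_guild_db(path) -> pd.DataFrame:
    """Read a FUNGuild-style flat lookup (taxon, taxonomicLevel, trophicMode,
    guild, confidenceRanking); extra columns are preserved but ignored."""
    raw = _read_tsv(path)
    for col in GUILD_DB_COLUMNS:
        if col not in raw.columns:
            raise FormatError(f"{path}: guild db missing mandatory column {col!r}")
    db = raw.copy()
    db["taxon"] = db["taxon"].str.strip()
    db["taxonomicLevel"] = db["taxonomicLevel"].str.strip().str.lower()
    return db


def validate_dataset(
    table: CountTable,
    metadata: SampleMetadata,
    taxonomy: TaxonomyTable | None = None,
    strict: bool = True,
) -> list[str]:
    """Cross-file consistency check; returns warning messages.

    Every count-table sample must have a metadata row (always an error).
    Extra metadata samples and taxonomy gaps are errors when ``strict``,
    warnings otherwise.
    """
    warnings: list[str] = []
    missing = set(table.sample_ids) - set(metadata.sample_ids)
    if missing:
        raise ConsistencyError(
            f"samples in count table without metadata: {sorted(missing)}"
        )
    extra = set(metadata.sample_ids) - set(table.sample_ids)
    if extra:
        msg = f"metadata samples absent from count table: {sorted(extra)}"
        if strict:
            raise ConsistencyError(msg)
        warnings.append(msg)
        log.warning(msg)
    if taxonomy is not None:
        untaxed = set(table.otu_ids) - set(taxonomy.otu_ids)
        if untaxed:
            msg = f"{len(untaxed)} OTUs lack taxonomy rows"
            if strict:
                raise ConsistencyError(msg)
            warnings.append(msg)
            log.warning(msg)
    return warnings


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------


def write_network(network: nx.Graph, path, format: str = "graphml") -> None:
    """Write a co-occurrence network as GraphML or an edge CSV.

    GraphML carries all node attributes (taxon, guild, trophic group,
    proportional abundance, degree, betweenness, hub flag) and edge
    attributes (r, q, sign); the edge CSV has columns
    source,target,r,q,sign.
    """
    if format == "graphml":
        g = network.copy()
        for _, data in g.nodes(data=True):
            for k, v in list(data.items()):
                if v is None:
                    data[k] = ""
        nx.write_graphml(g, path)
    elif format == "edge_csv":
        rows = [
            {
                "source": u,
                "target": v,
                "r": d.get("r", np.nan),
                "q": d.get("q", np.nan),
                "sign": "positive" if d.get("r", 0.0) >= 0 else "negative",
            }
            for u, v, d in network.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "r", "q", "sign"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path) -> nx.Graph:
    return nx.read_graphml(path)
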