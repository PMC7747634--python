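"""Domain types and I/O for sample-by-OTU count tables.

The universal currency of the pipeline is a :class:`CountTable`: a
samples × OTUs matrix of non-negative integer read counts, typically
rarefied to even depth before any downstream analysis.  Sample metadata
(coordinates plus environmental covariates), OTU→group maps and
group→body-size tables round out the inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "CountTable",
    "SampleInfo",
    "TaxonMap",
    "BodySizeRecord",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxon_map",
    "write_taxon_map",
    "read_body_sizes",
    "write_body_sizes",
    "rarefy",
    "filter_dominant_groups",
]


class FormatError(ValueError):
    """A file or table violates the format contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CountTable:
    """Samples × OTUs non-negative integer read-count matrix.

    Parameters
    ----------
    sample_ids : ordered sample identifiers (rows).
    otu_ids : ordered OTU identifiers (columns).
    counts : integer array of shape (n_samples, n_otus); whole-number
        floats are coerced, anything else is rejected.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = np.round(counts).astype(np.int64)
            bad = ~np.isclose(counts.astype(float), as_int)
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise FormatError(
                    f"non-integer count at sample {self.sample_ids[i]!r}, "
                    f"OTU {self.otu_ids[j]!r}: {counts[i, j]!r}"
                )
            counts = as_int
        counts = counts.astype(np.int64)
        if (counts < 0).any():
            i, j = map(int, np.argwhere(counts < 0)[0])
            raise FormatError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}: {counts[i, j]}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        self.counts = counts

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_otus(self, otu_ids: Sequence[str]) -> "CountTable":
        idx = {o: k for k, o in enumerate(self.otu_ids)}
        missing = [o for o in otu_ids if o not in idx]
        if missing:
            raise KeyError(f"unknown OTU ids: {missing[:5]}")
        cols = [idx[o] for o in otu_ids]
        return CountTable(list(self.sample_ids), list(otu_ids), self.counts[:, cols])

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = {s: k for k, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return CountTable(list(sample_ids), list(self.otu_ids), self.counts[rows, :])

    def drop_empty_samples(self) -> "CountTable":
        keep = self.row_sums > 0
        return CountTable(
            [s for s, k in zip(self.sample_ids, keep) if k],
            list(self.otu_ids),
            self.counts[keep, :],
        )


@dataclass
class SampleInfo:
    """One sample's coordinates and environmental covariates."""

    sample_id: str
    latitude: float
    longitude: float
    env: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise FormatError(f"latitude {self.latitude} out of [-90, 90] for {self.sample_id!r}")
        if not -180.0 <= self.longitude <= 180.0:
            raise FormatError(f"longitude {self.longitude} out of [-180, 180] for {self.sample_id!r}")
        for k, v in self.env.items():
            if not np.isfinite(v):
                raise FormatError(f"non-finite env value {k}={v!r} for {self.sample_id!r}")


@dataclass
class TaxonMap:
    """Map from OTU id to its taxonomic/functional group (one group each)."""

    mapping: dict[str, str]

    def group_of(self, otu_id: str) -> str:
        return self.mapping[otu_id]

    def groups(self) -> list[str]:
        out: list[str] = []
        for g in self.mapping.values():
            if g not in out:
                out.append(g)
        return out

    def otus_in(self, group: str) -> list[str]:
        return [o for o, g in self.mapping.items() if g == group]


@dataclass
class BodySizeRecord:
    """A group's characteristic body (propagule) size in micrometres."""

    group: str
    size_um: float

    def __post_init__(self) -> None:
        if not self.size_um > 0:
            raise FormatError(f"body size must be > 0, got {self.size_um} for {self.group!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, dialect: str = "tsv") -> CountTable:
    """Read a count table.

    ``tsv``: samples as rows, OTUs as columns, header row of OTU ids,
    first column sample ids.  ``biom-text``: BIOM classic dense text
    (``#OTU ID`` header, OTUs as rows, samples as columns) — transposed
    on read.
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif dialect == "biom-text":
        lines = path.read_text().splitlines()
        start = next(
            (k for k, ln in enumerate(lines) if ln.startswith("#OTU ID")), None
        )
        if start is None:
            raise FormatError(f"{path}: no '#OTU ID' header line (not BIOM classic text)")
        header = lines[start].lstrip("#").split("\t")
        rows = [ln.split("\t") for ln in lines[start + 1 :] if ln.strip()]
        df = pd.DataFrame(rows, columns=header).set_index("OTU ID")
        df = df.apply(pd.to_numeric, errors="coerce").T
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        df_num = df.apply(pd.to_numeric, errors="coerce")
        bad = df_num.isna() & df.notna()
        if bad.to_numpy().any():
            i, j = map(int, np.argwhere(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric count at sample {df.index[i]!r}, "
                f"OTU {df.columns[j]!r}: {df.iat[i, j]!r}"
            )
        df = df_num
    if df.isna().to_numpy().any():
        i, j = map(int, np.argwhere(df.isna().to_numpy())[0])
        raise FormatError(f"{path}: missing count at sample {df.index[i]!r}, OTU {df.columns[j]!r}")
    return CountTable.from_dataframe(df)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(Path(path), sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> list[SampleInfo]:
    """Read sample metadata CSV: sample_id, latitude, longitude, then env columns.

    Non-numeric extra columns are ignored with a logged warning; a
    non-numeric cell in an otherwise numeric column is a format error.
    """
    df = pd.read_csv(Path(path))
    cols = {c.lower(): c for c in df.columns}
    for needed in ("sample_id", "latitude", "longitude"):
        if needed not in cols:
            raise FormatError(f"{path}: missing required column {needed!r}")
    out: list[SampleInfo] = []
    env_cols = [c for c in df.columns if c.lower() not in ("sample_id", "latitude", "longitude")]
    numeric_env: list[str] = []
    for c in env_cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        if coerced.notna().all():
            df[c] = coerced
            numeric_env.append(c)
        elif pd.to_numeric(df[c], errors="coerce").isna().all():
            logger.warning("metadata column %r is non-numeric; ignored", c)
        else:
            bad = coerced.isna()
            raise FormatError(
                f"{path}: non-numeric value in env column {c!r} "
                f"(sample {df.loc[bad, cols['sample_id']].iloc[0]!r})"
            )
    for _, row in df.iterrows():
        out.append(
            SampleInfo(
                sample_id=str(row[cols["sample_id"]]),
                latitude=float(row[cols["latitude"]]),
                longitude=float(row[cols["longitude"]]),
                env={c: float(row[c]) for c in numeric_env},
            )
        )
    return out


def write_metadata(samples: Iterable[SampleInfo], path: str | Path) -> None:
    rows = []
    for s in samples:
        rows.append({"sample_id": s.sample_id, "latitude": s.latitude, "longitude": s.longitude, **s.env})
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_taxon_map(path: str | Path) -> TaxonMap:
    df = pd.read_csv(Path(path), sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns otu_id, group")
    otu_col, group_col = df.columns[:2]
    if df[otu_col].duplicated().any():
        dup = df.loc[df[otu_col].duplicated(), otu_col].iloc[0]
        raise FormatError(f"{path}: OTU {dup!r} mapped to more than one group")
    return TaxonMap({str(o): str(g) for o, g in zip(df[otu_col], df[group_col])})


def write_taxon_map(taxa: TaxonMap, path: str | Path) -> None:
    pd.DataFrame(
        {"otu_id": list(taxa.mapping), "group": list(taxa.mapping.values())}
    ).to_csv(Path(path), sep="\t", index=False)


def read_body_sizes(path: str | Path) -> list[BodySizeRecord]:
    df = pd.read_csv(Path(path))
    cols = {c.lower(): c for c in df.columns}
    if "group" not in cols or "size_um" not in cols:
        raise FormatError(f"{path}: expected columns group, size_um")
    if df[cols["group"]].duplicated().any():
        raise FormatError(f"{path}: duplicate group in body-size table")
    return [
        BodySizeRecord(str(g), float(s))
        for g, s in zip(df[cols["group"]], df[cols["size_um"]])
    ]


def write_body_sizes(sizes: Iterable[BodySizeRecord], path: str | Path) -> None:
    pd.DataFrame([{"group": r.group, "size_um": r.size_um} for r in sizes]).to_csv(
        Path(path), index=False
    )


# ---------------------------------------------------------------------------
# rarefaction and the dominant-group filter
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each sample is drawn from a multivariate hypergeometric distribution
    on its own counts, so no reads are invented for OTUs absent from the
    sample and row sums equal ``depth`` exactly.  One seed governs the
    whole table via per-sample substreams, so the result is deterministic
    and independent of sample order elsewhere in the pipeline.
    """
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    short = [s for s, n in zip(table.sample_ids, table.row_sums) if n < depth]
    if short:
        raise ValueError(
            f"samples with fewer than {depth} reads cannot be rarefied: {short}"
        )
    children = np.random.SeedSequence(seed).spawn(table.n_samples)
    out = np.empty_like(table.counts)
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return CountTable(list(table.sample_ids), list(table.otu_ids), out)


def filter_dominant_groups(
    table: CountTable,
    taxa: TaxonMap,
    min_rel_abund: float = 0.01,
    min_presence: float = 0.80,
) -> list[tuple[str, CountTable]]:
    """Select dominant groups: pooled relative abundance ≥ ``min_rel_abund``
    across the whole table AND present (≥1 read over the group's OTUs) in
    ≥ ``min_presence`` of samples.

    Returns ``(group, sub-table)`` pairs ordered by descending pooled
    abundance; each sub-table keeps only that group's OTU columns and all
    samples.
    """
    unmapped = [o for o in table.otu_ids if o not in taxa.mapping]
    if unmapped:
        raise KeyError(f"OTUs without a group mapping: {unmapped[:10]}")
    total = table.counts.sum()
    if total == 0:
        raise ValueError("empty count table")
    result: list[tuple[str, float, CountTable]] = []
    for group in taxa.groups():
        otus = [o for o in table.otu_ids if taxa.mapping[o] == group]
        if not otus:
            continue
        sub = table.select_otus(otus)
        pooled = sub.counts.sum() / total
        presence = (sub.row_sums > 0).mean()
        if pooled >= min_rel_abund and presence >= min_presence:
            result.append((group, pooled, sub))
        else:
            logger.info(
                "group %s excluded (pooled abundance %.4f, presence %.2f)",
                group, pooled, presence,
            )
    result.sort(key=lambda t: -t[1])
    return [(g, sub) for g, _, sub in result]
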