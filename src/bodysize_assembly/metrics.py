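"""Community and geographic distance metrics.

Bray-Curtis dissimilarity and alpha diversity (richness, Chao1) on
rarefied count tables, plus haversine great-circle distances between
sampling sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_model import CountTable, SampleInfo

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "DistanceMatrix",
    "AlphaDiversity",
    "bray_curtis",
    "alpha_diversity",
    "geographic_distance",
    "EARTH_RADIUS_KM",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance/dissimilarity matrix with ids."""

    ids: list[str]
    values: np.ndarray
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("matrix has negative entries")
        self.values = v

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed (pdist) order."""
        return squareform(self.values, checks=False)

    def pairs(self) -> list[tuple[str, str]]:
        n = len(self.ids)
        return [(self.ids[i], self.ids[j]) for i in range(n) for j in range(i + 1, n)]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            Path(path), sep="\t", index_label="id"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, units: str = "dimensionless") -> "DistanceMatrix":
        df = pd.read_csv(Path(path), sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(), units)


@dataclass
class AlphaDiversity:
    sample_id: str
    richness: int
    chao1: float

    def __post_init__(self) -> None:
        if self.richness < 0:
            raise ValueError("richness must be >= 0")
        if self.chao1 < self.richness - 1e-9:
            raise ValueError("chao1 must be >= richness")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity BC(x,y) = Σ|x−y| / Σ(x+y)."""
    if (table.row_sums == 0).any():
        empty = [s for s, n in zip(table.sample_ids, table.row_sums) if n == 0]
        raise ValueError(f"all-zero samples have undefined Bray-Curtis: {empty}")
    d = pdist(table.counts.astype(float), metric="braycurtis")
    return DistanceMatrix(list(table.sample_ids), squareform(d), "dimensionless")


def _chao1(row: np.ndarray) -> float:
    s_obs = int((row > 0).sum())
    f1 = int((row == 1).sum())
    f2 = int((row == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    # bias-corrected form when no doubletons are observed
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity(table: CountTable) -> list[AlphaDiversity]:
    """Observed richness and the Chao1 richness estimator per sample.

    Chao1 = S_obs + F1²/(2 F2) with singleton/doubleton counts F1/F2;
    the bias-corrected variant S_obs + F1(F1−1)/(2(F2+1)) is used when
    F2 = 0 to avoid division by zero.
    """
    out = []
    for sid, row in zip(table.sample_ids, table.counts):
        out.append(AlphaDiversity(sid, int((row > 0).sum()), _chao1(row)))
    return out


def geographic_distance(samples: Sequence[SampleInfo]) -> DistanceMatrix:
    """Haversine great-circle distance matrix (km), Earth radius 6371 km."""
    lat = np.radians([s.latitude for s in samples])
    lon = np.radians([s.longitude for s in samples])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix([s.sample_id for s in samples], d, "km")
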