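"""Outlying Mean Index (OMI) niche analysis.

Each OTU's niche position is its abundance-weighted mean location in
standardized environmental space; its OMI is the squared Euclidean
distance between that position and the study-area mean (the origin after
centering, with every site weighted equally).  Low OMI = conditions used
match the regional average = wide niche breadth; high OMI = marginal
niche, i.e. stronger environmental selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import CountTable, SampleInfo, TaxonMap

logger = logging.getLogger(__name__)

__all__ = ["OMIRecord", "standardize_environment", "omi_per_otu", "group_omi"]


@dataclass
class OMIRecord:
    otu_id: str
    niche_position: np.ndarray  # coordinates in standardized env space
    omi: float                  # squared distance from the study centroid
    weight: int                 # OTU total abundance

    def __post_init__(self) -> None:
        if self.omi < 0:
            raise ValueError("omi must be >= 0")


def standardize_environment(
    samples: Sequence[SampleInfo],
    variables: Sequence[str] | None = None,
    pca: bool = False,
) -> pd.DataFrame:
    """Center and scale environmental variables to mean 0, population
    (divide-by-n) standard deviation 1.

    With ``pca=True`` the standardized table is additionally rotated
    onto its principal axes, keeping all non-null components; since this
    is an orthogonal rotation of a full-rank space, OMI values are
    identical either way.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 sites")
    if variables is None:
        variables = list(samples[0].env)
    if not variables:
        raise ValueError("no environmental variables given")
    data = np.array([[s.env[v] for v in variables] for s in samples], dtype=float)
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=0)
    constant = [v for v, s in zip(variables, sd) if s == 0]
    if constant:
        raise ValueError(f"constant environmental variables cannot be standardized: {constant}")
    z = (data - mean) / sd
    ids = [s.sample_id for s in samples]
    if pca:
        # full-rank rotation via SVD; component count = rank of z
        u, sv, vt = np.linalg.svd(z, full_matrices=False)
        keep = sv > 1e-10 * sv.max()
        z = z @ vt[keep].T
        cols = [f"PC{k + 1}" for k in range(int(keep.sum()))]
        return pd.DataFrame(z, index=ids, columns=cols)
    return pd.DataFrame(z, index=ids, columns=list(variables))


def omi_per_otu(table: CountTable, env: pd.DataFrame) -> list[OMIRecord]:
    """OMI for every OTU with at least one read.

    ``env`` is the standardized site × variable table; the study-area
    centroid is the unweighted mean of site coordinates (the origin
    after centering — every site counts equally, regardless of its
    richness or read total).
    """
    if list(env.index) != list(table.sample_ids):
        if set(env.index) != set(table.sample_ids):
            raise ValueError("environment and count table have mismatched sample ids")
        env = env.loc[table.sample_ids]
    coords = env.to_numpy(dtype=float)
    centroid = coords.mean(axis=0)
    out: list[OMIRecord] = []
    totals = table.counts.sum(axis=0)
    for k, otu in enumerate(table.otu_ids):
        total = int(totals[k])
        if total == 0:
            continue
        w = table.counts[:, k] / total
        pos = w @ coords
        out.append(OMIRecord(otu, pos, float(((pos - centroid) ** 2).sum()), total))
    return out


def group_omi(
    records: Sequence[OMIRecord], taxa: TaxonMap
) -> pd.DataFrame:
    """Per-group OMI summary: unweighted mean over member OTUs (the
    headline statistic) plus the abundance-weighted mean and OTU count."""
    if not records:
        raise ValueError("no OMI records given")
    rows = []
    by_group: dict[str, list[OMIRecord]] = {}
    for r in records:
        g = taxa.mapping.get(r.otu_id)
        if g is None:
            raise KeyError(f"OTU {r.otu_id!r} has no group mapping")
        by_group.setdefault(g, []).append(r)
    for g in taxa.groups():
        members = by_group.get(g, [])
        if not members:
            logger.warning("group %s has no occurring OTUs; skipped in OMI summary", g)
            continue
        omis = np.array([r.omi for r in members])
        weights = np.array([r.weight for r in members], dtype=float)
        rows.append(
            {
                "group": g,
                "mean_omi": float(omis.mean()),
                "weighted_mean_omi": float((omis * weights).sum() / weights.sum()),
                "n_otus": len(members),
            }
        )
    return pd.DataFrame(rows).set_index("group")
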