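"""Abundance-based β-null deviation model.

Each null replicate reassembles every sample under two hard constraints
taken from the observed table — the sample's richness R_j and its read
total N_j — by (1) drawing R_j distinct OTUs with selection probability
proportional to each OTU's occurrence (number of samples occupied), and
(2) seeding each selected OTU with one read and distributing the
remaining N_j − R_j reads multinomially with probabilities proportional
to the selected OTUs' total observed abundances.  The null deviation
value (NDV) of a sample pair is its observed Bray-Curtis dissimilarity
minus the mean dissimilarity over the null replicates: NDV near 0 means
assembly indistinguishable from stochastic reassembly; NDV near ±1 means
strongly deterministic structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .data_model import CountTable, TaxonMap

logger = logging.getLogger(__name__)

__all__ = ["NDVResult", "null_assemble", "ndv", "group_ndv"]


@dataclass
class NDVResult:
    pair_ids: list[tuple[str, str]]
    observed_bc: np.ndarray   # per pair, condensed order
    null_mean_bc: np.ndarray  # per pair, mean over replicates
    ndv: np.ndarray           # observed − null mean, per pair
    n_reps: int
    mean_ndv: float
    mean_abs_ndv: float


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw k distinct indices, successively weighted by ``weights``.

    Exponential-clock construction: index i gets key E_i / w_i with
    E_i ~ Exp(1); the k smallest keys are exactly a sequential weighted
    sample without replacement.  Zero-weight indices are never drawn.
    """
    w = np.asarray(weights, dtype=float)
    positive = int((w > 0).sum())
    if k > positive:
        raise ValueError(
            f"cannot draw {k} distinct OTUs from {positive} with positive weight"
        )
    keys = np.full(w.shape, np.inf)
    pos = w > 0
    keys[pos] = rng.exponential(size=int(pos.sum())) / w[pos]
    if k == len(w):
        return np.arange(len(w))
    idx = np.argpartition(keys, k)[:k]
    return idx


def null_assemble(
    table: CountTable, seed: int | None = None, rng: np.random.Generator | None = None
) -> CountTable:
    """One richness- and read-total-preserving null reassembly of ``table``."""
    if rng is None:
        rng = np.random.default_rng(seed)
    occurrence = (table.counts > 0).sum(axis=0).astype(float)
    abundance = table.counts.sum(axis=0).astype(float)
    out = np.zeros_like(table.counts)
    for j in range(table.n_samples):
        row = table.counts[j]
        r_j = int((row > 0).sum())
        n_j = int(row.sum())
        if r_j == 0:
            continue
        sel = _weighted_sample_without_replacement(occurrence, r_j, rng)
        out[j, sel] = 1
        remaining = n_j - r_j
        if remaining > 0:
            p = abundance[sel]
            p = p / p.sum()
            out[j, sel] += rng.multinomial(remaining, p)
    return CountTable(list(table.sample_ids), list(table.otu_ids), out)


def ndv(table: CountTable, n_reps: int = 999, seed: int | None = None) -> NDVResult:
    """Null deviation values for every unordered sample pair.

    Observed Bray-Curtis per pair minus the mean Bray-Curtis of
    ``n_reps`` independent null reassemblies (default 999).
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if table.n_samples < 2:
        raise ValueError("NDV needs at least 2 samples")
    if (table.row_sums == 0).any():
        raise ValueError("NDV undefined with all-zero samples; drop them first")
    rng = np.random.default_rng(seed)
    observed = pdist(table.counts.astype(float), metric="braycurtis")
    null_sum = np.zeros_like(observed)
    for _ in range(n_reps):
        null = null_assemble(table, rng=rng)
        null_sum += pdist(null.counts.astype(float), metric="braycurtis")
    null_mean = null_sum / n_reps
    dev = observed - null_mean
    n = table.n_samples
    pair_ids = [
        (table.sample_ids[i], table.sample_ids[j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return NDVResult(
        pair_ids=pair_ids,
        observed_bc=observed,
        null_mean_bc=null_mean,
        ndv=dev,
        n_reps=n_reps,
        mean_ndv=float(dev.mean()),
        mean_abs_ndv=float(np.abs(dev).mean()),
    )


def group_ndv(
    table: CountTable,
    taxa: TaxonMap,
    groups: list[tuple[str, CountTable]],
    n_reps: int = 999,
    seed: int | None = None,
) -> list[tuple[str, NDVResult]]:
    """NDV per dominant group, each on its own sample × group-OTU sub-table.

    Samples with zero reads of a group are dropped (and logged) for that
    group; groups left with fewer than 2 non-empty samples are skipped
    with a warning.  Occurrence and abundance weights come from the
    group sub-table itself.
    """
    child_seeds = np.random.SeedSequence(seed).spawn(len(groups))
    out: list[tuple[str, NDVResult]] = []
    for (group, sub), child in zip(groups, child_seeds):
        nonempty = sub.drop_empty_samples()
        dropped = sub.n_samples - nonempty.n_samples
        if dropped:
            logger.info("group %s: dropped %d empty samples for NDV", group, dropped)
        if nonempty.n_samples < 2:
            logger.warning("group %s skipped: fewer than 2 non-empty samples", group)
            continue
        rng_seed = int(child.generate_state(1)[0] % (2**31))
        out.append((group, ndv(nonempty, n_reps=n_reps, seed=rng_seed)))
    return out
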