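"""Sloan neutral community model: dispersal-rate estimation.

The model predicts the occurrence frequency of taxon i across a set of
local communities of size N from its mean relative abundance p_i in the
metacommunity and a single dispersal (immigration) rate m:

    Freq_i = 1 − I(1/N | N·m·p_i, N·m·(1−p_i)),

where I(x | α, β) is the regularized incomplete beta function — the CDF
of the beta occupancy approximation — evaluated at the detection
threshold of one individual (relative abundance 1/N).  m is estimated by
least squares of observed occurrence frequencies on this prediction;
fit quality is the generalized R² = 1 − SSerr/SStotal, which can be
negative for poorly fitting communities and is deliberately not clipped.

A binomial-sampling null (local communities as random subsets of the
metacommunity, Freq_i = 1 − (1 − p_i)^N) provides the no-drift,
no-dispersal-limitation comparison; the two models are compared by AIC
over bootstrap replicates resampling OTUs with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .data_model import CountTable

__all__ = [
    "NeutralFit",
    "BinomialComparison",
    "predicted_frequency",
    "fit_sloan",
    "wilson_ci",
    "compare_binomial",
]


def predicted_frequency(p, m: float, n_individuals: int):
    """Neutral-model occurrence frequency for relative abundance ``p``.

    Vectorized over ``p``.  Limits: p = 0 → 0 and p = 1 → 1 (degenerate
    beta distributions).
    """
    if not 0 < m <= 1:
        raise ValueError(f"dispersal rate m must be in (0, 1], got {m}")
    if n_individuals < 1:
        raise ValueError(f"community size N must be >= 1, got {n_individuals}")
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("relative abundances must lie in [0, 1]")
    nm = n_individuals * m
    out = np.empty(p.shape, dtype=float)
    interior = (p > 0) & (p < 1)
    out[p == 0] = 0.0
    out[p == 1] = 1.0
    if interior.any():
        a = nm * p[interior]
        b = nm * (1.0 - p[interior])
        out[interior] = 1.0 - special.betainc(a, b, 1.0 / n_individuals)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class NeutralFit:
    m: float
    n_individuals: int
    otu_ids: list[str]
    freq: np.ndarray             # observed occurrence frequency per OTU
    mean_rel_abund: np.ndarray   # p_i per OTU
    predicted: np.ndarray        # model frequency at fitted m
    r_squared: float
    ci_lower: np.ndarray         # Wilson 95% band around the prediction
    ci_upper: np.ndarray
    partition: list[str]         # {above, within, below} the CI band
    n_samples: int


@dataclass
class BinomialComparison:
    aic_neutral_mean: float
    aic_binomial_mean: float
    delta_aic_mean: float        # AIC(neutral) − AIC(binomial); negative favors neutral
    delta_aic_ci: tuple[float, float]
    n_boot: int
    aic_neutral: np.ndarray = field(repr=False, default=None)
    aic_binomial: np.ndarray = field(repr=False, default=None)


def wilson_ci(freq_hat: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score 95% interval for a proportion ``freq_hat`` of ``n`` trials."""
    if not 0 <= freq_hat <= 1:
        raise ValueError(f"proportion must be in [0, 1], got {freq_hat}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    p = float(freq_hat)
    denom = 1.0 + z * z / n
    center = (p + z * z / (2.0 * n)) / denom
    half = (z / denom) * np.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n))
    return (max(0.0, center - half), min(1.0, center + half))


def _sum_sq_err(m: float, p: np.ndarray, freq: np.ndarray, n_ind: int) -> float:
    pred = predicted_frequency(p, m, n_ind)
    return float(((freq - pred) ** 2).sum())


def _fit_m(p: np.ndarray, freq: np.ndarray, n_ind: int) -> float:
    # bounded scalar least squares with multi-start: the objective can be
    # nearly flat toward the m -> 1 boundary
    best_m, best_obj = None, np.inf
    for lo, hi in ((1e-6, 0.05), (0.02, 0.3), (0.2, 1.0)):
        res = optimize.minimize_scalar(
            _sum_sq_err,
            bounds=(lo, hi),
            args=(p, freq, n_ind),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun < best_obj:
            best_obj, best_m = float(res.fun), float(res.x)
    if best_m is None or not np.isfinite(best_obj):
        raise RuntimeError("neutral-model fit failed to converge on any bracket")
    return best_m


def fit_sloan(table: CountTable, n_individuals: int | None = None) -> NeutralFit:
    """Fit the neutral model to a rarefied count table.

    N is the common row sum (rarefaction depth); p_i is each OTU's mean
    relative abundance across samples; Freq_i is the fraction of samples
    occupied.  OTUs absent everywhere are excluded before fitting.

    For tables with unequal row sums (e.g. a group's sub-table of an
    evenly rarefied whole-community table) pass ``n_individuals``
    explicitly, typically the mean row sum; p_i is then the mean of
    per-sample relative abundances.
    """
    sums = table.row_sums
    if (sums == 0).any():
        raise ValueError("drop all-zero samples before fitting")
    if n_individuals is None:
        if len(set(sums.tolist())) != 1:
            raise ValueError(
                "unequal per-sample read totals; rarefy the table to even depth "
                "first or pass n_individuals explicitly"
            )
        n_ind = int(sums[0])
    else:
        if n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        n_ind = int(n_individuals)
    present = table.counts.sum(axis=0) > 0
    if present.sum() < 10:
        raise ValueError(f"need >= 10 occurring OTUs to fit, have {int(present.sum())}")
    otu_ids = [o for o, keep in zip(table.otu_ids, present) if keep]
    counts = table.counts[:, present]
    n_samples = table.n_samples
    p = (counts / sums[:, None]).mean(axis=0)
    freq = (counts > 0).mean(axis=0)
    m = _fit_m(p, freq, n_ind)
    pred = predicted_frequency(p, m, n_ind)
    ss_err = float(((freq - pred) ** 2).sum())
    ss_tot = float(((freq - freq.mean()) ** 2).sum())
    r2 = 1.0 - ss_err / ss_tot if ss_tot > 0 else float("nan")
    bounds = np.array([wilson_ci(f, n_samples) for f in pred])
    lower, upper = bounds[:, 0], bounds[:, 1]
    partition = [
        "above" if f > u else "below" if f < lo else "within"
        for f, lo, u in zip(freq, lower, upper)
    ]
    return NeutralFit(
        m=m,
        n_individuals=n_ind,
        otu_ids=otu_ids,
        freq=freq,
        mean_rel_abund=p,
        predicted=pred,
        r_squared=r2,
        ci_lower=lower,
        ci_upper=upper,
        partition=partition,
        n_samples=n_samples,
    )


def binomial_frequency(p, n_individuals: int):
    """Occurrence frequency under pure binomial subsampling: 1 − (1−p)^N."""
    p = np.asarray(p, dtype=float)
    out = 1.0 - (1.0 - p) ** n_individuals
    if out.ndim == 0:
        return float(out)
    return out


def _aic_ls(ss_err: float, n: int, k: int) -> float:
    # Gaussian-likelihood AIC for a least-squares fit with k free parameters
    return n * np.log(max(ss_err, 1e-300) / n) + 2.0 * k


def compare_binomial(
    table: CountTable,
    fit: NeutralFit,
    n_boot: int = 1000,
    seed: int | None = None,
) -> BinomialComparison:
    """AIC comparison of the neutral model (k = 1) against binomial
    subsampling (k = 0) over bootstrap replicates resampling OTUs with
    replacement; the neutral m is refitted within each replicate."""
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    rng = np.random.default_rng(seed)
    p = fit.mean_rel_abund
    freq = fit.freq
    n_ind = fit.n_individuals
    n_otus = len(p)
    aic_n = np.empty(n_boot)
    aic_b = np.empty(n_boot)
    for b in range(n_boot):
        idx = (
            np.arange(n_otus)
            if n_boot == 1
            else rng.integers(0, n_otus, size=n_otus)
        )
        pb, fb = p[idx], freq[idx]
        mb = _fit_m(pb, fb, n_ind)
        ss_n = _sum_sq_err(mb, pb, fb, n_ind)
        ss_b = float(((fb - binomial_frequency(pb, n_ind)) ** 2).sum())
        aic_n[b] = _aic_ls(ss_n, n_otus, k=1)
        aic_b[b] = _aic_ls(ss_b, n_otus, k=0)
    delta = aic_n - aic_b
    lo, hi = (
        (float(delta[0]), float(delta[0]))
        if n_boot == 1
        else tuple(np.percentile(delta, [2.5, 97.5]))
    )
    return BinomialComparison(
        aic_neutral_mean=float(aic_n.mean()),
        aic_binomial_mean=float(aic_b.mean()),
        delta_aic_mean=float(delta.mean()),
        delta_aic_ci=(float(lo), float(hi)),
        n_boot=n_boot,
        aic_neutral=aic_n,
        aic_binomial=aic_b,
    )
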