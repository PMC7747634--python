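"""Spatial/environmental variation partitioning of community composition.

Community variation (Hellinger-transformed counts, redundancy analysis)
is decomposed into pure environmental, pure spatial, shared and residual
fractions using Ezekiel-adjusted R² of the env-only, spatial-only and
joint models.  Spatial predictors are Moran's eigenvector maps built
with the classical PCNM recipe: truncate the geographic distance matrix
at the longest minimum-spanning-tree edge, replace beyond-threshold
distances by four times the threshold, double-center, and keep the
positive-eigenvalue eigenvectors scaled by the square root of their
eigenvalues.  Predictors enter through forward selection with the
double stopping criterion (global-model significance gate, per-step
permutation test at alpha, and the global adjusted-R² cap); the two
pure fractions are tested by residual-permutation partial RDA.
Negative adjusted fractions are reported as-is, never clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .data_model import CountTable
from .metrics import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VarPartResult",
    "hellinger",
    "build_mem",
    "forward_select",
    "variation_partition",
]


@dataclass
class VarPartResult:
    pure_env: float
    pure_spatial: float
    shared: float
    residual: float
    unadjusted: dict[str, float] = field(default_factory=dict)
    selected_env: list[str] = field(default_factory=list)
    selected_mem: list[str] = field(default_factory=list)
    p_pure_env: float = float("nan")
    p_pure_spatial: float = float("nan")
    r2_adj_env: float = float("nan")
    r2_adj_spatial: float = float("nan")
    r2_adj_both: float = float("nan")


def hellinger(counts: np.ndarray) -> np.ndarray:
    """Hellinger transform: sqrt of row-relative abundances."""
    counts = np.asarray(counts, dtype=float)
    sums = counts.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise ValueError("all-zero rows cannot be Hellinger-transformed")
    return np.sqrt(counts / sums)


def _as_response(response) -> np.ndarray:
    """Accept a CountTable (Hellinger-transformed here) or a pre-transformed
    numeric matrix, and return the column-centered response."""
    if isinstance(response, CountTable):
        y = hellinger(response.counts)
    else:
        y = np.asarray(response, dtype=float)
    return y - y.mean(axis=0)


def _orthobasis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of the centered predictors."""
    xc = x - x.mean(axis=0)
    if xc.size == 0:
        return np.empty((x.shape[0], 0))
    q, r = np.linalg.qr(xc)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def _r2(y: np.ndarray, basis: np.ndarray) -> float:
    ss_tot = float((y**2).sum())
    if basis.shape[1] == 0:
        return 0.0
    ss_fit = float(((basis.T @ y) ** 2).sum())
    return ss_fit / ss_tot


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Ezekiel's adjustment: 1 − (1 − R²)(n − 1)/(n − 1 − k)."""
    if k == 0:
        return 0.0
    if n - 1 - k <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - k)


# ---------------------------------------------------------------------------
# Moran's eigenvector maps (classical PCNM)
# ---------------------------------------------------------------------------

def build_mem(geo: DistanceMatrix) -> pd.DataFrame:
    """Spatial eigenvectors from a truncated geographic distance matrix."""
    n = len(geo.ids)
    if n < 4:
        raise ValueError(f"need at least 4 sites to build MEMs, have {n}")
    d = geo.values.copy()
    off = ~np.eye(n, dtype=bool)
    if (d[off] == 0).any():
        logger.warning("duplicate site coordinates; jittering zero distances by 1e-6 km")
        d[off & (d == 0)] = 1e-6
    mst = minimum_spanning_tree(d)
    threshold = float(mst.data.max())
    trunc = d.copy()
    trunc[trunc > threshold] = 4.0 * threshold
    np.fill_diagonal(trunc, 0.0)
    a = -0.5 * trunc**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    g = (g + g.T) / 2.0
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-8 * max(abs(eigval[0]), 1.0)
    keep = eigval > tol
    vecs = eigvec[:, keep] * np.sqrt(eigval[keep])
    cols = [f"MEM{k + 1}" for k in range(int(keep.sum()))]
    return pd.DataFrame(vecs, index=geo.ids, columns=cols)


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = list(df.columns[~keep])
    if dropped:
        logger.warning("dropping constant candidate predictors: %s", dropped)
    return (df.loc[:, keep] - df.loc[:, keep].mean(axis=0)) / sd[keep]


def _global_test(y: np.ndarray, x: np.ndarray, n_perm: int, rng: np.random.Generator):
    basis = _orthobasis(x)
    k = basis.shape[1]
    n = y.shape[0]
    r2 = _r2(y, basis)
    if n - 1 - k <= 0:
        return r2, k, 1.0
    f_obs = (r2 / k) / ((1.0 - r2) / (n - 1 - k))
    exceed = 0
    for _ in range(n_perm):
        yp = y[rng.permutation(n)]
        r2p = _r2(yp, basis)
        fp = (r2p / k) / ((1.0 - r2p) / (n - 1 - k))
        if fp >= f_obs:
            exceed += 1
    return r2, k, (exceed + 1) / (n_perm + 1)


def forward_select(
    response,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> list[str]:
    """Forward selection of predictors for the community response.

    ``response`` is a CountTable (Hellinger-transformed internally) or an
    already-transformed matrix; ``candidates`` a site × predictor table
    (standardized internally).  Selection stops when the best remaining
    candidate's residual-permutation p exceeds ``alpha`` or when the
    cumulative adjusted R² would exceed that of the global model; a
    non-significant global model selects nothing.
    """
    rng = np.random.default_rng(seed)
    y = _as_response(response)
    x_all = _standardize(candidates)
    if x_all.shape[1] == 0:
        return []
    n = y.shape[0]
    r2_global, k_global, p_global = _global_test(y, x_all.to_numpy(), n_perm, rng)
    if p_global > alpha:
        logger.info("global model not significant (p=%.3f); nothing selected", p_global)
        return []
    adj_global = adjusted_r2(r2_global, n, k_global)
    ss_tot = float((y**2).sum())
    selected: list[str] = []
    q = np.empty((n, 0))
    y_res = y.copy()
    ss_res = ss_tot
    remaining = list(x_all.columns)
    while remaining:
        best_name, best_gain, best_r = None, -1.0, None
        for name in remaining:
            v = x_all[name].to_numpy()
            r = v - v.mean()
            if q.shape[1]:
                r = r - q @ (q.T @ r)
            norm = np.linalg.norm(r)
            if norm < 1e-10:
                continue
            r = r / norm
            gain = float(((r @ y_res) ** 2).sum())
            if gain > best_gain:
                best_name, best_gain, best_r = name, gain, r
        if best_name is None:
            break
        df_res = n - 1 - (len(selected) + 1)
        if df_res <= 0:
            break
        f_obs = best_gain / ((ss_res - best_gain) / df_res)
        # residual permutation under the reduced (currently selected) model
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        r_perm = best_r[perms]                       # (n_perm, n)
        gains = ((r_perm @ y_res) ** 2).sum(axis=1)  # (n_perm,)
        f_perm = gains / ((ss_res - gains) / df_res)
        p = (int((f_perm >= f_obs).sum()) + 1) / (n_perm + 1)
        if p > alpha:
            break
        r2_new = 1.0 - (ss_res - best_gain) / ss_tot
        adj_new = adjusted_r2(r2_new, n, len(selected) + 1)
        if adj_new > adj_global + 1e-12:
            logger.info("adjusted R² would exceed the global model; stopping")
            break
        selected.append(best_name)
        remaining.remove(best_name)
        q = np.hstack([q, best_r[:, None]])
        y_res = y_res - best_r[:, None] * (best_r @ y_res)
        ss_res -= best_gain
    return selected


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def _partial_test(
    y: np.ndarray,
    x: np.ndarray,
    z: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value for the effect of X given Z (partial RDA),
    permuting residuals of the reduced (Z-only) model."""
    n = y.shape[0]
    qz = _orthobasis(z) if z.size else np.empty((n, 0))
    qfull = _orthobasis(np.hstack([z, x]) if z.size else x)
    df1 = qfull.shape[1] - qz.shape[1]
    df2 = n - 1 - qfull.shape[1]
    if df1 <= 0 or df2 <= 0:
        return float("nan")

    def f_stat(yy: np.ndarray) -> float:
        ss_full = float(((qfull.T @ yy) ** 2).sum())
        ss_z = float(((qz.T @ yy) ** 2).sum()) if qz.shape[1] else 0.0
        ss_res = float((yy**2).sum()) - ss_full
        return ((ss_full - ss_z) / df1) / (ss_res / df2)

    f_obs = f_stat(y)
    fitted = qz @ (qz.T @ y) if qz.shape[1] else np.zeros_like(y)
    resid = y - fitted
    exceed = 0
    for _ in range(n_perm):
        yp = fitted + resid[rng.permutation(n)]
        yp = yp - yp.mean(axis=0)
        if f_stat(yp) >= f_obs:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


def variation_partition(
    response,
    env: pd.DataFrame | None,
    mem: pd.DataFrame | None,
    n_perm: int = 999,
    seed: int | None = None,
) -> VarPartResult:
    """Partition community variation between an environmental block and a
    spatial (MEM) block.

    Fractions come from adjusted R² of the env-only, spatial-only and
    joint RDA models: pure_env = R²adj(both) − R²adj(spatial),
    pure_spatial = R²adj(both) − R²adj(env), shared is the complement
    within R²adj(both), residual = 1 − R²adj(both).  The two pure
    fractions are tested by residual-permutation partial RDA (the shared
    fraction is not testable and gets no p-value).
    """
    rng = np.random.default_rng(seed)
    y = _as_response(response)
    n = y.shape[0]
    env_x = env.to_numpy(dtype=float) if env is not None and env.shape[1] else np.empty((n, 0))
    mem_x = mem.to_numpy(dtype=float) if mem is not None and mem.shape[1] else np.empty((n, 0))
    if env_x.shape[1] == 0 and mem_x.shape[1] == 0:
        raise ValueError("both predictor blocks are empty")

    def block_r2(x: np.ndarray) -> tuple[float, int]:
        basis = _orthobasis(x)
        return _r2(y, basis), basis.shape[1]

    r2_env, k_env = block_r2(env_x)
    r2_spa, k_spa = block_r2(mem_x)
    r2_both, k_both = block_r2(np.hstack([env_x, mem_x]))
    adj_env = adjusted_r2(r2_env, n, k_env)
    adj_spa = adjusted_r2(r2_spa, n, k_spa)
    adj_both = adjusted_r2(r2_both, n, k_both)
    unadj = {
        "pure_env": r2_both - r2_spa,
        "pure_spatial": r2_both - r2_env,
        "shared": r2_env + r2_spa - r2_both,
        "residual": 1.0 - r2_both,
    }
    p_env = (
        _partial_test(y, env_x, mem_x, n_perm, rng) if env_x.shape[1] else float("nan")
    )
    p_spa = (
        _partial_test(y, mem_x, env_x, n_perm, rng) if mem_x.shape[1] else float("nan")
    )
    return VarPartResult(
        pure_env=adj_both - adj_spa,
        pure_spatial=adj_both - adj_env,
        shared=adj_env + adj_spa - adj_both,
        residual=1.0 - adj_both,
        unadjusted=unadj,
        selected_env=list(env.columns) if env is not None else [],
        selected_mem=list(mem.columns) if mem is not None else [],
        p_pure_env=p_env,
        p_pure_spatial=p_spa,
        r2_adj_env=adj_env,
        r2_adj_spatial=adj_spa,
        r2_adj_both=adj_both,
    )
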