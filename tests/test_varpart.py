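import numpy as np
import pandas as pd
import pytest

from bodysize_assembly.data_model import CountTable
from bodysize_assembly.metrics import DistanceMatrix
from bodysize_assembly.varpart import (
    build_mem,
    forward_select,
    hellinger,
    variation_partition,
)

# Eigenvalues of the classical PCNM construction on a regular 10-site
# transect spanning 900 km (truncation at the 100 km MST edge), frozen
# from an independent R vegan::pcnm run on the same coordinates.
VEGAN_PCNM_EIGENVALUES = [
    206188.02992468,
    182412.94978298,
    142312.25195028,
    104220.35613535,
    58652.77425901,
    19156.15586933,
]


def _regular_transect(n=10, span=900.0) -> DistanceMatrix:
    x = np.linspace(0, span, n)
    d = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix([f"s{i}" for i in range(n)], d, "km")


class TestBuildMEM:
    def test_matches_vegan_pcnm_eigenvalues(self):
        mem = build_mem(_regular_transect())
        eigvals = (mem.to_numpy() ** 2).sum(axis=0)
        assert np.allclose(eigvals, VEGAN_PCNM_EIGENVALUES, rtol=1e-6)

    def test_columns_orthogonal(self):
        mem = build_mem(_regular_transect(12)).to_numpy()
        gram = mem.T @ mem
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6

    def test_vector_count_order_n_over_2(self):
        n = 20
        mem = build_mem(_regular_transect(n))
        assert n // 3 <= mem.shape[1] <= 2 * n // 3

    def test_first_vector_is_coarsest_wave(self):
        n = 10
        mem = build_mem(_regular_transect(n))
        half_cosine = np.cos(np.pi * np.arange(n) / (n - 1))
        r = np.corrcoef(half_cosine, mem.iloc[:, 0])[0, 1]
        assert abs(r) > 0.9

    def test_duplicate_sites_jittered(self, caplog):
        x = np.array([0.0, 0.0, 10.0, 20.0, 30.0])
        d = np.abs(x[:, None] - x[None, :])
        geo = DistanceMatrix([f"s{i}" for i in range(5)], d, "km")
        with caplog.at_level("WARNING"):
            mem = build_mem(geo)
        assert mem.shape[0] == 5

    def test_too_few_sites(self):
        with pytest.raises(ValueError, match="4 sites"):
            build_mem(_regular_transect(3))


def _make_response(x: np.ndarray, rng: np.random.Generator, noise=0.05, p=12):
    """Community-like response matrix driven by predictor x."""
    loadings = rng.normal(size=p)
    y = np.outer(x, loadings) + noise * rng.normal(size=(len(x), p))
    return y


class TestForwardSelect:
    def test_perfect_predictor_selected_first(self):
        rng = np.random.default_rng(0)
        n = 25
        cands = pd.DataFrame(
            rng.normal(size=(n, 4)), columns=["v1", "v2", "v3", "v4"]
        )
        y = _make_response(cands["v1"].to_numpy(), rng, noise=0.01)
        for seed in range(5):
            sel = forward_select(y, cands, n_perm=99, seed=seed)
            assert sel and sel[0] == "v1"

    def test_pure_noise_selects_nothing_usually(self):
        n = 25
        empty = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            cands = pd.DataFrame(rng.normal(size=(n, 5)),
                                 columns=[f"v{i}" for i in range(5)])
            y = rng.normal(size=(n, 10))
            if not forward_select(y, cands, alpha=0.05, n_perm=199, seed=seed):
                empty += 1
        assert empty >= 18  # type-I control at the 0.05 level

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        cands = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        y = _make_response(cands["b"].to_numpy(), rng, noise=0.3)
        assert forward_select(y, cands, n_perm=99, seed=11) == forward_select(
            y, cands, n_perm=99, seed=11
        )


class TestVariationPartition:
    def test_unadjusted_fractions_sum_to_one_exactly(self, rng):
        n = 20
        env = pd.DataFrame(rng.normal(size=(n, 2)), columns=["e1", "e2"])
        mem = pd.DataFrame(rng.normal(size=(n, 3)), columns=["M1", "M2", "M3"])
        counts = rng.integers(1, 30, size=(n, 10))
        t = CountTable([f"s{i}" for i in range(n)], [f"o{j}" for j in range(10)], counts)
        res = variation_partition(t, env, mem, n_perm=49, seed=0)
        assert sum(res.unadjusted.values()) == pytest.approx(1.0, abs=1e-12)
        adj = res.pure_env + res.pure_spatial + res.shared + res.residual
        assert adj == pytest.approx(1.0, abs=1e-9)

    def test_env_driven_orthogonal_design(self):
        # env and spatial blocks orthogonal; response built from env only
        rng = np.random.default_rng(1)
        n = 40
        basis = np.linalg.qr(rng.normal(size=(n, 4)))[0]
        env = pd.DataFrame(basis[:, :2], columns=["e1", "e2"])
        mem = pd.DataFrame(basis[:, 2:], columns=["M1", "M2"])
        y = _make_response(env["e1"].to_numpy(), rng, noise=0.02) + _make_response(
            env["e2"].to_numpy(), rng, noise=0.02
        )
        res = variation_partition(y, env, mem, n_perm=99, seed=2)
        assert abs(res.pure_spatial) < 0.02
        # exact orthogonality shows in the unadjusted overlap; the adjusted
        # shared fraction absorbs the Ezekiel penalty of the ~zero spatial model
        assert abs(res.unadjusted["shared"]) < 0.02
        assert res.pure_env > 0.5

    def test_noise_response_fractions_near_zero(self):
        n = 50
        for seed in range(20):
            rng = np.random.default_rng(seed)
            env = pd.DataFrame(rng.normal(size=(n, 2)), columns=["e1", "e2"])
            mem = pd.DataFrame(rng.normal(size=(n, 2)), columns=["M1", "M2"])
            y = rng.normal(size=(n, 15))
            res = variation_partition(y, env, mem, n_perm=9, seed=seed)
            for frac in (res.pure_env, res.pure_spatial, res.shared):
                assert abs(frac) < 0.05

    def test_block_relabel_symmetry(self, rng):
        n = 25
        env = pd.DataFrame(rng.normal(size=(n, 2)), columns=["e1", "e2"])
        mem = pd.DataFrame(rng.normal(size=(n, 2)), columns=["M1", "M2"])
        y = rng.normal(size=(n, 8)) + np.outer(env["e1"], rng.normal(size=8))
        a = variation_partition(y, env, mem, n_perm=29, seed=5)
        b = variation_partition(y, mem, env, n_perm=29, seed=5)
        assert a.pure_env == pytest.approx(b.pure_spatial, abs=1e-10)
        assert a.pure_spatial == pytest.approx(b.pure_env, abs=1e-10)
        assert a.shared == pytest.approx(b.shared, abs=1e-10)

    def test_joint_model_dominates_blocks(self, rng):
        n = 25
        env = pd.DataFrame(rng.normal(size=(n, 2)), columns=["e1", "e2"])
        mem = pd.DataFrame(rng.normal(size=(n, 3)), columns=["M1", "M2", "M3"])
        y = rng.normal(size=(n, 12))
        res = variation_partition(y, env, mem, n_perm=9, seed=6)
        # monotonicity holds for the raw R² (the adjusted version can drop
        # when a block adds no signal, by design of the adjustment)
        u = res.unadjusted
        r2_both = 1.0 - u["residual"]
        r2_env = r2_both - u["pure_spatial"]
        r2_spatial = r2_both - u["pure_env"]
        assert r2_both >= max(r2_env, r2_spatial) - 1e-9

    def test_empty_blocks_rejected(self, rng):
        y = rng.normal(size=(10, 5))
        with pytest.raises(ValueError, match="empty"):
            variation_partition(y, None, None, n_perm=9, seed=0)


class TestHellinger:
    def test_rows_unit_norm(self, rng):
        counts = rng.integers(1, 40, size=(6, 9))
        h = hellinger(counts)
        assert np.allclose((h**2).sum(axis=1), 1.0)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            hellinger(np.array([[0, 0], [1, 2]]))
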