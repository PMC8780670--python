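"""Moran's I, its permutation test, the per-stratum screen, and the differential filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from lrnet.moran import differential_filter, knn_graph, moran_test, morans_i, screen_genes
from lrnet.synthetic import SyntheticConfig, generate


def ring_coords(n):
    theta = 2 * np.pi * np.arange(n) / n
    return np.c_[np.cos(theta), np.sin(theta)]


class TestKnnGraph:
    def test_collinear_middle_node_gains_neighbor_by_symmetrization(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        g = knn_graph(coords, k=1)
        degrees = np.asarray(g.adjacency.sum(axis=1)).ravel()
        assert degrees[1] == 2  # both ends pick the middle point

    def test_k_equal_n_minus_one_is_complete(self):
        coords = np.random.default_rng(0).normal(size=(7, 2))
        g = knn_graph(coords, k=6)
        assert g.W == 7 * 6

    @pytest.mark.parametrize("k", [0, -1, 20])
    def test_invalid_k_raises(self, k):
        with pytest.raises(ValueError):
            knn_graph(np.random.default_rng(0).normal(size=(20, 2)), k=k)

    def test_matches_brute_force_on_random_clouds(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 30))
            k = int(rng.integers(1, 6))
            coords = rng.normal(size=(n, 2))
            g = knn_graph(coords, k=k)
            got = set(zip(*g.adjacency.nonzero()))
            assert got == oracles.brute_knn(coords, k)

    def test_nonfinite_coords_rejected(self):
        coords = np.array([[0.0, 0.0], [np.nan, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="finite"):
            knn_graph(coords, k=1)


class TestMoransI:
    def test_alternating_ring_is_perfect_dispersion(self):
        n = 24
        g = knn_graph(ring_coords(n), k=2)
        x = np.tile([1.0, -1.0], n // 2)
        assert morans_i(x, g) == pytest.approx(-1.0, abs=1e-12)

    def test_constant_vector_is_flagged_undefined(self):
        g = knn_graph(ring_coords(10), k=2)
        assert math.isnan(morans_i(np.ones(10), g))
        i, p = moran_test(np.full(10, 3.0), g, n_perm=99, seed=0)
        assert math.isnan(i) and math.isnan(p)

    def test_matches_dense_quadratic_form(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 50))
            g = knn_graph(rng.normal(size=(n, 2)), k=int(rng.integers(1, min(6, n))))
            x = rng.normal(size=n)
            assert morans_i(x, g) == pytest.approx(oracles.dense_moran(x, g.adjacency), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(min_value=-10, max_value=10).filter(lambda v: abs(v) > 1e-6),
        b=st.floats(min_value=-10, max_value=10),
    )
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(5)
        g = knn_graph(rng.normal(size=(30, 2)), k=4)
        x = rng.normal(size=30)
        assert morans_i(a * x + b, g) == pytest.approx(morans_i(x, g), rel=1e-9, abs=1e-9)


class TestMoranTest:
    def test_permutation_mean_matches_randomization_expectation(self, rng):
        n = 60
        g = knn_graph(rng.normal(size=(n, 2)), k=5)
        x = rng.normal(size=n)
        z = x - x.mean()
        denom = z @ z
        vals = [
            (n / g.W) * (zp @ (g.adjacency @ zp)) / denom
            for zp in (rng.permutation(z) for _ in range(4000))
        ]
        assert np.mean(vals) == pytest.approx(-1 / (n - 1), abs=0.01)

    def test_strong_gradient_is_highly_significant(self, rng):
        coords = rng.normal(size=(200, 2))
        g = knn_graph(coords, k=10)
        i, p = moran_test(coords[:, 0], g, n_perm=999, seed=3)
        assert i > 0.5
        assert p <= 0.01

    def test_analytic_approximation_agrees_in_tail_behavior(self, rng):
        coords = rng.normal(size=(200, 2))
        g = knn_graph(coords, k=10)
        _, p_smooth = moran_test(coords[:, 0], g, method="analytic")
        assert p_smooth < 1e-6
        _, p_null = moran_test(rng.normal(size=200), g, method="analytic")
        assert p_null > 0.01

    def test_too_few_permutations_rejected(self, rng):
        g = knn_graph(rng.normal(size=(20, 2)), k=3)
        with pytest.raises(ValueError):
            moran_test(rng.normal(size=20), g, n_perm=50)


def smooth_screen_config(seed=11, n_cells=400):
    return SyntheticConfig(
        cell_types=("ct1",),
        clusters_per_type=(("ct1", 1),),
        conditions=("condA", "condB"),
        cells_per_group=n_cells,
        genes=("SMOOTH01", "NULL001", "NULL002", "RARE01"),
        smooth=(
            (("SMOOTH01", "ct1", "condA"), (0.05, 0.65)),
        ),
        detection=((("RARE01", "ct1", "condA"), 0.004), (("RARE01", "ct1", "condB"), 0.004)),
        base_detection=0.35,
        seed=seed,
    )


class TestScreenGenes:
    def test_planted_smooth_gene_is_present_and_rare_gene_is_gated(self):
        ds = generate(smooth_screen_config())
        res = screen_genes(
            ds.matrix, ds.annotation, ds.coords, "ct1", "condA",
            k=15, n_perm=199, seed=0,
        )
        res = res.set_index("gene")
        assert bool(res.at["SMOOTH01", "present"])
        assert res.at["SMOOTH01", "I"] > 0.1
        # detected in <1% of cells: never present regardless of I
        assert res.at["RARE01", "frac_expr"] < 0.01
        assert not bool(res.at["RARE01", "present"])

    def test_stratum_smaller_than_k_plus_one_is_skipped(self):
        ds = generate(smooth_screen_config(n_cells=10))
        res = screen_genes(ds.matrix, ds.annotation, ds.coords, "ct1", "condA", k=15, n_perm=199)
        assert len(res) == 0

    def test_negative_moran_gene_is_never_present(self):
        # alternating values on a ring give I = -1; force them in as raw counts
        import scipy.sparse as sp
        n = 40
        coords = pd.DataFrame(ring_coords(n), columns=["dim1", "dim2"],
                              index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"))
        counts = np.tile([3, 1], n // 2)[None, :]
        from lrnet.expression import ExpressionMatrix
        m = ExpressionMatrix(sp.csr_matrix(counts), pd.Index(["ALT"]), coords.index)
        ann = pd.DataFrame({"cell_id": coords.index, "cell_type": "ct1",
                            "cluster_id": "c1", "condition": "condA", "sample_id": "s1"})
        res = screen_genes(m, ann, coords, "ct1", "condA", k=2, n_perm=199, seed=0)
        assert res.at[0, "I"] < 0
        assert not bool(res.at[0, "present"])


class TestDifferentialFilter:
    @staticmethod
    def make_res(entries, **params):
        defaults = {"k": 15, "min_frac": 0.01, "alpha": 0.05, "n_perm": 199, "method": "permutation"}
        defaults.update(params)
        df = pd.DataFrame(
            [
                {"gene": g, "group": "ct1", "condition": "x", "I": i, "p": 0.001,
                 "q": 0.01, "frac_expr": 0.5, "present": present, "reason": ""}
                for (g, i, present) in entries
            ],
            columns=["gene", "group", "condition", "I", "p", "q", "frac_expr", "present", "reason"],
        )
        df.attrs["moran_params"] = defaults
        return df

    def test_rule_table_with_boundary_cases(self):
        res_a = self.make_res([
            ("ONE_HIGH", 0.15, True),     # single-condition, I > 0.1 -> retained
            ("ONE_LOW", 0.05, True),      # single-condition, I <= 0.1 -> dropped
            ("ONE_EDGE", 0.10, True),     # exactly 0.1: strict > -> dropped
            ("BOTH_FAR", 0.30, True),     # |delta| = 0.25 -> retained
            ("BOTH_NEAR", 0.30, True),    # |delta| = 0.05 -> dropped
            ("BOTH_EDGE", 0.30, True),    # |delta| = 0.1 exactly -> dropped
            ("ABSENT", 0.50, False),      # not present on either side -> not listed
        ])
        res_b = self.make_res([
            ("BOTH_FAR", 0.05, True),
            ("BOTH_NEAR", 0.25, True),
            ("BOTH_EDGE", 0.20, True),
            ("B_ONLY_HIGH", 0.12, True),
        ])
        calls = differential_filter(res_a, res_b).set_index("gene")
        assert "ABSENT" not in calls.index
        decisions = calls["decision"].to_dict()
        assert decisions == {
            "ONE_HIGH": "retained",
            "ONE_LOW": "dropped",
            "ONE_EDGE": "dropped",
            "BOTH_FAR": "retained",
            "BOTH_NEAR": "dropped",
            "BOTH_EDGE": "dropped",
            "B_ONLY_HIGH": "retained",
        }
        assert calls.at["BOTH_FAR", "pattern"] == "both"
        assert calls.at["ONE_HIGH", "pattern"] == "A_only"
        assert calls.at["B_ONLY_HIGH", "pattern"] == "B_only"

    def test_parameter_mismatch_is_an_error(self):
        res_a = self.make_res([("G", 0.3, True)])
        res_b = self.make_res([("G", 0.3, True)], k=30)
        with pytest.raises(ValueError, match="mismatch"):
            differential_filter(res_a, res_b)


def test_planted_condition_specific_recovery():
    """20 condition-specific smooth genes vs 480 nulls over 1000 cells: the
    differential filter recovers >= 90% of the planted genes and admits <= 2 nulls."""
    n_smooth, n_null = 20, 480
    genes = tuple(f"S{i:02d}" for i in range(n_smooth)) + tuple(f"N{i:03d}" for i in range(n_null))
    config = SyntheticConfig(
        cell_types=("ct1",),
        clusters_per_type=(("ct1", 1),),
        conditions=("condA", "condB"),
        cells_per_group=500,
        genes=genes,
        smooth=tuple(((f"S{i:02d}", "ct1", "condA"), (0.05, 0.65)) for i in range(n_smooth)),
        base_detection=0.35,
        seed=20260929,
    )
    ds = generate(config)
    # 999 permutations: with a 500-gene BH family and ~20 true positives, the
    # minimum attainable q is p_min * m / rank ~= 0.001 * 500 / 20 = 0.025;
    # at 199 permutations (p_min = 0.005) q <= 0.05 would be unreachable.
    kwargs = dict(k=15, n_perm=999, min_frac=0.01, alpha=0.05)
    res_a = screen_genes(ds.matrix, ds.annotation, ds.coords, "ct1", "condA", seed=1, **kwargs)
    res_b = screen_genes(ds.matrix, ds.annotation, ds.coords, "ct1", "condB", seed=2, **kwargs)
    calls = differential_filter(res_a, res_b)
    retained = set(calls.loc[calls["decision"] == "retained", "gene"])
    planted = {f"S{i:02d}" for i in range(n_smooth)}
    assert len(retained & planted) >= 0.9 * n_smooth
    assert len(retained - planted) <= 2
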