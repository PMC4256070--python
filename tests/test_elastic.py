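import numpy as np
import pytest

from channelkit.elastic import (
    ElasticNetwork,
    anm_correlation,
    build_hessian,
    build_kirchhoff,
    decompose,
    degenerate_groups,
    gnm_correlation,
    mode_contribution,
    mode_shape,
    normalized_cross_correlation,
)
from channelkit.errors import NetworkError
from channelkit.structures import CoarseStructure
from channelkit.synthetic import make_chain, make_ring
from conftest import random_structure


def two_nodes(d=5.0):
    return CoarseStructure(["A", "A"], [1, 2], [[0, 0, 0], [d, 0, 0]])


class TestKirchhoff:
    def test_two_node_matrix(self):
        net = build_kirchhoff(two_nodes(), cutoff=10)
        np.testing.assert_array_equal(net.matrix, [[1, -1], [-1, 1]])

    def test_path3_spectrum(self):
        # independent oracle: direct 3x3 eigensolve of the path Laplacian
        oracle = np.linalg.eigvalsh(
            np.array([[1, -1, 0], [-1, 2, -1], [0, -1, 1]], float)
        )
        net = build_kirchhoff(make_chain(3, 8.0), cutoff=10)
        d = decompose(net)
        np.testing.assert_allclose(d.eigenvalues, oracle, atol=1e-10)
        np.testing.assert_allclose(d.eigenvalues, [0, 1, 3], atol=1e-10)

    @pytest.mark.parametrize(
        "n,expected",
        [
            (6, sorted(2 - 2 * np.cos(2 * np.pi * k / 6) for k in range(6))),
            (4, sorted(2 - 2 * np.cos(2 * np.pi * k / 4) for k in range(4))),
        ],
    )
    def test_ring_circulant_closed_form(self, n, expected):
        d = decompose(build_kirchhoff(make_ring(n, 3.8), cutoff=4.0))
        np.testing.assert_allclose(d.eigenvalues, expected, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_row_sums_exactly_zero(self, seed):
        s = random_structure(60, seed=seed, box=25.0)
        net = build_kirchhoff(s, cutoff=10)
        np.testing.assert_array_equal(net.matrix.sum(axis=1), np.zeros(60))
        assert np.all(net.matrix == net.matrix.T)

    def test_off_diagonal_is_minus_one_within_cutoff(self):
        s = random_structure(30, seed=4, box=20.0)
        net = build_kirchhoff(s, cutoff=10)
        for i in range(30):
            for j in range(i + 1, 30):
                within = np.linalg.norm(s.coords[i] - s.coords[j]) <= 10
                assert net.matrix[i, j] == (-1.0 if within else 0.0)

    def test_disconnected_graph_warns_and_gets_extra_zero_modes(self, caplog):
        s = CoarseStructure(
            ["A"] * 4, [1, 2, 3, 4],
            [[0, 0, 0], [3, 0, 0], [100, 0, 0], [103, 0, 0]],
        )
        with caplog.at_level("WARNING"):
            net = build_kirchhoff(s, cutoff=10)
        assert not net.connected
        assert any("components" in r.message for r in caplog.records)
        assert decompose(net).zero_mode_count == 2


def pair_energy(coords_flat, coords0, pairs):
    x = coords_flat.reshape(-1, 3)
    x0 = coords0
    e = 0.0
    for i, j in pairs:
        d = np.linalg.norm(x[i] - x[j])
        d0 = np.linalg.norm(x0[i] - x0[j])
        e += 0.5 * (d - d0) ** 2
    return e


class TestHessian:
    def test_block_row_sums_are_zero_blocks(self):
        s = random_structure(25, seed=3, box=20.0)
        net = build_hessian(s, cutoff=15)
        h = net.matrix
        n = len(s)
        for i in range(n):
            block_sum = sum(
                h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] for j in range(n)
            )
            np.testing.assert_allclose(block_sum, np.zeros((3, 3)), atol=1e-12)

    def test_matches_finite_difference_oracle(self):
        s = random_structure(20, seed=9, box=12.0)
        net = build_hessian(s, cutoff=1e6)  # all pairs connected
        pairs = [(i, j) for i in range(20) for j in range(i + 1, 20)]
        x0 = s.coords.flatten()
        h = 1e-4
        n = len(x0)
        numeric = np.zeros((n, n))
        for a in range(n):
            ea = np.zeros(n)
            ea[a] = h
            for b in range(a, n):
                eb = np.zeros(n)
                eb[b] = h
                numeric[a, b] = numeric[b, a] = (
                    pair_energy(x0 + ea + eb, s.coords, pairs)
                    - pair_energy(x0 + ea - eb, s.coords, pairs)
                    - pair_energy(x0 - ea + eb, s.coords, pairs)
                    + pair_energy(x0 - ea - eb, s.coords, pairs)
                ) / (4 * h * h)
        scale = np.max(np.abs(numeric))
        np.testing.assert_allclose(net.matrix, numeric, atol=1e-5 * scale)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_connected_structure_has_exactly_six_zero_modes(self, seed):
        s = random_structure(30, seed=seed, box=18.0)
        d = decompose(build_hessian(s, cutoff=25.0))
        assert d.zero_mode_count == 6

    def test_two_node_nonzero_mode_is_along_axis(self):
        d = decompose(build_hessian(two_nodes(5.0), cutoff=10))
        assert d.zero_mode_count == 5  # 1D spring: single non-zero mode
        vec = d.mode_vector(1).reshape(2, 3)
        # displacement purely along x (the inter-node axis)
        np.testing.assert_allclose(vec[:, 1:], 0.0, atol=1e-10)

    def test_collinear_geometry_warns(self, caplog):
        with caplog.at_level("WARNING"):
            build_hessian(make_chain(5, 3.8), cutoff=20)
        assert any("collinear" in r.message for r in caplog.records)


class TestDecompose:
    def test_non_psd_matrix_is_error(self):
        bad = ElasticNetwork("GNM", np.diag([-1.0, 1.0]), 10, 1.0, 2, True)
        with pytest.raises(NetworkError, match="not PSD"):
            decompose(bad)

    def test_eigenvectors_orthonormal(self, bundle_gnm):
        v = bundle_gnm.eigenvectors
        np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)

    def test_c4_degenerate_slow_pairs(self, bundle_gnm):
        groups = degenerate_groups(bundle_gnm, n_modes=6)
        degenerate_pairs = [g for g in groups if len(g) >= 2]
        assert len(degenerate_pairs) >= 2

    def test_deterministic_eigenvector_sign(self, bundle):
        d1 = decompose(build_kirchhoff(bundle))
        d2 = decompose(build_kirchhoff(bundle))
        np.testing.assert_array_equal(d1.eigenvectors, d2.eigenvectors)
        for k in range(d1.eigenvectors.shape[1]):
            col = d1.eigenvectors[:, k]
            assert col[np.argmax(np.abs(col))] > 0


class TestGnmCorrelation:
    def test_two_node_msf_and_cross_term(self):
        d = decompose(build_kirchhoff(two_nodes(), cutoff=10))
        c = gnm_correlation(d, "all")
        # oracle: 3 * pinv(Γ), pinv = ¼[[1,−1],[−1,1]]
        np.testing.assert_allclose(c, [[0.75, -0.75], [-0.75, 0.75]], atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_mode_equals_scaled_pseudoinverse(self, seed):
        s = random_structure(40, seed=seed, box=20.0)
        d = decompose(build_kirchhoff(s, cutoff=10))
        c = gnm_correlation(d, "all")
        oracle = 3.0 * np.linalg.pinv(
            build_kirchhoff(s, cutoff=10).matrix, hermitian=True
        )
        np.testing.assert_allclose(c, oracle, atol=1e-8)

    def test_requesting_zero_mode_is_error(self, bundle_gnm):
        with pytest.raises(NetworkError, match="zero modes"):
            gnm_correlation(bundle_gnm, [0])

    def test_symmetric_structure_equal_diagonal(self, bundle, bundle_gnm):
        msf = np.diag(gnm_correlation(bundle_gnm, "all"))
        per_chain = msf.reshape(4, -1)
        for k in range(1, 4):
            np.testing.assert_allclose(per_chain[k], per_chain[0], atol=1e-8)


class TestAnmCorrelation:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_full_mode_equals_trace_of_pseudoinverse_blocks(self, seed):
        s = random_structure(25, seed=seed, box=18.0)
        net = build_hessian(s, cutoff=20)
        d = decompose(net)
        c = anm_correlation(d, "all")
        hinv = np.linalg.pinv(net.matrix, hermitian=True, rcond=1e-10)
        n = len(s)
        oracle = np.array(
            [
                [np.trace(hinv[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]) for j in range(n)]
                for i in range(n)
            ]
        )
        np.testing.assert_allclose(c, oracle, atol=1e-8)

    def test_single_mode_cauchy_schwarz(self, bundle_anm):
        c = anm_correlation(bundle_anm, [1])
        diag = np.diag(c)
        assert np.all(c**2 <= np.outer(diag, diag) + 1e-12)

    def test_c4_invariant_under_cyclic_chain_permutation(self, bundle, bundle_anm):
        c = anm_correlation(bundle_anm, "all")
        n = len(bundle) // 4
        perm = np.roll(np.arange(len(bundle)).reshape(4, n), 1, axis=0).flatten()
        np.testing.assert_allclose(c[np.ix_(perm, perm)], c, atol=1e-6)


class TestNormalizedCrossCorrelation:
    def test_diagonal_exactly_one(self, bundle_gnm):
        c = normalized_cross_correlation(gnm_correlation(bundle_gnm, "all"))
        np.testing.assert_array_equal(np.diag(c), np.ones(len(c)))

    def test_two_node_single_mode_perfectly_anticorrelated(self):
        d = decompose(build_kirchhoff(two_nodes(), cutoff=10))
        c = normalized_cross_correlation(gnm_correlation(d, [1]))
        assert c[0, 1] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_bounded_in_unit_interval(self, seed):
        s = random_structure(30, seed=seed, box=18.0)
        d = decompose(build_kirchhoff(s, cutoff=10))
        c = normalized_cross_correlation(gnm_correlation(d, "all"))
        assert np.nanmax(np.abs(c)) <= 1 + 1e-12

    def test_zero_diagonal_excluded_with_warning(self, caplog):
        raw = np.array([[1.0, 0.0], [0.0, 0.0]])
        with caplog.at_level("WARNING"):
            c = normalized_cross_correlation(raw)
        assert np.isnan(c[1, 1]) and c[0, 0] == 1.0
        assert any("excluding" in r.message for r in caplog.records)


class TestModeContribution:
    def test_equal_eigenvalues_share_equally(self):
        # ring 4: non-zero eigenvalues {2, 2, 4}
        d = decompose(build_kirchhoff(make_ring(4, 3.8), cutoff=4))
        total_inv = 1 / 2 + 1 / 2 + 1 / 4
        assert mode_contribution(d, 1) == pytest.approx(100 * (1 / 2) / total_inv)
        assert mode_contribution(d, 2) == pytest.approx(mode_contribution(d, 1))

    def test_ring6_slow_mode_closed_form(self):
        d = decompose(build_kirchhoff(make_ring(6, 3.8), cutoff=4))
        expected = 100 * 1.0 / (1 + 1 + 1 / 3 + 1 / 3 + 1 / 4)
        assert mode_contribution(d, 1) == pytest.approx(expected)
        assert expected == pytest.approx(34.2857, abs=1e-3)

    @pytest.mark.parametrize("seed", [0, 2])
    def test_contributions_sum_to_100(self, seed):
        s = random_structure(35, seed=seed, box=18.0)
        d = decompose(build_kirchhoff(s, cutoff=10))
        total = sum(
            mode_contribution(d, k)
            for k in range(1, len(d.nonzero_eigenvalues) + 1)
        )
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_literal_convention_differs(self, bundle_gnm):
        inv = mode_contribution(bundle_gnm, 1, "inverse")
        lit = mode_contribution(bundle_gnm, 1, "literal")
        assert inv > lit  # slowest mode dominates only under inverse weighting

    def test_zero_mode_request_is_error(self, bundle_gnm):
        with pytest.raises(NetworkError):
            mode_contribution(bundle_gnm, 0)


class TestModeShape:
    def test_shapes_non_negative(self, bundle_gnm, bundle_anm):
        assert np.all(mode_shape(bundle_gnm, 1) >= 0)
        assert np.all(mode_shape(bundle_anm, 1) >= 0)

    def test_gnm_shape_matches_single_mode_diagonal(self, bundle_gnm):
        np.testing.assert_allclose(
            mode_shape(bundle_gnm, 2),
            np.diag(gnm_correlation(bundle_gnm, [2])),
            atol=1e-12,
        )
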