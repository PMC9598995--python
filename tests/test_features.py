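"""Feature encodings: distance maps, spatial filtering, SVD, SS, rASA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bindfeat import fixtures as fx
from bindfeat.constants import MAX_ASA_THEORETICAL
from bindfeat.features import (
    DistanceMap,
    FeatureEncoder,
    distance_map,
    merge_ss,
    neighborhood,
    onehot,
    rasa,
    spatial_filter,
    ss_onehot,
    svd_reduce,
)
from bindfeat.structio import ProteinStructure, Residue, ValidationError

from conftest import random_coords_dmap


def chain(coords, pid="t"):
    return ProteinStructure(pid, [
        Residue(i + 1, "A", tuple(map(float, c))) for i, c in enumerate(coords)
    ])


class TestDistanceMap:
    def test_single_residue(self):
        dm = distance_map(chain([[0, 0, 0]]))
        np.testing.assert_array_equal(dm.matrix, [[0.0]])

    def test_3_4_5_triangle(self):
        dm = distance_map(chain([[0, 0, 0], [3, 4, 0]]))
        np.testing.assert_allclose(dm.matrix, [[0, 5], [5, 0]])

    def test_matches_double_loop(self):
        """Brute-force pairwise oracle on a random 10-residue chain."""
        s = fx.synth_structure(10, "perturbed_chain", seed=11)
        dm = distance_map(s)
        xyz = s.ca_coords
        brute = np.array([
            [np.sqrt(((xyz[i] - xyz[j]) ** 2).sum()) for j in range(10)]
            for i in range(10)
        ])
        np.testing.assert_allclose(dm.matrix, brute, atol=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 30))
    def test_symmetric_zero_diagonal(self, seed, length):
        dm = random_coords_dmap(seed, length)
        np.testing.assert_allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)
        assert np.all(dm.matrix >= 0)


class TestNeighborhood:
    def test_radius_zero_is_self_only(self):
        dm = random_coords_dmap(3, 12)
        for i in (1, 5, 12):
            np.testing.assert_array_equal(neighborhood(dm, i, 0.0), [i])

    def test_collinear_geometry(self):
        dm = distance_map(chain([[0, 0, 0], [4, 0, 0], [8, 0, 0]]))
        np.testing.assert_array_equal(neighborhood(dm, 2, 5.0), [1, 2, 3])
        np.testing.assert_array_equal(neighborhood(dm, 1, 5.0), [1, 2])

    def test_saturates_at_chain_diameter(self):
        dm = random_coords_dmap(4, 15)
        assert len(neighborhood(dm, 7, dm.diameter + 1)) == 15

    def test_negative_radius_rejected(self):
        dm = random_coords_dmap(5, 5)
        with pytest.raises(ValueError):
            neighborhood(dm, 1, -1.0)


class TestSpatialFilter:
    def test_radius_zero_is_identity(self):
        dm = random_coords_dmap(6, 20)
        P = np.random.default_rng(6).random((20, 30))
        np.testing.assert_array_equal(spatial_filter(P, dm, 0.0), P)

    def test_mean_of_two(self):
        dm = distance_map(chain([[0, 0, 0], [5, 0, 0]]))
        P = np.vstack([np.ones(30), 3 * np.ones(30)])
        out = spatial_filter(P, dm, 7.0)
        np.testing.assert_allclose(out, 2 * np.ones((2, 30)))

    def test_equals_brute_force_neighborhood_mean(self):
        """Per-residue explicit loop oracle on a 15-residue fixture."""
        dm = random_coords_dmap(7, 15, spread=8.0)
        P = np.random.default_rng(7).random((15, 30))
        out = spatial_filter(P, dm, 7.0)
        for i in range(15):
            nbr = [j for j in range(15) if dm.matrix[i, j] <= 7.0]
            np.testing.assert_allclose(out[i], P[nbr].mean(axis=0),
                                       atol=1e-12)

    def test_large_radius_gives_global_mean_rows(self):
        dm = random_coords_dmap(8, 12)
        P = np.random.default_rng(8).random((12, 30))
        out = spatial_filter(P, dm, dm.diameter)
        np.testing.assert_allclose(out, np.tile(P.mean(0), (12, 1)),
                                   atol=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.0, 15.0))
    def test_output_within_column_hull(self, seed, radius):
        """Means cannot escape the per-column min/max of the input."""
        dm = random_coords_dmap(seed, 14)
        P = np.random.default_rng(seed).random((14, 30))
        out = spatial_filter(P, dm, radius)
        assert np.all(out >= P.min(axis=0) - 1e-12)
        assert np.all(out <= P.max(axis=0) + 1e-12)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(st.integers(0, 10_000))
    def test_permutation_equivariance(self, seed):
        """Relabeling residues consistently permutes the output rows."""
        rng = np.random.default_rng(seed)
        dm = random_coords_dmap(seed, 13)
        P = rng.random((13, 30))
        perm = rng.permutation(13)
        dm_p = DistanceMap("p", dm.matrix[np.ix_(perm, perm)])
        out = spatial_filter(P, dm, 6.0)
        out_p = spatial_filter(P[perm], dm_p, 6.0)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-12)

    def test_dimension_mismatch(self):
        dm = random_coords_dmap(9, 10)
        with pytest.raises(ValidationError):
            spatial_filter(np.zeros((9, 30)), dm, 5.0)


class TestSvdReduce:
    def test_full_rank_preserves_frobenius_norm(self):
        dm = random_coords_dmap(10, 12)
        out = svd_reduce(dm, 12)
        assert np.linalg.norm(out) == pytest.approx(
            np.linalg.norm(dm.matrix), rel=1e-10
        )

    def test_full_rank_reconstruction(self):
        """A' V_kᵀ = A V Vᵀ reconstructs A when k = L."""
        dm = random_coords_dmap(11, 10)
        A = dm.matrix
        _, s, vt = np.linalg.svd(A)
        out = svd_reduce(dm, 10)
        # recover the sign-fixed V the implementation used
        V = vt.T.copy()
        flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(10)])
        V *= flip
        np.testing.assert_allclose(out @ V.T, A, atol=1e-8)

    @pytest.mark.parametrize("k", [2, 5, 8])
    def test_truncation_error_is_discarded_spectrum(self, k):
        """‖A − A V_k V_kᵀ‖_F equals sqrt(sum of discarded σ²)."""
        dm = random_coords_dmap(12, 12)
        A = dm.matrix
        out, s = svd_reduce(dm, k, return_spectrum=True)
        _, _, vt = np.linalg.svd(A)
        V = vt.T[:, :k]
        flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(k)])
        recon_err = np.linalg.norm(A - out @ (V * flip).T)
        assert recon_err == pytest.approx(np.sqrt((s[k:] ** 2).sum()),
                                          abs=1e-8)

    def test_projection_columns_orthonormal_and_sorted(self):
        dm = random_coords_dmap(13, 15)
        out, s = svd_reduce(dm, 15, return_spectrum=True)
        assert np.all(np.diff(s) <= 1e-9)
        # A'ᵀA' = V Σᵀ Σ Vᵀ has the singular values on its diagonal squared
        _, sv, vt = np.linalg.svd(dm.matrix)
        V = vt.T[:, :15]
        np.testing.assert_allclose(V.T @ V, np.eye(15), atol=1e-8)

    def test_sign_determinism(self):
        dm = random_coords_dmap(14, 9)
        a = svd_reduce(dm, 4)
        b = svd_reduce(DistanceMap("b", dm.matrix.copy()), 4)
        np.testing.assert_array_equal(a, b)

    def test_k_out_of_range(self):
        dm = random_coords_dmap(15, 6)
        with pytest.raises(ValueError):
            svd_reduce(dm, 7)
        with pytest.raises(ValueError):
            svd_reduce(dm, 0)


class TestSecondaryStructure:
    @pytest.mark.parametrize("code,expected", [
        ("H", "H"), ("G", "H"), ("I", "H"),
        ("B", "E"), ("E", "E"),
        ("T", "C"), ("S", "C"), (" ", "C"), ("P", "C"), ("?", "C"),
    ])
    def test_merge_rules(self, code, expected):
        assert merge_ss(code) == expected

    def test_idempotent_on_merged_states(self):
        for c in "HEC":
            assert merge_ss(merge_ss(c)) == merge_ss(c)

    def test_onehot_rows(self, chain25):
        _, _, _, records = chain25
        out = ss_onehot(records)
        assert out.shape == (25, 3)
        np.testing.assert_array_equal(out.sum(axis=1), np.ones(25))


class TestRasa:
    def test_definition_and_bounds(self):
        assert rasa(MAX_ASA_THEORETICAL["A"], "A") == 1.0
        assert rasa(0.0, "W") == 0.0
        assert rasa(MAX_ASA_THEORETICAL["G"] * 1.2, "G") == 1.0  # clipped
        assert rasa(64.5, "A") == pytest.approx(0.5)

    def test_unknown_residue(self):
        with pytest.raises(KeyError):
            rasa(10.0, "X")


class TestOneHot:
    def test_single_residue(self):
        row = onehot("A")
        assert row.shape == (1, 20)
        assert row[0, 0] == 1.0 and row.sum() == 1.0

    def test_rows_sum_to_one_and_distinct(self):
        out = onehot("ACD")
        np.testing.assert_array_equal(out.sum(axis=1), np.ones(3))
        assert len(set(map(int, out.argmax(axis=1)))) == 3

    def test_nonstandard_maps_to_zero_row(self):
        with pytest.warns(UserWarning, match="non-standard"):
            out = onehot("AXU")
        np.testing.assert_array_equal(out[1:], np.zeros((2, 20)))


class TestFeatureEncoder:
    def test_blocks_shapes_and_metadata(self, chain25):
        s, profile, _, records = chain25
        fs = FeatureEncoder(radius=7.0, k=8).encode(s, profile, records)
        assert fs.block_widths == {
            "onehot": 20, "hhblits": 30, "space_hhblits": 30,
            "svd": 8, "ss": 3, "rasa": 1,
        }
        assert fs.metadata == {"radius": 7.0, "k": 8}
        assert np.all((fs.blocks["rasa"] >= 0) & (fs.blocks["rasa"] <= 1))

    def test_radius_zero_space_block_equals_profile(self, chain25):
        s, profile, _, records = chain25
        fs = FeatureEncoder(radius=0.0, blocks=("hhblits", "space_hhblits")
                            ).encode(s, profile)
        np.testing.assert_array_equal(fs.blocks["space_hhblits"],
                                      fs.blocks["hhblits"])

    def test_missing_inputs_error(self, chain25):
        s, profile, _, _ = chain25
        with pytest.raises(ValidationError):
            FeatureEncoder(blocks=("ss",)).encode(s, profile)
        with pytest.raises(ValidationError):
            FeatureEncoder(blocks=("hhblits",)).encode(s)

    def test_concat_layout(self, chain25):
        s, profile, _, records = chain25
        fs = FeatureEncoder().encode(s, profile, records)
        X, slices = fs.concat(("onehot", "svd", "rasa"))
        assert X.shape == (25, 29)
        assert slices == {"onehot": (0, 20), "svd": (20, 28),
                          "rasa": (28, 29)}
        np.testing.assert_array_equal(X[:, 20:28], fs.blocks["svd"])
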