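"""Jaccard / PCoA / multivariate dispersion / CA axis 1 / LTG strength.

The fixture-matrix expectations were computed independently with the R
package vegan (betadisper with type="centroid" on Jaccard distances, and
cca site scores with scaling="none") and frozen here, so the distance-to-
centroid and correspondence-analysis implementations are checked against
the reference used in community ecology.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from paleobeta.metrics import (
    CorrespondenceAnalysis,
    DistanceMatrix,
    PCoA,
    beta_diversity,
    ca_axis1,
    jaccard_matrix,
    ltg_strength,
    multivariate_dispersion,
)

# vegan::betadisper(vegdist(X, "jaccard"), type="centroid") on fixture_matrix
VEGAN_DISTANCES = np.array(
    [0.5340802, 0.5187699, 0.4227601, 0.5530096, 0.5203596, 0.4636887, 0.5263285, 0.4644318]
)
VEGAN_BETA = 0.500428546158
# vegan::cca(X): axis-1 site scores, scaling="none", and first eigenvalue
VEGAN_CA1 = np.array(
    [0.8854778, 0.1875842, 0.6063575, -1.8399621, -0.2605864, 1.0929995, 1.3649235, -0.6327043]
)
VEGAN_CA_EIG = 0.39781825958


class TestJaccard:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            ([[1, 1, 0], [1, 1, 0]], 0.0),            # identical composition
            ([[1, 1, 0, 0], [0, 0, 1, 1]], 1.0),      # disjoint
            ([[1, 1, 0], [0, 1, 1]], 2.0 / 3.0),      # {a,b} vs {b,c}
        ],
    )
    def test_pairwise_values(self, rows, expected):
        d = jaccard_matrix(np.array(rows))
        assert d.values[0, 1] == pytest.approx(expected)

    def test_empty_locality_rejected(self):
        with pytest.raises(ValueError, match="zero taxa"):
            jaccard_matrix(np.array([[1, 1], [0, 0]]))

    @given(
        st.integers(0, 2**63 - 1).map(
            lambda s: (np.random.default_rng(s).random((6, 9)) < 0.5).astype(int)
        )
    )
    def test_triangle_inequality(self, X):
        X[X.sum(axis=1) == 0, 0] = 1
        d = jaccard_matrix(X).values
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestPCoA:
    def test_euclidean_configuration_recovered(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 2.0], [-1.0, 1.0]])
        D = squareform(pdist(pts))
        emb = PCoA().fit(D)
        got = squareform(pdist(emb.coordinates_))
        assert np.allclose(got, D, atol=1e-8)
        assert emb.imag_coordinates_.shape[1] == 0

    def test_equidistant_points_give_simplex_spectrum(self):
        n = 6
        D = np.ones((n, n)) - np.eye(n)
        emb = PCoA().fit(D)
        pos = emb.eigenvalues_[emb.eigenvalues_ > 1e-9]
        assert len(pos) == n - 1
        assert np.allclose(pos, pos[0])

    def test_two_point_symmetry(self):
        emb = PCoA().fit(np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert np.allclose(np.abs(emb.coordinates_.ravel()), 0.25)

    def test_eigenvalue_sum_equals_trace(self, fixture_matrix):
        d = jaccard_matrix(fixture_matrix)
        emb = PCoA().fit(d)
        assert emb.eigenvalues_.sum() == pytest.approx(emb.trace_, abs=1e-8)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            PCoA().fit(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestDispersion:
    def test_identical_compositions_give_zero_beta(self):
        X = np.tile([1, 0, 1, 1], (5, 1))
        assert beta_diversity(X) == pytest.approx(0.0, abs=1e-10)

    def test_matches_vegan_betadisper(self, fixture_matrix):
        res = multivariate_dispersion(jaccard_matrix(fixture_matrix))
        assert np.allclose(res.distances, VEGAN_DISTANCES, atol=1e-7)
        assert res.beta == pytest.approx(VEGAN_BETA, abs=1e-9)

    def test_euclidean_input_equals_brute_force_centroid(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 4))
        D = squareform(pdist(pts))
        res = multivariate_dispersion(D)
        want = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        assert np.allclose(np.sort(res.distances), np.sort(want), atol=1e-8)
        assert res.n_clamped == 0

    def test_symmetric_three_locality_example(self):
        X = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
        res = multivariate_dispersion(jaccard_matrix(X))
        assert np.allclose(res.distances, res.distances[0])

    def test_invariant_to_row_and_column_order(self, fixture_matrix):
        rng = np.random.default_rng(0)
        shuffled = fixture_matrix.sample(frac=1, random_state=1)[
            rng.permutation(fixture_matrix.columns)
        ]
        assert beta_diversity(shuffled) == pytest.approx(beta_diversity(fixture_matrix))


class TestCorrespondenceAnalysis:
    def test_matches_vegan_cca_axis1(self, fixture_matrix):
        ca = CorrespondenceAnalysis(method="svd", rescale=False).fit(fixture_matrix)
        got = ca.site_scores_.to_numpy()
        sign = np.sign(got[0] * VEGAN_CA1[0])
        assert np.allclose(sign * got, VEGAN_CA1, atol=1e-6)
        assert ca.eigenvalue_ == pytest.approx(VEGAN_CA_EIG, abs=1e-9)

    def test_reciprocal_averaging_agrees_with_svd(self, fixture_matrix):
        a = CorrespondenceAnalysis(method="svd", rescale=False).fit(fixture_matrix)
        b = CorrespondenceAnalysis(method="reciprocal", rescale=False).fit(fixture_matrix)
        sa, sb = a.site_scores_.to_numpy(), b.site_scores_.to_numpy()
        sign = np.sign(sa[0] * sb[0])
        assert np.allclose(sa, sign * sb, atol=1e-6)
        assert a.eigenvalue_ == pytest.approx(b.eigenvalue_, abs=1e-6)

    def test_two_block_matrix_separates_blocks(self):
        X = np.zeros((6, 6), dtype=int)
        X[:3, :3] = 1
        X[3:, 3:] = 1
        with pytest.warns(UserWarning, match="disconnected"):
            scores = ca_axis1(X, rescale=False).to_numpy()
        assert max(scores[:3]) < min(scores[3:]) or min(scores[:3]) > max(scores[3:])

    def test_banded_gradient_order_preserved(self):
        # banded diagonal incidence: sites ordered along a perfect gradient
        n, m = 10, 12
        X = np.zeros((n, m), dtype=int)
        for i in range(n):
            X[i, i : i + 3] = 1
        scores = ca_axis1(X, rescale=False).to_numpy()
        order = np.argsort(scores)
        assert list(order) == list(range(n)) or list(order) == list(range(n))[::-1]

    def test_permutation_invariance_up_to_sign(self, fixture_matrix):
        base = ca_axis1(fixture_matrix, rescale=False)
        perm = fixture_matrix.sample(frac=1, random_state=3)
        got = ca_axis1(perm, rescale=False).reindex(base.index)
        sign = np.sign(got.iloc[0] * base.iloc[0])
        assert np.allclose(base.to_numpy(), sign * got.to_numpy(), atol=1e-8)

    def test_rescaling_preserves_order(self, fixture_matrix):
        raw = ca_axis1(fixture_matrix, rescale=False)
        scaled = ca_axis1(fixture_matrix, rescale=True)
        # monotone (possibly sign-flipped) transform of the raw scores
        rho = np.corrcoef(
            pd.Series(raw).rank(), pd.Series(scaled).rank()
        )[0, 1]
        assert abs(rho) == pytest.approx(1.0)

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            CorrespondenceAnalysis().fit(np.array([[1, 1], [0, 0]]))


class TestLtgStrength:
    def test_perfectly_linear_scores(self):
        lat = np.array([30.0, 35.0, 40.0, 45.0])
        res = ltg_strength(2.0 * lat - 3.0, lat)
        assert res.r_squared == pytest.approx(1.0)

    def test_three_point_closed_form(self):
        lat = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 0.0])
        # OLS: slope 0, fitted = mean, SSE = 2/3, SST = 2/3 -> R^2 = 0
        assert ltg_strength(y, lat).r_squared == pytest.approx(0.0, abs=1e-12)

    def test_permutation_null_is_small(self):
        rng = np.random.default_rng(12)
        lat = np.linspace(25, 55, 200)
        r2 = [
            ltg_strength(rng.permutation(np.arange(200.0)), lat).r_squared
            for _ in range(500)
        ]
        assert np.percentile(r2, 95) < 0.05

    def test_affine_latitude_invariance(self):
        rng = np.random.default_rng(3)
        lat = rng.uniform(25, 55, 30)
        scores = rng.normal(size=30)
        a = ltg_strength(scores, lat).r_squared
        b = ltg_strength(scores, 2.5 * lat - 40.0).r_squared
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_variance_latitude_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ltg_strength(np.arange(5.0), np.full(5, 40.0))


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(ids=("a", "b"), values=np.array([[0.0, 1.0], [0.5, 0.0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(ids=("a", "b"), values=np.array([[0.5, 1.0], [1.0, 0.0]]))


def test_distance_matrix_csv_round_trip(fixture_matrix, tmp_path):
    d = jaccard_matrix(fixture_matrix)
    d.to_csv(tmp_path / "d.csv")
    back = DistanceMatrix.from_csv(tmp_path / "d.csv")
    assert back.ids == d.ids
    assert np.allclose(back.values, d.values, atol=1e-12)
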