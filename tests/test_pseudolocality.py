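"""Spatial distribution fitting, pseudo-locality sampling, bias trials."""

import numpy as np
import pytest
from scipy import stats

from paleobeta.occio import EmptyMatrixError
from paleobeta.pseudolocality import (
    BiasSpec,
    apply_bias,
    fit_spatial_distribution,
    replicate_ensemble,
    project_ranges_to_matrix,
    sample_pseudo_localities,
)
from paleobeta.ranges import GeoBounds, GeodesicDisk, central_angle_deg


def _coords(lat, lon):
    return np.column_stack([lat, lon])


class TestDistributionFitting:
    def test_normal_data_selects_normal_with_accurate_mean(self):
        rng = np.random.default_rng(1)
        lat = rng.normal(40, 3, 5000)
        lon = rng.normal(-100, 10, 5000)
        fit = fit_spatial_distribution(_coords(lat, lon))
        assert fit.lat.family == "normal"
        # MLE sampling error at n=5000: se = 3/sqrt(5000) ~ 0.042; 0.12 ~ 3 se
        assert fit.lat.params[0] == pytest.approx(40.0, abs=0.12)

    def test_beta_shaped_data_selects_beta(self):
        rng = np.random.default_rng(2)
        lat = stats.beta(2, 5).rvs(5000, random_state=rng) * 20 + 30
        lon = rng.normal(-100, 10, 5000)
        fit = fit_spatial_distribution(_coords(lat, lon))
        assert fit.lat.family == "beta"

    def test_gamma_shaped_data_selects_gamma(self):
        rng = np.random.default_rng(3)
        lat = stats.gamma(2, scale=3).rvs(5000, random_state=rng) + 25
        lon = rng.normal(-100, 10, 5000)
        fit = fit_spatial_distribution(_coords(lat, lon))
        assert fit.lat.family == "gamma"

    def test_minimum_point_guard(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_spatial_distribution(_coords(np.arange(5.0) + 30, np.arange(5.0) - 100))

    def test_constant_axis_rejected(self):
        lat = np.full(20, 40.0)
        lon = np.linspace(-110, -90, 20)
        with pytest.raises(ValueError, match="degenerate"):
            fit_spatial_distribution(_coords(lat, lon))


class TestSampling:
    @pytest.fixture
    def normal_fit(self):
        rng = np.random.default_rng(4)
        return fit_spatial_distribution(
            _coords(rng.normal(40, 3, 3000), rng.normal(-100, 8, 3000))
        )

    def test_deterministic_per_seed(self, normal_fit):
        a = sample_pseudo_localities(normal_fit, 100, seed=7)
        b = sample_pseudo_localities(normal_fit, 100, seed=7)
        assert np.array_equal(a, b)

    def test_sample_mean_converges(self, normal_fit):
        pts = sample_pseudo_localities(normal_fit, 10000, seed=1)
        # CLT at n=10^4: 2 se = 2 * 3 / 100 = 0.06
        assert pts[:, 0].mean() == pytest.approx(normal_fit.lat.params[0], abs=0.06)

    def test_exactly_n_points_inside_bounds(self, normal_fit):
        bounds = GeoBounds(38, 42, -104, -96)
        pts = sample_pseudo_localities(normal_fit, 500, bounds=bounds, seed=2)
        assert pts.shape == (500, 2)
        assert bounds.contains(pts[:, 0], pts[:, 1]).all()

    def test_incompatible_bounds_error(self, normal_fit):
        bounds = GeoBounds(80, 85, 100, 110)   # far outside the fitted support
        with pytest.raises(ValueError, match="rejection rate"):
            sample_pseudo_localities(normal_fit, 50, bounds=bounds, seed=3)

    def test_moment_convergence_of_variance(self, normal_fit):
        pts = sample_pseudo_localities(normal_fit, 10000, seed=5)
        want = float(normal_fit.lat.frozen().var())
        assert pts[:, 0].var() == pytest.approx(want, rel=0.08)

    def test_n_below_two_rejected(self, normal_fit):
        with pytest.raises(ValueError):
            sample_pseudo_localities(normal_fit, 1)


class TestRangeProjection:
    def test_covering_range_present_everywhere(self):
        pts = _coords(np.linspace(35, 45, 10), np.linspace(-105, -95, 10))
        big = GeodesicDisk(40.0, -100.0, 60.0)
        m = project_ranges_to_matrix({"A a": big, "B b": big}, pts)
        assert m.data.to_numpy().all() and m.n_localities == 10

    def test_boundary_point_counts_as_present(self):
        center = (40.0, -100.0)
        pt = np.array([[43.0, -104.0]])
        radius = float(central_angle_deg(pt[0, 0], pt[0, 1], *center))
        disk = GeodesicDisk(*center, radius)
        assert bool(disk.contains(pt[:, 0], pt[:, 1])[0])
        m = project_ranges_to_matrix(
            {"A a": disk, "B b": GeodesicDisk(*center, 90.0)},
            np.vstack([pt, pt + 0.1]),
            min_occurrences=1,
        )
        assert m.data.loc["P0000", "A a"] == 1

    def test_matches_brute_force_point_in_disk(self):
        rng = np.random.default_rng(6)
        pts = _coords(rng.uniform(30, 50, 20), rng.uniform(-120, -80, 20))
        disks = {
            f"S{k} s{k}": GeodesicDisk(rng.uniform(30, 50), rng.uniform(-120, -80),
                                       rng.uniform(3, 25))
            for k in range(20)
        }
        m = project_ranges_to_matrix(disks, pts, min_occurrences=1)
        for taxon, disk in disks.items():
            if taxon not in m.taxa:
                continue
            for i, loc in enumerate(m.localities):
                want = central_angle_deg(pts[i, 0], pts[i, 1],
                                         disk.center_lat, disk.center_lon) <= disk.radius_deg
                assert m.data.loc[loc, taxon] == int(want)

    def test_no_overlap_is_error(self):
        pts = _coords([40.0, 41.0], [-100.0, -101.0])
        far = GeodesicDisk(-40.0, 100.0, 1.0)
        with pytest.raises(ValueError, match="no species overlaps"):
            project_ranges_to_matrix({"A a": far}, pts)


@pytest.fixture
def filterable_matrix():
    rng = np.random.default_rng(7)
    pts = _coords(rng.uniform(30, 50, 30), rng.uniform(-120, -80, 30))
    disks = {
        f"S{k} s{k}": GeodesicDisk(rng.uniform(30, 50), rng.uniform(-120, -80),
                                   rng.uniform(8, 30))
        for k in range(12)
    }
    return project_ranges_to_matrix(disks, pts)


class TestBias:
    def test_taxonomic_removal_count(self, filterable_matrix):
        n = filterable_matrix.n_taxa
        masses = {t: 10.0 for t in filterable_matrix.taxa}
        spec = BiasSpec("taxonomic", 0.5)
        out = apply_bias(filterable_matrix, masses, spec, seed=1)
        assert out.n_taxa <= n - n // 2

    def test_all_large_bodied_unchanged(self, filterable_matrix):
        masses = {t: 10.0 for t in filterable_matrix.taxa}
        out = apply_bias(filterable_matrix, masses, BiasSpec("body-mass", 0.5), seed=1)
        assert out.taxa == filterable_matrix.taxa

    def test_never_removes_large_species(self, filterable_matrix):
        masses = {t: (2.0 if i % 2 else 8.0) for i, t in enumerate(filterable_matrix.taxa)}
        out = apply_bias(filterable_matrix, masses, BiasSpec("body-mass", 0.75), seed=2)
        large = {t for t, m in masses.items() if m >= 5.0}
        kept = set(out.taxa)
        assert large & set(filterable_matrix.taxa) <= kept | _stranded(filterable_matrix, out)

    def test_seed_reproducible(self, filterable_matrix):
        masses = {t: 10.0 for t in filterable_matrix.taxa}
        a = apply_bias(filterable_matrix, masses, BiasSpec("taxonomic", 0.25), seed=9)
        b = apply_bias(filterable_matrix, masses, BiasSpec("taxonomic", 0.25), seed=9)
        assert a.taxa == b.taxa and a.localities == b.localities

    def test_fraction_rounding_floor(self, filterable_matrix):
        # floor(fraction * pool) taxa are removed, so a fraction too small
        # to reach one whole taxon is a no-op
        masses = {t: 10.0 for t in filterable_matrix.taxa}
        frac = 0.9 / filterable_matrix.n_taxa
        out = apply_bias(filterable_matrix, masses, BiasSpec("taxonomic", frac), seed=0)
        assert out.taxa == filterable_matrix.taxa

    def test_missing_mass_is_error(self, filterable_matrix):
        with pytest.raises(ValueError, match="mass for every taxon"):
            apply_bias(filterable_matrix, {}, BiasSpec("body-mass", 0.25), seed=0)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            BiasSpec("taxonomic", 1.5)
        with pytest.raises(ValueError):
            BiasSpec("unknown", 0.5)


def _stranded(before, after):
    """Taxa lost only through the re-applied minimum-occurrence filter."""
    return set(before.taxa) - set(after.taxa)


class TestReplicateEnsemble:
    def test_requested_count(self):
        ens = replicate_ensemble(lambda s: s, n_reps=25, base_seed=0)
        assert len(ens) == 25 and len(set(ens.seeds)) == 25

    def test_single_replicate_summary(self):
        ens = replicate_ensemble(lambda s: 3.5, n_reps=1, base_seed=0)
        mean, se = ens.summarize(lambda v: v)
        assert mean == 3.5 and np.isnan(se)

    def test_failure_reports_replicate_index(self):
        def boom(seed):
            raise RuntimeError("nope")

        with pytest.raises(RuntimeError, match="replicate 0"):
            replicate_ensemble(boom, n_reps=3, base_seed=0)

    def test_order_independent_seeds(self):
        a = replicate_ensemble(lambda s: s, n_reps=10, base_seed=5)
        b = [a.replicates[i] for i in range(10)]
        from paleobeta._seeding import derive_seed

        assert b == [derive_seed(5, "replicate", i) for i in range(10)]
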