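"""Climate grids, envelope-consensus models, evaluation metrics, projection."""

import numpy as np
import pandas as pd
import pytest

from paleobeta.climate import (
    ClimateEnvelopeEnsemble,
    ClimateGrid,
    apply_scenario,
    evaluate,
    filter_rare,
    fit_envelope,
    make_climate_grid,
    presences_to_range,
    project,
    sample_presences,
    species_presence_on_grid,
)
from paleobeta.ranges import GeoBounds, GeodesicDisk, central_angle_deg
from paleobeta.synthetic import generate_species_pool

BOUNDS = GeoBounds(10.0, 60.0, -125.0, -70.0)


@pytest.fixture(scope="module")
def grid():
    return make_climate_grid(BOUNDS, seed=0)


class TestGrid:
    def test_structure(self, grid):
        assert len(grid) > 1000
        assert grid.cells.cell_id.is_unique
        assert np.isfinite(grid.cells[["mat", "wintert", "map"]].to_numpy()).all()

    def test_temperature_decreases_poleward(self, grid):
        by_lat = grid.cells.groupby("lat").mat.mean()
        assert (np.diff(by_lat.to_numpy()) < 0).all()

    def test_scenario_shift(self, grid):
        warmed = apply_scenario(grid, {"mat": 2.0, "wintert": 2.0}, "plus2")
        assert np.allclose(warmed.cells.mat, grid.cells.mat + 2.0)
        assert warmed.scenario == "plus2"

    def test_unknown_variable_rejected(self, grid):
        with pytest.raises(ValueError):
            apply_scenario(grid, {"rainfall": 1.0}, "x")

    def test_duplicate_cells_rejected(self, grid):
        cells = pd.concat([grid.cells, grid.cells.iloc[:1]])
        with pytest.raises(ValueError, match="duplicate"):
            ClimateGrid(cells=cells)


class TestPresenceSampling:
    def test_covering_and_empty_ranges(self, grid):
        everywhere = GeodesicDisk(35.0, -100.0, 179.0)
        assert sample_presences(everywhere, grid).all()
        nowhere = GeodesicDisk(-80.0, 100.0, 1.0)
        assert not sample_presences(nowhere, grid).any()

    def test_matches_point_in_disk_oracle(self, grid):
        disk = GeodesicDisk(40.0, -100.0, 12.0)
        got = sample_presences(disk, grid)
        lats = grid.cells.lat.to_numpy()
        lons = grid.cells.lon.to_numpy()
        want = central_angle_deg(lats, lons, 40.0, -100.0) <= 12.0
        assert np.array_equal(got, want)

    def test_empty_grid_rejected(self, grid):
        empty = ClimateGrid(cells=grid.cells.iloc[:0])
        with pytest.raises(ValueError, match="empty"):
            sample_presences(GeodesicDisk(40, -100, 5), empty)


class TestRareFilter:
    def test_boundary(self):
        counts = {"a": 19, "b": 20, "c": 500}
        kept, removed = filter_rare(counts, min_cells=20)
        assert kept == ["b", "c"] and removed == ["a"]

    def test_zero_threshold_keeps_all(self):
        kept, removed = filter_rare({"a": 0, "b": 3}, min_cells=0)
        assert kept == ["a", "b"] and removed == []


class TestEnvelopeEnsemble:
    def test_envelope_bounds_inside_presence_span(self, grid):
        pres = (grid.cells["map"].between(400, 900)).to_numpy()
        model = fit_envelope(pres, grid)
        lo, hi = model.bounds_["map"]
        assert 400 <= lo < hi <= 900

    def test_separable_climate_gives_perfect_pcc(self, grid):
        # complete separation drops the logistic member (with a warning);
        # with an untrimmed envelope the consensus classifies perfectly
        pres = (grid.cells["mat"] > 15.0).to_numpy()
        with pytest.warns(UserWarning, match="separation"):
            model = fit_envelope(pres, grid, percentiles=(0.0, 100.0))
        assert model.logit_params_ is None
        assert model.train_metrics_.pcc == pytest.approx(1.0)
        # the default percentile trim deliberately sacrifices the 5% tails
        trimmed = fit_envelope(pres, grid)
        assert 0.9 < trimmed.train_metrics_.pcc < 1.0

    def test_generative_recovery_overlap(self, grid):
        pool = generate_species_pool(50, bounds=BOUNDS, seed=3, temp_breadth=3.0)
        overlaps = []
        for s in pool.species:
            true = species_presence_on_grid(s, grid, level=0.5)
            if true.sum() < 20:
                continue
            model = fit_envelope(true, grid)
            pred = model.predict(grid.X)
            overlaps.append((true & pred).sum() / (true | pred).sum())
        assert len(overlaps) >= 40
        assert np.median(overlaps) > 0.8

    def test_no_presences_rejected(self, grid):
        with pytest.raises(ValueError, match="no presences"):
            fit_envelope(np.zeros(len(grid), dtype=bool), grid)

    def test_sklearn_params_roundtrip(self):
        est = ClimateEnvelopeEnsemble(percentiles=(5.0, 95.0))
        assert est.get_params()["percentiles"] == (5.0, 95.0)
        est.set_params(percentiles=(2.5, 97.5))
        assert est.percentiles == (2.5, 97.5)


class TestEvaluate:
    def test_perfect_predictions(self):
        obs = np.array([1, 1, 0, 0], dtype=bool)
        m = evaluate(np.array([0.9, 0.8, 0.1, 0.2]), obs)
        assert (m.auc, m.tss, m.pcc) == (1.0, 1.0, 1.0)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        m = evaluate(rng.random(2000), rng.random(2000) < 0.5)
        assert m.auc == pytest.approx(0.5, abs=0.03)

    def test_hand_computed_contingency(self):
        # TP=40, FN=10, TN=30, FP=20 -> TSS = 0.8 + 0.6 - 1 = 0.4, PCC = 0.7
        obs = np.r_[np.ones(50), np.zeros(50)].astype(bool)
        pred = np.r_[np.ones(40), np.zeros(10), np.ones(20), np.zeros(30)]
        m = evaluate(pred, obs, threshold=0.5)
        assert m.tss == pytest.approx(0.4)
        assert m.pcc == pytest.approx(0.7)

    def test_matches_brute_force_confusion(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = rng.integers(20, 100)
            scores = rng.random(n)
            obs = rng.random(n) < 0.5
            if obs.all() or not obs.any():
                continue
            m = evaluate(scores, obs, threshold=0.4)
            pred = scores >= 0.4
            tp = int((pred & obs).sum()); fn = int((~pred & obs).sum())
            tn = int((~pred & ~obs).sum()); fp = int((pred & ~obs).sum())
            assert m.pcc == pytest.approx((tp + tn) / n)
            assert m.tss == pytest.approx(tp / (tp + fn) + tn / (tn + fp) - 1.0)
            # rank (Mann-Whitney) AUC oracle by pair counting
            pos, neg = scores[obs], scores[~obs]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert m.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_one_class_reported_missing(self):
        m = evaluate(np.array([0.2, 0.7]), np.array([True, True]))
        assert np.isnan(m.auc) and np.isnan(m.tss) and m.pcc >= 0


class TestProjection:
    def test_identity_scenario_equals_training_prediction(self, grid):
        pres = species_presence_on_grid(
            generate_species_pool(5, bounds=BOUNDS, seed=9, temp_breadth=3.0).species[0],
            grid,
        )
        if pres.sum() < 20:
            pres = (grid.cells["mat"].between(5, 15)).to_numpy()
        model = fit_envelope(pres, grid)
        same = apply_scenario(grid, {"mat": 0.0}, "identity")
        assert np.array_equal(project(model, same), model.predict(grid.X))

    def test_determinism(self, grid):
        pres = (grid.cells["mat"].between(5, 15)).to_numpy()
        model = fit_envelope(pres, grid)
        a = project(model, grid)
        b = project(model, grid)
        assert np.array_equal(a, b)

    def test_warming_shifts_presence_poleward(self, grid):
        pres = (grid.cells["mat"].between(5, 15)).to_numpy()
        model = fit_envelope(pres, grid)
        warmed = apply_scenario(grid, {"mat": 3.0, "wintert": 3.0}, "plus3")
        now = project(model, grid)
        fut = project(model, warmed)
        lat = grid.cells.lat.to_numpy()
        assert lat[fut].mean() > lat[now].mean() + 2.0

    def test_variable_subset_models_project(self, grid):
        pres = (grid.cells["mat"].between(5, 15)).to_numpy()
        model = ClimateEnvelopeEnsemble(variables=("mat", "wintert")).fit(grid.X, pres)
        assert set(model.bounds_) == {"mat", "wintert"}
        assert project(model, grid).sum() > 0

    def test_envelope_idempotence(self, grid):
        pres = (grid.cells["mat"].between(5, 15)).to_numpy()
        model = fit_envelope(pres, grid)
        pred = model.predict(grid.X)
        refit = fit_envelope(pred, grid)
        lo0, hi0 = model.bounds_["mat"]
        lo1, hi1 = refit.bounds_["mat"]
        width = hi0 - lo0
        assert abs(lo1 - lo0) < 0.1 * width and abs(hi1 - hi0) < 0.1 * width

    def test_presences_to_range_roundtrip(self, grid):
        pres = (grid.cells["mat"].between(5, 15)).to_numpy()
        rng_ = presences_to_range(grid, pres)
        got = rng_.contains(grid.cells.lat.to_numpy(), grid.cells.lon.to_numpy())
        assert np.array_equal(got, pres)


def test_grid_csv_round_trip(grid, tmp_path):
    grid.to_csv(tmp_path / "grid.csv")
    back = ClimateGrid.from_csv(tmp_path / "grid.csv")
    assert back.scenario == grid.scenario
    pd.testing.assert_frame_equal(
        back.cells.reset_index(drop=True), grid.cells.reset_index(drop=True),
        check_exact=False,
    )
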