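"""SDM fitting, spatial-block cross-validation, projection, averaging."""

import numpy as np
import pandas as pd
import pytest

import jorospread as j
import jorospread.sdm as sdm


class TestStandardize:
    def test_constant_column_fatal_and_named(self):
        df = pd.DataFrame({"flat": [2.0, 2.0, 2.0], "ok": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            sdm.standardize(df)

    def test_simple_column(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        std, _ = sdm.standardize(df)
        np.testing.assert_allclose(std["x"], [-1.0, 0.0, 1.0])

    def test_round_trip_inverse(self, rng):
        df = pd.DataFrame(rng.normal(5, 3, size=(50, 3)), columns=list("abc"))
        std, params = sdm.standardize(df)
        back = params.inverse(std)
        np.testing.assert_allclose(back.to_numpy(), df.to_numpy(), atol=1e-12)

    def test_params_reused_on_new_data(self, rng):
        train = pd.DataFrame({"x": rng.normal(10, 2, 100)})
        _, params = sdm.standardize(train)
        new = pd.DataFrame({"x": [10.0]})
        assert params.transform(new)["x"].iloc[0] == pytest.approx(
            (10.0 - train["x"].mean()) / train["x"].std(ddof=1)
        )


class TestSpatialBlocks:
    def test_nearby_points_share_fold(self, rng):
        lon = np.concatenate([rng.uniform(-100, -70, 500), [-84.0, -83.9]])
        lat = np.concatenate([rng.uniform(25, 50, 500), [34.0, 34.05]])
        table = pd.DataFrame({"lon": lon, "lat": lat})
        folds = sdm.assign_spatial_blocks(table, block_size_km=860, k=5, seed=0)
        assert folds[-1] == folds[-2]  # 10 km apart with 860 km blocks

    def test_folds_partition_points(self, rng):
        table = pd.DataFrame(
            {"lon": rng.uniform(-100, -70, 300), "lat": rng.uniform(25, 50, 300)}
        )
        folds = sdm.assign_spatial_blocks(table, block_size_km=400, k=6, seed=1)
        assert len(folds) == 300
        assert set(folds) <= set(range(1, 7))
        assert len(set(folds)) == 6  # round-robin dealing fills every fold

    def test_too_few_blocks_fatal_with_count(self, rng):
        table = pd.DataFrame(
            {"lon": rng.uniform(-84, -83, 50), "lat": rng.uniform(33, 34, 50)}
        )
        with pytest.raises(ValueError, match=r"\d+ non-empty"):
            sdm.assign_spatial_blocks(table, block_size_km=860, k=10, seed=0)


class TestAUC:
    def test_matches_pairwise_concordance(self, rng):
        """Rank-statistic AUC equals the O(n^2) concordance count."""
        pres = rng.normal(0.6, 0.3, 12)
        bg = rng.normal(0.4, 0.3, 8)
        brute = np.mean([
            1.0 if p > b else 0.5 if p == b else 0.0 for p in pres for b in bg
        ])
        assert sdm.auc_rank(pres, bg) == pytest.approx(brute, abs=1e-12)

    def test_ties_get_half_credit(self):
        assert sdm.auc_rank(np.array([0.5, 0.5]), np.array([0.5])) == 0.5


def _perfect_table(rng, n=200):
    """Labelled table whose single predictor exactly encodes the label."""
    y = rng.uniform(size=n) < 0.4
    x = np.where(y, 1.0, -1.0) + rng.normal(0, 0.01, n)
    return pd.DataFrame(
        {
            "lon": rng.uniform(-100, -70, n),
            "lat": rng.uniform(25, 50, n),
            "x": x,
            "label": np.where(y, "presence", "background"),
        }
    )


class TestCrossValidate:
    def test_perfect_separation_auc_one(self, rng):
        table = _perfect_table(rng)
        folds = sdm.assign_spatial_blocks(table, block_size_km=500, k=4, seed=0)
        results, mean_auc, _ = sdm.cross_validate(
            "glm", table, folds, predictors=["x"],
            config=sdm.SDMConfig(min_presences=5),
        )
        assert all(r.auc == 1.0 for r in results)
        assert mean_auc == 1.0

    def test_constant_half_predictions_mae(self):
        """A model predicting 0.5 everywhere has MAE 0.5 on any labels."""
        model = sdm.FittedSDM(
            model_kind="glm", predictors=["x"],
            _predict=lambda df: np.full(len(df), 0.5),
        )
        table = pd.DataFrame(
            {"x": [0.0] * 10, "label": ["presence"] * 5 + ["background"] * 5}
        )
        p = model.predict(table)
        y = (table["label"] == "presence").to_numpy(float)
        assert np.mean(np.abs(y - p)) == 0.5

    def test_single_class_fold_skipped(self, rng):
        table = _perfect_table(rng, n=120)
        folds = np.where(table["label"] == "presence", 1, 2)
        folds[:40] = 3  # only fold 3 is mixed
        results, _, _ = sdm.cross_validate(
            "glm", table, folds, predictors=["x"],
            config=sdm.SDMConfig(min_presences=5),
        )
        assert [r.fold_id for r in results] == [3]


class TestFitSDM:
    def test_too_few_presences_fatal(self, rng):
        table = _perfect_table(rng, n=40)
        with pytest.raises(ValueError, match="presences"):
            sdm.fit_sdm("glm", table, predictors=["x"],
                        config=sdm.SDMConfig(min_presences=30))

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValueError, match="kind"):
            sdm.fit_sdm("boost", _perfect_table(rng), predictors=["x"])

    def test_predictions_bounded(self, sdm_table):
        std, _, _ = sdm_table
        for kind in sdm.MODEL_KINDS:
            m = sdm.fit_sdm(kind, std, config=sdm.SDMConfig(rf_trees=30), seed=0)
            p = m.predict(std)
            assert p.min() >= 0.0 and p.max() <= 1.0

    def test_all_kinds_separate_logistic_truth(self, sdm_table):
        """On a landscape whose truth is logistic in one predictor, every
        model family reaches block-CV AUC > 0.9 at n = 2000."""
        std, _, _ = sdm_table
        folds = sdm.assign_spatial_blocks(std, block_size_km=250, k=5, seed=2)
        for kind in sdm.MODEL_KINDS:
            _, mean_auc, mean_mae = sdm.cross_validate(
                kind, std, folds, config=sdm.SDMConfig(rf_trees=100), seed=0
            )
            assert mean_auc > 0.9, f"{kind}: AUC {mean_auc:.3f}"
            assert 0.0 < mean_mae < 0.5

    def test_label_permutation_auc_near_half(self, sdm_table, rng):
        """Permuted labels destroy the signal: mean AUC within 0.5 +/- 0.05."""
        std, _, _ = sdm_table
        table = std.copy()
        table["label"] = rng.permutation(table["label"].to_numpy())
        folds = sdm.assign_spatial_blocks(table, block_size_km=250, k=5, seed=3)
        _, mean_auc, _ = sdm.cross_validate("glm", table, folds, seed=0)
        assert abs(mean_auc - 0.5) < 0.05


class TestProject:
    def test_consistency_with_point_predictions(self, sdm_table, rng):
        """Projected raster cells agree with direct predict() on the
        extracted cell values (100 random valid cells)."""
        std, params, layers = sdm_table
        model = sdm.fit_sdm("glm", std, seed=0)
        raster = sdm.project(model, layers, params)
        rows = rng.integers(0, raster.n_rows, 100)
        cols = rng.integers(0, raster.n_cols, 100)
        for r, c in zip(rows, cols):
            vals = {lay.name: lay.values[r, c] for lay in layers}
            if any(np.isnan(v) for v in vals.values()):
                continue
            df = params.transform(pd.DataFrame([vals]))
            assert raster.values[r, c] == pytest.approx(
                model.predict(df)[0], abs=1e-10
            )

    def test_constant_rasters_constant_suitability(self, sdm_table):
        std, params, layers = sdm_table
        model = sdm.fit_sdm("glm", std, seed=0)
        const = [
            j.geodata.RasterLayer(name=lay.name, x_min=0, y_min=0, cell=1.0,
                                  values=np.full((3, 3), 0.7))
            for lay in layers
        ]
        out = sdm.project(model, const, params)
        assert np.ptp(out.values) == 0.0

    def test_nodata_propagates(self, sdm_table):
        std, params, layers = sdm_table
        model = sdm.fit_sdm("glm", std, seed=0)
        holey = []
        for lay in layers:
            v = lay.values.copy()
            holey.append(
                j.geodata.RasterLayer(name=lay.name, x_min=lay.x_min,
                                      y_min=lay.y_min, cell=lay.cell, values=v)
            )
        holey[0].values[0, 0] = np.nan
        out = sdm.project(model, holey, params)
        assert np.isnan(out.values[0, 0])

    def test_missing_predictor_layer_fatal(self, sdm_table):
        std, params, layers = sdm_table
        model = sdm.fit_sdm("glm", std, seed=0)
        with pytest.raises(ValueError, match="missing"):
            sdm.project(model, layers[:1], params)


class TestAverageModels:
    @staticmethod
    def raster(vals):
        return j.geodata.RasterLayer(name="r", x_min=0, y_min=0, cell=1.0,
                                     values=np.asarray(vals, dtype=float))

    def test_four_cell_values(self):
        rasters = [self.raster([[v]]) for v in (0.2, 0.4, 0.6, 0.8)]
        assert sdm.average_models(rasters).values[0, 0] == pytest.approx(0.5)

    def test_all_equal_identity(self, rng):
        v = rng.uniform(size=(4, 4))
        out = sdm.average_models([self.raster(v)] * 4)
        np.testing.assert_allclose(out.values, v, atol=1e-15)

    def test_matches_brute_force_and_bounds(self, rng):
        stack = [rng.uniform(size=(5, 5)) for _ in range(4)]
        out = sdm.average_models([self.raster(v) for v in stack])
        np.testing.assert_allclose(out.values, sum(stack) / 4, atol=1e-12)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_nodata_propagates(self):
        a = self.raster([[0.5, np.nan]])
        b = self.raster([[0.5, 0.5]])
        out = sdm.average_models([a, b])
        assert np.isnan(out.values[0, 1]) and out.values[0, 0] == 0.5


class TestMethodProperties:
    def test_block_cv_not_more_optimistic_than_random(self):
        """On spatially autocorrelated, clustered data, spatial-block CV
        yields AUC at or below random-split CV on average (the optimism
        the blocking is designed to remove), over 20 replicates."""
        deltas = []
        for rep in range(20):
            spec = j.simulate.LandscapeSpec(
                predictors=("x1", "x2"),
                coefficients={"x1": (1.0, 0.0), "x2": (0.0, 0.0)},
                length_scale=15.0,
                intercept=-1.0,
            )
            layers, truth = j.simulate.make_landscape(spec, seed=100 + rep)
            bias = j.simulate.BiasSpec(
                clusters=((-87.0, 33.0, 0.8, 30.0), (-83.0, 37.0, 0.8, 30.0)),
                floor=0.05,
            )
            occs = j.simulate.sample_presences(truth, 150, bias=bias,
                                               seed=200 + rep)
            pres = j.geodata.extract_values([(o.lon, o.lat) for o in occs],
                                            layers)
            bg = j.geodata.sample_background(layers[0], 300, seed=300 + rep)
            bgv = j.geodata.extract_values([(p.lon, p.lat) for p in bg],
                                           layers, label="background")
            table, _ = j.sdm.standardize(
                j.geodata.samples_to_frame(pres + bgv)
            )
            rng = np.random.default_rng(400 + rep)
            block = sdm.assign_spatial_blocks(table, block_size_km=220, k=4,
                                              seed=rep)
            random = rng.integers(1, 5, len(table))
            cfg = sdm.SDMConfig(min_presences=10)
            _, auc_block, _ = sdm.cross_validate("glm", table, block,
                                                 config=cfg)
            _, auc_rand, _ = sdm.cross_validate("glm", table, random,
                                                config=cfg)
            deltas.append(auc_block - auc_rand)
        assert np.mean(deltas) <= 0.01

    def test_maxent_linear_unregularized_matches_glm(self, sdm_table):
        """With linear features only and no penalty, the maximum-entropy
        logistic model induces the same cell ranking as the linear GLM."""
        from scipy.stats import spearmanr

        std, _, _ = sdm_table
        glm = sdm.fit_sdm("glm", std, config=sdm.SDMConfig(glm_terms="linear"))
        mx = sdm.fit_sdm(
            "maxent_like", std,
            config=sdm.SDMConfig(maxent_features=("linear",),
                                 maxent_c=np.inf),
        )
        grid = std.sample(400, random_state=0)
        rho = spearmanr(glm.predict(grid), mx.predict(grid)).statistic
        assert rho > 0.999

    def test_gam_partial_response_unimodal(self):
        """With a quadratic (unimodal) truth in one predictor, the fitted
        GAM partial response has a single interior maximum in >= 90% of
        20 replicates."""
        hits = 0
        for rep in range(20):
            spec = j.simulate.LandscapeSpec(
                predictors=("x1", "x2"),
                coefficients={"x1": (0.0, -1.5), "x2": (0.3, 0.0)},
                intercept=1.0,
            )
            layers, truth = j.simulate.make_landscape(spec, seed=500 + rep)
            occs = j.simulate.sample_presences(truth, 400, seed=600 + rep)
            pres = j.geodata.extract_values([(o.lon, o.lat) for o in occs],
                                            layers)
            bg = j.geodata.sample_background(layers[0], 600, seed=700 + rep)
            bgv = j.geodata.extract_values([(p.lon, p.lat) for p in bg],
                                           layers, label="background")
            std, _ = j.sdm.standardize(j.geodata.samples_to_frame(pres + bgv))
            gam = sdm.fit_sdm("gam", std)
            grid = pd.DataFrame(
                {"x1": np.linspace(-1.8, 1.8, 41), "x2": 0.0}
            )
            resp = gam.predict(grid)
            peak = int(np.argmax(resp))
            interior = 0 < peak < 40
            rises = np.all(np.diff(resp[: peak + 1]) > -1e-9) if interior else False
            falls = np.all(np.diff(resp[peak:]) < 1e-9) if interior else False
            hits += int(interior and rises and falls)
        assert hits >= 18
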