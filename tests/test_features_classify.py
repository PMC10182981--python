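"""Per-cell features, neighbourhood smoothing, classifier, and slide QC."""

import numpy as np
import pytest

from eastils.classify import CellClassifier, classify_cells, qc_slide, train_classifier
from eastils.features import compute_features, smooth_features
from eastils.segmentation import DetectionParams, detect_nuclei, expand_cells
from eastils.stain import ODImage
from eastils.synthetic import CLASSES, TileSpec, generate_tile
from eastils.pipeline import analyze_tile, match_cells_to_truth

from test_segmentation import disk_od_image


def analyzed_disk(radius_um=4.0, od=0.8):
    hema = disk_od_image(radius_um, od=od, size_um=80.0)
    eosin = ODImage(np.full_like(hema.values, 0.2), hema.microns_per_pixel, ("eosin",))
    cells = expand_cells(detect_nuclei(hema))
    return compute_features(cells, hema, eosin)


class TestComputeFeatures:
    def test_uniform_nucleus_has_zero_od_sd(self):
        cells = analyzed_disk()
        assert cells[0].features["nucleus_hematoxylin_sd"] == pytest.approx(0.0, abs=1e-9)

    def test_circular_nucleus_circularity_near_one(self):
        cells = analyzed_disk(radius_um=5.0)
        assert cells[0].features["nucleus_circularity"] > 0.95

    def test_elongated_fibroblast_measured_eccentric(self):
        spec = TileSpec(n_tumor=0, n_lymphocyte=0, n_fibroblast=6, n_other=0, seed=6)
        tile, truth = generate_tile(spec)
        cells, _ = analyze_tile(tile)
        assert len(cells) == len(truth.cells)
        for c in cells:
            assert c.features["nucleus_eccentricity"] >= 0.8

    def test_all_features_finite(self, eval_tiles):
        for c in eval_tiles[0].cells:
            vals = np.array(list(c.features.values()))
            assert np.isfinite(vals).all()
            assert 0 < c.features["nucleus_circularity"] <= 1


class TestSmoothFeatures:
    def test_isolated_cell_keeps_own_value(self):
        cells = analyzed_disk()
        smooth_features(cells, 25.0)
        f = cells[0].features
        assert f["nucleus_area_smoothed_25um"] == pytest.approx(f["nucleus_area"], rel=1e-12)

    def test_identical_neighbors_preserve_constant(self):
        hema = disk_od_image(3.0, size_um=80.0, center=(30.0, 40.0),
                             extra_disks=[(50.0, 40.0)])
        eosin = ODImage(np.full_like(hema.values, 0.2), 0.5, ("eosin",))
        cells = compute_features(expand_cells(detect_nuclei(hema)), hema, eosin)
        smooth_features(cells, 25.0)
        a, b = cells
        key = "nucleus_hematoxylin_mean"
        assert a.features[key] == pytest.approx(b.features[key], abs=1e-9)
        assert a.features[key + "_smoothed_25um"] == pytest.approx(a.features[key], abs=1e-9)

    def test_matches_brute_force_weighted_mean(self, eval_tiles):
        at = eval_tiles[0]
        cells = at.cells
        radius = 25.0
        sigma2 = 2.0 * (radius / 2.0) ** 2
        centers = np.array([c.centroid_um for c in cells])
        names = [k for k in cells[0].features if "_smoothed_" not in k]
        for i in range(0, len(cells), 7):
            d2 = ((centers - centers[i]) ** 2).sum(axis=1)
            sel = d2 <= radius**2
            w = np.exp(-d2[sel] / sigma2)
            for name in names[::11]:
                vals = np.array([c.features[name] for c in cells])[sel]
                expected = (w * vals).sum() / w.sum()
                got = cells[i].features[f"{name}_smoothed_25um"]
                assert got == pytest.approx(expected, abs=1e-9)


def separable_features(n_per_class=500, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k, label in enumerate(CLASSES):
        mu = np.zeros(6)
        mu[k % 6] = 3.0
        mu[(k + 2) % 6] = -2.0
        X.append(rng.normal(mu, 1.0, size=(n_per_class, 6)))
        y += [label] * n_per_class
    return np.vstack(X), np.array(y)


class TestClassifier:
    def test_separable_classes_high_holdout_accuracy(self):
        X, y = separable_features(2000, seed=1)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(y))
        cut = int(0.8 * len(y))
        model = CellClassifier(random_state=0).fit(X[idx[:cut]], y[idx[:cut]])
        acc = (model.predict(X[idx[cut:]]) == y[idx[cut:]]).mean()
        assert acc >= 0.95

    def test_permuted_labels_give_chance_accuracy(self):
        X, y = separable_features(500, seed=2)
        rng = np.random.default_rng(3)
        y_perm = rng.permutation(y)
        idx = rng.permutation(len(y))
        cut = int(0.8 * len(y))
        model = CellClassifier(random_state=0).fit(X[idx[:cut]], y_perm[idx[:cut]])
        acc = (model.predict(X[idx[cut:]]) == y_perm[idx[cut:]]).mean()
        assert 0.15 <= acc <= 0.35

    def test_same_seed_identical_weights(self):
        X, y = separable_features(100, seed=4)
        m1 = CellClassifier(random_state=7).fit(X, y)
        m2 = CellClassifier(random_state=7).fit(X, y)
        for w1, w2 in zip(m1.net_.coefs_, m2.net_.coefs_):
            assert np.array_equal(w1, w2)

    def test_probabilities_sum_to_one(self):
        X, y = separable_features(200, seed=5)
        model = CellClassifier(random_state=0).fit(X, y)
        proba = model.predict_proba(X[:50])
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_single_class_input_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 4))
        with pytest.raises(ValueError):
            CellClassifier().fit(X, np.array(["tumor"] * 50))

    def test_tie_breaks_toward_class_order(self):
        model = CellClassifier()
        model.classes_ = np.array(CLASSES)
        proba = np.array([[0.25, 0.25, 0.25, 0.25], [0.1, 0.1, 0.7, 0.1]])
        labels = model.classes_[np.argmax(proba, axis=1)]
        assert labels[0] == "tumor"
        assert labels[1] == "stromal"

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        X, y = separable_features(200, seed=6)
        model = CellClassifier(random_state=0).fit(X, y)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = CellClassifier.load(path)
        assert np.array_equal(model.predict(X), loaded.predict(X))
        assert np.allclose(model.predict_proba(X), loaded.predict_proba(X), atol=1e-12)

    def test_end_to_end_planted_classes_recovered(self, eval_tiles, trained_model):
        """>= 95% of planted cells receive their planted class across the suite."""
        total, correct = 0, 0
        for at in eval_tiles:
            classify_cells(trained_model, at.cells)
            for c, ref in zip(at.cells, at.reference_labels):
                if ref is not None:
                    total += 1
                    correct += c.class_label == ref
        assert correct / total >= 0.95

    def test_schema_mismatch_rejected(self, eval_tiles, trained_model):
        cell = analyzed_disk()[0]  # no smoothed features computed
        with pytest.raises(ValueError):
            classify_cells(trained_model, [cell])


class TestQC:
    def test_exactly_ten_percent_passes(self):
        report = qc_slide(["tumor"] * 90 + ["other"] * 10, ["tumor"] * 100)
        assert report.fraction == pytest.approx(0.10)
        assert report.passed

    def test_eleven_percent_fails(self):
        report = qc_slide(["tumor"] * 89 + ["other"] * 11, ["tumor"] * 100)
        assert not report.passed

    def test_all_correct_passes(self):
        report = qc_slide(["tumor"] * 20, ["tumor"] * 20)
        assert report.fraction == 0.0 and report.passed

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            qc_slide([], [])
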