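"""Shared fixtures: an analyzed synthetic tile suite and a trained classifier.

The tile suite is the standard evaluation condition for the image pipeline:
26 seeded lymphocyte-rich tiles (8 tumor, 30 lymphocytes, 8 fibroblasts,
4 "other" per 150x150 µm tile, well-separated placement), the first 6 used
to train the cell classifier from ground-truth labels, the remaining 20
held out for evaluation.  Building it runs the full stain → detect →
expand → featurize path once per session.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pytest

from eastils.classify import CellClassifier, train_classifier
from eastils.pipeline import analyze_tile, match_cells_to_truth
from eastils.synthetic import SyntheticGroundTruth, TileSpec, generate_tile

N_TRAIN_TILES = 6
N_EVAL_TILES = 20
SUITE_SEED_BASE = 100

SUITE_SPEC = TileSpec(n_tumor=8, n_lymphocyte=30, n_fibroblast=8, n_other=4)


@dataclass
class AnalyzedTile:
    truth: SyntheticGroundTruth
    cells: list
    reference_labels: list  # per detection; None = unmatched (false positive)


@pytest.fixture(scope="session")
def tile_suite() -> list[AnalyzedTile]:
    suite = []
    for i in range(N_TRAIN_TILES + N_EVAL_TILES):
        spec = dataclasses.replace(SUITE_SPEC, seed=SUITE_SEED_BASE + i)
        tile, truth = generate_tile(spec)
        cells, _ = analyze_tile(tile)
        refs = match_cells_to_truth(cells, truth)
        suite.append(AnalyzedTile(truth, cells, refs))
    return suite


@pytest.fixture(scope="session")
def trained_model(tile_suite) -> CellClassifier:
    cells, labels = [], []
    for at in tile_suite[:N_TRAIN_TILES]:
        for c, r in zip(at.cells, at.reference_labels):
            if r is not None:
                cells.append(c)
                labels.append(r)
    return train_classifier(cells, labels, random_state=0)


@pytest.fixture(scope="session")
def eval_tiles(tile_suite) -> list[AnalyzedTile]:
    return tile_suite[N_TRAIN_TILES:]
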