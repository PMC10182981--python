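"""Per-cell morphometric and staining features, plus neighbourhood smoothing.

For every detected cell, intensity statistics (mean/sd/min/max of
hematoxylin and eosin OD) are computed in three compartments — nucleus,
cytoplasm ring (cell minus nucleus) and whole cell — alongside nucleus
shape descriptors.  Classification is then stabilised by appending, for
each base feature, a distance-weighted neighbourhood mean over cells within
25 and 50 µm, so that a cell is described both by itself and by its local
context.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import regionprops

from .segmentation import CellObject
from .stain import ODImage

__all__ = ["compute_features", "smooth_features", "SMOOTHING_RADII_UM"]

SMOOTHING_RADII_UM = (25.0, 50.0)

_STATS = ("mean", "sd", "min", "max")


def _od_stats(values: np.ndarray) -> tuple[float, float, float, float]:
    if values.size == 0:
        return (0.0, 0.0, 0.0, 0.0)
    return (float(values.mean()), float(values.std()), float(values.min()), float(values.max()))


def _sample_channel(channel: ODImage, cell: CellObject,
                    indices: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """OD values of the source channel under detection-grid pixels."""
    plane = channel.plane
    rr, cc = indices
    scale = cell.grid_mpp / channel.microns_per_pixel
    r_src = np.clip(((rr + 0.5) * scale).astype(int), 0, plane.shape[0] - 1)
    c_src = np.clip(((cc + 0.5) * scale).astype(int), 0, plane.shape[1] - 1)
    return plane[r_src, c_src]


def compute_features(cells: list[CellObject], hema: ODImage, eosin: ODImage) -> list[CellObject]:
    """Populate ``cell.features`` for every cell (in place; returns the list).

    Requires nucleus and cell geometry (run detection and expansion first).
    Cells clipped by the image border are flagged with ``clipped = 1``.
    """
    for cell in cells:
        if cell.cell_indices is None:
            raise ValueError("cells lack expanded geometry; run expand_cells first")
        feats: dict[str, float] = {}
        rr_n, cc_n = cell.nucleus_indices
        rr_c, cc_c = cell.cell_indices
        nucleus_set = set(zip(rr_n.tolist(), cc_n.tolist()))
        ring = [(r, c) for r, c in zip(rr_c.tolist(), cc_c.tolist()) if (r, c) not in nucleus_set]
        ring_idx = (np.array([p[0] for p in ring], dtype=int),
                    np.array([p[1] for p in ring], dtype=int))
        compartments = {
            "nucleus": (rr_n, cc_n),
            "cytoplasm": ring_idx,
            "cell": (rr_c, cc_c),
        }
        for comp_name, idx in compartments.items():
            for stain_name, channel in (("hematoxylin", hema), ("eosin", eosin)):
                vals = _sample_channel(channel, cell, idx) if idx[0].size else np.array([])
                for stat_name, v in zip(_STATS, _od_stats(vals)):
                    feats[f"{comp_name}_{stain_name}_{stat_name}"] = v

        # nucleus shape on the detection grid
        r0, c0 = rr_n.min(), cc_n.min()
        sub = np.zeros((rr_n.max() - r0 + 3, cc_n.max() - c0 + 3), dtype=np.uint8)
        sub[rr_n - r0 + 1, cc_n - c0 + 1] = 1
        props = regionprops(sub)[0]
        mpp = cell.grid_mpp
        # Crofton estimator: less rasterization bias than the chain-code perimeter
        perimeter_um = max(props.perimeter_crofton * mpp, 1e-9)
        area = cell.nucleus_area_um2
        feats["nucleus_area"] = area
        feats["nucleus_perimeter"] = perimeter_um
        feats["nucleus_circularity"] = min(1.0, 4.0 * np.pi * area / perimeter_um**2)
        feats["nucleus_eccentricity"] = float(props.eccentricity)
        feats["nucleus_max_caliper"] = float(props.feret_diameter_max) * mpp
        feats["cell_nucleus_area_ratio"] = (cell.cell_area_um2 or area) / area

        h, w = cell.grid_shape
        feats["clipped"] = float(
            rr_c.min() == 0 or cc_c.min() == 0 or rr_c.max() == h - 1 or cc_c.max() == w - 1
        )
        cell.features = feats
    return cells


def smooth_features(cells: list[CellObject], radius_um: float) -> list[CellObject]:
    """Append Gaussian distance-weighted neighbourhood means of all base features.

    For each cell i and base feature f, the appended value is
    ``sum_j w_ij f_j / sum_j w_ij`` over cells j (including i itself) whose
    centroids lie within ``radius_um``, with ``w_ij = exp(-d_ij^2 / (2 (radius/2)^2))``.
    An isolated cell keeps its own value.  Already-smoothed columns are not
    re-smoothed.
    """
    if not cells:
        return cells
    if cells[0].features is None:
        raise ValueError("base features missing; run compute_features first")
    base_names = [k for k in cells[0].features if "_smoothed_" not in k]
    centers = np.array([c.centroid_um for c in cells])
    F = np.array([[c.features[k] for k in base_names] for c in cells])
    tree = cKDTree(centers)
    sigma2 = 2.0 * (radius_um / 2.0) ** 2
    suffix = f"_smoothed_{radius_um:g}um"
    for i, cell in enumerate(cells):
        nbrs = tree.query_ball_point(centers[i], radius_um)
        d2 = ((centers[nbrs] - centers[i]) ** 2).sum(axis=1)
        w = np.exp(-d2 / sigma2)
        sm = (w[:, None] * F[nbrs]).sum(axis=0) / w.sum()
        for name, v in zip(base_names, sm):
            cell.features[name + suffix] = float(v)
    return cells
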