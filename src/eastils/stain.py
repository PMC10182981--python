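"""H&E stain handling: optical density, per-slide stain-vector estimation, deconvolution.

Brightfield H&E obeys Beer–Lambert mixing in optical-density (OD) space:
``OD = -log10(I / I0)`` is linear in the per-stain dye concentrations, so a
pixel's 3-channel OD is ``c_h * v_h + c_e * v_e`` for unit stain vectors
``v_h`` (hematoxylin) and ``v_e`` (eosin).  Staining intensity drifts from
slide to slide, so the stain vectors are re-estimated per slide by a
Macenko-style plane fit before deconvolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageTile",
    "StainProfile",
    "ODImage",
    "StainEstimationError",
    "DEFAULT_HEMATOXYLIN",
    "DEFAULT_EOSIN",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_vectors",
    "deconvolve",
    "recompose",
]

#: Conventional H&E absorbance directions (unit vectors, RGB order).
DEFAULT_HEMATOXYLIN = np.array([0.65, 0.70, 0.29]) / np.linalg.norm([0.65, 0.70, 0.29])
DEFAULT_EOSIN = np.array([0.07, 0.99, 0.11]) / np.linalg.norm([0.07, 0.99, 0.11])

_OD_EPS_INTENSITY = 1.0  # intensity floor inside the log (8-bit units)


class StainEstimationError(ValueError):
    """Raised when a tile's OD cloud is too degenerate to fit stain vectors."""


@dataclass
class ImageTile:
    """An RGB tile with physical pixel calibration.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array of transmitted-light intensities.
    microns_per_pixel : physical edge length of one pixel, µm.
    origin_um : (x, y) offset of the tile's top-left corner in slide coordinates.
    """

    pixels: np.ndarray
    microns_per_pixel: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ODImage:
    """Optical-density image: raw 3-channel or per-stain concentration channels."""

    values: np.ndarray  # (H, W, C) float, C = 3 (raw OD) or n_stains
    microns_per_pixel: float
    channel_names: tuple[str, ...] = ("red", "green", "blue")
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("OD values must be finite")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be positive")

    def channel(self, name: str) -> "ODImage":
        """Single named channel as a (H, W, 1) ODImage."""
        idx = self.channel_names.index(name)
        return ODImage(
            self.values[..., idx : idx + 1],
            self.microns_per_pixel,
            (name,),
            self.origin_um,
        )

    @property
    def plane(self) -> np.ndarray:
        """2-D view of a single-channel image."""
        if self.values.shape[2] != 1:
            raise ValueError("plane requires a single-channel ODImage")
        return self.values[..., 0]


@dataclass
class StainProfile:
    """Unit stain vectors plus per-channel background intensity.

    ``hematoxylin`` and ``eosin`` are unit OD 3-vectors; ``residual`` completes
    an invertible basis (defaults to their normalized cross product).
    """

    hematoxylin: np.ndarray = field(default_factory=lambda: DEFAULT_HEMATOXYLIN.copy())
    eosin: np.ndarray = field(default_factory=lambda: DEFAULT_EOSIN.copy())
    residual: np.ndarray | None = None
    background: np.ndarray = field(default_factory=lambda: np.array([255.0, 255.0, 255.0]))

    def __post_init__(self) -> None:
        self.hematoxylin = _unit(np.asarray(self.hematoxylin, dtype=float))
        self.eosin = _unit(np.asarray(self.eosin, dtype=float))
        cos = float(np.clip(self.hematoxylin @ self.eosin, -1.0, 1.0))
        if np.degrees(np.arccos(cos)) <= 1.0:
            raise ValueError("hematoxylin and eosin vectors are near-collinear")
        if self.residual is None:
            self.residual = _unit(np.cross(self.hematoxylin, self.eosin))
        else:
            self.residual = _unit(np.asarray(self.residual, dtype=float))
        self.background = np.asarray(self.background, dtype=float)
        if np.any(self.background <= 0):
            raise ValueError("background intensity must be positive per channel")

    @property
    def matrix(self) -> np.ndarray:
        """Stain matrix with rows (hematoxylin, eosin, residual)."""
        return np.vstack([self.hematoxylin, self.eosin, self.residual])

    def to_json(self) -> str:
        return json.dumps(
            {
                "hematoxylin": self.hematoxylin.tolist(),
                "eosin": self.eosin.tolist(),
                "residual": self.residual.tolist(),
                "background": self.background.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "StainProfile":
        d = json.loads(text)
        return cls(
            hematoxylin=np.array(d["hematoxylin"]),
            eosin=np.array(d["eosin"]),
            residual=np.array(d["residual"]),
            background=np.array(d["background"]),
        )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length stain vector")
    return v / n


def rgb_to_od(tile: ImageTile, background: np.ndarray | None = None) -> ODImage:
    """Convert an RGB tile to 3-channel optical density.

    ``OD = -log10(max(I, 1) / I0)`` per channel; intensities above the
    background clamp to OD 0.
    """
    I0 = np.asarray(background if background is not None else [255.0, 255.0, 255.0], dtype=float)
    if np.any(I0 <= 0):
        raise ValueError("background intensity I0 must be positive per channel")
    I = np.maximum(tile.pixels.astype(float), _OD_EPS_INTENSITY)
    od = -np.log10(I / I0)
    od = np.maximum(od, 0.0)
    return ODImage(od, tile.microns_per_pixel, ("red", "green", "blue"), tile.origin_um)


def od_to_rgb(od: ODImage, background: np.ndarray | None = None) -> ImageTile:
    """Invert the OD transform: ``I = I0 * 10**(-OD)``, rounded and clipped to 8 bit."""
    I0 = np.asarray(background if background is not None else [255.0, 255.0, 255.0], dtype=float)
    I = I0 * np.power(10.0, -od.values)
    pixels = np.clip(np.rint(I), 0, 255).astype(np.uint8)
    return ImageTile(pixels, od.microns_per_pixel, od.origin_um)


def estimate_stain_vectors(
    tile: ImageTile,
    background: np.ndarray | None = None,
    od_threshold: float = 0.15,
    background_margin: float = 2.0,
    angle_percentile: float = 1.0,
    min_pixels: int = 100,
) -> StainProfile:
    """Per-slide stain-vector recalibration by a Macenko-style plane fit.

    Pixels with OD magnitude below ``od_threshold`` or any channel within
    ``background_margin`` intensity units of the background are excluded; the
    top-2 principal directions of the remaining OD cloud define the stain
    plane, and the extreme directions within the plane (at the
    ``angle_percentile`` / ``100 - angle_percentile`` angle quantiles) are
    taken as the two stain vectors.  The hematoxylin label goes to the vector
    with the larger blue OD component.

    Raises
    ------
    StainEstimationError
        If too few stained pixels remain or the OD cloud is effectively
        one-dimensional (e.g. pure background or a single stain).
    """
    I0 = np.asarray(background if background is not None else [255.0, 255.0, 255.0], dtype=float)
    od = rgb_to_od(tile, I0).values.reshape(-1, 3)
    near_bg = (tile.pixels.reshape(-1, 3).astype(float) >= (I0 - background_margin)).all(axis=1)
    keep = (np.linalg.norm(od, axis=1) >= od_threshold) & ~near_bg
    pts = od[keep]
    if pts.shape[0] < min_pixels:
        raise StainEstimationError(
            f"only {pts.shape[0]} stained pixels above OD {od_threshold}; need {min_pixels}"
        )

    # top-2 principal directions of the (uncentered) OD cloud
    cov = pts.T @ pts / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] < 1e-6 * max(evals[0], 1e-12):
        raise StainEstimationError("OD cloud is one-dimensional; cannot span a stain plane")
    e1, e2 = evecs[:, 0], evecs[:, 1]
    # orient the basis so projections are positive on average (ODs are nonnegative)
    if (pts @ e1).sum() < 0:
        e1 = -e1
    proj = np.stack([pts @ e1, pts @ e2], axis=1)
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [angle_percentile, 100.0 - angle_percentile])
    v_lo = _unit(np.cos(lo) * e1 + np.sin(lo) * e2)
    v_hi = _unit(np.cos(hi) * e1 + np.sin(hi) * e2)
    # stain absorbances are nonnegative: clamp tiny negative leakage
    v_lo = _unit(np.maximum(v_lo, 0.0)) if np.any(v_lo < 0) and np.all(v_lo > -0.2) else v_lo
    v_hi = _unit(np.maximum(v_hi, 0.0)) if np.any(v_hi < 0) and np.all(v_hi > -0.2) else v_hi
    if np.any(v_lo < 0) or np.any(v_hi < 0):
        raise StainEstimationError("fitted stain vectors have negative absorbance components")
    # hematoxylin = vector with the larger blue OD component (tie -> first)
    if v_lo[2] >= v_hi[2]:
        hema, eos = v_lo, v_hi
    else:
        hema, eos = v_hi, v_lo
    try:
        return StainProfile(hematoxylin=hema, eosin=eos, background=I0)
    except ValueError as exc:  # near-collinear fit
        raise StainEstimationError(str(exc)) from exc


def deconvolve(od: ODImage, profile: StainProfile) -> ODImage:
    """Unmix a 3-channel OD image into per-stain concentration channels.

    Solves the 3x3 system ``od = conc @ stain_matrix`` per pixel; negative
    concentrations are clamped to zero.
    """
    if od.values.shape[2] != 3:
        raise ValueError("deconvolve expects a 3-channel OD image")
    M = profile.matrix
    if abs(np.linalg.det(M)) < 1e-8:
        raise ValueError("singular stain matrix")
    conc = od.values.reshape(-1, 3) @ np.linalg.inv(M)
    conc = np.maximum(conc, 0.0)
    return ODImage(
        conc.reshape(od.values.shape),
        od.microns_per_pixel,
        ("hematoxylin", "eosin", "residual"),
        od.origin_um,
    )


def recompose(stains: ODImage, profile: StainProfile) -> ODImage:
    """Remix per-stain channels back to 3-channel OD (inverse of :func:`deconvolve`)."""
    od = stains.values.reshape(-1, 3) @ profile.matrix
    return ODImage(
        od.reshape(stains.values.shape),
        stains.microns_per_pixel,
        ("red", "green", "blue"),
        stains.origin_um,
    )
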