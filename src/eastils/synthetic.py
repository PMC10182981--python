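"""Synthetic H&E tiles and patient cohorts with known ground truth.

Tiles are composed in optical-density space via Beer–Lambert: a flat eosin
"stroma" background plus elliptical nuclei that absorb hematoxylin, then
``I = I0 * 10**(-OD)`` with additive Gaussian noise applied in OD space so
stain recovery stays exactly invertible.  Every planted nucleus is recorded
(center, class, rasterized polygon, exact pixel area), which makes the tile
a complete oracle for detection, classification and easTILs% scoring.

Cohorts emulate a neoadjuvant-trial table: per-patient easTILs%, a
pathologist sTILs% correlated with it, pCR outcome, treatment arm, receptor
status, disease type, event-free survival, and (for residual disease)
paired posttreatment scores.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import binary_dilation
from shapely.geometry import box as shapely_box
from skimage.draw import ellipse as draw_ellipse

from .geometry import mask_to_polygon
from .stain import DEFAULT_EOSIN, DEFAULT_HEMATOXYLIN, ImageTile, StainProfile

__all__ = [
    "CLASSES",
    "ClassMorphology",
    "TileSpec",
    "PlantedCell",
    "SyntheticGroundTruth",
    "OvercrowdedError",
    "generate_tile",
    "CohortSpec",
    "generate_cohort",
]

#: Canonical class order used throughout the pipeline (ties break toward tumor).
CLASSES = ("tumor", "lymphocyte", "stromal", "other")


class OvercrowdedError(RuntimeError):
    """Requested cell count could not be placed without overlap."""


@dataclass
class ClassMorphology:
    """Nucleus geometry and staining for one cell class.

    ``mean_radius_um`` is the geometric-mean radius sqrt(a*b) of the nucleus
    ellipse; ``eccentricity`` fixes the axis ratio b/a = (1 - e^2)^(1/2).
    ``hematoxylin_od`` is the (uniform) OD amplitude inside the nucleus.
    """

    mean_radius_um: float
    radius_sd_um: float
    eccentricity: float
    hematoxylin_od: float
    od_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.eccentricity < 1:
            raise ValueError("eccentricity must be in [0, 1)")
        if self.mean_radius_um <= 0 or self.hematoxylin_od <= 0:
            raise ValueError("radius and OD amplitude must be positive")


# Defaults chosen so the four classes are separable by size, shape and OD:
# lymphocytes small/round/dark, tumor nuclei large/moderate, fibroblasts
# (the "stromal" class) elongated/pale, "other" tiny dense apoptotic-body-like
# fragments that sit just above the 10 µm² detection floor.
DEFAULT_MORPHOLOGY: dict[str, ClassMorphology] = {
    "tumor": ClassMorphology(6.0, 0.6, 0.30, 0.50, 0.04),
    "lymphocyte": ClassMorphology(2.6, 0.2, 0.15, 0.90, 0.05),
    "stromal": ClassMorphology(4.0, 0.4, 0.90, 0.40, 0.03),
    "other": ClassMorphology(2.2, 0.08, 0.20, 1.40, 0.05),
}


@dataclass
class TileSpec:
    """Recipe for one synthetic tile.

    Physical size in µm; the default pixel size matches a 20x brightfield
    scanner calibration of 0.4986 µm/pixel.
    """

    width_um: float = 150.0
    height_um: float = 150.0
    microns_per_pixel: float = 0.4986
    n_tumor: int = 10
    n_lymphocyte: int = 10
    n_fibroblast: int = 10
    n_other: int = 0
    n_lymphocyte_pairs: int = 0  # planted close enough to merge after smoothing (watershed test)
    pair_spacing_um: float = 6.0  # center-to-center spacing within a pair
    morphology: dict[str, ClassMorphology] = field(
        default_factory=lambda: {k: dataclasses.replace(v) for k, v in DEFAULT_MORPHOLOGY.items()}
    )
    stroma_eosin_od: float = 0.25
    nucleus_eosin_od: float = 0.05  # nuclei displace the eosinophilic stroma
    noise_sigma_od: float = 0.02
    hematoxylin_vector: np.ndarray = field(default_factory=lambda: DEFAULT_HEMATOXYLIN.copy())
    eosin_vector: np.ndarray = field(default_factory=lambda: DEFAULT_EOSIN.copy())
    background_intensity: float = 255.0
    min_gap_um: float = 4.0  # clearance between planted nuclei ("well-separated" regime)
    edge_margin_um: float = 2.0
    max_retries: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        for n in (self.n_tumor, self.n_lymphocyte, self.n_fibroblast, self.n_other,
                  self.n_lymphocyte_pairs):
            if n < 0:
                raise ValueError("cell counts must be nonnegative")
        self.hematoxylin_vector = np.asarray(self.hematoxylin_vector, dtype=float)
        self.eosin_vector = np.asarray(self.eosin_vector, dtype=float)
        for v in (self.hematoxylin_vector, self.eosin_vector):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError("stain vectors must have unit norm")


@dataclass
class PlantedCell:
    center_um: tuple[float, float]  # (x, y)
    class_label: str
    polygon: object  # shapely polygon of the rasterized nucleus, µm coords
    area_um2: float
    mask_indices: tuple[np.ndarray, np.ndarray]  # (rows, cols) of nucleus pixels


@dataclass
class SyntheticGroundTruth:
    cells: list[PlantedCell]
    class_areas_um2: dict[str, float]
    region_polygon: object  # whole-tile rectangle, µm
    region_area_um2: float
    eastils_percent: float

    def recompute_eastils(self) -> float:
        stromal = self.region_area_um2 - self.class_areas_um2["tumor"]
        return 100.0 * self.class_areas_um2["lymphocyte"] / stromal


def _ellipse_axes(morph: ClassMorphology, rng: np.random.Generator) -> tuple[float, float]:
    r = max(0.3, rng.normal(morph.mean_radius_um, morph.radius_sd_um))
    ratio = np.sqrt(1.0 - morph.eccentricity**2)  # b/a
    a = r / np.sqrt(ratio)
    return a, a * ratio


def _place(
    occupied: np.ndarray,
    shape: tuple[int, int],
    a_px: float,
    b_px: float,
    theta: float,
    center_px: tuple[float, float],
    gap_px: float,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Rasterize a candidate nucleus; None if it collides or leaves the tile."""
    r0, c0 = center_px
    # collision test with a clearance halo
    rr_h, cc_h = draw_ellipse(r0, c0, a_px + gap_px, b_px + gap_px, shape=None, rotation=theta)
    if (rr_h < 0).any() or (cc_h < 0).any() or (rr_h >= shape[0]).any() or (cc_h >= shape[1]).any():
        return None
    if occupied[rr_h, cc_h].any():
        return None
    rr, cc = draw_ellipse(r0, c0, a_px, b_px, shape=shape, rotation=theta)
    if rr.size == 0:
        return None
    return rr, cc


def generate_tile(spec: TileSpec) -> tuple[ImageTile, SyntheticGroundTruth]:
    """Render one tile and its complete ground truth.

    Deterministic for a fixed ``spec.seed``.  Raises :class:`OvercrowdedError`
    if a cell cannot be placed without overlap within ``spec.max_retries``
    attempts.
    """
    rng = np.random.default_rng(spec.seed)
    mpp = spec.microns_per_pixel
    H = int(round(spec.height_um / mpp))
    W = int(round(spec.width_um / mpp))
    occupied = np.zeros((H, W), dtype=bool)
    hema = np.zeros((H, W), dtype=float)
    gap_px = spec.min_gap_um / mpp
    margin = spec.edge_margin_um

    requests: list[str] = (
        ["tumor"] * spec.n_tumor
        + ["lymphocyte"] * spec.n_lymphocyte
        + ["stromal"] * spec.n_fibroblast
        + ["other"] * spec.n_other
    )
    cells: list[PlantedCell] = []

    def commit(label: str, rr: np.ndarray, cc: np.ndarray, od_amp: float) -> PlantedCell:
        occupied[rr, cc] = True
        hema[rr, cc] = od_amp
        mask = np.zeros((H, W), dtype=bool)
        mask[rr, cc] = True
        poly = mask_to_polygon(mask, mpp)
        cx = (cc.mean() + 0.5) * mpp
        cy = (rr.mean() + 0.5) * mpp
        return PlantedCell((cx, cy), label, poly, rr.size * mpp**2, (rr, cc))

    def plant(label: str) -> PlantedCell:
        morph = spec.morphology[label]
        for _ in range(spec.max_retries):
            a_um, b_um = _ellipse_axes(morph, rng)
            theta = rng.uniform(0, np.pi)
            x = rng.uniform(margin + a_um, spec.width_um - margin - a_um)
            y = rng.uniform(margin + a_um, spec.height_um - margin - a_um)
            hit = _place(occupied, (H, W), a_um / mpp, b_um / mpp, theta, (y / mpp, x / mpp), gap_px)
            if hit is None:
                continue
            od_amp = max(0.05, rng.normal(morph.hematoxylin_od, morph.od_sd))
            return commit(label, *hit, od_amp)
        raise OvercrowdedError(f"could not place a '{label}' nucleus after {spec.max_retries} tries")

    for label in requests:
        cells.append(plant(label))

    # touching pairs: second lymphocyte at sub-diameter spacing from the first,
    # allowed to touch its partner (clearance halo waived) but nothing else
    morph_l = spec.morphology["lymphocyte"]
    for _ in range(spec.n_lymphocyte_pairs):
        first = plant("lymphocyte")
        cells.append(first)
        partner_free = np.zeros((H, W), dtype=bool)
        partner_free[first.mask_indices] = True
        partner_free = binary_dilation(partner_free, iterations=int(np.ceil(gap_px)) + 1)
        fy, fx = first.center_um[1] / mpp, first.center_um[0] / mpp
        d_px = spec.pair_spacing_um / mpp
        second = None
        for _ in range(spec.max_retries):
            ang = rng.uniform(0, 2 * np.pi)
            a_um, b_um = _ellipse_axes(morph_l, rng)
            theta = rng.uniform(0, np.pi)
            ctr = (fy + d_px * np.sin(ang), fx + d_px * np.cos(ang))
            hit = _place(occupied & ~partner_free, (H, W), a_um / mpp, b_um / mpp, theta, ctr, gap_px)
            if hit is not None:
                rr, cc = hit
                keep = ~occupied[rr, cc]  # touching, never sharing, pixels
                rr, cc = rr[keep], cc[keep]
                if rr.size == 0:
                    continue
                od_amp = max(0.05, rng.normal(morph_l.hematoxylin_od, morph_l.od_sd))
                second = commit("lymphocyte", rr, cc, od_amp)
                break
        if second is None:
            raise OvercrowdedError("could not place the touching partner of a lymphocyte pair")
        cells.append(second)

    # compose: OD = hema * v_h + stroma_eosin * v_e (+ noise), then exponentiate
    eosin = np.full((H, W), spec.stroma_eosin_od)
    eosin[occupied] = spec.nucleus_eosin_od
    od = hema[..., None] * spec.hematoxylin_vector + eosin[..., None] * spec.eosin_vector
    if spec.noise_sigma_od > 0:
        od = od + rng.normal(0.0, spec.noise_sigma_od, od.shape)
    od = np.maximum(od, 0.0)
    pixels = np.clip(np.rint(spec.background_intensity * 10.0**(-od)), 0, 255).astype(np.uint8)
    tile = ImageTile(pixels, mpp)

    class_areas = {c: 0.0 for c in CLASSES}
    for cell in cells:
        class_areas[cell.class_label] += cell.area_um2
    region_area = float(H * W) * mpp**2
    from shapely.geometry import box as shapely_box

    region = shapely_box(0.0, 0.0, W * mpp, H * mpp)
    stromal_area = region_area - class_areas["tumor"]
    eastils = 100.0 * class_areas["lymphocyte"] / stromal_area
    gt = SyntheticGroundTruth(cells, class_areas, region, region_area, eastils)
    return tile, gt


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Recipe for a synthetic neoadjuvant cohort.

    Two outcome models:

    * ``mode="group_medians"`` — draw the pCR flag at ``pcr_rate``, then draw
      easTILs% from a gamma distribution whose median matches the outcome
      group (defaults 36.1% for pCR, 14.8% for residual disease).
    * ``mode="logistic"`` — draw easTILs% from the marginal gamma, then
      pCR ~ Bernoulli(expit(intercept + slope * easTILs%)).

    sTILs% is linear in easTILs% plus Gaussian noise, truncated to [0, 100].
    Event-free survival is exponential with a per-outcome rate and uniform
    administrative censoring.
    """

    n_patients: int = 113
    mode: str = "group_medians"
    pcr_rate: float = 33 / 113
    median_eastils_pcr: float = 36.1
    median_eastils_rd: float = 14.8
    gamma_shape: float = 2.0
    logistic_intercept: float = -2.0
    logistic_slope: float = 0.05
    marginal_median_eastils: float = 17.0
    stils_slope: float = 0.6
    stils_intercept: float = 0.0
    stils_noise_sd: float = 18.0  # chosen so corr(easTILs%, sTILs%) ~ 0.6 at the default spread
    bevacizumab_fraction: float = 98 / 211
    hr_positive_fraction: float = 144 / 211
    ibc_fraction: float = 24 / 211
    efs_rate_pcr: float = 0.004   # events per month
    efs_rate_rd: float = 0.012
    censor_window_months: tuple[float, float] = (36.0, 72.0)
    post_eastils_ratio: float = 0.5  # posttreatment / pretreatment median ratio in RD
    post_noise_log_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("group_medians", "logistic"):
            raise ValueError("mode must be 'group_medians' or 'logistic'")
        if not 0 <= self.pcr_rate <= 1:
            raise ValueError("pcr_rate must be a probability")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")


def _gamma_scale_for_median(shape: float, median: float) -> float:
    return median / sps.gamma.ppf(0.5, shape)


COHORT_COLUMNS = [
    "patient_id", "eastils_percent", "stils_percent", "pcr", "arm",
    "hr_positive", "er_positive", "disease_type", "efs_months", "efs_event",
    "post_eastils_percent", "post_stils_percent",
]


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort table; one row per patient, reproducible under seed."""
    if spec.n_patients < 0:
        raise ValueError("n_patients must be nonnegative")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    k = spec.gamma_shape
    if spec.mode == "group_medians":
        pcr = rng.random(n) < spec.pcr_rate
        scale = np.where(
            pcr,
            _gamma_scale_for_median(k, spec.median_eastils_pcr),
            _gamma_scale_for_median(k, spec.median_eastils_rd),
        )
        eastils = rng.gamma(k, scale)
    else:
        eastils = rng.gamma(k, _gamma_scale_for_median(k, spec.marginal_median_eastils), n)
        p = 1.0 / (1.0 + np.exp(-(spec.logistic_intercept + spec.logistic_slope * eastils)))
        pcr = rng.random(n) < p

    stils = spec.stils_intercept + spec.stils_slope * eastils + rng.normal(0, spec.stils_noise_sd, n)
    stils = np.clip(stils, 0.0, 100.0)

    arm = np.where(rng.random(n) < spec.bevacizumab_fraction, "chemo+bev", "chemo")
    hr_pos = rng.random(n) < spec.hr_positive_fraction
    # HR+ is defined as ER+ and/or PR+; most HR+ tumors are ER+
    er_pos = hr_pos & (rng.random(n) < 0.9)
    disease = np.where(rng.random(n) < spec.ibc_fraction, "IBC", "LABC")

    rate = np.where(pcr, spec.efs_rate_pcr, spec.efs_rate_rd)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(*spec.censor_window_months, n)
    efs_months = np.minimum(t_event, t_cens)
    efs_event = t_event <= t_cens

    # paired posttreatment scores exist only for residual disease
    post_e = np.where(
        ~pcr,
        eastils * spec.post_eastils_ratio * np.exp(rng.normal(0, spec.post_noise_log_sd, n)),
        np.nan,
    )
    post_s = np.where(
        ~pcr,
        np.clip(spec.stils_slope * post_e + rng.normal(0, spec.stils_noise_sd, n), 0, 100),
        np.nan,
    )

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "eastils_percent": eastils,
            "stils_percent": stils,
            "pcr": pcr,
            "arm": arm,
            "hr_positive": hr_pos,
            "er_positive": er_pos,
            "disease_type": disease,
            "efs_months": efs_months,
            "efs_event": efs_event,
            "post_eastils_percent": post_e,
            "post_stils_percent": post_s,
        }
    )
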