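"""Seeded synthetic B-mode lung images and cohort tables with known truth.

The image model is first-order speckle: per-pixel echo amplitude is drawn
from a Rayleigh law whose scale depends on tissue class (chest-wall soft
tissue above the pleura; a bright pleural band; a dark aerated-lung field
below, with horizontal reverberation bands — A-lines — at integer multiples
of the pleural depth and optional vertical B-line bands; a tissue-like
consolidation region when configured). Amplitude is attenuated
exponentially along the aerated path traversed above each pixel, then
log-compressed to the displayed 0-255 range with a configurable dynamic
range, and quantized. Two qualitative behaviors of real lung images are
built in and verified by tests: mean echo intensity in the sub-pleural
region of interest rises with consolidation extent and falls as an aerated
gap separates the consolidation from the pleura (reverberation weakens when
a lesion is small or far from the pleural line).

The cohort generator emulates the study's group structure: CT-negative
hemithoraxes with Gray units around 39 +/- 9, CT-positive ones around
93 +/- 26, a monotone Gray-unit/nonaerated-volume relation and an inverse
Gray-unit/pleural-distance relation, and CXR/LUS labels that favor larger
and shallower lesions through logistic links. A fast table-only mode draws
Gray units directly from those links; the image mode renders every
hemithorax and scores it with the quantification operator.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .data import QLUS_CUTOFF, CohortTable, HemithoraxRecord
from .quantify import BModeImage, quantify_image

__all__ = [
    "ConsolidationGeometry",
    "SimulationConfig",
    "GroundTruth",
    "CohortParams",
    "simulate_bmode",
    "simulate_cohort",
    "save_image_png",
]


@dataclass(frozen=True)
class ConsolidationGeometry:
    """A rectangular consolidation below the pleural band.

    ``top_gap_mm`` is the aerated gap between the pleural band and the lesion
    top (0 = subpleural); ``height_mm``/``width_mm`` its axial and lateral
    extent; ``center_col_frac`` its lateral center as a fraction of width.
    """

    top_gap_mm: float = 0.0
    height_mm: float = 25.0
    width_mm: float = 25.0
    center_col_frac: float = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one synthetic B-mode frame."""

    depth_mm: float = 60.0
    width_mm: float = 40.0
    axial_spacing_mm: float = 0.2
    lateral_spacing_mm: float = 0.25
    pleural_depth_mm: float = 15.0
    pleural_thickness_mm: float = 1.0
    # Rayleigh amplitude scales per tissue class (consolidation > aerated)
    scale_tissue: float = 5.0
    scale_aerated: float = 1.6
    scale_consolidation: float = 6.0
    scale_pleura: float = 30.0
    # reverberation (A-line) bands at k * pleural depth, k = 2, 3, ...
    n_a_lines: int = 2
    a_line_decay: float = 0.45
    # vertical B-line bands (bright columns from the pleura down)
    n_b_lines: int = 0
    b_line_width_mm: float = 1.5
    # exponential attenuation accumulated along aerated path (per mm)
    attenuation_per_mm: float = 0.025
    # log compression: dB relative to norm_amplitude mapped onto [0, 255]
    dynamic_range_db: float = 45.0
    norm_amplitude: float = 100.0
    # nominal slab thickness converting 2-D mask area to a volume
    slab_thickness_mm: float = 80.0
    consolidation: ConsolidationGeometry | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "depth_mm", "width_mm", "axial_spacing_mm", "lateral_spacing_mm",
            "pleural_thickness_mm", "scale_tissue", "scale_aerated",
            "scale_consolidation", "scale_pleura", "dynamic_range_db",
            "norm_amplitude", "slab_thickness_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scale_consolidation <= self.scale_aerated:
            raise ValueError("consolidation scale must exceed the aerated-lung scale")
        if not 0 <= self.pleural_depth_mm < self.depth_mm:
            raise ValueError("pleural depth must lie inside the image")
        if self.attenuation_per_mm < 0:
            raise ValueError("attenuation must be nonnegative")
        c = self.consolidation
        if c is not None:
            bottom = self.pleural_depth_mm + self.pleural_thickness_mm + c.top_gap_mm + c.height_mm
            if c.top_gap_mm < 0 or c.height_mm <= 0 or c.width_mm <= 0:
                raise ValueError("consolidation geometry must be nonnegative/positive")
            if bottom > self.depth_mm or c.width_mm > self.width_mm:
                raise ValueError("consolidation does not fit inside the image")

    def to_json(self, **kwargs) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("consolidation") is not None:
            d["consolidation"] = ConsolidationGeometry(**d["consolidation"])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator knows: the stand-in for a CT reference."""

    consolidation_mask: np.ndarray  # boolean grid, image shape
    pleural_depth_mm: float
    distance_from_pleura_mm: float | None
    lesion_size_mm: float | None
    nonaerated_volume_ml: float

    def to_dict(self) -> dict:
        return {
            "pleural_depth_mm": self.pleural_depth_mm,
            "distance_from_pleura_mm": self.distance_from_pleura_mm,
            "lesion_size_mm": self.lesion_size_mm,
            "nonaerated_volume_ml": self.nonaerated_volume_ml,
            "consolidation_area_px": int(self.consolidation_mask.sum()),
        }


def simulate_bmode(config: SimulationConfig) -> tuple[BModeImage, GroundTruth]:
    """Render one synthetic frame. Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_rows = int(round(config.depth_mm / config.axial_spacing_mm))
    n_cols = int(round(config.width_mm / config.lateral_spacing_mm))
    depths = (np.arange(n_rows) + 0.5) * config.axial_spacing_mm  # row centers

    pleura_top = config.pleural_depth_mm
    pleura_bot = pleura_top + config.pleural_thickness_mm
    in_pleura = (depths >= pleura_top) & (depths < pleura_bot)
    above = depths < pleura_top

    scale = np.full((n_rows, n_cols), config.scale_aerated)
    scale[above, :] = config.scale_tissue
    scale[in_pleura, :] = config.scale_pleura

    # A-lines: reverberation bands at integer multiples of the pleural depth,
    # decaying geometrically with the repetition order.
    for k in range(2, 2 + config.n_a_lines):
        top = k * config.pleural_depth_mm
        band = (depths >= top) & (depths < top + config.pleural_thickness_mm)
        if band.any():
            scale[band, :] = np.maximum(
                scale[band, :], config.scale_pleura * config.a_line_decay ** (k - 1)
            )

    # B-lines: bright vertical bands from the pleural band to the bottom.
    b_line_cols = np.zeros(n_cols, dtype=bool)
    if config.n_b_lines > 0:
        half_w = max(1, int(round(config.b_line_width_mm / config.lateral_spacing_mm / 2)))
        centers = rng.integers(half_w, n_cols - half_w, size=config.n_b_lines)
        for c in centers:
            b_line_cols[c - half_w : c + half_w + 1] = True
        below = depths >= pleura_bot
        scale[np.ix_(below, b_line_cols)] = np.maximum(
            scale[np.ix_(below, b_line_cols)], config.scale_pleura * 0.8
        )

    # consolidation region
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    c = config.consolidation
    if c is not None:
        top = pleura_bot + c.top_gap_mm
        rows = (depths >= top) & (depths < top + c.height_mm)
        w_cols = int(round(c.width_mm / config.lateral_spacing_mm))
        c0 = int(round(c.center_col_frac * n_cols - w_cols / 2))
        c0 = min(max(c0, 0), n_cols - w_cols)
        mask[rows, c0 : c0 + w_cols] = True
        scale[mask] = config.scale_consolidation

    amplitude = rng.rayleigh(scale=scale)

    # attenuation accumulates only along aerated lung traversed above a pixel
    aerated = (~above[:, None]) & (~in_pleura[:, None]) & (~mask) & (~b_line_cols[None, :])
    aerated = aerated & (depths[:, None] >= pleura_bot)
    path_mm = np.cumsum(aerated * config.axial_spacing_mm, axis=0)
    below = depths >= pleura_bot
    amplitude[below, :] *= np.exp(-config.attenuation_per_mm * path_mm[below, :])

    # log compression onto the displayed 8-bit range
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(amplitude / config.norm_amplitude)
    gray = 255.0 * np.clip(1.0 + db / config.dynamic_range_db, 0.0, 1.0)
    image = BModeImage(
        np.round(gray).astype(np.uint8),
        config.axial_spacing_mm,
        config.lateral_spacing_mm,
        metadata={"synthetic": True, "seed": config.seed},
    )

    if c is not None:
        area_mm2 = float(mask.sum()) * config.axial_spacing_mm * config.lateral_spacing_mm
        volume_ml = area_mm2 * config.slab_thickness_mm / 1000.0
        truth = GroundTruth(mask, config.pleural_depth_mm, c.top_gap_mm,
                            max(c.height_mm, c.width_mm), volume_ml)
    else:
        truth = GroundTruth(mask, config.pleural_depth_mm, None, None, 0.0)
    return image, truth


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class CohortParams:
    """Distributions and links behind the synthetic cohort.

    Defaults emulate the study regime: CT-negative Gray units centered on 39
    with SD 9 (truncated at the largest CT-negative value observed, 52, so the
    healthy upper tail matches the ~95% specificity regime rather than a
    Gaussian tail); CT-positive Gray units produced by a saturating monotone
    link in nonaerated volume minus a linear pleural-distance penalty; and
    logistic CXR/LUS links that favor larger, shallower lesions.
    """

    # CT-negative Gray-unit distribution (truncated normal)
    neg_gu_mean: float = 39.0
    neg_gu_sd: float = 9.0
    neg_gu_bounds: tuple[float, float] = (0.0, 52.0)
    # lesion geometry for CT-positive rows
    subpleural_prob: float = 0.6
    distance_gamma_shape: float = 2.0
    distance_gamma_scale: float = 12.0
    size_lognorm_mu: float = math.log(52.0)
    size_lognorm_sigma: float = 0.75
    size_bounds: tuple[float, float] = (8.0, 230.0)
    volume_factor_mu: float = math.log(3.4)  # volume = size * lognormal factor
    volume_factor_sigma: float = 0.5
    volume_bounds: tuple[float, float] = (20.0, 1100.0)
    # Gray-unit link: gu = base + span * v/(v + half_sat) - dist_slope * distance + noise
    gu_base: float = 40.0
    gu_span: float = 95.0
    gu_half_sat_ml: float = 120.0
    gu_distance_slope: float = 0.7
    gu_noise_sd: float = 11.0
    # label links, logit scale
    cxr_intercept: float = -1.0
    cxr_size_coef: float = 0.03
    cxr_distance_coef: float = -0.03
    lus_intercept: float = 2.5
    lus_size_coef: float = 0.02
    lus_distance_coef: float = -0.4
    # false-positive probabilities on CT-negative rows
    cxr_fp_prob: float = 0.2
    lus_fp_prob: float = 0.05
    cutoff: float = QLUS_CUTOFF
    # image-mode rendering template (consolidation geometry is filled per row)
    image_template: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.subpleural_prob <= 1:
            raise ValueError("subpleural_prob must be a probability")
        for name in ("neg_gu_sd", "distance_gamma_shape", "distance_gamma_scale",
                     "size_lognorm_sigma", "gu_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for p in (self.cxr_fp_prob, self.lus_fp_prob):
            if not 0 <= p <= 1:
                raise ValueError("false-positive probabilities must be in [0, 1]")


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, n) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _positive_lesion(rng: np.random.Generator, p: CohortParams) -> tuple[float, float, float]:
    """Draw (distance_mm, size_mm, volume_ml) for one CT-positive row."""
    if rng.random() < p.subpleural_prob:
        dist = 0.0
    else:
        dist = float(np.round(max(1.0, rng.gamma(p.distance_gamma_shape, p.distance_gamma_scale))))
    size = float(np.round(np.clip(rng.lognormal(p.size_lognorm_mu, p.size_lognorm_sigma),
                                  *p.size_bounds)))
    volume = float(np.round(np.clip(size * rng.lognormal(p.volume_factor_mu, p.volume_factor_sigma),
                                    *p.volume_bounds)))
    return dist, size, volume


def expected_gray_units(volume_ml: float, distance_mm: float, p: CohortParams) -> float:
    """The noise-free Gray-unit link used by the table-only generator."""
    return (p.gu_base + p.gu_span * volume_ml / (volume_ml + p.gu_half_sat_ml)
            - p.gu_distance_slope * distance_mm)


def _render_positive(
    rng: np.random.Generator, p: CohortParams, dist: float, size: float
) -> tuple[float, float]:
    """Image-mode Gray units and mask-derived volume for one positive row."""
    t = p.image_template
    max_height = t.depth_mm - t.pleural_depth_mm - t.pleural_thickness_mm - dist - 1.0
    if max_height <= 2.0:
        dist = max(0.0, t.depth_mm - t.pleural_depth_mm - t.pleural_thickness_mm - 5.0)
        max_height = t.depth_mm - t.pleural_depth_mm - t.pleural_thickness_mm - dist - 1.0
    geometry = ConsolidationGeometry(
        top_gap_mm=dist,
        height_mm=min(size, max_height),
        width_mm=min(size, t.width_mm),
    )
    config = dataclasses.replace(
        t, consolidation=geometry, seed=int(rng.integers(0, 2**31 - 1))
    )
    image, truth = simulate_bmode(config)
    result = quantify_image(image, config.pleural_depth_mm, cutoff=p.cutoff)
    return result.mean_gray_units, truth.nonaerated_volume_ml


def simulate_cohort(
    n_pos: int,
    n_neg: int,
    params: CohortParams | None = None,
    seed: int = 0,
    mode: str = "table",
) -> tuple[CohortTable, list[GroundTruth | None]]:
    """Generate a synthetic cohort of ``n_pos`` CT-positive and ``n_neg``
    CT-negative hemithorax rows.

    ``mode='table'`` draws Gray units directly from the configured links
    (fast); ``mode='image'`` renders a B-mode frame per row and scores it with
    the quantification operator, so the whole pipeline is exercised. All
    randomness flows from one generator seeded by ``seed``; reruns are
    identical.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be nonnegative")
    if mode not in ("table", "image"):
        raise ValueError(f"unknown mode {mode!r}")
    p = params or CohortParams()
    rng = np.random.default_rng(seed)
    records: list[HemithoraxRecord] = []
    truths: list[GroundTruth | None] = []

    for i in range(n_pos):
        dist, size, volume = _positive_lesion(rng, p)
        if mode == "table":
            gu = expected_gray_units(volume, dist, p) + rng.normal(0.0, p.gu_noise_sd)
            gu = float(np.round(np.clip(gu, 0.0, 255.0)))
            truths.append(None)
        else:
            gu, volume = _render_positive(rng, p, dist, size)
            image_truth = GroundTruth(np.empty(0, dtype=bool), p.image_template.pleural_depth_mm,
                                      dist, size, volume)
            truths.append(image_truth)
        cxr = rng.random() < _sigmoid(p.cxr_intercept + p.cxr_size_coef * size
                                      + p.cxr_distance_coef * dist)
        lus = rng.random() < _sigmoid(p.lus_intercept + p.lus_size_coef * size
                                      + p.lus_distance_coef * dist)
        records.append(HemithoraxRecord(
            patient_id=i + 1,
            region="Unlisted",
            ct_label=True,
            cxr_label=bool(cxr),
            lus_label=bool(lus),
            qlus_label=gu > p.cutoff,
            distance_from_pleura_mm=dist,
            lesion_size_mm=size,
            nonaerated_volume_ml=volume,
            gray_units=gu,
        ))

    for i in range(n_neg):
        if mode == "table":
            gu = float(np.round(_truncated_normal(
                rng, p.neg_gu_mean, p.neg_gu_sd, *p.neg_gu_bounds, 1)[0]))
            truths.append(None)
        else:
            config = dataclasses.replace(
                p.image_template, consolidation=None, seed=int(rng.integers(0, 2**31 - 1))
            )
            image, truth = simulate_bmode(config)
            gu = quantify_image(image, config.pleural_depth_mm, cutoff=p.cutoff).mean_gray_units
            truths.append(truth)
        records.append(HemithoraxRecord(
            patient_id=n_pos + i + 1,
            region="Unlisted",
            ct_label=False,
            cxr_label=bool(rng.random() < p.cxr_fp_prob),
            lus_label=bool(rng.random() < p.lus_fp_prob),
            qlus_label=gu > p.cutoff,
            nonaerated_volume_ml=0.0,
            gray_units=gu,
        ))

    return CohortTable(records, provenance="synthetic"), truths


def save_image_png(image: BModeImage, truth: GroundTruth, path) -> None:
    """Write the frame as 8-bit PNG plus a JSON sidecar with the ground truth."""
    from PIL import Image

    Image.fromarray(image.intensities, mode="L").save(path)
    sidecar = str(path) + ".json"
    meta = truth.to_dict()
    meta["axial_spacing_mm"] = image.axial_spacing_mm
    meta["lateral_spacing_mm"] = image.lateral_spacing_mm
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
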