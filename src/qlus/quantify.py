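"""Grayscale quantification of B-mode lung ultrasound images.

The score is a first-order statistic: within a region of interest extending
axially from the pleural line to the bottom of the image, the 256-bin
frequency distribution of 8-bit echo intensities (Gray units) is formed and
its mean retained. A depth profile of mean echo intensity over thin (default
0.2 mm) horizontal slices is computed alongside. The pneumonia call is
positive if and only if the mean Gray-unit score is strictly above the
cutoff (default 48): strictness is forced by the study data, where a score
of exactly 48 was called negative and 52 positive.

The pleural-line depth is an *input* — from image metadata, configuration,
or the heuristic detector below; in the original workflow the region of
interest was placed manually.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data import QLUS_CUTOFF

__all__ = [
    "BModeImage",
    "RegionOfInterest",
    "EchoProfile",
    "GrayHistogram",
    "QuantificationResult",
    "InvalidROIError",
    "PleuralLineNotFound",
    "detect_pleural_line",
    "extract_roi",
    "slice_profile",
    "gray_histogram",
    "classify_qlus",
    "quantify_image",
    "read_bmode_png",
    "read_bmode_dicom",
]

DEFAULT_SLICE_THICKNESS_MM = 0.2


class InvalidROIError(ValueError):
    """The requested region of interest is empty or outside the image."""


class PleuralLineNotFound(RuntimeError):
    """Automatic pleural-line detection failed; supply the depth explicitly."""


@dataclass(frozen=True)
class BModeImage:
    """A single-frame 8-bit grayscale B-mode image.

    Rows run down the image in increasing depth; ``axial_spacing_mm`` and
    ``lateral_spacing_mm`` give the physical size of one pixel.
    """

    intensities: np.ndarray
    axial_spacing_mm: float
    lateral_spacing_mm: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("intensities must be a nonempty 2-D grid")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "intensities", arr.astype(np.uint8))
        if self.axial_spacing_mm <= 0 or self.lateral_spacing_mm <= 0:
            raise ValueError("pixel spacings must be positive")

    @property
    def n_rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_cols(self) -> int:
        return self.intensities.shape[1]

    @property
    def depth_mm(self) -> float:
        return self.n_rows * self.axial_spacing_mm

    @property
    def width_mm(self) -> float:
        return self.n_cols * self.lateral_spacing_mm


@dataclass(frozen=True)
class RegionOfInterest:
    top_depth_mm: float
    bottom_depth_mm: float
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if not self.top_depth_mm < self.bottom_depth_mm:
            raise InvalidROIError("ROI must have positive axial extent")
        if self.col_start < 0 or self.col_stop <= self.col_start:
            raise InvalidROIError("ROI column bounds are invalid")


@dataclass(frozen=True)
class EchoProfile:
    """Mean echo intensity per thin horizontal depth slice of the ROI."""

    slice_thickness_mm: float
    means: np.ndarray  # per-slice mean intensity, ordered by depth
    pixel_counts: np.ndarray

    @property
    def n_slices(self) -> int:
        return len(self.means)

    def weighted_mean(self) -> float:
        """Pixel-count-weighted mean of slice means (equals the ROI pixel mean)."""
        return float(np.average(self.means, weights=self.pixel_counts))


@dataclass(frozen=True)
class GrayHistogram:
    """256-bin frequency distribution of Gray units with its mean."""

    counts: np.ndarray  # counts[level] for level 0..255
    total: int
    mean_gray_units: float

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "GrayHistogram":
        counts = np.asarray(counts, dtype=np.int64)
        total = int(counts.sum())
        if total == 0:
            raise InvalidROIError("cannot build a histogram from zero pixels")
        mean = float(np.dot(np.arange(256), counts) / total)
        return cls(counts=counts, total=total, mean_gray_units=mean)


def detect_pleural_line(
    image: BModeImage,
    search_band_mm: tuple[float, float] | None = None,
    smoothing_mm: float = 1.0,
) -> float:
    """Heuristic pleural-line depth: the brightest smoothed row in a band.

    The pleural line is the dominant horizontal echo near the top of a lung
    image, so the row whose (axially smoothed) mean intensity is maximal
    within ``search_band_mm`` is a serviceable locator for simulated and
    typical clinical frames. It is an aid only — callers may always override
    with a known depth.

    Raises
    ------
    PleuralLineNotFound
        If the image is flat (zero variance) inside the band.
    """
    if search_band_mm is None:
        search_band_mm = (0.5, image.depth_mm / 2.0)
    lo, hi = search_band_mm
    if not 0 <= lo < hi <= image.depth_mm:
        raise ValueError(f"search band {search_band_mm} outside image depth {image.depth_mm}")
    row_means = image.intensities.mean(axis=1)
    size = max(1, int(round(smoothing_mm / image.axial_spacing_mm)))
    smooth = ndimage.uniform_filter1d(row_means, size=size, mode="nearest")
    r_lo = int(math.ceil(lo / image.axial_spacing_mm))
    r_hi = max(r_lo + 1, int(hi / image.axial_spacing_mm))
    band = smooth[r_lo:r_hi]
    if band.size == 0 or np.ptp(band) == 0:
        raise PleuralLineNotFound("no intensity structure in the search band")
    return float((r_lo + int(np.argmax(band))) * image.axial_spacing_mm)


def extract_roi(
    image: BModeImage,
    pleural_depth_mm: float,
    lateral_bounds: tuple[int, int] | None = None,
) -> tuple[RegionOfInterest, np.ndarray]:
    """ROI from the pleural line to the bottom of the image.

    The pleural-line row itself is included: the first ROI row is the first
    image row at or below ``pleural_depth_mm``. The ROI spans the full width
    unless ``lateral_bounds`` (half-open column range) is given.
    """
    if not 0 <= pleural_depth_mm < image.depth_mm:
        raise InvalidROIError(
            f"pleural depth {pleural_depth_mm} mm outside image depth {image.depth_mm} mm"
        )
    # first row whose top edge is at or below the pleural depth
    r0 = int(math.ceil(pleural_depth_mm / image.axial_spacing_mm - 1e-9))
    if r0 >= image.n_rows:
        raise InvalidROIError("pleural depth leaves an empty ROI")
    c0, c1 = lateral_bounds if lateral_bounds is not None else (0, image.n_cols)
    if not (0 <= c0 < c1 <= image.n_cols):
        raise InvalidROIError(f"lateral bounds {lateral_bounds} outside image")
    roi = RegionOfInterest(
        top_depth_mm=r0 * image.axial_spacing_mm,
        bottom_depth_mm=image.depth_mm,
        col_start=c0,
        col_stop=c1,
    )
    return roi, image.intensities[r0:, c0:c1]


def slice_profile(
    sub_image: np.ndarray,
    axial_spacing_mm: float,
    slice_thickness_mm: float = DEFAULT_SLICE_THICKNESS_MM,
) -> EchoProfile:
    """Group ROI rows into consecutive depth bins and average each bin.

    A trailing partial slice is kept, so every ROI pixel contributes to
    exactly one slice.
    """
    if slice_thickness_mm <= 0:
        raise ValueError("slice thickness must be positive")
    sub_image = np.asarray(sub_image)
    if sub_image.size == 0:
        raise InvalidROIError("empty ROI")
    n_rows, n_cols = sub_image.shape
    depths = np.arange(n_rows) * axial_spacing_mm
    idx = np.floor(depths / slice_thickness_mm + 1e-9).astype(int)
    n_slices = idx[-1] + 1
    row_sums = sub_image.sum(axis=1, dtype=np.int64)
    sums = np.bincount(idx, weights=row_sums, minlength=n_slices)
    counts = np.bincount(idx, minlength=n_slices) * n_cols
    return EchoProfile(
        slice_thickness_mm=slice_thickness_mm,
        means=sums / counts,
        pixel_counts=counts,
    )


def gray_histogram(sub_image: np.ndarray) -> GrayHistogram:
    """256-bin integer histogram of the ROI pixels and its mean Gray units."""
    sub_image = np.asarray(sub_image)
    if sub_image.size == 0:
        raise InvalidROIError("empty ROI")
    counts = np.bincount(sub_image.ravel().astype(np.int64), minlength=256)
    return GrayHistogram.from_counts(counts)


def classify_qlus(mean_gu: float, cutoff: float = QLUS_CUTOFF) -> bool:
    """Pneumonia call: positive iff the mean Gray-unit score is strictly above the cutoff."""
    if not 0 <= mean_gu <= 255:
        raise ValueError(f"mean Gray units {mean_gu} outside [0, 255]")
    return mean_gu > cutoff


@dataclass(frozen=True)
class QuantificationResult:
    roi: RegionOfInterest
    profile: EchoProfile
    histogram: GrayHistogram
    mean_gray_units: float
    label: bool
    cutoff: float

    def to_dict(self) -> dict:
        return {
            "mean_gray_units": self.mean_gray_units,
            "label": int(self.label),
            "cutoff": self.cutoff,
            "roi": {
                "top_depth_mm": self.roi.top_depth_mm,
                "bottom_depth_mm": self.roi.bottom_depth_mm,
                "col_start": self.roi.col_start,
                "col_stop": self.roi.col_stop,
            },
            "slice_thickness_mm": self.profile.slice_thickness_mm,
            "slice_means": [float(m) for m in self.profile.means],
            "slice_pixel_counts": [int(c) for c in self.profile.pixel_counts],
            "histogram_counts": [int(c) for c in self.histogram.counts],
            "total_pixels": self.histogram.total,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def quantify_image(
    image: BModeImage,
    pleural_depth_mm: float,
    *,
    cutoff: float = QLUS_CUTOFF,
    slice_thickness_mm: float = DEFAULT_SLICE_THICKNESS_MM,
    lateral_bounds: tuple[int, int] | None = None,
) -> QuantificationResult:
    """Full quantification: ROI -> depth profile + histogram -> score -> call."""
    roi, sub = extract_roi(image, pleural_depth_mm, lateral_bounds)
    profile = slice_profile(sub, image.axial_spacing_mm, slice_thickness_mm)
    hist = gray_histogram(sub)
    mean_gu = hist.mean_gray_units
    return QuantificationResult(
        roi=roi,
        profile=profile,
        histogram=hist,
        mean_gray_units=mean_gu,
        label=classify_qlus(mean_gu, cutoff),
        cutoff=cutoff,
    )


def read_bmode_png(path, axial_spacing_mm: float, lateral_spacing_mm: float) -> BModeImage:
    """Read an 8-bit PNG as a B-mode image; pixel spacing must be supplied."""
    from PIL import Image

    with Image.open(path) as im:
        if im.mode not in ("L", "I;16", "I", "P", "RGB", "RGBA"):
            raise ValueError(f"unsupported PNG mode {im.mode}")
        arr = np.asarray(im.convert("L"))
    return BModeImage(arr, axial_spacing_mm, lateral_spacing_mm, metadata={"source": str(path)})


def read_bmode_dicom(
    path,
    axial_spacing_mm: float | None = None,
    lateral_spacing_mm: float | None = None,
) -> BModeImage:
    """Read a single-frame grayscale DICOM as an 8-bit B-mode image.

    Pixel spacing is taken from the PixelSpacing element (row spacing =
    axial, column spacing = lateral) unless overridden; if the file carries
    no spacing, overrides are required. Monochrome photometric
    interpretations are rescaled to the displayed 0-255 range (MONOCHROME1
    is inverted); color (e.g. Doppler) frames are rejected.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise ValueError("color DICOM frames are not supported; grayscale B-mode only")
    if int(getattr(ds, "NumberOfFrames", 1)) != 1:
        raise ValueError("multi-frame DICOM is not supported; store single frames")
    arr = ds.pixel_array.astype(np.float64)
    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    if photometric == "MONOCHROME1":
        arr = arr.max() - arr
    if arr.max() > 255 or arr.min() < 0 or arr.max() == arr.min():
        lo, hi = float(arr.min()), float(arr.max())
        arr = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo) * 255.0
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is not None:
        axial = axial_spacing_mm if axial_spacing_mm is not None else float(spacing[0])
        lateral = lateral_spacing_mm if lateral_spacing_mm is not None else float(spacing[1])
    else:
        if axial_spacing_mm is None or lateral_spacing_mm is None:
            raise ValueError("DICOM carries no PixelSpacing; spacing overrides are required")
        axial, lateral = axial_spacing_mm, lateral_spacing_mm
    meta = {"source": str(path), "photometric": photometric}
    return BModeImage(np.round(arr), axial, lateral, metadata=meta)
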