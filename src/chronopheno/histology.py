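"""Fluorescence-section quantification.

Implements the study's ImageJ-style rules: amyloid plaques are segmented as
connected components brighter than the image mean plus ``k_sd`` standard
deviations, kept only when "well circumscribed" (a configurable circularity
and minimum-area filter); per-subject plaque size is taken from the 3 largest
plaques as equivalent circular diameters in micrometres; percent area is the
fraction of pixels above the same mean+SD threshold; overall staining
intensity can be normalized to a reference group (e.g. the vehicle-treated
nontransgenic mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "SectionImage",
    "Plaque",
    "PlaqueSet",
    "HistologyError",
    "read_section_image",
    "write_section_tiff",
    "to_8bit",
    "detect_plaques",
    "top3_plaque_sizes",
    "percent_area",
    "mean_intensity",
]

REGIONS = ("prefrontal_cortex", "dorsal_hippocampus", "anterior_hypothalamus")
CHANNELS = ("Abeta", "PER1")


class HistologyError(ValueError):
    pass


@dataclass
class SectionImage:
    """One cropped, single-channel fluorescence section (region of interest)."""

    pixels: np.ndarray
    pixel_size_um: float
    region: str | None = None
    subject_id: str | None = None
    channel: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise HistologyError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise HistologyError("intensities must be finite and non-negative")
        if self.pixel_size_um <= 0:
            raise HistologyError("pixel_size_um must be positive")
        if self.region is not None and self.region not in REGIONS:
            raise HistologyError(f"unknown region {self.region!r}")
        if self.channel is not None and self.channel not in CHANNELS:
            raise HistologyError(f"unknown channel {self.channel!r}")


@dataclass
class Plaque:
    centroid_px: tuple[float, float]
    area_px: int
    area_um2: float
    equivalent_diameter_um: float
    circularity: float
    mean_intensity: float


@dataclass
class PlaqueSet:
    plaques: list[Plaque] = field(default_factory=list)
    threshold_used: float = float("nan")
    image_mean: float = float("nan")
    image_sd: float = float("nan")

    def __len__(self) -> int:
        return len(self.plaques)


def read_section_image(path, pixel_size_um: float, region: str | None = None,
                       subject_id: str | None = None,
                       channel: str | None = None) -> SectionImage:
    """Load a grayscale TIFF/PNG section; pixel size comes from the caller
    (sidecar config or CLI flag), since acquisition metadata is unreliable.

    Multi-channel images are rejected rather than silently flattened.
    """
    from pathlib import Path

    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim != 2:
        raise HistologyError(
            f"{path}: expected a single-channel 2-D image, got shape {px.shape}")
    return SectionImage(pixels=px.astype(float), pixel_size_um=pixel_size_um,
                        region=region, subject_id=subject_id, channel=channel)


def write_section_tiff(image: SectionImage, path) -> None:
    import tifffile

    tifffile.imwrite(path, image.pixels.astype(np.float32))


def to_8bit(image: SectionImage) -> SectionImage:
    """Linear min-max rescale of intensities to the integer range 0-255.

    A constant image maps to all zeros. Pixel rank order is preserved, so
    mean+SD thresholding before or after conversion selects the same pixels
    (up to 8-bit quantization).
    """
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        out = np.zeros_like(px)
    else:
        out = np.round((px - lo) / (hi - lo) * 255.0)
    return replace(image, pixels=out)


def detect_plaques(image: SectionImage, k_sd: float = 1.0,
                   min_area_um2: float = 50.0,
                   min_circularity: float = 0.4,
                   opening_radius_px: int = 1) -> PlaqueSet:
    """Segment plaques by mean + k_sd x SD thresholding with a shape filter.

    The binary mask is cleaned by a small morphological opening (removes
    single-pixel noise speckle) and hole filling before 8-connected component
    labeling; components smaller than ``min_area_um2`` or with circularity
    4*pi*area/perimeter^2 below ``min_circularity`` (i.e. not "well
    circumscribed") are discarded.
    """
    px = image.pixels
    mu, sd = float(px.mean()), float(px.std())
    if sd == 0:
        raise HistologyError("zero-variance image: threshold undefined")
    thr = mu + k_sd * sd
    mask = px > thr
    if opening_radius_px > 0:
        mask = morphology.opening(mask, morphology.disk(opening_radius_px))
    mask = ndimage.binary_fill_holes(mask)
    labels = measure.label(mask, connectivity=2)
    pxa = image.pixel_size_um ** 2
    plaques: list[Plaque] = []
    for prop in measure.regionprops(labels, intensity_image=px):
        area_um2 = prop.area * pxa
        if area_um2 < min_area_um2:
            continue
        perim = prop.perimeter
        circ = 4.0 * np.pi * prop.area / perim ** 2 if perim > 0 else 1.0
        circ = min(circ, 1.0)
        if circ < min_circularity:
            continue
        plaques.append(Plaque(
            centroid_px=tuple(float(c) for c in prop.centroid),
            area_px=int(prop.area),
            area_um2=float(area_um2),
            equivalent_diameter_um=float(2.0 * np.sqrt(area_um2 / np.pi)),
            circularity=float(circ),
            mean_intensity=float(prop.intensity_mean),
        ))
    return PlaqueSet(plaques=plaques, threshold_used=thr, image_mean=mu, image_sd=sd)


def top3_plaque_sizes(ps: PlaqueSet) -> list[float]:
    """Equivalent diameters (um) of the up-to-3 largest plaques, descending.

    Ties in area break to the plaque whose centroid comes first in row-major
    order, making the ranking deterministic.
    """
    ranked = sorted(
        ps.plaques,
        key=lambda p: (-p.area_um2, p.centroid_px[0], p.centroid_px[1]))
    return [p.equivalent_diameter_um for p in ranked[:3]]


def percent_area(image: SectionImage, k_sd: float = 1.0) -> float:
    """Percent of pixels brighter than mean + k_sd x SD of the image.

    Invariant under positive affine intensity rescaling, since the threshold
    co-transforms with the pixel values.
    """
    px = image.pixels
    mu, sd = float(px.mean()), float(px.std())
    if sd == 0:
        raise HistologyError("zero-variance image: percent area undefined")
    return 100.0 * float(np.mean(px > mu + k_sd * sd))


def mean_intensity(image: SectionImage, reference_mean: float | None = None
                   ) -> tuple[float, float | None]:
    """Raw mean intensity over the ROI and, optionally, the fold change
    relative to a reference-group mean (e.g. vehicle-treated nontransgenic)."""
    raw = float(image.pixels.mean())
    if reference_mean is None:
        return raw, None
    if reference_mean <= 0:
        raise HistologyError("reference mean must be positive")
    return raw, raw / reference_mean
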