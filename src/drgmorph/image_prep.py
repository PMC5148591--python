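"""Image pre-processing: thresholding, debris removal, soma segmentation.

Mirrors the manual pre-processing applied to neurofilament-stained
confocal images before Sholl analysis: the 8-bit grayscale image is
thresholded, pixels belonging to debris, unspecific background staining
or neurites of adjacent neurons are removed, and the soma is segmented
so its diameter can be measured and its pixels excluded from
intersection counting.  The manual removal of foreign structures is
replaced by a deterministic surrogate: only the connected component
containing the soma seed point is retained.

Coordinate conventions: 0-based pixel indices, origin top-left, x
rightward (columns), y downward (rows); physical position of a pixel is
``index * pixel_size`` µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk, opening, remove_small_objects

from .errors import (
    InvalidParameterError,
    NoForegroundError,
    SeedNotOnForegroundError,
    SomaNotFoundError,
)


@dataclass
class CleanMask:
    """Binary foreground containing exactly one soma-connected component."""

    mask: np.ndarray          # bool, (rows, cols)
    soma_center: tuple[float, float]  # (x, y) pixels
    pixel_size: float         # µm / pixel


@dataclass
class SomaSegment:
    """Soma mask within a CleanMask plus its physical size."""

    mask: np.ndarray          # bool, subset of the clean mask
    soma_diameter: float      # µm (maximum Feret diameter)

    @property
    def soma_radius(self) -> float:
        return self.soma_diameter / 2.0


def threshold_image(image: np.ndarray, method: str = "otsu",
                    level: int | None = None) -> np.ndarray:
    """Binarise an 8-bit grayscale image; foreground = pixels >= threshold.

    ``method`` is ``"otsu"`` (between-class-variance maximising threshold)
    or ``"fixed"`` with an explicit ``level``.  A constant image carries
    no separable foreground and raises :class:`NoForegroundError`.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise InvalidParameterError("expected a single-plane 2-D image")
    if np.ptp(image) == 0:
        raise NoForegroundError("constant image: no foreground to threshold")
    if method == "otsu":
        thr = threshold_otsu(image)
        # threshold_otsu returns the upper edge of the background class;
        # foreground is defined inclusively as >= next gray level
        return image > thr
    if method == "fixed":
        if level is None:
            raise InvalidParameterError("fixed thresholding requires a level")
        return image >= level
    raise InvalidParameterError(f"unknown threshold method {method!r}")


def clean_mask(mask: np.ndarray, soma_center: tuple[float, float],
               pixel_size: float, min_component_px: int = 20) -> CleanMask:
    """Keep only the 8-connected component containing the soma seed.

    Speckle smaller than ``min_component_px`` is dropped first; then
    every component other than the one containing ``soma_center`` —
    debris blobs, background staining, neurites of adjacent neurons —
    is removed regardless of size.  Idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    x, y = soma_center
    row, col = int(round(y)), int(round(x))
    if not (0 <= row < mask.shape[0] and 0 <= col < mask.shape[1]):
        raise SeedNotOnForegroundError("soma seed lies outside the image")
    if not mask[row, col]:
        raise SeedNotOnForegroundError("soma seed pixel is background")
    if min_component_px > 1:
        # drop components strictly smaller than min_component_px
        despeckled = remove_small_objects(mask, max_size=min_component_px - 1,
                                          connectivity=2)
        # never drop the seed's own component, whatever its size
        if despeckled[row, col]:
            mask = despeckled
    labels = label(mask, connectivity=2)
    keep = labels == labels[row, col]
    return CleanMask(mask=keep, soma_center=(float(x), float(y)),
                     pixel_size=float(pixel_size))


def segment_soma(clean: CleanMask, opening_radius_px: int) -> SomaSegment:
    """Separate the soma from its neurites by morphological opening.

    Opening with a disk strictly wider than the neurite line width
    erases the thin neurites and keeps the soma; of what survives, the
    component containing the soma seed is the soma mask.  The soma
    diameter is the maximum Feret diameter of that region in µm.

    ``opening_radius_px`` should be about ``ceil(1.5 * line_width)`` for
    line widths in pixels.
    """
    if not clean.mask.any():
        raise SomaNotFoundError("clean mask is empty")
    opened = opening(clean.mask, footprint=disk(opening_radius_px))
    if not opened.any():
        raise SomaNotFoundError("opening removed all foreground: no soma-scale blob")
    labels = label(opened, connectivity=2)
    x, y = clean.soma_center
    row, col = int(round(y)), int(round(x))
    lbl = labels[row, col]
    if lbl == 0:
        # seed shaved off by opening: fall back to the nearest opened pixel
        rows, cols = np.nonzero(opened)
        nearest = np.argmin((rows - row) ** 2 + (cols - col) ** 2)
        lbl = labels[rows[nearest], cols[nearest]]
    soma = labels == lbl
    props = regionprops(soma.astype(np.uint8))[0]
    # feret_diameter_max spans pixel boundaries; the physical rim runs
    # through the outermost pixel centers, so correct by one pixel
    feret_px = max(1.0, float(props.feret_diameter_max) - 1.0)
    return SomaSegment(mask=soma, soma_diameter=feret_px * clean.pixel_size)
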