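"""Automatic body/phantom contouring on axial CT slices.

The boundary of the patient (or phantom) is recovered slice by slice with a
fixed sequence: threshold at -200 HU (skin is near 0 HU, the surround is air
near -1000 HU), label the connected components, keep the one with the
largest area (this discards the patient table, clothing, tubing), then fill
every enclosed hole so that low-attenuation interior structures — lungs,
bowel gas, sinuses — stay inside the region of interest.  The resulting mask
feeds the water-equivalent-diameter computation; only its pixel membership
is consumed downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .image_io import CTVolume

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_HU = -200.0


class ContouringError(RuntimeError):
    pass


class NoBodyFoundError(ContouringError):
    """No above-threshold pixels on a slice."""


@dataclass
class BodyMask:
    """Per-slice binary body region aligned with a :class:`CTVolume`.

    Attributes
    ----------
    mask : (n_slices, rows, cols) bool array; filled body region.
    found : per-slice flag; False where no body was detected (air-only slice).
    truncated : per-slice flag; True where the body touches the image border,
        i.e. anatomy may extend beyond the field of view (no correction is
        applied; the diameter is then an underestimate).
    """

    mask: np.ndarray
    found: np.ndarray
    truncated: np.ndarray

    @property
    def area_px(self) -> np.ndarray:
        return self.mask.sum(axis=(1, 2))

    @property
    def n_found(self) -> int:
        return int(self.found.sum())


def threshold_slice(hu_slice: np.ndarray, threshold: float = DEFAULT_THRESHOLD_HU) -> np.ndarray:
    """Binary field: True where HU >= threshold."""
    hu_slice = np.asarray(hu_slice, dtype=float)
    if not np.all(np.isfinite(hu_slice)):
        raise ContouringError("slice contains non-finite HU values")
    return hu_slice >= threshold


def largest_component(binary: np.ndarray) -> np.ndarray:
    """Connected component of maximal area (8-connectivity).

    Equal-area ties break toward the component whose centroid is nearest the
    image center (the patient is normally centered); a warning is logged.
    """
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        raise NoBodyFoundError("no pixels above threshold on this slice")
    props = measure.regionprops(labels)
    areas = np.array([p.area for p in props])
    best = np.flatnonzero(areas == areas.max())
    if len(best) > 1:
        center = (np.array(binary.shape) - 1) / 2.0
        dists = [np.linalg.norm(np.array(props[i].centroid) - center) for i in best]
        choice = best[int(np.argmin(dists))]
        logger.warning("equal-area components (%d px); keeping the most central one",
                       int(areas.max()))
    else:
        choice = best[0]
    return labels == props[choice].label


def fill_interior(component: np.ndarray) -> np.ndarray:
    """Fill every hole fully enclosed by the component."""
    return ndimage.binary_fill_holes(component)


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def contour_slice(hu_slice: np.ndarray, threshold: float = DEFAULT_THRESHOLD_HU) -> np.ndarray:
    """threshold -> largest component -> fill, for a single slice."""
    return fill_interior(largest_component(threshold_slice(hu_slice, threshold)))


def auto_contour(volume: CTVolume, threshold: float = DEFAULT_THRESHOLD_HU) -> BodyMask:
    """Contour every slice of ``volume``.

    Slices where no body is found are flagged (``found=False``) and carry an
    empty mask; downstream averages exclude them.  If no slice contains a
    body the volume is rejected.
    """
    n = volume.n_slices
    mask = np.zeros(volume.hu.shape, dtype=bool)
    found = np.zeros(n, dtype=bool)
    truncated = np.zeros(n, dtype=bool)
    for i in range(n):
        try:
            m = contour_slice(volume.hu[i], threshold)
        except NoBodyFoundError:
            warnings.warn(f"slice {i + 1}: no body found; excluded from averages",
                          stacklevel=2)
            continue
        mask[i] = m
        found[i] = True
        truncated[i] = _touches_border(m)
        if truncated[i]:
            logger.warning("slice %d: body touches image border; truncation suspected",
                           i + 1)
    if not found.any():
        raise ContouringError("no body found on any slice")
    return BodyMask(mask=mask, found=found, truncated=truncated)
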