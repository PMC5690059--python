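r"""Water-equivalent diameter: per-slice, all-slice, and n-slice estimators.

The water-equivalent diameter is the diameter of the water cylinder that
attenuates X-rays like the patient cross-section:

    D_W = 2 * sqrt[ (mean_HU/1000 + 1) * A_ROI / pi ]

with ``A_ROI`` the body-region area in cm^2 and ``mean_HU`` the mean HU over
that region.  For a uniform water region (0 HU) this reduces to the diameter
of the equal-area circle.  The all-slice value D_W,all is the unweighted mean
of per-slice diameters; D_W,n approximates it from n slices spread evenly
along the longitudinal axis, with the percentage difference

    PD = 100 * (D_W,n - D_W,all) / D_W,all
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .contouring import BodyMask
from .image_io import CTVolume

logger = logging.getLogger(__name__)

#: physical floor of the HU scale; a mean below this (noise, calibration
#: drift) would make the radicand negative and is clamped
MEAN_HU_FLOOR = -1000.0

DEFAULT_N_VALUES = (1, 3, 5, 7, 9)


@dataclass(frozen=True)
class SliceMetrics:
    """Region area, mean attenuation and water-equivalent diameter of one slice."""

    index: int          # 0-based slice index in the volume
    z_mm: float         # longitudinal position
    area_cm2: float
    mean_hu: float
    dw_cm: float


@dataclass
class ScanMetrics:
    """Per-slice metrics plus the scan-level diameter estimators."""

    slices: list[SliceMetrics]
    dw_all: float
    dw_n: dict[int, float] = field(default_factory=dict)
    pd_n: dict[int, float] = field(default_factory=dict)
    selected_indices: dict[int, list[int]] = field(default_factory=dict)
    n_excluded: int = 0


def slice_dw(mean_hu: float, area_cm2: float) -> float:
    """Water-equivalent diameter (cm) of a region from mean HU and area.

    The mean HU is clamped at -1000 (pure air gives D_W = 0).
    """
    if area_cm2 <= 0:
        raise ValueError(f"region area must be positive, got {area_cm2}")
    if mean_hu < MEAN_HU_FLOOR:
        logger.warning("mean HU %.1f below %.0f; clamped", mean_hu, MEAN_HU_FLOOR)
        mean_hu = MEAN_HU_FLOOR
    return 2.0 * float(np.sqrt((1.0 + mean_hu / 1000.0) * area_cm2 / np.pi))


def per_slice_metrics(volume: CTVolume, body: BodyMask) -> list[SliceMetrics]:
    """Area (cm^2), mean HU and D_W for every slice with a detected body.

    Slices flagged not-found are skipped (logged); callers can compare
    ``len(result)`` with ``volume.n_slices``.
    """
    if body.mask.shape != volume.hu.shape:
        raise ValueError("mask shape does not match volume")
    out = []
    for i in range(volume.n_slices):
        if not body.found[i]:
            logger.warning("slice %d excluded: no body", i + 1)
            continue
        m = body.mask[i]
        area_cm2 = float(m.sum()) * volume.pixel_area_cm2
        mean_hu = float(volume.hu[i][m].mean())
        out.append(SliceMetrics(
            index=i,
            z_mm=float(volume.slice_positions[i]),
            area_cm2=area_cm2,
            mean_hu=mean_hu,
            dw_cm=slice_dw(mean_hu, area_cm2),
        ))
    return out


def dw_all(metrics: list[SliceMetrics]) -> float:
    """Unweighted mean of per-slice diameters over the included slices."""
    if not metrics:
        raise ValueError("no slices to average")
    return float(np.mean([m.dw_cm for m in metrics]))


def select_slices(n_total: int, n: int) -> list[int]:
    """Indices of n slices spread evenly over [0, n_total-1].

    Endpoints are included and the selection is symmetric about the center;
    n=1 returns the central slice.  Fractional positions round half away
    from the center, which keeps the selection symmetric.
    """
    if n < 1 or n > n_total:
        raise ValueError(f"cannot select {n} slices from {n_total}")
    if n == 1:
        return [(n_total - 1) // 2]
    center = (n_total - 1) / 2.0
    idx = []
    for i in range(n):
        pos = i * (n_total - 1) / (n - 1)
        frac = pos - np.floor(pos)
        if abs(frac - 0.5) < 1e-9:
            j = int(np.floor(pos)) if pos < center else int(np.ceil(pos))
        else:
            j = int(round(pos))
        idx.append(j)
    return sorted(set(idx))


def dw_n(metrics: list[SliceMetrics], n: int) -> tuple[float, list[int]]:
    """n-slice estimator of D_W,all and the selected slice indices.

    Selection runs over the included (body-found) slices in order.
    """
    sel = select_slices(len(metrics), n)
    value = float(np.mean([metrics[j].dw_cm for j in sel]))
    return value, [metrics[j].index for j in sel]


def percent_diff(dw_n_val: float, dw_all_val: float) -> float:
    """Signed percentage difference of an estimator from D_W,all."""
    return 100.0 * (dw_n_val - dw_all_val) / dw_all_val


def scan_metrics(volume: CTVolume, body: BodyMask,
                 n_values=DEFAULT_N_VALUES) -> ScanMetrics:
    """Full diameter report: per-slice metrics, D_W,all, D_W,n and PD."""
    slices = per_slice_metrics(volume, body)
    if not slices:
        raise ValueError("no usable slices in scan")
    all_val = dw_all(slices)
    sm = ScanMetrics(slices=slices, dw_all=all_val,
                     n_excluded=volume.n_slices - len(slices))
    for n in n_values:
        if n > len(slices):
            logger.warning("n=%d exceeds %d usable slices; skipped", n, len(slices))
            continue
        val, sel = dw_n(slices, n)
        sm.dw_n[n] = val
        sm.pd_n[n] = percent_diff(val, all_val)
        sm.selected_indices[n] = sel
    return sm
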