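"""Ground-truthed synthetic CT volumes for validating the pipeline.

Phantoms are piecewise-uniform HU fields over analytic geometry — a uniform
PMMA disk (the 16/32-cm CTDI phantoms, ~120 HU), an elliptical thorax with
two air-filled lung ellipses, or a head ellipse — rasterized on a CT-like
grid over a -1000 HU air background, optionally with a high-attenuation
table slab below the body and Gaussian HU noise.

Because the geometry is analytic, the true water-equivalent diameter of
every slice is known exactly (continuous areas and the area-weighted mean
HU), alongside a pixel-level oracle computed from the rasterized mask.  A
per-slice scale profile along the longitudinal axis emulates head-like
(flat dome, tapered ends) and thorax-like (smoothly varying) anatomy for
the few-slice estimator study.

Rasterization uses pixel-center inclusion: a pixel belongs to a shape iff
its center lies inside (boundary counts as inside).  This fixes the pixel
oracle exactly.  No projection or reconstruction physics is emulated; the
phantoms live directly in the HU domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dw_core import slice_dw
from .image_io import CTVolume

AIR_HU = -1000.0


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: center (cx, cy) and semi-axes (ax, ay), in cm.

    x runs along columns (lateral), y along rows (anterior-posterior,
    increasing downward); the origin is the image center.
    """

    cx_cm: float
    cy_cm: float
    ax_cm: float
    ay_cm: float
    hu: float

    @property
    def area_cm2(self) -> float:
        return math.pi * self.ax_cm * self.ay_cm

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (((x - self.cx_cm) / self.ax_cm) ** 2
                + ((y - self.cy_cm) / self.ay_cm) ** 2) <= 1.0

    def scaled(self, f: float) -> "Ellipse":
        return replace(self, cx_cm=self.cx_cm * f, cy_cm=self.cy_cm * f,
                       ax_cm=self.ax_cm * f, ay_cm=self.ay_cm * f)


@dataclass(frozen=True)
class TableSpec:
    """Patient-table slab below the body: a thin high-HU rectangle."""

    width_cm: float = 45.0
    thickness_cm: float = 2.0
    gap_cm: float = 1.0      # air gap between body and table; 0 = tangent
    hu: float = 300.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic phantom volume."""

    kind: str                      # disk | ellipse_thorax | ellipse_head
    body: Ellipse
    internal: tuple[Ellipse, ...] = ()
    table: TableSpec | None = None
    noise_sigma: float = 0.0       # HU
    pixel_spacing_mm: float = 1.0
    grid: tuple[int, int] = (512, 512)
    n_slices: int = 1
    z_profile: tuple[float, ...] | None = None   # per-slice geometry scale
    slice_spacing_mm: float = 3.0
    seed: int = 0

    def profile(self) -> np.ndarray:
        if self.z_profile is None:
            return np.ones(self.n_slices)
        p = np.asarray(self.z_profile, dtype=float)
        if p.shape != (self.n_slices,) or np.any(p <= 0):
            raise GeometryError("z_profile must give a positive scale per slice")
        return p


@dataclass
class SyntheticPhantom:
    """A generated volume with its analytic and pixel-level ground truth."""

    spec: PhantomSpec
    ct: CTVolume
    body_mask: np.ndarray            # (n_slices, rows, cols) bool, table excluded
    slice_dw_analytic: np.ndarray    # cm, from continuous geometry
    slice_dw_raster: np.ndarray      # cm, pixel oracle from the noiseless raster
    dw_all_analytic: float = field(init=False)

    def __post_init__(self) -> None:
        self.dw_all_analytic = float(np.mean(self.slice_dw_analytic))


# ---------------------------------------------------------------------------
# spec factories: the standard study objects
# ---------------------------------------------------------------------------

def disk_spec(diameter_cm: float = 32.0, hu_body: float = 120.0, **kw) -> PhantomSpec:
    """Uniform PMMA-like disk, the CTDI phantom cross-section."""
    r = diameter_cm / 2.0
    return PhantomSpec(kind="disk", body=Ellipse(0, 0, r, r, hu_body), **kw)


def thorax_spec(axes_cm: tuple[float, float] = (30.0, 20.0),
                hu_body: float = 40.0, hu_lung: float = -850.0, **kw) -> PhantomSpec:
    """Elliptical thorax with two air-dominated lung ellipses.

    ``axes_cm`` are full lateral x AP extents; lungs are placed
    symmetrically inside the body.
    """
    ax, ay = axes_cm[0] / 2.0, axes_cm[1] / 2.0
    lungs = (
        Ellipse(-0.42 * ax, -0.05 * ay, 0.33 * ax, 0.55 * ay, hu_lung),
        Ellipse(+0.42 * ax, -0.05 * ay, 0.33 * ax, 0.55 * ay, hu_lung),
    )
    return PhantomSpec(kind="ellipse_thorax", body=Ellipse(0, 0, ax, ay, hu_body),
                       internal=lungs, **kw)


def head_spec(axes_cm: tuple[float, float] = (16.0, 19.0),
              hu_body: float = 60.0, **kw) -> PhantomSpec:
    """Head-like ellipse with no internal air."""
    ax, ay = axes_cm[0] / 2.0, axes_cm[1] / 2.0
    return PhantomSpec(kind="ellipse_head", body=Ellipse(0, 0, ax, ay, hu_body), **kw)


# ---------------------------------------------------------------------------
# longitudinal profiles
# ---------------------------------------------------------------------------

def head_profile(n_slices: int, depth: float = 0.08, power: float = 0.25) -> np.ndarray:
    """Head-like scale profile: a flat dome with concave taper at both ends.

    f(u) = 1 - depth*|2u-1|^power over u in [0, 1].  With power < 0.5 the
    taper is concentrated at the scan ends, so the central slice exceeds
    the longitudinal mean and evenly spread few-slice samples approach the
    mean from above as n grows.
    """
    if n_slices < 2:
        return np.ones(n_slices)
    u = np.linspace(0.0, 1.0, n_slices)
    return 1.0 - depth * np.abs(2.0 * u - 1.0) ** power


def thorax_profile(n_slices: int, seed: int = 0, amplitude: float = 0.05) -> np.ndarray:
    """Thorax-like scale profile: smooth low-order variation along z."""
    rng = np.random.default_rng(seed)
    u = np.linspace(0.0, 1.0, n_slices)
    f = np.ones(n_slices)
    for harmonic in (1, 2):
        amp = amplitude * rng.uniform(0.3, 1.0) / harmonic
        phase = rng.uniform(0.0, 2.0 * math.pi)
        f += amp * np.sin(2.0 * math.pi * harmonic * u + phase)
    return f


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def analytic_slice_dw(spec: PhantomSpec) -> np.ndarray:
    """Exact per-slice D_W from continuous areas and area-weighted mean HU."""
    body = spec.body
    a_out = body.area_cm2
    # internal structures replace body material; they scale with the slice,
    # so the area-weighted mean HU is profile-independent and D_W scales
    # linearly with the per-slice factor
    mean_hu = body.hu
    for s in spec.internal:
        mean_hu += (s.hu - body.hu) * s.area_cm2 / a_out
    base = slice_dw(mean_hu, a_out)
    return spec.profile() * base


def _grids_cm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = spec.grid
    s = spec.pixel_spacing_mm / 10.0
    y = (np.arange(rows) - (rows - 1) / 2.0) * s
    x = (np.arange(cols) - (cols - 1) / 2.0) * s
    return np.meshgrid(x, y)


def _check_fov(spec: PhantomSpec, allow_truncation: bool) -> None:
    rows, cols = spec.grid
    s = spec.pixel_spacing_mm / 10.0
    half_x, half_y = cols * s / 2.0, rows * s / 2.0
    fmax = float(spec.profile().max())
    b = spec.body
    if (abs(b.cx_cm) + b.ax_cm) * fmax > half_x or (abs(b.cy_cm) + b.ay_cm) * fmax > half_y:
        if not allow_truncation:
            raise GeometryError(
                f"body extent exceeds the {2*half_x:.1f}x{2*half_y:.1f} cm field "
                "of view; enlarge the grid or pass allow_truncation=True"
            )


def _table_mask(spec: PhantomSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    t = spec.table
    fmax = float(spec.profile().max())
    y_top = spec.body.cy_cm * fmax + spec.body.ay_cm * fmax + t.gap_cm
    if t.gap_cm < 0:
        raise GeometryError("table overlaps the body (negative gap)")
    return (np.abs(x) <= t.width_cm / 2.0) & (y >= y_top) & (y <= y_top + t.thickness_cm)


def generate(spec: PhantomSpec, allow_truncation: bool = False) -> SyntheticPhantom:
    """Rasterize ``spec`` into a CT volume with full ground truth.

    With a fixed seed the result is bit-reproducible.
    """
    _check_fov(spec, allow_truncation)
    x, y = _grids_cm(spec)
    profile = spec.profile()
    pix_cm2 = (spec.pixel_spacing_mm / 10.0) ** 2

    hu = np.full((spec.n_slices, *spec.grid), AIR_HU)
    body_mask = np.zeros_like(hu, dtype=bool)
    raster_dw = np.empty(spec.n_slices)

    table_px = None
    if spec.table is not None:
        table_px = _table_mask(spec, x, y)

    for i, f in enumerate(profile):
        bm = spec.body.scaled(f).contains(x, y)
        sl = np.where(bm, spec.body.hu, AIR_HU)
        for s in spec.internal:
            sm = s.scaled(f).contains(x, y)
            sl = np.where(sm, s.hu, sl)
        # pixel oracle from the noiseless raster, table excluded
        n_px = int(bm.sum())
        raster_dw[i] = slice_dw(float(sl[bm].mean()), n_px * pix_cm2)
        if table_px is not None:
            if table_px.sum() >= n_px:
                raise GeometryError("table artifact area must stay below the body area")
            sl = np.where(table_px & ~bm, spec.table.hu, sl)
        hu[i] = sl
        body_mask[i] = bm

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, hu.shape)

    z = np.arange(spec.n_slices) * spec.slice_spacing_mm
    ct = CTVolume(hu, (spec.pixel_spacing_mm, spec.pixel_spacing_mm), z)
    return SyntheticPhantom(
        spec=spec, ct=ct, body_mask=body_mask,
        slice_dw_analytic=analytic_slice_dw(spec),
        slice_dw_raster=raster_dw,
    )


def add_table_artifact(phantom: SyntheticPhantom, table: TableSpec) -> SyntheticPhantom:
    """Regenerate ``phantom`` with a table slab injected below the body."""
    return generate(replace(phantom.spec, table=table))
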