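"""Engineered excitation PSF and the 42-slot tracking pattern.

The excitation profile is a single engineered PSF consisting of three Gaussian
foci placed on the perimeter of a 2 um circle, one in focus and the other two
shifted 400 nm out of focus in either direction.  Tracking selects one focus at
a time: a deflector moves the chosen Gaussian into the circle center (an
aperture blocks the other two), so the lateral shot position together with the
identity of the selected focus encodes a full 3D excitation position.

The tracking pattern is a 13-point xy layout repeated on each of the three
z-layers, with one blank (laser-off) slot per z-layer move: 42 slots of 20 us
at a 50 kHz pulse rate, i.e. a 0.84 ms pattern period.

All positions are in nm; times in the schedule are in microseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, RectBivariateSpline

from ._interp import trilinear

__all__ = [
    "PSFStack",
    "BeamGeometry",
    "Slot",
    "ShotSchedule",
    "PatternConfig",
    "build_synthetic_psf",
    "load_psf_stack",
    "save_psf_stack",
    "interpolate_psf",
    "build_tracking_pattern",
    "psf_value",
    "shot_displacements",
]

SLOT_PERIOD_US = 20.0
EXCITATION_WINDOW_US = 10.0
#: reconstruction volume (x, y, z) in nm
RECONSTRUCTION_VOLUME_NM = (950.0, 950.0, 1390.0)


@dataclass(frozen=True)
class BeamGeometry:
    """Geometry of the three-Gaussian engineered excitation PSF.

    Parameters
    ----------
    circle_diameter:
        Diameter (nm) of the circle on whose perimeter the three foci sit.
    axial_offsets:
        Axial focus offsets (nm) of the three Gaussians, symmetric about the
        focal plane.
    lateral_waist:
        1/e^2 lateral beam radius (nm) of each Gaussian focus.
    axial_waist:
        1/e^2 axial half-length (nm) of each focus.
    perimeter_angles_deg:
        Angular positions of the three foci on the circle perimeter.
    """

    circle_diameter: float = 2000.0
    axial_offsets: tuple[float, float, float] = (-400.0, 0.0, 400.0)
    lateral_waist: float = 250.0
    axial_waist: float = 600.0
    perimeter_angles_deg: tuple[float, float, float] = (90.0, 210.0, 330.0)

    def __post_init__(self) -> None:
        if self.lateral_waist <= 0 or self.axial_waist <= 0:
            raise ValueError("beam waists must be positive")
        if self.circle_diameter <= 0:
            raise ValueError("circle diameter must be positive")
        if len(self.axial_offsets) != 3 or len(self.perimeter_angles_deg) != 3:
            raise ValueError("exactly three Gaussian foci are required")
        off = np.sort(np.asarray(self.axial_offsets, dtype=float))
        if not np.allclose(off + off[::-1], 0.0):
            raise ValueError("axial offsets must be symmetric about the focal plane")

    def focus_centers(self) -> np.ndarray:
        """(3, 3) array of focus center positions (x, y, z) in nm."""
        r = self.circle_diameter / 2.0
        ang = np.deg2rad(np.asarray(self.perimeter_angles_deg, dtype=float))
        return np.column_stack(
            [r * np.cos(ang), r * np.sin(ang), np.asarray(self.axial_offsets, float)]
        )


@dataclass
class PSFStack:
    """A 3D nonnegative excitation-intensity grid.

    ``intensities`` is indexed ``[z, y, x]`` (TIFF page order); ``voxel_size``
    and ``origin`` are (dx, dy, dz) and the world position (nm) of voxel
    ``[0, 0, 0]`` relative to the PSF reference point (circle center at the
    focal plane).
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array (z, y, x)")
        if np.any(np.asarray(self.voxel_size) <= 0):
            raise ValueError("voxel size must be positive")
        if self.intensities.min() < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.intensities.shape
        return (nx, ny, nz)

    @property
    def max_intensity(self) -> float:
        if not hasattr(self, "_max_intensity"):
            self._max_intensity = float(self.intensities.max())
        return self._max_intensity

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (nm) of voxel centers along x, y, z."""
        nx, ny, nz = self.shape_xyz
        dx, dy, dz = self.voxel_size
        ox, oy, oz = self.origin
        return (
            ox + dx * np.arange(nx),
            oy + dy * np.arange(ny),
            oz + dz * np.arange(nz),
        )

    def extent(self) -> np.ndarray:
        """(3, 2) min/max world coordinate covered per axis (x, y, z)."""
        x, y, z = self.axes()
        return np.array([[x[0], x[-1]], [y[0], y[-1]], [z[0], z[-1]]])

    def value(self, r: np.ndarray, outside: str = "error") -> np.ndarray:
        """Trilinear interpolation of the stack at world positions ``r`` (nm).

        ``r`` is shape (..., 3) in (x, y, z) order.  ``outside`` controls the
        handling of positions beyond the grid extent: ``"error"`` raises,
        ``"zero"`` returns 0.
        """
        r = np.asarray(r, dtype=float)
        if r.shape[-1] != 3:
            raise ValueError("positions must have shape (..., 3)")
        scalar = r.ndim == 1
        pts = r.reshape(-1, 3)
        idx = (pts - np.asarray(self.origin)) / np.asarray(self.voxel_size)
        if outside == "error":
            nx, ny, nz = self.shape_xyz
            inb = (
                (idx[:, 0] >= 0) & (idx[:, 0] <= nx - 1)
                & (idx[:, 1] >= 0) & (idx[:, 1] <= ny - 1)
                & (idx[:, 2] >= 0) & (idx[:, 2] <= nz - 1)
            )
            if not inb.all():
                raise ValueError("position outside PSF stack extent")
        elif outside != "zero":
            raise ValueError(f"unknown outside mode {outside!r}")
        out = trilinear(self.intensities, idx)
        out = np.clip(out, 0.0, None)
        return float(out[0]) if scalar else out.reshape(r.shape[:-1])


def psf_value(stack: PSFStack, r: np.ndarray, outside: str = "error") -> np.ndarray:
    """Excitation intensity at world position(s) ``r`` by trilinear lookup."""
    return stack.value(r, outside=outside)


def build_synthetic_psf(
    geometry: BeamGeometry,
    voxel_size: tuple[float, float, float] = (10.0, 10.0, 10.0),
    extent: tuple[tuple[float, float], ...] | None = None,
    peak: float = 1.0,
) -> PSFStack:
    """Construct the three-Gaussian engineered PSF on a voxel grid.

    Each focus contributes ``peak * exp(-2 rho^2 / w_l^2 - 2 dz^2 / w_a^2)``
    where ``rho`` is the lateral distance to the focus center.  The default
    extent covers all three foci plus three lateral waists of margin.

    Deterministic for fixed inputs.
    """
    voxel_size = tuple(float(v) for v in voxel_size)
    if any(v <= 0 for v in voxel_size):
        raise ValueError("voxel size must be positive")
    centers = geometry.focus_centers()
    if extent is None:
        mlat = 3.0 * geometry.lateral_waist
        max_ax = (
            float(np.max(np.abs(np.asarray(geometry.axial_offsets))))
            + 3.0 * geometry.axial_waist
        )
        lim = float(np.max(np.abs(centers[:, :2]))) + mlat
        extent = ((-lim, lim), (-lim, lim), (-max_ax, max_ax))
    extent_arr = np.asarray(extent, dtype=float)
    if extent_arr.shape != (3, 2) or np.any(extent_arr[:, 1] <= extent_arr[:, 0]):
        raise ValueError("extent must give a positive span (lo, hi) per axis")
    ns = [int(np.floor((hi - lo) / v)) + 1 for (lo, hi), v in zip(extent_arr, voxel_size)]
    if any(n < 2 for n in ns):
        raise ValueError("grid extent too small for the requested voxel size")
    xs, ys, zs = (
        extent_arr[a, 0] + voxel_size[a] * np.arange(ns[a]) for a in range(3)
    )
    wl2 = geometry.lateral_waist**2
    wa2 = geometry.axial_waist**2
    out = np.zeros((len(zs), len(ys), len(xs)), dtype=np.float32)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    for iz, z in enumerate(zs):  # slice-wise to bound memory
        plane = np.zeros_like(yy)
        for cx, cy, cz in centers:
            plane += np.exp(
                -2.0 * ((xx - cx) ** 2 + (yy - cy) ** 2) / wl2
                - 2.0 * (z - cz) ** 2 / wa2
            )
        out[iz] = peak * plane
    return PSFStack(out, voxel_size, (float(xs[0]), float(ys[0]), float(zs[0])))


def load_psf_stack(
    path,
    voxel_size: tuple[float, float, float],
    origin: tuple[float, float, float] | None = None,
) -> PSFStack:
    """Load a PSF z-stack from a multi-page TIFF (one page per z-plane).

    Negative camera values are clipped to zero.  If ``origin`` is omitted the
    grid is centered on the world origin.
    """
    import tifffile

    arr = np.asarray(tifffile.imread(str(path)), dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("PSF stack must be a 3D image stack")
    if arr.shape[0] < 2:
        raise ValueError("PSF stack needs at least 2 z-planes to interpolate axially")
    arr = np.clip(arr, 0.0, None)
    if origin is None:
        nz, ny, nx = arr.shape
        dx, dy, dz = voxel_size
        origin = (-(nx - 1) * dx / 2.0, -(ny - 1) * dy / 2.0, -(nz - 1) * dz / 2.0)
    return PSFStack(arr, tuple(float(v) for v in voxel_size), tuple(map(float, origin)))


def save_psf_stack(stack: PSFStack, path) -> None:
    """Write a PSF stack as a multi-page TIFF (z-planes as pages)."""
    import tifffile

    tifffile.imwrite(
        str(path), np.asarray(stack.intensities, dtype=np.float32), photometric="minisblack"
    )


def save_psf_hdf5(stack: PSFStack, path) -> None:
    import h5py

    with h5py.File(str(path), "w") as f:
        d = f.create_dataset("psf/intensities", data=stack.intensities)
        d.attrs["voxel_size_nm"] = stack.voxel_size
        d.attrs["origin_nm"] = stack.origin


def load_psf_hdf5(path) -> PSFStack:
    import h5py

    with h5py.File(str(path), "r") as f:
        d = f["psf/intensities"]
        return PSFStack(d[...], tuple(d.attrs["voxel_size_nm"]), tuple(d.attrs["origin_nm"]))


def interpolate_psf(
    stack: PSFStack, target_voxel: tuple[float, float, float] = (10.0, 10.0, 10.0)
) -> PSFStack:
    """Resample a PSF stack to a finer voxel grid by separable cubic splines.

    Interpolation runs first along z, then in each xy plane.  The light field
    of a diffraction-limited excitation profile is smooth at the camera
    sampling scale, so spline interpolation preserves original samples and
    introduces no structure finer than the optics can produce.  Negative
    spline overshoot is clipped to zero.
    """
    target_voxel = tuple(float(v) for v in target_voxel)
    if any(t <= 0 for t in target_voxel):
        raise ValueError("target voxel size must be positive")
    if any(t > s + 1e-9 for t, s in zip(target_voxel, stack.voxel_size)):
        raise ValueError("target voxel size must not be coarser than the source")
    if target_voxel == tuple(stack.voxel_size):
        return PSFStack(stack.intensities.copy(), stack.voxel_size, stack.origin)
    x, y, z = stack.axes()
    nx_new = int(np.floor((x[-1] - x[0]) / target_voxel[0])) + 1
    ny_new = int(np.floor((y[-1] - y[0]) / target_voxel[1])) + 1
    nz_new = int(np.floor((z[-1] - z[0]) / target_voxel[2])) + 1
    xn = x[0] + target_voxel[0] * np.arange(nx_new)
    yn = y[0] + target_voxel[1] * np.arange(ny_new)
    zn = z[0] + target_voxel[2] * np.arange(nz_new)
    data = np.asarray(stack.intensities, dtype=float)
    # axis 0 of the array is z
    if len(z) >= 4:
        zi = CubicSpline(z, data, axis=0)(zn)
    else:
        from scipy.interpolate import interp1d

        zi = interp1d(z, data, axis=0, kind="linear")(zn)
    out = np.empty((nz_new, ny_new, nx_new), dtype=np.float32)
    for k in range(nz_new):
        ky = min(3, len(y) - 1)
        kx = min(3, len(x) - 1)
        out[k] = RectBivariateSpline(y, x, zi[k], kx=kx, ky=ky)(yn, xn)
    np.clip(out, 0.0, None, out=out)
    return PSFStack(out, target_voxel, (float(xn[0]), float(yn[0]), float(zn[0])))


# ---------------------------------------------------------------------------
# tracking pattern
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Slot:
    """One 20 us pulse slot: a beam offset or a blank repositioning slot."""

    offset: tuple[float, float, float]  # effective focus offset (nm), z = layer depth
    z_layer: int
    is_blank: bool
    t_start_us: float
    excitation_window_us: float = EXCITATION_WINDOW_US


def _default_layout_xy(lateral_span: float = 950.0) -> np.ndarray:
    """13-point per-plane xy layout: center + inner square + outer ring.

    The outer ring (8 points on the square of side ``lateral_span``) covers
    the full lateral reconstruction volume for fast reporters; the inner
    square corners form the slow-reporter MINFLUX-like unit.
    """
    h = lateral_span / 2.0  # 475
    q = lateral_span / 4.0  # 237.5
    return np.array(
        [
            (0.0, 0.0),
            (q, q), (-q, q), (-q, -q), (q, -q),
            (h, h), (0.0, h), (-h, h), (-h, 0.0),
            (-h, -h), (0.0, -h), (h, -h), (h, 0.0),
        ]
    )


def _serpentine(points: np.ndarray) -> np.ndarray:
    """Visit points row-by-row in y, alternating x direction (few large moves)."""
    pts = [tuple(p) for p in points]
    rows: dict[float, list[tuple[float, float]]] = {}
    for p in pts:
        rows.setdefault(round(p[1], 6), []).append(p)
    order = []
    for i, yv in enumerate(sorted(rows, reverse=True)):
        row = sorted(rows[yv], key=lambda p: p[0], reverse=bool(i % 2))
        order.extend(row)
    return np.array(order)


@dataclass(frozen=True)
class PatternConfig:
    lateral_span: float = 950.0
    axial_span: float = 1390.0
    layout_xy: np.ndarray | None = None  # overrides the default 13-point layout
    layer_order: tuple[int, int, int] = (0, 1, 2)
    serpentine: bool = True


@dataclass
class ShotSchedule:
    """Ordered 42-slot shot schedule: 3 z-layers x 13 shots + 3 blanks."""

    slots: list[Slot]
    slot_period_us: float = SLOT_PERIOD_US

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    @property
    def pattern_period_ms(self) -> float:
        return self.n_slots * self.slot_period_us * 1e-3

    @property
    def blank_mask(self) -> np.ndarray:
        return np.array([s.is_blank for s in self.slots])

    @property
    def illuminated(self) -> np.ndarray:
        return ~self.blank_mask

    @property
    def offsets(self) -> np.ndarray:
        """(n_slots, 3) effective focus offsets; blanks hold (0, 0, 0)."""
        return np.array([s.offset for s in self.slots])

    @property
    def z_layers(self) -> np.ndarray:
        return np.array([s.z_layer for s in self.slots])

    @property
    def t_start_us(self) -> np.ndarray:
        return np.array([s.t_start_us for s in self.slots])

    def to_frame(self) -> pd.DataFrame:
        off = self.offsets
        return pd.DataFrame(
            {
                "slot": np.arange(self.n_slots),
                "x_nm": off[:, 0],
                "y_nm": off[:, 1],
                "z_nm": off[:, 2],
                "z_layer": self.z_layers,
                "is_blank": self.blank_mask,
                "t_start_us": self.t_start_us,
            }
        )

    def to_table(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_tracking_pattern(
    config: PatternConfig | None = None,
    geometry: BeamGeometry | None = None,
) -> ShotSchedule:
    """Build the 42-slot tracking schedule.

    Each z-layer's 13 shots run contiguously (one axial layer is completed
    before moving to the next, minimizing axial moves); every layer change
    costs one blank slot while the beam is repositioned.
    """
    config = config or PatternConfig()
    geometry = geometry or BeamGeometry()
    xy = config.layout_xy
    if xy is None:
        xy = _default_layout_xy(config.lateral_span)
    xy = np.asarray(xy, dtype=float)
    if config.serpentine:
        xy = _serpentine(xy)
    axial = np.asarray(geometry.axial_offsets, dtype=float)
    half = np.array([config.lateral_span / 2, config.lateral_span / 2, config.axial_span / 2])
    slots: list[Slot] = []
    t = 0.0
    for layer in config.layer_order:
        zl = axial[layer]
        for x, y in xy:
            if np.any(np.abs(np.array([x, y, zl])) > half + 1e-9):
                raise ValueError("shot offset outside the reconstruction volume")
            slots.append(Slot((float(x), float(y), float(zl)), layer, False, t))
            t += SLOT_PERIOD_US
        # blank slot: beam move to the next z-layer
        slots.append(Slot((0.0, 0.0, 0.0), layer, True, t))
        t += SLOT_PERIOD_US
    return ShotSchedule(slots)


def shot_displacements(schedule: ShotSchedule, geometry: BeamGeometry) -> np.ndarray:
    """(n_slots, 3) whole-PSF displacement per slot, in nm.

    A shot places the selected z-layer's Gaussian at the slot's lateral
    offset: the whole engineered PSF is displaced laterally so the chosen
    perimeter focus lands at the target, while the aperture suppresses the
    other two foci (their tails at >1 um are negligible).  The axial offset of
    a shot is carried by the identity of the focus, not by a physical z move,
    so the displacement z-component is 0.
    """
    centers = geometry.focus_centers()
    off = schedule.offsets
    disp = np.zeros_like(off)
    for i, s in enumerate(schedule.slots):
        if s.is_blank:
            continue
        px, py, _ = centers[s.z_layer]
        disp[i] = (off[i, 0] - px, off[i, 1] - py, 0.0)
    return disp
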