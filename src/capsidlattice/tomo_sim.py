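"""Forward simulation of cryo-tomogram volumes from capsid lattice models.

Renders a structural template (Gaussian-blob hexamer/pentamer unit) at every
lattice site of a :class:`~capsidlattice.capsid_models.CapsidModel`, with
optional membrane shell and ribonucleoprotein (RNP) interior, then degrades
the volume with the missing-wedge Fourier mask of a limited tilt range and
additive white Gaussian noise.  Subtomograms are extracted at real-valued
positions by spline interpolation.

Axis conventions: volume arrays are indexed ``[z, y, x]``; positions are
``(x, y, z)`` vectors in voxels; the tomographic tilt axis is ``y`` and the
beam direction is ``z``, so the missing wedge opens around the ``kz`` axis.
Model space (nm) maps to volume space (Å) at 10 Å per nm.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy import ndimage

from ._geom import normalize
from .capsid_models import CapsidModel

NM_PER_ANGSTROM = 0.1
ANGSTROM_PER_NM = 10.0


class OutOfBoundsError(ValueError):
    """A site or extraction position does not fit inside the volume."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class DensityVolume:
    """3D scalar field with isotropic voxel size (Å) and voxel origin."""

    values: np.ndarray  # [z, y, x]
    voxel_size: float  # Å per voxel
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))  # voxels, (x,y,z)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def copy_with(self, values: np.ndarray) -> "DensityVolume":
        return DensityVolume(values, self.voxel_size, self.origin.copy())

    # -- MRC2014 I/O (mode 2, float32) ----------------------------------

    def write_mrc(self, path) -> None:
        grid = gemmi.FloatGrid(np.ascontiguousarray(self.values, dtype=np.float32))
        grid.spacegroup = gemmi.SpaceGroup("P1")
        nz, ny, nx = self.values.shape
        grid.set_unit_cell(gemmi.UnitCell(
            nz * self.voxel_size, ny * self.voxel_size, nx * self.voxel_size,
            90.0, 90.0, 90.0))
        m = gemmi.Ccp4Map()
        m.grid = grid
        m.update_ccp4_header()
        m.set_header_float(50, float(self.origin[0] * self.voxel_size))
        m.set_header_float(51, float(self.origin[1] * self.voxel_size))
        m.set_header_float(52, float(self.origin[2] * self.voxel_size))
        m.write_ccp4_map(str(path))

    @classmethod
    def read_mrc(cls, path) -> "DensityVolume":
        m = gemmi.read_ccp4_map(str(path))
        values = np.array(m.grid, copy=True)
        voxel = m.grid.unit_cell.a / m.grid.shape[0]
        origin = np.array([m.header_float(50), m.header_float(51),
                           m.header_float(52)]) / voxel
        return cls(values=values, voxel_size=float(voxel), origin=origin)


@dataclass
class ImagingParams:
    """Missing-wedge and noise model of a reconstructed tomogram."""

    tilt_axis: str = "y"
    tilt_range_deg: tuple[float, float] = (-60.0, 60.0)
    snr: float = 0.5
    blur_b_factor: float = 0.0  # Å^2 amplitude envelope (CTF-corrected data)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.tilt_range_deg
        if not (-90.0 <= lo < hi <= 90.0):
            raise ValueError("tilt range must satisfy -90 <= min < max <= 90")
        if self.tilt_axis not in ("x", "y"):
            raise ValueError("tilt axis must be 'x' or 'y'")


@dataclass
class StructureTemplate:
    """Small density template of a lattice unit, centred on its symmetry axis."""

    density: DensityVolume
    symmetry_order: int
    kind: str  # immature | mature | pentamer

    @property
    def values(self) -> np.ndarray:
        return self.density.values

    @property
    def radius_voxels(self) -> float:
        return max(self.density.shape) / 2.0


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

_TEMPLATE_ORDERS = {"immature": 6, "mature": 6, "pentamer": 5}

#: the centre of a volume of edge n sits on voxel index n // 2 on every axis
def volume_center(n: int) -> float:
    return float(n // 2)


def rotate_volume(values: np.ndarray, R: np.ndarray, order: int = 1) -> np.ndarray:
    """Rotate a cubic volume about its centre voxel by the (x,y,z) matrix R.

    A feature at position p (relative to the centre) moves to R p.
    """
    n = values.shape[0]
    c = np.full(3, volume_center(n))
    Rzyx = np.asarray(R, dtype=float)[::-1, ::-1]
    Minv = Rzyx.T  # orthonormal inverse
    offset = c - Minv @ c
    return ndimage.affine_transform(values, Minv, offset=offset,
                                    order=order, mode="constant", cval=0.0)


def _shear_fft(values: np.ndarray, shear_axis: int, coord_axis: int,
               amount: float) -> np.ndarray:
    """Shear a volume along one axis by an FFT phase ramp (band-limited exact).

    ``shear_axis`` coordinates are displaced by ``amount`` times the (centred)
    coordinate along ``coord_axis``.
    """
    n = values.shape[shear_axis]
    k = np.fft.fftfreq(n)
    c = volume_center(values.shape[coord_axis])
    coord = np.arange(values.shape[coord_axis]) - c
    shape_k = [1, 1, 1]
    shape_c = [1, 1, 1]
    shape_k[shear_axis] = n
    shape_c[coord_axis] = len(coord)
    phase = np.exp(-2j * np.pi * k.reshape(shape_k)
                   * (amount * coord).reshape(shape_c))
    ft = np.fft.fft(values, axis=shear_axis)
    return np.fft.ifft(ft * phase, axis=shear_axis).real


def rotate_z_exact(values: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotate about the z axis by FFT shears (plus exact 90-degree turns).

    For compact, band-limited content this is accurate to float rounding,
    and rotations compose exactly — which makes Cn symmetrization an
    idempotent projection.
    """
    quarter = int(np.round(angle_rad / (np.pi / 2)))
    residual = angle_rad - quarter * (np.pi / 2)
    out = values
    q = quarter % 4
    if q:
        # np.rot90 in the (y, x) plane turns by -90 deg per k about the
        # array centre (n-1)/2; k = -q realizes +90 q, and a one-voxel roll
        # moves the pivot to the centre-voxel convention n//2 (even n)
        out = np.rot90(out, k=(-q) % 4, axes=(1, 2))
        if values.shape[1] % 2 == 0:
            out = np.roll(out, (1 if q in (2, 3) else 0,
                                1 if q in (1, 2) else 0), axis=(1, 2))
    if abs(residual) > 1e-12:
        a = -np.tan(residual / 2.0)
        b = np.sin(residual)
        out = _shear_fft(out, 2, 1, a)   # x by y
        out = _shear_fft(out, 1, 2, b)   # y by x
        out = _shear_fft(out, 2, 1, a)
    return out


def symmetrize(values: np.ndarray, order: int, interp_order: int = 1) -> np.ndarray:
    """Average a volume over Cn rotations about its z axis (idempotent).

    Rotations use the exact FFT-shear method; the volume is zero-padded in
    x and y first so shear wrap-around cannot fold content back in.
    """
    nz, ny, nx = values.shape
    pad = max(4, ny // 2)
    padded = np.zeros((nz, ny + 2 * pad, nx + 2 * pad), dtype=np.float64)
    padded[:, pad:pad + ny, pad:pad + nx] = values
    # keep the centre convention: centre voxel moves from n//2 to n//2+pad,
    # which (ny + 2 pad)//2 equals exactly
    out = padded.copy()
    for j in range(1, order):
        out += rotate_z_exact(padded, 2 * np.pi * j / order)
    out /= order
    return out[:, pad:pad + ny, pad:pad + nx]


def _gaussian_blob(grid, center, sigma):
    zz, yy, xx = grid
    r2 = ((xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2)
    return np.exp(-r2 / (2.0 * sigma ** 2))


def make_template(kind: str, spacing: float = 10.0, voxel_size: float = 5.4,
                  box: int = 24) -> StructureTemplate:
    """Parametric Gaussian-blob template of a capsid lattice unit.

    ``spacing`` is the lattice constant in nm; the unit's protomer ring
    radius scales with it.  The immature unit has two radial (here: two z)
    protein layers, CA-NTD over CA-CTD, plus an inner six-helix bundle of
    rods 15 Å apart; the mature unit is a single CA layer; the pentamer is
    the five-fold analogue of the mature unit.  The returned density is
    exactly C(n)-symmetric about z by construction.
    """
    if kind not in _TEMPLATE_ORDERS:
        raise ValueError(f"unknown template kind {kind!r}")
    order = _TEMPLATE_ORDERS[kind]
    c = volume_center(box)
    ax = np.arange(box)
    grid = np.meshgrid(ax, ax, ax, indexing="ij")  # z, y, x

    # protomer ring; the pentamer packs more tightly around its symmetry
    # axis than the hexamer
    ring_frac = 0.26 if kind == "pentamer" else 0.32
    ring_radius_A = ring_frac * spacing * ANGSTROM_PER_NM
    ring_r = ring_radius_A / voxel_size
    sigma = max(1.1, 9.0 / voxel_size)
    vol = np.zeros((box, box, box), dtype=np.float64)

    def add_ring(z_off_vox, amplitude=1.0, radius=ring_r):
        for j in range(order):
            ang = 2 * np.pi * j / order
            cen = (c + radius * np.cos(ang), c + radius * np.sin(ang), c + z_off_vox)
            vol[...] += amplitude * _gaussian_blob(grid, cen, sigma)

    layer_A = 20.0 / voxel_size  # half-separation of the two Gag layers
    if kind == "immature":
        # the two Gag layers have different effective protomer-ring radii
        # (the NTD lattice is wider than the CTD lattice on the curved
        # shell, cf. their distinct hexamer spacings)
        add_ring(+layer_A, radius=1.18 * ring_r)  # CA-NTD layer (outward)
        add_ring(-layer_A, radius=0.82 * ring_r)  # CA-CTD layer
        # six-helix bundle: rods parallel to z, adjacent axes 15 Å apart
        rod_circle_r = (15.0 / (2.0 * np.sin(np.pi / 6.0))) / voxel_size
        rod_sigma = max(0.9, 4.0 / voxel_size)
        rod_lo = -layer_A - 23.0 / voxel_size
        for j in range(6):
            ang = 2 * np.pi * j / 6.0
            cx = c + rod_circle_r * np.cos(ang)
            cy = c + rod_circle_r * np.sin(ang)
            for zo in np.arange(rod_lo, -layer_A + 1e-9, 0.8):
                vol += 0.45 * _gaussian_blob(grid, (cx, cy, c + zo), rod_sigma)
    else:
        add_ring(0.0)

    # enforce exact Cn symmetry (sums of blobs are symmetric up to rounding)
    sym = symmetrize(vol, order, interp_order=3)
    sym /= sym.max()
    density = DensityVolume(sym.astype(np.float32), voxel_size)
    return StructureTemplate(density=density, symmetry_order=order, kind=kind)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_capsid(model: CapsidModel, template: StructureTemplate,
                  voxel_size: float | None = None,
                  box_shape: tuple[int, int, int] | int | None = None,
                  include_membrane: bool = False,
                  include_rnp: bool = False,
                  membrane_amplitude: float = 0.8,
                  rnp_amplitude: float = 0.3,
                  center_on: np.ndarray | None = None) -> DensityVolume:
    """Sum the oriented template over all lattice sites of a model.

    The model centroid is placed at the volume centre.  Each site's frame
    maps the template's +z (symmetry axis) onto the site's outward normal.
    Linear in template amplitude.  Raises :class:`OutOfBoundsError` listing
    the offending sites when the model does not fit with one template
    radius of margin.
    """
    if voxel_size is None:
        voxel_size = template.density.voxel_size
    centers_vox = model.centers * ANGSTROM_PER_NM / voxel_size
    centroid = (centers_vox.mean(axis=0) if center_on is None
                else np.asarray(center_on, dtype=float)
                * ANGSTROM_PER_NM / voxel_size)
    tbox = template.density.shape[0]
    margin = tbox / 2.0
    if box_shape is None:
        extent = 2.0 * (np.abs(centers_vox - centroid).max() + margin + 2)
        n = int(np.ceil(extent / 2.0) * 2)
        box_shape = (n, n, n)
    elif np.isscalar(box_shape):
        box_shape = (int(box_shape),) * 3
    shape = tuple(int(s) for s in box_shape)
    half = np.array([shape[2], shape[1], shape[0]]) / 2.0  # (x, y, z)
    pos = centers_vox - centroid + half  # (x, y, z) voxel positions

    lo_ok = (pos - margin >= 0).all(axis=1)
    hi_ok = (pos[:, 0] + margin <= shape[2]) & (pos[:, 1] + margin <= shape[1]) \
        & (pos[:, 2] + margin <= shape[0])
    bad = np.where(~(lo_ok & hi_ok))[0]
    if len(bad):
        raise OutOfBoundsError(
            f"sites {bad.tolist()} do not fit in box {shape} with margin {margin:.0f}"
        )

    out = np.zeros(shape, dtype=np.float64)
    tmpl = template.values.astype(np.float64)
    tc = volume_center(tbox)
    pad = 2
    n_out = tbox + 2 * pad
    for i in range(model.n_sites):
        R = model.orientations[i]  # columns: site x, y, z axes in world coords
        base = np.floor(pos[i]).astype(int)
        frac = pos[i] - base  # (x, y, z)
        # world voxel w -> template voxel t = R^T (w - site_pos) + tc.
        # The output subbox starts at world voxel base - tc - pad (per axis),
        # so for output index j: w - site_pos = j - (tc + pad + frac).
        Rzyx_T = R.T[::-1, ::-1]  # R^T re-indexed from (x,y,z) to (z,y,x)
        shift = np.full(3, tc + pad) + frac[::-1]
        offset_zyx = np.full(3, tc) - Rzyx_T @ shift
        rotated = ndimage.affine_transform(
            tmpl, Rzyx_T, offset=offset_zyx, output_shape=(n_out,) * 3,
            order=1, mode="constant", cval=0.0)
        z0, y0, x0 = (base[2] - int(tc) - pad, base[1] - int(tc) - pad,
                      base[0] - int(tc) - pad)
        zs, ys, xs = (slice(max(z0, 0), min(z0 + n_out, shape[0])),
                      slice(max(y0, 0), min(y0 + n_out, shape[1])),
                      slice(max(x0, 0), min(x0 + n_out, shape[2])))
        ts = tuple(slice(s.start - o, s.stop - o)
                   for s, o in zip((zs, ys, xs), (z0, y0, x0)))
        out[zs, ys, xs] += rotated[ts]

    if include_membrane and model.membrane_radius is not None:
        out += membrane_amplitude * _spherical_shell(
            shape, half, model.membrane_radius * ANGSTROM_PER_NM / voxel_size,
            thickness=40.0 / voxel_size / 2.355)
    if include_rnp:
        radial = np.linalg.norm(model.centers - model.centers.mean(axis=0), axis=1)
        rnp_r = max(radial.min() * ANGSTROM_PER_NM / voxel_size - margin, 3.0)
        out += rnp_amplitude * _filled_ball(shape, half, rnp_r)
    return DensityVolume(out.astype(np.float32), voxel_size)


def _radius_grid(shape, center_xyz):
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    return np.sqrt((xx - center_xyz[0]) ** 2 + (yy - center_xyz[1]) ** 2
                   + (zz - center_xyz[2]) ** 2)


def _spherical_shell(shape, center_xyz, radius, thickness):
    r = _radius_grid(shape, center_xyz)
    return np.exp(-((r - radius) ** 2) / (2.0 * thickness ** 2))


def _filled_ball(shape, center_xyz, radius):
    r = _radius_grid(shape, center_xyz)
    return 1.0 / (1.0 + np.exp((r - radius) / 1.5))


# ---------------------------------------------------------------------------
# Degradation
# ---------------------------------------------------------------------------


def wedge_mask(shape: tuple[int, ...], params: ImagingParams) -> np.ndarray:
    """Boolean Fourier mask of the tilt-accessible region (numpy fft layout).

    A Fourier point is sampled when its in-plane angle in the plane normal
    to the tilt axis lies inside the tilt range (Friedel-symmetrized).
    """
    freqs = [np.fft.fftfreq(s) for s in shape]  # z, y, x
    kz, ky, kx = np.meshgrid(*freqs, indexing="ij")
    trans = kx if params.tilt_axis == "y" else ky
    phi = np.degrees(np.arctan2(np.abs(kz), np.abs(trans)))
    lo, hi = params.tilt_range_deg
    lim = max(abs(lo), abs(hi))
    return phi <= lim + 1e-9


def apply_missing_wedge(vol: DensityVolume, params: ImagingParams) -> DensityVolume:
    """Zero all Fourier coefficients outside the tilt-accessible region."""
    mask = wedge_mask(vol.shape, params)
    if mask.all():  # full tilt range: exact identity
        return vol.copy_with(vol.values.copy())
    ft = np.fft.fftn(vol.values.astype(np.float64))
    out = np.fft.ifftn(ft * mask).real
    return vol.copy_with(out.astype(np.float32))


def add_noise(vol: DensityVolume, snr: float, mask: np.ndarray | None = None,
              seed: int = 0) -> DensityVolume:
    """Additive white Gaussian noise at a target in-mask variance ratio.

    ``snr`` is signal variance over noise variance measured inside ``mask``
    (whole volume when None); ``snr=inf`` returns the input unchanged.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return vol.copy_with(vol.values.copy())
    sel = np.ones(vol.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    if not sel.any():
        raise ValueError("mask is empty")
    sig_var = float(vol.values[sel].var())
    if sig_var == 0:
        raise ValueError("signal variance inside mask is zero")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(sig_var / snr), size=vol.shape)
    return vol.copy_with((vol.values + noise).astype(np.float32))


# ---------------------------------------------------------------------------
# Subtomogram extraction
# ---------------------------------------------------------------------------


@dataclass
class SubtomogramSet:
    """Extracted boxes plus the shared wedge descriptor of their tomogram."""

    boxes: np.ndarray  # (N, box, box, box), [z, y, x]
    positions: np.ndarray  # (N, 3) extraction centres, voxels (x, y, z)
    voxel_size: float
    wedge: ImagingParams | None = None

    @property
    def n(self) -> int:
        return len(self.boxes)

    @property
    def box(self) -> int:
        return self.boxes.shape[1]

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        for i, b in enumerate(self.boxes):
            DensityVolume(b, self.voxel_size).write_mrc(
                os.path.join(directory, f"subtomo_{i:05d}.mrc"))
        table = pd.DataFrame(self.positions, columns=["x", "y", "z"])
        if self.wedge is not None:
            table["tilt_min"] = self.wedge.tilt_range_deg[0]
            table["tilt_max"] = self.wedge.tilt_range_deg[1]
        table.to_csv(os.path.join(directory, "positions.tsv"), sep="\t", index=False)

    @classmethod
    def load(cls, directory) -> "SubtomogramSet":
        table = pd.read_csv(os.path.join(directory, "positions.tsv"), sep="\t")
        boxes, voxel = [], None
        for i in range(len(table)):
            dv = DensityVolume.read_mrc(
                os.path.join(directory, f"subtomo_{i:05d}.mrc"))
            boxes.append(dv.values)
            voxel = dv.voxel_size
        wedge = None
        if "tilt_min" in table:
            wedge = ImagingParams(tilt_range_deg=(float(table["tilt_min"][0]),
                                                  float(table["tilt_max"][0])))
        return cls(boxes=np.asarray(boxes),
                   positions=table[["x", "y", "z"]].to_numpy(dtype=float),
                   voxel_size=voxel, wedge=wedge)


def extract_subtomograms(vol: DensityVolume, positions, box: int,
                         wedge: ImagingParams | None = None) -> SubtomogramSet:
    """One cubic box per position; integer positions are exact voxel copies.

    Positions are (x, y, z) voxel coordinates of the box centre (the centre
    falls on voxel index box // 2, matching the render/template convention).
    Real-valued positions use cubic-spline interpolation.  Positions without
    a half-box margin raise an error naming the offending index.
    """
    if box % 2 != 0:
        raise ValueError("box size must be even")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    half = box // 2
    shape_xyz = np.array([vol.shape[2], vol.shape[1], vol.shape[0]])
    for i, p in enumerate(positions):
        if np.any(p - half < -1e-9) or np.any(p + half > shape_xyz + 1e-9):
            raise ValueError(f"position {i} at {p} lacks a half-box margin")
    offs = np.arange(box) - half
    boxes = np.empty((len(positions), box, box, box), dtype=np.float32)
    for i, p in enumerate(positions):
        if np.allclose(p, np.round(p), atol=1e-9):
            x0, y0, z0 = (int(round(v)) - half for v in p)
            boxes[i] = vol.values[z0:z0 + box, y0:y0 + box, x0:x0 + box]
        else:
            zz, yy, xx = np.meshgrid(p[2] + offs, p[1] + offs, p[0] + offs,
                                     indexing="ij")
            boxes[i] = ndimage.map_coordinates(
                vol.values, [zz, yy, xx], order=3, mode="constant", cval=0.0)
    return SubtomogramSet(boxes=boxes, positions=positions,
                          voxel_size=vol.voxel_size, wedge=wedge)
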