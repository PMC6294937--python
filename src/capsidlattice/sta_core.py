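"""Subtomogram alignment, averaging, and map post-processing.

Implements the reference-free hierarchical alignment workflow used for
retroviral lattice analysis: particles seeded on a spherical or picked
surface, constrained cross-correlation (CCC) scoring restricted to the
tilt-sampled Fourier region, iterative angular/translational grid search
with symmetrized half-set references and an adaptive low-pass filter,
duplicate and low-CCC filtering, wedge-compensated Fourier averaging,
gold-standard Fourier shell correlation with phase-randomization
correction, and Guinier B-factor sharpening.

Orientation convention: a particle's ``orientation`` matrix R maps the
reference frame into the particle frame, i.e. the subtomogram is modelled
as wedge(shift(rotate_R(reference))).  Unit quaternions/matrices are used
internally; ZYZ intrinsic Euler angles (degrees) at all I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd
from scipy import ndimage

from ._geom import (
    euler_zyz_from_matrix,
    fibonacci_sphere,
    frame_from_z,
    matrix_from_euler_zyz,
    normalize,
    rotation_angle,
)
from .tomo_sim import (
    DensityVolume,
    ImagingParams,
    SubtomogramSet,
    rotate_volume,
    symmetrize,
    wedge_mask,
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Particle:
    """One lattice subunit hypothesis: pose, score, bookkeeping."""

    position: np.ndarray  # (3,) voxels (x, y, z), real-valued
    orientation: np.ndarray  # (3, 3) reference->particle rotation
    ccc: float = 0.0
    half_set: int = 1
    virus_id: str = "v0"
    flags: set = field(default_factory=set)
    source_index: int | None = None  # index of the extracted box, if known

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)

    @property
    def retained(self) -> bool:
        return not self.flags


@dataclass
class AlignmentConfig:
    """Hierarchical alignment schedule.

    Defaults follow the standard coarse-to-fine recipe: start at coarse
    binning with a 40-Å low-pass filter, then finer binning with an
    adaptive low-pass (the frequency where the current half-map FSC drops
    below 0.5, floored at the previous filter) and a decreasing angular
    search range.
    """

    binning_schedule: tuple[int, ...] = (4, 2, 1)
    iterations_per_bin: tuple[int, ...] = (3, 3, 2)
    lowpass_A: float = 40.0  # initial low-pass, Å
    angular_range_deg: tuple[float, ...] = (24.0, 12.0, 6.0)
    angular_step_deg: tuple[float, ...] = (12.0, 6.0, 3.0)
    symmetry_order: int = 6
    mask_kind: str = "sphere"  # sphere | cylinder
    mask_radius_frac: float = 0.45  # soft mask radius / box
    mask_z_half_frac: float = 0.30  # cylinder half-height / box
    duplicate_min_dist: float | None = None  # voxels; default 0.5 x spacing
    ccc_keep_fraction: float = 0.9
    adaptive_lowpass: bool = True
    max_shift_frac: float = 0.35  # translational search radius / box
    full_inplane_first: bool = True  # search the whole symmetry wedge at level 0
    asym_iterations: int = 0  # level-0 iterations with no symmetry applied
    # (reference-free starts need unsymmetrized references so azimuthal
    # contrast can emerge before Cn symmetrization is switched on)

    def __post_init__(self) -> None:
        n = len(self.binning_schedule)
        if not (len(self.iterations_per_bin) == len(self.angular_range_deg)
                == len(self.angular_step_deg) == n):
            raise ValueError("schedule lists must have equal lengths")
        if any(a < b for a, b in zip(self.angular_range_deg,
                                     self.angular_range_deg[1:])):
            pass  # non-increasing ranges are the norm; increasing allowed but odd


@dataclass
class FscCurve:
    """Per-shell correlation between two half maps."""

    shell_freq: np.ndarray  # 1/Å, strictly increasing
    fsc: np.ndarray
    corrected_fsc: np.ndarray | None = None
    randomization_freq: float | None = None

    def resolution_at(self, threshold: float = 0.143) -> float:
        """1/frequency (Å) where the corrected (or raw) curve first crosses."""
        curve = self.corrected_fsc if self.corrected_fsc is not None else self.fsc
        f, c = self.shell_freq, np.asarray(curve)
        for i in range(1, len(f)):
            if c[i] < threshold <= c[i - 1]:
                # linear interpolation inside the crossing shell
                t = (c[i - 1] - threshold) / (c[i - 1] - c[i])
                freq = f[i - 1] + t * (f[i] - f[i - 1])
                return float(1.0 / freq)
        return float(1.0 / f[-1])  # better than Nyquist

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"freq_invA": self.shell_freq, "fsc": self.fsc})
        if self.corrected_fsc is not None:
            df["corrected_fsc"] = self.corrected_fsc
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


def seed_on_sphere(center, radius: float, oversample_spacing: float,
                   seed: int = 0) -> list[Particle]:
    """Quasi-uniform oversampled seeds on a sphere, z along the radial.

    The count follows the area argument n = 4 pi r^2 / spacing^2; in-plane
    angles are randomized (seeded) so the lattice direction is unbiased.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    n = max(1, int(round(4.0 * np.pi * radius ** 2 / oversample_spacing ** 2)))
    rng = np.random.default_rng(seed)
    dirs = fibonacci_sphere(n)
    particles = []
    for d in dirs:
        R = frame_from_z(d)
        a = rng.uniform(0, 2 * np.pi)
        Rz = np.array([[np.cos(a), -np.sin(a), 0],
                       [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        particles.append(Particle(position=center + radius * d, orientation=R @ Rz))
    return particles


def seed_on_density_peaks(vol: DensityVolume, center, radius: float,
                          spacing: float, lowpass_A: float = 40.0,
                          shell_half_width: float | None = None,
                          seed: int = 0) -> list[Particle]:
    """Template-free picking: local density maxima on a spherical shell.

    The volume is low-pass filtered, sampled on a dense quasi-uniform shell
    around the expected capsid radius (several radii within
    ``shell_half_width``), and greedy non-maximum suppression at
    0.7 x spacing keeps one seed per putative lattice unit.  Orientations:
    z along the outward radial, in-plane angle randomized (seeded).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    if shell_half_width is None:
        shell_half_width = 0.25 * spacing
    lp_frac = min(1.0, 2.0 * vol.voxel_size / lowpass_A)
    ft = np.fft.fftn(vol.values.astype(np.float64))
    smooth = np.fft.ifftn(ft * _lowpass_mask(vol.shape, lp_frac)).real

    n_dense = max(64, int(round(4.0 * np.pi * radius ** 2
                                / (0.45 * spacing) ** 2)))
    dirs = fibonacci_sphere(n_dense)
    radii = radius + np.linspace(-shell_half_width, shell_half_width, 3)
    cand_pos, cand_val = [], []
    shape_xyz = np.array([vol.shape[2], vol.shape[1], vol.shape[0]])
    for r in radii:
        pts = center + r * dirs
        inside = np.all(pts >= 1, axis=1) & np.all(pts <= shape_xyz - 2, axis=1)
        pts = pts[inside]
        vals = ndimage.map_coordinates(smooth, [pts[:, 2], pts[:, 1],
                                                pts[:, 0]], order=1)
        cand_pos.append(pts)
        cand_val.append(vals)
    cand_pos = np.vstack(cand_pos)
    cand_val = np.concatenate(cand_val)

    order = np.argsort(-cand_val, kind="stable")
    kept: list[int] = []
    min_d = 0.7 * spacing
    for i in order:
        p = cand_pos[i]
        if all(np.linalg.norm(p - cand_pos[j]) >= min_d for j in kept):
            kept.append(int(i))
    rng = np.random.default_rng(seed)
    particles = []
    for i in kept:
        d = normalize(cand_pos[i] - center)
        a = rng.uniform(0, 2 * np.pi)
        Rz = np.array([[np.cos(a), -np.sin(a), 0],
                       [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        particles.append(Particle(position=cand_pos[i],
                                  orientation=frame_from_z(d) @ Rz))
    return particles


def seed_on_surface(surface_points, spacing: float, seed: int = 0) -> list[Particle]:
    """Seeds on a smooth surface interpolated through manual picks.

    Star-shaped pick sets are fit as a sphere plus a smooth radial offset
    field (RBF over unit directions); near-planar pick sets fall back to a
    plane fit.  Seeds honour the requested spacing; z follows the local
    surface normal.
    """
    pts = np.atleast_2d(np.asarray(surface_points, dtype=float))
    if len(pts) < 4:
        raise ValueError("need at least 4 surface picks")
    centred = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centred, compute_uv=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise ValueError("surface picks are collinear")

    if svals[2] < 0.05 * svals[1]:  # effectively planar picks
        _, _, vt = np.linalg.svd(centred)
        e1, e2, nrm = vt[0], vt[1], vt[2]
        uv = centred @ np.column_stack([e1, e2])
        umin, vmin = uv.min(axis=0) - spacing / 2
        umax, vmax = uv.max(axis=0) + spacing / 2
        particles = []
        vstep = spacing * np.sqrt(3) / 2
        row = 0
        v = vmin
        while v <= vmax:
            u = umin + (spacing / 2 if row % 2 else 0.0)
            while u <= umax:
                p = pts.mean(axis=0) + u * e1 + v * e2
                particles.append(Particle(position=p, orientation=frame_from_z(nrm)))
                u += spacing
            v += vstep
            row += 1
        return particles

    # sphere + radial offset fit
    centre, r0 = _fit_sphere(pts)
    dirs = normalize(pts - centre)
    radii = np.linalg.norm(pts - centre, axis=1)
    from scipy.interpolate import RBFInterpolator
    rbf = RBFInterpolator(dirs, radii - r0, kernel="thin_plate_spline",
                          smoothing=1e-6)
    n = max(1, int(round(4.0 * np.pi * r0 ** 2 / spacing ** 2)))
    seed_dirs = fibonacci_sphere(n)
    offs = rbf(seed_dirs)
    rng = np.random.default_rng(seed)
    particles = []
    eps = 1e-3
    for d, off in zip(seed_dirs, offs):
        r = r0 + float(off)
        # numeric surface normal from the local radius gradient
        t1 = normalize(np.cross(d, [0.912, 0.315, 0.261]))
        t2 = np.cross(d, t1)
        dr1 = float(rbf(normalize(d + eps * t1)[None])[0] - off) / eps
        dr2 = float(rbf(normalize(d + eps * t2)[None])[0] - off) / eps
        nrm = normalize(d - (dr1 / r) * t1 - (dr2 / r) * t2)
        a = rng.uniform(0, 2 * np.pi)
        Rz = np.array([[np.cos(a), -np.sin(a), 0],
                       [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        particles.append(Particle(position=centre + r * d,
                                  orientation=frame_from_z(nrm) @ Rz))
    return particles


def _fit_sphere(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere fit."""
    A = np.column_stack([2 * pts, np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:3]
    r = np.sqrt(sol[3] + centre @ centre)
    return centre, float(r)


# ---------------------------------------------------------------------------
# Masks and scoring
# ---------------------------------------------------------------------------


def soft_spherical_mask(box: int, radius: float, soft_edge: float = 3.0) -> np.ndarray:
    ax = np.arange(box)
    c = box // 2
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt((xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2)
    m = np.clip((radius + soft_edge - r) / soft_edge, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * m)


def soft_cylindrical_mask(box: int, radius: float, z_half: float,
                          soft_edge: float = 3.0) -> np.ndarray:
    """Soft cylinder about z: excludes membrane above / RNP below the lattice."""
    ax = np.arange(box)
    c = box // 2
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt((xx - c) ** 2 + (yy - c) ** 2)
    mr = np.clip((radius + soft_edge - r) / soft_edge, 0.0, 1.0)
    mz = np.clip((z_half + soft_edge - np.abs(zz - c)) / soft_edge, 0.0, 1.0)
    m = mr * mz
    return 0.5 - 0.5 * np.cos(np.pi * m)


def _lowpass_mask(shape, frac: float | None) -> np.ndarray:
    """Boolean mask of |k| <= frac * Nyquist (frac in (0, 1])."""
    freqs = [np.fft.fftfreq(s) for s in shape]
    kz, ky, kx = np.meshgrid(*freqs, indexing="ij")
    k = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
    if frac is None:
        return np.ones(shape, dtype=bool)
    return k <= 0.5 * frac + 1e-12


def score_ccc(subtomo: np.ndarray, reference: np.ndarray,
              orientation: np.ndarray | None = None,
              shift: np.ndarray | None = None,
              mask: np.ndarray | None = None,
              wedge: ImagingParams | None = None,
              lowpass_frac: float | None = None) -> float:
    """Constrained cross-correlation inside the sampled Fourier region.

    The reference is brought into the particle frame (rotated by
    ``orientation`` and shifted), both volumes are soft-masked in real
    space, and the normalized correlation is computed over Fourier
    components inside (wedge mask ∩ low-pass band), excluding DC — which
    makes the score invariant to additive offset and positive scaling.
    """
    a = np.asarray(subtomo, dtype=np.float64)
    b = np.asarray(reference, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shapes must match")
    if orientation is not None and not np.allclose(orientation, np.eye(3)):
        b = rotate_volume(b, orientation, order=1)
    if shift is not None and np.any(np.asarray(shift) != 0):
        b = ndimage.shift(b, np.asarray(shift, dtype=float)[::-1], order=1)
    if mask is not None:
        a = a * mask
        b = b * mask
    region = _lowpass_mask(a.shape, lowpass_frac)
    if wedge is not None:
        region = region & wedge_mask(a.shape, wedge)
    region = region.copy()
    region[0, 0, 0] = False  # exclude DC: offset invariance
    if not region.any():
        raise ValueError("empty Fourier region")
    fa = np.fft.fftn(a)[region]
    fb = np.fft.fftn(b)[region]
    num = float(np.real(np.vdot(fa, fb)))
    den = float(np.linalg.norm(fa) * np.linalg.norm(fb))
    if den == 0:
        return 0.0
    return float(np.clip(num / den, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Averaging
# ---------------------------------------------------------------------------


def average_particles(subtomos: SubtomogramSet, particles: list[Particle],
                      symmetry_order: int = 1,
                      coverage_floor: float = 0.2) -> tuple[DensityVolume, float]:
    """Wedge-compensated Fourier-space average of retained particles.

    Each box is shifted and rotated back into the reference frame; its
    missing-wedge mask is rotated alongside.  The average divides the
    coefficient sum by the per-voxel wedge occupancy (floored), zero-fills
    voxels with no coverage, applies Cn symmetry about z, and reports the
    covered-voxel fraction.
    """
    kept = [p for p in particles if p.retained]
    if not kept:
        raise ValueError("no retained particles to average")
    box = subtomos.box
    num = np.zeros((box, box, box), dtype=np.complex128)
    wsum = np.zeros((box, box, box), dtype=np.float64)
    base_wedge = (wedge_mask((box, box, box), subtomos.wedge)
                  if subtomos.wedge is not None else np.ones((box,) * 3, bool))
    freqs = np.fft.fftfreq(box)
    kz, ky, kx = np.meshgrid(freqs, freqs, freqs, indexing="ij")
    kvec = np.stack([kx, ky, kz])  # (3, ...) in (x, y, z)

    for p in kept:
        idx = _nearest_box_index(subtomos, p)
        vol = subtomos.boxes[idx].astype(np.float64)
        shift = p.position - subtomos.positions[idx]
        if np.any(np.abs(shift) > 1e-9):
            vol = ndimage.shift(vol, -shift[::-1], order=1, mode="constant")
        aligned = rotate_volume(vol, p.orientation.T, order=1)
        num += np.fft.fftn(aligned)
        if subtomos.wedge is not None:
            # F_aligned(k) = F_box(R k): the box's wedge support, rotated
            rk = np.einsum("ij,j...->i...", p.orientation, kvec)
            w = _wedge_at(rk, subtomos.wedge)
        else:
            w = base_wedge
        wsum += w
    covered = wsum >= coverage_floor
    avg = np.zeros_like(num)
    avg[covered] = num[covered] / wsum[covered]
    out = np.fft.ifftn(avg).real
    if symmetry_order > 1:
        out = symmetrize(out, symmetry_order)
    coverage = float(covered.mean())
    return DensityVolume(out.astype(np.float32), subtomos.voxel_size), coverage


def _wedge_at(kvec_xyz: np.ndarray, params: ImagingParams) -> np.ndarray:
    kx, ky, kz = kvec_xyz
    trans = kx if params.tilt_axis == "y" else ky
    phi = np.degrees(np.arctan2(np.abs(kz), np.abs(trans)))
    lim = max(abs(params.tilt_range_deg[0]), abs(params.tilt_range_deg[1]))
    return (phi <= lim + 1e-9).astype(float)


def _nearest_box_index(subtomos: SubtomogramSet, p: Particle) -> int:
    if p.source_index is not None:
        return int(p.source_index)
    d = np.linalg.norm(subtomos.positions - p.position, axis=1)
    return int(np.argmin(d))


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def _angular_grid(range_deg: float, step_deg: float,
                  inplane_range_deg: float | None = None,
                  inplane_step_deg: float | None = None) -> list[np.ndarray]:
    """Cone + in-plane rotation offsets around identity.

    The local z axis is tipped by beta <= range_deg in azimuthal directions
    alpha (cone search, Rz(a) Ry(b) Rz(-a)), combined with an in-plane spin
    Rz(g) with |g| <= inplane_range_deg.  The grid is sorted by total
    rotation magnitude; ties in correlation break toward the smaller
    rotation because the scan requires strict improvement.
    """
    if inplane_range_deg is None:
        inplane_range_deg = range_deg
    if inplane_step_deg is None:
        inplane_step_deg = step_deg
    betas = np.arange(0.0, range_deg + 1e-9, step_deg)
    gammas = np.arange(-inplane_range_deg, inplane_range_deg + 1e-9,
                       inplane_step_deg)
    if not len(gammas):
        gammas = np.array([0.0])
    rots = []
    for b in betas:
        if b == 0:
            alphas = [0.0]
        else:
            n_az = max(6, int(round(2 * np.pi * np.sin(np.deg2rad(b))
                                    / np.deg2rad(step_deg))))
            alphas = np.arange(n_az) * 360.0 / n_az
        for a in alphas:
            cone = matrix_from_euler_zyz(np.array([a, b, -a]))
            for g in gammas:
                cg, sg = np.cos(np.deg2rad(g)), np.sin(np.deg2rad(g))
                spin = np.array([[cg, -sg, 0.0], [sg, cg, 0.0], [0.0, 0.0, 1.0]])
                rots.append(cone @ spin)
    mags = [rotation_angle(R) for R in rots]
    order = np.argsort(mags, kind="stable")
    out, seen = [], []
    for i in order:
        R = rots[i]
        if any(rotation_angle(R.T @ S) < 1e-6 for S in seen[-80:]):
            continue
        seen.append(R)
        out.append(R)
    return out


def _quadratic_peak(cc: np.ndarray, peak: tuple[int, int, int]) -> np.ndarray:
    """Sub-voxel 3D peak position by separable quadratic interpolation."""
    out = np.array(peak, dtype=float)
    for ax in range(3):
        idx = list(peak)
        vals = []
        for d in (-1, 0, 1):
            idx[ax] = (peak[ax] + d) % cc.shape[ax]
            vals.append(cc[tuple(idx)])
        denom = vals[0] - 2 * vals[1] + vals[2]
        if abs(denom) > 1e-12:
            out[ax] += 0.5 * (vals[0] - vals[2]) / denom
    return out


def align_to_reference(box: np.ndarray, reference: np.ndarray,
                       current: np.ndarray,
                       grid: list[np.ndarray],
                       mask: np.ndarray | None,
                       wedge: ImagingParams | None,
                       lowpass_frac: float | None,
                       max_shift: float,
                       box_mask: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Grid-search the best (rotation, shift) of the reference into a box.

    ``mask`` is a reference-frame soft mask (z = lattice normal); it is
    applied to the reference before each trial rotation so it travels with
    the pose.  ``box_mask`` is an optional loose mask applied to the
    subtomogram itself.  Returns (orientation, shift in voxels (x, y, z),
    ccc at the optimum).
    """
    n = box.shape[0]
    region = _lowpass_mask(box.shape, lowpass_frac)
    if wedge is not None:
        region = region & wedge_mask(box.shape, wedge)
    region = region.copy()
    region[0, 0, 0] = False

    # Matched-filter translation search: the soft mask travels with the
    # (rotated) reference; the subtomogram itself is left unmasked so no
    # centred envelope biases the peak toward zero shift, and the
    # normalization is global (shift-independent), so placements where the
    # masked reference overlaps real lattice energy win.
    box_f = np.fft.ifftn(np.fft.fftn(box) * region).real
    m = np.ones_like(box) if mask is None else mask
    W = float(m.sum())
    fbx = np.fft.fftn(box_f)
    box_norm = float(np.linalg.norm(
        box_f * np.sqrt(np.clip(m.mean(), 1e-6, None))))
    if box_norm == 0:  # featureless box: no signal in the sampled band
        return current, np.zeros(3), 0.0

    best = (None, None, -np.inf)
    for dR in grid:
        R = current @ dR
        ref_rot = rotate_volume(reference, R, order=1)
        mu_ref = float((ref_rot * m).sum() / W)
        r_hat = m * (ref_rot - mu_ref)
        r_f = np.fft.ifftn(np.fft.fftn(r_hat) * region).real
        r_norm = float(np.linalg.norm(r_f))
        if r_norm == 0:
            continue
        num = np.fft.ifftn(fbx * np.conj(np.fft.fftn(r_f))).real
        cc = num / (box_norm * r_norm)
        peak_flat = int(np.argmax(cc))
        pk = np.unravel_index(peak_flat, cc.shape)
        # shifts are cyclic; re-centre around zero
        shift_zyx = _quadratic_peak(cc, pk)
        shift_zyx = (shift_zyx + n / 2) % n - n / 2
        if np.linalg.norm(shift_zyx) > max_shift:
            shift_zyx = np.zeros(3)
            score = float(cc[0, 0, 0])
        else:
            score = float(cc[pk])
        if score > best[2] + 1e-12:
            best = (R, shift_zyx[::-1].copy(), score)
    R, shift_xyz, score = best
    return R, shift_xyz, float(np.clip(score, -1.0, 1.0))


def _bin_volume(values: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return values
    n = values.shape[0] - values.shape[0] % factor
    v = values[:n, :n, :n]
    s = n // factor
    return v.reshape(s, factor, s, factor, s, factor).mean(axis=(1, 3, 5))


def assign_half_sets(particles: list[Particle]) -> None:
    """Deterministic even/odd split within each virus."""
    counters: dict[str, int] = {}
    for p in particles:
        k = counters.get(p.virus_id, 0)
        p.half_set = 1 + (k % 2)
        counters[p.virus_id] = k + 1


def align_particles(subtomos: SubtomogramSet, reference: DensityVolume | None,
                    particles: list[Particle], config: AlignmentConfig,
                    seed: int = 0,
                    verbose: bool = False) -> tuple[list[Particle], DensityVolume]:
    """Hierarchical iterative alignment with symmetrized half-set references.

    Per binning level, the configured number of iterations of (angular grid
    search around the current orientation, translational search by
    correlation peak with sub-voxel quadratic interpolation); after each
    iteration the reference of each half set is replaced by the symmetrized
    average of its particles.  The reference starts from the average at
    seeded poses when ``reference`` is None (reference-free).
    """
    if not particles:
        raise ValueError("empty particle list")
    if reference is not None and not np.all(np.isfinite(reference.values)):
        raise ValueError("non-finite reference")
    particles = [replace(p, position=p.position.copy(),
                         orientation=p.orientation.copy(),
                         flags=set(p.flags)) for p in particles]
    if (len(particles) == subtomos.n
            and all(p.source_index is None for p in particles)):
        for i, p in enumerate(particles):
            p.source_index = i
    assign_half_sets(particles)
    box0 = subtomos.box
    voxel0 = subtomos.voxel_size

    prev_lowpass_frac = None
    for level, binning in enumerate(config.binning_schedule):
        factor = int(binning)  # binning is absolute w.r.t. the given boxes
        binned_boxes = np.asarray([_bin_volume(b, factor) for b in subtomos.boxes])
        level_set = SubtomogramSet(
            boxes=binned_boxes, positions=subtomos.positions / factor,
            voxel_size=voxel0 * factor, wedge=subtomos.wedge)
        box = level_set.box
        if config.mask_kind == "cylinder":
            mask = soft_cylindrical_mask(box, config.mask_radius_frac * box,
                                         config.mask_z_half_frac * box)
        else:
            mask = soft_spherical_mask(box, config.mask_radius_frac * box)
        # the first level must search the full in-plane symmetry wedge
        # (seeds have random in-plane spin); later levels refine locally
        inplane = (180.0 / max(config.symmetry_order, 1)
                   if level == 0 and config.full_inplane_first
                   else config.angular_range_deg[level])
        grid = _angular_grid(config.angular_range_deg[level],
                             config.angular_step_deg[level],
                             inplane_range_deg=max(
                                 inplane, config.angular_range_deg[level]))
        # low-pass as a fraction of this level's Nyquist
        nyq_A = 2.0 * level_set.voxel_size
        lp_frac = min(1.0, nyq_A / config.lowpass_A) if config.lowpass_A else None

        scaled = [replace(p, position=p.position / factor,
                          orientation=p.orientation.copy(),
                          flags=set(p.flags)) for p in particles]
        for it in range(config.iterations_per_bin[level]):
            sym = (1 if level == 0 and it < config.asym_iterations
                   else config.symmetry_order)
            refs = {}
            for hs in (1, 2):
                half = [p for p in scaled if p.half_set == hs and p.retained]
                if not half:
                    half = [p for p in scaled if p.retained]
                ref_vol, _ = average_particles(level_set, half, sym)
                refs[hs] = ref_vol.values
            if config.adaptive_lowpass and it + level > 0:
                fsc = gold_standard_fsc(
                    DensityVolume(refs[1] * mask, level_set.voxel_size),
                    DensityVolume(refs[2] * mask, level_set.voxel_size),
                    mask=None, randomization_freq=None)
                half_freq = _fsc_crossing(fsc, 0.5)
                # cap below Nyquist: small half-set averages overestimate
                # their own resolution (alignment overfitting)
                cand = min(0.85, 2.0 * half_freq * level_set.voxel_size)
                lp_frac = max(lp_frac, cand) if prev_lowpass_frac is None \
                    else max(prev_lowpass_frac, cand)
            prev_lowpass_frac = lp_frac
            box_mask = soft_spherical_mask(box, 0.47 * box)
            mean_ccc = 0.0
            for p in scaled:
                R, shift, score = align_to_reference(
                    p_box(level_set, p), refs[p.half_set], p.orientation, grid,
                    mask, level_set.wedge, lp_frac,
                    max_shift=box * config.max_shift_frac,
                    box_mask=box_mask)
                p.orientation = R
                idx = _nearest_box_index(level_set, p)
                p.position = level_set.positions[idx] + shift
                p.ccc = score
                mean_ccc += score
            if verbose:
                print(f"[align] bin{binning} iter{it}: lp_frac={lp_frac:.2f} "
                      f"step={config.angular_step_deg[level]:.1f}deg "
                      f"mean_ccc={mean_ccc / len(scaled):.3f}")
        for p, q in zip(particles, scaled):
            p.orientation = q.orientation
            p.position = q.position * factor
            p.ccc = q.ccc
            p.half_set = q.half_set

    final_avg, _ = average_particles(subtomos, particles, config.symmetry_order)
    return particles, final_avg


def p_box(subtomos: SubtomogramSet, p: Particle) -> np.ndarray:
    return subtomos.boxes[_nearest_box_index(subtomos, p)]


def _fsc_crossing(fsc: FscCurve, threshold: float) -> float:
    """Frequency (1/Å) where the raw curve first drops below threshold."""
    for f, c in zip(fsc.shell_freq, fsc.fsc):
        if c < threshold:
            return float(f)
    return float(fsc.shell_freq[-1])


# ---------------------------------------------------------------------------
# Particle filtering
# ---------------------------------------------------------------------------


def remove_duplicates(particles: list[Particle], min_dist: float) -> list[Particle]:
    """Greedy by descending CCC: flag particles within min_dist of a kept one."""
    if min_dist <= 0:
        raise ValueError("min_dist must be positive")
    order = sorted(range(len(particles)),
                   key=lambda i: (-particles[i].ccc, i))
    kept_pos: list[np.ndarray] = []
    for i in order:
        p = particles[i]
        if any(np.linalg.norm(p.position - q) < min_dist for q in kept_pos):
            p.flags.add("removed_duplicate")
        else:
            kept_pos.append(p.position)
    return particles


def threshold_ccc(particles: list[Particle], keep_fraction: float) -> list[Particle]:
    """Flag the lowest-CCC (1 - keep_fraction) of particles as low_ccc."""
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    for p in particles:
        p.flags.discard("low_ccc")
    n_flag = len(particles) - int(np.ceil(keep_fraction * len(particles)))
    if n_flag <= 0:
        return particles
    order = sorted(range(len(particles)),
                   key=lambda i: (particles[i].ccc, i))
    for i in order[:n_flag]:
        particles[i].flags.add("low_ccc")
    return particles


# ---------------------------------------------------------------------------
# FSC and sharpening
# ---------------------------------------------------------------------------


def _shell_indices(shape, voxel_size):
    freqs = [np.fft.fftfreq(s, d=voxel_size) for s in shape]
    kz, ky, kx = np.meshgrid(*freqs, indexing="ij")
    k = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
    n_shells = shape[0] // 2
    nyq = 0.5 / voxel_size
    edges = np.linspace(0, nyq, n_shells + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_shells - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return idx, centers


def _fsc_of(f1, f2, idx, n_shells):
    num = np.bincount(idx.ravel(), weights=np.real(f1 * np.conj(f2)).ravel(),
                      minlength=n_shells)
    d1 = np.bincount(idx.ravel(), weights=np.abs(f1).ravel() ** 2,
                     minlength=n_shells)
    d2 = np.bincount(idx.ravel(), weights=np.abs(f2).ravel() ** 2,
                     minlength=n_shells)
    den = np.sqrt(d1 * d2)
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


def _randomize_phases(ft: np.ndarray, k: np.ndarray, beyond: float,
                      rng: np.random.Generator) -> np.ndarray:
    out = ft.copy()
    sel = k > beyond
    phases = rng.uniform(0, 2 * np.pi, size=int(sel.sum()))
    out[sel] = np.abs(ft[sel]) * np.exp(1j * phases)
    return out


def gold_standard_fsc(half1: DensityVolume, half2: DensityVolume,
                      mask: np.ndarray | None = None,
                      randomization_freq: float | None = None,
                      seed: int = 0) -> FscCurve:
    """Masked FSC with phase-randomization correction.

    ``randomization_freq`` (1/Å) defaults to the frequency where the
    unmasked FSC first drops below 0.8.  Beyond it, the curve is corrected
    as (FSC_t - FSC_n) / (1 - FSC_n), where FSC_n is the FSC of the two
    maps with phases randomized past that frequency and the same mask
    applied — removing mask-induced correlation.
    """
    if half1.shape != half2.shape:
        raise ValueError("half maps must share a shape")
    v1 = half1.values.astype(np.float64)
    v2 = half2.values.astype(np.float64)
    if not (np.any(v1) and np.any(v2)):
        raise ValueError("all-zero half map")
    voxel = half1.voxel_size
    idx, centers = _shell_indices(v1.shape, voxel)
    n_shells = len(centers)

    m = np.ones_like(v1) if mask is None else np.asarray(mask, dtype=np.float64)
    f1m = np.fft.fftn(v1 * m)
    f2m = np.fft.fftn(v2 * m)
    fsc_masked = _fsc_of(f1m, f2m, idx, n_shells)

    if randomization_freq is None:
        f1 = np.fft.fftn(v1)
        f2 = np.fft.fftn(v2)
        fsc_unmasked = _fsc_of(f1, f2, idx, n_shells)
        randomization_freq = float(centers[-1])
        for f, c in zip(centers, fsc_unmasked):
            if c < 0.8:
                randomization_freq = float(f)
                break

    freqs = [np.fft.fftfreq(s, d=voxel) for s in v1.shape]
    kz, ky, kx = np.meshgrid(*freqs, indexing="ij")
    k = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
    rng = np.random.default_rng(seed)
    r1 = np.fft.ifftn(_randomize_phases(np.fft.fftn(v1), k,
                                        randomization_freq, rng)).real
    r2 = np.fft.ifftn(_randomize_phases(np.fft.fftn(v2), k,
                                        randomization_freq, rng)).real
    fr1 = np.fft.fftn(r1 * m)
    fr2 = np.fft.fftn(r2 * m)
    fsc_rand = _fsc_of(fr1, fr2, idx, n_shells)

    corrected = fsc_masked.copy()
    beyond = centers > randomization_freq * 1.05  # skip the transition shell
    denom = 1.0 - fsc_rand[beyond]
    corrected[beyond] = np.where(
        np.abs(denom) > 1e-6,
        (fsc_masked[beyond] - fsc_rand[beyond]) / denom,
        0.0)
    return FscCurve(shell_freq=centers, fsc=fsc_masked,
                    corrected_fsc=corrected,
                    randomization_freq=randomization_freq)


def sharpen_map(vol: DensityVolume, fsc: FscCurve | None = None,
                b_factor: float | str = "auto",
                fit_band_A: tuple[float, float] | None = None,
                lowpass_A: float | None = None) -> tuple[DensityVolume, float]:
    """Guinier B-factor sharpening.

    Auto mode fits ln(spherically averaged structure factor) against
    s^2 / 4 (s in 1/Å) over the fit band and applies exp(+B s^2 / 4) up to
    the FSC resolution, with a soft low-pass beyond.  Fixed mode applies
    the given B directly.  Returns (sharpened map, B used).
    """
    v = vol.values.astype(np.float64)
    voxel = vol.voxel_size
    idx, centers = _shell_indices(v.shape, voxel)
    ft = np.fft.fftn(v)
    amps = np.bincount(idx.ravel(), weights=np.abs(ft).ravel(),
                       minlength=len(centers))
    counts = np.bincount(idx.ravel(), minlength=len(centers))
    radial = np.divide(amps, counts, out=np.zeros_like(amps), where=counts > 0)

    if b_factor == "auto":
        if fit_band_A is None:
            lo = 1.0 / (8.0 * voxel)  # from ~1/4 Nyquist
            hi = centers[-1] * 0.9
        else:
            lo, hi = 1.0 / fit_band_A[0], 1.0 / fit_band_A[1]
        sel = (centers >= lo) & (centers <= hi) & (radial > 0)
        if sel.sum() < 3:
            raise ValueError("fit band has fewer than 3 shells")
        x = centers[sel] ** 2 / 4.0
        y = np.log(radial[sel])
        slope, _ = np.polyfit(x, y, 1)
        b = float(-slope)
    else:
        b = float(b_factor)

    freqs = [np.fft.fftfreq(s, d=voxel) for s in v.shape]
    kz, ky, kx = np.meshgrid(*freqs, indexing="ij")
    k2 = kx ** 2 + ky ** 2 + kz ** 2
    filt = np.exp(b * k2 / 4.0)
    if lowpass_A is None and fsc is not None:
        lowpass_A = fsc.resolution_at(0.143)
    if lowpass_A is not None:
        kc = 1.0 / lowpass_A
        edge = 0.05 / voxel / v.shape[0] * 4  # a few shells wide
        soft = np.clip((kc + edge - np.sqrt(k2)) / edge, 0.0, 1.0)
        filt = filt * (0.5 - 0.5 * np.cos(np.pi * soft))
    out = np.fft.ifftn(ft * filt).real
    return vol.copy_with(out.astype(np.float32)), b


# ---------------------------------------------------------------------------
# Particle table I/O (STAR with TSV fallback)
# ---------------------------------------------------------------------------

_STAR_COLUMNS = {
    "x": "_capsidCoordinateX",
    "y": "_capsidCoordinateY",
    "z": "_capsidCoordinateZ",
    "rot": "_capsidAngleRot",
    "tilt": "_capsidAngleTilt",
    "psi": "_capsidAnglePsi",
    "ccc": "_capsidScoreCCC",
    "half_set": "_capsidHalfSet",
    "virus_id": "_capsidVirusID",
    "flags": "_capsidFlags",
}


def particles_to_frame(particles: list[Particle]) -> pd.DataFrame:
    eulers = euler_zyz_from_matrix(np.array([p.orientation for p in particles])) \
        if particles else np.empty((0, 3))
    return pd.DataFrame({
        "x": [p.position[0] for p in particles],
        "y": [p.position[1] for p in particles],
        "z": [p.position[2] for p in particles],
        "rot": eulers[:, 0] if len(particles) else [],
        "tilt": eulers[:, 1] if len(particles) else [],
        "psi": eulers[:, 2] if len(particles) else [],
        "ccc": [p.ccc for p in particles],
        "half_set": [p.half_set for p in particles],
        "virus_id": [p.virus_id for p in particles],
        "flags": [";".join(sorted(p.flags)) for p in particles],
    })


def frame_to_particles(df: pd.DataFrame) -> list[Particle]:
    mats = matrix_from_euler_zyz(df[["rot", "tilt", "psi"]].to_numpy(dtype=float)) \
        if len(df) else np.empty((0, 3, 3))
    out = []
    for i in range(len(df)):
        row = df.iloc[i]
        flags = set(str(row.get("flags", "")).split(";")) - {"", "nan"}
        out.append(Particle(
            position=np.array([row["x"], row["y"], row["z"]], dtype=float),
            orientation=mats[i], ccc=float(row["ccc"]),
            half_set=int(row["half_set"]), virus_id=str(row["virus_id"]),
            flags=flags))
    return out


def write_star(particles: list[Particle], path) -> None:
    """Particle table as a STAR file (positions voxels, ZYZ Eulers degrees)."""
    df = particles_to_frame(particles)
    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    loop = block.init_loop("", list(_STAR_COLUMNS.values()))
    for _, row in df.iterrows():
        loop.add_row([_star_quote(row[k]) for k in _STAR_COLUMNS])
    doc.write_file(str(path))


def _star_quote(v) -> str:
    s = f"{v:.8g}" if isinstance(v, (float, np.floating)) else str(v)
    return s if s else "."


def read_star(path) -> list[Particle]:
    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()
    data = {}
    for key, tag in _STAR_COLUMNS.items():
        col = block.find_loop(tag)
        data[key] = ["" if x == "." else x for x in col]
    df = pd.DataFrame(data)
    for k in ("x", "y", "z", "rot", "tilt", "psi", "ccc"):
        df[k] = df[k].astype(float)
    df["half_set"] = df["half_set"].astype(int)
    return frame_to_particles(df)


def write_tsv(particles: list[Particle], path) -> None:
    particles_to_frame(particles).to_csv(path, sep="\t", index=False,
                                         float_format="%.8g")


def read_tsv(path) -> list[Particle]:
    return frame_to_particles(pd.read_csv(path, sep="\t", keep_default_na=False))
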