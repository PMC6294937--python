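"""Rigid-body fitting of coordinate models into density maps, and idealized
helix-bundle construction for charged-assembly-helix (CAH) analysis.

The fit maximizes the real-space correlation between the map and a
Gaussian-rendered model density (blurred to the map's nominal resolution)
over the six rigid-body parameters, by deterministic local optimization
from a given start — mirroring an interactive fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ._geom import euler_zyz_from_matrix
from .tomo_sim import DensityVolume

#: canonical alpha-helix geometry
ALPHA_RISE_PER_RESIDUE = 1.5  # Å along the helix axis
ALPHA_TWIST_DEG = 100.0  # rotation per residue
ALPHA_CA_RADIUS = 2.3  # Å, C-alpha distance from the axis


@dataclass
class CoordinateModel:
    """Atomic positions (Å) with minimal per-atom labelling."""

    positions: np.ndarray  # (N, 3) Å
    chains: list[str] = field(default_factory=list)
    residue_indices: np.ndarray | None = None
    atom_names: list[str] = field(default_factory=list)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        n = len(self.positions)
        if not self.chains:
            self.chains = ["A"] * n
        if self.residue_indices is None:
            self.residue_indices = np.arange(1, n + 1)
        if not self.atom_names:
            self.atom_names = ["CA"] * n
        if self.weights is None:
            self.weights = np.ones(n)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    about: np.ndarray | None = None) -> "CoordinateModel":
        c = self.positions.mean(axis=0) if about is None else np.asarray(about)
        pos = (self.positions - c) @ np.asarray(rotation).T + c + translation
        return CoordinateModel(pos, list(self.chains),
                               self.residue_indices.copy(),
                               list(self.atom_names), self.weights.copy())

    # -- PDB I/O ---------------------------------------------------------

    @classmethod
    def from_pdb(cls, path) -> "CoordinateModel":
        st = gemmi.read_structure(str(path))
        pos, chains, resi, names, weights = [], [], [], [], []
        for model in st:
            for chain in model:
                for res in chain:
                    for atom in res:
                        pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        chains.append(chain.name)
                        resi.append(res.seqid.num)
                        names.append(atom.name)
                        weights.append(atom.element.weight)
            break
        return cls(np.asarray(pos), chains, np.asarray(resi), names,
                   np.asarray(weights))

    def to_pdb(self, path) -> None:
        st = gemmi.Structure()
        st.name = "capsidlattice model"
        model = gemmi.Model("1")
        chain_map: dict[str, gemmi.Chain] = {}
        for i in range(self.n_atoms):
            cn = self.chains[i]
            if cn not in chain_map:
                chain_map[cn] = gemmi.Chain(cn)
            chain = chain_map[cn]
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(self.residue_indices[i]), " ")
            atom = gemmi.Atom()
            atom.name = self.atom_names[i]
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*self.positions[i])
            res.add_atom(atom)
            chain.add_residue(res)
        for chain in chain_map.values():
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))


@dataclass
class FitResult:
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,) Å
    correlation: float
    n_evaluations: int

    def to_tsv(self, path) -> None:
        rot, tilt, psi = euler_zyz_from_matrix(self.rotation[None])[0]
        pd.DataFrame([{
            "euler_rot_deg": rot, "euler_tilt_deg": tilt, "euler_psi_deg": psi,
            "tx_A": self.translation[0], "ty_A": self.translation[1],
            "tz_A": self.translation[2],
            "correlation": self.correlation,
            "n_evaluations": self.n_evaluations,
        }]).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Helix geometry
# ---------------------------------------------------------------------------


def helix_length(n_residues: int, rise_per_residue: float = ALPHA_RISE_PER_RESIDUE
                 ) -> tuple[float, int]:
    """Axial length of an ideal alpha-helix: (exact Å, integer part)."""
    if n_residues < 0 or rise_per_residue <= 0:
        raise ValueError("inputs must be positive")
    exact = n_residues * rise_per_residue
    return float(exact), int(exact)


def residues_for_length(length: float,
                        rise_per_residue: float = ALPHA_RISE_PER_RESIDUE) -> int:
    """Number of residues whose ideal helix spans the given axial length."""
    if length < 0 or rise_per_residue <= 0:
        raise ValueError("inputs must be positive")
    return int(length / rise_per_residue)


def residue_span_length(first: int, last: int,
                        rise_per_residue: float = ALPHA_RISE_PER_RESIDUE
                        ) -> tuple[float, int]:
    """Helix length of an inclusive residue span (e.g. 222-256 -> 35 aa)."""
    n = last - first + 1
    return helix_length(n, rise_per_residue)


def build_helix_bundle(n_helices: int, bundle_radius: float, n_residues: int,
                       rise_per_residue: float = ALPHA_RISE_PER_RESIDUE,
                       tilt_deg: float = 0.0) -> CoordinateModel:
    """Ideal C-alpha alpha-helix backbones with axes on a circle about z.

    The bundle is Cn-symmetric about z: helix j is helix 0 rotated by
    360 j / n degrees.  ``bundle_radius`` is the helix-axis circle radius,
    so adjacent axes are 2 r sin(pi/n) apart.  ``tilt_deg`` tips each helix
    axis within its axial plane (0 = parallel to z).
    """
    if n_helices < 1:
        raise ValueError("need at least one helix")
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    i = np.arange(n_residues)
    # canonical helix along z, centred axially
    ang = np.deg2rad(ALPHA_TWIST_DEG) * i
    z = (i - (n_residues - 1) / 2.0) * rise_per_residue
    helix = np.column_stack([ALPHA_CA_RADIUS * np.cos(ang),
                             ALPHA_CA_RADIUS * np.sin(ang), z])
    if tilt_deg:
        helix = helix @ Rotation.from_euler("y", tilt_deg, degrees=True
                                            ).as_matrix().T
    helix[:, 0] += bundle_radius

    pos, chains, resi = [], [], []
    for j in range(n_helices):
        Rz = Rotation.from_euler("z", 360.0 * j / n_helices, degrees=True
                                 ).as_matrix()
        pos.append(helix @ Rz.T)
        chains += [chr(ord("A") + j)] * n_residues
        resi += list(range(1, n_residues + 1))
    return CoordinateModel(np.vstack(pos), chains, np.asarray(resi),
                           ["CA"] * (n_helices * n_residues))


# ---------------------------------------------------------------------------
# Rigid-body fitting
# ---------------------------------------------------------------------------


def render_model_density(model: CoordinateModel, like: DensityVolume,
                         resolution: float) -> np.ndarray:
    """Gaussian density of the model on the map's grid (sigma from resolution)."""
    sigma_A = resolution / 2.355  # FWHM = nominal resolution
    voxel = like.voxel_size
    sigma = sigma_A / voxel
    out = np.zeros(like.shape, dtype=np.float64)
    half = int(np.ceil(3 * sigma))
    shape = like.shape
    for p, w in zip(model.positions, model.weights):
        v = p / voxel - like.origin  # (x, y, z) voxel coords
        base = np.round(v).astype(int)
        z0, y0, x0 = base[2] - half, base[1] - half, base[0] - half
        zs = slice(max(z0, 0), min(base[2] + half + 1, shape[0]))
        ys = slice(max(y0, 0), min(base[1] + half + 1, shape[1]))
        xs = slice(max(x0, 0), min(base[0] + half + 1, shape[2]))
        if zs.start >= zs.stop or ys.start >= ys.stop or xs.start >= xs.stop:
            continue
        zz, yy, xx = np.meshgrid(np.arange(zs.start, zs.stop),
                                 np.arange(ys.start, ys.stop),
                                 np.arange(xs.start, xs.stop), indexing="ij")
        r2 = (xx - v[0]) ** 2 + (yy - v[1]) ** 2 + (zz - v[2]) ** 2
        out[zs, ys, xs] += w * np.exp(-r2 / (2 * sigma ** 2))
    return out


def _pose_matrix(rotvec: np.ndarray) -> np.ndarray:
    return Rotation.from_rotvec(rotvec).as_matrix()


def rigid_body_fit(model: CoordinateModel, density: DensityVolume,
                   resolution: float,
                   initial_rotation: np.ndarray | None = None,
                   initial_translation: np.ndarray | None = None,
                   max_iter: int = 400) -> FitResult:
    """Local maximization of map/model real-space correlation.

    Six pose parameters (rotation vector, translation) are refined from the
    given start with a derivative-free simplex search; deterministic for a
    fixed start.  The model pivots about its centroid.
    """
    if model.n_atoms < 3:
        raise ValueError("need at least 3 atoms")
    svals = np.linalg.svd(model.positions - model.positions.mean(axis=0),
                          compute_uv=False)
    if svals[1] < 1e-9:
        raise ValueError("model atoms are collinear")
    map_vals = density.values.astype(np.float64)
    map_c = map_vals - map_vals.mean()
    map_norm = np.linalg.norm(map_c)
    if map_norm == 0:
        raise ValueError("map has zero variance")

    R0 = np.eye(3) if initial_rotation is None else np.asarray(initial_rotation)
    t0 = np.zeros(3) if initial_translation is None else np.asarray(
        initial_translation, dtype=float)
    n_eval = 0

    def negcorr(params):
        nonlocal n_eval
        n_eval += 1
        R = _pose_matrix(params[:3]) @ R0
        t = t0 + params[3:]
        dens = render_model_density(model.transformed(R, t), density, resolution)
        dc = dens - dens.mean()
        dn = np.linalg.norm(dc)
        if dn == 0:
            return 0.0
        return -float(np.dot(dc.ravel(), map_c.ravel()) / (dn * map_norm))

    res = minimize(negcorr, np.zeros(6), method="Nelder-Mead",
                   options={"maxiter": max_iter, "xatol": 1e-3, "fatol": 1e-6,
                            "initial_simplex": _initial_simplex()})
    R = _pose_matrix(res.x[:3]) @ R0
    t = t0 + res.x[3:]
    return FitResult(rotation=R, translation=t, correlation=-float(res.fun),
                     n_evaluations=n_eval)


def _initial_simplex() -> np.ndarray:
    """Simplex spanning ~3 deg rotations and ~1.5 Å translations."""
    s = np.zeros((7, 6))
    for i in range(6):
        s[i + 1, i] = 0.05 if i < 3 else 1.5
    return s
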