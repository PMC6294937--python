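"""Ground-truth retroviral capsid lattice geometries.

This module generates the idealized subunit lattices that the rest of the
package renders, images, and re-detects: immature Gag shells (hexamer-only
spheres with one large gap plus small defects), mature closed fullerene
polyhedra (Goldberg duals), fullerene cones with the canonical 5/7 pentamer
split between the narrow and wide ends, wound spiral sheets, and nested
multi-layer cores.

Conventions
-----------
* Model space is in nanometres.  Each lattice site carries a right-handed
  orthonormal frame whose z axis is the outward lattice normal and whose x
  axis is an in-plane reference direction.
* ``ring_order`` is 6 for a hexamer site and 5 for a pentamer site
  (a +pi/3 disclination).  Heptamers are never generated.
* Bonds connect nearest lattice neighbours; every bond length lies within
  [0.8, 1.2] x the model spacing.
* Closed components obey fullerene topology: exactly 12 pentamers and the
  discrete Euler relation V - E + F = 2.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree, ConvexHull

from ._geom import (
    fibonacci_sphere,
    frames_from_z,
    normalize,
    quats_to_rotmats,
    rotmats_to_quats,
)

BOND_WINDOW = (0.8, 1.2)

MORPHOLOGIES = (
    "immature_sphere",
    "closed_polyhedron",
    "fullerene_cone",
    "spiral",
    "nested",
    "sheet",
)


class InvalidParameterError(ValueError):
    """Raised when generator parameters cannot produce a valid lattice."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class LatticeSite:
    """A single capsomer site: position (nm), local frame, ring order, layer."""

    center: np.ndarray
    orientation: np.ndarray  # 3x3, columns = local x, y, z in world coords
    ring_order: int
    layer_index: int = 0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.ring_order not in (5, 6):
            raise InvalidParameterError(f"ring_order must be 5 or 6, got {self.ring_order}")
        R = self.orientation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise InvalidParameterError("orientation must be orthonormal with det +1")


@dataclass
class CapsidModel:
    """A full ground-truth lattice: sites, bonds, and generation provenance."""

    centers: np.ndarray  # (N, 3) nm
    orientations: np.ndarray  # (N, 3, 3)
    ring_order: np.ndarray  # (N,) int, 5 or 6
    layer_index: np.ndarray  # (N,) int
    bonds: np.ndarray  # (M, 2) int, each row sorted
    morphology: str
    spacing: float  # nm, generator target hexamer-hexamer distance
    seed: int | None = None
    membrane_radius: float | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.ring_order = np.asarray(self.ring_order, dtype=int)
        self.layer_index = np.asarray(self.layer_index, dtype=int)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        if self.morphology not in MORPHOLOGIES:
            raise InvalidParameterError(f"unknown morphology {self.morphology!r}")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.centers)

    @property
    def sites(self) -> list[LatticeSite]:
        return [
            LatticeSite(self.centers[i], self.orientations[i],
                        int(self.ring_order[i]), int(self.layer_index[i]))
            for i in range(self.n_sites)
        ]

    def bond_lengths(self) -> np.ndarray:
        if len(self.bonds) == 0:
            return np.empty(0)
        d = self.centers[self.bonds[:, 0]] - self.centers[self.bonds[:, 1]]
        return np.linalg.norm(d, axis=1)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_sites))
        g.add_edges_from(map(tuple, self.bonds))
        return g

    def normals(self) -> np.ndarray:
        """Outward lattice normal of each site (local z in world coords)."""
        return self.orientations[:, :, 2]

    def validate(self) -> None:
        """Check structural invariants; raise InvalidParameterError on failure."""
        if self.bonds.size:
            if np.any(self.bonds[:, 0] == self.bonds[:, 1]):
                raise InvalidParameterError("self-bond found")
            if self.bonds.max() >= self.n_sites or self.bonds.min() < 0:
                raise InvalidParameterError("bond endpoint out of range")
            bl = self.bond_lengths()
            # nested layers may have different lattice constants
            layer_spacings = self.params.get("layer_spacings")
            if layer_spacings is not None:
                ref = np.asarray(layer_spacings)[self.layer_index[self.bonds[:, 0]]]
            else:
                ref = np.full(len(bl), self.spacing)
            rel = bl / ref
            if rel.min() < BOND_WINDOW[0] - 1e-9 or rel.max() > BOND_WINDOW[1] + 1e-9:
                raise InvalidParameterError(
                    f"relative bond lengths [{rel.min():.3f}, {rel.max():.3f}] "
                    f"outside window {BOND_WINDOW}"
                )
        if not np.all(np.isin(self.ring_order, (5, 6))):
            raise InvalidParameterError("ring_order values must be 5 or 6")
        if self.morphology == "immature_sphere" and np.any(self.ring_order == 5):
            raise InvalidParameterError("immature shells are hexamer-only")
        census = pentamer_census(self)
        if not census["euler_ok"]:
            raise InvalidParameterError("a closed component violates V - E + F = 2")

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path_or_buf) -> None:
        """Write the model as a plain-text table (sites + explicit bond list)."""
        header = {
            "morphology": self.morphology,
            "spacing": self.spacing,
            "seed": self.seed,
            "membrane_radius": self.membrane_radius,
            "params": self.params,
        }
        quats = rotmats_to_quats(self.orientations)
        lines = ["# capsidlattice model", "# " + json.dumps(header),
                 "x\ty\tz\tqw\tqx\tqy\tqz\tring_order\tlayer_index"]
        for i in range(self.n_sites):
            c, q = self.centers[i], quats[i]
            lines.append(
                f"{c[0]:.9g}\t{c[1]:.9g}\t{c[2]:.9g}\t"
                f"{q[0]:.12g}\t{q[1]:.12g}\t{q[2]:.12g}\t{q[3]:.12g}\t"
                f"{self.ring_order[i]}\t{self.layer_index[i]}"
            )
        lines.append("# bonds")
        for a, b in self.bonds:
            lines.append(f"#B\t{a}\t{b}")
        text = "\n".join(lines) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "CapsidModel":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        header: dict = {}
        rows, bonds = [], []
        for line in io.StringIO(text):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#B\t"):
                _, a, b = line.split("\t")
                bonds.append((int(a), int(b)))
            elif line.startswith("# {"):
                header = json.loads(line[2:])
            elif line.startswith("#") or line.startswith("x\t"):
                continue
            else:
                rows.append([float(v) for v in line.split("\t")])
        arr = np.asarray(rows, dtype=float)
        if arr.size == 0:
            raise InvalidParameterError("empty model table")
        quats = arr[:, 3:7]
        return cls(
            centers=arr[:, :3],
            orientations=quats_to_rotmats(quats),
            ring_order=arr[:, 7].astype(int),
            layer_index=arr[:, 8].astype(int),
            bonds=np.asarray(bonds, dtype=int).reshape(-1, 2),
            morphology=header.get("morphology", "sheet"),
            spacing=float(header.get("spacing", 1.0)),
            seed=header.get("seed"),
            membrane_radius=header.get("membrane_radius"),
            params=header.get("params", {}),
        )


# ---------------------------------------------------------------------------
# Shared construction helpers
# ---------------------------------------------------------------------------


def _bonds_by_window(centers: np.ndarray, spacing: float,
                     layer_index: np.ndarray | None = None) -> np.ndarray:
    """Bond every pair with distance in the window; never across layers."""
    tree = cKDTree(centers)
    pairs = tree.query_pairs(BOND_WINDOW[1] * spacing, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=int)
    d = np.linalg.norm(centers[pairs[:, 0]] - centers[pairs[:, 1]], axis=1)
    keep = d >= BOND_WINDOW[0] * spacing
    if layer_index is not None:
        keep &= layer_index[pairs[:, 0]] == layer_index[pairs[:, 1]]
    pairs = pairs[keep]
    return np.sort(pairs, axis=1)


def _mean_nn_distance(centers: np.ndarray) -> float:
    tree = cKDTree(centers)
    d, _ = tree.query(centers, k=2)
    return float(d[:, 1].mean())


def _spring_relax(centers: np.ndarray, bonds: np.ndarray, rest: float,
                  n_iter: int = 300, step: float = 0.15,
                  pressure: float = 0.0) -> np.ndarray:
    """Relax positions so bond lengths approach ``rest``.

    A weak repulsion between close non-bonded pairs keeps the mesh from
    collapsing; ``pressure`` adds a gentle push away from the centroid for
    closed shells.
    """
    x = centers.copy()
    i, j = bonds[:, 0], bonds[:, 1]
    n = len(x)
    for it in range(n_iter):
        f = np.zeros_like(x)
        d = x[i] - x[j]
        dist = np.linalg.norm(d, axis=1, keepdims=True)
        dist = np.where(dist < 1e-9, 1e-9, dist)
        spring = (rest - dist) / rest * (d / dist)
        np.add.at(f, i, spring)
        np.add.at(f, j, -spring)
        if it % 10 == 0:
            tree = cKDTree(x)
            close = tree.query_pairs(0.95 * rest, output_type="ndarray")
            if len(close):
                bond_set = {tuple(b) for b in np.sort(bonds, axis=1)}
                mask = np.array([tuple(p) not in bond_set
                                 for p in np.sort(close, axis=1)])
                close = close[mask]
        if len(close):
            a, b = close[:, 0], close[:, 1]
            d2 = x[a] - x[b]
            dd = np.linalg.norm(d2, axis=1, keepdims=True)
            dd = np.where(dd < 1e-9, 1e-9, dd)
            rep = (0.95 * rest - dd) / rest * (d2 / dd)
            np.add.at(f, a, rep)
            np.add.at(f, b, -rep)
        if pressure:
            c = x.mean(axis=0)
            f += pressure * normalize(x - c)
        x += step * rest * f / max(1.0, n ** 0)
    return x


def _orient_sites(centers: np.ndarray, bonds: np.ndarray,
                  outward_hint: np.ndarray) -> np.ndarray:
    """Per-site frames: z = outward normal from the local bond plane."""
    n = len(centers)
    nbrs: list[list[int]] = [[] for _ in range(n)]
    for a, b in bonds:
        nbrs[a].append(b)
        nbrs[b].append(a)
    zs = np.empty((n, 3))
    hints = np.empty((n, 3))
    for v in range(n):
        if len(nbrs[v]) >= 2:
            rel = centers[nbrs[v]] - centers[v]
            # normal of best-fit plane through the neighbours
            _, _, vt = np.linalg.svd(rel - rel.mean(axis=0))
            z = vt[2]
        else:
            z = outward_hint[v]
        if np.dot(z, outward_hint[v]) < 0:
            z = -z
        zs[v] = z / np.linalg.norm(z)
        hints[v] = (centers[nbrs[v][0]] - centers[v]) if nbrs[v] else np.array([1.0, 0, 0])
    return frames_from_z(zs, hints)


# ---------------------------------------------------------------------------
# Immature shell
# ---------------------------------------------------------------------------


def generate_immature_shell(radius: float, spacing: float, gap_fraction: float = 0.15,
                            n_small_defects: int = 3, seed: int = 0,
                            membrane_offset: float = 6.0) -> CapsidModel:
    """Hexamer-only quasi-hexagonal sphere packing with one large gap.

    The immature Gag shell is modelled as a relaxed quasi-uniform packing on
    a sphere of the given radius (the CA-layer radius), with one contiguous
    spherical-cap gap covering ``gap_fraction`` of the surface and
    ``n_small_defects`` additional holes of 1-3 sites each.  The viral
    membrane sits ``membrane_offset`` nm above the CA layer;
    ``membrane_radius`` records its bilayer midplane (a convention — particle
    diameters are quoted at the membrane).
    """
    if radius <= 2 * spacing:
        raise InvalidParameterError("radius must exceed twice the spacing")
    if not 0 <= gap_fraction < 1:
        raise InvalidParameterError("gap_fraction must be in [0, 1)")
    area_per_site = (np.sqrt(3.0) / 2.0) * spacing ** 2
    n = int(round(4.0 * np.pi * radius ** 2 / area_per_site))
    if n * (1 - gap_fraction) < 10:
        raise InvalidParameterError("parameters leave fewer than 10 sites")
    rng = np.random.default_rng(seed)
    pts = radius * fibonacci_sphere(n)
    pts = _relax_on_sphere(pts, radius, spacing, rng)

    # one contiguous spherical-cap gap
    if gap_fraction > 0:
        axis = normalize(rng.standard_normal(3))
        cos_cut = 1.0 - 2.0 * gap_fraction  # cap area fraction f <-> cos(theta)
        keep = (pts @ axis) / radius < cos_cut
        pts = pts[keep]
    # small irregular defects: 1-3 adjacent sites each
    for _ in range(int(n_small_defects)):
        if len(pts) <= 12:
            break
        k = int(rng.integers(1, 4))
        centre = int(rng.integers(len(pts)))
        d = np.linalg.norm(pts - pts[centre], axis=1)
        pts = np.delete(pts, np.argsort(d)[:k], axis=0)
    if len(pts) < 10:
        raise InvalidParameterError("parameters leave fewer than 10 sites")

    bonds = _bonds_by_window(pts, spacing)
    outward = normalize(pts)
    model = CapsidModel(
        centers=pts,
        orientations=_orient_sites(pts, bonds, outward),
        ring_order=np.full(len(pts), 6),
        layer_index=np.zeros(len(pts), dtype=int),
        bonds=bonds,
        morphology="immature_sphere",
        spacing=spacing,
        seed=seed,
        membrane_radius=radius + membrane_offset,
        params={"gap_fraction": gap_fraction, "n_small_defects": n_small_defects,
                "membrane_offset": membrane_offset},
    )
    return model


def _relax_on_sphere(pts: np.ndarray, radius: float, spacing: float,
                     rng: np.random.Generator, n_iter: int = 80) -> np.ndarray:
    """Short in-surface relaxation toward even hexagonal packing."""
    x = pts.copy()
    for _ in range(n_iter):
        tree = cKDTree(x)
        pairs = tree.query_pairs(1.35 * spacing, output_type="ndarray")
        f = np.zeros_like(x)
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            d = x[i] - x[j]
            dist = np.linalg.norm(d, axis=1, keepdims=True)
            push = (spacing - dist) / spacing * (d / dist)
            np.add.at(f, i, push)
            np.add.at(f, j, -push)
        # tangential step, then re-project to the sphere
        radial = normalize(x)
        f -= (f * radial).sum(axis=1, keepdims=True) * radial
        x = x + 0.2 * spacing * f
        x = radius * normalize(x)
    return x


# ---------------------------------------------------------------------------
# Closed Goldberg shells
# ---------------------------------------------------------------------------


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            v += [(0, a, b), (a, b, 0), (b, 0, a)]
    verts = normalize(np.asarray(v, dtype=float))
    faces = ConvexHull(verts).simplices.copy()
    # consistent right-handed winding (outward normals): a chiral Caspar-Klug
    # lattice is mirrored by inconsistently wound faces
    for f in faces:
        a, b, c = verts[f]
        if np.dot(np.cross(b - a, c - a), a + b + c) < 0:
            f[1], f[2] = f[2], f[1]
    return verts, faces


def generate_closed_shell(h: int, k: int = 0, radius: float = 25.0) -> CapsidModel:
    """Closed fullerene shell: the Caspar-Klug (h, k) lattice on a sphere.

    Sites are the capsomer centres of the Goldberg-dual construction:
    exactly 12 pentamers (at the icosahedral 5-fold axes) and 10(T - 1)
    hexamers with T = h^2 + hk + k^2, scaled so the shell has the given
    circumradius in nm.
    """
    h, k = int(h), int(k)
    if h < 0 or k < 0 or (h, k) == (0, 0):
        raise InvalidParameterError("(h, k) must be non-negative and not (0, 0)")
    if h == 0:
        h, k = k, 0  # same lattice by symmetry
    t_number = h * h + h * k + k * k
    verts, faces = _icosahedron()

    # triangular-lattice basis and the CK triangle corners in lattice coords
    e1 = np.array([1.0, 0.0])
    e2 = np.array([0.5, np.sqrt(3.0) / 2.0])
    b2 = h * e1 + k * e2
    c2 = -k * e1 + (h + k) * e2  # b rotated by +60 deg
    m = np.column_stack([b2, c2])
    minv = np.linalg.inv(m)

    pts = []
    i_range = range(-k - 1, h + k + 2)
    j_range = range(-1, h + 2 * k + 2)
    for fa, fb, fc in faces:
        A, B, C = verts[fa], verts[fb], verts[fc]
        for i in i_range:
            for j in j_range:
                p2 = i * e1 + j * e2
                beta, gamma = minv @ p2
                lam = np.array([1.0 - beta - gamma, beta, gamma])
                if np.all(lam >= -1e-9):
                    pts.append(lam[0] * A + lam[1] * B + lam[2] * C)
    pts = normalize(np.asarray(pts))

    # merge duplicates generated on shared face edges/corners
    approx_spacing = np.sqrt(4.0 * np.pi / ((np.sqrt(3) / 2) * (10 * t_number + 2)))
    tree = cKDTree(pts)
    pairs = tree.query_pairs(0.35 * approx_spacing, output_type="ndarray")
    g = nx.Graph()
    g.add_nodes_from(range(len(pts)))
    g.add_edges_from(map(tuple, pairs))
    centers = np.array(
        [normalize(pts[list(comp)].mean(axis=0)) for comp in nx.connected_components(g)]
    )
    if len(centers) != 10 * t_number + 2:
        raise RuntimeError(
            f"Caspar-Klug construction produced {len(centers)} sites, "
            f"expected {10 * t_number + 2}"
        )

    # points are in convex position: hull edges are the exact lattice bonds
    hull = ConvexHull(centers)
    edge_set = set()
    for tri in hull.simplices:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[0], tri[2])):
            edge_set.add((min(a, b), max(a, b)))
    bonds = np.asarray(sorted(edge_set), dtype=int)
    deg = np.zeros(len(centers), dtype=int)
    np.add.at(deg, bonds.ravel(), 1)
    if not np.all(np.isin(deg, (5, 6))) or int((deg == 5).sum()) != 12:
        raise RuntimeError("geodesic bond assignment failed to isolate 12 pentamers")
    ring_order = np.where(deg == 5, 5, 6)

    # short tangential relaxation evens out the flat-map edge-length spread
    rest = float(np.mean(np.linalg.norm(
        centers[bonds[:, 0]] - centers[bonds[:, 1]], axis=1)))
    for _ in range(60):
        f = np.zeros_like(centers)
        d = centers[bonds[:, 0]] - centers[bonds[:, 1]]
        dist = np.linalg.norm(d, axis=1, keepdims=True)
        spring = (rest - dist) / rest * (d / dist)
        np.add.at(f, bonds[:, 0], spring)
        np.add.at(f, bonds[:, 1], -spring)
        f -= (f * centers).sum(axis=1, keepdims=True) * centers
        centers = normalize(centers + 0.2 * rest * f)
    centers = radius * centers

    model = CapsidModel(
        centers=centers,
        orientations=_orient_sites(centers, bonds, normalize(centers)),
        ring_order=ring_order,
        layer_index=np.zeros(len(centers), dtype=int),
        bonds=bonds,
        morphology="closed_polyhedron",
        spacing=float(np.mean(np.linalg.norm(
            centers[bonds[:, 0]] - centers[bonds[:, 1]], axis=1))),
        seed=None,
        params={"h": h, "k": k, "t_number": t_number, "radius": radius},
    )
    return model


# ---------------------------------------------------------------------------
# Fullerene cone
# ---------------------------------------------------------------------------


def _strip_walk(bottom: np.ndarray, top: np.ndarray, updeg: np.ndarray,
                offset: int = 0) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Triangulated annulus between two vertex rings.

    ``updeg[i]`` is the number of top-ring vertices bonded to bottom vertex
    i; consecutive bottom vertices share their boundary top vertex, which
    makes every face a triangle.  Returns the cross edges and the resulting
    per-top-vertex down-degree.
    """
    na, nb = len(bottom), len(top)
    if updeg.sum() != na + nb:
        raise RuntimeError("inconsistent strip degrees")
    if np.any(updeg < 1):
        raise RuntimeError("strip requires every bottom vertex to reach the top ring")
    edges = []
    downdeg = np.zeros(nb, dtype=int)
    t = offset % nb
    for i in range(na):
        for j in range(updeg[i]):
            tj = (t + j) % nb
            edges.append((int(bottom[i]), int(top[tj])))
            downdeg[tj] += 1
        t = (t + updeg[i] - 1) % nb
    return edges, downdeg


def _place_ring_pentamers(tipdeg: np.ndarray, count: int,
                          blocked: set[int] | None = None) -> list[int]:
    """Choose pentamer slots on a ring so cross-degrees stay uniform.

    A pentamer at tip-degree 1 keeps its up-degree at the regular value 2;
    tip-degree 2 (up-degree 1) is acceptable; higher tip-degrees would leave
    the pentamer unable to reach the next ring.  Slots next to a seam column
    (tip-degree >= 3) or in ``blocked`` (e.g. adjacent to a pentamer of the
    previous ring) are avoided, and chosen slots are spread evenly so
    disclinations never become adjacent.
    """
    n = len(tipdeg)
    blocked = blocked or set()
    seam_adjacent = {
        (i + d) % n for i in range(n) if tipdeg[i] >= 3 for d in (-1, 0, 1)
    }

    def usable(i: int) -> bool:
        return tipdeg[i] <= 2 and i not in blocked and i not in seam_adjacent

    best: list[int] | None = None
    best_score = None
    for offset in range(n):
        chosen: list[int] = []
        for c in range(count):
            target = (offset + int(round(c * n / count))) % n
            placed = False
            for good_only in (True, False):  # prefer growth-seam slots
                for delta in range(n // 2 + 1):
                    for cand in ((target + delta) % n, (target - delta) % n):
                        if good_only and tipdeg[cand] != 1:
                            continue
                        if usable(cand) and all(
                            min((cand - p) % n, (p - cand) % n) >= 2 for p in chosen
                        ):
                            chosen.append(cand)
                            placed = True
                            break
                    if placed:
                        break
                if placed:
                    break
            if not placed:
                break
        if len(chosen) < count:
            continue
        min_sep = min(
            (min((a - b) % n, (b - a) % n) for a in chosen for b in chosen if a != b),
            default=n,
        )
        n_good = sum(tipdeg[i] == 1 for i in chosen)
        score = (n_good, min_sep)
        if best_score is None or score > best_score:
            best, best_score = chosen, score
    if best is None:
        # fall back: allow separation 2 and seam-adjacent slots
        ranked = sorted((i for i in range(n) if tipdeg[i] <= 2 and i not in blocked),
                        key=lambda i: (tipdeg[i] != 1, i))
        best = []
        for cand in ranked:
            if len(best) >= count:
                break
            if all(min((cand - p) % n, (p - cand) % n) >= 2 for p in best):
                best.append(cand)
        if len(best) < count:
            raise RuntimeError("cannot place separated pentamers on ring")
    return sorted(best)


def _cone_ring_plan(n_hex_target: int) -> tuple[list[tuple[int, int]], int, int]:
    """Ring sizes and per-ring pentamer counts for a closed 5/7 cone.

    Structure, narrow to wide: a tip apex pentamer, a 5-ring, then a 10-ring
    carrying ``p2`` pentamers plus single pentamers on the following rings
    until the 5 narrow disclinations have flattened the growth rate to one
    site per ring; a hexamer-only conical body; one wide "shoulder" ring
    carrying 6 (or 7) evenly spread pentamers that flips the growth rate to
    -5 (or -6); and a uniform descent closed by a base apex, which is the
    12th pentamer when the descent step is 5 and a hexamer when it is 6
    (in which case the shoulder carries 7).  Returns the plan
    [(ring_size, n_pentamers), ...] (apexes excluded), the hexamer count,
    and the descent step.
    """
    def _compositions(total: int, max_parts: int):
        if total == 0:
            yield ()
            return
        for first in range(min(total, 4), 0, -1):
            if max_parts >= 1:
                for rest in _compositions(total - first, max_parts - 1):
                    yield (first,) + rest

    from itertools import product

    candidates = []
    narrows = []
    seen = set()
    for comp in _compositions(4, 4):
        # narrow section: recurrence r_next = 2 r - r_prev - pentamers; each
        # ring can absorb at most as many pentamers as it has growth seams
        # (the incoming slope).  Hexamer-only gap rings between placements
        # give fine-grained control of the cone size.
        for gaps in product(range(7), repeat=len(comp)):
            if sum(gaps) > 6:
                continue
            narrow = [(5, 0)]
            r_prev, r = 5, 10
            slope, ok = 5, True
            for g, c in zip(gaps, comp):
                for _ in range(g):
                    narrow.append((r, 0))
                    r_prev, r = r, 2 * r - r_prev
                if c > slope:
                    ok = False
                    break
                narrow.append((r, c))
                r_prev, r = r, 2 * r - r_prev - c
                slope = r - r_prev
                if slope < 1:
                    ok = False
                    break
            if ok and slope == 1:
                key = tuple(narrow)
                if key not in seen:
                    seen.add(key)
                    narrows.append((narrow, r))
    for narrow, entry in narrows:
        for shoulder_p, step, final in ((6, 5, 5),):
            # the five descent seams need one clear grid residue: w >= 20
            w = ((entry + step - 1) // step) * step
            while w < max(20, entry):
                w += step
            while w < 300:
                body = [(s, 0) for s in range(entry, w)]
                tail = [(s, 0) for s in range(w - step, final - 1, -step)]
                plan = narrow + body + [(w, shoulder_p)] + tail
                n_sites = 2 + sum(size for size, _ in plan)  # + both apexes
                n_hex = n_sites - 12
                err = abs(n_hex - n_hex_target) / n_hex_target
                # how far down the cone the last narrow pentamer sits; a
                # compact tip keeps the 5/7 split cleanly separated
                last_pent = max(size for size, c in narrow if c > 0)
                spread = last_pent / w
                candidates.append((err, spread, w, step, plan, n_hex))
                if n_hex > n_hex_target * 1.5 + 30:
                    break
                w += step
    if not candidates:
        raise InvalidParameterError("no cone plan found for target")
    within = [c for c in candidates if c[0] <= 0.10]
    if within:
        # meet the size tolerance, then prefer the most cone-like geometry
        _, _, _, step, plan, n_hex = min(within, key=lambda c: (c[1], c[0], c[2]))
    else:
        _, _, _, step, plan, n_hex = min(candidates, key=lambda c: (c[0], c[1], c[2]))
    return plan, n_hex, step


def generate_fullerene_cone(n_hex_target: int = 200, narrow_pentamers: int = 5,
                            wide_pentamers: int = 7, seed: int = 0,
                            spacing: float = 10.0) -> CapsidModel:
    """Closed fullerene cone with 5 pentamers at the narrow end, 7 at the wide.

    The triangulation is built exactly (ring-stacked, all faces triangles,
    every pentamer isolated among hexamers) and then spring-relaxed in 3D so
    all bond lengths approach ``spacing`` (default 10 nm, the mature CA
    hexamer spacing).  Only the canonical 5/7 split is supported.
    """
    if narrow_pentamers + wide_pentamers != 12:
        raise InvalidParameterError("pentamer split must sum to 12")
    if (narrow_pentamers, wide_pentamers) != (5, 7):
        raise InvalidParameterError("only the canonical 5/7 split is supported")
    if n_hex_target < 100:
        raise InvalidParameterError(
            "n_hex_target must be at least 100: the smallest closed 5/7 cone "
            "this ring construction supports has ~105 hexamers"
        )

    plan, _, step = _cone_ring_plan(n_hex_target)
    sizes = [size for size, _ in plan]

    # ---- combinatorics -------------------------------------------------
    n_sites = 2 + sum(sizes)
    apex_n = 0
    ring_ids: list[np.ndarray] = []
    next_id = 1
    for size in sizes:
        ring_ids.append(np.arange(next_id, next_id + size))
        next_id += size
    apex_w = next_id
    ring_order = np.full(n_sites, 6, dtype=int)
    ring_order[apex_n] = 5
    if step == 5:  # base apex is the 12th pentamer; with step 6 it is a hexamer
        ring_order[apex_w] = 5

    edges: list[tuple[int, int]] = []
    # narrow apex fan
    first = ring_ids[0]
    edges += [(apex_n, int(v)) for v in first]
    tipdeg = np.ones(len(first), dtype=int)
    # ring cycles
    for ids in ring_ids:
        nr = len(ids)
        edges += [(int(ids[i]), int(ids[(i + 1) % nr])) for i in range(nr)]
    # strips, narrow to wide, with pentamer placement as we go
    blocked: set[int] = set()
    for r in range(len(plan) - 1):
        size, n_pent = plan[r]
        ids = ring_ids[r]
        ro = np.full(size, 6, dtype=int)
        if n_pent >= 6:
            # shoulder ring: one pentamer absorbs the body growth seam, the
            # rest sit evenly between so the descent seams stay uniform
            seams = np.where(tipdeg == 1)[0]
            if len(seams) != 1:
                raise RuntimeError("shoulder ring expects exactly one growth seam")
            s0 = int(seams[0])
            pos = [s0] + sorted(
                (s0 + int((j + 0.5) * size / (n_pent - 1))) % size
                for j in range(n_pent - 1)
            )
            pos = sorted(set(pos))
            if len(pos) != n_pent:
                raise RuntimeError("shoulder pentamer placement collided")
            ro[pos] = 5
            ring_order[ids[pos]] = 5
        elif n_pent:
            pos = _place_ring_pentamers(tipdeg, n_pent, blocked)
            ro[pos] = 5
            ring_order[ids[pos]] = 5
        updeg = ro - 2 - tipdeg
        new_edges, tipdeg = _strip_walk(ids, ring_ids[r + 1], updeg)
        edges += new_edges
        # slots of the next ring adjacent to a pentamer just placed
        pent_ids = set(ids[ro == 5].tolist())
        next_pos = {int(v): i for i, v in enumerate(ring_ids[r + 1])}
        blocked = {next_pos[b] for a, b in new_edges if a in pent_ids}
    # wide apex fan closes the final ring
    last = ring_ids[-1]
    if len(last) != (5 if step == 5 else 6):
        raise RuntimeError("cone plan ends on a ring of unexpected size")
    edges += [(apex_w, int(v)) for v in last]

    deg = np.zeros(n_sites, dtype=int)
    earr = np.asarray(edges)
    np.add.at(deg, earr.ravel(), 1)
    if not np.array_equal(deg, ring_order):
        raise RuntimeError("cone combinatorics inconsistent with ring orders")

    # ---- geometry ------------------------------------------------------
    centers = np.zeros((n_sites, 3))
    row_h = (np.sqrt(3) / 2) * spacing
    z = 0.0
    prev_rho = 0.0
    adjacency: list[list[int]] = [[] for _ in range(n_sites)]
    for a, b in edges:
        adjacency[a].append(b)
        adjacency[b].append(a)
    phase = 0.0
    for r, ids in enumerate(ring_ids):
        nr = len(ids)
        rho = nr * spacing / (2 * np.pi)
        dz = np.sqrt(max(row_h ** 2 - (rho - prev_rho) ** 2, (0.3 * row_h) ** 2))
        z -= dz
        if r > 0:
            # phase continuity: align with mean angle of tip-side neighbours
            prev_set = set(ring_ids[r - 1].tolist())
            ang = []
            for idx, v in enumerate(ids):
                nb = [u for u in adjacency[v] if u in prev_set]
                if nb:
                    th = np.arctan2(centers[nb, 1].mean(), centers[nb, 0].mean())
                    ang.append(th - 2 * np.pi * idx / nr)
            phase = np.angle(np.mean(np.exp(1j * np.asarray(ang)))) if ang else phase
        th = phase + 2 * np.pi * np.arange(nr) / nr
        centers[ids] = np.column_stack(
            [rho * np.cos(th), rho * np.sin(th), np.full(nr, z)]
        )
        prev_rho = rho
    centers[apex_n] = [0.0, 0.0, 0.35 * row_h]
    centers[apex_w] = [0.0, 0.0, z - 0.75 * row_h]

    bonds = np.sort(earr, axis=1)
    centers = _spring_relax(centers, bonds, spacing, n_iter=400, pressure=0.08)
    centers -= centers.mean(axis=0)
    # the inflation pressure stretches bonds ~10%; rescale so the mean bond
    # length equals the requested lattice constant exactly
    mean_bond = float(np.mean(np.linalg.norm(
        centers[bonds[:, 0]] - centers[bonds[:, 1]], axis=1)))
    centers *= spacing / mean_bond

    axis_order = np.argsort(-centers[:, 2])  # narrow end at +z
    outward = _outward_from_centroid(centers, bonds)
    model = CapsidModel(
        centers=centers,
        orientations=_orient_sites(centers, bonds, outward),
        ring_order=ring_order,
        layer_index=np.zeros(n_sites, dtype=int),
        bonds=bonds,
        morphology="fullerene_cone",
        spacing=float(np.mean(np.linalg.norm(
            centers[bonds[:, 0]] - centers[bonds[:, 1]], axis=1))),
        seed=seed,
        params={"n_hex_target": n_hex_target, "narrow_pentamers": narrow_pentamers,
                "wide_pentamers": wide_pentamers, "axis_order_hint": int(axis_order[0])},
    )
    return model


def _outward_from_centroid(centers: np.ndarray, bonds: np.ndarray) -> np.ndarray:
    return normalize(centers - centers.mean(axis=0))


# ---------------------------------------------------------------------------
# Spiral core
# ---------------------------------------------------------------------------


def generate_spiral_core(outer_radius: float = 30.0, pitch: float = 12.0,
                         turns: float = 2.0, spacing: float = 10.0,
                         seed: int = 0) -> CapsidModel:
    """Open spiral sheet: a lattice wound ``turns`` times around the core axis.

    The generating surface is a sphere-like shell whose radius grows by
    ``pitch`` per winding (an Archimedean spiral in cross-section), truncated
    near the poles, so every full turn contributes about 4*pi of integrated
    Gaussian curvature.  Pentamers are assigned where the discrete angle
    deficit of the relaxed mesh demands them (one +pi/3 disclination each),
    so a two-turn spiral carries more than 12.
    """
    if pitch < spacing:
        raise InvalidParameterError("pitch below spacing: windings self-intersect")
    if turns < 1:
        raise InvalidParameterError("need at least one turn")
    inner = outer_radius - pitch * turns
    if inner < 2 * spacing:
        raise InvalidParameterError("outer_radius too small for the requested turns")

    def radius_at(w: float) -> float:
        return inner + pitch * w

    theta_min = np.arccos(0.93)  # truncate the poles; the sheet stays open
    n_rows = max(4, int(round(np.pi * radius_at(turns / 2) / ((np.sqrt(3) / 2) * spacing))))
    thetas = np.linspace(theta_min, np.pi - theta_min, n_rows)

    pts, row_of = [], []
    for rix, th in enumerate(thetas):
        # arc-length parameterize the winding curve at fixed polar angle
        wgrid = np.linspace(0.0, turns, 2000)
        r = radius_at(wgrid)
        x = r * np.sin(th) * np.cos(2 * np.pi * wgrid)
        y = r * np.sin(th) * np.sin(2 * np.pi * wgrid)
        zz = r * np.cos(th)
        curve = np.column_stack([x, y, np.full_like(x, 0.0)])
        seglen = np.linalg.norm(np.diff(curve, axis=0), axis=1)
        s_cum = np.concatenate([[0.0], np.cumsum(seglen)])
        n_pts = max(2, int(s_cum[-1] / spacing))
        s_targets = np.linspace(0.0, s_cum[-1], n_pts)
        if rix % 2 == 1 and n_pts > 2:  # stagger alternate rows
            s_targets = s_targets + 0.5 * (s_targets[1] - s_targets[0])
            s_targets = s_targets[s_targets <= s_cum[-1]]
        w_at = np.interp(s_targets, s_cum, wgrid)
        rr = radius_at(w_at)
        px = rr * np.sin(th) * np.cos(2 * np.pi * w_at)
        py = rr * np.sin(th) * np.sin(2 * np.pi * w_at)
        pz = rr * np.cos(th)
        for p, w in zip(np.column_stack([px, py, pz]), w_at):
            pts.append((p, w))
            row_of.append(rix)
    centers = np.asarray([p for p, _ in pts])
    wvals = np.asarray([w for _, w in pts])
    row_of = np.asarray(row_of)

    # triangulate adjacent rows by merging on the winding parameter
    edges: set[tuple[int, int]] = set()
    for rix in range(n_rows):
        idx = np.where(row_of == rix)[0]
        order = idx[np.argsort(wvals[idx])]
        for a, b in zip(order[:-1], order[1:]):
            edges.add((min(a, b), max(a, b)))
        if rix + 1 < n_rows:
            jdx = np.where(row_of == rix + 1)[0]
            jorder = jdx[np.argsort(wvals[jdx])]
            ia = ib = 0
            wa, wb = wvals[order], wvals[jorder]
            edges.add((min(order[0], jorder[0]), max(order[0], jorder[0])))
            while ia < len(order) - 1 or ib < len(jorder) - 1:
                adv_a = ib >= len(jorder) - 1 or (
                    ia < len(order) - 1 and wa[ia + 1] <= wb[ib + 1]
                )
                if adv_a:
                    ia += 1
                else:
                    ib += 1
                a, b = order[ia], jorder[ib]
                edges.add((min(a, b), max(a, b)))
                # close the triangle behind the advancing pointer
                prev = order[ia - 1] if adv_a else jorder[ib - 1]
                edges.add((min(prev, b if adv_a else a), max(prev, b if adv_a else a)))
    bonds = np.asarray(sorted(edges), dtype=int)
    centers = _spring_relax(centers, bonds, spacing, n_iter=250)

    # prune relaxed edges that strayed outside the bond window
    bl = np.linalg.norm(centers[bonds[:, 0]] - centers[bonds[:, 1]], axis=1)
    bonds = bonds[(bl >= BOND_WINDOW[0] * spacing) & (bl <= BOND_WINDOW[1] * spacing)]

    ring_order = _assign_disclinations(centers, bonds)
    outward = normalize(centers - centers.mean(axis=0))
    model = CapsidModel(
        centers=centers,
        orientations=_orient_sites(centers, bonds, outward),
        ring_order=ring_order,
        layer_index=np.zeros(len(centers), dtype=int),
        bonds=bonds,
        morphology="spiral",
        spacing=spacing,
        seed=seed,
        params={"outer_radius": outer_radius, "pitch": pitch, "turns": turns},
    )
    return model


def interior_angle_deficits(centers: np.ndarray, bonds: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Discrete angle deficit 2*pi - sum(incident angles) per vertex.

    Returns (deficits, interior_mask); a vertex is interior when its
    neighbours form a closed fan (every incident edge borders two triangles).
    """
    n = len(centers)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(map(tuple, bonds))
    deficits = np.zeros(n)
    interior = np.zeros(n, dtype=bool)
    for v in range(n):
        nbrs = list(g.neighbors(v))
        if len(nbrs) < 3:
            continue
        # order neighbours around v by angle in the local tangent plane
        rel = centers[nbrs] - centers[v]
        _, _, vt = np.linalg.svd(rel - rel.mean(axis=0))
        zax = vt[2]
        xax = rel[0] - np.dot(rel[0], zax) * zax
        xax /= np.linalg.norm(xax)
        yax = np.cross(zax, xax)
        ang = np.arctan2(rel @ yax, rel @ xax)
        order = np.argsort(ang)
        ring = [nbrs[o] for o in order]
        closed_fan = all(g.has_edge(ring[i], ring[(i + 1) % len(ring)])
                         for i in range(len(ring)))
        if not closed_fan:
            continue
        total = 0.0
        for i in range(len(ring)):
            a = centers[ring[i]] - centers[v]
            b = centers[ring[(i + 1) % len(ring)]] - centers[v]
            cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
            total += np.arccos(np.clip(cosang, -1.0, 1.0))
        deficits[v] = 2 * np.pi - total
        interior[v] = True
    return deficits, interior


def _assign_disclinations(centers: np.ndarray, bonds: np.ndarray) -> np.ndarray:
    """Mark interior vertices as pentamers where angle deficit concentrates."""
    deficits, interior = interior_angle_deficits(centers, bonds)
    total = deficits[interior].sum()
    n_pent = max(0, int(round(total / (np.pi / 3))))
    ring_order = np.full(len(centers), 6, dtype=int)
    adjacency = {tuple(b) for b in bonds} | {tuple(b[::-1]) for b in bonds}
    order = np.argsort(-deficits)
    placed: list[int] = []
    for v in order:
        if len(placed) >= n_pent:
            break
        if not interior[v] or deficits[v] <= np.pi / 12:
            continue
        if any((v, p) in adjacency for p in placed):
            continue
        placed.append(int(v))
    ring_order[placed] = 5
    return ring_order


# ---------------------------------------------------------------------------
# Nested cores
# ---------------------------------------------------------------------------


def generate_nested_cores(layer_specs: list[dict]) -> CapsidModel:
    """Union of independently generated concentric layers (no inter-layer bonds).

    Each spec is a dict with a ``morphology`` key (``closed_polyhedron`` or
    ``spiral``) plus that generator's keyword arguments; radii must be
    strictly decreasing with at least one lattice spacing of clearance.
    """
    if not layer_specs:
        raise InvalidParameterError("need at least one layer spec")
    layers: list[CapsidModel] = []
    for spec in layer_specs:
        spec = dict(spec)
        morph = spec.pop("morphology")
        if morph == "closed_polyhedron":
            layers.append(generate_closed_shell(**spec))
        elif morph == "spiral":
            layers.append(generate_spiral_core(**spec))
        else:
            raise InvalidParameterError(f"unsupported layer morphology {morph!r}")

    radii = [np.linalg.norm(m.centers - m.centers.mean(axis=0), axis=1).max()
             for m in layers]
    if len(layers) > 1 and not all(a > b for a, b in zip(radii, radii[1:])):
        raise InvalidParameterError("layer radii must be strictly decreasing")

    centers = np.vstack([m.centers for m in layers])
    orientations = np.concatenate([m.orientations for m in layers])
    ring_order = np.concatenate([m.ring_order for m in layers])
    layer_index = np.concatenate(
        [np.full(m.n_sites, li, dtype=int) for li, m in enumerate(layers)]
    )
    offset, bonds = 0, []
    for m in layers:
        bonds.append(m.bonds + offset)
        offset += m.n_sites
    bonds = np.vstack(bonds)

    spacing = float(max(m.spacing for m in layers))
    for la, lb in zip(layers, layers[1:]):
        dmin = cKDTree(la.centers).query(lb.centers)[0].min()
        if dmin < spacing:
            raise InvalidParameterError(
                f"layers overlap: clearance {dmin:.2f} nm below one spacing"
            )

    model = CapsidModel(
        centers=centers,
        orientations=orientations,
        ring_order=ring_order,
        layer_index=layer_index,
        bonds=bonds,
        morphology="nested",
        spacing=spacing,
        seed=None,
        params={"n_layers": len(layers),
                "layer_spacings": [m.spacing for m in layers]},
    )
    return model


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------


def pentamer_census(model: CapsidModel) -> dict:
    """Per-component pentamer/hexamer/boundary counts plus an Euler check.

    A component is closed when every bond borders exactly two triangles; for
    closed components V - E + F = 2 must hold (F counted as mesh triangles).
    Boundary sites are sites with coordination below their ring order.
    """
    g = model.graph()
    triangles_per_edge: dict[tuple[int, int], int] = {}
    tri_count_per_comp: dict[int, int] = {}
    comp_of = {}
    comps = list(nx.connected_components(g))
    for ci, comp in enumerate(comps):
        for v in comp:
            comp_of[v] = ci
    n_tri = np.zeros(len(comps), dtype=int)
    adj = {v: set(g.neighbors(v)) for v in g.nodes}
    for a, b in g.edges:
        common = adj[a] & adj[b]
        triangles_per_edge[(min(a, b), max(a, b))] = len(common)
        for c in common:
            if c > max(a, b):
                n_tri[comp_of[a]] += 1

    components = []
    euler_ok = True
    degree = dict(g.degree)
    for ci, comp in enumerate(comps):
        comp = sorted(comp)
        ro = model.ring_order[comp]
        deg = np.array([degree[v] for v in comp])
        edges_in = [e for e in g.edges(comp) if comp_of[e[0]] == ci]
        closed = len(edges_in) > 0 and all(
            triangles_per_edge[(min(a, b), max(a, b))] == 2 for a, b in edges_in
        )
        v_cnt, e_cnt, f_cnt = len(comp), len(edges_in), int(n_tri[ci])
        comp_euler_ok = (not closed) or (v_cnt - e_cnt + f_cnt == 2)
        euler_ok &= comp_euler_ok
        layer = int(np.bincount(model.layer_index[comp]).argmax())
        components.append({
            "component": ci,
            "layer_index": layer,
            "n_sites": v_cnt,
            "n_pentamers": int((ro == 5).sum()),
            "n_hexamers": int((ro == 6).sum()),
            "n_boundary": int((deg < ro).sum()),
            "closed": bool(closed),
            "euler_ok": bool(comp_euler_ok),
        })
    return {
        "components": components,
        "n_pentamers": int((model.ring_order == 5).sum()),
        "n_hexamers": int((model.ring_order == 6).sum()),
        "euler_ok": bool(euler_ok),
    }


def total_angle_deficit(model: CapsidModel) -> float:
    """Total disclination content: pi/3 per pentamer by convention."""
    return (np.pi / 3) * float((model.ring_order == 5).sum())
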