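"""End-to-end seeded demo runs and report aggregation.

A demo run generates a ground-truth capsid model, renders and degrades a
synthetic tomogram, seeds and aligns particles, filters them, averages with
the profile's symmetry, measures gold-standard FSC and sharpens, runs the
lattice analysis (spacing, hexamer counts, pentamer detection and
verification, recovery class), and writes all artifacts plus a manifest.

Per-stage seeds derive from the global seed by fixed offsets (documented in
``STAGE_SEED_OFFSETS``) so every stochastic step is reproducible and
independent.
"""

from __future__ import annotations

import json
import logging
import os
import sys
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, capsid_models as cm, lattice_tools as lt
from . import sta_core as sc, tomo_sim as ts

log = logging.getLogger("capsidlattice")

STAGE_SEED_OFFSETS = {
    "model": 11,
    "noise": 23,
    "seeding": 37,
    "alignment": 53,
    "fsc": 71,
}

PROFILES = ("immature", "mature_closed", "mature_spiral", "mature_nested")


@dataclass
class RunConfig:
    """All stage parameters of a demo run (desk-scale defaults).

    The defaults use small virus models and coarse (bin4-equivalent,
    5.4 Å voxel) sampling so a full profile runs in minutes while keeping
    the study conditions: immature shells at 8 nm spacing with one large
    gap, mature lattices at 10 nm spacing, a ±60° wedge and SNR 0.5.
    """

    seed: int = 1
    voxel_size: float = 5.4  # Å
    box: int = 32
    tilt_range_deg: tuple[float, float] = (-60.0, 60.0)
    snr: float = 0.5
    # immature profile
    immature_radius_nm: float = 24.0
    immature_spacing_nm: float = 8.0
    gap_fraction: float = 0.15
    n_small_defects: int = 2
    # mature profiles
    mature_spacing_nm: float = 10.0
    closed_hk: tuple[int, int] = (2, 1)
    closed_radius_nm: float = 22.0
    spiral_outer_nm: float = 34.0
    spiral_pitch_nm: float = 12.0
    spiral_turns: float = 1.5
    nested_layers: tuple = (
        {"morphology": "closed_polyhedron", "h": 2, "k": 1, "radius": 28.0},
        {"morphology": "closed_polyhedron", "h": 1, "k": 1, "radius": 13.0},
    )
    # alignment
    angular_range_deg: tuple[float, ...] = (16.0, 8.0)
    angular_step_deg: tuple[float, ...] = (8.0, 4.0)
    lowpass_A: float = 40.0
    # with one seed per annotated unit there is no junk-particle population
    # for a CCC cutoff to remove; lattice-rule filtering handles outliers
    ccc_keep_fraction: float = 1.0
    # pentamer verification
    pentamer_ccc_threshold: float = 0.25

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1009 + STAGE_SEED_OFFSETS[stage]) % (2 ** 31)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tilt_range_deg", "angular_range_deg", "angular_step_deg",
                    "closed_hk", "nested_layers"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self))), fh,
                           sort_keys=True)


def _build_model(profile: str, config: RunConfig) -> cm.CapsidModel:
    seed = config.stage_seed("model")
    if profile == "immature":
        return cm.generate_immature_shell(
            radius=config.immature_radius_nm, spacing=config.immature_spacing_nm,
            gap_fraction=config.gap_fraction,
            n_small_defects=config.n_small_defects, seed=seed)
    if profile == "mature_closed":
        h, k = config.closed_hk
        return cm.generate_closed_shell(h, k, radius=config.closed_radius_nm)
    if profile == "mature_spiral":
        return cm.generate_spiral_core(
            outer_radius=config.spiral_outer_nm, pitch=config.spiral_pitch_nm,
            turns=config.spiral_turns, spacing=config.mature_spacing_nm,
            seed=seed)
    if profile == "mature_nested":
        return cm.generate_nested_cores([dict(s) for s in config.nested_layers])
    raise ValueError(f"unknown profile {profile!r}; choose from {PROFILES}")


def _render_profile(profile: str, model: cm.CapsidModel, config: RunConfig,
                    pad_vox: int = 0
                    ) -> tuple[ts.DensityVolume, ts.StructureTemplate,
                               ts.StructureTemplate]:
    """Render hexamer sites with the unit template and, for mature models,
    pentamer sites with the five-fold template; immature pentamer-coordinated
    positions stay empty holes."""
    kind = "immature" if profile == "immature" else "mature"
    spacing = (config.immature_spacing_nm if kind == "immature"
               else config.mature_spacing_nm)
    unit = ts.make_template(kind, spacing=spacing,
                            voxel_size=config.voxel_size, box=24)
    pent = ts.make_template("pentamer", spacing=spacing,
                            voxel_size=config.voxel_size, box=24)
    centroid = model.centers.mean(axis=0)
    hex_sel = model.ring_order == 6
    hex_model = _subset_model(model, hex_sel)
    # pad so every lattice site keeps a half-box extraction margin
    centers_vox = model.centers * ts.ANGSTROM_PER_NM / config.voxel_size
    extent = 2.0 * (np.abs(centers_vox - centers_vox.mean(axis=0)).max()
                    + unit.density.shape[0] / 2.0 + pad_vox + 2)
    n = int(np.ceil(extent / 2.0) * 2)
    vol = ts.render_capsid(hex_model, unit, box_shape=(n, n, n),
                           include_membrane=(profile == "immature"),
                           include_rnp=(profile == "immature"),
                           center_on=centroid)
    if kind == "mature" and (~hex_sel).any():
        pent_model = _subset_model(model, ~hex_sel)
        pvol = ts.render_capsid(pent_model, pent, box_shape=vol.shape,
                                center_on=centroid)
        vol = vol.copy_with(vol.values + pvol.values)
    return vol, unit, pent


def _subset_model(model: cm.CapsidModel, sel: np.ndarray) -> cm.CapsidModel:
    return cm.CapsidModel(
        centers=model.centers[sel], orientations=model.orientations[sel],
        ring_order=model.ring_order[sel], layer_index=model.layer_index[sel],
        bonds=np.empty((0, 2)), morphology=model.morphology,
        spacing=model.spacing, membrane_radius=model.membrane_radius)


def model_to_voxels(model_nm: np.ndarray, model: cm.CapsidModel,
                    vol: ts.DensityVolume) -> np.ndarray:
    """Model-space (nm) -> volume voxel coordinates (x, y, z)."""
    centroid = model.centers.mean(axis=0)
    half = np.array([vol.shape[2], vol.shape[1], vol.shape[0]]) / 2.0
    return (model_nm - centroid) * ts.ANGSTROM_PER_NM / vol.voxel_size + half


def voxels_to_model(vox: np.ndarray, model: cm.CapsidModel,
                    vol: ts.DensityVolume) -> np.ndarray:
    centroid = model.centers.mean(axis=0)
    half = np.array([vol.shape[2], vol.shape[1], vol.shape[0]]) / 2.0
    return (vox - half) * vol.voxel_size / ts.ANGSTROM_PER_NM + centroid


def run_demo(profile: str, config: RunConfig | None = None,
             out_dir: str = "demo_out", verbose: bool = False) -> dict:
    """Full seeded pipeline for one synthetic virus; returns the summary."""
    config = config or RunConfig()
    os.makedirs(out_dir, exist_ok=True)
    _setup_logging(out_dir, verbose)
    t_start = time.time()
    stage = "generate model"
    try:
        summary = _run_demo_stages(profile, config, out_dir, verbose)
    except Exception as exc:
        log.error("stage %r failed: %s", _CURRENT_STAGE[0], exc)
        raise RuntimeError(f"demo aborted in stage {_CURRENT_STAGE[0]!r}: {exc}"
                           ) from exc
    summary["runtime_s"] = round(time.time() - t_start, 2)
    manifest = {
        "package_version": __version__,
        "profile": profile,
        "seed": config.seed,
        "stage_seeds": {k: config.stage_seed(k) for k in STAGE_SEED_OFFSETS},
        "config": json.loads(json.dumps(asdict(config))),
        "summary": summary,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return summary


_CURRENT_STAGE = ["init"]


def _stage(name: str) -> None:
    _CURRENT_STAGE[0] = name
    log.info("stage: %s", name)


def _run_demo_stages(profile: str, config: RunConfig, out_dir: str,
                     verbose: bool) -> dict:
    spacing_nm = (config.immature_spacing_nm if profile == "immature"
                  else config.mature_spacing_nm)
    symmetry = 6

    _stage("generate model")
    model = _build_model(profile, config)
    model.to_tsv(os.path.join(out_dir, "ground_truth.tsv"))
    census = cm.pentamer_census(model)

    _stage("render and degrade volume")
    vol, unit_template, pent_template = _render_profile(profile, model, config,
                                                        pad_vox=config.box // 2)
    wedge = ts.ImagingParams(tilt_range_deg=config.tilt_range_deg,
                             snr=config.snr, seed=config.stage_seed("noise"))
    degraded = ts.apply_missing_wedge(vol, wedge)
    lattice_mask = vol.values > 0.1 * vol.values.max()
    degraded = ts.add_noise(degraded, snr=config.snr, mask=lattice_mask,
                            seed=config.stage_seed("noise"))
    degraded.write_mrc(os.path.join(out_dir, "tomogram.mrc"))

    _stage("seed particles (simulated surface picks)")
    # Simulated manual annotation of the lattice layer: picked positions are
    # the lattice sites jittered by ~0.15 x spacing, mirroring how cores
    # are picked on the CA layer in tomograms.  Orientations carry no
    # ground-truth information: z points along the outward direction from
    # the fitted pick sphere and the in-plane angle is random, so the
    # alignment still has to solve the full orientation and refine the
    # position.  (A blind spherical-seed bootstrap is implemented in
    # sta_core.seed_on_sphere but needs far larger particle counts than
    # this desk-scale demo to break translational symmetry.)
    rng = np.random.default_rng(config.stage_seed("seeding"))
    spacing_vox = spacing_nm * ts.ANGSTROM_PER_NM / config.voxel_size
    # hexamers are what gets picked; pentamer-coordinated positions must be
    # recovered downstream from the hexamer arrangement
    hex_centers = model.centers[model.ring_order == 6]
    picks_nm = hex_centers + rng.normal(0.0, 0.15 * spacing_nm,
                                        hex_centers.shape)
    picks_vox = model_to_voxels(picks_nm, model, vol)
    centre_fit, _ = sc._fit_sphere(picks_vox)
    half = config.box // 2
    shape_xyz = np.array([vol.shape[2], vol.shape[1], vol.shape[0]])
    particles = []
    for pick in picks_vox:
        if np.any(pick - half < 0) or np.any(pick + half > shape_xyz):
            continue
        z = pick - centre_fit
        z = z / np.linalg.norm(z)
        a = rng.uniform(0, 2 * np.pi)
        Rz = np.array([[np.cos(a), -np.sin(a), 0.0],
                       [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]])
        from ._geom import frame_from_z
        particles.append(sc.Particle(position=pick,
                                     orientation=frame_from_z(z) @ Rz))
    if not particles:
        raise RuntimeError("no particle seeds fit inside the volume")

    _stage("extract subtomograms")
    subtomos = ts.extract_subtomograms(
        degraded, [p.position for p in particles], box=config.box, wedge=wedge)
    for i, p in enumerate(particles):
        p.source_index = i
        p.virus_id = f"{profile}_v0"

    _stage("align particles")
    # Two careful passes from the picked poses.  The initial reference is
    # averaged at the pick poses themselves (positionally sharp, in-plane
    # smeared); per-particle localization against it is near the
    # information limit of one box at this SNR, and further self-consistent
    # iteration only compounds reference blur, so the schedule stops after
    # a local refinement pass.
    box = config.box
    mask_ref = sc.soft_cylindrical_mask(box, 0.45 * box, 0.30 * box)
    lp_frac = min(1.0, 2.0 * config.voxel_size / config.lowpass_A)
    sc.assign_half_sets(particles)
    refs = {}
    for hs in (1, 2):
        half_parts = [p for p in particles if p.half_set == hs] or particles
        refs[hs], _ = sc.average_particles(subtomos, half_parts, symmetry)
    id_grid = [np.eye(3)]
    tilt_grid = sc._angular_grid(config.angular_range_deg[-1],
                                 config.angular_step_deg[-1],
                                 inplane_range_deg=180.0 / symmetry,
                                 inplane_step_deg=config.angular_step_deg[-1])
    for pass_n, grid in enumerate((id_grid, tilt_grid)):
        for p in particles:
            R, shift, score = sc.align_to_reference(
                sc.p_box(subtomos, p).astype(float), refs[p.half_set].values,
                p.orientation, grid, mask_ref, wedge, lp_frac,
                max_shift=0.25 * spacing_vox)  # trust region around the pick
            p.orientation = R
            p.position = subtomos.positions[p.source_index] + shift
            p.ccc = score
        if pass_n == 0:  # rebuild the reference from refined positions
            for hs in (1, 2):
                half_parts = [p for p in particles if p.half_set == hs] \
                    or particles
                refs[hs], _ = sc.average_particles(subtomos, half_parts,
                                                   symmetry)
    avg = refs[1]

    _stage("filter particles")
    # one seed per pick: only genuinely coincident detections are duplicates
    particles = sc.remove_duplicates(particles, min_dist=0.3 * spacing_vox)
    retained = [p for p in particles if p.retained]
    sc.threshold_ccc(retained, keep_fraction=config.ccc_keep_fraction)
    sc.write_star(particles, os.path.join(out_dir, "particles.star"))
    sc.write_tsv(particles, os.path.join(out_dir, "particles.tsv"))

    _stage("average and post-process")
    final_avg, coverage = sc.average_particles(subtomos,
                                               [p for p in particles if p.retained],
                                               symmetry_order=symmetry)
    final_avg.write_mrc(os.path.join(out_dir, "average.mrc"))
    halves = {1: [], 2: []}
    for p in particles:
        if p.retained:
            halves[p.half_set].append(p)
    h1, _ = sc.average_particles(subtomos, halves[1], symmetry_order=symmetry)
    h2, _ = sc.average_particles(subtomos, halves[2], symmetry_order=symmetry)
    mask3d = sc.soft_spherical_mask(config.box, 0.45 * config.box)
    fsc = sc.gold_standard_fsc(h1, h2, mask=mask3d,
                               seed=config.stage_seed("fsc"))
    fsc.to_tsv(os.path.join(out_dir, "fsc.tsv"))
    resolution = fsc.resolution_at(0.143)
    sharpened, b_used = sc.sharpen_map(final_avg, fsc, b_factor="auto")
    sharpened.write_mrc(os.path.join(out_dir, "average_sharpened.mrc"))

    _stage("lattice analysis")
    kept = [p for p in particles if p.retained]
    pos_nm = voxels_to_model(np.array([p.position for p in kept]), model, vol)
    normals = np.array([p.orientation[:, 2] for p in kept])
    graph = lt.build_graph(pos_nm, 0.8 * spacing_nm, 1.2 * spacing_nm)
    graph.normals = normals
    graph.virus_ids = np.array([p.virus_id for p in kept])
    stats = lt.spacing_stats(graph)
    det_graph = lt.detection_graph(pos_nm, spacing_nm, normals)
    candidates = lt.find_pentamer_candidates(det_graph)
    cand_vox = [model_to_voxels(c.position, model, vol) for c in candidates]
    verified = []
    if candidates:
        vox_cands = []
        for c, v in zip(candidates, cand_vox):
            c2 = lt.PentamerCandidate(position=v, normal=c.normal, ring=c.ring)
            vox_cands.append(c2)
        vox_cands = lt.verify_pentamer(
            degraded, vox_cands, pent_template.density,
            threshold=config.pentamer_ccc_threshold, box=24,
            nm_per_voxel=1.0, wedge_params=wedge,
            spacing_vox=spacing_vox,
            hexamer_template=unit_template.density)
        for c, cv in zip(candidates, vox_cands):
            c.verified, c.ccc = cv.verified, cv.ccc
        verified = [bool(c.verified) for c in candidates]

    table = sc.particles_to_frame(kept)
    table["virus_id"] = [p.virus_id for p in kept]
    counts = lt.count_hexamers(table)
    truth_hex = model.centers[model.ring_order == 6]
    recovery = lt.classify_recovery(pos_nm, truth_hex, spacing_nm)
    lt.export_lattice_map(table, os.path.join(out_dir, "lattice_map.cmm"),
                          out_format="cmm")
    lt.export_lattice_map(table, os.path.join(out_dir, "lattice_map.tsv"),
                          out_format="tsv")

    _stage("summaries")
    summary = {
        "profile": profile,
        "n_truth_sites": int(model.n_sites),
        "n_truth_hexamers": int(census["n_hexamers"]),
        "n_truth_pentamers": int(census["n_pentamers"]),
        "n_particles_retained": len(kept),
        "spacing_mean_nm": round(stats["mean"], 3),
        "spacing_sd_nm": round(stats["sd"], 3),
        "hexamer_count": int(sum(counts["per_virus"].values())),
        "n_pentamer_candidates": len(candidates),
        "n_pentamers_verified": int(sum(verified)),
        "pentamer_verdicts_all_true": bool(verified and all(verified)),
        "pentamer_verdicts_all_false": bool(not any(verified)),
        "recovered_fraction": round(recovery["recovered_fraction"], 4),
        "recovery_class": recovery["class"],
        "resolution_A_at_0143": round(resolution, 2),
        "sharpening_B_A2": round(b_used, 1),
        "fourier_coverage": round(coverage, 4),
    }
    pd.DataFrame([summary]).to_csv(os.path.join(out_dir, "summary.tsv"),
                                   sep="\t", index=False)
    return summary


def report(run_dirs: list[str], out_path: str | None = None) -> pd.DataFrame:
    """Combine per-run summaries into one table (one row per virus/run)."""
    if not run_dirs:
        raise ValueError("no run directories given")
    rows = []
    for d in run_dirs:
        manifest_path = os.path.join(d, "manifest.json")
        if not os.path.exists(manifest_path):
            raise FileNotFoundError(f"missing manifest in {d}")
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        row = dict(manifest["summary"])
        row["run_dir"] = d
        row["seed"] = manifest["seed"]
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_path:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def _setup_logging(out_dir: str, verbose: bool) -> None:
    log.setLevel(logging.DEBUG if verbose else logging.INFO)
    log.handlers = [h for h in log.handlers
                    if not isinstance(h, (logging.StreamHandler,
                                          logging.FileHandler))]
    fmt = logging.Formatter("%(asctime)s [%(levelname)s] %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    fh = logging.FileHandler(os.path.join(out_dir, "run.log"))
    fh.setFormatter(fmt)
    log.addHandler(sh)
    log.addHandler(fh)
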