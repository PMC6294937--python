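# Output file schemas

All artifacts are plain text except MRC2014 density maps (mode 2 float).

## Ground-truth model TSV (`capsid_models.CapsidModel.to_tsv`)

Header lines start with `#`; the second line is a JSON record of
`morphology`, `spacing` (nm), `seed`, `membrane_radius` (nm), and the
generator parameters. Data columns (tab-separated):

| column | meaning |
| --- | --- |
| `x y z` | site centre, nm |
| `qw qx qy qz` | unit quaternion of the site frame (w,x,y,z; z column of the frame is the outward normal) |
| `ring_order` | 6 = hexamer, 5 = pentamer |
| `layer_index` | 0-based shell layer |

Bond rows follow as `#B <i> <j>` (site indices).

## Particle tables (`sta_core.write_star` / `write_tsv`)

STAR block `particles` (tags `_capsid*`) or an equivalent TSV with columns:

| column | meaning |
| --- | --- |
| `x y z` | particle position, voxels (0-based, real-valued) |
| `rot tilt psi` | intrinsic ZYZ Euler angles, degrees (reference → particle) |
| `ccc` | constrained cross-correlation at the aligned pose, [-1, 1] |
| `half_set` | 1 or 2 (gold-standard split) |
| `virus_id` | string label of the source virus |
| `flags` | `;`-joined labels (`removed_duplicate`, `low_ccc`, `false_positive`); empty = retained |

## FSC curves (`FscCurve.to_tsv`)

| column | meaning |
| --- | --- |
| `freq_invA` | shell-centre spatial frequency, 1/Å |
| `fsc` | masked half-map FSC |
| `corrected_fsc` | phase-randomization-corrected FSC (when computed) |

## Lattice maps

`*.cmm`: Chimera XML marker set; one `<marker>` per retained particle with
`x y z` (same units as the input table), `r g b` colour (per-virus CCC
scale, min = red to max = green), `radius`, and the virus id in `note`.

`*.tsv`: the particle table plus `color_r color_g color_b` columns;
re-importable with `lattice_tools.read_lattice_map`.

## Demo summary (`summary.tsv`, one row per run)

| column | meaning |
| --- | --- |
| `profile` | demo profile name |
| `n_truth_sites / n_truth_hexamers / n_truth_pentamers` | generator ground truth |
| `n_particles_retained` | particles with no flags after filtering |
| `spacing_mean_nm / spacing_sd_nm` | lattice-graph edge statistics |
| `hexamer_count` | retained-particle census (flagged excluded) |
| `n_pentamer_candidates` | detected pentamer-coordinated positions |
| `n_pentamers_verified` | candidates whose density verification passed |
| `pentamer_verdicts_all_true / _all_false` | the occupancy contrast summary |
| `recovered_fraction / recovery_class` | fraction of truth sites matched within 0.5 × spacing; fully ≥ 0.95, nearly ≥ 0.80, else partially |
| `resolution_A_at_0143` | corrected-FSC resolution at the 0.143 cutoff, Å |
| `sharpening_B_A2` | Guinier-fit B factor applied, Å² |
| `fourier_coverage` | fraction of Fourier voxels with wedge coverage in the average |
| `runtime_s` | wall-clock runtime |

`manifest.json` records the package version, profile, global seed, derived
per-stage seeds, the full run configuration, and the summary.

## Acceptance results (`results/acceptance.json`)

One object per target id with `value` (the measured quantity) and `n` (the
problem size used, here the site count of the generated model).
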