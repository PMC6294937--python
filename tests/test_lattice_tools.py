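"""Lattice-graph analysis: spacing, pentamer detection, counting, curvature."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from capsidlattice import capsid_models as cm
from capsidlattice import lattice_tools as lt

from conftest import flat_hex_patch


def hexamer_graph(model: cm.CapsidModel, layer: int | None = None
                  ) -> lt.LatticeGraph:
    sel = model.ring_order == 6
    if layer is not None:
        sel &= model.layer_index == layer
        spacing = model.params["layer_spacings"][layer]
    else:
        spacing = model.spacing
    return lt.detection_graph(model.centers[sel], spacing,
                              model.normals()[sel])


class TestBuildGraph:
    def test_interior_coordination_six_on_flat_patch(self):
        pts = flat_hex_patch(8, 10.0)
        g = lt.build_graph(pts, 8.0, 12.0)
        coord = g.coordination
        interior = []
        for i, p in enumerate(pts):
            d = np.linalg.norm(pts - p, axis=1)
            if (d[d > 1e-9] < 12.0).sum() == 6:
                interior.append(i)
        assert len(interior) > 10
        assert (coord[interior] == 6).all()

    def test_window_excludes_second_shell(self):
        # second-shell neighbours sit at sqrt(3) x spacing > 1.2 x spacing
        pts = flat_hex_patch(6, 10.0)
        g = lt.build_graph(pts, 8.0, 12.0)
        lengths = g.edge_lengths()
        assert lengths.max() < np.sqrt(3) * 10.0 * 0.999
        assert lengths.max() <= 12.0

    def test_binned_equals_brute_force(self, rng):
        pts = rng.uniform(0, 100, (500, 3))
        brute = lt.build_graph(pts, 5.0, 12.0, method="brute")
        binned = lt.build_graph(pts, 5.0, 12.0, method="binned")
        assert np.array_equal(brute.edges, binned.edges)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            lt.build_graph(np.zeros((3, 3)), 5.0, 5.0)


class TestSpacingStats:
    def test_generated_lattice_recovers_spacing(self, shell_t7):
        # full lattice graph: the mean neighbour distance is the generator
        # spacing (hexamer-only graphs run slightly high because the short
        # hexamer-pentamer bonds are excluded)
        g = lt.build_graph(shell_t7.centers, 0.8 * shell_t7.spacing,
                           1.2 * shell_t7.spacing)
        stats = lt.spacing_stats(g)
        assert abs(stats["mean"] - shell_t7.spacing) / shell_t7.spacing < 0.01

    def test_jittered_positions_unbiased(self):
        rng = np.random.default_rng(0)
        means = []
        for seed in range(10):
            pts = flat_hex_patch(7, 10.0)
            pts = pts + np.random.default_rng(seed).normal(0, 0.3, pts.shape)
            g = lt.build_graph(pts, 8.0, 12.0)
            means.append(lt.spacing_stats(g)["mean"])
        pooled = np.mean(means)
        # jitter inflates edge lengths only to second order
        assert abs(pooled - 10.0) < 2 * 0.3 / np.sqrt(len(means))

    def test_empty_graph_rejected(self):
        g = lt.build_graph(np.array([[0.0, 0, 0], [100.0, 0, 0]]), 5.0, 12.0)
        with pytest.raises(ValueError):
            lt.spacing_stats(g)


class TestPentamerDetection:
    def test_closed_shell_yields_twelve(self, shell_t7):
        g = hexamer_graph(shell_t7)
        cands = lt.find_pentamer_candidates(g)
        assert len(cands) == 12
        truth = shell_t7.centers[shell_t7.ring_order == 5]
        d, _ = cKDTree(truth).query([c.position for c in cands])
        assert d.max() < 0.5 * shell_t7.spacing

    def test_cone_yields_twelve(self, cone_model):
        g = hexamer_graph(cone_model)
        cands = lt.find_pentamer_candidates(g)
        assert len(cands) == 12
        truth = cone_model.centers[cone_model.ring_order == 5]
        d, _ = cKDTree(truth).query([c.position for c in cands])
        assert d.max() < 0.5 * cone_model.spacing

    def test_flat_sheet_yields_none(self):
        g = lt.build_graph(flat_hex_patch(8, 10.0), 8.0, 12.0)
        assert lt.find_pentamer_candidates(g) == []

    def test_nested_shells_yield_twelve_per_layer(self, nested_model):
        total = 0
        for layer in (0, 1):
            g = hexamer_graph(nested_model, layer=layer)
            total += len(lt.find_pentamer_candidates(g))
        assert total == 24

    def test_jitter_robustness(self, shell_t7):
        # positional jitter sigma = 0.05 x spacing leaves the census intact
        sel = shell_t7.ring_order == 6
        base = shell_t7.centers[sel]
        spacing = shell_t7.spacing
        for seed in range(10):
            pts = base + np.random.default_rng(seed).normal(
                0, 0.05 * spacing, base.shape)
            g = lt.detection_graph(pts, spacing, shell_t7.normals()[sel])
            assert len(lt.find_pentamer_candidates(g)) == 12

    def test_node_order_invariance(self, shell_t3):
        sel = shell_t3.ring_order == 6
        pts = shell_t3.centers[sel]
        spacing = shell_t3.spacing
        g1 = lt.build_graph(pts, 0.8 * spacing, 1.2 * spacing)
        perm = np.random.default_rng(3).permutation(len(pts))
        g2 = lt.build_graph(pts[perm], 0.8 * spacing, 1.2 * spacing)
        c1 = sorted(tuple(np.round(c.position, 4))
                    for c in lt.find_pentamer_candidates(g1))
        c2 = sorted(tuple(np.round(c.position, 4))
                    for c in lt.find_pentamer_candidates(g2))
        assert c1 == c2


class TestVerifyPentamer:
    def _setup(self):
        from capsidlattice import tomo_sim as ts
        pent = ts.make_template("pentamer", spacing=10.0, box=24)
        vol = ts.DensityVolume(np.zeros((48, 48, 48), np.float32), 5.4)
        cand = lt.PentamerCandidate(position=np.array([24.0, 24.0, 24.0]),
                                    normal=np.array([0.0, 0.0, 1.0]),
                                    ring=(0, 1, 2, 3, 4))
        return pent, vol, cand

    def test_degenerate_threshold_all_true(self):
        pent, vol, cand = self._setup()
        out = lt.verify_pentamer(vol, [cand], pent.density, threshold=-1,
                                 box=24, nm_per_voxel=1.0, spacing_vox=18.5)
        assert out[0].verified is True

    def test_zero_norm_template_rejected(self):
        from capsidlattice import tomo_sim as ts
        _, vol, cand = self._setup()
        empty = ts.DensityVolume(np.zeros((24,) * 3, np.float32), 5.4)
        with pytest.raises(ValueError):
            lt.verify_pentamer(vol, [cand], empty, box=24, nm_per_voxel=1.0)

    def test_empty_candidate_list(self):
        pent, vol, _ = self._setup()
        assert lt.verify_pentamer(vol, [], pent.density) == []

    def test_rendered_pentamer_verifies_true_hole_false(self):
        # noise-free sanity: a box containing the pentamer density verifies
        # true, an empty region verifies false
        from capsidlattice import tomo_sim as ts
        pent = ts.make_template("pentamer", spacing=10.0, box=24)
        vol_values = np.zeros((48, 48, 48), np.float32)
        vol_values[6:30, 6:30, 6:30] = pent.values  # unit centred at 18
        vol = ts.DensityVolume(vol_values, 5.4)
        at_unit = lt.PentamerCandidate(position=np.array([18.0, 18.0, 18.0]),
                                       normal=np.array([0.0, 0.0, 1.0]),
                                       ring=())
        in_void = lt.PentamerCandidate(position=np.array([38.0, 38.0, 38.0]),
                                       normal=np.array([0.0, 0.0, 1.0]),
                                       ring=())
        out = lt.verify_pentamer(vol, [at_unit, in_void], pent.density,
                                 threshold=0.25, box=24, nm_per_voxel=1.0,
                                 spacing_vox=18.5)
        assert out[0].verified is True
        assert out[1].verified is False


class TestCounting:
    def _table(self, n, virus="v0", flags=None):
        return pd.DataFrame({
            "x": np.arange(n, dtype=float), "y": 0.0, "z": 0.0,
            "virus_id": virus,
            "flags": flags if flags is not None else [""] * n,
        })

    def test_exact_count(self):
        out = lt.count_hexamers(self._table(350))
        assert out["per_virus"]["v0"] == 350

    def test_flagged_excluded(self):
        flags = ["low_ccc"] * 10 + [""] * 340
        out = lt.count_hexamers(self._table(350, flags=flags))
        assert out["per_virus"]["v0"] == 340

    def test_group_summary_matches_direct_recomputation(self):
        df = pd.concat([self._table(100, "a"), self._table(120, "b"),
                        self._table(90, "c")])
        df["group"] = ["g1"] * 220 + ["g2"] * 90
        out = lt.count_hexamers(df, group_by="group")
        assert out["groups"]["g1"]["mean"] == pytest.approx(110.0)
        assert out["groups"]["g2"]["n_viruses"] == 1


class TestFalsePositiveFilter:
    def _clean_lattice(self, shell):
        pos = shell.centers
        return pd.DataFrame({"x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
                             "virus_id": "v0", "ccc": 0.8, "flags": ""})

    def test_planted_outlier_in_bilayer_flagged(self, shell_t7):
        df = self._clean_lattice(shell_t7)
        membrane_r = 30.0
        outlier = pd.DataFrame({"x": [membrane_r], "y": [0.0], "z": [0.0],
                                "virus_id": "v0", "ccc": [0.8], "flags": [""]})
        df = pd.concat([df, outlier], ignore_index=True)
        out = lt.filter_false_positives(
            df, membrane_center=np.zeros(3), membrane_radius=membrane_r,
            layer_window=(18.0, 26.0), lattice_window=(8.0, 15.0),
            min_neighbor_support=2)
        flagged = out["flags"].str.contains("false_positive")
        assert flagged.iloc[-1]
        assert not flagged.iloc[:-1].any()

    def test_clean_lattice_unflagged(self, shell_t7):
        df = self._clean_lattice(shell_t7)
        out = lt.filter_false_positives(
            df, membrane_center=np.zeros(3), membrane_radius=30.0,
            layer_window=(18.0, 26.0), lattice_window=(8.0, 15.0),
            min_neighbor_support=2)
        assert not out["flags"].str.contains("false_positive").any()

    def test_rule_union_order_independent(self, shell_t7):
        df = self._clean_lattice(shell_t7)
        df.loc[0, "z"] += 50.0  # isolated and outside the layer
        kw = dict(membrane_center=np.zeros(3), membrane_radius=30.0,
                  layer_window=(18.0, 26.0), lattice_window=(8.0, 15.0),
                  min_neighbor_support=2)
        once = lt.filter_false_positives(df, **kw)
        twice = lt.filter_false_positives(once, **kw)
        assert (once["flags"] == twice["flags"]).all()


class TestRecovery:
    def test_perfect_detection_is_fully(self, shell_t3):
        out = lt.classify_recovery(shell_t3.centers, shell_t3,
                                   shell_t3.spacing)
        assert out["recovered_fraction"] == 1.0
        assert out["class"] == "fully"

    @pytest.mark.parametrize("frac,cls", [(0.85, "nearly"),
                                          (0.5, "partially")])
    def test_partial_detection_classes(self, shell_t7, frac, cls):
        n = int(round(frac * shell_t7.n_sites))
        out = lt.classify_recovery(shell_t7.centers[:n], shell_t7,
                                   shell_t7.spacing)
        assert out["class"] == cls

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            lt.classify_recovery(np.zeros((1, 3)), np.empty((0, 3)), 10.0)


class TestCurvature:
    def test_closed_shell_integrates_to_4pi(self, shell_t7):
        g = lt.build_graph(shell_t7.centers, 0.8 * shell_t7.spacing,
                           1.2 * shell_t7.spacing)
        out = lt.total_curvature(g)
        assert out["total"] == pytest.approx(4 * np.pi, rel=0.05)

    def test_nested_shells_integrate_per_component(self, nested_model):
        spacings = nested_model.params["layer_spacings"]
        per_comp = []
        for layer in (0, 1):
            sel = nested_model.layer_index == layer
            g = lt.build_graph(nested_model.centers[sel],
                               0.8 * spacings[layer], 1.2 * spacings[layer])
            per_comp.append(lt.total_curvature(g)["total"])
        for val in per_comp:
            assert val == pytest.approx(4 * np.pi, rel=0.05)
        assert sum(per_comp) == pytest.approx(8 * np.pi, rel=0.05)

    def test_flat_sheet_interior_deficit_zero(self):
        g = lt.build_graph(flat_hex_patch(8, 10.0), 8.0, 12.0)
        out = lt.total_curvature(g)
        assert abs(out["total"]) < 0.05

    def test_deficit_counts_pentamers(self, cone_model):
        g = lt.build_graph(cone_model.centers, 0.8 * cone_model.spacing,
                           1.2 * cone_model.spacing)
        out = lt.total_curvature(g)
        assert round(out["total"] / (np.pi / 3)) == 12


class TestLatticeMap:
    def _table(self):
        rng = np.random.default_rng(1)
        n = 20
        return pd.DataFrame({
            "x": rng.uniform(0, 50, n), "y": rng.uniform(0, 50, n),
            "z": rng.uniform(0, 50, n),
            "rot": 0.0, "tilt": 0.0, "psi": 0.0,
            "ccc": rng.uniform(0.2, 0.9, n),
            "virus_id": ["a"] * 10 + ["b"] * 10, "flags": "",
        })

    def test_min_red_max_green_per_virus(self, tmp_path):
        df = self._table()
        path = tmp_path / "map.tsv"
        lt.export_lattice_map(df, path, out_format="tsv")
        back = lt.read_lattice_map(path)
        for v in ("a", "b"):
            sub = back[back["virus_id"] == v]
            lo = sub.loc[sub["ccc"].idxmin()]
            hi = sub.loc[sub["ccc"].idxmax()]
            assert (lo["color_r"], lo["color_g"]) == (1.0, 0.0)
            assert (hi["color_r"], hi["color_g"]) == (0.0, 1.0)

    def test_degenerate_scale_maps_to_mid(self, tmp_path):
        df = self._table()
        df["ccc"] = 0.5
        path = tmp_path / "map.tsv"
        lt.export_lattice_map(df, path, out_format="tsv")
        back = lt.read_lattice_map(path)
        assert np.allclose(back["color_r"], 0.5)
        assert np.allclose(back["color_g"], 0.5)

    def test_tsv_round_trip_positions(self, tmp_path):
        df = self._table()
        path = tmp_path / "map.tsv"
        lt.export_lattice_map(df, path, out_format="tsv")
        back = lt.read_lattice_map(path)
        assert np.allclose(back[["x", "y", "z"]].to_numpy(),
                           df[["x", "y", "z"]].to_numpy(), atol=1e-6)

    def test_cmm_is_valid_xml_with_markers(self, tmp_path):
        from xml.etree import ElementTree as ET
        df = self._table()
        path = tmp_path / "map.cmm"
        lt.export_lattice_map(df, path, out_format="cmm")
        root = ET.parse(path).getroot()
        assert root.tag == "marker_set"
        assert len(root.findall("marker")) == len(df)

    def test_unknown_format_lists_supported(self, tmp_path):
        with pytest.raises(ValueError, match="cmm, tsv"):
            lt.export_lattice_map(self._table(), tmp_path / "x", "bild")
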