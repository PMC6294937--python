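"""Forward-model correctness: templates, rendering, wedge, noise, extraction."""

import numpy as np
import pytest

from capsidlattice import capsid_models as cm
from capsidlattice import tomo_sim as ts
from capsidlattice._geom import frame_from_z


def _single_site_model(center=(0.0, 0.0, 0.0), R=None):
    return cm.CapsidModel(
        centers=np.asarray([center]), orientations=(np.eye(3) if R is None
                                                    else R)[None],
        ring_order=[6], layer_index=[0], bonds=np.empty((0, 2)),
        morphology="sheet", spacing=10.0)


class TestTemplates:
    @pytest.mark.parametrize("kind,order", [("immature", 6), ("mature", 6),
                                            ("pentamer", 5)])
    def test_rotational_symmetry(self, kind, order):
        # probe with the exact FFT-shear rotation so interpolation error of
        # the probe itself does not mask the template property
        t = ts.make_template(kind, spacing=8.0 if kind == "immature" else 10.0)
        rot = ts.rotate_z_exact(t.values.astype(float), 2 * np.pi / order)
        rms = np.sqrt(((rot - t.values) ** 2).mean())
        assert rms / np.sqrt((t.values ** 2).mean()) < 0.01

    def test_immature_thicker_than_mature(self, immature_template,
                                          mature_template):
        # z-extent (layer thickness) of the immature unit exceeds the
        # single-layer mature unit
        def z_extent(t):
            prof = t.values.sum(axis=(1, 2))
            above = np.where(prof > 0.05 * prof.max())[0]
            return above[-1] - above[0]

        assert z_extent(immature_template) > z_extent(mature_template)

    def test_rod_bundle_spacing(self, immature_template):
        # six rods parallel to z with adjacent axes 15 A apart lie on a
        # circle of radius 15 A
        t = immature_template
        vox = t.density.voxel_size
        c = t.density.shape[0] // 2
        # rods occupy the region below the CTD layer
        zsel = slice(2, c - int(25.0 / vox))
        sub = t.values[zsel].sum(axis=0)
        # peak radius of the azimuthally averaged rod density
        yy, xx = np.meshgrid(*(np.arange(s) for s in sub.shape), indexing="ij")
        r = np.sqrt((xx - c) ** 2 + (yy - c) ** 2)
        rings = np.arange(0, int(c), 1)
        prof = np.array([sub[(r >= a) & (r < a + 1)].mean() for a in rings])
        peak_r_A = np.argmax(prof) * vox
        circle_r = 15.0 / (2 * np.sin(np.pi / 6))  # = 15 A
        assert abs(peak_r_A - circle_r) <= vox


class TestRender:
    def test_single_site_equals_template(self, mature_template):
        vol = ts.render_capsid(_single_site_model(), mature_template,
                               box_shape=32)
        box = ts.extract_subtomograms(vol, [[16, 16, 16]], box=24).boxes[0]
        rms = np.sqrt(((box - mature_template.values) ** 2).mean())
        assert rms < 0.02 * mature_template.values.max()

    def test_linearity_two_distant_sites(self, mature_template):
        m2 = cm.CapsidModel(
            centers=np.array([[-15.0, 0, 0], [15.0, 0, 0]]),
            orientations=np.stack([np.eye(3)] * 2), ring_order=[6, 6],
            layer_index=[0, 0], bonds=np.empty((0, 2)), morphology="sheet",
            spacing=10.0)
        v1 = ts.render_capsid(_single_site_model(), mature_template,
                              box_shape=80)
        v2 = ts.render_capsid(m2, mature_template, box_shape=80)
        assert v2.values.sum() == pytest.approx(2 * v1.values.sum(), rel=0.005)

    def test_amplitude_linearity(self, mature_template):
        scaled = ts.StructureTemplate(
            density=ts.DensityVolume(3.0 * mature_template.values,
                                     mature_template.density.voxel_size),
            symmetry_order=6, kind="mature")
        v1 = ts.render_capsid(_single_site_model(), mature_template,
                              box_shape=32)
        v3 = ts.render_capsid(_single_site_model(), scaled, box_shape=32)
        assert np.allclose(v3.values, 3.0 * v1.values, atol=1e-5)

    def test_rotation_equivariance(self, mature_template):
        R = frame_from_z(np.array([1.0, 1.0, 1.0]))
        c = np.array([[0.0, 0, 0], [12.0, 0, 0], [0, 12.0, 0]])
        ident = np.stack([np.eye(3)] * 3)
        mA = cm.CapsidModel(centers=c, orientations=ident, ring_order=[6] * 3,
                            layer_index=[0] * 3, bonds=np.empty((0, 2)),
                            morphology="sheet", spacing=12.0)
        mB = cm.CapsidModel(centers=(R @ c.T).T,
                            orientations=np.einsum("ij,njk->nik", R, ident),
                            ring_order=[6] * 3, layer_index=[0] * 3,
                            bonds=np.empty((0, 2)), morphology="sheet",
                            spacing=12.0)
        vA = ts.render_capsid(mA, mature_template, box_shape=64)
        vB = ts.render_capsid(mB, mature_template, box_shape=64)
        vArot = ts.rotate_volume(vA.values, R, order=3)
        rms = np.sqrt(((vArot - vB.values) ** 2).mean())
        assert rms < 0.05 * vB.values.max()

    def test_out_of_bounds_lists_sites(self, mature_template):
        with pytest.raises(ts.OutOfBoundsError, match=r"\[0\]"):
            ts.render_capsid(_single_site_model(center=(50.0, 0, 0)),
                             mature_template, box_shape=32,
                             center_on=np.zeros(3))


class TestMissingWedge:
    def test_full_tilt_range_is_identity(self, rng):
        v = ts.DensityVolume(rng.standard_normal((32, 32, 32)), 5.4)
        out = ts.apply_missing_wedge(v, ts.ImagingParams(
            tilt_range_deg=(-90, 90)))
        rel = np.linalg.norm(out.values - v.values) / np.linalg.norm(v.values)
        assert rel < 1e-10

    def test_idempotent_projection(self, rng):
        v = ts.DensityVolume(rng.standard_normal((32, 32, 32)), 5.4)
        p = ts.ImagingParams(tilt_range_deg=(-60, 60))
        w1 = ts.apply_missing_wedge(v, p)
        w2 = ts.apply_missing_wedge(w1, p)
        rel = np.linalg.norm(w2.values - w1.values) / np.linalg.norm(v.values)
        assert rel < 1e-6

    def test_white_noise_variance_equals_mask_fraction(self, rng):
        v = ts.DensityVolume(rng.standard_normal((48, 48, 48)), 5.4)
        p = ts.ImagingParams(tilt_range_deg=(-60, 60))
        out = ts.apply_missing_wedge(v, p)
        frac = ts.wedge_mask(v.shape, p).mean()
        assert out.values.var() / v.values.var() == pytest.approx(frac,
                                                                  rel=0.02)

    def test_invalid_tilt_range(self):
        with pytest.raises(ValueError):
            ts.ImagingParams(tilt_range_deg=(60, -60))


class TestNoise:
    def test_snr_one_variance_ratio(self, rng):
        sig = ts.DensityVolume(
            rng.standard_normal((64, 64, 64)).astype(np.float32), 5.4)
        noisy = ts.add_noise(sig, snr=1.0, seed=3)
        ratio = sig.values.var() / (noisy.values - sig.values).var()
        assert 0.9 < ratio < 1.1

    def test_infinite_snr_identity(self, rng):
        sig = ts.DensityVolume(rng.standard_normal((16,) * 3), 5.4)
        assert np.array_equal(ts.add_noise(sig, np.inf).values, sig.values)

    def test_seeded_determinism(self, rng):
        sig = ts.DensityVolume(rng.standard_normal((16,) * 3), 5.4)
        a = ts.add_noise(sig, 0.5, seed=11)
        b = ts.add_noise(sig, 0.5, seed=11)
        assert np.array_equal(a.values, b.values)

    def test_zero_variance_rejected(self):
        flat = ts.DensityVolume(np.ones((16,) * 3), 5.4)
        with pytest.raises(ValueError):
            ts.add_noise(flat, snr=1.0)


class TestExtraction:
    def test_integer_positions_exact_copy(self, rng):
        v = ts.DensityVolume(rng.standard_normal((40, 40, 40)), 5.4)
        sub = ts.extract_subtomograms(v, [[20, 18, 22]], box=16)
        assert np.array_equal(
            sub.boxes[0], v.values[14:30, 10:26, 12:28])

    def test_count_matches_positions(self, rng):
        v = ts.DensityVolume(rng.standard_normal((40, 40, 40)), 5.4)
        sub = ts.extract_subtomograms(v, [[20, 20, 20]] * 5, box=16)
        assert sub.n == 5

    def test_margin_violation_names_index(self, rng):
        v = ts.DensityVolume(rng.standard_normal((40, 40, 40)), 5.4)
        with pytest.raises(ValueError, match="position 1"):
            ts.extract_subtomograms(v, [[20, 20, 20], [3, 20, 20]], box=16)

    def test_odd_box_rejected(self, rng):
        v = ts.DensityVolume(rng.standard_normal((40,) * 3), 5.4)
        with pytest.raises(ValueError):
            ts.extract_subtomograms(v, [[20, 20, 20]], box=15)


class TestMrcIO:
    def test_bit_exact_round_trip(self, tmp_path, rng):
        v = ts.DensityVolume(
            rng.standard_normal((24, 24, 24)).astype(np.float32), 5.4,
            origin=np.array([1.0, 2.0, 3.0]))
        path = tmp_path / "vol.mrc"
        v.write_mrc(path)
        back = ts.DensityVolume.read_mrc(path)
        assert np.array_equal(back.values, v.values)
        assert back.voxel_size == pytest.approx(5.4, abs=1e-6)
        assert np.allclose(back.origin, v.origin, atol=1e-5)

    def test_subtomogram_set_round_trip(self, tmp_path, rng):
        v = ts.DensityVolume(rng.standard_normal((40,) * 3), 5.4)
        sub = ts.extract_subtomograms(
            v, [[20, 20, 20], [18, 22, 20]], box=16,
            wedge=ts.ImagingParams(tilt_range_deg=(-60, 60)))
        sub.save(tmp_path / "subs")
        back = ts.SubtomogramSet.load(tmp_path / "subs")
        assert np.array_equal(back.boxes, sub.boxes)
        assert np.allclose(back.positions, sub.positions)
        assert back.wedge.tilt_range_deg == (-60, 60)
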