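import json

import numpy as np
import pandas as pd
import pytest

from fibsemga import materials as M
from fibsemga import synthetic_data as sd
from fibsemga.montecarlo import GeometryError


class TestDepthStepPhantom:
    def test_stained_voxel_count(self):
        spec = sd.DepthStepPhantomSpec()
        phantom = sd.make_depth_step_phantom(spec)
        # counting oracle: 5 squares x (30/3)^2 lateral voxels x (5/2.5) z voxels
        expected = 5 * 10 * 10 * 2
        assert (phantom.material_ids == 1).sum() == expected

    def test_no_gallium_when_fraction_zero(self):
        phantom = sd.make_depth_step_phantom(sd.DepthStepPhantomSpec(ga_fraction=0.0))
        for mat in phantom.materials:
            assert "Ga" not in mat.composition.symbols

    def test_implantation_reaches_both_materials(self):
        phantom = sd.make_depth_step_phantom(sd.DepthStepPhantomSpec(ga_fraction=0.25))
        for mat in phantom.materials:
            assert mat.composition.fraction_of("Ga") == pytest.approx(0.25)

    def test_layers_fill_their_depth_interval(self):
        spec = sd.DepthStepPhantomSpec()
        phantom = sd.make_depth_step_phantom(spec)
        ids = phantom.material_ids
        # third square occupies exactly z-voxels 4..5 (10-15 nm at 2.5 nm pitch)
        stained_z = np.unique(np.nonzero(ids.sum(axis=(0, 1)))[0])
        assert stained_z.tolist() == list(range(0, 10))
        x0, x1, y0, y1 = sd.feature_footprints(spec)[2]
        block = ids[int(x0 // 3) : int(x1 // 3), int(y0 // 3) : int(y1 // 3), :]
        assert (block[:, :, 4:6] == 1).all()
        assert (block[:, :, :4] == 0).all() and (block[:, :, 6:] == 0).all()

    def test_overlapping_layers_rejected(self):
        with pytest.raises(ValueError):
            sd.DepthStepPhantomSpec(layer_depths=((0.0, 5.0), (2.5, 7.5)))

    def test_snap_warning(self):
        with pytest.warns(UserWarning, match="snapped"):
            sd.make_depth_step_phantom(sd.DepthStepPhantomSpec(square_size=31.0))


class TestVesiclePhantom:
    def test_shell_matches_brute_force(self):
        spec = sd.VesiclePhantomSpec()
        phantom = sd.make_vesicle_phantom(spec)
        ids = phantom.material_ids
        nx, ny, nz = ids.shape
        cx = nx * 3.0 / 2.0
        cz = spec.center_depth
        r = spec.outer_diameter / 2.0
        count = 0
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    d = np.sqrt(
                        ((i + 0.5) * 3.0 - cx) ** 2
                        + ((j + 0.5) * 3.0 - cx) ** 2
                        + ((k + 0.5) * 3.0 - cz) ** 2
                    )
                    inside = r - spec.membrane_thickness < d <= r
                    count += inside
                    assert bool(ids[i, j, k]) == inside
        assert count == (ids == 1).sum() > 0

    def test_stain_zero_gives_matrix_shell(self):
        phantom = sd.make_vesicle_phantom(sd.VesiclePhantomSpec(stain_fraction=0.0))
        m0, m1 = phantom.materials
        assert m0.composition.as_dict() == m1.composition.as_dict()

    def test_nearly_solid_sphere_limit(self):
        spec = sd.VesiclePhantomSpec(membrane_thickness=19.9)
        phantom = sd.make_vesicle_phantom(spec)
        # all voxels within the outer radius except a tiny core are shell
        assert (phantom.material_ids == 1).sum() > 900

    def test_out_of_grid_rejected(self):
        with pytest.raises(GeometryError):
            sd.make_vesicle_phantom(sd.VesiclePhantomSpec(center_depth=10.0))
        with pytest.raises(ValueError):
            sd.VesiclePhantomSpec(membrane_thickness=25.0)


class TestHAADFProfileGenerator:
    @pytest.mark.parametrize("R", [1.0, 2.26, 3.9])
    def test_noiseless_max_over_plateau_is_target(self, R):
        spec = sd.HAADFProfileSpec(jump_ratio=R, poisson_noise=False)
        tab, truth = sd.synth_haadf_profile(spec, 0)
        inside = tab.position_nm >= spec.interface
        assert tab.intensity[inside].max() / spec.plateau == pytest.approx(
            R, abs=1e-6
        )
        assert truth["jump_ratio"] == R

    def test_vacuum_is_dark(self):
        spec = sd.HAADFProfileSpec(poisson_noise=False)
        tab, _ = sd.synth_haadf_profile(spec, 0)
        assert (tab.intensity[tab.position_nm < spec.interface] == 0).all()

    def test_flat_when_r_is_one(self):
        spec = sd.HAADFProfileSpec(jump_ratio=1.0, poisson_noise=False)
        tab, _ = sd.synth_haadf_profile(spec, 0)
        inside = tab.intensity[tab.position_nm >= spec.interface].values
        assert inside == pytest.approx(spec.plateau)

    def test_seeded_determinism(self):
        spec = sd.HAADFProfileSpec()
        t1, _ = sd.synth_haadf_profile(spec, 5)
        t2, _ = sd.synth_haadf_profile(spec, 5)
        pd.testing.assert_frame_equal(t1, t2)
        t3, _ = sd.synth_haadf_profile(spec, 6)
        assert not t1.intensity.equals(t3.intensity)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            sd.HAADFProfileSpec(jump_ratio=0.5)
        with pytest.raises(ValueError):
            sd.HAADFProfileSpec(onset_width=-1.0)


class TestEELSGenerator:
    def test_pure_power_law_recovery(self):
        spec = sd.EELSSpectrumSpec(edges=(), poisson_noise=False)
        tab, _ = sd.synth_eels_spectrum(spec, 0)
        from fibsemga.eels_quant import EELSSpectrum, fit_background

        A, r = fit_background(EELSSpectrum.from_table(tab), (300.0, 500.0))
        assert A == pytest.approx(spec.background_amplitude, rel=1e-9)
        assert r == pytest.approx(spec.background_exponent, abs=1e-9)

    def test_noiseless_edge_integral_exact(self):
        edge = sd.EELSEdgeSpec("C", 284.0, 12345.0)
        spec = sd.EELSSpectrumSpec(edges=(edge,), poisson_noise=False)
        E = sd.eels_energy_axis(spec)
        with_edge = sd.eels_model(spec, E)
        background = spec.background_amplitude * E ** (-spec.background_exponent)
        win = (E >= 284.0) & (E < 384.0)
        net = (with_edge - background)[win].sum() * spec.dispersion
        assert net == pytest.approx(12345.0, rel=1e-6)

    def test_overlapping_windows_warn(self):
        edges = (sd.EELSEdgeSpec("C", 284.0, 1.0), sd.EELSEdgeSpec("N", 300.0, 1.0))
        with pytest.warns(UserWarning, match="overlap"):
            sd.EELSSpectrumSpec(edges=edges)

    def test_onset_outside_range_rejected(self):
        with pytest.raises(ValueError):
            sd.EELSSpectrumSpec(edges=(sd.EELSEdgeSpec("C", 100.0, 1.0),))

    def test_sample_spec_encodes_ratio(self):
        spec = sd.eels_sample_spec(0.2, sigma_o_over_c=0.3, sigma_ga_over_o=0.5)
        c, ga = spec.edges
        assert ga.integral / c.integral == pytest.approx(0.2 * 0.5 * 0.3)

    def test_reference_spec_stoichiometry(self):
        spec = sd.eels_reference_spec(sigma_o=0.3, sigma_ga_over_o=0.8)
        o, ga = spec.edges
        assert ga.integral / o.integral == pytest.approx((2.0 / 3.0) * 0.8)

    def test_seeded_determinism(self):
        spec = sd.eels_sample_spec(0.117)
        t1, _ = sd.synth_eels_spectrum(spec, 9)
        t2, _ = sd.synth_eels_spectrum(spec, 9)
        pd.testing.assert_frame_equal(t1, t2)


class TestWriters:
    def test_profile_csv_and_sidecar(self, tmp_path):
        tab, truth = sd.synth_haadf_profile(sd.HAADFProfileSpec(), 0)
        out = tmp_path / "profile.csv"
        sd.write_profile(tab, truth, out)
        back = pd.read_csv(out)
        assert list(back.columns) == ["position_nm", "intensity"]
        side = json.loads((tmp_path / "profile.truth.json").read_text())
        assert side["jump_ratio"] == 3.9

    def test_phantom_hdf5_round_trip(self, tmp_path):
        phantom = sd.make_depth_step_phantom(sd.DepthStepPhantomSpec())
        out = tmp_path / "phantom.h5"
        sd.write_phantom(phantom, out)
        import h5py

        with h5py.File(out) as fh:
            assert np.array_equal(fh["material_ids"][...], phantom.material_ids)
            assert tuple(fh.attrs["voxel_size_nm"]) == phantom.voxel_size
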