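import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibsemga import haadf_quant as hq
from fibsemga import materials as M
from fibsemga import synthetic_data as sd
from fibsemga.electron_physics import HAADFCrossSectionModel


def profile_from_table(tab) -> hq.LineProfile:
    return hq.LineProfile(tab.position_nm.values, tab.intensity.values)


class TestExtractProfile:
    def test_constant_image(self):
        img = np.full((40, 60), 7.0)
        prof = hq.extract_profile(img, 1.0, (5.0, 20.0), (55.0, 20.0), 10.0)
        assert prof.intensities == pytest.approx(7.0)

    def test_replicated_rows_round_trip(self):
        base = np.linspace(10, 50, 80)
        img = np.tile(base, (30, 1))
        prof = hq.extract_profile(img, 1.0, (0.5, 15.0), (79.5, 15.0), 8.0)
        assert prof.intensities == pytest.approx(base[: prof.n], rel=1e-12)

    def test_full_width_equals_column_means(self):
        rng = np.random.default_rng(0)
        img = rng.random((20, 30))
        prof = hq.extract_profile(img, 1.0, (0.5, 10.0), (29.5, 10.0), 20.0)
        assert prof.intensities == pytest.approx(img.mean(axis=0), rel=1e-12)

    def test_band_truncation_warns(self):
        img = np.ones((10, 30))
        with pytest.warns(UserWarning, match="truncated"):
            hq.extract_profile(img, 1.0, (0.5, 1.0), (29.5, 1.0), 10.0)

    def test_degenerate_line_rejected(self):
        with pytest.raises(hq.ProfileError):
            hq.extract_profile(np.ones((5, 5)), 1.0, (1.0, 1.0), (1.0, 1.0), 2.0)


class TestJumpRatio:
    def test_recovers_target_sharp_peak(self):
        vals = []
        for seed in range(40):
            tab, _ = sd.synth_haadf_profile(sd.HAADFProfileSpec(), seed)
            vals.append(hq.jump_ratio(profile_from_table(tab)).jump_ratio)
        assert np.mean(vals) == pytest.approx(3.9, abs=0.1)

    def test_recovers_section_edge_shape(self):
        spec = sd.HAADFProfileSpec(
            jump_ratio=2.26, onset_width=20.0, decay_length=80.0, extent=800.0
        )
        vals, onsets, decays = [], [], []
        for seed in range(40):
            tab, _ = sd.synth_haadf_profile(spec, seed)
            res = hq.jump_ratio(profile_from_table(tab))
            vals.append(res.jump_ratio)
            onsets.append(res.onset_width_nm)
            decays.append(res.decay_length_nm)
        assert np.mean(vals) == pytest.approx(2.26, abs=0.05)
        # the 10-90 % rise convention resolves ~0.8 of the generator onset
        assert 10.0 < np.mean(onsets) < 22.0
        assert np.mean(decays) == pytest.approx(80.0, rel=0.15)

    def test_flat_block_gives_unity(self):
        tab, _ = sd.synth_haadf_profile(
            sd.HAADFProfileSpec(jump_ratio=1.0, poisson_noise=False), 0
        )
        res = hq.jump_ratio(profile_from_table(tab))
        assert res.jump_ratio == pytest.approx(1.0, abs=1e-9)

    def test_vacuum_side_autodetection(self):
        tab, _ = sd.synth_haadf_profile(sd.HAADFProfileSpec(), 1)
        prof = profile_from_table(tab)
        flipped = hq.LineProfile(
            prof.positions, prof.intensities[::-1].copy()
        )
        r1 = hq.jump_ratio(prof)
        r2 = hq.jump_ratio(flipped)
        assert r1.vacuum_side == "left" and r2.vacuum_side == "right"
        assert r1.jump_ratio == pytest.approx(r2.jump_ratio, rel=1e-9)

    def test_unreliable_plateau_raises(self):
        x = np.arange(100.0)
        y = np.concatenate([np.zeros(20), 1000.0 * (1 + 5.0 * (np.arange(80) % 2))])
        with pytest.raises(hq.ProfileError):
            hq.jump_ratio(hq.LineProfile(x, y))

    def test_too_short_profile_rejected(self):
        with pytest.raises(hq.ProfileError):
            hq.jump_ratio(hq.LineProfile(np.arange(10.0), np.ones(10)))

    def test_peak_estimator_options(self):
        tab, _ = sd.synth_haadf_profile(sd.HAADFProfileSpec(poisson_noise=False), 0)
        prof = profile_from_table(tab)
        raw = hq.jump_ratio(prof, peak_estimator="max").jump_ratio
        smooth = hq.jump_ratio(prof, peak_estimator="smoothed3").jump_ratio
        assert raw > smooth  # averaging flattens the sharp onset
        with pytest.raises(ValueError):
            hq.jump_ratio(prof, peak_estimator="median")


scenario_strategy = st.builds(
    lambda rc, ro, rn: M.RetentionScenario({"C": rc, "O": ro, "N": rn}, "random"),
    st.floats(min_value=0.05, max_value=1.0),
    st.floats(min_value=0.0, max_value=1.0),
    st.floats(min_value=0.0, max_value=1.0),
)


class TestInversion:
    def test_forward_inverse_are_exact_inverses_at_flagship_ratio(self, epon, sigma_model):
        R = hq.forward_jump_ratio(0.38, epon, M.NO_LOSS, sigma_model)
        back = hq.invert_jump_ratio(R, epon, M.NO_LOSS, sigma_model)
        assert back.ga_c_ratio == pytest.approx(0.38, abs=1e-9)

    @given(st.floats(min_value=1.0, max_value=6.0), scenario_strategy)
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_round_trip_property(self, R, scenario):
        epon = M.preset("epon_araldite")
        model = HAADFCrossSectionModel()
        est = hq.invert_jump_ratio(R, epon, scenario, model)
        if est.ga_c_ratio >= 0:
            assert hq.forward_jump_ratio(
                est.ga_c_ratio, epon, scenario, model
            ) == pytest.approx(R, abs=1e-9)

    def test_unity_ratio_full_retention_gives_zero(self, epon, sigma_model):
        est = hq.invert_jump_ratio(1.0, epon, M.NO_LOSS, sigma_model)
        assert est.ga_c_ratio == pytest.approx(0.0, abs=1e-12)
        assert est.at_percent_ga == pytest.approx(0.0, abs=1e-10)

    def test_subunity_and_zero_carbon_rejected(self, epon, sigma_model):
        with pytest.raises(ValueError):
            hq.invert_jump_ratio(0.9, epon, M.NO_LOSS, sigma_model)
        with pytest.raises(ValueError):
            hq.invert_jump_ratio(
                2.0, epon, M.RetentionScenario({"C": 0.0}), sigma_model
            )

    def test_forward_at_zero_matches_hand_algebra(self, epon, sigma_model):
        # R(g=0) = sum ret_i f_i sigma_i / sum f_i sigma_i, H excluded
        f = epon.composition.as_dict()
        sig = {s: sigma_model.effective_sigma(z) for s, z in [("C", 6), ("O", 8), ("N", 7)]}
        plateau = sum(f[s] * sig[s] for s in ("C", "O", "N"))
        retained = 0.5 * f["C"] * sig["C"] + 0.5 * f["N"] * sig["N"]
        expected = retained / plateau
        assert hq.forward_jump_ratio(
            0.0, epon, M.C50_O100, sigma_model
        ) == pytest.approx(expected, rel=1e-12)
        assert expected < 1.0

    def test_monotone_in_measured_ratio(self, epon, sigma_model):
        ratios = [
            hq.invert_jump_ratio(r, epon, M.NO_LOSS, sigma_model).ga_c_ratio
            for r in np.linspace(1.0, 5.0, 20)
        ]
        assert np.all(np.diff(ratios) > 0)

    def test_mass_loss_raises_inverted_ratio(self, epon, sigma_model):
        for R in (2.26, 3.9):
            no_loss = hq.invert_jump_ratio(R, epon, M.NO_LOSS, sigma_model)
            loss = hq.invert_jump_ratio(R, epon, M.C50_O100, sigma_model)
            assert loss.ga_c_ratio > no_loss.ga_c_ratio

    def test_at_percent_consistency(self, epon, sigma_model):
        est = hq.invert_jump_ratio(3.0, epon, M.NO_LOSS, sigma_model)
        assert est.at_percent_ga == pytest.approx(
            100 * est.ga_c_ratio / (1 + est.ga_c_ratio)
        )


class TestProfileToCompositionPipeline:
    def test_median_bias_under_noise(self, epon, sigma_model):
        # generate noisy profiles of known R, measure, invert; median Ga:C
        # within 3 % of the noise-free inversion
        target = hq.invert_jump_ratio(3.9, epon, M.NO_LOSS, sigma_model).ga_c_ratio
        estimates = []
        for seed in range(50):
            tab, _ = sd.synth_haadf_profile(sd.HAADFProfileSpec(), seed)
            measured = hq.jump_ratio(profile_from_table(tab)).jump_ratio
            estimates.append(
                hq.invert_jump_ratio(measured, epon, M.NO_LOSS, sigma_model).ga_c_ratio
            )
        assert abs(np.median(estimates) / target - 1) < 0.03
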