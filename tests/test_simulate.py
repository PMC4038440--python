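"""Synthetic specimen generator: determinism, elastic limit, presets."""

import numpy as np
import pytest

from elastometry import (SimulationConfig, analyze_bulge_trace,
                         available_presets, generate_dot_frames_on_cap,
                         simulate_bulge_cohort, simulate_creep_test,
                         simulate_relaxation, simulate_uniaxial_test)
from elastometry.simulate import _h_of_psi, _psi_of_h


class TestConfig:
    def test_preset_loading(self):
        cfg = SimulationConfig.from_preset("sweet_cherry_2012")
        assert cfg.E_inst == 23.2 and cfg.eps_fracture_mean == 0.20
        assert "maintained" in available_presets()

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            SimulationConfig.from_preset("nope")

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            SimulationConfig(E_inst=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(edge_failure_prob=1.5)


class TestPsiInversion:
    def test_round_trip(self):
        h = np.linspace(0.01, 8.0, 40)
        psi = _psi_of_h(h, 6.0, 0.1)
        back = _h_of_psi(psi, 6.0, 0.1)
        assert np.allclose(back, h, atol=1e-10)

    def test_monotone(self):
        h = np.linspace(0.0, 10.0, 100)
        assert np.all(np.diff(_psi_of_h(h, 6.0, 0.1)) > 0)


class TestBulgeCohort:
    def test_determinism(self):
        cfg = SimulationConfig(seed=9, E_cv=0.25, eps_fracture_cv=0.18,
                               noise_sd_height=0.01, noise_sd_pressure=0.1)
        a, ta = simulate_bulge_cohort(cfg, 4)
        b, tb = simulate_bulge_cohort(cfg, 4)
        assert np.array_equal(ta.E, tb.E)
        for (tra, _), (trb, _) in zip(a, b):
            assert np.array_equal(tra.pressure_p, trb.pressure_p)
            assert np.array_equal(tra.height_h, trb.height_h)

    def test_deterministic_fracture_threshold(self):
        cfg = SimulationConfig(eps_fracture_mean=0.2, eps_fracture_cv=0.0,
                               seed=0, edge_failure_prob=0.0)
        specimens, truth = simulate_bulge_cohort(cfg, 3)
        assert np.allclose(truth.eps_fracture, 0.2)
        R = cfg.orifice_D / 2
        for trace, meta in specimens:
            res = analyze_bulge_trace(trace, meta)
            # first sample at/above the threshold defines fracture
            assert res.eps_fracture >= 0.2
            assert res.eps_fracture == pytest.approx(0.2, abs=0.005)

    def test_elastic_limit_linear_in_psi(self):
        """With creep off, pressure is exactly E·ψ(h): the pipeline's
        pointwise modulus equals the generator modulus everywhere."""
        cfg = SimulationConfig(E_inst=20.0, seed=1, edge_failure_prob=0.0)
        specimens, _ = simulate_bulge_cohort(cfg, 1)
        trace, meta = specimens[0]
        res = analyze_bulge_trace(trace, meta)
        plateau = ((res.strain >= 0.02)
                   & (np.arange(len(res.strain)) <= res.fracture_index))
        assert np.allclose(res.modulus[plateau], 20.0, rtol=1e-9)

    def test_viscoelastic_softer_than_elastic(self):
        cfg = SimulationConfig(E_inst=16.0, creep_m=0.005, seed=1,
                               edge_failure_prob=0.0)
        specimens, _ = simulate_bulge_cohort(cfg, 1)
        res = analyze_bulge_trace(*specimens[0])
        assert res.E < 16.0
        assert res.E > 8.0  # creep softens but does not collapse the modulus

    def test_pressure_strain_near_linear(self):
        cfg = SimulationConfig(E_inst=23.2, seed=2, edge_failure_prob=0.0)
        specimens, _ = simulate_bulge_cohort(cfg, 1)
        res = analyze_bulge_trace(*specimens[0])
        assert res.pressure_strain_r2 >= 0.98


class TestUniaxialGenerator:
    def test_determinism(self):
        cfg = SimulationConfig(nu=0.74, noise_sd_marker=0.01, seed=4)
        a = simulate_uniaxial_test(cfg)
        b = simulate_uniaxial_test(cfg)
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.marker_xy, fb.marker_xy)

    def test_nu_zero_keeps_width(self):
        tr = simulate_uniaxial_test(SimulationConfig(nu=1e-15, seed=0))
        widths = [f.transverse_distance() for f in tr.frames]
        assert np.allclose(widths, 3.0, atol=1e-9)

    def test_frame_cadence(self):
        tr = simulate_uniaxial_test(SimulationConfig(seed=0), duration=300.0)
        assert len(tr.frames) == 20
        assert np.allclose(np.diff(tr.time), 15.0)


class TestCreepGenerator:
    def test_determinism(self):
        cfg = SimulationConfig.from_preset("creep_default", seed=6,
                                           noise_sd_pressure=0.1)
        a = simulate_creep_test(cfg)
        b = simulate_creep_test(cfg)
        assert np.array_equal(a.pressure, b.pressure)
        assert np.array_equal(a.strain, b.strain)

    def test_table3_directionality(self):
        """Maintained vs released presets: stiffer skin with lower fracture
        strain when the in-vivo strain is kept, while fracture pressure is
        the same within noise."""
        from scipy import stats
        from elastometry import filter_edge_failures
        res_by_arm = {}
        for arm, seed in (("maintained", 11), ("released", 12)):
            cfg = SimulationConfig.from_preset(arm, seed=seed)
            specimens, _ = simulate_bulge_cohort(cfg, 10)
            out = [analyze_bulge_trace(tr, m).mechanical for tr, m in specimens]
            kept, _ = filter_edge_failures(out)
            res_by_arm[arm] = kept
        E_m = np.mean([s.E for s in res_by_arm["maintained"]])
        E_r = np.mean([s.E for s in res_by_arm["released"]])
        eps_m = np.mean([s.eps_fracture for s in res_by_arm["maintained"]])
        eps_r = np.mean([s.eps_fracture for s in res_by_arm["released"]])
        assert E_m > E_r
        assert eps_m < eps_r
        p_m = [s.p_fracture for s in res_by_arm["maintained"]]
        p_r = [s.p_fracture for s in res_by_arm["released"]]
        _, p_val = stats.ttest_ind(p_m, p_r, equal_var=False)
        assert p_val > 0.05


class TestDotFrameGenerator:
    def test_prepends_flat_reference(self):
        cfg = SimulationConfig(seed=0)
        frames, geoms = generate_dot_frames_on_cap(cfg, [10.0, 20.0])
        assert geoms[0].height_h == 0.0
        assert len(frames) == 3

    def test_unit_amplification_matches_height_strain(self):
        from elastometry import (biaxial_strain_from_height,
                                 corrected_bulge_strains)
        cfg = SimulationConfig(center_amplification_g=1.0, seed=0)
        frames, geoms = generate_dot_frames_on_cap(cfg, np.linspace(0, 40, 6))
        res = corrected_bulge_strains(frames, geoms)
        for r, g in zip(res, geoms[1:]):
            assert r.eps_biaxial_calculated == pytest.approx(
                biaxial_strain_from_height(g), rel=1e-9)


class TestRelaxationGenerator:
    def test_zero_release_identical(self):
        cfg = SimulationConfig(in_vivo_release_strain=0.0, seed=0)
        b, a = simulate_relaxation(cfg)
        assert np.array_equal(b.marker_xy, a.marker_xy)

    def test_determinism(self):
        cfg = SimulationConfig(in_vivo_release_strain=0.155,
                               noise_sd_marker=0.01, seed=8)
        b1, a1 = simulate_relaxation(cfg)
        b2, a2 = simulate_relaxation(cfg)
        assert np.array_equal(a1.marker_xy, a2.marker_xy)
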