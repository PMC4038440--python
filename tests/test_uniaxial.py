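"""Uniaxial/marker analysis: strains, Poisson's ratio, arc correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from elastometry import (CapGeometry, DotFrame, SimulationConfig,
                         UniaxialTest, UniaxialTrace, area_release_strain,
                         biaxial_from_orthogonal, biaxial_strain_from_height,
                         corrected_bulge_strains, generate_dot_frames_on_cap,
                         marker_strains, poisson_ratio, simulate_relaxation,
                         simulate_uniaxial_test)
from elastometry.uniaxial import shoelace_area


def square_frame(ts, sx=1.0, sy=1.0, force=0.0):
    base = np.array([[-1.5, -1.5], [1.5, -1.5], [1.5, 1.5], [-1.5, 1.5]])
    return DotFrame(ts, base * np.array([sx, sy]), force)


class TestMarkerStrains:
    def test_plain_stretch(self):
        tr = UniaxialTrace(np.array([0.0, 15.0]), np.array([0.0, 1.0]),
                           (square_frame(0), square_frame(15, sy=1.1)))
        eps = marker_strains(tr)
        assert eps[1, 0] == pytest.approx(0.10, abs=1e-12)
        assert eps[1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_no_deformation(self):
        tr = UniaxialTrace(np.array([0.0, 15.0]), np.array([0.0, 1.0]),
                           (square_frame(0), square_frame(15)))
        assert np.allclose(marker_strains(tr), 0.0)

    def test_transverse_negative_under_tension(self):
        tr = simulate_uniaxial_test(SimulationConfig(nu=0.5, seed=0),
                                    duration=120.0)
        eps = marker_strains(tr)
        assert np.all(eps[1:, 1] < 0)
        # generator identity ε_t = −ν·ε_a
        assert eps[-1, 1] == pytest.approx(-0.5 * eps[-1, 0], rel=1e-9)


class TestPoissonRatio:
    def test_constructed_slopes(self):
        # axial 0.050/N, transverse −0.037/N
        F = np.array([0.0, 1.0, 2.0, 3.0])
        frames = tuple(square_frame(15 * i, sx=1 - 0.037 * f, sy=1 + 0.050 * f,
                                    force=f) for i, f in enumerate(F))
        res = poisson_ratio(UniaxialTrace(np.arange(4.0) * 15, F, frames))
        assert res.nu == pytest.approx(0.74, abs=1e-9)

    def test_zero_transverse_slope(self):
        tr = simulate_uniaxial_test(SimulationConfig(nu=1e-12, seed=0))
        res = poisson_ratio(tr)
        assert res.nu == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_noise_free(self):
        tr = simulate_uniaxial_test(SimulationConfig(nu=0.74, seed=0))
        res = poisson_ratio(tr)
        assert res.nu == pytest.approx(0.74, abs=1e-6)
        assert res.r2_axial >= 0.999 and res.r2_transverse >= 0.999

    def test_recovery_under_marker_noise(self):
        """ν recovered within 3% averaging 10 seeded noisy tests."""
        nus = []
        for s in range(10):
            cfg = SimulationConfig(nu=0.74, noise_sd_marker=0.01, seed=200 + s)
            nus.append(poisson_ratio(simulate_uniaxial_test(cfg)).nu)
        assert np.mean(nus) == pytest.approx(0.74, rel=0.03)

    def test_force_strain_linear(self):
        tr = simulate_uniaxial_test(SimulationConfig(nu=0.74, seed=0))
        res = UniaxialTest(tr).fit()
        assert res.poisson.r2_axial >= 0.999
        assert "Poisson" in res.summary()


class TestBiaxialFromOrthogonal:
    @pytest.mark.parametrize("e1,e2,expected", [
        (0.1, 0.1, 0.21),
        (0.0, 0.3, 0.3),
        (0.338, 0.338, 0.7902),   # √1.79 − 1 in each direction
    ])
    def test_examples(self, e1, e2, expected):
        assert biaxial_from_orthogonal(e1, e2) == pytest.approx(expected,
                                                                abs=2e-4)

    def test_domain(self):
        with pytest.raises(ValueError):
            biaxial_from_orthogonal(-1.0, 0.1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(e1=st.floats(-0.5, 1.0), e2=st.floats(-0.5, 1.0))
    def test_symmetric_and_matches_shoelace(self, e1, e2):
        assert biaxial_from_orthogonal(e1, e2) == pytest.approx(
            biaxial_from_orthogonal(e2, e1), rel=1e-12, abs=1e-12)
        # area strain of the marker quadrilateral under the same stretch
        f0 = square_frame(0)
        f1 = square_frame(1, sx=1 + e1, sy=1 + e2)
        area_strain = shoelace_area(f1.marker_xy) / shoelace_area(f0.marker_xy) - 1
        assert biaxial_from_orthogonal(e1, e2) == pytest.approx(
            area_strain, rel=1e-9, abs=1e-12)


class TestCorrectedBulgeStrains:
    def test_flat_frames_reduce_to_chord_strains(self):
        frames = [square_frame(0), square_frame(1, sx=1.05, sy=1.05)]
        geoms = [CapGeometry(6.0, 0.0), CapGeometry(6.0, 0.0)]
        res = corrected_bulge_strains(frames, geoms)
        assert res[0].eps_longitudinal == pytest.approx(0.05, abs=1e-12)
        assert res[0].eps_latitudinal == pytest.approx(0.05, abs=1e-12)

    def test_isotropic_cap_gap_zero(self):
        cfg = SimulationConfig(E_inst=23.2, seed=0)
        frames, geoms = generate_dot_frames_on_cap(cfg, np.linspace(0, 40, 6))
        res = corrected_bulge_strains(frames, geoms)
        assert all(r.isotropy_gap < 1e-9 for r in res)

    def test_center_amplification_round_trip(self):
        cfg = SimulationConfig(E_inst=23.2, center_amplification_g=2.16,
                               seed=0)
        frames, geoms = generate_dot_frames_on_cap(cfg, np.linspace(0, 40, 9))
        res = corrected_bulge_strains(frames, geoms)
        for r, g in zip(res, geoms[1:]):
            mean_eps = biaxial_strain_from_height(g)
            assert r.eps_biaxial_calculated / mean_eps == pytest.approx(
                2.16, rel=0.01)

    def test_requires_flat_reference(self):
        frames = [square_frame(0), square_frame(1, sx=1.05, sy=1.05)]
        geoms = [CapGeometry(6.0, 1.0), CapGeometry(6.0, 1.5)]
        with pytest.raises(ValueError):
            corrected_bulge_strains(frames, geoms)


class TestAreaReleaseStrain:
    def test_identical_frames(self):
        assert area_release_strain(square_frame(0), square_frame(1)) == 0.0

    def test_construction(self):
        after = square_frame(1, sx=1 / np.sqrt(1.155), sy=1 / np.sqrt(1.155))
        assert area_release_strain(square_frame(0), after) == pytest.approx(
            0.155, abs=1e-9)

    def test_three_to_two_square(self):
        before = square_frame(0)
        after = square_frame(1, sx=2 / 3, sy=2 / 3)
        assert area_release_strain(before, after) == pytest.approx(1.25,
                                                                   abs=1e-12)

    def test_simulated_round_trip(self):
        b, a = simulate_relaxation(SimulationConfig(in_vivo_release_strain=0.155,
                                                    seed=0))
        assert area_release_strain(b, a) == pytest.approx(0.155, abs=1e-9)

    def test_noisy_recovery(self):
        """Mean recovery within 5% over 10 seeded noisy frame pairs."""
        vals = []
        for s in range(10):
            cfg = SimulationConfig(in_vivo_release_strain=0.155,
                                   noise_sd_marker=0.01, seed=300 + s)
            vals.append(area_release_strain(*simulate_relaxation(cfg)))
        assert np.mean(vals) == pytest.approx(0.155, rel=0.05)


class TestDotFrameValidation:
    def test_non_convex_rejected(self):
        xy = np.array([[0, 0], [2, 0], [0.5, 0.5], [0, 2]])
        with pytest.raises(ValueError):
            DotFrame(0.0, xy)

    def test_duplicate_points_rejected(self):
        xy = np.array([[0, 0], [1, 0], [1, 1], [0, 0]])
        with pytest.raises(ValueError):
            DotFrame(0.0, xy)
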