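import numpy as np
import pytest
from scipy import integrate

from evmetrics import CoatedSphereModel, MALSSlice
from evmetrics.mals import (AF4Model, af4_psd, default_angles, form_factor,
                            invert_diameter, per_particle_rayleigh,
                            slice_number_count)
from evmetrics.simulate import simulate_mals_elugram


def quadrature_form_factor(model, outer_diameter, angle_deg):
    """Independent oracle: radial integral of the excess-index profile.

    A(q) = ∫ Δn(r) 4π r² sinc(qr) dr over the core and shell regions,
    evaluated by adaptive quadrature; P = (A(q)/A(0))².
    """
    q = float(model.scattering_vector(angle_deg))
    r_out = outer_diameter / 2.0
    r_in = r_out - model.shell_thickness

    def dn(r):
        return model.n_core - model.n_medium if r < r_in else model.n_shell - model.n_medium

    def integrand(r, qq):
        kernel = 1.0 if qq * r == 0 else np.sin(qq * r) / (qq * r)
        return dn(r) * 4 * np.pi * r**2 * kernel

    a_q = sum(
        integrate.quad(integrand, lo, hi, args=(q,), limit=200)[0]
        for lo, hi in ((0, r_in), (r_in, r_out))
    )
    a_0 = sum(
        integrate.quad(integrand, lo, hi, args=(0.0,), limit=200)[0]
        for lo, hi in ((0, r_in), (r_in, r_out))
    )
    return (a_q / a_0) ** 2


class TestFormFactor:
    def test_normalized_at_vanishing_angle(self, optics):
        assert form_factor(optics, 150.0, 1e-6) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_shell_equals_homogeneous_sphere(self):
        m = CoatedSphereModel(n_shell=1.3540)  # shell index = core index
        for d, ang in [(80.0, 45.0), (150.0, 90.0), (250.0, 120.0)]:
            q = m.scattering_vector(ang)
            x = q * d / 2
            homog = (3 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
            assert abs(form_factor(m, d, ang) - homog) < 1e-12

    @pytest.mark.parametrize("d", [60.0, 150.0, 300.0])
    @pytest.mark.parametrize("ang", [30.0, 90.0, 150.0])
    def test_agrees_with_quadrature_oracle(self, optics, d, ang):
        got = form_factor(optics, d, ang)
        want = quadrature_form_factor(optics, d, ang)
        assert got == pytest.approx(want, rel=1e-6)

    def test_bounded_and_continuous(self, optics):
        angles = np.linspace(1, 179, 400)
        p = np.array([form_factor(optics, 180.0, a) for a in angles])
        assert np.all(p > 0) and np.all(p <= 1.0 + 1e-12)
        assert np.max(np.abs(np.diff(p))) < 0.05

    def test_too_thin_diameter_errors(self, optics):
        with pytest.raises(ValueError, match="shell"):
            form_factor(optics, 10.0, 90.0)


class TestPerParticleContribution:
    def test_quadratic_in_contrast(self):
        m1 = CoatedSphereModel(n_core=1.354, n_shell=1.400, n_medium=1.334)
        m2 = CoatedSphereModel(n_core=1.374, n_shell=1.466, n_medium=1.334)  # doubled contrasts
        r1 = per_particle_rayleigh(m1, 100.0, 1e-5)
        r2 = per_particle_rayleigh(m2, 100.0, 1e-5)
        assert r2 / r1 == pytest.approx(4.0, rel=1e-9)

    def test_d6_scaling_in_rayleigh_limit(self, optics):
        # strict d^6 requires the contrast profile to scale with the particle,
        # i.e. a homogeneous sphere; a fixed-thickness shell grows its
        # polarizability slower than d^3, so the coated ratio falls below 64
        homog = CoatedSphereModel(n_shell=1.3540)
        r1 = per_particle_rayleigh(homog, 40.0, 5.0)
        r2 = per_particle_rayleigh(homog, 80.0, 5.0)
        assert r2 / r1 == pytest.approx(64.0, rel=0.02)
        c1 = per_particle_rayleigh(optics, 40.0, 5.0)
        c2 = per_particle_rayleigh(optics, 80.0, 5.0)
        assert 16.0 < c2 / c1 < 64.0

    def test_zero_contrast_gives_zero(self):
        m = CoatedSphereModel(n_core=1.334, n_shell=1.334, n_medium=1.334)
        assert per_particle_rayleigh(m, 100.0, 90.0) == 0.0


class TestInversion:
    @pytest.mark.parametrize("d", [80.0, 150.0, 250.0])
    def test_noiseless_round_trip_within_one_nm(self, optics, d):
        sim = simulate_mals_elugram([(d, 1000.0)], optics, noise_sd=0.0, seed=0)
        inv = invert_diameter(sim.slices[0], optics)
        assert inv.diameter_nm == pytest.approx(d, abs=1.0)
        assert not inv.at_boundary

    def test_isotropic_profile_flags_lower_boundary(self, optics):
        s = MALSSlice("s", default_angles(), np.ones(16))
        inv = invert_diameter(s, optics)
        assert inv.at_boundary
        assert inv.diameter_nm == 30.0

    def test_all_zero_slice_errors(self, optics):
        s = MALSSlice("s", default_angles(), np.zeros(16))
        with pytest.raises(ValueError, match="zero"):
            invert_diameter(s, optics)

    def test_count_recovery_within_tenth_percent(self, optics):
        sim = simulate_mals_elugram([(150.0, 1000.0)], optics, noise_sd=0.0, seed=0)
        inv = invert_diameter(sim.slices[0], optics)
        count = slice_number_count(sim.slices[0], inv.diameter_nm, optics)
        assert count == pytest.approx(1000.0, rel=1e-3)

    def test_zero_intensity_gives_zero_count(self, optics):
        s = MALSSlice("s", default_angles(), np.r_[0.0, np.ones(15)])
        assert slice_number_count(s, 100.0, optics) == 0.0

    def test_halved_contrast_roughly_quadruples_count(self, optics):
        # counting is quadratic in contrast: a wrong refractive index moves
        # the count by the square of the contrast error
        sim = simulate_mals_elugram([(150.0, 1000.0)], optics, noise_sd=0.0, seed=0)
        halved = CoatedSphereModel(n_core=1.344, n_shell=1.367, n_medium=1.334)
        inv = invert_diameter(sim.slices[0], halved)
        count = slice_number_count(sim.slices[0], inv.diameter_nm, halved)
        assert count / 1000.0 == pytest.approx(4.0, rel=0.15)


class TestAF4Pipeline:
    def test_single_population_unimodal_with_mode_at_150(self, optics, config):
        diams = np.linspace(120, 180, 13)
        counts = 500 * np.exp(-0.5 * ((diams - 150) / 10) ** 2)
        sim = simulate_mals_elugram(list(zip(diams, counts)), optics, seed=0)
        res = af4_psd(sim.slices, optics, config=config)
        # 150 nm sits on a bin edge, so the mode bin is one of its neighbours
        mode_mid = res.psd.bin_midpoints[int(np.argmax(res.psd.counts))]
        assert abs(mode_mid - 150.0) <= 5.0
        assert res.pnc_per_ml == pytest.approx(counts.sum(), rel=0.01)

    def test_empty_elugram(self, optics):
        res = af4_psd([], optics)
        assert res.pnc_per_ml == 0.0
        assert res.psd.n == 0

    def test_two_populations_recovered_bimodal(self, optics, config):
        slices = []
        for center in (100.0, 200.0):
            d = np.linspace(center - 15, center + 15, 7)
            c = 300 * np.exp(-0.5 * ((d - center) / 5) ** 2)
            slices += list(zip(d, c))
        sim = simulate_mals_elugram(slices, optics, seed=0)
        res = af4_psd(sim.slices, optics, config=config)
        occupied = res.psd.bin_midpoints[res.psd.counts > 0]
        assert occupied.min() < 110 and occupied.max() > 190
        # a gap between the recovered populations
        gap = (res.psd.counts[(res.psd.bin_midpoints > 130) & (res.psd.bin_midpoints < 170)] == 0)
        assert gap.all()

    def test_model_results_summary(self, optics):
        sim = simulate_mals_elugram([(150.0, 1000.0)], optics, seed=0)
        res = AF4Model(sim.slices, optics).fit()
        text = res.summary()
        assert "PNC" in text and "slices fitted       1" in text

    def test_linearity_in_counts(self, optics):
        one = simulate_mals_elugram([(150.0, 500.0)], optics, seed=0)
        two = simulate_mals_elugram([(150.0, 1000.0)], optics, seed=0)
        np.testing.assert_allclose(
            2 * one.slices[0].intensities, two.slices[0].intensities, rtol=1e-12
        )
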