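"""Hydraulic closures, penetration depths and areal flux partitioning."""

import warnings

import numpy as np
import pandas as pd
import pytest

import sanddbl
from sanddbl import scaling as sc
from sanddbl import synthetic, upscaling as up


@pytest.fixture(scope="module")
def reference_site():
    return up.SiteRecord(
        grain_size_um=290.0, u_bw_m_s=0.1, temperature_C=20.0, salinity=35.0,
        o2_bw_umol_L=250.0, no3_bw_umol_L=10.0, r_o2_umol_L_h=26.0,
        r_den_umol_N_L_h=1.0, porosity=0.4,
    )


@pytest.fixture(scope="module")
def deep_nitrate_site():
    """Site whose nitrate zone extends well below the oxic zone (no boundary
    degeneracy between the two depths)."""
    return up.SiteRecord(
        grain_size_um=290.0, u_bw_m_s=0.1, temperature_C=20.0, salinity=35.0,
        o2_bw_umol_L=250.0, no3_bw_umol_L=30.0, r_o2_umol_L_h=26.0,
        r_den_umol_N_L_h=0.3, porosity=0.4,
    )


@pytest.fixture(scope="module")
def powerlaw_fit(scaling_ensemble):
    return sc.fit_anoxic_powerlaw(scaling_ensemble)


class TestHydraulics:
    def test_printed_closures(self, reference_site):
        h = up.hydraulics(reference_site)
        assert h.wavelength_m == pytest.approx(0.1421, rel=1e-6)
        assert h.wavenumber_per_m == pytest.approx(2 * np.pi / 0.1421, rel=1e-6)
        assert h.permeability_m2 == pytest.approx(6.1e-11, rel=0.01)
        assert h.conductivity_m_s == pytest.approx(6.0e-4, rel=0.06)
        assert h.head_m == pytest.approx(1.0e-4, rel=1e-9)
        assert h.u_pore_m_s == pytest.approx(
            h.wavenumber_per_m * h.conductivity_m_s * h.head_m
        )

    def test_no_bottom_current_no_pore_flow(self, reference_site):
        still = up.SiteRecord(**{**reference_site.__dict__, "u_bw_m_s": 0.0})
        h = up.hydraulics(still)
        assert h.head_m == 0.0
        assert h.u_pore_m_s == 0.0

    def test_warmer_water_is_less_viscous_more_conductive(self, reference_site):
        cold = up.hydraulics(up.SiteRecord(**{**reference_site.__dict__,
                                              "temperature_C": 5.0}))
        warm = up.hydraulics(up.SiteRecord(**{**reference_site.__dict__,
                                              "temperature_C": 25.0}))
        assert warm.nu_m2_s < cold.nu_m2_s
        assert warm.conductivity_m_s > cold.conductivity_m_s


class TestMixingDepth:
    def test_zero_at_time_zero(self, reference_site):
        h = up.hydraulics(reference_site)
        assert up.mixing_depth(0.0, h, 0.4) == 0.0

    def test_direct_evaluation(self, reference_site):
        h = up.hydraulics(reference_site)
        z = up.mixing_depth(3.46e4, h, 0.4)
        assert z == pytest.approx(0.037, abs=0.002)

    def test_concave_in_time(self, reference_site):
        h = up.hydraulics(reference_site)
        t = np.linspace(0.0, 2e5, 50)
        z = np.array([up.mixing_depth(ti, h, 0.4) for ti in t])
        assert np.all(np.diff(z) > 0)            # increasing
        assert np.all(np.diff(z, 2) < 1e-12)     # concave
        # doubling t adds less than ln(2)/k
        k = h.wavenumber_per_m
        assert (up.mixing_depth(2 * 3.46e4, h, 0.4)
                - up.mixing_depth(3.46e4, h, 0.4)) < np.log(2) / k


class TestPenetrationDepths:
    def test_chained_evaluation(self, reference_site):
        h = up.hydraulics(reference_site)
        z_o2, z_no3 = up.penetration_depths(reference_site, h)
        # 250 umol/L at 26 umol/L/h -> ~9.6 h -> ~3.7 cm
        assert z_o2 == pytest.approx(0.037, abs=0.002)
        assert z_no3 > 0

    def test_no_o2_means_no_oxic_zone(self, reference_site):
        anoxic_bw = up.SiteRecord(**{**reference_site.__dict__, "o2_bw_umol_L": 0.0})
        h = up.hydraulics(anoxic_bw)
        z_o2, _ = up.penetration_depths(anoxic_bw, h)
        assert z_o2 == 0.0

    def test_zero_rates_rejected(self, reference_site):
        broken = up.SiteRecord(**{**reference_site.__dict__, "r_o2_umol_L_h": 0.0})
        with pytest.raises(ValueError):
            up.penetration_depths(broken, up.hydraulics(broken))


class TestColonyRateScaling:
    def test_identity_at_unit_fraction(self):
        assert up.scale_bulk_to_colony_rate(46.0, 1.0) == pytest.approx(0.046)

    def test_thousandfold_concentration(self):
        # 46 umol/L/h in 1/1000 of pore volume -> 46 mmol/L/h
        assert up.scale_bulk_to_colony_rate(46.0, 1e-3) == pytest.approx(46.0)

    def test_halving_fraction_doubles_rate(self):
        assert up.scale_bulk_to_colony_rate(46.0, 1 / 500) == pytest.approx(23.0)

    def test_biovolume_chain_matches_grain_model_constant_scale(self):
        # the chain behind R_c_min: -46 umol/L/h -> ~885 mmol/L/h magnitude
        assert up.colony_rate_from_biovolume(46.0) == pytest.approx(884.6, rel=1e-3)


class TestSeawaterProperties:
    def test_o2_saturation_plausible_marine_values(self):
        # colder and fresher water holds more O2
        assert up.o2_saturation_umol_L(5.0, 35.0) > up.o2_saturation_umol_L(25.0, 35.0)
        assert up.o2_saturation_umol_L(15.0, 0.0) > up.o2_saturation_umol_L(15.0, 35.0)
        assert 200.0 < up.o2_saturation_umol_L(15.0, 35.0) < 320.0

    def test_diffusivity_increases_with_temperature(self):
        assert up.o2_diffusivity(25.0) == pytest.approx(1.1e-9, rel=1e-6)
        assert up.o2_diffusivity(5.0) < up.o2_diffusivity(25.0)


class TestMicroenvFlux:
    def test_zero_powerlaw_gives_zero_microenv_fraction(self, reference_site):
        fit = sc.PowerLawFit(prefactor=0.0, exponent=1.0, r_squared=1.0)
        res = up.microenv_flux(reference_site, fit=fit)
        assert res.flux_microenv_umol_N_m2_h == 0.0
        assert res.fraction_microenv == 0.0

    def test_synthetic_sites_yield_valid_ordered_fractions(self, powerlaw_fit):
        sites = synthetic.make_site_table(seed=11, n_sites=8)
        for site in sites:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = up.microenv_flux(site, fit=powerlaw_fit)
            assert 0.0 <= res.fraction_microenv <= 1.0
            assert res.fraction_low <= res.fraction_microenv <= res.fraction_high
            assert res.z_o2_m >= 0.0 and res.z_no3_m >= 0.0

    def test_microenv_flux_linear_in_denitrification_rate(self, deep_nitrate_site,
                                                          powerlaw_fit):
        base = up.microenv_flux(deep_nitrate_site, fit=powerlaw_fit)
        doubled_site = up.SiteRecord(**{**deep_nitrate_site.__dict__,
                                        "r_den_umol_N_L_h": 0.6})
        doubled = up.microenv_flux(doubled_site, fit=powerlaw_fit)
        assert doubled.flux_microenv_umol_N_m2_h == pytest.approx(
            2 * base.flux_microenv_umol_N_m2_h, rel=1e-9
        )

    def test_fraction_non_increasing_in_bottom_water_o2(self, deep_nitrate_site,
                                                        powerlaw_fit):
        fracs = []
        for o2 in (150.0, 250.0, 350.0):
            site = up.SiteRecord(**{**deep_nitrate_site.__dict__,
                                    "o2_bw_umol_L": o2})
            fracs.append(up.microenv_flux(site, fit=powerlaw_fit).fraction_microenv)
        assert np.all(np.diff(fracs) <= 1e-9)

    def test_microsite_prevalence_non_increasing_in_bottom_velocity(
            self, deep_nitrate_site, powerlaw_fit):
        """Faster bottom water thins the DBL, so the per-layer anoxic
        microenvironment fraction falls; the *share* of total denitrification
        hosted by microsites varies only weakly (the oxic zone deepens at the
        same time) and is not asserted monotone."""
        prevalence, shares = [], []
        for u in (0.1, 0.15, 0.2):
            site = up.SiteRecord(**{**deep_nitrate_site.__dict__, "u_bw_m_s": u})
            res = up.microenv_flux(site, fit=powerlaw_fit)
            prevalence.append(res.layer_anoxic_fraction.sum())
            shares.append(res.fraction_microenv)
        assert np.all(np.diff(prevalence) <= 1e-9)
        assert np.ptp(shares) < 0.05

    def test_shallow_nitrate_warns_and_zeroes_anoxic_flux(self, reference_site,
                                                          powerlaw_fit):
        site = up.SiteRecord(**{**reference_site.__dict__,
                                "no3_bw_umol_L": 0.5, "r_den_umol_N_L_h": 10.0})
        with pytest.warns(UserWarning):
            res = up.microenv_flux(site, fit=powerlaw_fit)
        assert res.flux_anoxic_zone_umol_N_m2_h == 0.0
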