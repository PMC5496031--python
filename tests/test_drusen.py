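"""Basal efflux arithmetic, drusen growth and macrophage clearance."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcdsim.drusen import (
    MacrophageParams,
    apoai_ch_concentration,
    apob_ch_flux,
    basal_abca1_flux,
    deposit_density_from_growth_calibration,
    drusen_clearance_timecourse,
    drusen_growth_rate,
    drusen_height,
    macrophage_clearance_flux,
    required_macrophage_density,
)
from rcdsim.units import MIN_PER_YEAR


class TestEffluxArithmetic:
    def test_basal_abca1_flux(self):
        """Scaling the apical ABCA1 flux by the 6.37 apical:basal expression
        ratio gives ~1.06 pg/mm^2/min."""
        assert basal_abca1_flux(6.73, 6.37) == pytest.approx(1.06, abs=0.005)
        assert basal_abca1_flux(5.0, 1.0000001) == pytest.approx(5.0, rel=1e-6)
        assert basal_abca1_flux(13.46, 6.37) == pytest.approx(2.113, abs=0.001)

    def test_apob_ch_flux(self):
        """Liver-equivalent 967 pg/mm^2/min scaled by ApoB and MTP expression
        (0.075 x 0.04) gives ~2.9, the printed ~3."""
        assert apob_ch_flux(967.0, 0.075, 0.04) == pytest.approx(2.901, rel=1e-9)
        assert apob_ch_flux(967.0, 1.0, 1.0) == 967.0
        assert apob_ch_flux(0.0, 0.075, 0.04) == 0.0

    def test_apoai_concentrations(self, params):
        """Fluxes of 1 and 6 pg/mm^2/min across 1.2e-4 cm/s sustain
        0.0014-0.0083 mg Ch/dl, ~0.01-0.06 mg ApoA-I/dl."""
        ch1, apoai1 = apoai_ch_concentration(1.0, 1.2e-4, 0.14)
        ch6, apoai6 = apoai_ch_concentration(6.0, 1.2e-4, 0.14)
        assert ch1 == pytest.approx(0.0014, abs=5e-5)
        assert ch6 == pytest.approx(0.0084, abs=2e-4)
        assert apoai1 == pytest.approx(0.01, abs=1e-3)
        assert apoai6 == pytest.approx(0.06, abs=4e-3)


class TestGrowth:
    def test_density_calibration(self):
        """1 pg/mm^2/min <-> 0.7 um/year pins the deposit Ch density near
        7.51e8 pg/mm^3 (~0.75 g/cm^3)."""
        rho = deposit_density_from_growth_calibration(1.0, 0.7)
        assert rho == pytest.approx(7.509e8, rel=1e-3)
        # scale invariance of the calibration pair
        assert deposit_density_from_growth_calibration(2.0, 1.4) == pytest.approx(rho)
        assert deposit_density_from_growth_calibration(6.0, 4.2) == pytest.approx(rho)

    def test_growth_rate_bounds(self, params):
        rho = params.efflux.deposit_ch_density
        assert drusen_growth_rate(1.0, rho) == pytest.approx(0.7, rel=1e-9)
        assert drusen_growth_rate(6.0, rho) == pytest.approx(4.2, rel=1e-9)
        assert drusen_growth_rate(0.0, rho) == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(flux=st.floats(0.0, 20.0), k=st.floats(0.1, 10.0))
    def test_growth_proportional_to_flux(self, params, flux, k):
        rho = params.efflux.deposit_ch_density
        assert drusen_growth_rate(k * flux, rho) == pytest.approx(
            k * drusen_growth_rate(flux, rho), rel=1e-12, abs=1e-15
        )

    def test_fifty_year_heights(self):
        """Bounding growth rates give 35-210 um after five decades."""
        assert drusen_height(4.2, 50.0) == pytest.approx(210.0)
        assert drusen_height(0.7, 50.0) == pytest.approx(35.0)
        assert drusen_height(1.3, 0.0) == 0.0


class TestClearance:
    def test_clearance_flux_at_baseline(self, params):
        """1000 cells/mm^2 at 25 ug/ml ApoA-I (Km 5) clear
        1000 x 0.0579 x 25/30 = 48.25 pg/mm^2/min."""
        mac = params.macrophage  # baseline density 1000, ApoA-I 25
        assert macrophage_clearance_flux(mac) == pytest.approx(48.25, rel=1e-9)
        assert macrophage_clearance_flux(mac.with_density(0.0)) == 0.0
        sat = replace(mac, saturating_apoai=True)
        assert macrophage_clearance_flux(sat) == pytest.approx(57.9, rel=1e-9)

    def test_limiting_clearance_time_about_3_years(self, params):
        """120 um at 1000 cells/mm^2 with saturating ApoA-I clears in ~3 y."""
        mac = replace(params.macrophage, saturating_apoai=True)
        traj = drusen_clearance_timecourse(120.0, mac, params.efflux)
        assert traj.time_to_clear / MIN_PER_YEAR == pytest.approx(3.0, abs=0.15)
        assert traj.heights[-1] == 0.0

    def test_500_cells_takes_more_than_5_years(self, params):
        traj = drusen_clearance_timecourse(
            120.0, params.macrophage.with_density(500.0), params.efflux
        )
        assert traj.time_to_clear / MIN_PER_YEAR > 5.0

    def test_5000_cells_takes_less_than_1_year(self, params):
        traj = drusen_clearance_timecourse(
            120.0, params.macrophage.with_density(5000.0), params.efflux
        )
        assert traj.time_to_clear / MIN_PER_YEAR < 1.0

    def test_no_macrophages_no_clearance(self, params):
        traj = drusen_clearance_timecourse(
            120.0, params.macrophage.with_density(0.0), params.efflux
        )
        assert traj.time_to_clear is None
        assert np.all(traj.heights == 120.0)

    def test_deposition_slows_clearance(self, params):
        plain = drusen_clearance_timecourse(120.0, params.macrophage, params.efflux)
        with_dep = drusen_clearance_timecourse(
            120.0, params.macrophage, params.efflux, include_deposition=True
        )
        assert with_dep.time_to_clear > plain.time_to_clear

    def test_time_inverse_in_density_and_vmax(self, params):
        """At a fixed saturation factor the clearance time is inversely
        proportional to density and to per-cell vmax."""
        mac = params.macrophage
        t1 = drusen_clearance_timecourse(120.0, mac, params.efflux).time_to_clear
        t2 = drusen_clearance_timecourse(
            120.0, mac.with_density(2 * mac.density), params.efflux
        ).time_to_clear
        t3 = drusen_clearance_timecourse(
            120.0, replace(mac, vmax_per_cell=2 * mac.vmax_per_cell), params.efflux
        ).time_to_clear
        assert t2 == pytest.approx(t1 / 2, rel=1e-9)
        assert t3 == pytest.approx(t1 / 2, rel=1e-9)

    def test_time_decreasing_and_saturating_in_apoai(self, params):
        """Raising ApoA-I shortens the clearance time, converging to the
        saturating-flag limit."""
        mac = params.macrophage
        times = [
            drusen_clearance_timecourse(
                120.0, replace(mac, c_apoai_brm=c), params.efflux
            ).time_to_clear
            for c in (6.25, 25.0, 250.0, 25000.0)
        ]
        assert np.all(np.diff(times) < 0)
        limit = drusen_clearance_timecourse(
            120.0, replace(mac, saturating_apoai=True), params.efflux
        ).time_to_clear
        assert times[-1] == pytest.approx(limit, rel=1e-3)

    def test_cleared_mass_bookkeeping(self, params):
        """Cleared Ch mass per unit area equals h0 x rho."""
        mac = replace(params.macrophage, saturating_apoai=True)
        traj = drusen_clearance_timecourse(120.0, mac, params.efflux)
        mass = macrophage_clearance_flux(mac) * traj.time_to_clear
        assert mass == pytest.approx(0.120 * params.efflux.deposit_ch_density, rel=1e-9)


class TestRequiredDensity:
    def test_ten_month_clearance_density(self, params):
        """Clearing 120 um in 10 months at saturating ApoA-I needs
        ~3,550 cells/mm^2 (printed as ~3,500)."""
        mac = replace(params.macrophage, saturating_apoai=True)
        dens = required_macrophage_density(120.0, 10 * MIN_PER_YEAR / 12, mac, params.efflux)
        assert dens == pytest.approx(3553.0, abs=2.0)
        assert dens == pytest.approx(3500.0, rel=0.05)

    def test_inverse_proportional_to_time(self, params):
        mac = replace(params.macrophage, saturating_apoai=True)
        d1 = required_macrophage_density(120.0, 1e5, mac, params.efflux)
        d2 = required_macrophage_density(120.0, 2e5, mac, params.efflux)
        assert d2 == pytest.approx(d1 / 2, rel=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(
        h0=st.floats(1.0, 300.0),
        t_clear=st.floats(1e4, 1e7),
        sat=st.booleans(),
    )
    def test_round_trip_with_timecourse(self, params, h0, t_clear, sat):
        """Running the clearance simulation at the required density clears
        h0 at exactly t_clear."""
        mac = replace(params.macrophage, saturating_apoai=sat)
        dens = required_macrophage_density(h0, t_clear, mac, params.efflux)
        traj = drusen_clearance_timecourse(h0, mac.with_density(dens), params.efflux)
        assert traj.time_to_clear == pytest.approx(t_clear, rel=1e-9)
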