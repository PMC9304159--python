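"""RRHO thermochemistry, composite assembly, isotope and scaling operations."""

import math

import numpy as np
import pytest

from oxoscope.constants import CM1_TO_KCAL, HC_OVER_KB, R_KCAL
from oxoscope.masses import ISOTOPES
from oxoscope.qc_records import Geometry, QCRecord, SchemaError
from oxoscope.synthetic_data import HarmonicPrescription, gen_harmonic_system
from oxoscope.thermochem import (
    assemble,
    hessian_frequencies,
    isotope_frequencies,
    rrho,
    scale_frequencies,
)


def make_record(frequencies=None, geometry=None, **kw):
    defaults = dict(label="t", charge=0, multiplicity=1, e_high=-1.0)
    defaults.update(kw)
    return QCRecord(frequencies=frequencies, geometry=geometry, **defaults)


class TestRRHO:
    def test_single_mode_zpe(self):
        th = rrho(make_record(frequencies=[1000.0]), T=298.15)
        assert th.zpe == pytest.approx(1.4296, abs=1e-4)

    def test_single_atom_translational_only(self):
        g = Geometry.from_atoms([("Fe", (0, 0, 0))])
        th = rrho(make_record(geometry=g, multiplicity=5, frequencies=[]), T=298.15)
        assert th.zpe == 0.0
        # enthalpy correction is 5/2 RT (translation + PV), no rotation
        assert th.h_corr == pytest.approx(2.5 * R_KCAL * 298.15, abs=1e-9)
        assert th.S > 30  # Sackur-Tetrode entropy for a heavy atom

    def test_ts_excludes_imaginary_mode(self):
        th = rrho(make_record(frequencies=[-1495.0, 3000.0, 1000.0]))
        assert th.n_imag == 1
        assert th.zpe == pytest.approx(0.5 * 4000.0 * CM1_TO_KCAL, abs=1e-9)

    def test_two_imaginary_modes_warn_but_excluded(self):
        with pytest.warns(UserWarning, match="imaginary"):
            th = rrho(make_record(frequencies=[-1495.0, -300.0, 1000.0]))
        assert th.n_imag == 2 and th.warned_extra_imag

    def test_no_modes_no_geometry_errors(self):
        with pytest.raises(SchemaError):
            rrho(make_record(frequencies=[]))

    def test_g_equals_h_minus_ts(self):
        g = Geometry.from_atoms([("O", (0, 0, 0)), ("O", (0, 0, 1.21))])
        th = rrho(make_record(frequencies=[1580.0], geometry=g, multiplicity=3))
        assert th.g_corr == pytest.approx(th.h_corr - th.T * th.S / 1000.0, abs=1e-9)

    def test_frequencies_vs_hessian_route_agree(self):
        presc = HarmonicPrescription(
            masses=[12.0, 15.99491461956, 1.00782503207],
            wavenumbers=[3100.0, 1750.0, 1200.0], elements=["C", "O", "H"],
            label="hco")
        rec = gen_harmonic_system(presc, seed=4)
        nu = hessian_frequencies(rec.hessian, rec.geometry)
        via_freq = rrho(make_record(frequencies=nu, geometry=rec.geometry,
                                    multiplicity=rec.multiplicity))
        via_hess = rrho(rec)
        assert via_freq.g_corr == pytest.approx(via_hess.g_corr, abs=0.01)

    def test_high_temperature_entropy_limit(self):
        # for hc nu / kB T < 0.05 the mode entropy approaches R(1 + ln(kBT/hc nu))
        nu, T = 20.0, 8000.0
        assert HC_OVER_KB * nu / T < 0.05
        th = rrho(make_record(frequencies=[nu]), T=T)
        s_limit = R_KCAL * (1.0 + math.log(T / (HC_OVER_KB * nu))) * 1000.0
        assert th.S == pytest.approx(s_limit, rel=0.01)

    def test_projection_leaves_internal_mode_count(self):
        presc = HarmonicPrescription(
            masses=[12.0] * 4, wavenumbers=[3000.0, 2000.0, 1500.0,
                                            1000.0, 800.0, 600.0],
            elements=["C"] * 4, label="c4")
        rec = gen_harmonic_system(presc, seed=2)
        nu = hessian_frequencies(rec.hessian, rec.geometry)
        assert len(nu) == 6  # 3N-6
        np.testing.assert_allclose(
            sorted(nu), [600, 800, 1000, 1500, 2000, 3000], atol=1e-6)


class TestAssemble:
    def test_zero_components(self):
        g = Geometry.from_atoms([("Fe", (0, 0, 0))])
        rec = make_record(e_high=0.0, e_solv=0.0, e_disp=0.0,
                          frequencies=[], geometry=g, multiplicity=5)
        asm = assemble(rec, rrho(rec), "E+ZPE+solv")
        assert asm.e_total == pytest.approx(0.0, abs=1e-12)

    def test_hartree_conversion_with_zpe(self):
        rec = make_record(e_high=-0.1, e_solv=0.0, e_disp=0.0,
                          frequencies=[1000.0])
        th = rrho(rec)
        asm = assemble(rec, th, "E+ZPE+solv")
        expected = -0.1 * 627.5095 + th.zpe
        assert asm.e_total == pytest.approx(expected, abs=1e-9)

    def test_relative_energy_mirrors_spin_gap(self):
        f = [1000.0]
        r1 = make_record(e_high=-0.1, e_solv=0.0, e_disp=0.0, frequencies=f)
        r2 = make_record(e_high=-0.1 + 0.016573, e_solv=0.0, e_disp=0.0,
                         frequencies=f)
        th = rrho(r1)
        gap = assemble(r2, th, "E+ZPE+solv").e_total \
            - assemble(r1, th, "E+ZPE+solv").e_total
        assert gap == pytest.approx(10.4, abs=1e-3)

    def test_component_sum_invariant(self):
        rec = make_record(e_high=-0.5, e_solv=-0.01, e_disp=-0.005,
                          frequencies=[1500.0, 900.0])
        th = rrho(rec)
        for scheme in ("E+ZPE+solv", "E+ZPE+solv+disp", "G"):
            asm = assemble(rec, th, scheme)
            assert asm.e_total == pytest.approx(
                sum(asm.components.values()), abs=1e-9)

    def test_missing_solvation_named(self):
        rec = make_record(e_high=-0.5, frequencies=[1000.0])
        th = rrho(rec)
        with pytest.raises(SchemaError, match="E_solv"):
            assemble(rec, th, "E+ZPE+solv")


class TestIsotopes:
    def test_empty_substitution_is_identity(self, feo_record):
        nu0 = hessian_frequencies(feo_record.hessian, feo_record.geometry)
        nu1 = isotope_frequencies(feo_record.hessian, feo_record.geometry, {})
        np.testing.assert_allclose(nu1, nu0, atol=1e-8)

    def test_feo_18o_shift_matches_reduced_mass_oracle(self, feo_record):
        m_fe, m_o16, m_o18 = (ISOTOPES["Fe56"], ISOTOPES["O16"], ISOTOPES["O18"])
        mu16 = m_fe * m_o16 / (m_fe + m_o16)
        mu18 = m_fe * m_o18 / (m_fe + m_o18)
        expected = 860.0 * math.sqrt(mu16 / mu18)
        nu18 = isotope_frequencies(
            feo_record.hessian, feo_record.geometry, {1: "O18"})
        assert nu18[0] == pytest.approx(expected, abs=1e-6)
        assert 860.0 - nu18[0] == pytest.approx(38.0, abs=0.2)

    def test_deuteration_scales_stretches_within_harmonic_bounds(self):
        presc = HarmonicPrescription(
            masses=[12.0] + [1.00782503207] * 4,
            wavenumbers=[3050.0, 3020.0, 2990.0, 2960.0, 1450.0, 1440.0,
                         1300.0, 1200.0, 900.0],
            elements=["C", "H", "H", "H", "H"], label="ch4like")
        rec = gen_harmonic_system(presc, seed=9)
        nu0 = hessian_frequencies(rec.hessian, rec.geometry)
        nu_d = isotope_frequencies(
            rec.hessian, rec.geometry, {i: "D" for i in range(1, 5)})
        ratio = np.sort(nu_d) / np.sort(nu0)
        assert np.all(ratio <= 1.0 + 1e-9)
        assert np.all(ratio >= 1.0 / math.sqrt(2.0) - 1e-9)

    def test_heavier_isotope_never_raises_any_frequency(self):
        presc = HarmonicPrescription(
            masses=[14.0030740048, 15.99491461956, 1.00782503207],
            wavenumbers=[2800.0, 1600.0, 1100.0],
            elements=["N", "O", "H"], label="noh")
        rec = gen_harmonic_system(presc, seed=11)
        nu0 = np.sort(hessian_frequencies(rec.hessian, rec.geometry))
        for idx, new_mass in ((0, 15.0001), (1, 17.99916196), (2, 2.0141)):
            nu1 = np.sort(isotope_frequencies(
                rec.hessian, rec.geometry, {idx: new_mass}))
            assert np.all(nu1 <= nu0 + 1e-8)


class TestScaling:
    def test_reported_scaled_stretch(self):
        assert scale_frequencies(np.array([860.0]), 0.95)[0] == pytest.approx(817.0)

    def test_identity(self):
        nu = np.array([3000.0, -1495.0])
        np.testing.assert_array_equal(scale_frequencies(nu, 1.0), nu)

    def test_imaginary_left_unscaled(self):
        out = scale_frequencies(np.array([-1495.0, 3000.0]), 0.95)
        np.testing.assert_allclose(out, [-1495.0, 2850.0])

    def test_scale_bounds(self):
        with pytest.raises(ValueError):
            scale_frequencies(np.array([1000.0]), 1.5)
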