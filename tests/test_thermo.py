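"""Closed-form thermodynamics: Debye-Hückel, Legendre transform,
pseudoisomer aggregation and the potential-conversion helpers."""
import math

import numpy as np
import pytest

from redoxqc import thermo
from redoxqc.thermo import (
    CONSTANTS,
    AqueousConditions,
    PhysicalConstants,
    ProtonationSpecies,
)

RT = CONSTANTS.rt_kj(298.15)
LN10 = math.log(10.0)
F = CONSTANTS.F


class TestDebyeHuckel:
    @pytest.mark.parametrize(
        "z,nh,i", [(0, 0, 0.25), (5, 0, 0.0), (1, 1, 0.5), (-2, 4, 1.0)]
    )
    def test_vanishes_when_z2_equals_nh_or_no_ions(self, z, nh, i):
        if z * z == nh or i == 0:
            assert thermo.debye_huckel_term(z, nh, i) == 0.0

    def test_closed_form_single_charge(self):
        # -alpha * 1 * 0.5 / (1 + 1.6*0.5)
        expected = -2.91482 * 0.5 / 1.8
        assert thermo.debye_huckel_term(1, 0, 0.25) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(-0.80967, abs=1e-5)

    def test_even_in_charge_sign(self):
        assert thermo.debye_huckel_term(3, 2, 0.25) == thermo.debye_huckel_term(
            -3, 2, 0.25
        )

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError, match="ionic_strength"):
            thermo.debye_huckel_term(1, 0, -0.1)


class TestLegendreTransform:
    def test_identity_at_reference_state(self):
        sp = ProtonationSpecies(charge=-1, n_hydrogens=3, dg0=12.5)
        cond = AqueousConditions(ph=0.0, ionic_strength=0.0)
        # the z^2 - N_H factor is nonzero but sqrt(I) = 0
        assert thermo.legendre_transform_species(sp, cond) == 12.5

    def test_single_proton_at_ph7(self):
        sp = ProtonationSpecies(charge=0, n_hydrogens=1, dg0=0.0)
        cond = AqueousConditions(ph=7.0, ionic_strength=0.0)
        expected = RT * LN10 * 7.0
        got = thermo.legendre_transform_species(sp, cond)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(39.955, abs=2e-3)

    def test_linearity_in_ph(self):
        sp = ProtonationSpecies(charge=1, n_hydrogens=4, dg0=-3.0)
        for ph in (2.0, 6.5, 11.0):
            step = thermo.legendre_transform_species(
                sp, AqueousConditions(ph=ph + 1, ionic_strength=0.25)
            ) - thermo.legendre_transform_species(
                sp, AqueousConditions(ph=ph, ionic_strength=0.25)
            )
            assert step == pytest.approx(4 * RT * LN10, rel=1e-10)


class TestPseudoisomer:
    def test_single_species_identity(self):
        assert thermo.pseudoisomer_energy([17.3]) == pytest.approx(17.3, rel=1e-12)

    def test_degenerate_pair_gains_rt_ln2(self):
        g = 5.0
        expected = g - RT * math.log(2.0)
        assert thermo.pseudoisomer_energy([g, g]) == pytest.approx(expected, rel=1e-12)
        assert g - thermo.pseudoisomer_energy([g, g]) == pytest.approx(1.7182, abs=1e-4)

    def test_matches_brute_force_summation(self):
        energies = [0.0, 50.0, 3.7, -1.2]
        brute = -RT * math.log(sum(math.exp(-g / RT) for g in energies))
        assert thermo.pseudoisomer_energy(energies) == pytest.approx(brute, rel=1e-12)
        # the +50 kJ/mol species is irrelevant at room temperature
        assert thermo.pseudoisomer_energy([0.0, 50.0]) == pytest.approx(0.0, abs=1e-8)

    def test_bounded_by_minimum_and_monotone_in_species(self):
        energies = [4.0, 7.0, 2.5]
        agg = thermo.pseudoisomer_energy(energies)
        assert agg <= min(energies)
        assert thermo.pseudoisomer_energy(energies + [1.0]) < agg

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            thermo.pseudoisomer_energy([])


def _ladder(charge, n_h, pkas=()):
    species = [ProtonationSpecies(charge, n_h, 0.0)]
    dg = 0.0
    for j, pka in enumerate(pkas, start=1):
        dg += RT * LN10 * pka
        species.append(ProtonationSpecies(charge - j, n_h - j, dg))
    return species


class TestReactionTransformedPotential:
    def test_identity_at_reference_conditions(self):
        cond = AqueousConditions(ph=0.0, ionic_strength=0.0)
        e = thermo.reaction_transformed_potential(
            -0.321, _ladder(0, 4), _ladder(0, 6), cond
        )
        assert e == pytest.approx(-0.321, rel=1e-12)

    def test_two_proton_couple_has_59mV_slope(self):
        e0 = 0.1
        for ph in (3.0, 7.0, 11.0):
            cond = AqueousConditions(ph=ph, ionic_strength=0.0)
            e = thermo.reaction_transformed_potential(
                e0, _ladder(0, 4), _ladder(0, 6), cond
            )
            expected = e0 - RT * 1000.0 * LN10 * ph / F
            assert e == pytest.approx(expected, rel=1e-10)
        # at pH 7 the shift is the classic -414.1 mV
        cond7 = AqueousConditions(ph=7.0, ionic_strength=0.0)
        shift = thermo.reaction_transformed_potential(
            0.0, _ladder(0, 4), _ladder(0, 6), cond7
        )
        assert shift * 1000 == pytest.approx(-414.10, abs=0.05)

    def test_reduced_side_pka_at_the_ph_raises_potential_by_rtln2(self):
        cond = AqueousConditions(ph=7.0, ionic_strength=0.0)
        base = thermo.reaction_transformed_potential(
            0.0, _ladder(0, 4), _ladder(0, 6), cond
        )
        with_pka = thermo.reaction_transformed_potential(
            0.0, _ladder(0, 4), _ladder(0, 6, pkas=(7.0,)), cond
        )
        gain = (with_pka - base) * 1000
        assert gain == pytest.approx(RT * math.log(2) * 1e6 / (2 * F), rel=1e-9)
        assert gain == pytest.approx(8.90, abs=0.01)

    def test_inconsistent_ladder_rejected(self):
        bad = [ProtonationSpecies(0, 4, 0.0), ProtonationSpecies(0, 2, 10.0)]
        with pytest.raises(ValueError, match="step"):
            thermo.reaction_transformed_potential(
                0.0, _ladder(0, 4), bad, AqueousConditions()
            )


class TestMillimolarStandard:
    def test_one_to_one_couple_unchanged(self):
        cond = AqueousConditions()
        for cat in ("G1", "G2", "G4"):
            stoich = thermo.category_stoichiometry(cat)
            assert thermo.to_millimolar_standard(-0.2, stoich, cond) == pytest.approx(
                -0.2, rel=1e-12
            )

    def test_ammonia_substrate_shifts_by_rtln1000(self):
        cond = AqueousConditions()
        stoich = thermo.category_stoichiometry("G3")
        shifted = thermo.to_millimolar_standard(-0.136, stoich, cond)
        assert abs(shifted - (-0.136)) * 1000 == pytest.approx(88.73, abs=0.01)

    def test_molar_standard_state_is_identity(self):
        cond = AqueousConditions(standard_concentration=1.0)
        for cat in ("G1", "G2", "G3", "G4"):
            stoich = thermo.category_stoichiometry(cat)
            assert thermo.to_millimolar_standard(-0.2, stoich, cond) == -0.2

    def test_g3_moves_toward_g2_at_millimolar(self):
        """Carbonyl->hydroxycarbon and carbonyl->amine couples with the same
        underlying energetics must coincide at the 1 mM state; the ammonia
        dilution therefore has to *lower* the G3 potential."""
        cond = AqueousConditions()
        e_g2 = -0.225
        e_g3_standard = e_g2 + 0.0887343925152446  # same chemistry, 1 M state
        e_g3_m = thermo.to_millimolar_standard(
            e_g3_standard, thermo.category_stoichiometry("G3"), cond
        )
        assert e_g3_m == pytest.approx(e_g2, abs=1e-6)


class TestCarrierHelpers:
    def test_activation_correction_shifts_by_250mV(self):
        assert thermo.activation_correction(-0.550) == pytest.approx(-0.300, rel=1e-12)
        e = -0.4812
        assert thermo.activation_correction(e) - 0.250 == pytest.approx(e)

    def test_activation_shift_from_hydrolysis_energy(self):
        # 50 kJ/mol over two electrons: the unrounded basis of the +250 mV default
        assert thermo.activation_shift_from_hydrolysis(50.0) * 1000 == pytest.approx(
            259.1, abs=0.05
        )

    def test_equilibrium_ratio_identity_and_reference_values(self):
        assert thermo.equilibrium_ratio(-0.3, -0.3) == 1.0
        # NAD(P) at -330 mV vs a carbonyl couple at -225 mV
        ratio = thermo.equilibrium_ratio(-0.330, -0.225)
        assert ratio == pytest.approx(3547.5, abs=0.5)
        assert round(ratio / 100) * 100 == 3500  # two significant figures
        assert thermo.equilibrium_ratio(-0.330, -0.268) == pytest.approx(
            124.78, abs=0.01
        )

    def test_equilibrium_ratio_reciprocal_under_swap(self):
        a, b = -0.330, -0.225
        assert thermo.equilibrium_ratio(a, b) * thermo.equilibrium_ratio(
            b, a
        ) == pytest.approx(1.0, rel=1e-12)

    def test_reversibility_window(self):
        assert thermo.reversibility_window(-0.38, -0.25, 1.0) == (-0.38, -0.25)
        lo, hi = thermo.reversibility_window(-0.380, -0.250, 1e4, round_to_mv=5.0)
        assert (lo, hi) == (pytest.approx(-0.500), pytest.approx(-0.130))
        lo, hi = thermo.reversibility_window(0.0, 0.0, 1e2)
        assert hi * 1000 == pytest.approx(59.16, abs=0.01)
        with pytest.raises(ValueError):
            thermo.reversibility_window(-0.3, -0.2, 0.5)

    def test_keq_shift(self):
        assert thermo.keq_shift_to_potential(1.0) == 0.0
        shift = thermo.keq_shift_to_potential(350.0) * 1000
        assert shift == pytest.approx(75.25, abs=0.01)
        assert round(shift / 5) * 5 == 75
        assert thermo.keq_shift_to_potential(1e4) * 1000 == pytest.approx(
            118.31, abs=0.01
        )
        with pytest.raises(ValueError):
            thermo.keq_shift_to_potential(0.0)


class TestConversionsAndTypes:
    def test_volts_energy_round_trip(self):
        for e in (-0.55, -0.015, 0.3):
            back = thermo.kj_per_mol_to_volts(thermo.volts_to_kj_per_mol(e))
            assert back == pytest.approx(e, rel=1e-12)

    def test_constants_immutable_and_positive(self):
        with pytest.raises(Exception):
            CONSTANTS.F = 1.0  # type: ignore[misc]
        with pytest.raises(ValueError):
            PhysicalConstants(R=-1.0)

    def test_conditions_validated(self):
        with pytest.raises(ValueError):
            AqueousConditions(ionic_strength=-0.1)
        with pytest.raises(ValueError):
            AqueousConditions(temperature=0.0)

    def test_estimate_requires_millimolar_state_for_em(self):
        cond = AqueousConditions(standard_concentration=1.0)
        with pytest.raises(ValueError, match="1 mM"):
            thermo.PotentialEstimate("p", -0.2, -0.3, -0.3, "qc_raw", cond)
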