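"""Landscape assembly, spin ordering, selectivity, RDS, spin densities, H-bonds."""

import numpy as np
import pytest

from oxoscope.landscape import (
    Contact,  # noqa: F401 - re-exported dataclass used in type sanity below
    Landscape,
    StationaryPoint,
    group_spin,
    hbond_census,
    rds,
    relative_table,
    selectivity_from_barriers,
    selectivity_report,
    spin_ordering,
    spin_ordering_from_energies,
)
from oxoscope.qc_records import Geometry, QCRecord
from oxoscope.synthetic_data import (
    TABLE1_DG,
    LandscapePrescription,
    gen_landscape,
    preset_landscape,
)


def simple_record(label, e_high, freqs=(1000.0,), **kw):
    return QCRecord(label=label, charge=0, multiplicity=5, e_high=e_high,
                    e_solv=0.0, e_disp=0.0,
                    frequencies=np.array(freqs, dtype=float), **kw)


class TestRelativeTable:
    def test_single_reference_row_is_zero(self):
        pt = StationaryPoint(simple_record("re", -100.0), role="Re", model="M")
        table = relative_table(Landscape([pt]))
        assert table.loc[0, "dE_zpe"] == 0.0 and table.loc[0, "dG"] == 0.0

    def test_prescribed_barriers_recovered(self):
        scape = gen_landscape(preset_landscape("tauD-modelB"), seed=5)
        table = relative_table(scape).set_index("label")
        for label, expected in (("B_TS1_C2S", 9.3), ("B_TS1_C2R", 10.9),
                                ("B_TS1_C1S", 11.8), ("B_TS1_C1R", 12.2),
                                ("B_IM1_C2S", -8.1), ("B_IM1_C1S", -8.8)):
            assert table.loc[label, "dE_zpe"] == pytest.approx(expected, abs=1e-9)

    def test_gauge_invariance_under_constant_shift(self):
        presc = preset_landscape("tauD-modelB")
        scape = gen_landscape(presc, seed=5)
        t0 = relative_table(scape).set_index("label")
        for p in scape.points:
            p.record.e_high += 0.731  # same constant on every species
        t1 = relative_table(scape).set_index("label")
        np.testing.assert_allclose(t1["dE_zpe"], t0["dE_zpe"], atol=1e-8)
        np.testing.assert_allclose(t1["dG"], t0["dG"], atol=1e-8)

    def test_ts_requires_single_imaginary_mode(self):
        with pytest.raises(ValueError, match="exactly one imaginary"):
            StationaryPoint(simple_record("ts", -1.0), role="TS1_HA", pathway="C1R")

    def test_minimum_requires_no_imaginary_mode(self):
        with pytest.raises(ValueError, match="no imaginary"):
            StationaryPoint(simple_record("re", -1.0, freqs=(-900.0, 1000.0)),
                            role="Re")

    def test_one_reference_per_slice_enforced(self):
        pts = [StationaryPoint(simple_record(f"re{i}", -100.0), role="Re",
                               model="M") for i in range(2)]
        with pytest.raises(ValueError, match="exactly one"):
            Landscape(pts)


class TestSpinOrdering:
    def test_published_gap_fixture(self):
        so = spin_ordering_from_energies({1: 19.2, 3: 10.4, 5: 0.0, 7: 10.9})
        assert so.ground_multiplicity == 5
        assert [m for m, _ in so.ordering] == [5, 3, 7, 1]
        assert [g for _, g in so.ordering] == pytest.approx([0.0, 10.4, 10.9, 19.2])

    def test_single_multiplicity_trivial(self):
        pt = StationaryPoint(simple_record("re", -100.0), role="Re", model="M")
        so = spin_ordering([pt])
        assert so.ground_multiplicity == 5 and so.ordering == [(5, 0.0)]

    def test_permutation_invariance(self, rng):
        energies = {1: 19.2, 3: 10.4, 5: 0.0, 7: 10.9}
        items = list(energies.items())
        for _ in range(5):
            perm = [items[i] for i in rng.permutation(len(items))]
            assert spin_ordering_from_energies(dict(perm)) == \
                spin_ordering_from_energies(energies)

    def test_duplicate_multiplicity_rejected(self):
        pts = [StationaryPoint(simple_record(f"re{i}", -100.0 - i), role="Re",
                               model=f"M{i}") for i in range(2)]
        with pytest.raises(ValueError, match="duplicate"):
            spin_ordering(pts)

    def test_generated_gaps_recovered(self):
        scape = gen_landscape(preset_landscape("tauD-modelB"), seed=8)
        so = spin_ordering([p for p in scape.points if p.role == "Re"])
        gaps = dict(so.ordering)
        assert so.ground_multiplicity == 5
        assert gaps[3] == pytest.approx(10.4, abs=1e-9)
        assert gaps[7] == pytest.approx(10.9, abs=1e-9)
        assert gaps[1] == pytest.approx(19.2, abs=1e-9)


class TestSelectivity:
    @pytest.mark.parametrize("model,expected_carbon", [
        ("B", "C2"), ("C", "C1"), ("DA", "C1"), ("DB", "C2"),
    ])
    def test_published_barrier_sets_reproduce_selectivity_reversal(
            self, model, expected_carbon):
        verdict = selectivity_from_barriers(TABLE1_DG[model], model=model)
        assert verdict.dominant_carbon == expected_carbon

    def test_model_c_dominant_c1(self):
        verdict = selectivity_from_barriers(TABLE1_DG["C"])
        assert verdict.dominant_carbon == "C1" and verdict.call == "dominant"

    def test_model_b_lowest_and_window(self):
        verdict = selectivity_from_barriers(TABLE1_DG["B"])
        assert verdict.lowest_pathway == "C2S"
        assert verdict.window == pytest.approx(2.3, abs=1e-12)

    def test_equal_barriers_unselective(self):
        verdict = selectivity_from_barriers(
            {"C1R": 10.0, "C1S": 10.0, "C2S": 10.0, "C2R": 10.0})
        assert verdict.dominant_carbon == "none"
        assert verdict.call == "unselective"
        for f in verdict.fractions.values():
            assert f == pytest.approx(0.25, rel=1e-12)

    def test_report_from_generated_landscape(self):
        scape = gen_landscape(preset_landscape("tauD-modelC"), seed=2)
        report = selectivity_report(scape)
        assert report["C"].dominant_carbon == "C1"
        assert report["C"].barriers["C1R"] == pytest.approx(17.1, abs=1e-9)


class TestRDS:
    def _two_ts_landscape(self, ts1=9.3, ts2=2.0):
        presc = LandscapePrescription(
            model="M", spin=5,
            ts1_de_zpe={"C1R": ts1}, ts1_dg={"C1R": ts1},
            im1_de_zpe={"C1R": -8.0},
            ts2_de_zpe={"C1R": ts2}, ts2_dg={"C1R": ts2},
        )
        return gen_landscape(presc, seed=1)

    def test_highest_ts_wins(self):
        res = rds(self._two_ts_landscape(), "C1R")
        assert res.role == "TS1_HA" and res.energy == pytest.approx(9.3, abs=1e-9)

    def test_single_ts(self):
        presc = LandscapePrescription(model="M", ts1_de_zpe={"C2S": 11.0})
        res = rds(gen_landscape(presc, seed=1), "C2S")
        assert res.role == "TS1_HA" and not res.tie

    def test_tie_prefers_earlier_step_and_flags(self):
        res = rds(self._two_ts_landscape(ts1=9.3, ts2=9.3), "C1R")
        assert res.role == "TS1_HA" and res.tie

    def test_estimated_barriers_excluded(self):
        presc = LandscapePrescription(
            model="M", ts1_de_zpe={"C1R": 5.0},
            im1_de_zpe={"C1R": -8.0},
            ts2_de_zpe={"C1R": 9.0}, ts2_estimated={"C1R"})
        res = rds(gen_landscape(presc, seed=1), "C1R")
        assert res.role == "TS1_HA"

    def test_no_ts_errors(self):
        presc = LandscapePrescription(model="M", ts1_de_zpe={"C1R": 5.0})
        with pytest.raises(ValueError, match="no located"):
            rds(gen_landscape(presc, seed=1), "C2S")


class TestGroupSpin:
    def rec(self, rho):
        return QCRecord(label="s", charge=0, multiplicity=5, e_high=-1.0,
                        spin_densities=np.array(rho))

    def test_total_conservation(self):
        rho = [3.05, 0.55, -0.60, -0.02, 0.02]
        gs = group_spin(self.rec(rho), {"all": list(range(5))})
        assert gs.groups["all"] == pytest.approx(sum(rho), abs=1e-12)
        assert gs.remainder == 0.0

    def test_substrate_group_value(self):
        # FeO carries ~3.6, substrate a down-spin radical of -0.60
        rho = [3.05, 0.55, -0.25, -0.20, -0.15]
        gs = group_spin(self.rec(rho), {"FeO": [0, 1], "substrate": [2, 3, 4]})
        assert gs.groups["substrate"] == pytest.approx(-0.60, abs=1e-12)

    def test_empty_group_and_remainder(self):
        gs = group_spin(self.rec([1.0, 2.0]), {"empty": []})
        assert gs.groups["empty"] == 0.0
        assert gs.remainder == pytest.approx(3.0)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            group_spin(self.rec([1.0, 2.0]), {"a": [0], "b": [0]})

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            group_spin(self.rec([1.0]), {"a": [3]})

    def test_random_disjoint_partitions_conserve_total(self, rng):
        rho = rng.uniform(-1, 1, size=12)
        rec = self.rec(rho)
        idx = rng.permutation(12)
        groups = {"g1": list(idx[:4]), "g2": list(idx[4:9])}
        gs = group_spin(rec, groups)
        assert gs.groups["g1"] + gs.groups["g2"] + gs.remainder == \
            pytest.approx(rho.sum(), abs=1e-9)


class TestHbond:
    def test_amine_oxo_contact_distance_only(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.961]])
        contacts = hbond_census(coords, donors=[0], acceptors=[1], d_max=2.5)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(1.961, abs=1e-9)

    def test_threshold_excludes(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.961]])
        assert hbond_census(coords, [0], [1], d_max=1.5) == []

    def test_angle_mode_filters_bent_contacts(self):
        # donor-H pointing at acceptor (linear) vs 90-degree geometry
        g = Geometry.from_atoms([
            ("N", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 1.0)),
            ("O", (0.0, 0.0, 2.8)), ("O", (0.0, 1.9, 1.0))])
        linear = hbond_census(g, donors=[(0, 1)], acceptors=[2, 3],
                              d_max=2.0, angle_min=120.0)
        assert [c.acceptor for c in linear] == [2]

    def test_angle_mode_without_hydrogens_suggests_distance_only(self):
        with pytest.raises(ValueError, match="distance-only"):
            hbond_census(np.zeros((2, 3)), donors=[0], acceptors=[1],
                         mode="angle")

    def test_lattice_count_matches_brute_force(self, rng):
        coords = rng.uniform(0, 12, size=(30, 3))
        donors = list(range(10))
        acceptors = list(range(10, 30))
        contacts = hbond_census(coords, donors, acceptors, d_max=3.0)
        brute = sum(
            1 for d in donors for a in acceptors
            if np.linalg.norm(coords[a] - coords[d]) <= 3.0)
        assert len(contacts) == brute
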