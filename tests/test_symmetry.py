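"""d-spacings, reflection enumeration and orbit reduction, checked against
independent brute-force oracles and (where available) gemmi."""

import io
import math

import numpy as np
import pytest

from natsad.symmetry import (
    SpaceGroup,
    UnitCell,
    count_unique,
    d_spacing,
    enumerate_reflections,
    parse_triplet,
    reduce_unique,
    write_reflections,
)

from conftest import (
    BUNDLED_GROUPS,
    oracle_d,
    oracle_enumerate,
    oracle_is_absent,
    oracle_orbits,
    oracle_unique_count,
    random_cell,
)


class TestDSpacing:
    def test_cubic_axis(self):
        assert d_spacing(UnitCell(10, 10, 10), (1, 0, 0)) == pytest.approx(10.0)

    def test_cubic_body_diagonal(self):
        assert d_spacing(UnitCell(10, 10, 10), (1, 1, 1)) == pytest.approx(
            10 / math.sqrt(3)
        )

    def test_triclinic_matches_reciprocal_basis_oracle(self):
        cell = UnitCell(7, 9, 11, 95, 100, 105)
        assert d_spacing(cell, (1, 2, 3)) == pytest.approx(
            oracle_d(cell, (1, 2, 3)), rel=1e-10
        )

    def test_random_cells_match_oracle(self, rng):
        for _ in range(20):
            cell = random_cell("triclinic", rng)
            hkl = tuple(int(x) for x in rng.integers(-5, 6, size=3))
            if hkl == (0, 0, 0):
                continue
            assert d_spacing(cell, hkl) == pytest.approx(
                oracle_d(cell, hkl), rel=1e-10
            )

    def test_zero_triple_rejected(self):
        with pytest.raises(ValueError):
            d_spacing(UnitCell(10, 10, 10), (0, 0, 0))


class TestEnumeration:
    def test_cubic_count_is_32(self):
        """a=10, d_min=5: exactly the triples with h^2+k^2+l^2 <= 4."""
        refl = enumerate_reflections(UnitCell(10, 10, 10), 5.0)
        assert len(refl) == 32
        expected = {
            (h, k, l)
            for h in range(-2, 3)
            for k in range(-2, 3)
            for l in range(-2, 3)
            if (h, k, l) != (0, 0, 0) and h * h + k * k + l * l <= 4
        }
        assert {r.hkl for r in refl.entries} == expected

    def test_empty_beyond_longest_axis(self):
        refl = enumerate_reflections(UnitCell(10, 12, 14), 15.0)
        assert len(refl) == 0

    def test_axis_permutation_invariance(self):
        count_abc = len(enumerate_reflections(UnitCell(11, 14, 17), 3.0))
        count_cab = len(enumerate_reflections(UnitCell(17, 11, 14), 3.0))
        assert count_abc == count_cab

    def test_matches_brute_force_on_random_cell(self, rng):
        cell = random_cell("triclinic", rng)
        mine = {r.hkl for r in enumerate_reflections(cell, 4.0).entries}
        assert mine == set(oracle_enumerate(cell, 4.0))

    def test_non_positive_dmin_rejected(self):
        with pytest.raises(ValueError):
            enumerate_reflections(UnitCell(10, 10, 10), 0.0)


class TestOperatorParsing:
    @pytest.mark.parametrize(
        "triplet", ["x,y,z", "-x,y+1/2,-z", "-y,x-y,z+1/3", "x+1/2,y+1/2,z"]
    )
    def test_roundtrip_through_triplet(self, triplet):
        op = parse_triplet(triplet)
        assert parse_triplet(op.triplet()) == op

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            parse_triplet("x,y")
        with pytest.raises(ValueError):
            parse_triplet("x,q,z")

    def test_group_closure_enforced(self):
        with pytest.raises(ValueError, match="closed"):
            SpaceGroup.from_triplets("broken", ["x,y,z", "-x,y+1/2,-z",
                                                "x,-y,z+1/4"])

    def test_space_group_from_file(self, tmp_path):
        path = tmp_path / "custom.txt"
        path.write_text("# Hermann-Mauguin: P 21\nx,y,z\n-x,y+1/2,-z\n")
        sg = SpaceGroup.from_file(path)
        assert sg.symbol == "P 21"
        assert sg.order == 2

    def test_unknown_symbol_lists_alternatives(self):
        with pytest.raises(LookupError, match="operator file"):
            SpaceGroup.from_symbol("P213")


class TestReduction:
    def test_p1_friedel_merging_halves_count(self):
        cell = UnitCell(10, 10, 10)
        refl = enumerate_reflections(cell, 5.0)
        merged = reduce_unique(refl, SpaceGroup.from_symbol("P1"),
                               merge_friedel=True)
        assert len(merged) == len(refl) // 2
        assert merged.n_unique == 16

    def test_p21_screw_axis_absences(self):
        """(0, k, 0) with odd k: phase exp(2 pi i k/2) = -1 under the screw."""
        sg = SpaceGroup.from_symbol("P21")
        cell = UnitCell(10, 10, 10)
        refl = enumerate_reflections(cell, 2.0)
        reduced = reduce_unique(refl, sg, merge_friedel=True)
        by_hkl = {r.hkl: r for r in reduced.entries}
        assert by_hkl[(0, 1, 0)].absent
        assert by_hkl[(0, 3, 0)].absent
        assert not by_hkl[(0, 2, 0)].absent
        assert not by_hkl[(0, 4, 0)].absent
        # and the flags agree with the hand phase-restriction oracle everywhere
        for r in reduced.entries:
            assert r.absent == oracle_is_absent(sg, r.hkl)

    def test_reduction_idempotent(self):
        sg = SpaceGroup.from_symbol("P212121")
        cell = UnitCell(20, 20, 20)
        reduced = reduce_unique(enumerate_reflections(cell, 4.0), sg)
        again = reduce_unique(reduced, sg)
        assert {r.hkl for r in again.entries} == {r.hkl for r in reduced.entries}
        assert again.n_unique == reduced.n_unique

    def test_orbit_sizes_sum_to_enumerated_count(self):
        cell = UnitCell(20, 20, 20)
        sg = SpaceGroup.from_symbol("P212121")
        indices = [r.hkl for r in enumerate_reflections(cell, 4.0).entries]
        orbits = oracle_orbits(sg, indices, merge_friedel=True)
        assert sum(len(o) for o in orbits) == len(indices)
        assert len(orbits) == len(reduce_unique(
            enumerate_reflections(cell, 4.0), sg, merge_friedel=True))

    def test_no_centrics_from_pure_rotations_unmerged(self):
        """Rotation-only group, Friedel off: no orbit contains -h."""
        sg = SpaceGroup.from_symbol("P212121")
        cell = UnitCell(20, 20, 20)
        reduced = reduce_unique(enumerate_reflections(cell, 4.0), sg,
                                merge_friedel=False)
        # 2-fold rotations do map some zone reflections to -h: (h,0,0) etc.
        # are genuinely centric. Away from the zones nothing is centric.
        for r in reduced.entries:
            if 0 not in r.hkl:
                assert not r.centric

    def test_centric_flags_match_definition(self):
        sg = SpaceGroup.from_symbol("C2")
        cell = UnitCell(15, 15, 15, 90, 95, 90)
        reduced = reduce_unique(enumerate_reflections(cell, 3.0), sg)
        rots = [np.array(op.rot) for op in sg.operators]
        for r in reduced.entries:
            h = np.array(r.hkl)
            expected = any(tuple(h @ rot) == tuple(-h) for rot in rots)
            assert r.centric == expected

    def test_p212121_count_matches_orbit_oracle(self):
        cell = UnitCell(20, 20, 20)
        sg = SpaceGroup.from_symbol("P212121")
        assert count_unique(cell, sg, 4.0) == oracle_unique_count(cell, sg, 4.0)

    def test_c2_count_matches_orbit_oracle(self):
        cell = UnitCell(15, 15, 15, 90, 95, 90)
        sg = SpaceGroup.from_symbol("C2")
        assert count_unique(cell, sg, 3.0) == oracle_unique_count(cell, sg, 3.0)

    @pytest.mark.parametrize("symbol", sorted(BUNDLED_GROUPS))
    def test_all_bundled_groups_match_oracle_on_random_cells(self, symbol, rng):
        system, d_min = BUNDLED_GROUPS[symbol]
        sg = SpaceGroup.from_symbol(symbol)
        cell = random_cell(system, rng)
        assert count_unique(cell, sg, d_min) == oracle_unique_count(cell, sg, d_min)

    def test_unmerged_counts_exceed_merged(self):
        cell = UnitCell(20, 20, 20)
        sg = SpaceGroup.from_symbol("P212121")
        merged = count_unique(cell, sg, 4.0, merge_friedel=True)
        unmerged = count_unique(cell, sg, 4.0, merge_friedel=False)
        assert merged < unmerged <= 2 * merged


class TestGemmiCrossCheck:
    """Independent route: gemmi's symmetry engine as the oracle."""

    gemmi = pytest.importorskip("gemmi")

    @pytest.mark.parametrize(
        "symbol, cell_par, d_min",
        [
            ("P212121", (20, 20, 20, 90, 90, 90), 4.0),
            ("C2", (15, 16, 17, 90, 95, 90), 3.0),
            ("P6122", (22, 22, 30, 90, 90, 120), 3.5),
            ("R3", (20, 20, 30, 90, 90, 120), 3.5),
            ("F222", (20, 24, 28, 90, 90, 90), 3.5),
        ],
    )
    def test_unique_counts(self, symbol, cell_par, d_min):
        import gemmi

        sg = gemmi.SpaceGroup(symbol)
        ops = sg.operations()
        gcell = gemmi.UnitCell(*cell_par)
        uniq = set()
        hmax = [int(np.ceil(ax / d_min)) for ax in cell_par[:3]]
        for h in range(-hmax[0], hmax[0] + 1):
            for k in range(-hmax[1], hmax[1] + 1):
                for l in range(-hmax[2], hmax[2] + 1):
                    if (h, k, l) == (0, 0, 0):
                        continue
                    if gcell.calculate_d((h, k, l)) < d_min - 1e-9:
                        continue
                    if ops.is_systematically_absent((h, k, l)):
                        continue
                    best = None
                    for op in ops:
                        img = op.apply_to_hkl((h, k, l))
                        for m in (img, [-x for x in img]):
                            t = tuple(m)
                            if best is None or t > best:
                                best = t
                    uniq.add(best)
        mine = count_unique(UnitCell(*cell_par), SpaceGroup.from_symbol(symbol),
                            d_min)
        assert mine == len(uniq)


class TestMonotonicityAndExport:
    def test_count_monotone_in_resolution(self):
        cell = UnitCell(20, 25, 30)
        sg = SpaceGroup.from_symbol("P212121")
        assert count_unique(cell, sg, 2.0) >= count_unique(cell, sg, 3.0)

    def test_fixed_width_export_roundtrip(self):
        cell = UnitCell(10, 10, 10)
        reduced = reduce_unique(enumerate_reflections(cell, 5.0),
                                SpaceGroup.from_symbol("P1"))
        buf = io.StringIO()
        write_reflections(buf, reduced)
        lines = [ln for ln in buf.getvalue().splitlines()
                 if not ln.startswith("#")]
        assert len(lines) == len(reduced)
        h, k, l, d, centric, absent = lines[0].split()
        assert (int(h), int(k), int(l)) in {r.hkl for r in reduced.entries}
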