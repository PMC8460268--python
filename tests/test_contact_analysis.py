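import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coaclash.contact_analysis import (
    VdwRadiiTable,
    census_residue_table,
    census_union,
    clash_profile,
    count_clashes,
    distinct_protein_atoms,
    distinct_protein_residues,
    score_clashes,
    short_contact_census,
    vdw_overlap,
)
from coaclash.coa_geometry import generate_conformers
from coaclash.errors import ParameterError, UnknownElementError
from coaclash.structure_io import AtomRecord, select_atoms
from coaclash.synthetic_data import angle_in_windows, make_tunnel_fixture


def _atom(serial, name, element, xyz, res_seq=1, chain="A", res_name="ALA"):
    return AtomRecord(serial, name, element, res_name, res_seq, chain,
                      np.asarray(xyz, dtype=float))


def brute_force_clash_count(protein_atoms, flag_atoms, flag_coords, radii, threshold):
    """Independent all-pairs O(n·m) scan."""
    count = 0
    for p in protein_atoms:
        rp = radii.radius(p.element)
        hit = False
        for fa, fx in zip(flag_atoms, flag_coords):
            d = float(np.linalg.norm(p.xyz - fx))
            if rp + radii.radius(fa.element) - d > threshold:
                hit = True
                break
        count += hit
    return count


class TestVdwOverlap:
    @pytest.mark.parametrize(
        "d,expected", [(3.00, 0.40), (3.40, 0.00), (3.20, 0.20)]
    )
    def test_two_carbons(self, d, expected):
        a = _atom(1, "CA", "C", (0, 0, 0))
        b = _atom(2, "CA", "C", (d, 0, 0))
        assert vdw_overlap(a, b, VdwRadiiTable.default()) == pytest.approx(expected)

    def test_overlap_point_two_is_not_a_clash(self):
        a = _atom(1, "CA", "C", (0, 0, 0))
        b = _atom(2, "CB", "C", (3.20, 0, 0))
        res = count_clashes([a], [b], radii=VdwRadiiTable.default(), threshold=0.25)
        assert res.clash_count == 0

    def test_unknown_element(self):
        a = _atom(1, "CA", "C", (0, 0, 0))
        b = _atom(2, "XX", "Zz", (1, 0, 0))
        with pytest.raises(UnknownElementError, match="Zz"):
            vdw_overlap(a, b, VdwRadiiTable.default())


class TestRadiiTable:
    def test_default_values(self):
        t = VdwRadiiTable.default()
        assert t.radius("C") == 1.70
        assert t.radius("n") == 1.55  # case-insensitive

    def test_out_of_band_radius_rejected(self):
        with pytest.raises(ParameterError):
            VdwRadiiTable({"C": 3.5})

    def test_tsv_round_trip(self, tmp_path):
        t = VdwRadiiTable({"C": 1.7, "N": 1.55}, source="test")
        path = tmp_path / "radii.tsv"
        t.to_tsv(path)
        back = VdwRadiiTable.from_tsv(path)
        assert back.as_dict() == t.as_dict()


class TestCountClashes:
    def test_no_geometry_overlap_gives_zero(self):
        protein = [_atom(1, "CA", "C", (0, 0, 0))]
        flag = [_atom(2, "F1", "C", (50, 0, 0))]
        res = count_clashes(protein, flag)
        assert (res.clash_count, res.score, res.contacts) == (0, 0, [])

    def test_empty_flag_gives_zero(self):
        res = count_clashes([_atom(1, "CA", "C", (0, 0, 0))], [])
        assert res.clash_count == 0

    def test_distinct_atom_counting(self):
        protein = [_atom(1, "CA", "C", (0, 0, 0))]
        flag = [
            _atom(2, "F1", "C", (1, 0, 0)),
            _atom(3, "F2", "C", (0, 1, 0)),
            _atom(4, "F3", "C", (0, 0, 1)),
        ]
        res = count_clashes(protein, flag)
        assert res.clash_count == 1
        assert len(res.contacts) == 3

    def test_non_backbone_selection_rejected(self):
        protein = [_atom(1, "CG", "C", (0, 0, 0))]
        with pytest.raises(ParameterError, match="CG"):
            count_clashes(protein, [_atom(2, "F1", "C", (1, 0, 0))])

    def test_matches_brute_force_on_tunnel_every_angle(self, tunnel):
        radii = VdwRadiiTable.default()
        conf = generate_conformers(tunnel.split, 5.0)
        sel = select_atoms(tunnel.structure, tunnel.n_domain().selection)
        for angle, frame in zip(conf.angles, conf.flag_coords):
            res = count_clashes(sel, tunnel.split.flag, flag_coords=frame,
                                radii=radii, threshold=tunnel.threshold)
            oracle = brute_force_clash_count(
                sel, tunnel.split.flag, frame, radii, tunnel.threshold
            )
            assert res.clash_count == oracle

    def test_permuting_atom_order_changes_no_count(self, tunnel):
        rng = np.random.default_rng(3)
        conf = generate_conformers(tunnel.split, 90.0)
        sel = select_atoms(tunnel.structure, tunnel.n_domain().selection)
        shuffled = [sel[i] for i in rng.permutation(len(sel))]
        for frame in conf.flag_coords:
            a = count_clashes(sel, tunnel.split.flag, flag_coords=frame)
            b = count_clashes(shuffled, tunnel.split.flag, flag_coords=frame)
            assert a.clash_count == b.clash_count

    def test_raising_threshold_never_increases_count(self, tunnel):
        conf = generate_conformers(tunnel.split, 30.0)
        sel = select_atoms(tunnel.structure, tunnel.n_domain().selection)
        frame = conf.flag_coords[3]
        counts = [
            count_clashes(sel, tunnel.split.flag, flag_coords=frame,
                          threshold=t).clash_count
            for t in (0.0, 0.25, 0.5, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestScoreClashes:
    @pytest.mark.parametrize(
        "count,score",
        [(0, 0), (1, 0), (2, 1), (9, 1), (10, 2), (29, 2), (30, 3), (35, 3)],
    )
    def test_legend_thresholds(self, count, score):
        assert score_clashes(count) == score

    def test_step_function_on_integers_0_100(self):
        expected = [
            3 if n >= 30 else 2 if n >= 10 else 1 if n >= 2 else 0
            for n in range(101)
        ]
        assert [score_clashes(n) for n in range(101)] == expected

    @given(st.integers(min_value=0, max_value=500))
    @settings(deadline=None, derandomize=True)
    def test_monotone_nondecreasing(self, n):
        assert score_clashes(n + 1) >= score_clashes(n)

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            score_clashes(-1)


class TestClashProfile:
    def test_profile_covers_every_angle_once(self, tunnel):
        conf = generate_conformers(tunnel.split, 1.0)
        sel = select_atoms(tunnel.structure, tunnel.n_domain().selection)
        prof = clash_profile(None, conf, sel, donor_id="toy")
        assert len(prof.results) == 360
        assert [r.angle for r in prof.results] == list(range(360))

    def test_nonzero_only_inside_analytic_window(self, tunnel):
        conf = generate_conformers(tunnel.split, 1.0)
        sel = select_atoms(tunnel.structure, tunnel.n_domain().selection)
        prof = clash_profile(None, conf, sel)
        for r in prof.results:
            if r.score > 0:
                assert angle_in_windows(r.angle, tunnel.expected_clash_window)

    def test_window_interior_actually_clashes(self, tunnel):
        conf = generate_conformers(tunnel.split, 1.0)
        sel = select_atoms(tunnel.structure, tunnel.n_domain().selection)
        prof = clash_profile(None, conf, sel)
        by_angle = {r.angle: r.clash_count for r in prof.results}
        w0, w1 = tunnel.params["wall_azimuth"]
        for angle in range(int(w0), int(w1) + 1):
            assert by_angle[float(angle)] > 0

    def test_summary_mean(self, tunnel):
        conf = generate_conformers(tunnel.split, 45.0)
        sel = select_atoms(tunnel.structure, tunnel.n_domain().selection)
        prof = clash_profile(None, conf, sel)
        counts = [r.clash_count for r in prof.results]
        assert prof.summary["mean_clash_count"] == pytest.approx(np.mean(counts))

    def test_csv_export(self, tunnel, tmp_path):
        import pandas as pd

        conf = generate_conformers(tunnel.split, 90.0)
        sel = select_atoms(tunnel.structure, tunnel.n_domain().selection)
        prof = clash_profile(None, conf, sel)
        path = tmp_path / "profile.csv"
        prof.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["angle", "clash_count", "score"]
        assert len(df) == 4


class TestCensus:
    def test_cutoff_behavior(self):
        protein = [_atom(1, "CA", "C", (0, 0, 0))]
        near = [_atom(2, "S1P", "S", (2.4, 0, 0))]
        far = [_atom(3, "S1P", "S", (2.6, 0, 0))]
        assert len(short_contact_census(protein, near, cutoff=2.5)) == 1
        assert len(short_contact_census(protein, far, cutoff=2.5)) == 0

    def test_zero_cutoff_empty(self):
        protein = [_atom(1, "CA", "C", (0, 0, 0))]
        ligand = [_atom(2, "F1", "C", (0.5, 0, 0))]
        assert short_contact_census(protein, ligand, cutoff=0.0) == []

    def test_widening_cutoff_never_loses_contacts(self):
        rng = np.random.default_rng(11)
        protein = [_atom(i, "CA", "C", x) for i, x in
                   enumerate(rng.uniform(-4, 4, (30, 3)))]
        ligand = [_atom(100 + i, "F", "C", x) for i, x in
                  enumerate(rng.uniform(-4, 4, (10, 3)))]
        sizes = [len(short_contact_census(protein, ligand, cutoff=c))
                 for c in (1.0, 2.0, 2.5, 4.0)]
        assert sizes == sorted(sizes)

    def test_union_keeps_closest_observation(self):
        protein = [_atom(1, "CA", "C", (0, 0, 0))]
        c1 = short_contact_census(protein, [_atom(2, "F1", "C", (2.4, 0, 0))])
        c2 = short_contact_census(protein, [_atom(2, "F1", "C", (1.9, 0, 0))])
        union = census_union([c1, c2])
        assert len(union) == 1
        assert union[0].distance == pytest.approx(1.9)

    def test_distinct_counting_helpers(self):
        protein = [
            _atom(1, "CA", "C", (0, 0, 0), res_seq=1),
            _atom(2, "CB", "C", (0.5, 0, 0), res_seq=1),
            _atom(3, "CA", "C", (1.0, 0, 0), res_seq=2),
        ]
        ligand = [_atom(9, "F1", "C", (0.2, 0, 0))]
        census = short_contact_census(protein, ligand, cutoff=2.5)
        assert distinct_protein_atoms(census) == 3
        assert distinct_protein_residues(census) == 2


class TestResidueTable:
    def test_empty_census(self):
        assert len(census_residue_table([])) == 0

    def test_aggregation_counts(self):
        protein = [
            _atom(1, "CA", "C", (0, 0, 0), res_seq=5),
            _atom(2, "CB", "C", (0.3, 0, 0), res_seq=5),
            _atom(3, "N", "N", (0.6, 0, 0), res_seq=5),
            _atom(4, "CA", "C", (2.0, 0, 0), res_seq=9),
        ]
        ligand = [_atom(9, "F1", "C", (0.0, 0.5, 0))]
        census = short_contact_census(protein, ligand, cutoff=2.5)
        table = census_residue_table(census)
        assert list(table["n_contact_atoms"]) == [3, 1]
        assert list(table["res_seq"]) == [5, 9]
        assert table["min_distance"].is_monotonic_increasing

    def test_matches_brute_force_groupby(self, tunnel):
        # census of the toy flag against the wall at a clashing pose
        from coaclash.coa_geometry import rotate_flag

        sel = select_atoms(tunnel.structure, tunnel.n_domain().selection)
        frame = rotate_flag(tunnel.split, 90.0)
        flag_moved = [a.moved_to(x) for a, x in zip(tunnel.split.flag, frame)]
        census = short_contact_census(sel, flag_moved, cutoff=4.0)
        table = census_residue_table(census)
        brute = {}
        for c in census:
            k = (c.protein_atom.chain, c.protein_atom.res_seq)
            brute.setdefault(k, set()).add(c.protein_atom.name)
        assert len(table) == len(brute)
        got = dict(zip(zip(table["chain"], table["res_seq"]), table["n_contact_atoms"]))
        assert got == {k: len(v) for k, v in brute.items()}
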