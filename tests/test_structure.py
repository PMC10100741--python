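import itertools

import numpy as np
import pytest

from tfcoev.msa import AlignedFamily
from tfcoev.simulate import PlacedResidue, generate_toy_complex
from tfcoev.structure import (
    ComplexRejectedError,
    MappingError,
    classify_fcrps,
    compare_spatial,
    foldx_mutation_list,
    load_complex,
    map_columns_to_residues,
    parse_foldx_ddg,
    residue_distances,
)

from oracles import min_distance_oracle


def _chain_complex(coords_by_res, dna_atoms, resolution=2.0):
    """Protein chain A with one ALA per entry plus DNA chain B."""
    spec = [
        PlacedResidue("A", i + 1, "ALA", [(f"C{k}", *c) for k, c in enumerate(atoms)])
        for i, atoms in enumerate(coords_by_res)
    ]
    spec.append(PlacedResidue("B", 1, "DT", [(f"P{k}", *a) for k, a in enumerate(dna_atoms)]))
    return generate_toy_complex(spec, resolution=resolution)


class TestLoadComplex:
    def test_resolution_cutoff(self, toy_spec, tmp_path):
        path = tmp_path / "lowres.pdb"
        with pytest.raises(ComplexRejectedError, match="resolution"):
            generate_toy_complex(toy_spec, resolution=4.5, path=path)

    def test_accepts_toy_complex(self, toy_spec):
        cx = generate_toy_complex(toy_spec)
        assert cx.protein_chains() == ["A"]
        assert len(cx.dna_residues) == 1

    def test_protein_only_rejected(self, tmp_path):
        text = (
            "REMARK   2 RESOLUTION.    2.00 ANGSTROMS.\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\nEND\n"
        )
        path = tmp_path / "protein_only.pdb"
        path.write_text(text)
        with pytest.raises(ComplexRejectedError, match="no DNA chain"):
            load_complex(path)

    def test_missing_resolution_needs_override(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      2  P    DA B   1       3.000   4.000   0.000"
            "  1.00  0.00           P\nEND\n"
        )
        path = tmp_path / "nores.pdb"
        path.write_text(text)
        with pytest.raises(ComplexRejectedError, match="resolution"):
            load_complex(path)
        cx = load_complex(path, allow_missing_resolution=True)
        assert cx.resolution is None


class TestMapping:
    def _msa(self):
        return AlignedFamily.from_sequences(
            ["seed", "other"], ["AC-DEF", "ACWDEF"]
        )

    def test_exact_substring_mapping(self):
        msa = self._msa()
        chain = [(n + 10, ch) for n, ch in enumerate("GGACDEFGG")]
        mapping = map_columns_to_residues(msa, "seed", chain)
        assert mapping == {0: 12, 1: 13, 3: 14, 4: 15, 5: 16}

    def test_gap_columns_unmapped(self):
        msa = self._msa()
        chain = [(n + 1, ch) for n, ch in enumerate("ACDEF")]
        mapping = map_columns_to_residues(msa, "seed", chain)
        assert 2 not in mapping

    def test_substituted_residue_excluded(self):
        msa = AlignedFamily.from_sequences(["seed"], ["ACDEFGHIKL"])
        chain = [(n + 1, ch) for n, ch in enumerate("ACDEFRHIKL")]  # G->R
        mapping = map_columns_to_residues(msa, "seed", chain)
        assert set(mapping) == set(range(10)) - {5}
        assert mapping[6] == 7

    def test_low_identity_refused(self):
        msa = AlignedFamily.from_sequences(["seed"], ["ACDEFGHIKL"])
        chain = [(n + 1, ch) for n, ch in enumerate("WWWWWYYYYY")]
        with pytest.raises(MappingError):
            map_columns_to_residues(msa, "seed", chain)


class TestDistances:
    def test_three_four_five(self, toy_spec):
        cx = generate_toy_complex(toy_spec)
        msa = AlignedFamily.from_sequences(["seed"], ["R"])
        dmap = residue_distances(cx, {"A": {0: 1}})
        assert dmap.dna_distances[0] == pytest.approx(5.0)

    def test_minimum_over_atoms(self):
        cx = _chain_complex([[(0, 0, 12.0), (0, 0, 7.0)]], [(0, 0, 0)])
        dmap = residue_distances(cx, {"A": {0: 1}})
        assert dmap.dna_distances[0] == pytest.approx(7.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        coords = [rng.uniform(-20, 20, (3, 3)).round(3) for _ in range(5)]
        dna = rng.uniform(-20, 20, (4, 3)).round(3)
        cx = _chain_complex(coords, dna)
        dmap = residue_distances(cx, {"A": {c: c + 1 for c in range(5)}})
        # oracle runs on the parsed atoms, the same input the package sees
        parsed = [r.atoms.tolist() for r in cx.protein_residues]
        parsed_dna = cx.dna_atoms().tolist()
        for i, j in itertools.combinations(range(5), 2):
            expected = min_distance_oracle(parsed[i], parsed[j])
            assert dmap.pair(i, j) == pytest.approx(expected, abs=1e-9)
        for i in range(5):
            expected = min_distance_oracle(parsed[i], parsed_dna)
            assert dmap.dna_distances[i] == pytest.approx(expected, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        coords = [rng.uniform(-10, 10, (2, 3)).round(3) for _ in range(4)]
        dna = rng.uniform(-10, 10, (3, 3)).round(3)
        # rotation about z by 30 degrees plus translation
        theta = np.pi / 6
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        t = np.array([5.0, -3.0, 2.0])
        moved = [np.round(c @ R.T + t, 3) for c in coords]
        dna_moved = np.round(dna @ R.T + t, 3)
        d1 = residue_distances(
            _chain_complex(coords, dna), {"A": {c: c + 1 for c in range(4)}}
        )
        d2 = residue_distances(
            _chain_complex(moved, dna_moved), {"A": {c: c + 1 for c in range(4)}}
        )
        for key in d1.pair_distances:
            # coordinates go through 3-decimal PDB fields, hence the tolerance
            assert d1.pair_distances[key] == pytest.approx(
                d2.pair_distances[key], abs=5e-3
            )


class TestFcrps:
    def _dmap(self, dists):
        from tfcoev.structure import DistanceMap

        return DistanceMap({}, dists)

    def test_far_endpoint_makes_fcrp(self):
        out = classify_fcrps({(0, 1)}, self._dmap({0: 12.0, 1: 4.0}))
        assert out["table"]["is_fcrp"].tolist() == [True]

    def test_strict_inequality_at_cutoff(self):
        out = classify_fcrps({(0, 1)}, self._dmap({0: 9.9, 1: 9.9}))
        assert out["table"]["is_fcrp"].tolist() == [False]

    def test_unmapped_endpoint_counted_uncovered(self):
        out = classify_fcrps({(0, 1), (0, 2)}, self._dmap({0: 3.0, 1: 4.0}))
        assert out["n_classified"] == 1
        assert out["n_uncovered"] == 1

    def test_fraction_monotone_in_cutoff(self):
        rng = np.random.default_rng(2)
        dists = {i: float(rng.uniform(0, 30)) for i in range(12)}
        crps = {(i, i + 1) for i in range(0, 12, 2)}
        fractions = [
            classify_fcrps(crps, self._dmap(dists), cutoff=c)["fcrp_fraction"]
            for c in (5.0, 10.0, 15.0, 20.0)
        ]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))


class TestSpatialComparison:
    def test_separated_groups_direction(self):
        out = compare_spatial([5.0] * 10 + [5.1], [20.0] * 10 + [20.1])
        assert out["direction"] == "crp_closer"
        assert out["p_value"] < 1e-6

    def test_identical_groups_high_p(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(10, 2, 20).tolist()
        out = compare_spatial(vals, list(vals))
        assert out["p_value"] == pytest.approx(1.0)


class TestFoldxIo:
    def test_mutation_line_format(self):
        text = foldx_mutation_list([("A", 49, "R", "G")])
        assert text == "RA49G;\n"

    def test_wildtype_checked_against_structure(self, toy_spec):
        cx = generate_toy_complex(toy_spec)  # ARG at A 1
        assert foldx_mutation_list([("A", 1, "R", "A")], cx) == "RA1A;\n"
        with pytest.raises(ValueError, match="mismatch"):
            foldx_mutation_list([("A", 1, "K", "A")], cx)

    def test_replicates_averaged_and_flagged(self):
        lines = ["mutant replicate ddg"]
        for r, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0], 1):
            lines.append(f"RA49G {r} {v}")
        for r in range(1, 6):
            lines.append(f"KA50A {r} 0.5")
        table = parse_foldx_ddg("\n".join(lines))
        row = table.set_index("mutant").loc["RA49G"]
        assert row["mean_ddg"] == pytest.approx(3.0)
        assert bool(row["disruptive"])  # 3.0 > 2 kcal/mol
        assert not bool(table.set_index("mutant").loc["KA50A", "disruptive"])

    def test_wrong_replicate_count_warns(self):
        text = "\n".join(f"RA49G {r} 2.5" for r in range(1, 4))
        with pytest.warns(UserWarning):
            table = parse_foldx_ddg(text)
        assert bool(table.loc[0, "disruptive"])  # mean 2.5 > 2
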