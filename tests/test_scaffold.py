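"""Structural-context extraction: loading, sphere neighborhoods,
native/starting splits, numbered FASTA, minimize-adjacent lists."""

import numpy as np
import pytest

from ribodesign import (
    ResidueSelection,
    adjacent_min_res,
    context_to_fasta,
    load_structure,
    select_sphere_neighborhood,
    split_native_starting,
)
from ribodesign.scaffold import Atom, Residue, Structure, write_pdb
from ribodesign.fixtures import make_ideal_helix


def _point_residue(chain, number, xyz, name="G"):
    return Residue(chain, number, name, "rna", (Atom("C1'", "C", *xyz),))


class TestStructure:
    def test_duplicate_residue_number_rejected(self):
        residues = [
            _point_residue("A", 5, (0, 0, 0)),
            _point_residue("A", 5, (1, 0, 0), name="C"),
        ]
        with pytest.raises(ValueError, match="duplicate residue number 5"):
            Structure(residues)

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            Structure([_point_residue("A", 1, (float("nan"), 0, 0))])

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError, match="no residues"):
            Structure([])


class TestLoadStructure:
    def test_helix_round_trip_preserves_coordinates(self, helix4, tmp_path):
        path = tmp_path / "helix.pdb"
        write_pdb(helix4, path)
        reloaded = load_structure(path, format="pdb")
        assert len(reloaded) == 8
        for orig, new in zip(helix4.residues, reloaded.residues):
            assert orig.key == new.key
            assert new.polymer_class == "rna"
            for a, b in zip(orig.atoms, new.atoms):
                assert np.allclose(a.xyz, b.xyz, atol=1e-3)

    def test_author_numbering_preserved(self, helix4, tmp_path):
        path = tmp_path / "helix.pdb"
        write_pdb(helix4, path)
        reloaded = load_structure(path)
        assert ("A", 2225) in reloaded and ("B", 2091) in reloaded

    def test_unparseable_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not mmcif at all\n")
        with pytest.raises(ValueError, match="cannot parse"):
            load_structure(bad, format="mmcif")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_structure(tmp_path / "nope.pdb")

    def test_unknown_format_name(self, tmp_path):
        p = tmp_path / "x.pdb"
        p.write_text("END\n")
        with pytest.raises(ValueError, match="unknown format"):
            load_structure(p, format="xyz")


class TestSphereNeighborhood:
    def test_radius_zero_gives_no_neighbors(self, helix4):
        sel = ResidueSelection((("A", 2225),), "designed")
        ctx = select_sphere_neighborhood(helix4, sel, 0.0)
        assert len(ctx.neighbors) == 0

    def test_two_residue_toy_inclusion_threshold(self):
        s = Structure(
            [_point_residue("A", 1, (0, 0, 0)), _point_residue("A", 2, (10.0, 0, 0))]
        )
        sel = ResidueSelection((("A", 1),), "d")
        assert select_sphere_neighborhood(s, sel, 15.0).neighbors.ids == (("A", 2),)
        assert select_sphere_neighborhood(s, sel, 5.0).neighbors.ids == ()
        # boundary: exactly at radius is included (<= comparison)
        assert select_sphere_neighborhood(s, sel, 10.0).neighbors.ids == (("A", 2),)

    def test_missing_designed_residue_lists_ids(self, helix4):
        sel = ResidueSelection((("A", 2225), ("C", 99)), "d")
        with pytest.raises(KeyError, match="C:99"):
            select_sphere_neighborhood(helix4, sel, 10.0)

    def test_monotone_in_radius(self, helix4):
        sel = ResidueSelection((("A", 2226),), "d")
        small = set(select_sphere_neighborhood(helix4, sel, 20.0).neighbors.ids)
        large = set(select_sphere_neighborhood(helix4, sel, 25.0).neighbors.ids)
        assert small <= large

    def test_agrees_with_brute_force_oracle_on_random_toys(self):
        """Residue-level inclusion must match an all-heavy-atom-pairs scan."""
        rng = np.random.default_rng(42)
        for trial in range(10):
            n_res = int(rng.integers(5, 50))
            residues = []
            for i in range(n_res):
                n_atoms = int(rng.integers(1, 4))
                atoms = tuple(
                    Atom(f"X{k}", "C", *rng.uniform(-30, 30, 3)) for k in range(n_atoms)
                )
                residues.append(Residue("A", i + 1, "G", "rna", atoms))
            s = Structure(residues)
            designed_ids = tuple(
                ("A", int(i) + 1)
                for i in rng.choice(n_res, size=int(rng.integers(1, 4)), replace=False)
            )
            sel = ResidueSelection(designed_ids, "d")
            radius = float(rng.uniform(5, 40))
            ctx = select_sphere_neighborhood(s, sel, radius)

            dpts = np.vstack(
                [[a.xyz for a in s[key].atoms] for key in designed_ids]
            )
            expected = set()
            for res in residues:
                if res.key in set(designed_ids):
                    continue
                pts = np.array([a.xyz for a in res.atoms])
                dmin = np.sqrt(
                    ((pts[:, None, :] - dpts[None, :, :]) ** 2).sum(-1)
                ).min()
                if dmin <= radius:
                    expected.add(res.key)
            assert set(ctx.neighbors.ids) == expected, f"trial {trial}"


class TestSplitNativeStarting:
    def test_partition_identity(self, helix4):
        sel = ResidueSelection.from_spec("A:2225-2228", "designed")
        ctx = select_sphere_neighborhood(helix4, sel, 25.0)
        native, starting = split_native_starting(ctx)
        assert len(native) == len(starting) + len(ctx.designed)
        assert set(native.keys()) == set(starting.keys()) | set(ctx.designed.ids)
        assert set(starting.keys()).isdisjoint(ctx.designed.ids)

    def test_round_trip_preserves_coordinates(self, helix4, tmp_path):
        sel = ResidueSelection.from_spec("A:2225-2228", "designed")
        ctx = select_sphere_neighborhood(helix4, sel, 25.0)
        native, starting = split_native_starting(ctx)
        for model, fname in ((native, "native.pdb"), (starting, "starting.pdb")):
            path = tmp_path / fname
            write_pdb(model, path)
            reloaded = load_structure(path)
            assert set(reloaded.keys()) == set(model.keys())
            for key in model.keys():
                for a, b in zip(model[key].atoms, reloaded[key].atoms):
                    assert np.allclose(a.xyz, b.xyz, atol=1e-3)


class TestContextToFasta:
    def test_rna_lowercase_with_numbered_header(self, helix4):
        segments = context_to_fasta(helix4)
        by_header = {seg.header: seg.sequence for seg in segments}
        assert by_header["A:2225-2228"] == "gcgu"
        assert by_header["B:2088-2091"] == "acgc"

    def test_numbering_gap_splits_segments(self):
        residues = [
            _point_residue("A", 2227, (0, 0, 0), "C"),
            _point_residue("A", 2228, (3, 0, 0), "G"),
            _point_residue("A", 2230, (6, 0, 0), "U"),
        ]
        segments = context_to_fasta(Structure(residues))
        assert [(s.header, s.sequence) for s in segments] == [
            ("A:2227-2228", "cg"),
            ("A:2230-2230", "u"),
        ]

    def test_letter_to_residue_number_round_trip(self, helix4):
        for seg in context_to_fasta(helix4):
            for i in range(len(seg.sequence)):
                number = seg.position_of(i)
                assert seg.start <= number <= seg.end
                assert number - seg.start == i

    def test_unknown_residue_name_raises(self):
        res = Residue("A", 1, "XXX", "rna", (Atom("C1'", "C", 0, 0, 0),))
        with pytest.raises(ValueError, match="XXX"):
            context_to_fasta(Structure([res]))

    def test_ions_are_skipped(self):
        residues = [
            _point_residue("A", 1, (0, 0, 0), "G"),
            Residue("A", 2, "MG", "other", (Atom("MG", "MG", 5, 0, 0),)),
        ]
        segments = context_to_fasta(Structure(residues))
        assert len(segments) == 1 and segments[0].sequence == "g"


class TestAdjacentMinRes:
    def test_contiguous_block_yields_flanks(self, helix4):
        six = make_ideal_helix(6, "agcguc", start_numbers=(2224, 2086))
        sel = ResidueSelection.from_spec("A:2225-2228", "d")
        assert adjacent_min_res(six, sel).ids == (("A", 2224), ("A", 2229))

    def test_whole_chain_designed_gives_empty(self, helix4):
        sel = ResidueSelection.from_spec("A:2225-2228", "d")
        assert adjacent_min_res(helix4, sel).ids == ()

    def test_separator_between_blocks_appears_once(self):
        s = Structure([_point_residue("A", n, (3.0 * n, 0, 0)) for n in range(1, 6)])
        sel = ResidueSelection((("A", 1), ("A", 2), ("A", 4), ("A", 5)), "d")
        assert adjacent_min_res(s, sel).ids == (("A", 3),)
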