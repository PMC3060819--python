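import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import dihedral_reference
from pbrefine.structure_io import (BackboneChain, ChainNotFoundError,
                                   DihedralUndefinedError, compute_dihedral,
                                   read_fasta, read_structure, write_pb_fasta,
                                   write_pdb)
from pbrefine.synthetic import build_backbone, build_from_phi_psi


def _write_synthetic_pdb(tmp_path, chain, name="toy.pdb"):
    path = tmp_path / name
    write_pdb(chain, path)
    return path


class TestComputeDihedral:
    def test_cis_is_zero(self):
        p = [np.array([1.0, 1, 0]), np.array([0.0, 0, 0]),
             np.array([1.0, 0, 0]), np.array([2.0, 1, 0])]
        assert compute_dihedral(*p) == pytest.approx(0.0, abs=1e-9)

    def test_trans_is_180(self):
        p = [np.array([1.0, 1, 0]), np.array([0.0, 0, 0]),
             np.array([1.0, 0, 0]), np.array([2.0, -1, 0])]
        assert compute_dihedral(*p) == pytest.approx(180.0, abs=1e-9)

    def test_collinear_raises(self):
        with pytest.raises(DihedralUndefinedError):
            compute_dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_matches_independent_reference(self, rng):
        for _ in range(200):
            pts = rng.normal(size=(4, 3)) * 5
            expected = dihedral_reference(*pts)
            assert compute_dihedral(*pts) == pytest.approx(expected, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_reversal(self, seed):
        # IUPAC torsion angles do not depend on the viewing direction:
        # dihedral(p4,p3,p2,p1) == dihedral(p1,p2,p3,p4)
        pts = np.random.default_rng(seed).normal(size=(4, 3)) * 4
        try:
            fwd = compute_dihedral(*pts)
        except DihedralUndefinedError:
            return
        rev = compute_dihedral(*pts[::-1])
        diff = abs(((fwd - rev) + 180.0) % 360.0 - 180.0)
        assert diff < 1e-9

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_negated_under_mirror_reflection(self, seed):
        pts = np.random.default_rng(seed).normal(size=(4, 3)) * 4
        try:
            fwd = compute_dihedral(*pts)
        except DihedralUndefinedError:
            return
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        rev = compute_dihedral(*mirrored)
        diff = abs(((fwd + rev) + 180.0) % 360.0 - 180.0)
        assert diff < 1e-9


class TestReadStructure:
    def test_terminal_dihedral_definedness(self, tmp_path):
        chain = build_from_phi_psi([-120, -120, -120, -120], [120, 120, 120, 120])
        path = _write_synthetic_pdb(tmp_path, chain)
        got = read_structure(path, chain="A")
        assert len(got) == 4
        assert got.residues[0].phi is None
        assert all(r.phi is not None for r in got.residues[1:])
        assert got.residues[-1].psi is None
        assert all(r.psi is not None for r in got.residues[:-1])

    def test_chain_break_flagged_and_dihedrals_undefined(self, tmp_path):
        chain = build_backbone("d" * 10)
        # shove residues 6.. (0-based index 5) 10 A away
        for res in chain.residues[5:]:
            for attr in ("n", "ca", "c", "o"):
                setattr(res, attr, getattr(res, attr) + np.array([0.0, 0.0, 10.0]))
        path = _write_synthetic_pdb(tmp_path, chain)
        got = read_structure(path, chain="A")
        assert got.residues[5].chain_break_before
        assert got.residues[5].phi is None
        assert got.residues[4].psi is None

    def test_incomplete_residue_dropped(self, tmp_path, caplog):
        chain = build_backbone("d" * 6)
        path = tmp_path / "partial.pdb"
        lines = _write_synthetic_pdb(tmp_path, chain, "full.pdb").read_text().splitlines()
        # drop N and C of residue 3 -> CA-only residue
        kept = [l for l in lines
                if not (l.startswith("ATOM") and l[22:26].strip() == "3"
                        and l[12:16].strip() in ("N", "C", "O"))]
        path.write_text("\n".join(kept) + "\n")
        import logging

        with caplog.at_level(logging.WARNING, logger="pbrefine.structure_io"):
            got = read_structure(path, chain="A")
        assert len(got) == 5
        assert "incomplete backbone" in caplog.text

    def test_missing_chain_raises(self, tmp_path):
        path = _write_synthetic_pdb(tmp_path, build_backbone("d" * 6))
        with pytest.raises(ChainNotFoundError):
            read_structure(path, chain="B")

    def test_mmcif_read(self, tmp_path):
        import biotite.structure.io.pdb as pdb
        import biotite.structure.io.pdbx as pdbx

        chain = build_backbone("d" * 6 + "mmmm" + "d" * 6)
        pdb_path = _write_synthetic_pdb(tmp_path, chain)
        arr = pdb.get_structure(pdb.PDBFile.read(str(pdb_path)), model=1)
        cif = pdbx.CIFFile()
        pdbx.set_structure(cif, arr)
        cif_path = tmp_path / "toy.cif"
        cif.write(str(cif_path))
        got = read_structure(cif_path, chain="A")
        assert len(got) == len(chain)
        for a, b in zip(chain.residues, got.residues):
            assert np.allclose(a.ca, b.ca, atol=1e-3)

    def test_roundtrip_coordinates_within_pdb_precision(self, tmp_path, rng):
        from pbrefine.synthetic import random_compatible_string

        chain = build_backbone(random_compatible_string(rng, 20))
        path = _write_synthetic_pdb(tmp_path, chain)
        got = read_structure(path, chain="A")
        assert len(got) == len(chain)
        for a, b in zip(chain.residues, got.residues):
            for attr in ("n", "ca", "c"):
                assert np.allclose(getattr(a, attr), getattr(b, attr), atol=1e-3)


class TestPBFasta:
    def test_write_and_roundtrip(self, tmp_path):
        from pbrefine.pb_alphabet import PBSequence

        seq = PBSequence(symbols="ZZmmmmmmZZ", header="toy|chain A|residues 1-10")
        path = tmp_path / "pb.fasta"
        write_pb_fasta([seq], path)
        records = read_fasta(path)
        assert records == [("toy|chain A|residues 1-10", "ZZmmmmmmZZ")]

    def test_five_residue_chain_is_all_undefined(self, tmp_path):
        from pbrefine.pb_alphabet import assign_pbs

        chain = build_backbone("ddddd")
        seq = assign_pbs(chain)
        assert seq.symbols == "ZZdZZ"  # only the central window is complete
        path = tmp_path / "pb.fasta"
        write_pb_fasta([seq], path)
        assert read_fasta(path)[0][1] == "ZZdZZ"

    def test_empty_list_gives_empty_file(self, tmp_path):
        path = tmp_path / "empty.fasta"
        write_pb_fasta([], path)
        assert path.read_text() == ""

    def test_long_sequences_wrapped_at_60(self, tmp_path):
        from pbrefine.pb_alphabet import PBSequence

        seq = PBSequence(symbols="m" * 130, header="long")
        path = tmp_path / "pb.fasta"
        write_pb_fasta([seq], path)
        lines = path.read_text().splitlines()
        assert [len(l) for l in lines[1:]] == [60, 60, 10]
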