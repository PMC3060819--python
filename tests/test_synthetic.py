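import copy

import numpy as np
import pytest

from pbrefine.pb_alphabet import assign_pbs
from pbrefine.structure_io import read_structure
from pbrefine.synthetic import (FIXTURE_KINDS, IdealGeometry, build_backbone,
                                generate_pair_fixture, make_pair_fixture,
                                perturb_conformation, perturb_rigid,
                                random_compatible_string,
                                rebuild_segment_in_place,
                                transition_compatibility)


class TestIdealGeometry:
    def test_defaults_valid(self):
        g = IdealGeometry()
        assert g.omega == 180.0

    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            IdealGeometry(n_ca=-1.0)
        with pytest.raises(ValueError):
            IdealGeometry(ang_n_ca_c=190.0)


class TestBuildBackbone:
    def test_helix_roundtrip(self):
        chain = build_backbone("m" * 10)
        assert assign_pbs(chain).symbols == "ZZ" + "m" * 6 + "ZZ"

    def test_strand_roundtrip(self):
        chain = build_backbone("d" * 10)
        assert assign_pbs(chain).symbols == "ZZ" + "d" * 6 + "ZZ"

    def test_ca_ca_distance_is_trans_peptide(self):
        chain = build_backbone("dddddmmmmm")
        ca = chain.ca_coords()
        steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.allclose(steps, 3.8, atol=0.05)

    def test_rejects_undefined_symbol(self):
        with pytest.raises(ValueError):
            build_backbone("mmZmm")

    def test_rejects_too_short(self):
        with pytest.raises(ValueError):
            build_backbone("mmm")

    def test_requested_dihedrals_realized(self, alphabet):
        chain = build_backbone("dddmmmddd")
        for i, s in enumerate("dddmmmddd"):
            proto = alphabet.prototypes[s]
            if i > 0:
                assert chain.residues[i].phi == pytest.approx(proto[3], abs=1e-6)
            if i < 8:
                assert chain.residues[i].psi == pytest.approx(proto[4], abs=1e-6)


class TestCompatibleStrings:
    def test_roundtrip_100_percent(self, rng):
        for _ in range(25):
            s = random_compatible_string(rng, 30)
            got = assign_pbs(build_backbone(s)).symbols
            assert got[2:-2] == s[2:-2]

    def test_table_contains_native_transitions(self, alphabet):
        from pbrefine.pb_alphabet import PB_LABELS

        table = transition_compatibility(alphabet)
        for x, y in ("fk", "kl", "lm", "mm", "mn", "no", "op", "pa", "ac", "dd"):
            assert table[PB_LABELS.index(x), PB_LABELS.index(y)]

    def test_seeded_reproducibility(self):
        s1 = random_compatible_string(np.random.default_rng(5), 30)
        s2 = random_compatible_string(np.random.default_rng(5), 30)
        assert s1 == s2


class TestPerturbRigid:
    def test_identity_transform_is_noop(self):
        chain = build_backbone("d" * 12)
        moved = perturb_rigid(chain, (4, 8))
        for a, b in zip(chain.residues, moved.residues):
            assert np.allclose(a.ca, b.ca, atol=1e-12)

    def test_interior_pbs_preserved_and_deviation_created(self):
        chain = build_backbone("d" * 6 + "fklmmmmmmnopac" + "d" * 6)
        moved = perturb_rigid(chain, (8, 18), translation=(0.0, 0.0, 6.0))
        before = assign_pbs(chain).symbols
        after = assign_pbs(moved).symbols
        # interior of the moved block keeps its dihedrals, hence its PBs
        assert after[11:15] == before[11:15]
        shift = np.array([r.ca for r in moved.residues[8:18]]) - \
            np.array([r.ca for r in chain.residues[8:18]])
        assert np.allclose(np.linalg.norm(shift, axis=1), 6.0, atol=1e-9)

    def test_lever_arm_grows_deviation(self):
        chain = build_backbone("d" * 20)
        moved = perturb_rigid(chain, (10, 20), rotation_deg=30.0,
                              axis=(0.0, 0.0, 1.0))
        dev = np.linalg.norm(
            np.array([r.ca for r in moved.residues[10:]]) -
            np.array([r.ca for r in chain.residues[10:]]), axis=1)
        # deviations increase away from the pivot (centroid of the segment)
        assert dev[-1] > dev[len(dev) // 2] * 1.2

    def test_range_validation(self):
        chain = build_backbone("d" * 8)
        with pytest.raises(ValueError):
            perturb_rigid(chain, (5, 20))


class TestPerturbConformation:
    def test_helix_to_strand_swap(self):
        s = perturb_conformation("kkmmmmkk", (2, 6), "dddd")
        assert s == "kkddddkk"

    def test_identity_replacement(self):
        s = "kkmmmmkk"
        assert perturb_conformation(s, (2, 6), s[2:6]) == s

    def test_length_changing_replacement(self):
        s = perturb_conformation("kkmmmmkk", (2, 6), "dddddd")
        assert s == "kkddddddkk"
        assert len(s) == 10


class TestRebuildSegment:
    def test_upstream_flank_untouched_downstream_pinned(self):
        chain = build_backbone("d" * 8 + "m" * 6 + "d" * 8)
        rebuilt = rebuild_segment_in_place(chain, 8, 14, "d" * 6)
        for k in range(8):
            assert np.allclose(chain.residues[k].ca, rebuilt.residues[k].ca)
        for k in range(14, 22):
            assert np.allclose(chain.residues[k].ca, rebuilt.residues[k].ca)
        # the rebuilt strand wanders away from the original helix
        mid_dev = np.linalg.norm(
            chain.residues[12].ca - rebuilt.residues[12].ca)
        assert mid_dev > 3.0


class TestPairFixtures:
    @pytest.mark.parametrize("kind", FIXTURE_KINDS)
    def test_files_written_and_reread(self, tmp_path, kind):
        paths = make_pair_fixture(kind, seed=1, outdir=tmp_path)
        c1 = read_structure(paths["structure1"], chain="A")
        c2 = read_structure(paths["structure2"], chain="A")
        assert len(c1) >= 5 and len(c2) >= 5
        assert paths["truth_file"].exists()
        assert paths["truth"]["kind"] == kind

    def test_pdb_roundtrip_dihedrals_within_half_degree(self, tmp_path):
        paths = make_pair_fixture("displaced", seed=2, outdir=tmp_path)
        fixture = generate_pair_fixture("displaced", seed=2)
        reread = read_structure(paths["structure1"], chain="A")
        for a, b in zip(fixture.chain1.residues, reread.residues):
            for angle in ("phi", "psi"):
                va, vb = getattr(a, angle), getattr(b, angle)
                if va is None or vb is None:
                    assert va == vb
                else:
                    diff = abs(va - vb) % 360.0
                    assert min(diff, 360.0 - diff) < 0.5

    def test_identical_fixture_is_identical(self):
        fx = generate_pair_fixture("identical", seed=0)
        assert np.allclose(fx.chain1.ca_coords(), fx.chain2.ca_coords())
        assert fx.aligned_row1 == fx.aligned_row2

    def test_fixture_deterministic_per_seed(self):
        a = generate_pair_fixture("displaced", seed=9)
        b = generate_pair_fixture("displaced", seed=9)
        assert np.allclose(a.chain2.ca_coords(), b.chain2.ca_coords())
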