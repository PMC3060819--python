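"""Ground-truth fixture generation: backbones from PB strings and perturbations.

Backbones are constructed by sequential internal-to-Cartesian (NeRF-style)
placement with ideal peptide geometry and omega = 180.  Residue i takes its
(phi, psi) from the central position of the prototype of ``pb_string[i]``,
so overlapping windows match prototypes at their centres; re-assignment then
recovers the generating string at interior positions for transition-
compatible strings (verified empirically, not assumed).
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .pb_alphabet import (PB_LABELS, PBAlphabet, assign_pbs, load_alphabet)
from .structure_io import (BackboneChain, Residue, _compute_chain_dihedrals,
                           _flag_breaks, write_fasta, write_pdb,
                           DEFAULT_BREAK_CUTOFF)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IdealGeometry:
    """Standard trans-peptide bond lengths (A) and angles (degrees)."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.5
    omega: float = 180.0

    def __post_init__(self):
        for v in (self.n_ca, self.ca_c, self.c_n, self.c_o):
            if v <= 0:
                raise ValueError("bond lengths must be positive")
        for v in (self.ang_n_ca_c, self.ang_ca_c_n, self.ang_c_n_ca,
                  self.ang_ca_c_o):
            if not 0 < v < 180:
                raise ValueError("bond angles must be in (0, 180)")


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d such that |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (NeRF construction step)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_from_phi_psi(phis: Sequence[float], psis: Sequence[float],
                       geometry: IdealGeometry = IdealGeometry(),
                       chain_id: str = "A",
                       structure_id: str = "synthetic") -> BackboneChain:
    """Sequentially place an all-ALA backbone with the given dihedral series.

    ``phis[0]`` is unused (no preceding C); ``psis[-1]`` is used only to
    place the final carbonyl oxygen.
    """
    n_res = len(phis)
    if n_res != len(psis):
        raise ValueError("phi and psi series must have equal length")
    if n_res < 1:
        raise ValueError("need at least one residue")
    g = geometry
    coords_n = [np.zeros(3)]
    coords_ca = [np.array([g.n_ca, 0.0, 0.0])]
    ang = np.radians(g.ang_n_ca_c)
    coords_c = [coords_ca[0] + g.ca_c * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_res):
        n_next = place_atom(coords_n[i - 1], coords_ca[i - 1], coords_c[i - 1],
                            g.c_n, g.ang_ca_c_n, psis[i - 1])
        ca_next = place_atom(coords_ca[i - 1], coords_c[i - 1], n_next,
                             g.n_ca, g.ang_c_n_ca, g.omega)
        c_next = place_atom(coords_c[i - 1], n_next, ca_next,
                            g.ca_c, g.ang_n_ca_c, phis[i])
        coords_n.append(n_next)
        coords_ca.append(ca_next)
        coords_c.append(c_next)
    residues = []
    for i in range(n_res):
        o = place_atom(coords_n[i], coords_ca[i], coords_c[i],
                       g.c_o, g.ang_ca_c_o, psis[i] + 180.0)
        residues.append(Residue(
            seq_label=str(i + 1), aa="A",
            n=coords_n[i], ca=coords_ca[i], c=coords_c[i], o=o,
        ))
    _flag_breaks(residues, DEFAULT_BREAK_CUTOFF)
    _compute_chain_dihedrals(residues)
    return BackboneChain(chain_id=chain_id, residues=residues,
                         structure_id=structure_id)


def pb_center_angles(pb_string: str,
                     alphabet: Optional[PBAlphabet] = None
                     ) -> tuple[list[float], list[float]]:
    """Per-residue (phi, psi) from the central position of each PB prototype."""
    if alphabet is None:
        alphabet = load_alphabet()
    bad = set(pb_string) - set(PB_LABELS)
    if bad:
        raise ValueError(f"cannot generate undefined conformation: {sorted(bad)}")
    phis = [float(alphabet.prototypes[s][3]) for s in pb_string]
    psis = [float(alphabet.prototypes[s][4]) for s in pb_string]
    return phis, psis


def build_backbone(pb_string: str,
                   geometry: IdealGeometry = IdealGeometry(),
                   alphabet: Optional[PBAlphabet] = None,
                   structure_id: str = "synthetic") -> BackboneChain:
    """Backbone whose (phi, psi) series follows the PB string's centres."""
    if len(pb_string) < 5:
        raise ValueError("need at least 5 residues for a meaningful PB chain")
    phis, psis = pb_center_angles(pb_string, alphabet)
    return build_from_phi_psi(phis, psis, geometry, structure_id=structure_id)


def _transform_chain_segment(chain: BackboneChain, start: int, end: int,
                             rotation: np.ndarray, translation: np.ndarray
                             ) -> BackboneChain:
    out = copy.deepcopy(chain)
    seg = out.residues[start:end]
    pivot = np.mean([r.ca for r in seg], axis=0)
    for r in seg:
        for attr in ("n", "ca", "c", "o"):
            xyz = getattr(r, attr)
            if xyz is None:
                continue
            setattr(r, attr, rotation @ (xyz - pivot) + pivot + translation)
    _flag_breaks(out.residues, DEFAULT_BREAK_CUTOFF)
    _compute_chain_dihedrals(out.residues)
    return out


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (normalized) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def perturb_rigid(chain: BackboneChain, residue_range: tuple[int, int],
                  rotation_deg: float = 0.0,
                  translation=(0.0, 0.0, 0.0),
                  axis=(0.0, 0.0, 1.0)) -> BackboneChain:
    """Rigidly displace residues [start, end) about the segment centroid.

    Internal dihedrals of the moved segment are unchanged; the junction
    residues' dihedrals (and hence PBs) change implicitly, and chain breaks
    are flagged where the peptide bond is stretched past the cutoff.  A
    clash (< 1.0 A between moved and fixed CA atoms) only warns.
    """
    start, end = residue_range
    if not (0 <= start < end <= len(chain)):
        raise ValueError("residue range outside chain")
    R = rotation_about_axis(axis, rotation_deg)
    out = _transform_chain_segment(chain, start, end, R, np.asarray(translation, dtype=float))
    moved = np.array([r.ca for r in out.residues[start:end]])
    fixed = [r.ca for k, r in enumerate(out.residues) if not start <= k < end]
    if fixed:
        dmin = np.min(np.linalg.norm(
            moved[:, None, :] - np.asarray(fixed)[None, :, :], axis=2))
        if dmin < 1.0:
            warnings.warn(f"rigid perturbation causes atom clash ({dmin:.2f} A)")
    return out


def perturb_conformation(pb_string: str, residue_range: tuple[int, int],
                         replacement: str) -> str:
    """Splice a replacement PB substring (possibly of different length)."""
    start, end = residue_range
    if not (0 <= start <= end <= len(pb_string)):
        raise ValueError("residue range outside string")
    return pb_string[:start] + replacement + pb_string[end:]


def rebuild_segment_in_place(chain: BackboneChain, start: int, end: int,
                             new_pb: str,
                             geometry: IdealGeometry = IdealGeometry(),
                             alphabet: Optional[PBAlphabet] = None
                             ) -> BackboneChain:
    """Rebuild residues [start, end) with a new conformation, anchored at the
    upstream flank; downstream residues keep their ORIGINAL coordinates, so a
    chain break typically appears at the downstream junction (mimicking a
    local conformational change under a fixed global frame)."""
    phis = [r.phi if r.phi is not None else -120.0 for r in chain.residues]
    psis = [r.psi if r.psi is not None else 120.0 for r in chain.residues]
    new_phis, new_psis = pb_center_angles(new_pb, alphabet)
    phis = phis[:start] + new_phis + phis[end:]
    psis = psis[:start] + new_psis + psis[end:]
    rebuilt = build_from_phi_psi(phis, psis, geometry,
                                 chain_id=chain.chain_id,
                                 structure_id=chain.structure_id + "_mut")
    new_end = start + len(new_pb)
    offset = len(new_pb) - (end - start)
    out = copy.deepcopy(rebuilt)
    # pin the downstream flank at its original location
    for k in range(new_end, len(out.residues)):
        orig = chain.residues[k - offset]
        res = out.residues[k]
        res.n = orig.n.copy()
        res.ca = orig.ca.copy()
        res.c = orig.c.copy()
        res.o = None if orig.o is None else orig.o.copy()
    # upstream flank is bitwise-identical already (same prefix dihedrals)
    for k, res in enumerate(out.residues):
        res.seq_label = str(k + 1)
    _flag_breaks(out.residues, DEFAULT_BREAK_CUTOFF)
    _compute_chain_dihedrals(out.residues)
    return out


# ---------------------------------------------------------------------------
# transition compatibility and random PB strings

_COMPAT_CACHE: dict[tuple, np.ndarray] = {}

#: overlap rmsda (degrees) below which y is accepted as successor of x
SUCCESSOR_RMSDA_CUTOFF = 25.0


def transition_compatibility(alphabet: Optional[PBAlphabet] = None,
                             cutoff: float = SUCCESSOR_RMSDA_CUTOFF) -> np.ndarray:
    """16x16 boolean successor table derived from prototype overlap.

    Prototype windows of consecutive residues overlap by six dihedrals:
    x's angles at (psi(i-1) .. phi(i+2)) must agree with its successor y's
    angles at (psi(i-2) .. phi(i+1)).  (x, y) is compatible when the rmsda
    over those six overlapping positions is below ``cutoff`` — this recovers
    the alphabet's native transitions (e.g. f->k->l->m->n->o->p->a->c->d).
    """
    if alphabet is None:
        alphabet = load_alphabet()
    key = (tuple(sorted(alphabet.prototypes)), cutoff)
    cached = _COMPAT_CACHE.get(key)
    if cached is not None:
        return cached
    from .pb_alphabet import wrap_angle_diff

    proto = alphabet.matrix()
    table = np.zeros((16, 16), dtype=bool)
    for i in range(16):
        for j in range(16):
            d = wrap_angle_diff(proto[i, 2:8], proto[j, 0:6])
            table[i, j] = float(np.sqrt(np.mean(d * d))) < cutoff
    _COMPAT_CACHE[key] = table
    return table


def random_compatible_string(rng: np.random.Generator, length: int,
                             alphabet: Optional[PBAlphabet] = None,
                             max_tries: int = 50) -> str:
    """Random walk on the transition-compatibility graph, verified by a
    build/assign round trip; incompatible draws are resampled under the rng."""
    if alphabet is None:
        alphabet = load_alphabet()
    table = transition_compatibility(alphabet).copy()
    # keep only states that can sustain arbitrarily long walks (no dead ends)
    alive = np.ones(16, dtype=bool)
    changed = True
    while changed:
        changed = False
        for i in range(16):
            if alive[i] and not np.any(table[i] & alive):
                alive[i] = False
                changed = True
    starts = np.flatnonzero(alive)
    if starts.size == 0:
        raise RuntimeError("compatibility graph has no sustainable states")
    for _ in range(max_tries):
        symbols = [int(rng.choice(starts))]
        for _ in range(length - 1):
            successors = np.flatnonzero(table[symbols[-1]] & alive)
            symbols.append(int(rng.choice(successors)))
        s = "".join(PB_LABELS[k] for k in symbols)
        chain = build_backbone(s, alphabet=alphabet)
        got = assign_pbs(chain, alphabet).symbols
        if got[2:-2] == s[2:-2]:
            return s
        logger.info("string %s failed round trip; resampling", s)
    raise RuntimeError("could not generate a transition-compatible string")


# ---------------------------------------------------------------------------
# pair fixtures

FIXTURE_KINDS = ("identical", "displaced", "conformational", "indel")

_FLANK = "d" * 16
_DISPLACED_CORE = "fklmmmmmmnopac"


def _aligned_rows(len1: int, len2: int, columns) -> tuple[str, str]:
    row1 = []
    row2 = []
    for i, j in columns:
        row1.append("A" if i is not None else "-")
        row2.append("A" if j is not None else "-")
    return "".join(row1), "".join(row2)


@dataclass
class PairFixture:
    kind: str
    seed: int
    chain1: BackboneChain
    chain2: BackboneChain
    aligned_row1: str
    aligned_row2: str
    truth: dict


def generate_pair_fixture(kind: str, seed: int) -> PairFixture:
    """Build a two-structure fixture with a known expected outcome."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"kind must be one of {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    if kind == "identical":
        s = _FLANK + _DISPLACED_CORE + _FLANK
        chain1 = build_backbone(s, structure_id=f"ident{seed}_1")
        chain2 = copy.deepcopy(chain1)
        chain2.structure_id = f"ident{seed}_2"
        n = len(chain1)
        row1 = row2 = "A" * n
        truth = {"kind": kind, "seed": seed, "expected_n_svrs": 0,
                 "expected_classification": ""}
        return PairFixture(kind, seed, chain1, chain2, row1, row2, truth)

    flank = _FLANK
    core = _DISPLACED_CORE
    s1 = flank + core + flank
    n_flank = len(flank)
    n_core = len(core)
    chain1 = build_backbone(s1, structure_id=f"{kind}{seed}_1")

    if kind == "displaced":
        # rigid shove of the core, mostly perpendicular to the local chain axis
        seg_ca = chain1.ca_coords()[n_flank:n_flank + n_core]
        axis_dir = seg_ca[-1] - seg_ca[0]
        axis_dir /= np.linalg.norm(axis_dir)
        rand = rng.normal(size=3)
        perp = rand - np.dot(rand, axis_dir) * axis_dir
        perp /= np.linalg.norm(perp)
        translation = 8.0 * perp
        rot_axis = rng.normal(size=3)
        chain2 = perturb_rigid(chain1, (n_flank, n_flank + n_core),
                               rotation_deg=float(rng.uniform(10, 25)),
                               translation=translation, axis=rot_axis)
        chain2.structure_id = f"{kind}{seed}_2"
        # misregistered initial alignment: core of chain1 shifted by 2 in chain2
        shift = 2
        cols: list[tuple[Optional[int], Optional[int]]] = []
        for k in range(n_flank):
            cols.append((k, k))
        for k in range(shift):
            cols.append((None, n_flank + k))
        for k in range(n_core - shift):
            cols.append((n_flank + k, n_flank + shift + k))
        for k in range(shift):
            cols.append((n_flank + n_core - shift + k, None))
        for k in range(n_flank):
            cols.append((n_flank + n_core + k, n_flank + n_core + k))
        row1, row2 = _aligned_rows(len(chain1), len(chain2), cols)
        truth = {"kind": kind, "seed": seed, "expected_n_svrs": 1,
                 "expected_classification": "similar",
                 "svr_span": (n_flank, n_flank + n_core + shift)}
        return PairFixture(kind, seed, chain1, chain2, row1, row2, truth)

    if kind == "conformational":
        # helix core in chain 1, strand core in chain 2 (same length)
        s1 = flank + "m" * 10 + flank
        chain1 = build_backbone(s1, structure_id=f"{kind}{seed}_1")
        chain2 = rebuild_segment_in_place(chain1, n_flank, n_flank + 10, "d" * 10)
        chain2.structure_id = f"{kind}{seed}_2"
        n = len(chain1)
        row1 = row2 = "A" * n
        truth = {"kind": kind, "seed": seed,
                 "expected_classification": "dissimilar",
                 "svr_span": (n_flank, n_flank + 10)}
        return PairFixture(kind, seed, chain1, chain2, row1, row2, truth)

    # indel: chain 2 carries a 2-residue insertion in the core
    insert_at = n_core // 2
    core2 = core[:insert_at] + "mm" + core[insert_at:]
    chain2 = rebuild_segment_in_place(chain1, n_flank, n_flank + n_core, core2)
    chain2.structure_id = f"{kind}{seed}_2"
    cols = []
    for k in range(n_flank):
        cols.append((k, k))
    for k in range(insert_at):
        cols.append((n_flank + k, n_flank + k))
    cols.append((None, n_flank + insert_at))
    cols.append((None, n_flank + insert_at + 1))
    for k in range(insert_at, n_core):
        cols.append((n_flank + k, n_flank + k + 2))
    for k in range(n_flank):
        cols.append((n_flank + n_core + k, n_flank + n_core + 2 + k))
    row1, row2 = _aligned_rows(len(chain1), len(chain2), cols)
    truth = {"kind": kind, "seed": seed,
             "expected_classification": "similar",
             "expected_min_gap_columns": 2,
             "svr_span": (n_flank, n_flank + n_core + 2)}
    return PairFixture(kind, seed, chain1, chain2, row1, row2, truth)


def make_pair_fixture(kind: str, seed: int, outdir) -> dict:
    """Write a fixture to disk: two PDB files, aligned FASTA, truth TSV.

    Returns a dict of the written paths plus the truth record.
    """
    fixture = generate_pair_fixture(kind, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p1 = outdir / f"{kind}_{seed}_1.pdb"
    p2 = outdir / f"{kind}_{seed}_2.pdb"
    aln = outdir / f"{kind}_{seed}_alignment.fasta"
    truth_path = outdir / f"{kind}_{seed}_truth.tsv"
    write_pdb(fixture.chain1, p1)
    write_pdb(fixture.chain2, p2)
    write_fasta([
        (fixture.chain1.structure_id, fixture.aligned_row1),
        (fixture.chain2.structure_id, fixture.aligned_row2),
    ], aln)
    with truth_path.open("w") as fh:
        fh.write("key\tvalue\n")
        for key, value in fixture.truth.items():
            fh.write(f"{key}\t{value}\n")
    return {"structure1": p1, "structure2": p2, "alignment": aln,
            "truth_file": truth_path, "truth": fixture.truth}
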