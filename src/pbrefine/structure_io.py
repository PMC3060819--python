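"""Reading protein backbones from PDB/mmCIF and basic geometry.

Backbone chains carry N/CA/C (and optionally O) coordinates per residue,
phi/psi dihedrals and chain-break flags.  Residues missing any of N, CA or C
are dropped (and logged); altlocs are resolved to the highest-occupancy
conformer; only standard amino-acid residues are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Peptide-bond C(i-1)-N(i) distance above which a chain break is flagged (Angstrom).
DEFAULT_BREAK_CUTOFF = 2.5

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to their parent
    "MSE": "M", "SEC": "U", "PYL": "O",
}


class ChainNotFoundError(KeyError):
    """Requested chain id is absent from the structure file."""


class EmptyChainError(ValueError):
    """Chain contains no residue with a complete N/CA/C backbone."""


class DihedralUndefinedError(ValueError):
    """Dihedral angle is geometrically undefined (collinear points)."""


@dataclass
class Residue:
    """One backbone residue: author label, amino acid, N/CA/C(/O) coordinates."""

    seq_label: str                  # author residue number + insertion code
    aa: str                         # one-letter amino acid
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: Optional[np.ndarray] = None
    phi: Optional[float] = None
    psi: Optional[float] = None
    chain_break_before: bool = False


@dataclass
class BackboneChain:
    """Ordered backbone residues of one chain, with dihedrals computed."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    structure_id: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC sign convention: a trans arrangement gives +180.

    Raises
    ------
    DihedralUndefinedError
        If three consecutive points are collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9 or norm_b2 < 1e-9:
        raise DihedralUndefinedError("collinear or coincident points")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def _compute_chain_dihedrals(residues: Sequence[Residue]) -> None:
    """Fill phi/psi in place; undefined at stretch boundaries and breaks."""
    for i, res in enumerate(residues):
        res.phi = None
        res.psi = None
        if i > 0 and not res.chain_break_before:
            try:
                res.phi = compute_dihedral(
                    residues[i - 1].c, res.n, res.ca, res.c)
            except DihedralUndefinedError:
                pass
        if i + 1 < len(residues) and not residues[i + 1].chain_break_before:
            try:
                res.psi = compute_dihedral(
                    res.n, res.ca, res.c, residues[i + 1].n)
            except DihedralUndefinedError:
                pass


def _flag_breaks(residues: Sequence[Residue], cutoff: float) -> None:
    for i in range(1, len(residues)):
        d = float(np.linalg.norm(residues[i].n - residues[i - 1].c))
        residues[i].chain_break_before = d > cutoff


def _load_atom_array(path: Path, model: int):
    """Read a structure file into a biotite AtomArray (altloc by occupancy)."""
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif", ".pdbx"}:
        from biotite.structure.io import pdbx

        cif = pdbx.CIFFile.read(str(path))
        return pdbx.get_structure(cif, model=model, altloc="occupancy",
                                  extra_fields=["occupancy"])
    from biotite.structure.io import pdb

    pdb_file = pdb.PDBFile.read(str(path))
    return pdb.get_structure(pdb_file, model=model, altloc="occupancy",
                             extra_fields=["occupancy"])


def read_structure(path, chain: str, model: int = 1,
                   break_cutoff: float = DEFAULT_BREAK_CUTOFF) -> BackboneChain:
    """Read one chain of a PDB or mmCIF file as a :class:`BackboneChain`.

    Parameters
    ----------
    path : str or Path
        PDB (.pdb/.ent) or mmCIF (.cif) file.
    chain : str
        Author chain identifier.
    model : int
        Model number (1-based); only one model is used.
    break_cutoff : float
        C(i-1)-N(i) distance (Angstrom) above which a chain break is flagged.
    """
    path = Path(path)
    atoms = _load_atom_array(path, model)
    chain_ids = set(atoms.chain_id)
    if chain not in chain_ids:
        raise ChainNotFoundError(
            f"chain {chain!r} not in {path.name} (has {sorted(chain_ids)})")
    sel = atoms[atoms.chain_id == chain]
    # keep standard (and mapped-modified) amino acids only; drops waters/ligands
    residues: list[Residue] = []
    # group by (res_id, ins_code) in file order
    order: list[tuple] = []
    groups: dict[tuple, dict] = {}
    ins = sel.ins_code if "ins_code" in sel.get_annotation_categories() else [""] * sel.array_length()
    for idx in range(sel.array_length()):
        res_name = sel.res_name[idx]
        if res_name not in _THREE_TO_ONE:
            continue
        key = (int(sel.res_id[idx]), str(ins[idx]).strip())
        if key not in groups:
            groups[key] = {"name": res_name}
            order.append(key)
        atom_name = sel.atom_name[idx]
        if atom_name in ("N", "CA", "C", "O") and atom_name not in groups[key]:
            groups[key][atom_name] = np.array(sel.coord[idx], dtype=float)
    for key in order:
        g = groups[key]
        if not all(a in g for a in ("N", "CA", "C")):
            logger.warning("dropping residue %s%s in %s chain %s: incomplete backbone",
                           key[0], key[1], path.name, chain)
            continue
        label = f"{key[0]}{key[1]}"
        residues.append(Residue(
            seq_label=label,
            aa=_THREE_TO_ONE[g["name"]],
            n=g["N"], ca=g["CA"], c=g["C"], o=g.get("O"),
        ))
    if not residues:
        raise EmptyChainError(f"no usable residues in {path.name} chain {chain}")
    _flag_breaks(residues, break_cutoff)
    _compute_chain_dihedrals(residues)
    return BackboneChain(chain_id=chain, residues=residues,
                         structure_id=path.stem)


def write_pb_fasta(sequences: Iterable, path) -> None:
    """Write PB sequences as plain FASTA (60-character lines).

    Accepts :class:`~pbrefine.pb_alphabet.PBSequence` objects (or anything
    with ``symbols``/``header`` attributes).
    """
    path = Path(path)
    with path.open("w") as fh:
        for seq in sequences:
            header = getattr(seq, "header", None) or getattr(seq, "name", "pb_sequence")
            symbols = getattr(seq, "symbols", None)
            if symbols is None:
                symbols = str(seq)
            fh.write(f">{header}\n")
            for i in range(0, len(symbols), 60):
                fh.write(symbols[i:i + 60] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Minimal FASTA reader returning (header, sequence) pairs."""
    records: list[tuple[str, str]] = []
    header = None
    parts: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(parts)))
                header = line[1:].strip()
                parts = []
            elif line.strip():
                parts.append(line.strip())
    if header is not None:
        records.append((header, "".join(parts)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Write (header, sequence) records as FASTA."""
    with Path(path).open("w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_pdb(chain: BackboneChain, path, chain_id: Optional[str] = None) -> None:
    """Write a backbone chain as fixed-width PDB ATOM records (N, CA, C, O)."""
    cid = (chain_id or chain.chain_id or "A")[:1]
    serial = 1
    with Path(path).open("w") as fh:
        for i, res in enumerate(chain.residues):
            res_num = res.seq_label
            # split trailing insertion code if any
            icode = " "
            num_part = res_num
            if num_part and num_part[-1].isalpha():
                icode = num_part[-1]
                num_part = num_part[:-1]
            resno = int(num_part)
            res3 = next((k for k, v in _THREE_TO_ONE.items() if v == res.aa), "ALA")
            atom_list = [("N", res.n), ("CA", res.ca), ("C", res.c)]
            if res.o is not None:
                atom_list.append(("O", res.o))
            for name, xyz in atom_list:
                pad_name = f" {name:<3s}"
                fh.write(
                    f"ATOM  {serial:>5d} {pad_name}{'':1s}{res3:>3s} {cid}"
                    f"{resno:>4d}{icode}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}\n")
                serial += 1
        fh.write("TER\nEND\n")
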