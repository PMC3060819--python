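"""The 16-letter Protein Block structural alphabet and backbone encoding.

Each Protein Block (PB) is a five-residue backbone prototype described by
eight dihedral angles ordered (psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i),
phi(i+1), psi(i+1), phi(i+2)).  A backbone is encoded one letter per residue
by choosing, at every residue with a complete eight-dihedral window, the
prototype with the lowest angular RMSD ("rmsda").  Positions without a full
window (the two residues at each end of a continuous stretch, and anything
touching a chain break) get the undefined symbol 'Z'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .structure_io import BackboneChain

PB_LABELS = "abcdefghijklmnop"
UNDEFINED_SYMBOL = "Z"

#: window offsets covered by one PB, relative to the central residue
WINDOW = (-2, -1, 0, 1, 2)


class UndefinedWindowError(ValueError):
    """An angle in the comparison window is undefined."""


@dataclass(frozen=True)
class PBAlphabet:
    """The 16 PB prototypes: label -> 8-vector of dihedrals (degrees)."""

    prototypes: dict[str, np.ndarray]
    undefined_symbol: str = UNDEFINED_SYMBOL

    def __post_init__(self):
        if sorted(self.prototypes) != list(PB_LABELS):
            raise ValueError("alphabet must define exactly the labels a..p")
        for label, vec in self.prototypes.items():
            v = np.asarray(vec, dtype=float)
            if v.shape != (8,):
                raise ValueError(f"prototype {label} is not an 8-vector")
            if np.any(v <= -180.0) or np.any(v > 180.0):
                raise ValueError(f"prototype {label} angles outside (-180, 180]")

    def matrix(self) -> np.ndarray:
        """16x8 prototype matrix in label order."""
        return np.array([self.prototypes[l] for l in PB_LABELS], dtype=float)


def load_alphabet(path: Optional[Path] = None) -> PBAlphabet:
    """Load the prototype table (TSV: label + 8 angles); default = shipped table."""
    if path is None:
        source = resources.files("pbrefine.data").joinpath("pb_prototypes.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    lines = [l for l in text.strip().splitlines() if l.strip()]
    prototypes: dict[str, np.ndarray] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        prototypes[parts[0]] = np.array([float(x) for x in parts[1:9]])
    return PBAlphabet(prototypes=prototypes)


@dataclass
class PBSequence:
    """A PB string index-linked to the residues of its source chain."""

    symbols: str
    chain: Optional[BackboneChain] = None
    header: str = ""

    def __post_init__(self):
        if self.chain is not None and len(self.symbols) != len(self.chain):
            raise ValueError("PB string length must equal residue count")
        bad = set(self.symbols) - set(PB_LABELS + UNDEFINED_SYMBOL)
        if bad:
            raise ValueError(f"invalid PB symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.symbols)

    def residue(self, position: int):
        """Residue at a symbol position (central residue of the PB window)."""
        if self.chain is None:
            raise ValueError("sequence is not linked to a chain")
        return self.chain.residues[position]


def wrap_angle_diff(a, b):
    """Absolute angular difference in [0, 180] degrees (elementwise)."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def rmsda(window, prototype) -> float:
    """Root mean square deviation of (wrapped) dihedral angles, in degrees."""
    w = np.asarray(window, dtype=float)
    p = np.asarray(prototype, dtype=float)
    if w.shape != (8,) or p.shape != (8,):
        raise ValueError("rmsda expects two 8-vectors")
    if np.any(~np.isfinite(w)) or np.any(~np.isfinite(p)):
        raise UndefinedWindowError("undefined angle in window")
    d = wrap_angle_diff(w, p)
    return float(np.sqrt(np.mean(d * d)))


def _dihedral_window(chain: BackboneChain, i: int) -> Optional[np.ndarray]:
    """8-dihedral window centred on residue i, or None if incomplete."""
    n = len(chain)
    if i - 2 < 0 or i + 2 >= n:
        return None
    # no chain break inside the 5-residue window
    for j in range(i - 1, i + 3):
        if chain.residues[j].chain_break_before:
            return None
    r = chain.residues
    vals = (r[i - 2].psi, r[i - 1].phi, r[i - 1].psi, r[i].phi,
            r[i].psi, r[i + 1].phi, r[i + 1].psi, r[i + 2].phi)
    if any(v is None for v in vals):
        return None
    return np.array(vals, dtype=float)


def assign_pbs(chain: BackboneChain, alphabet: Optional[PBAlphabet] = None) -> PBSequence:
    """Encode a backbone as a PB string (one symbol per residue).

    Ties in rmsda are broken by label order (a < b < ... < p), so the
    assignment is deterministic.
    """
    if alphabet is None:
        alphabet = load_alphabet()
    proto = alphabet.matrix()
    symbols = []
    for i in range(len(chain)):
        window = _dihedral_window(chain, i)
        if window is None:
            symbols.append(alphabet.undefined_symbol)
            continue
        d = wrap_angle_diff(window[None, :], proto)
        scores = np.sqrt(np.mean(d * d, axis=1))
        best = int(np.argmin(scores))  # argmin takes the first (lowest label) on ties
        symbols.append(PB_LABELS[best])
    first = chain.residues[0].seq_label if len(chain) else ""
    last = chain.residues[-1].seq_label if len(chain) else ""
    header = f"{chain.structure_id}|chain {chain.chain_id}|residues {first}-{last}"
    return PBSequence(symbols="".join(symbols), chain=chain, header=header)
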