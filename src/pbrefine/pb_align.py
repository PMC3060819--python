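"""Global affine-gap alignment of two PB strings under a substitution matrix.

The dynamic programme is Gotoh's three-state recursion maximizing the summed
substitution value (matrix min-max scaled to [0, 10]) minus affine gap costs:
a gap run of length L costs ``gap_open + (L - 1) * gap_extend``.  End gaps
are penalized by default — SVR boundaries are pinned by the flanking
conserved regions, so the alignment is genuinely global.  The undefined
symbol 'Z' scores 0 against everything.

Traceback ties are resolved with a fixed operation preference
(match > gap-in-sequence-2 > gap-in-sequence-1) so output is reproducible
bit-exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .pb_alphabet import PB_LABELS, UNDEFINED_SYMBOL

logger = logging.getLogger(__name__)

GAP = "-"
NEG_INF = float("-inf")


class MatrixFormatError(ValueError):
    """Substitution-matrix file is malformed or degenerate."""


@dataclass
class SubstitutionMatrix:
    """16x16 symmetric PB substitution matrix (raw + [0,10]-scaled forms)."""

    raw: np.ndarray
    name: str = "unnamed"

    scaled: np.ndarray = field(init=False)

    def __post_init__(self):
        raw = np.asarray(self.raw, dtype=float)
        if raw.shape != (16, 16):
            raise MatrixFormatError("matrix must be 16x16")
        if not np.allclose(raw, raw.T, atol=1e-9):
            warnings.warn("asymmetric matrix symmetrized by averaging")
            raw = (raw + raw.T) / 2.0
        self.raw = raw
        lo, hi = float(raw.min()), float(raw.max())
        if hi - lo < 1e-12:
            raise MatrixFormatError("degenerate matrix: all values equal")
        self.scaled = 10.0 * (raw - lo) / (hi - lo)

    def _index(self, symbol: str) -> int:
        idx = PB_LABELS.find(symbol)
        if idx < 0:
            raise KeyError(f"unknown PB symbol {symbol!r}")
        return idx

    def raw_value(self, a: str, b: str) -> float:
        if a == UNDEFINED_SYMBOL or b == UNDEFINED_SYMBOL:
            return 0.0
        return float(self.raw[self._index(a), self._index(b)])

    def scaled_value(self, a: str, b: str) -> float:
        if a == UNDEFINED_SYMBOL or b == UNDEFINED_SYMBOL:
            return 0.0
        return float(self.scaled[self._index(a), self._index(b)])


def load_matrix(path) -> SubstitutionMatrix:
    """Load a whitespace-delimited 16x16 matrix with a..p row/column labels."""
    path = Path(path)
    lines = [l for l in path.read_text().strip().splitlines()
             if l.strip() and not l.lstrip().startswith("#")]
    header = lines[0].split()
    if header and header[0].lower() in ("pb", ""):
        header = header[1:]
    if sorted(header) != list(PB_LABELS):
        raise MatrixFormatError(f"column labels must be a..p, got {header}")
    col_order = [PB_LABELS.index(h) for h in header]
    raw = np.full((16, 16), np.nan)
    if len(lines) != 17:
        raise MatrixFormatError("expected 16 data rows")
    for line in lines[1:]:
        parts = line.split()
        label = parts[0]
        if label not in PB_LABELS:
            raise MatrixFormatError(f"unknown row label {label!r}")
        try:
            values = [float(x) for x in parts[1:]]
        except ValueError as exc:
            raise MatrixFormatError(f"non-numeric cell in row {label}") from exc
        if len(values) != 16:
            raise MatrixFormatError(f"row {label} has {len(values)} cells")
        r = PB_LABELS.index(label)
        for c, v in zip(col_order, values):
            raw[r, c] = v
    if np.any(np.isnan(raw)):
        raise MatrixFormatError("matrix incomplete")
    return SubstitutionMatrix(raw=raw, name=path.stem)


def write_matrix(sm: SubstitutionMatrix, path) -> None:
    """Write the raw matrix in the same TSV dialect `load_matrix` reads."""
    with Path(path).open("w") as fh:
        fh.write("pb\t" + "\t".join(PB_LABELS) + "\n")
        for i, label in enumerate(PB_LABELS):
            fh.write(label + "\t"
                     + "\t".join(f"{sm.raw[i, j]:.6g}" for j in range(16))
                     + "\n")


def default_matrix() -> SubstitutionMatrix:
    """The shipped STAND-IN matrix, derived from inter-prototype angular
    distances; a user-supplied matrix should be preferred for real analyses."""
    from importlib import resources

    source = resources.files("pbrefine.data").joinpath("pb_substitution_standin.tsv")
    import tempfile

    # reuse the file parser on the packaged text
    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        fh.write(source.read_text())
        tmp = fh.name
    try:
        sm = load_matrix(tmp)
    finally:
        Path(tmp).unlink(missing_ok=True)
    sm.name = "angular-distance stand-in"
    return sm


@dataclass
class AlignParams:
    gap_open: float = 10.0
    gap_extend: float = 0.2
    end_gaps_penalized: bool = True

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclass
class PBAlignment:
    """Aligned pair of PB strings: columns of (symbol-or-'-', symbol-or-'-')."""

    columns: list[tuple[str, str]]
    dp_score: float = 0.0

    def __post_init__(self):
        for a, b in self.columns:
            if a == GAP and b == GAP:
                raise ValueError("gap/gap column")

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def row1(self) -> str:
        return "".join(a for a, _ in self.columns)

    @property
    def row2(self) -> str:
        return "".join(b for _, b in self.columns)

    def ungapped(self) -> tuple[str, str]:
        return (self.row1.replace(GAP, ""), self.row2.replace(GAP, ""))


def _validate_pb_string(s: str) -> None:
    bad = set(s) - set(PB_LABELS + UNDEFINED_SYMBOL)
    if bad:
        raise ValueError(f"invalid PB symbols: {sorted(bad)}")


def align(s1: str, s2: str, sm: SubstitutionMatrix,
          params: AlignParams = AlignParams()) -> PBAlignment:
    """Optimal global alignment of two PB strings (Gotoh affine-gap DP).

    The objective uses the [0,10]-scaled matrix; the first symbol of a gap
    run costs ``gap_open``, each further symbol ``gap_extend``.  With
    ``end_gaps_penalized=False`` terminal gap runs are free.
    """
    _validate_pb_string(s1)
    _validate_pb_string(s2)
    m, n = len(s1), len(s2)
    if m == 0 and n == 0:
        return PBAlignment(columns=[], dp_score=0.0)
    go, ge = params.gap_open, params.gap_extend
    end_go, end_ge = (go, ge) if params.end_gaps_penalized else (0.0, 0.0)

    # M: s1[i-1] aligned to s2[j-1]; X: gap in s2 (s1 consumed); Y: gap in s1
    M = np.full((m + 1, n + 1), NEG_INF)
    X = np.full((m + 1, n + 1), NEG_INF)
    Y = np.full((m + 1, n + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = -(end_go + (i - 1) * end_ge)
    for j in range(1, n + 1):
        Y[0, j] = -(end_go + (j - 1) * end_ge)
    for i in range(1, m + 1):
        si = s1[i - 1]
        for j in range(1, n + 1):
            sub = sm.scaled_value(si, s2[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub
            # terminal gap runs touch i==m or j==n borders; interior runs use full costs
            gox, gex = (end_go, end_ge) if j == n else (go, ge)
            X[i, j] = max(M[i - 1, j] - gox, X[i - 1, j] - gex,
                          Y[i - 1, j] - gox)
            goy, gey = (end_go, end_ge) if i == m else (go, ge)
            Y[i, j] = max(M[i, j - 1] - goy, Y[i, j - 1] - gey,
                          X[i, j - 1] - goy)
    score = max(M[m, n], X[m, n], Y[m, n])

    # deterministic traceback: prefer M, then X (gap in s2), then Y
    columns: list[tuple[str, str]] = []
    i, j = m, n
    eps = 1e-9
    if M[i, j] >= score - eps:
        state = "M"
    elif X[i, j] >= score - eps:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if state == "M":
            sub = sm.scaled_value(s1[i - 1], s2[j - 1])
            columns.append((s1[i - 1], s2[j - 1]))
            target = M[i, j] - sub
            i, j = i - 1, j - 1
            if M[i, j] >= target - eps:
                state = "M"
            elif X[i, j] >= target - eps:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            # column j == 0 runs are left-terminal (cost constants must match
            # the initialization, not the interior recurrence)
            gox, gex = (end_go, end_ge) if j in (0, n) else (go, ge)
            columns.append((s1[i - 1], GAP))
            target = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] - gox >= target - eps:
                state = "M"
            elif X[i, j] - gex >= target - eps:
                state = "X"
            else:
                state = "Y"
        else:
            goy, gey = (end_go, end_ge) if i in (0, m) else (go, ge)
            columns.append((GAP, s2[j - 1]))
            target = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] - goy >= target - eps:
                state = "M"
            elif Y[i, j] - gey >= target - eps:
                state = "Y"
            else:
                state = "X"
    columns.reverse()
    aln = PBAlignment(columns=columns, dp_score=float(score))
    assert aln.ungapped() == (s1, s2)
    return aln
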