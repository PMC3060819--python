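"""Segmentation of a superposed pairwise alignment into SCRs and SVRs.

A structurally conserved region (SCR) is a maximal run of at least
``min_scr_length`` consecutive non-gap alignment columns whose CA-CA
deviation (under the current rigid superposition) is below the cutoff
(default 3.0 A).  Every other column belongs to exactly one maximal
structurally variable region (SVR); gap columns are always SVR members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .pb_alphabet import PBSequence, UNDEFINED_SYMBOL

GAP = "-"


@dataclass
class ResiduePairAlignment:
    """Pairwise residue alignment: columns of (index-or-None, index-or-None).

    Indices refer to residue positions (0-based) within the two chains.
    """

    columns: list[tuple[Optional[int], Optional[int]]]
    source: str = ""

    def __post_init__(self):
        prev1 = prev2 = -1
        for k, (i, j) in enumerate(self.columns):
            if i is None and j is None:
                raise ValueError(f"column {k} is gap/gap")
            if i is not None:
                if i <= prev1:
                    raise ValueError("residue indices must strictly increase (seq 1)")
                prev1 = i
            if j is not None:
                if j <= prev2:
                    raise ValueError("residue indices must strictly increase (seq 2)")
                prev2 = j

    def __len__(self) -> int:
        return len(self.columns)


def alignment_from_fasta_strings(row1: str, row2: str,
                                 source: str = "input FASTA") -> ResiduePairAlignment:
    """Build a ResiduePairAlignment from two equal-length aligned strings."""
    if len(row1) != len(row2):
        raise ValueError("aligned rows must have equal length")
    cols = []
    i = j = 0
    for a, b in zip(row1, row2):
        gi = gj = None
        if a not in (GAP, "."):
            gi = i
            i += 1
        if b not in (GAP, "."):
            gj = j
            j += 1
        if gi is None and gj is None:
            continue
        cols.append((gi, gj))
    return ResiduePairAlignment(columns=cols, source=source)


@dataclass
class SegmentationParams:
    deviation_cutoff: float = 3.0      # Angstrom
    min_scr_length: int = 3            # residues
    min_svr_aligned_pbs: int = 3       # SVRs must have MORE than this many pairs

    def __post_init__(self):
        if self.deviation_cutoff <= 0 or self.min_scr_length <= 0 \
                or self.min_svr_aligned_pbs <= 0:
            raise ValueError("segmentation parameters must be positive")


@dataclass
class SVRSegment:
    """One maximal structurally variable run of alignment columns."""

    column_range: tuple[int, int]          # half-open [start, end)
    pb_sub_1: str = ""
    pb_sub_2: str = ""
    terminal: bool = False
    unalignable: bool = False
    before_alignment: Optional[object] = None   # PBAlignment
    after_alignment: Optional[object] = None    # PBAlignment

    @property
    def start(self) -> int:
        return self.column_range[0]

    @property
    def end(self) -> int:
        return self.column_range[1]

    def __len__(self) -> int:
        return self.end - self.start


def segment(alignment: ResiduePairAlignment,
            deviations: Sequence[Optional[float]],
            params: SegmentationParams = SegmentationParams()
            ) -> tuple[list[tuple[int, int]], list[SVRSegment]]:
    """Split alignment columns into SCR ranges and SVR segments.

    ``deviations`` holds one CA-CA distance (or None) per column.  Returns
    (scr_ranges, svr_segments); the ranges tile [0, n_columns) exactly.
    """
    n = len(alignment.columns)
    if n != len(deviations):
        raise ValueError("one deviation per alignment column required")
    if n == 0:
        return [], []
    conserved = [
        alignment.columns[k][0] is not None
        and alignment.columns[k][1] is not None
        and deviations[k] is not None
        and deviations[k] < params.deviation_cutoff
        for k in range(n)
    ]
    scr_ranges: list[tuple[int, int]] = []
    k = 0
    while k < n:
        if conserved[k]:
            run_start = k
            while k < n and conserved[k]:
                k += 1
            if k - run_start >= params.min_scr_length:
                scr_ranges.append((run_start, k))
        else:
            k += 1
    svrs: list[SVRSegment] = []
    pos = 0
    for start, end in scr_ranges + [(n, n)]:
        if pos < start:
            svrs.append(SVRSegment(
                column_range=(pos, start),
                terminal=(pos == 0 or start == n),
            ))
        pos = end
    return scr_ranges, svrs


def extract_svr_pb(svr: SVRSegment, alignment: ResiduePairAlignment,
                   pb1: PBSequence, pb2: PBSequence) -> tuple[str, str]:
    """Project each chain's PB symbols over the SVR's column span.

    Gap positions are dropped; 'Z' symbols are retained.  The substrings are
    stored on the segment; a segment where one side contributes no residues
    is marked unalignable.
    """
    s1 = []
    s2 = []
    for k in range(svr.start, svr.end):
        i, j = alignment.columns[k]
        if i is not None:
            s1.append(pb1.symbols[i])
        if j is not None:
            s2.append(pb2.symbols[j])
    svr.pb_sub_1 = "".join(s1)
    svr.pb_sub_2 = "".join(s2)
    svr.unalignable = len(svr.pb_sub_1) == 0 or len(svr.pb_sub_2) == 0
    return svr.pb_sub_1, svr.pb_sub_2


def attach_pb_substrings(svrs: list[SVRSegment], alignment: ResiduePairAlignment,
                         pb1: PBSequence, pb2: PBSequence) -> None:
    for svr in svrs:
        extract_svr_pb(svr, alignment, pb1, pb2)


def count_aligned_pb_pairs(alignment) -> int:
    """Number of columns aligning two defined (non-gap, non-'Z') PB symbols."""
    n = 0
    for a, b in alignment.columns:
        if a not in (None, GAP, UNDEFINED_SYMBOL) and b not in (None, GAP, UNDEFINED_SYMBOL):
            n += 1
    return n


def filter_complete(svrs: list[SVRSegment],
                    params: SegmentationParams = SegmentationParams(),
                    for_sdm: bool = False) -> list[SVRSegment]:
    """Keep "complete" SVRs: more than ``min_svr_aligned_pbs`` aligned PB
    pairs on the before-alignment.  With ``for_sdm=True`` terminal SVRs are
    excluded as well (they are dropped from the SDM analysis)."""
    kept = []
    for svr in svrs:
        if svr.before_alignment is None:
            continue
        if count_aligned_pb_pairs(svr.before_alignment) <= params.min_svr_aligned_pbs:
            continue
        if for_sdm and svr.terminal:
            continue
        kept.append(svr)
    return kept
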