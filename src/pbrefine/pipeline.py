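"""End-to-end refinement of one structure pair.

Stages: PB assignment -> global superposition (refitted on SCR columns) ->
per-column CA deviations -> SCR/SVR segmentation -> per-SVR PB re-alignment
-> scoring/classification/SDM -> report.  SCR equivalences pass through
untouched; only SVRs are re-aligned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import scoring
from .pb_align import (GAP, AlignParams, PBAlignment, SubstitutionMatrix, align)
from .pb_alphabet import UNDEFINED_SYMBOL, PBAlphabet, PBSequence, assign_pbs, load_alphabet
from .scoring import (DeltaRecord, ScoreParams, SDMParams, SVRScores,
                      compare, score_alignment)
from .segmentation import (ResiduePairAlignment, SegmentationParams,
                           SVRSegment, attach_pb_substrings,
                           count_aligned_pb_pairs, segment)
from .structure_io import BackboneChain
from .superpose import (RigidTransform, column_deviations, kabsch_fit,
                        pair_rmsd)

logger = logging.getLogger(__name__)


@dataclass
class SVRResult:
    """One SVR's refinement outcome."""

    svr: SVRSegment
    before: Optional[SVRScores] = None
    after: Optional[SVRScores] = None
    delta: Optional[DeltaRecord] = None
    refined_pairs: list[tuple[int, int]] = field(default_factory=list)
    refined: bool = False
    note: str = ""


@dataclass
class RefinementReport:
    """Full outcome of refining one structure pair."""

    pair_id: str
    chain1: BackboneChain
    chain2: BackboneChain
    pb1: PBSequence
    pb2: PBSequence
    alignment: ResiduePairAlignment
    transform: RigidTransform
    global_rmsd_scr: Optional[float]
    scr_ranges: list[tuple[int, int]]
    svr_results: list[SVRResult]
    refined_alignment: ResiduePairAlignment
    substitution_difference: np.ndarray
    notes: list[str] = field(default_factory=list)

    @property
    def n_svrs(self) -> int:
        return len(self.svr_results)


def _aligned_column_indices(alignment: ResiduePairAlignment) -> list[int]:
    return [k for k, (i, j) in enumerate(alignment.columns)
            if i is not None and j is not None]


def _fit_on_columns(alignment, chain1, chain2, column_idx):
    ca1 = np.array([chain1.residues[alignment.columns[k][0]].ca for k in column_idx])
    ca2 = np.array([chain2.residues[alignment.columns[k][1]].ca for k in column_idx])
    transform, rmsd = kabsch_fit(ca2, ca1)  # move chain2 onto chain1
    return transform, rmsd


def project_before_alignment(svr: SVRSegment, alignment: ResiduePairAlignment,
                             pb1: PBSequence, pb2: PBSequence) -> PBAlignment:
    """The input residue alignment over the SVR span, rendered in PB space."""
    columns = []
    for k in range(svr.start, svr.end):
        i, j = alignment.columns[k]
        a = pb1.symbols[i] if i is not None else GAP
        b = pb2.symbols[j] if j is not None else GAP
        columns.append((a, b))
    return PBAlignment(columns=columns)


def map_pb_to_residue_equivalences(pb_alignment: PBAlignment,
                                   residue_map_1: list[int],
                                   residue_map_2: list[int]
                                   ) -> list[tuple[int, int]]:
    """Map each aligned PB pair to its pair of central residues.

    ``residue_map_k`` gives the chain residue index for each position of the
    k-th ungapped PB substring.  Gap columns produce no pair.
    """
    pairs = []
    i = j = 0
    for a, b in pb_alignment.columns:
        gi = gj = None
        if a != GAP:
            gi = residue_map_1[i]
            i += 1
        if b != GAP:
            gj = residue_map_2[j]
            j += 1
        if gi is not None and gj is not None:
            pairs.append((gi, gj))
    return pairs


def _local_sdm(pairs: list[tuple[int, int]], chain1, chain2,
               n_total: int, sdm_params: SDMParams
               ) -> tuple[Optional[float], Optional[float]]:
    """Local Kabsch on the CA atoms of the equivalenced pairs -> (rmsd, SDM).

    Undefined (None, None) with fewer than 3 pairs.
    """
    if len(pairs) < 3 or n_total <= 0:
        return None, None
    ca1 = np.array([chain1.residues[i].ca for i, _ in pairs])
    ca2 = np.array([chain2.residues[j].ca for _, j in pairs])
    _, rmsd = kabsch_fit(ca2, ca1)
    try:
        value = scoring.sdm(rmsd, len(pairs), n_total, sdm_params)
    except scoring.UndefinedScoreError:
        value = None
    return rmsd, value


def substitution_difference(before: list[PBAlignment],
                            after: list[PBAlignment]) -> np.ndarray:
    """16x16 integer matrix of PB-pair count changes (after - before).

    Unordered pairs are accumulated symmetrically; 'Z' pairs are ignored.
    """
    from .pb_alphabet import PB_LABELS

    counts = np.zeros((16, 16), dtype=int)

    def accumulate(alignments, sign):
        for aln in alignments:
            for a, b in aln.columns:
                if a in (GAP, UNDEFINED_SYMBOL) or b in (GAP, UNDEFINED_SYMBOL):
                    continue
                i, j = PB_LABELS.index(a), PB_LABELS.index(b)
                counts[i, j] += sign
                if i != j:
                    counts[j, i] += sign

    accumulate(after, +1)
    accumulate(before, -1)
    return counts


def refine_pair(chain1: BackboneChain, chain2: BackboneChain,
                alignment: ResiduePairAlignment,
                sm: SubstitutionMatrix,
                alphabet: Optional[PBAlphabet] = None,
                seg_params: SegmentationParams = SegmentationParams(),
                align_params: AlignParams = AlignParams(),
                score_params: ScoreParams = ScoreParams(),
                sdm_params: SDMParams = SDMParams()) -> RefinementReport:
    """Refine the structurally variable regions of one pairwise alignment."""
    if alphabet is None:
        alphabet = load_alphabet()
    pb1 = assign_pbs(chain1, alphabet)
    pb2 = assign_pbs(chain2, alphabet)
    notes: list[str] = []

    aligned_cols = _aligned_column_indices(alignment)
    if len(aligned_cols) < 3:
        raise ValueError("alignment has fewer than 3 aligned residue pairs")

    # pass 1: fit on every aligned column, segment
    transform, _ = _fit_on_columns(alignment, chain1, chain2, aligned_cols)
    deviations = column_deviations(alignment, chain1, chain2, transform)
    scr_ranges, _ = segment(alignment, deviations, seg_params)

    # pass 2: refit on SCR columns only (the conserved core), re-segment
    scr_cols = [k for start, end in scr_ranges for k in range(start, end)]
    global_rmsd_scr: Optional[float] = None
    if len(scr_cols) >= 3:
        transform, global_rmsd_scr = _fit_on_columns(
            alignment, chain1, chain2, scr_cols)
        deviations = column_deviations(alignment, chain1, chain2, transform)
        scr_ranges, svrs = segment(alignment, deviations, seg_params)
        scr_cols = [k for start, end in scr_ranges for k in range(start, end)]
        if len(scr_cols) >= 3:
            global_rmsd_scr = pair_rmsd(
                np.array([chain1.residues[alignment.columns[k][0]].ca for k in scr_cols]),
                transform.apply(np.array(
                    [chain2.residues[alignment.columns[k][1]].ca for k in scr_cols])))
    else:
        notes.append("no SCR found; keeping all-column fit")
        _, svrs = segment(alignment, deviations, seg_params)

    attach_pb_substrings(svrs, alignment, pb1, pb2)
    if not svrs:
        notes.append("no variable regions")

    svr_results: list[SVRResult] = []
    before_alns: list[PBAlignment] = []
    after_alns: list[PBAlignment] = []
    for svr in svrs:
        result = SVRResult(svr=svr)
        svr.before_alignment = project_before_alignment(svr, alignment, pb1, pb2)
        result.before = score_alignment(svr.before_alignment, sm, score_params)
        res_idx_1 = [alignment.columns[k][0] for k in range(svr.start, svr.end)
                     if alignment.columns[k][0] is not None]
        res_idx_2 = [alignment.columns[k][1] for k in range(svr.start, svr.end)
                     if alignment.columns[k][1] is not None]
        n_total = min(len(res_idx_1), len(res_idx_2))
        before_pairs = [(i, j) for i, j in
                        (alignment.columns[k] for k in range(svr.start, svr.end))
                        if i is not None and j is not None]
        if result.before is not None:
            result.before.rmsd_local, result.before.sdm = _local_sdm(
                before_pairs, chain1, chain2, n_total, sdm_params)
        if svr.unalignable:
            result.note = "unrefined: one side contributes no residues"
            result.refined = False
            svr_results.append(result)
            continue
        try:
            svr.after_alignment = align(svr.pb_sub_1, svr.pb_sub_2, sm, align_params)
        except Exception as exc:   # pragma: no cover - defensive
            result.note = f"unrefined: alignment failed ({exc})"
            svr_results.append(result)
            continue
        result.after = score_alignment(svr.after_alignment, sm, score_params)
        result.refined_pairs = map_pb_to_residue_equivalences(
            svr.after_alignment, res_idx_1, res_idx_2)
        result.after.rmsd_local, result.after.sdm = _local_sdm(
            result.refined_pairs, chain1, chain2, n_total, sdm_params)
        result.delta = compare(result.before, result.after)
        result.refined = True
        before_alns.append(svr.before_alignment)
        after_alns.append(svr.after_alignment)
        svr_results.append(result)

    refined_alignment = _build_refined_alignment(
        alignment, scr_ranges, svr_results)
    report = RefinementReport(
        pair_id=f"{chain1.structure_id}:{chain1.chain_id}"
                f"__{chain2.structure_id}:{chain2.chain_id}",
        chain1=chain1, chain2=chain2, pb1=pb1, pb2=pb2,
        alignment=alignment, transform=transform,
        global_rmsd_scr=global_rmsd_scr,
        scr_ranges=scr_ranges, svr_results=svr_results,
        refined_alignment=refined_alignment,
        substitution_difference=substitution_difference(before_alns, after_alns),
        notes=notes,
    )
    return report


def _build_refined_alignment(alignment: ResiduePairAlignment,
                             scr_ranges: list[tuple[int, int]],
                             svr_results: list[SVRResult]) -> ResiduePairAlignment:
    """Stitch SCR columns (untouched) and refined SVR columns back together."""
    pieces: list[tuple[int, list]] = []
    for start, end in scr_ranges:
        pieces.append((start, [alignment.columns[k] for k in range(start, end)]))
    for result in svr_results:
        svr = result.svr
        if not result.refined or svr.after_alignment is None:
            cols = [alignment.columns[k] for k in range(svr.start, svr.end)]
        else:
            res_idx_1 = [alignment.columns[k][0] for k in range(svr.start, svr.end)
                         if alignment.columns[k][0] is not None]
            res_idx_2 = [alignment.columns[k][1] for k in range(svr.start, svr.end)
                         if alignment.columns[k][1] is not None]
            cols = []
            i = j = 0
            for a, b in svr.after_alignment.columns:
                gi = gj = None
                if a != GAP:
                    gi = res_idx_1[i]
                    i += 1
                if b != GAP:
                    gj = res_idx_2[j]
                    j += 1
                cols.append((gi, gj))
        pieces.append((svr.start, cols))
    pieces.sort(key=lambda p: p[0])
    columns = [col for _, cols in pieces for col in cols]
    return ResiduePairAlignment(columns=columns, source="refined")


# ---------------------------------------------------------------------------
# report serialization

def _fmt(x, digits=3):
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.{digits}f}"
    return str(x)


def svr_table_rows(report: RefinementReport) -> list[dict]:
    rows = []
    for idx, result in enumerate(report.svr_results):
        svr = result.svr
        b, a, d = result.before, result.after, result.delta
        rows.append({
            "svr_id": idx,
            "col_start": svr.start, "col_end": svr.end,
            "terminal": int(svr.terminal),
            "n_pairs_before": b.n_aligned_pairs if b else None,
            "n_pairs_after": a.n_aligned_pairs if a else None,
            "sap_before": b.sap if b else None,
            "sap_after": a.sap if a else None,
            "sca_before": b.sca if b else None,
            "sca_after": a.sca if a else None,
            "rmsd_before": b.rmsd_local if b else None,
            "rmsd_after": a.rmsd_local if a else None,
            "sdm_before": b.sdm if b else None,
            "sdm_after": a.sdm if a else None,
            "class_before": b.classification if b else None,
            "class_after": a.classification if a else None,
            "d_sap": d.d_sap if d else None,
            "d_sca": d.d_sca if d else None,
            "d_sdm": d.d_sdm if d else None,
            "d_gap_openings": d.d_gap_openings if d else None,
            "sap_cell": d.sap_cell if d else None,
            "sdm_cell": d.sdm_cell if d else None,
            "note": result.note,
        })
    return rows


def write_svr_table(report: RefinementReport, path) -> None:
    rows = svr_table_rows(report)
    header = ["svr_id", "col_start", "col_end", "terminal",
              "n_pairs_before", "n_pairs_after",
              "sap_before", "sap_after", "sca_before", "sca_after",
              "rmsd_before", "rmsd_after", "sdm_before", "sdm_after",
              "class_before", "class_after",
              "d_sap", "d_sca", "d_sdm", "d_gap_openings",
              "sap_cell", "sdm_cell", "note"]
    with Path(path).open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[k]) for k in header) + "\n")


def report_to_dict(report: RefinementReport) -> dict:
    return {
        "pair_id": report.pair_id,
        "global_rmsd_scr": report.global_rmsd_scr,
        "n_scrs": len(report.scr_ranges),
        "n_svrs": report.n_svrs,
        "scr_ranges": [list(r) for r in report.scr_ranges],
        "svrs": svr_table_rows(report),
        "substitution_difference": report.substitution_difference.tolist(),
        "refined_equivalences": [
            [report.chain1.residues[i].seq_label if i is not None else None,
             report.chain2.residues[j].seq_label if j is not None else None]
            for i, j in report.refined_alignment.columns
        ],
        "notes": report.notes,
    }


def write_report_json(report: RefinementReport, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(report_to_dict(report), fh, indent=1)
        fh.write("\n")


def refined_fasta_records(report: RefinementReport) -> list[tuple[str, str]]:
    """Aligned amino-acid and PB renditions of the refined alignment."""
    aa1, aa2, pbs1, pbs2 = [], [], [], []
    for i, j in report.refined_alignment.columns:
        aa1.append(report.chain1.residues[i].aa if i is not None else GAP)
        aa2.append(report.chain2.residues[j].aa if j is not None else GAP)
        pbs1.append(report.pb1.symbols[i] if i is not None else GAP)
        pbs2.append(report.pb2.symbols[j] if j is not None else GAP)
    c1 = f"{report.chain1.structure_id}:{report.chain1.chain_id}"
    c2 = f"{report.chain2.structure_id}:{report.chain2.chain_id}"
    return [
        (f"{c1}|aa|refined", "".join(aa1)),
        (f"{c2}|aa|refined", "".join(aa2)),
        (f"{c1}|pb|refined", "".join(pbs1)),
        (f"{c2}|pb|refined", "".join(pbs2)),
    ]
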