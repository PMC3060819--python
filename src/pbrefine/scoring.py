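"""Alignment scores (SAP, SCA), similarity classification, and SDM.

SAP ("score for aligned pairs") is the mean raw substitution-matrix value
over aligned PB pairs, gaps excluded.  SCA ("score for complete alignment")
additionally charges each gap column a fixed score of -3 and divides by the
full alignment length.  Both use the RAW matrix: the published cutoff
(-0.42) and worked scores (e.g. -2.07) are negative and therefore on the
raw, not the [0,10]-scaled, scale.

SDM is the Blundell-school structural distance metric,

    SDM = -100 * ln( w_equiv * PFTE + w_rms * (1 - RMS) )

with PFTE the fraction of topologically equivalent residues and
RMS = rmsd / max_rmsd, where max_rmsd defaults to 24.97 A (the corpus
maximum used in place of the metric's original 3.0 divisor).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .pb_alphabet import UNDEFINED_SYMBOL
from .pb_align import GAP, PBAlignment, SubstitutionMatrix

SIMILAR = "similar"
DISSIMILAR = "dissimilar"


class UndefinedScoreError(ValueError):
    """Score cannot be computed (e.g. zero aligned pairs for SAP)."""


@dataclass
class ScoreParams:
    gap_score: float = -3.0
    similarity_cutoff: float = -0.42


@dataclass
class SDMParams:
    max_rmsd: float = 24.97
    w_equiv: float = 0.5
    w_rms: float = 0.5

    def __post_init__(self):
        if self.w_equiv <= 0 or self.w_rms <= 0:
            raise ValueError("SDM weights must be positive")
        total = self.w_equiv + self.w_rms
        self.w_equiv /= total
        self.w_rms /= total


def _is_pair(a: str, b: str) -> bool:
    return a != GAP and b != GAP and a != UNDEFINED_SYMBOL and b != UNDEFINED_SYMBOL


def sap(alignment: PBAlignment, sm: SubstitutionMatrix) -> float:
    """Mean raw substitution value over aligned PB pairs ('Z' pairs excluded)."""
    total = 0.0
    n = 0
    for a, b in alignment.columns:
        if _is_pair(a, b):
            total += sm.raw_value(a, b)
            n += 1
    if n == 0:
        raise UndefinedScoreError("no aligned PB pairs")
    return total / n


def sca(alignment: PBAlignment, sm: SubstitutionMatrix,
        params: ScoreParams = ScoreParams()) -> float:
    """(sum of raw pair values + gap_score per gap column) / alignment length.

    Columns pairing a defined PB with 'Z' contribute 0 to the sum but count
    toward the length.
    """
    length = len(alignment.columns)
    if length == 0:
        raise UndefinedScoreError("empty alignment")
    total = 0.0
    for a, b in alignment.columns:
        if a == GAP or b == GAP:
            total += params.gap_score
        elif _is_pair(a, b):
            total += sm.raw_value(a, b)
    return total / length


def classify(sap_value: float, params: ScoreParams = ScoreParams()) -> str:
    """Conformationally similar iff SAP is strictly above the cutoff."""
    return SIMILAR if sap_value > params.similarity_cutoff else DISSIMILAR


def calibrate_cutoff(scr_saps: Sequence[float], quantile: float = 0.10) -> float:
    """Empirical lower quantile (linear interpolation) of SCR SAP scores.

    Lets users with their own matrix/corpus re-derive a similarity cutoff so
    that (1 - quantile) of conserved-region scores lie above it.
    """
    values = np.asarray(list(scr_saps), dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 calibration scores")
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must be in [0, 1]")
    return float(np.quantile(values, quantile, method="linear"))


def sdm(rmsd: float, n_equiv: int, n_total: int,
        params: SDMParams = SDMParams()) -> float:
    """Structural distance metric from a local superposition.

    PFTE = n_equiv / n_total; RMS = rmsd / max_rmsd (clamped to 1 with a
    warning if rmsd exceeds max_rmsd).
    """
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    if not (0 < n_equiv <= n_total):
        raise ValueError("require 0 < n_equiv <= n_total")
    rms = rmsd / params.max_rmsd
    if rms > 1.0:
        warnings.warn(f"rmsd {rmsd:.2f} exceeds max_rmsd {params.max_rmsd}; clamped")
        rms = 1.0
    pfte = n_equiv / n_total
    arg = params.w_equiv * pfte + params.w_rms * (1.0 - rms)
    if arg <= 0.0:
        raise UndefinedScoreError("SDM infinite: PFTE = 0 and RMS = 1")
    return -100.0 * math.log(arg)


@dataclass
class SVRScores:
    """Scores of one SVR alignment (before or after refinement)."""

    sap: Optional[float]
    sca: Optional[float]
    n_aligned_pairs: int
    n_gap_columns: int
    n_gap_openings: int
    length: int
    sdm: Optional[float] = None
    rmsd_local: Optional[float] = None
    classification: Optional[str] = None


def count_gap_openings(alignment: PBAlignment) -> int:
    """Number of maximal gap runs, summed over both rows."""
    openings = 0
    for row in (alignment.row1, alignment.row2):
        in_gap = False
        for ch in row:
            if ch == GAP and not in_gap:
                openings += 1
            in_gap = ch == GAP
    return openings


def score_alignment(alignment: PBAlignment, sm: SubstitutionMatrix,
                    params: ScoreParams = ScoreParams()) -> SVRScores:
    """Compute SAP/SCA/classification plus gap statistics for one alignment."""
    n_pairs = sum(1 for a, b in alignment.columns if _is_pair(a, b))
    n_gaps = sum(1 for a, b in alignment.columns if a == GAP or b == GAP)
    try:
        sap_value = sap(alignment, sm)
    except UndefinedScoreError:
        sap_value = None
    try:
        sca_value = sca(alignment, sm, params)
    except UndefinedScoreError:
        sca_value = None
    return SVRScores(
        sap=sap_value,
        sca=sca_value,
        n_aligned_pairs=n_pairs,
        n_gap_columns=n_gaps,
        n_gap_openings=count_gap_openings(alignment),
        length=len(alignment.columns),
        classification=None if sap_value is None else classify(sap_value, params),
    )


@dataclass
class DeltaRecord:
    """Before/after comparison of one SVR (positive delta = score went up)."""

    d_sap: Optional[float]
    d_sca: Optional[float]
    d_sdm: Optional[float]
    d_gap_fraction: Optional[float]
    d_gap_openings: int
    sap_cell: str      # better / equal / worse (by SAP; higher is better)
    sdm_cell: str      # better / equal / worse (by SDM; lower is better)


def _cell(delta: Optional[float], higher_is_better: bool, tol: float = 1e-9) -> str:
    if delta is None:
        return "undefined"
    if abs(delta) < tol:
        return "equal"
    improved = delta > 0 if higher_is_better else delta < 0
    return "better" if improved else "worse"


def compare(before: SVRScores, after: SVRScores) -> DeltaRecord:
    """Deltas (after - before) and the better/equal/worse grid cell."""

    def diff(a, b):
        return None if a is None or b is None else a - b

    d_sap = diff(after.sap, before.sap)
    d_sca = diff(after.sca, before.sca)
    d_sdm = diff(after.sdm, before.sdm)
    gf_before = before.n_gap_columns / before.length if before.length else None
    gf_after = after.n_gap_columns / after.length if after.length else None
    return DeltaRecord(
        d_sap=d_sap,
        d_sca=d_sca,
        d_sdm=d_sdm,
        d_gap_fraction=diff(gf_after, gf_before),
        d_gap_openings=after.n_gap_openings - before.n_gap_openings,
        sap_cell=_cell(d_sap, higher_is_better=True),
        sdm_cell=_cell(d_sdm, higher_is_better=False),
    )
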