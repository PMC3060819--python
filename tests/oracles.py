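"""Independent reference implementations used to check the package.

Everything here is deliberately naive (enumeration, direct formulas) and
shares no code path with the implementations under test.
"""

from __future__ import annotations

import math

import numpy as np

GAP = "-"


# ---------------------------------------------------------------------------
# dihedral

def dihedral_reference(p1, p2, p3, p4) -> float:
    """Signed dihedral via the two-plane atan2 formulation (degrees)."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    if ang > 180.0:
        ang -= 360.0
    return ang


# ---------------------------------------------------------------------------
# quaternion superposition (QCP-style rmsd)

def quaternion_rmsd(moving, fixed) -> float:
    """Optimal-superposition RMSD via the quaternion key-matrix eigenvalue."""
    A = np.asarray(moving, float)
    B = np.asarray(fixed, float)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    S = A.T @ B
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.max(np.linalg.eigvalsh(K))
    e0 = (np.sum(A * A) + np.sum(B * B)) / 2.0
    n = A.shape[0]
    msd = max(0.0, 2.0 * (e0 - lam) / n)
    return math.sqrt(msd)


# ---------------------------------------------------------------------------
# exhaustive global-alignment enumeration with affine gaps

def enumerate_alignments(s1: str, s2: str):
    """Yield every global alignment as a list of (char-or-'-', char-or-'-')."""

    def rec(i, j, prefix):
        if i == len(s1) and j == len(s2):
            yield list(prefix)
            return
        if i < len(s1) and j < len(s2):
            prefix.append((s1[i], s2[j]))
            yield from rec(i + 1, j + 1, prefix)
            prefix.pop()
        if i < len(s1):
            prefix.append((s1[i], GAP))
            yield from rec(i + 1, j, prefix)
            prefix.pop()
        if j < len(s2):
            prefix.append((GAP, s2[j]))
            yield from rec(i, j + 1, prefix)
            prefix.pop()

    yield from rec(0, 0, [])


def score_columns(columns, pair_score, gap_open, gap_extend,
                  end_gaps_penalized=True) -> float:
    """Score a column list: pair scores minus per-row affine gap-run costs."""
    total = 0.0
    for a, b in columns:
        if a != GAP and b != GAP:
            total += pair_score(a, b)
    n = len(columns)
    for row in (0, 1):
        k = 0
        while k < n:
            if columns[k][row] == GAP:
                start = k
                while k < n and columns[k][row] == GAP:
                    k += 1
                terminal = start == 0 or k == n
                if terminal and not end_gaps_penalized:
                    continue
                total -= gap_open + (k - start - 1) * gap_extend
            else:
                k += 1
    return total


def best_alignment_score(s1, s2, pair_score, gap_open, gap_extend,
                         end_gaps_penalized=True) -> float:
    best = -math.inf
    for cols in enumerate_alignments(s1, s2):
        best = max(best, score_columns(cols, pair_score, gap_open,
                                       gap_extend, end_gaps_penalized))
    return best


# ---------------------------------------------------------------------------
# segmentation by literal run-length rule

def segment_reference(eligible, min_len):
    """(scr_ranges, svr_ranges) from a per-column eligibility list."""
    n = len(eligible)
    scr = []
    k = 0
    while k < n:
        if eligible[k]:
            start = k
            while k < n and eligible[k]:
                k += 1
            if k - start >= min_len:
                scr.append((start, k))
        else:
            k += 1
    in_scr = [False] * n
    for a, b in scr:
        for t in range(a, b):
            in_scr[t] = True
    svr = []
    k = 0
    while k < n:
        if not in_scr[k]:
            start = k
            while k < n and not in_scr[k]:
                k += 1
            svr.append((start, k))
        else:
            k += 1
    return scr, svr


# ---------------------------------------------------------------------------
# naive per-column scores

def sap_reference(columns, raw_value, undefined="Z") -> float:
    vals = [raw_value(a, b) for a, b in columns
            if GAP not in (a, b) and undefined not in (a, b)]
    return sum(vals) / len(vals)


def sca_reference(columns, raw_value, gap_score=-3.0, undefined="Z") -> float:
    total = 0.0
    for a, b in columns:
        if a == GAP or b == GAP:
            total += gap_score
        elif undefined not in (a, b):
            total += raw_value(a, b)
    return total / len(columns)
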