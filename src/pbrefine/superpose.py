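"""Rigid-body superposition (Kabsch), RMSD, and per-column CA deviations."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


class UnderdeterminedFitError(ValueError):
    """Too few (or degenerate) points to determine a rigid transform."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> rotation @ x + translation."""

    rotation: np.ndarray      # 3x3, det +1
    translation: np.ndarray   # 3-vector

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflection is not a rigid transform")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ np.asarray(self.rotation).T + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        R = np.asarray(self.rotation)
        return RigidTransform(rotation=R.T, translation=-R.T @ np.asarray(self.translation))


def kabsch_fit(moving, fixed) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of `moving` onto `fixed`.

    Returns the proper (det +1) transform minimizing the summed squared
    distance over paired points, and the RMSD after applying it.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("point sets must have equal shape")
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape[0] < 3:
        raise UnderdeterminedFitError("need >= 3 paired 3-D points")
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    H = (moving - cm).T @ (fixed - cf)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    transform = RigidTransform(rotation=R, translation=t)
    diff = transform.apply(moving) - fixed
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return transform, rmsd


def pair_rmsd(coords1, coords2) -> float:
    """RMSD between already-superposed paired coordinates."""
    diff = np.asarray(coords1, dtype=float) - np.asarray(coords2, dtype=float)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def column_deviations(alignment, chain1, chain2,
                      transform: RigidTransform) -> list:
    """Per-column CA-CA distance after applying `transform` to chain2.

    Returns one value per alignment column; ``None`` for gap columns or
    columns whose residue lacks a CA atom.
    """
    out = []
    for col in alignment.columns:
        i, j = col
        if i is None or j is None:
            out.append(None)
            continue
        ca1 = chain1.residues[i].ca
        ca2 = chain2.residues[j].ca
        if ca1 is None or ca2 is None:
            logger.warning("column (%s,%s) missing CA; deviation undefined", i, j)
            out.append(None)
            continue
        ca2t = transform.apply(np.asarray(ca2)[None, :])[0]
        out.append(float(np.linalg.norm(np.asarray(ca1) - ca2t)))
    return out
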