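"""Vector geometry: distances, angles, Kabsch superposition, ensemble RMSF.

Distances are in Å and angles in degrees throughout, matching the units the
near-attack criterion is stated in (H–oxo distance window, H–oxo–Fe angle
threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure_io import Trajectory

logger = logging.getLogger("p450nac")

__all__ = [
    "RmsfResult",
    "pairwise_distance",
    "three_point_angle",
    "kabsch_superpose",
    "apply_transform",
    "ensemble_rmsf",
]

_DEGENERACY_TOL = 1e-6  # Å; minimum separation for a defined angle


def pairwise_distance(p, q) -> float:
    """Euclidean distance between two points (Å)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(p - q))


def three_point_angle(a, vertex, c) -> float:
    """Angle a–vertex–c in degrees, in [0, 180].

    For the near-attack criterion the vertex is the oxo atom: the angle is
    between the oxo→H and oxo→Fe vectors.
    """
    a = np.asarray(a, dtype=float)
    vertex = np.asarray(vertex, dtype=float)
    c = np.asarray(c, dtype=float)
    v1 = a - vertex
    v2 = c - vertex
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 <= _DEGENERACY_TOL or n2 <= _DEGENERACY_TOL:
        raise ValueError("degenerate angle: a point coincides with the vertex")
    cosine = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of mobile onto reference.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.  The
    rotation is always proper (determinant +1); a reflection that would fit
    better is corrected, so mirror-image point sets retain a positive RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("superposition requires N>=3 points of dimension 3")

    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    x = mobile - mob_center
    y = reference - ref_center

    # rank < 2 means the point set is a point or a line: rotation ill-defined
    if np.linalg.matrix_rank(x, tol=1e-8) < 2 or np.linalg.matrix_rank(y, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear or coincident) point set")

    covariance = x.T @ y
    u, _, vt = np.linalg.svd(covariance)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = ref_center - rotation @ mob_center
    fitted = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return rotation, translation, rmsd


def apply_transform(
    coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray
) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + np.asarray(
        translation
    )


@dataclass
class RmsfResult:
    """Per-residue root-mean-square fluctuation over an aligned ensemble."""

    entries: list[tuple[str, int, float]]  # (chain_id, residue_id, rmsf Å)
    selection: str

    def __post_init__(self) -> None:
        if any(rmsf < 0 for _, _, rmsf in self.entries):
            raise ValueError("RMSF must be non-negative")

    def fraction_below(self, threshold: float) -> float:
        """Fraction of residues with RMSF below threshold (Å)."""
        if not self.entries:
            return 0.0
        return sum(r < threshold for _, _, r in self.entries) / len(self.entries)


def ensemble_rmsf(
    structures: Sequence[Trajectory], atom_name: str = "CA",
    superpose: bool = True,
) -> RmsfResult:
    """Per-residue RMSF across a structural ensemble.

    One designated atom per residue (default the alpha carbon ``CA``) stands
    for the residue.  Residues missing the atom in any structure are dropped
    from fitting and reporting with a warning — crystal ensembles routinely
    have differing unresolved loops.  All structures are rigid-body superposed
    onto the first (single pass, no iterative mean refinement); the RMSF of a
    residue is the root-mean-square deviation of its atom from its ensemble
    mean position.  ``superpose=False`` skips the fit for ensembles that are
    already aligned (the fit is a least-squares compromise over all residues,
    so it redistributes a strictly local displacement slightly).
    """
    if len(structures) < 2:
        raise ValueError("ensemble RMSF requires at least 2 structures")

    per_structure: list[dict[tuple[str, int], np.ndarray]] = []
    for traj in structures:
        mapping: dict[tuple[str, int], np.ndarray] = {}
        for i, atom in enumerate(traj.topology):
            if atom.name == atom_name:
                mapping[(atom.chain_id, atom.residue_id)] = traj.frames[0, i]
        per_structure.append(mapping)

    common = set(per_structure[0])
    for mapping in per_structure[1:]:
        common &= set(mapping)
    if not common:
        raise ValueError(f"no residue carries atom {atom_name!r} in every structure")
    dropped = set().union(*per_structure) - common
    if dropped:
        logger.warning(
            "ensemble_rmsf: dropping %d residue(s) missing %r in some structures",
            len(dropped),
            atom_name,
        )
    keys = sorted(common)

    coords = np.array(
        [[mapping[key] for key in keys] for mapping in per_structure], dtype=float
    )  # (n_structures, n_residues, 3)

    reference = coords[0]
    aligned = np.empty_like(coords)
    aligned[0] = reference
    for s in range(1, coords.shape[0]):
        if superpose:
            rotation, translation, _ = kabsch_superpose(coords[s], reference)
            aligned[s] = apply_transform(coords[s], rotation, translation)
        else:
            aligned[s] = coords[s]

    mean = aligned.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))

    entries = [
        (chain, resid, float(value)) for (chain, resid), value in zip(keys, rmsf)
    ]
    return RmsfResult(entries=entries, selection=f"atom name {atom_name}")
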