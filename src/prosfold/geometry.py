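"""Rigid-body superposition, RMSD and radius of gyration.

The model-vs-experiment agreement of a segment is measured as the Calpha
RMSD after least-squares optimal superposition (Kabsch).  Compactness is
measured by the radius of gyration of the experimental segment's Calpha
trace, normalised by N^(1/3) so that compact globules of different length
are comparable (RG of a compact globule scales as N^(1/3)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ProsfoldError
from .structio import SegmentMapping, Structure


@dataclass
class Superposition:
    rotation: np.ndarray   # (3,3) proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class GyrationResult:
    rg: float
    n_residues: int
    nrg: float


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares optimal proper rotation+translation of b onto a.

    Returns the transform and the resulting RMSD.  Degenerate (collinear)
    point sets still yield a valid minimum; the rotation ambiguity is
    resolved by the SVD sign convention.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ProsfoldError(f"coordinate shapes differ or are not Nx3: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ProsfoldError(f"need at least 3 atoms for superposition, got {n}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ProsfoldError("non-finite coordinates")

    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    a0 = a - cen_a
    b0 = b - cen_b
    h = b0.T @ a0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cen_a - rot @ cen_b
    moved = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=n)


def segment_rmsd(exp: Structure, model: Structure, mapping: SegmentMapping) -> float:
    """Calpha RMSD between mapped region residues of the two structures."""
    if len(mapping) < 3:
        raise ProsfoldError(f"only {len(mapping)} mapped residue pairs; need >= 3")
    model_chain = model.chain(mapping.model_chain_id)
    exp_chain = exp.chain(mapping.exp_chain_id)
    ca_model = model_chain.ca_coords([mi for mi, _ in mapping.pairs])
    ca_exp = exp_chain.ca_coords([ei for _, ei in mapping.pairs])
    return kabsch_superpose(ca_exp, ca_model).rmsd


def radius_of_gyration(coords: np.ndarray) -> float:
    """Root mean square distance of points from their centroid (unweighted)."""
    c = np.asarray(coords, dtype=float)
    if c.ndim != 2 or c.shape[0] < 1:
        raise ProsfoldError("need at least one coordinate")
    centred = c - c.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred ** 2, axis=1))))


def normalized_rg(coords: np.ndarray) -> float:
    """RG / N^(1/3): length-normalised compactness of a Calpha trace."""
    c = np.asarray(coords, dtype=float)
    if c.shape[0] < 2:
        raise ProsfoldError("need at least two coordinates for nRG")
    return radius_of_gyration(c) / c.shape[0] ** (1.0 / 3.0)


def gyration(coords: np.ndarray) -> GyrationResult:
    c = np.asarray(coords, dtype=float)
    return GyrationResult(rg=radius_of_gyration(c), n_residues=c.shape[0],
                          nrg=normalized_rg(c))
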