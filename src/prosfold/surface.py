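"""Solvent accessible surface area and the interaction (ΔASA) filter.

SASA is computed with the Shrake–Rupley rolling-probe method: each heavy
atom carries a deterministic golden-spiral lattice of test points on a
sphere of radius r_vdw + r_probe; the accessible fraction is the fraction
of points not buried inside any neighbouring atom's augmented sphere.

Relative ASA divides each residue's area by its theoretical maximum
(Tien et al. 2013); mrASA/crASA are region means in the monomeric
(segment chain alone) and complex (with partner chains) contexts.  A
segment whose region loses no area upon adding its partners (ΔASA ≈ 0)
is not actually in contact and is discarded by the interaction filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._aa import DEFAULT_VDW, MAX_ASA, VDW_RADII
from .errors import ProsfoldError
from .structio import ProSRecord, Structure

PROBE_RADIUS = 1.4  # water probe, A
N_SPHERE_POINTS = 960


@dataclass
class SasaResult:
    per_atom: np.ndarray                      # (n_atoms,) A^2
    per_residue: dict[tuple[str, int], float]  # (chain_id, residue_index) -> A^2
    probe_radius: float
    n_points: int
    radii_set: str = "vdw-standard"


@dataclass
class RasaSummary:
    mrasa: float
    crasa: float
    delta_asa: float


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of n points on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _gather_atoms(structure: Structure, chain_subset: list[str] | None):
    coords, radii, keys = [], [], []
    ids = chain_subset if chain_subset is not None else structure.chain_ids
    for cid in ids:
        chain = structure.chain(cid)
        for ri, res in enumerate(chain.residues):
            for atom in res.atoms:
                if atom.element in ("H", "D"):
                    continue
                coords.append(atom.coord)
                radii.append(VDW_RADII.get(atom.element, DEFAULT_VDW))
                keys.append((cid, ri))
    return np.asarray(coords, dtype=float), np.asarray(radii), keys


def compute_sasa(structure: Structure, chain_subset: list[str] | None = None,
                 n_points: int = N_SPHERE_POINTS,
                 probe_radius: float = PROBE_RADIUS) -> SasaResult:
    """Shrake–Rupley SASA over the selected chains (heavy atoms only)."""
    coords, radii, keys = _gather_atoms(structure, chain_subset)
    if coords.size == 0:
        raise ProsfoldError("empty atom selection for SASA")
    aug = radii + probe_radius
    sphere = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * aug.max()
    per_atom = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + aug[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], aug[i] + max_reach / 2.0)
                      if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > aug[j] ** 2
        per_atom[i] = accessible.mean() * 4.0 * np.pi * aug[i] ** 2

    per_residue: dict[tuple[str, int], float] = {}
    for area, key in zip(per_atom, keys):
        per_residue[key] = per_residue.get(key, 0.0) + area
    return SasaResult(per_atom=per_atom, per_residue=per_residue,
                      probe_radius=probe_radius, n_points=n_points)


def _region_indices(structure: Structure, record: ProSRecord,
                    residue_indices: list[int] | None) -> list[int]:
    chain = structure.chain(record.exp_chain)
    if residue_indices is not None:
        return list(residue_indices)
    start, end = record.region
    idx = chain.residues_in_range(start, end)
    if not idx:
        raise ProsfoldError(
            f"{record.pros_id}: no residues numbered {start}-{end} on chain "
            f"{record.exp_chain}; pass mapped residue_indices instead")
    return idx


def region_rasa(structure: Structure, record: ProSRecord, context: str,
                residue_indices: list[int] | None = None,
                n_points: int = N_SPHERE_POINTS) -> float:
    """Mean relative ASA of the region in the given context.

    ``context`` is "monomeric" (segment chain isolated) or "complex"
    (segment chain plus the record's partner chains).  ``residue_indices``
    selects the region residues on the experimental chain; when omitted,
    author numbering inside the region is used (only safe when author
    numbering equals UniProt numbering, as in synthetic data).
    """
    if context == "monomeric":
        subset = [record.exp_chain]
    elif context == "complex":
        missing = [c for c in record.partner_chain_ids if c not in structure.chain_ids]
        if missing:
            raise ProsfoldError(f"{record.pros_id}: partner chains {missing} absent")
        subset = [record.exp_chain] + list(record.partner_chain_ids)
    else:
        raise ValueError(f"unknown context {context!r}")

    idx = _region_indices(structure, record, residue_indices)
    chain = structure.chain(record.exp_chain)
    sasa = compute_sasa(structure, subset, n_points=n_points)
    values = []
    for ri in idx:
        code = chain.residues[ri].code
        ref = MAX_ASA.get(code)
        if ref is None:  # 'X' residues have no reference area
            continue
        values.append(sasa.per_residue.get((record.exp_chain, ri), 0.0) / ref)
    if not values:
        raise ProsfoldError(f"{record.pros_id}: no region residue with a known max-ASA reference")
    return float(np.mean(values))


def region_delta_asa(structure: Structure, record: ProSRecord,
                     residue_indices: list[int] | None = None,
                     n_points: int = N_SPHERE_POINTS) -> float:
    """ΔASA: region area lost when the partner chains are added (A^2)."""
    if not record.partner_chain_ids:
        raise ProsfoldError(f"{record.pros_id}: no partner chains declared")
    missing = [c for c in record.partner_chain_ids if c not in structure.chain_ids]
    if missing:
        raise ProsfoldError(f"{record.pros_id}: partner chains {missing} absent")
    idx = _region_indices(structure, record, residue_indices)
    mono = compute_sasa(structure, [record.exp_chain], n_points=n_points)
    comp = compute_sasa(structure, [record.exp_chain] + list(record.partner_chain_ids),
                        n_points=n_points)
    delta = sum(mono.per_residue.get((record.exp_chain, ri), 0.0)
                - comp.per_residue.get((record.exp_chain, ri), 0.0)
                for ri in idx)
    return float(delta)


# quadrature noise below this is treated as "no burial"
DELTA_ASA_TOLERANCE = 1.0  # A^2


def interaction_filter(structure: Structure, record: ProSRecord,
                       residue_indices: list[int] | None = None,
                       n_points: int = N_SPHERE_POINTS,
                       tolerance: float = DELTA_ASA_TOLERANCE) -> tuple[float, bool]:
    """(ΔASA, keep): keep the record only if its region is buried by the
    partners (ΔASA above the quadrature tolerance)."""
    delta = region_delta_asa(structure, record, residue_indices, n_points=n_points)
    return delta, delta > tolerance


def rasa_summary(structure: Structure, record: ProSRecord,
                 residue_indices: list[int] | None = None,
                 n_points: int = N_SPHERE_POINTS) -> RasaSummary:
    mrasa = region_rasa(structure, record, "monomeric", residue_indices, n_points)
    crasa = region_rasa(structure, record, "complex", residue_indices, n_points)
    delta = region_delta_asa(structure, record, residue_indices, n_points)
    return RasaSummary(mrasa=mrasa, crasa=crasa, delta_asa=delta)
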