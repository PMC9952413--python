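"""DSSP-style secondary-structure assignment and helix/coil fractions.

Backbone hydrogen bonds are detected with the Kabsch–Sander electrostatic
model: the amide H is reconstructed 1.0 A from N, anti-parallel to the
preceding carbonyl C=O bond, and the donor–acceptor energy is

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  [kcal/mol]

with a bond called below -0.5 kcal/mol.  From the bond pattern, n->n+4
turn pairs give alpha-helix (H), n->n+3 gives 3-10 (G), n->n+5 gives pi
(I); bridge patterns give strand (E) or isolated bridge (B); remaining
turn residues are T, everything else C.

For the feature pipeline the eight states collapse to three: helix = {H}
(the features concern alpha-helix specifically), strand = {E, B}, coil =
everything else, so %Helix + %Strand + %Coil = 1 on any region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ProsfoldError
from .structio import Chain, Structure

HB_ENERGY_CUTOFF = -0.5   # kcal/mol
_Q1Q2_F = 0.084 * 332.0   # Kabsch-Sander coupling constant
_BREAK_DISTANCE = 2.5     # C(i-1)-N(i) beyond this is a chain break

HELIX_STATES = frozenset("H")
STRAND_STATES = frozenset("EB")


@dataclass
class SSAssignment:
    chain_id: str
    per_residue: str  # one letter of HGIEBTC per residue of the chain

    def region_fractions(self, indices: list[int]) -> tuple[float, float, float]:
        return region_ss_fractions(self, indices)


def _backbone(chain: Chain):
    n = len(chain.residues)
    coords = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O")}
    for i, res in enumerate(chain.residues):
        for name in ("N", "CA", "C", "O"):
            atom = res.atom(name)
            if atom is not None:
                coords[name][i] = atom.coord
    return coords


def _hbond_matrix(chain: Chain) -> np.ndarray:
    """hb[i, j] True when NH of residue i donates to C=O of residue j."""
    n = len(chain.residues)
    bb = _backbone(chain)
    N, CA, C, O = bb["N"], bb["CA"], bb["C"], bb["O"]

    # reconstructed amide hydrogens; none for prolines or chain starts/breaks
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        if chain.residues[i].code == "P":
            continue
        if np.isnan(N[i]).any() or np.isnan(C[i - 1]).any() or np.isnan(O[i - 1]).any():
            continue
        if np.linalg.norm(N[i] - C[i - 1]) > _BREAK_DISTANCE:
            continue
        co = C[i - 1] - O[i - 1]
        H[i] = N[i] + co / np.linalg.norm(co)

    hb = np.zeros((n, n), dtype=bool)
    valid_acc = ~np.isnan(C).any(axis=1) & ~np.isnan(O).any(axis=1)
    valid_don = ~np.isnan(H).any(axis=1)
    for i in np.flatnonzero(valid_don):
        for j in np.flatnonzero(valid_acc):
            if j in (i, i - 1):  # NH_i is covalently tied to C_{i-1}
                continue
            if np.isnan(CA[i]).any() or np.isnan(CA[j]).any():
                continue
            if np.linalg.norm(CA[i] - CA[j]) > 9.0:
                continue
            r_on = np.linalg.norm(N[i] - O[j])
            r_ch = np.linalg.norm(H[i] - C[j])
            r_oh = np.linalg.norm(H[i] - O[j])
            r_cn = np.linalg.norm(N[i] - C[j])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing geometry; DSSP treats as no bond
            energy = _Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            hb[i, j] = energy < HB_ENERGY_CUTOFF
    return hb


def assign_ss(structure: Structure, chain_id: str) -> SSAssignment:
    """Assign eight-state secondary structure to a full chain."""
    chain = structure.chain(chain_id)
    n = len(chain.residues)
    if n < 4:
        return SSAssignment(chain_id=chain_id, per_residue="C" * n)
    hb = _hbond_matrix(chain)

    # turn(k)[i]: C=O of i accepts from NH of i+k
    turn = {k: np.array([i + k < n and hb[i + k, i] for i in range(n)])
            for k in (3, 4, 5)}

    state = np.full(n, "C", dtype="<U1")

    # bridges: parallel/antiparallel ladder patterns
    bridge = np.zeros(n, dtype=bool)
    partner: dict[int, list[int]] = {}
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])
            anti = (hb[j, i] and hb[i, j]) or (hb[j + 1, i - 1] and hb[i + 1, j - 1])
            if para or anti:
                bridge[i] = bridge[j] = True
                partner.setdefault(i, []).append(j)
                partner.setdefault(j, []).append(i)

    # ladders: a bridge extended by an adjacent bridge becomes strand E
    for i in np.flatnonzero(bridge):
        ext = any(
            (abs(i2 - i) == 1 and any(abs(j2 - j) <= 1 for j in partner[i]))
            for i2 in (i - 1, i + 1) if i2 in partner
            for j2 in partner[i2]
        )
        state[i] = "E" if ext else "B"

    def _mark(kind: str, k: int):
        # two consecutive k-turns make residues i+1 .. i+k a helix of that kind
        for i in range(n - k - 1):
            if turn[k][i] and turn[k][i + 1]:
                for r in range(i + 1, i + k + 1):
                    if state[r] == "C" or (kind == "H" and state[r] in "GT"):
                        state[r] = kind

    _mark("H", 4)
    _mark("G", 3)
    _mark("I", 5)

    # remaining residues inside any single turn get T
    for k in (3, 4, 5):
        for i in np.flatnonzero(turn[k]):
            for r in range(i + 1, min(i + k, n)):
                if state[r] == "C":
                    state[r] = "T"

    return SSAssignment(chain_id=chain_id, per_residue="".join(state))


def region_ss_fractions(assignment: SSAssignment,
                        indices: list[int]) -> tuple[float, float, float]:
    """(frac_helix, frac_strand, frac_coil) over the given residue indices."""
    if not indices:
        raise ProsfoldError("empty region for secondary-structure fractions")
    states = [assignment.per_residue[i] for i in indices]
    n = len(states)
    helix = sum(s in HELIX_STATES for s in states) / n
    strand = sum(s in STRAND_STATES for s in states) / n
    return helix, strand, 1.0 - helix - strand
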