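"""Synthetic structure pairs and feature tables with known ground truth.

Structure pairs emulate the archetypes seen among conditionally folding
segments: a long alpha-helix, a short helix with terminal loops, a
helix-hairpin "domain-like" shape, and an extended coil.  An ideal
backbone (N, CA, C, O) is built from internal coordinates; the
"experimental" copy adds per-residue Gaussian coordinate noise and gets a
partner chain (in contact, so the ΔASA filter passes, or far away, so it
does not); the "model" copy stays ideal and carries a planted per-residue
confidence (pLDDT) in its B-factors.

Feature tables plant a linear RMSD model on block-correlated features so
the selection/regression/clustering/grouping machinery can be tested
against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError, ProsfoldError
from .structio import (
    Atom, Chain, ProSRecord, Residue, Structure, write_pdb_file,
    write_segment_table,
)

ARCHETYPES = ("long_helix", "short_helix_loops", "domain_like", "extended_coil")

# ideal peptide internal coordinates (A, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_HELIX_PHI, _HELIX_PSI = -57.0, -47.0

# proline lacks the amide H used for helix hydrogen bonds, so generated
# sequences avoid it; composition tests use explicit sequences instead
_SEQ_ALPHABET = "ACDEFGHIKLMNQRSTVWY"


@dataclass
class SynthSpec:
    archetype: str
    length: int
    noise_sigma: float = 0.0
    plddt_mean: float = 80.0
    seed: int = 0
    partner_contact: bool = True

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.length < 5:
            raise ValueError("length must be >= 5")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


# ---------------------------------------------------------------------------
# internal-coordinate backbone builder

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d given bond |cd|, angle b-c-d and torsion a-b-c-d."""
    ang, tor = np.deg2rad(angle), np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(tor),
                        bond * np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phis: np.ndarray, psis: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Backbone coordinates (N, CA, C, O per residue) from phi/psi lists.

    phi of the first residue and psi of the last only orient terminal
    atoms; omega is ideal trans (180 deg) throughout.
    """
    n_res = len(phis)
    if len(psis) != n_res:
        raise ValueError("phi and psi lists differ in length")
    res: list[dict[str, np.ndarray]] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    C = CA + _B_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    res.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n_res):
        prev = res[i - 1]
        Ni = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psis[i - 1])
        CAi = _place(prev["CA"], prev["C"], Ni, _B_N_CA, _A_C_N_CA, 180.0)
        Ci = _place(prev["C"], Ni, CAi, _B_CA_C, _A_N_CA_C, phis[i])
        res.append({"N": Ni, "CA": CAi, "C": Ci})
    for i in range(n_res):
        psi = psis[i] if i < n_res - 1 else -40.0
        res[i]["O"] = _place(res[i]["N"], res[i]["CA"], res[i]["C"],
                             _B_C_O, _A_CA_C_O, psi - 180.0)
    return res


def _torsions(archetype: str, length: int, rng: np.random.Generator):
    phis = np.full(length, _HELIX_PHI)
    psis = np.full(length, _HELIX_PSI)
    if archetype == "long_helix":
        return phis, psis
    if archetype == "extended_coil":
        phis = rng.uniform(-150.0, -90.0, length)
        psis = rng.uniform(100.0, 160.0, length)
        return phis, psis
    if archetype == "short_helix_loops":
        loop = max(3, int(round(0.3 * length)))
        phis[:loop] = rng.uniform(-150.0, -90.0, loop)
        psis[:loop] = rng.uniform(100.0, 160.0, loop)
        phis[-loop:] = rng.uniform(-150.0, -90.0, loop)
        psis[-loop:] = rng.uniform(100.0, 160.0, loop)
        return phis, psis
    # domain_like: helix-turn-helix hairpin; the turn torsions are jittered
    # until a clash-free hairpin is found (caller retries)
    turn_len = 4
    h = (length - turn_len) // 2
    t0 = h
    base = np.array([[-60.0, -30.0], [55.0, 45.0], [-90.0, 0.0], [-110.0, 130.0]])
    jitter = rng.normal(0.0, 10.0, (turn_len, 2))
    phis[t0:t0 + turn_len] = base[:, 0] + jitter[:, 0]
    psis[t0:t0 + turn_len] = base[:, 1] + jitter[:, 1]
    return phis, psis


def _has_clash(ca: np.ndarray, cutoff: float = 3.2) -> bool:
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    n = len(ca)
    i, j = np.triu_indices(n, k=3)
    return bool((d[i, j] < cutoff).any())


def _build_chain(archetype: str, length: int, rng: np.random.Generator,
                 max_tries: int = 100) -> list[dict[str, np.ndarray]]:
    for _ in range(max_tries):
        phis, psis = _torsions(archetype, length, rng)
        bb = build_backbone(phis, psis)
        ca = np.array([r["CA"] for r in bb])
        if not _has_clash(ca):
            return bb
    raise GenerationError(
        f"no clash-free {archetype} backbone of length {length} after {max_tries} tries")


def _make_chain(chain_id: str, seq: str, backbone, b_factors=None,
                first_number: int = 1) -> Chain:
    residues = []
    for i, (code, bb) in enumerate(zip(seq, backbone)):
        b = float(b_factors[i]) if b_factors is not None else 20.0
        atoms = [Atom(name=n, element=n[0], coord=np.array(bb[n]), b_factor=b)
                 for n in ("N", "CA", "C", "O")]
        residues.append(Residue(code=code, number=first_number + i, atoms=atoms))
    return Chain(chain_id=chain_id, residues=residues)


def _principal_axis(ca: np.ndarray) -> np.ndarray:
    centred = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    return vt[0]


def _all_coords(chain: Chain) -> np.ndarray:
    return np.array([a.coord for r in chain.residues for a in r.atoms])


def _place_partner(segment: Chain, partner: Chain, rng: np.random.Generator,
                   contact: bool, target_dist: float = 4.0) -> None:
    """Rigidly move the partner chain alongside the segment.

    Contact mode aims for a minimum interchain heavy-atom distance of
    ~4 A (guaranteeing burial, hence ΔASA > 0); far mode parks the
    partner 60 A away so ΔASA ≈ 0.
    """
    seg_ca = np.array([r.ca.coord for r in segment.residues])
    par_xyz = _all_coords(partner)
    par_ca = np.array([r.ca.coord for r in partner.residues])

    axis = _principal_axis(seg_ca)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    side = np.cross(axis, ref)
    side /= np.linalg.norm(side)

    # align partner principal axis with the segment axis
    p_axis = _principal_axis(par_ca)
    v = np.cross(p_axis, axis)
    s, c = np.linalg.norm(v), float(p_axis @ axis)
    if s < 1e-12:
        rot = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    centre = par_xyz.mean(axis=0)

    def move(offset: float):
        target = seg_ca.mean(axis=0) + side * offset
        for res in partner.residues:
            for atom in res.atoms:
                atom.coord = rot @ (atom.coord - centre) + target

    if not contact:
        move(60.0)
        return
    offset = 12.0
    for _ in range(8):
        saved = [(a, a.coord.copy()) for r in partner.residues for a in r.atoms]
        move(offset)
        seg_xyz = _all_coords(segment)
        par_now = _all_coords(partner)
        dmin = float(np.min(np.linalg.norm(
            seg_xyz[:, None, :] - par_now[None, :, :], axis=-1)))
        if abs(dmin - target_dist) < 0.2:
            return
        for atom, coord in saved:
            atom.coord = coord
        offset += target_dist - dmin
    move(offset)


def gen_structure_pair(spec: SynthSpec) -> tuple[Structure, Structure, ProSRecord]:
    """Generate (experimental-like, model-like, record) for one segment.

    The experimental structure holds the noisy segment (chain A) plus a
    partner helix (chain B); the model is the ideal monomeric chain with
    planted pLDDT in its B-factors.  Residues are numbered 1..length in
    both, standing in for UniProt numbering.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    seq = "".join(rng.choice(list(_SEQ_ALPHABET), L))
    backbone = _build_chain(spec.archetype, L, rng)

    plddt = np.clip(spec.plddt_mean + rng.normal(0.0, 3.0, L), 0.0, 100.0)
    model_chain = _make_chain("A", seq, backbone, b_factors=plddt)
    model = Structure(chains=[model_chain], source_id=f"model_{spec.archetype}_{spec.seed}")

    noisy = [{n: bb[n] + offset for n in bb}
             for bb, offset in zip(backbone, rng.normal(0.0, spec.noise_sigma, (L, 3)))]
    exp_chain = _make_chain("A", seq, noisy)

    par_len = max(10, min(20, L))
    par_seq = "".join(rng.choice(list(_SEQ_ALPHABET), par_len))
    partner = _make_chain("B", par_seq, _build_chain("long_helix", par_len, rng))
    _place_partner(exp_chain, partner, rng, contact=spec.partner_contact)
    exp = Structure(chains=[exp_chain, partner],
                    source_id=f"exp_{spec.archetype}_{spec.seed}")

    record = ProSRecord(
        uniprot_ac=f"SYN{spec.seed:05d}",
        ideal_id=f"IIDSYN{spec.seed:05d}",
        region=(1, L),
        reliability="verified",
        exp_source=exp.source_id,
        exp_chain="A",
        partner_chain_ids=["B"],
        model_source=model.source_id,
    )
    return exp, model, record


# ---------------------------------------------------------------------------
# study generator: the two-condition synthetic cohort

def gen_study(n_helix: int = 20, n_coil: int = 20,
              helix_length: int = 33, coil_length: int = 20,
              sigma_low: float = 0.5, sigma_high: float = 4.0,
              plddt_high: float = 85.0, plddt_low: float = 55.0,
              seed: int = 0):
    """Cohort of segment pairs under the study's two conditions.

    Low-noise long helices with high planted confidence emulate segments
    a predictor gets right (expected RMSD ≈ sigma_low*sqrt(3) < 1.76 A);
    high-noise extended coils with low confidence emulate segments it
    gets wrong (expected RMSD ≈ sigma_high*sqrt(3) > 4.13 A).

    Returns a list of (exp, model, record, truth) where truth holds the
    archetype and planted noise level.
    """
    out = []
    for k in range(n_helix + n_coil):
        is_helix = k < n_helix
        spec = SynthSpec(
            archetype="long_helix" if is_helix else "extended_coil",
            length=helix_length if is_helix else coil_length,
            noise_sigma=sigma_low if is_helix else sigma_high,
            plddt_mean=plddt_high if is_helix else plddt_low,
            seed=seed * 10000 + k,
        )
        exp, model, record = gen_structure_pair(spec)
        out.append((exp, model, record,
                    {"archetype": spec.archetype, "noise_sigma": spec.noise_sigma,
                     "expected_class": "excellent" if is_helix else "poor"}))
    return out


def write_study(outdir: str | Path, pairs=None, **kwargs) -> Path:
    """Write a generated cohort as PDB files + segment TSV + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if pairs is None:
        pairs = gen_study(**kwargs)
    records, truth = [], {}
    for exp, model, record, info in pairs:
        exp_path = outdir / f"{exp.source_id}.pdb"
        model_path = outdir / f"{model.source_id}.pdb"
        write_pdb_file(exp, exp_path)
        write_pdb_file(model, model_path)
        record.exp_source = str(exp_path)
        record.model_source = str(model_path)
        records.append(record)
        truth[record.pros_id] = info
    table = outdir / "segments.tsv"
    write_segment_table(records, table)
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return table


# ---------------------------------------------------------------------------
# feature-table generators

def _block_cov(names: list[str], blocks: list[list[str]], within_r: float) -> np.ndarray:
    cov = np.eye(len(names))
    pos = {n: i for i, n in enumerate(names)}
    for block in blocks:
        for a in block:
            for b in block:
                if a != b:
                    cov[pos[a], pos[b]] = within_r
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ProsfoldError("requested correlation matrix is not positive definite") from exc
    return cov


def gen_feature_table(n_pros: int, coefs: dict[str, float],
                      blocks: list[list[str]] | None = None,
                      within_r: float = 0.8, intercept: float = 2.5,
                      noise_sd: float = 1.0, seed: int = 0):
    """Feature table with a planted linear RMSD model.

    Features are multivariate normal with block-diagonal correlation
    (``blocks`` lists the feature names of each correlated block);
    rmsd = intercept + X @ coefs + N(0, noise_sd).  Returns (DataFrame
    with an ``rmsd`` column, truth dict).
    """
    names = list(coefs)
    if n_pros <= 2 * len(names) + 2:
        raise ProsfoldError(f"n_pros={n_pros} too small for {len(names)} features")
    blocks = blocks or []
    cov = _block_cov(names, blocks, within_r)
    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal(np.zeros(len(names)), cov, size=n_pros,
                                method="cholesky")
    beta = np.array([coefs[n] for n in names])
    y = intercept + x @ beta + rng.normal(0.0, noise_sd, n_pros)
    df = pd.DataFrame(x, columns=names)
    df.insert(0, "pros_id", [f"synth_{i:04d}" for i in range(n_pros)])
    df["rmsd"] = y
    truth = {"coefs": dict(coefs), "intercept": intercept, "noise_sd": noise_sd,
             "blocks": blocks, "within_r": within_r, "seed": seed}
    return df, truth


def gen_grouped_feature_table(n_pros: int, block1: list[str], block2: list[str],
                              coef: float = 1.0, intercept: float = 3.0,
                              inactive_sd: float = 0.02, seed: int = 0):
    """Cohort where each item's RMSD is driven by exactly one feature block.

    Half the items have active block-1 features (unit variance) and
    near-constant block-2 features, and vice versa; rmsd depends only on
    the active block.  ``inactive_sd`` is kept well below the active
    variance so the planted "depends only on one block" condition is
    unambiguous.  Ground-truth group labels (1/2) come back in the truth
    dict for testing the ablated-prediction group assignment.
    """
    names = block1 + block2
    rng = np.random.default_rng(seed)
    half = n_pros // 2
    groups = np.array([1] * half + [2] * (n_pros - half))
    x = np.empty((n_pros, len(names)))
    for i, g in enumerate(groups):
        active = slice(0, len(block1)) if g == 1 else slice(len(block1), len(names))
        row = rng.normal(0.0, inactive_sd, len(names))
        row[active] = rng.normal(0.0, 1.0, active.stop - active.start)
        x[i] = row
    y = intercept + coef * x.sum(axis=1) + rng.normal(0.0, 0.1, n_pros)
    df = pd.DataFrame(x, columns=names)
    df.insert(0, "pros_id", [f"grp_{i:04d}" for i in range(n_pros)])
    df["rmsd"] = y
    truth = {"groups": groups.tolist(), "block1": block1, "block2": block2}
    return df, truth
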