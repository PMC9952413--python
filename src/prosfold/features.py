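"""Per-segment feature vectors for the statistical pipeline.

All structural features (nRG, %Helix, %Strand, %Coil, mrASA, crASA and
the composition battery) are computed from the EXPERIMENTAL structure's
region; the confidence (pLDDT) comes from the model; the RMSD links the
two.  The composition is taken from the model (UniProt) sequence of the
region, which is complete, rather than from the possibly-gapped
experimental chain — composition is a sequence property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._aa import HYDROPHOBIC_AA, POLAR_AA, STANDARD_AA
from .errors import FeatureError, ProsfoldError
from . import geometry, secstruct, structio, surface
from .structio import ProSRecord, Structure

# fixed column order of the features TSV
FEATURE_COLUMNS = (
    ["pros_id", "rmsd", "length", "plddt", "mrasa", "crasa", "nrg",
     "frac_helix", "frac_strand", "frac_coil", "frac_polar", "frac_hydrophobic"]
    + [f"frac_{aa}" for aa in STANDARD_AA]
)

# the eleven features the class analysis selects from this battery
SELECTED_FEATURE_SET = ["plddt", "mrasa", "crasa", "nrg", "frac_helix",
                        "frac_coil", "frac_polar", "frac_hydrophobic",
                        "frac_A", "frac_L", "frac_S"]


@dataclass
class FeatureVector:
    pros_id: str
    rmsd: float
    length: int
    plddt: float
    mrasa: float
    crasa: float
    nrg: float
    frac_helix: float
    frac_strand: float
    frac_coil: float
    frac_polar: float
    frac_hydrophobic: float
    aa_frac: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, float]:
        d = {c: getattr(self, c) for c in FEATURE_COLUMNS if not c.startswith("frac_")
             or c in ("frac_helix", "frac_strand", "frac_coil",
                      "frac_polar", "frac_hydrophobic")}
        for aa in STANDARD_AA:
            d[f"frac_{aa}"] = self.aa_frac.get(aa, 0.0)
        return d


def composition(seq: str) -> tuple[dict[str, float], float, float]:
    """Amino-acid fractions plus the polar and hydrophobic group sums.

    'X' residues are excluded from the denominator; an all-X sequence is
    an error.
    """
    if not seq:
        raise ProsfoldError("empty sequence")
    counted = [c for c in seq if c in STANDARD_AA]
    if not counted:
        raise ProsfoldError("sequence has no standard residues")
    n = len(counted)
    aa_frac = {aa: counted.count(aa) / n for aa in STANDARD_AA}
    polar = sum(aa_frac[aa] for aa in POLAR_AA)
    hydrophobic = sum(aa_frac[aa] for aa in HYDROPHOBIC_AA)
    return aa_frac, polar, hydrophobic


def build_feature_vector(record: ProSRecord, exp: Structure, model: Structure,
                         sasa_points: int = surface.N_SPHERE_POINTS) -> FeatureVector:
    """Assemble the full feature vector for one segment.

    Errors in any component are re-raised labeled with the failing
    feature name.
    """
    mapping = structio.map_segment(record, exp, model)
    exp_idx = [ei for _, ei in mapping.pairs]
    model_chain = model.chains[0]
    exp_chain = exp.chain(record.exp_chain)

    def compute(name, fn):
        try:
            return fn()
        except ProsfoldError as exc:
            raise FeatureError(name, str(exc)) from exc

    rmsd = compute("rmsd", lambda: geometry.segment_rmsd(exp, model, mapping))
    plddt = compute("plddt", lambda: structio.model_plddt(model, record.region))
    nrg = compute("nrg", lambda: geometry.normalized_rg(exp_chain.ca_coords(exp_idx)))
    mrasa = compute("mrasa", lambda: surface.region_rasa(
        exp, record, "monomeric", exp_idx, n_points=sasa_points))
    crasa = compute("crasa", lambda: surface.region_rasa(
        exp, record, "complex", exp_idx, n_points=sasa_points))

    def ss_fractions():
        assignment = secstruct.assign_ss(exp, record.exp_chain)
        return secstruct.region_ss_fractions(assignment, exp_idx)

    frac_helix, frac_strand, frac_coil = compute("frac_helix", ss_fractions)

    start, end = record.region
    model_idx = model_chain.residues_in_range(start, end)
    seq = "".join(model_chain.residues[i].code for i in model_idx)
    aa_frac, polar, hydrophobic = compute("composition", lambda: composition(seq))

    return FeatureVector(
        pros_id=record.pros_id, rmsd=rmsd, length=record.length, plddt=plddt,
        mrasa=mrasa, crasa=crasa, nrg=nrg, frac_helix=frac_helix,
        frac_strand=frac_strand, frac_coil=frac_coil, frac_polar=polar,
        frac_hydrophobic=hydrophobic, aa_frac=aa_frac,
    )


def features_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into the canonical table (fixed column order)."""
    df = pd.DataFrame([v.to_dict() for v in vectors])
    return df.reindex(columns=FEATURE_COLUMNS)


def write_features_tsv(vectors: list[FeatureVector], path) -> None:
    features_table(vectors).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_features_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    missing = {"pros_id", "rmsd"} - set(df.columns)
    if missing:
        raise ProsfoldError(f"{path}: features table missing columns {sorted(missing)}")
    return df
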