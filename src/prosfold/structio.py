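"""Structure I/O and segment mapping.

Reads experimental structures (PDB/mmCIF) and predicted monomeric models
(PDB with per-residue confidence, pLDDT, in the B-factor column), and maps
a UniProt-numbered segment onto each chain.

Model residue numbering is trusted as UniProt numbering (the AlphaFold DB
convention).  Experimental author numbering is never trusted: the
correspondence between model and experimental residues is always
established by global sequence alignment (`map_segment`), because author
numbering frequently disagrees with UniProt.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import gemmi
import numpy as np
from Bio import Align

from ._aa import ONE_TO_THREE, THREE_TO_ONE
from .errors import (
    EmptyStructureError,
    MappingError,
    ParseError,
    RangeError,
)

Reliability = Literal["verified", "possible", "predicted"]
_RELIABILITIES = ("verified", "possible", "predicted")


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) in Angstrom
    b_factor: float = 0.0
    occupancy: float = 1.0


@dataclass
class Residue:
    """One polymer residue: one-letter code, author number, insertion code."""

    code: str  # one-letter, 'X' for unmapped nonstandard residues
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    name3: str = ""  # original three-letter name, kept for geometry output

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.code for r in self.residues)

    def ca_coords(self, indices: Iterable[int] | None = None) -> np.ndarray:
        idx = range(len(self.residues)) if indices is None else indices
        return np.array([self.residues[i].ca.coord for i in idx], dtype=float)

    def residues_in_range(self, start: int, end: int) -> list[int]:
        """Indices of residues whose author number lies in [start, end]."""
        return [i for i, r in enumerate(self.residues) if start <= r.number <= end]


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    source_id: str = ""

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.source_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]


@dataclass
class ProSRecord:
    """One conditionally folding segment (Protean Segment).

    ``region`` is 1-based and inclusive on both ends in UniProt numbering,
    so residues 139-171 span 33 residues.
    """

    uniprot_ac: str
    ideal_id: str
    region: tuple[int, int]
    reliability: Reliability
    exp_source: str
    exp_chain: str
    partner_chain_ids: list[str]
    model_source: str

    def __post_init__(self):
        start, end = self.region
        if start > end:
            raise ValueError(f"region start {start} > end {end}")
        if self.reliability not in _RELIABILITIES:
            raise ValueError(f"unknown reliability {self.reliability!r}")

    @property
    def length(self) -> int:
        return self.region[1] - self.region[0] + 1

    @property
    def pros_id(self) -> str:
        return f"{self.uniprot_ac}_{self.region[0]}-{self.region[1]}"


@dataclass
class SegmentMapping:
    """Residue correspondence for a segment present in both structures.

    ``pairs`` holds (model_residue_index, experimental_residue_index) into
    the respective chain residue lists, restricted to region residues with
    a Calpha on both sides; both coordinates are strictly increasing.
    """

    pairs: list[tuple[int, int]]
    coverage: float
    model_chain_id: str
    exp_chain_id: str

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# reading

def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve altlocs: keep the highest-occupancy copy of each atom name,
    ties broken by altloc identifier order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ + 1e-9:
            best[atom.name] = atom
    # preserve file order of first appearance
    seen, out = set(), []
    for atom in res:
        if atom.name not in seen:
            seen.add(atom.name)
            out.append(best[atom.name])
    return out


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Polymer (amino-acid) chains only; waters, ligands and hydrogens are
    dropped; altlocs resolved to highest occupancy; first model only for
    multi-model (NMR) files.
    """
    path = Path(path)
    fmt = {"pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no model in file")
    st.remove_hydrogens()

    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            info = gemmi.find_tabulated_residue(gres.name)
            is_aa = (info is not None and info.is_amino_acid()) or gres.name in THREE_TO_ONE
            if not is_aa:
                continue
            atoms = []
            for gatom in _pick_altlocs(gres):
                if gatom.element.name in ("H", "D"):
                    continue
                atoms.append(Atom(
                    name=gatom.name,
                    element=gatom.element.name.upper(),
                    coord=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    b_factor=gatom.b_iso,
                    occupancy=gatom.occ,
                ))
            if not atoms:
                continue
            residues.append(Residue(
                code=THREE_TO_ONE.get(gres.name, "X"),
                number=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                atoms=atoms,
                name3=gres.name,
            ))
        if any(r.ca is not None for r in residues):
            residues = [r for r in residues if r.ca is not None]
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    if not chains:
        raise EmptyStructureError(f"{path}: no polymer chain with Calpha atoms")
    return Structure(chains=chains, source_id=path.stem)


# ---------------------------------------------------------------------------
# writing

def write_pdb(structure: Structure) -> str:
    """Serialize to PDB text (ATOM records, one TER per chain)."""
    buf = io.StringIO()
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            name3 = res.name3 or ONE_TO_THREE.get(res.code, "UNK")
            for atom in res.atoms:
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                buf.write(
                    f"ATOM  {serial:5d} {name:<4s} {name3:>3s} "
                    f"{chain.chain_id:1s}{res.number:4d}{res.icode or ' ':1s}   "
                    f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
                serial += 1
        buf.write(f"TER   {serial:5d}\n")
        serial += 1
    buf.write("END\n")
    return buf.getvalue()


def write_pdb_file(structure: Structure, path: str | Path) -> None:
    Path(path).write_text(write_pdb(structure))


# ---------------------------------------------------------------------------
# model confidence

def model_plddt(model: Structure, region: tuple[int, int], chain_id: str | None = None) -> float:
    """Mean per-residue confidence (pLDDT, 0-100) over a UniProt region.

    The confidence is read from the B-factor of each residue's Calpha, one
    value per residue, as stored in AlphaFold DB model files.
    """
    chain = model.chain(chain_id) if chain_id else model.chains[0]
    start, end = region
    idx = chain.residues_in_range(start, end)
    found = {chain.residues[i].number for i in idx}
    missing = set(range(start, end + 1)) - found
    if missing:
        raise RangeError(
            f"region {start}-{end} not fully present in model "
            f"{model.source_id!r} ({len(missing)} residues missing)")
    return float(np.mean([chain.residues[i].ca.b_factor for i in idx]))


# ---------------------------------------------------------------------------
# segment mapping

def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    return aligner


def _aligned_columns(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    aln = _aligner().align(seq_a, seq_b)[0]
    cols: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        cols.extend(zip(range(a0, a1), range(b0, b1)))
    return cols


def map_segment(record: ProSRecord, exp: Structure, model: Structure,
                min_identity: float = 0.9) -> SegmentMapping:
    """Map the record's region between the model chain (UniProt numbering)
    and the experimental chain, by global sequence alignment.

    Only region residues with a Calpha on both sides enter the mapping;
    coverage is the mapped fraction of the region.  An alignment identity
    below ``min_identity`` over the region raises :class:`MappingError`
    (the experimental chain is probably the wrong one).
    """
    model_chain = model.chains[0]
    exp_chain = exp.chain(record.exp_chain)
    cols = _aligned_columns(model_chain.sequence, exp_chain.sequence)

    start, end = record.region
    region_cols = [(mi, ei) for mi, ei in cols
                   if start <= model_chain.residues[mi].number <= end]
    if not region_cols:
        raise MappingError(
            f"{record.pros_id}: no aligned residues in region on chain "
            f"{record.exp_chain} of {exp.source_id}")
    matches = sum(model_chain.residues[mi].code == exp_chain.residues[ei].code
                  for mi, ei in region_cols)
    identity = matches / len(region_cols)
    if identity < min_identity:
        raise MappingError(
            f"{record.pros_id}: region identity {identity:.2f} < {min_identity} "
            f"against chain {record.exp_chain} of {exp.source_id}")

    pairs = [(mi, ei) for mi, ei in region_cols
             if model_chain.residues[mi].ca is not None
             and exp_chain.residues[ei].ca is not None]
    if not pairs:
        raise MappingError(f"{record.pros_id}: no mapped residue has Calpha on both sides")
    return SegmentMapping(
        pairs=pairs,
        coverage=len(pairs) / record.length,
        model_chain_id=model_chain.chain_id,
        exp_chain_id=exp_chain.chain_id,
    )


# ---------------------------------------------------------------------------
# segment tables

SEGMENT_TABLE_COLUMNS = [
    "uniprot_ac", "ideal_id", "start", "end", "reliability",
    "exp_file", "exp_chain", "partner_chains", "model_file",
]


def read_segment_table(path: str | Path) -> list[ProSRecord]:
    """Read the TSV segment table (header row, columns as documented)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(SEGMENT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: segment table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        partners = [p for p in str(row.partner_chains).split(",") if p]
        records.append(ProSRecord(
            uniprot_ac=row.uniprot_ac,
            ideal_id=row.ideal_id,
            region=(int(row.start), int(row.end)),
            reliability=row.reliability,
            exp_source=row.exp_file,
            exp_chain=row.exp_chain,
            partner_chain_ids=partners,
            model_source=row.model_file,
        ))
    return records


def write_segment_table(records: list[ProSRecord], path: str | Path) -> None:
    import pandas as pd

    rows = [{
        "uniprot_ac": r.uniprot_ac, "ideal_id": r.ideal_id,
        "start": r.region[0], "end": r.region[1],
        "reliability": r.reliability, "exp_file": r.exp_source,
        "exp_chain": r.exp_chain,
        "partner_chains": ",".join(r.partner_chain_ids),
        "model_file": r.model_source,
    } for r in records]
    pd.DataFrame(rows, columns=SEGMENT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
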