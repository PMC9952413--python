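"""Dataset construction filters for segment tables.

Starting from an annotated table of conditionally folding segments, the
cohort is built by (1) dropping segments whose disorder/order evidence is
merely predicted, (2) dropping segments of at most 10 residues,
(3) keeping only the longest of a set of overlapping segments within one
protein, (4) dropping segments whose complex structure shows no actual
contact (ΔASA = 0), and finally (5) reducing redundancy by clustering
full-length protein sequences at 30% identity / 90% coverage and keeping
the protein with the longest segment from each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from Bio import Align

from .errors import ProsfoldError
from .structio import ProSRecord, Structure
from . import surface


@dataclass
class DatasetReport:
    input_count: int
    removed_predicted: int = 0
    removed_short: int = 0
    removed_overlap: int = 0
    removed_no_interaction: int = 0
    removed_redundant: int = 0
    final_records: list[ProSRecord] = field(default_factory=list)

    def check(self) -> None:
        total = (len(self.final_records) + self.removed_predicted
                 + self.removed_short + self.removed_overlap
                 + self.removed_no_interaction + self.removed_redundant)
        assert total == self.input_count, "removal counts do not add up"

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "removed_predicted": self.removed_predicted,
            "removed_short": self.removed_short,
            "removed_overlap": self.removed_overlap,
            "removed_no_interaction": self.removed_no_interaction,
            "removed_redundant": self.removed_redundant,
            "final_count": len(self.final_records),
            "final_ids": sorted(r.pros_id for r in self.final_records),
        }


MIN_LENGTH = 11  # segments of at most 10 residues are discarded


def _overlaps(a: ProSRecord, b: ProSRecord) -> bool:
    return a.region[0] <= b.region[1] and b.region[0] <= a.region[1]


def filter_segments(records: list[ProSRecord],
                    load_structure: Callable[[str], Structure] | None = None,
                    sasa_points: int = surface.N_SPHERE_POINTS) -> DatasetReport:
    """Apply the reliability, length, overlap and interaction filters.

    ``load_structure`` resolves a record's ``exp_source`` to a parsed
    structure for the ΔASA interaction check; when omitted, that step is
    skipped (e.g. when structures are checked elsewhere).  The result is
    independent of the input order.
    """
    report = DatasetReport(input_count=len(records))

    kept = []
    for r in records:
        if r.reliability == "predicted":
            report.removed_predicted += 1
        elif r.length < MIN_LENGTH:
            report.removed_short += 1
        else:
            kept.append(r)

    # within one protein, keep the longest of each overlapping set
    # (single-linkage overlap groups; ties -> smallest start)
    survivors: list[ProSRecord] = []
    by_protein: dict[str, list[ProSRecord]] = {}
    for r in kept:
        by_protein.setdefault(r.uniprot_ac, []).append(r)
    for group in by_protein.values():
        group = sorted(group, key=lambda r: r.region)
        clusters: list[list[ProSRecord]] = []
        for r in group:
            merged = None
            for cl in clusters:
                if any(_overlaps(r, o) for o in cl):
                    if merged is None:
                        cl.append(r)
                        merged = cl
                    else:  # r bridges two clusters -> merge them
                        merged.extend(cl)
                        cl.clear()
            if merged is None:
                clusters.append([r])
        for cl in clusters:
            if not cl:
                continue
            best = max(cl, key=lambda r: (r.length, -r.region[0]))
            survivors.append(best)
            report.removed_overlap += len(cl) - 1

    if load_structure is not None:
        checked = []
        for r in survivors:
            structure = load_structure(r.exp_source)
            _, keep = surface.interaction_filter(structure, r, n_points=sasa_points)
            if keep:
                checked.append(r)
            else:
                report.removed_no_interaction += 1
        survivors = checked

    report.final_records = sorted(survivors, key=lambda r: (r.uniprot_ac, r.region))
    report.check()
    return report


# ---------------------------------------------------------------------------
# redundancy reduction (BlastClust-style greedy single linkage)

def _identity_coverage(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Global-alignment identity over aligned columns and coverage of the
    shorter sequence."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    matched = identical = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for ai, bi in zip(range(a0, a1), range(b0, b1)):
            matched += 1
            identical += seq_a[ai] == seq_b[bi]
    if matched == 0:
        return 0.0, 0.0
    return identical / matched, matched / min(len(seq_a), len(seq_b))


def cluster_redundant(records: list[ProSRecord], sequences: dict[str, str],
                      min_identity: float = 0.30, min_coverage: float = 0.90,
                      ) -> tuple[list[list[str]], list[ProSRecord]]:
    """Single-linkage clustering of proteins; one representative per cluster.

    Two proteins are linked when their global pairwise identity is at
    least ``min_identity`` over an alignment covering at least
    ``min_coverage`` of the shorter sequence.  The representative of each
    cluster is the protein holding the longest segment (ties broken by
    lexicographic accession), and all that protein's records are kept.

    Returns (clusters as sorted accession lists, representative records).
    """
    accs = sorted({r.uniprot_ac for r in records})
    for acc in accs:
        if acc not in sequences:
            raise ProsfoldError(f"no full-length sequence for accession {acc}")

    parent = {a: a for a in accs}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(accs):
        for b in accs[i + 1:]:
            ident, cov = _identity_coverage(sequences[a], sequences[b])
            if ident >= min_identity and cov >= min_coverage:
                parent[find(a)] = find(b)

    clusters: dict[str, list[str]] = {}
    for a in accs:
        clusters.setdefault(find(a), []).append(a)

    by_protein: dict[str, list[ProSRecord]] = {}
    for r in records:
        by_protein.setdefault(r.uniprot_ac, []).append(r)

    reps: list[ProSRecord] = []
    cluster_lists = []
    for members in clusters.values():
        members = sorted(members)
        cluster_lists.append(members)
        best = min(members,
                   key=lambda acc: (-max(r.length for r in by_protein[acc]), acc))
        reps.extend(by_protein[best])
    reps.sort(key=lambda r: (r.uniprot_ac, r.region))
    return sorted(cluster_lists), reps
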