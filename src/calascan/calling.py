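"""Substitution calling and library QC statistics.

Each sequenced clone CDS is compared against the reference: equal-length
sequences take a fast codon-wise path; length mismatches are globally aligned
and any gap marks the clone as a frameshift (no substitution calls).  DNA
mutation counts are nucleotide-level and include synonymous changes, so
library QC is comparable with Sanger-based mutation-rate tables; amino-acid
substitution lists exclude synonymous changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .reference import ReferenceGene, round_half_up

__all__ = [
    "SubstitutionCall",
    "VariantRecord",
    "LibraryQC",
    "call_substitutions",
    "call_fasta",
    "library_qc",
    "substitution_table",
    "qc_table",
]

# Alignment parameters for the length-mismatch path (leftmost gap placement).
_ALIGNER = PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 1
_ALIGNER.mismatch_score = -1
_ALIGNER.open_gap_score = -5
_ALIGNER.extend_gap_score = -0.5


@dataclass(frozen=True)
class SubstitutionCall:
    """One amino-acid substitution in protein coordinates (e.g. Gly237Asp)."""

    residue_position: int
    wt_aa: str
    mut_aa: str
    wt_codon: str
    mut_codon: str
    part_id: str

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.residue_position}{self.mut_aa}"


@dataclass
class VariantRecord:
    clone_id: str
    library_id: str
    dna: str
    dna_mutation_count: int = 0
    substitutions: list[SubstitutionCall] = field(default_factory=list)
    qc_status: str = "ok"   # ok | frameshift | truncated | low_quality


@dataclass
class LibraryQC:
    """Library-level mutation-rate summary (the quality-table row).

    ``mutations_per_kb`` is the primary estimator, normalized by total bp
    sequenced; ``mutations_per_kb_region`` normalizes by the designed mutated
    region instead (the two coincide when sequencing covers exactly the
    mutated segment).  ``mutations_per_gene`` is the expected substitutions
    per reassembled gene, reported to one decimal.
    """

    library_id: str
    clones_sequenced: int
    clones_passing: int
    total_bp_sequenced: int
    total_mutations: int
    mutations_per_kb: float
    mutations_per_kb_region: float
    mutations_per_gene: float
    per_part_counts: dict[str, int]


def call_substitutions(variant_dna: str, gene: ReferenceGene,
                       clone_id: str = "", library_id: str = "") -> VariantRecord:
    """Call amino-acid substitutions of one clone CDS against the reference.

    Raises ``ValueError`` on non-ACGT characters.  A premature stop codon
    yields ``qc_status='truncated'``; any alignment gap (length mismatch)
    yields ``'frameshift'``; both carry no substitution calls.
    """
    dna = variant_dna.upper()
    if set(dna) - set("ACGT"):
        bad = sorted(set(dna) - set("ACGT"))
        raise ValueError(f"clone {clone_id or '?'}: non-nucleotide characters {bad}")
    ref = gene.cds
    rec = VariantRecord(clone_id=clone_id, library_id=library_id, dna=dna)

    if len(dna) != len(ref):
        # unequal lengths force >= 1 gap in the global alignment; classify as
        # frameshift and keep the aligned block count for diagnostics
        aln = _ALIGNER.align(ref, dna)[0]
        assert len(aln.aligned[0]) >= 1
        rec.qc_status = "frameshift"
        return rec

    n_dna = sum(1 for a, b in zip(ref, dna) if a != b)
    rec.dna_mutation_count = n_dna
    calls: list[SubstitutionCall] = []
    for i in range(gene.n_residues):
        wt_codon = ref[3 * i: 3 * i + 3]
        mut_codon = dna[3 * i: 3 * i + 3]
        if wt_codon == mut_codon:
            continue
        wt_aa = str(Seq(wt_codon).translate())
        mut_aa = str(Seq(mut_codon).translate())
        if mut_aa == "*":
            rec.qc_status = "truncated"
            rec.substitutions = []
            return rec
        if mut_aa == wt_aa:
            continue  # synonymous: counted at DNA level only
        residue = i + 1 + gene.numbering_offset
        calls.append(SubstitutionCall(
            residue_position=residue, wt_aa=wt_aa, mut_aa=mut_aa,
            wt_codon=wt_codon, mut_codon=mut_codon,
            part_id=gene.part_of(residue),
        ))
    rec.substitutions = calls
    return rec


def call_fasta(fasta_path: str | Path, gene: ReferenceGene,
               library_id: str = "") -> list[VariantRecord]:
    """Call substitutions for every record of a multi-FASTA of clone CDSs."""
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        records.append(call_substitutions(str(rec.seq), gene,
                                          clone_id=rec.id, library_id=library_id))
    return records


def library_qc(records: list[VariantRecord], gene: ReferenceGene,
               mutated_region_bp: int, library_id: str | None = None,
               bp_sequenced_per_clone: int | None = None,
               include_failed: bool = False) -> LibraryQC:
    """Compute the library mutation-rate summary from called variant records.

    Frameshift/low-quality clones (unusable alignments) are excluded from both
    numerator and denominator unless ``include_failed``.  Truncated clones
    (premature stop) are kept: a nonsense change is still a nucleotide
    substitution, and dropping its carriers — which hold more mutations than
    average — would bias the rate estimate downward.
    ``bp_sequenced_per_clone`` defaults to the mutated region length
    (sequencing targeted the mutagenized segment); pass the full CDS length if
    whole genes were sequenced.
    """
    if not records:
        raise ValueError("library_qc requires at least one variant record")
    if library_id is None:
        library_id = records[0].library_id
    usable = records if include_failed else \
        [r for r in records if r.qc_status in ("ok", "truncated")]
    if not usable:
        raise ValueError(f"no usable records in library {library_id}")
    per_clone_bp = bp_sequenced_per_clone or mutated_region_bp
    total_bp = per_clone_bp * len(usable)
    total_mut = sum(r.dna_mutation_count for r in usable)
    per_kb = 1000.0 * total_mut / total_bp
    per_kb_region = 1000.0 * total_mut / (mutated_region_bp * len(usable))
    per_gene = round_half_up(per_kb_region * mutated_region_bp / 1000.0, 1)

    part_counts: dict[str, int] = {p.part_id: 0 for p in gene.parts}
    for rec in usable:
        for call in rec.substitutions:
            part_counts[call.part_id] += 1

    return LibraryQC(
        library_id=library_id,
        clones_sequenced=len(records),
        clones_passing=len(usable),
        total_bp_sequenced=total_bp,
        total_mutations=total_mut,
        mutations_per_kb=per_kb,
        mutations_per_kb_region=per_kb_region,
        mutations_per_gene=per_gene,
        per_part_counts=part_counts,
    )


def substitution_table(records: list[VariantRecord]) -> pd.DataFrame:
    """Tabulate substitution calls (clone_id, position, wt, mut, part, qc)."""
    rows = []
    for rec in records:
        if not rec.substitutions:
            rows.append({"clone_id": rec.clone_id, "library_id": rec.library_id,
                         "position": pd.NA, "wt_aa": pd.NA, "mut_aa": pd.NA,
                         "part_id": pd.NA, "qc_status": rec.qc_status})
        for call in rec.substitutions:
            rows.append({"clone_id": rec.clone_id, "library_id": rec.library_id,
                         "position": call.residue_position, "wt_aa": call.wt_aa,
                         "mut_aa": call.mut_aa, "part_id": call.part_id,
                         "qc_status": rec.qc_status})
    return pd.DataFrame(rows)


def qc_table(qcs: list[LibraryQC]) -> pd.DataFrame:
    rows = []
    for qc in qcs:
        rows.append({
            "library_id": qc.library_id,
            "clones_sequenced": qc.clones_sequenced,
            "clones_passing": qc.clones_passing,
            "total_bp_sequenced": qc.total_bp_sequenced,
            "total_mutations": qc.total_mutations,
            "mutations_per_kb": round(qc.mutations_per_kb, 2),
            "mutations_per_gene": qc.mutations_per_gene,
        })
    return pd.DataFrame(rows)
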