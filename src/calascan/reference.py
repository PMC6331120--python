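"""Reference gene model for part-wise mutagenesis campaigns.

A coding sequence is decomposed into contiguous Golden Gate "parts" that are
mutagenized independently and recombined into the full-length gene.  This
module holds the gene/part geometry, degenerate-codon expansion, in-silico
part reassembly (junction-tag validated concatenation) and the arithmetic of
expected mutational load per reassembled gene.
"""

from __future__ import annotations

import configparser
import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "IUPAC_NUCLEOTIDES",
    "CodonExpansion",
    "PartDesign",
    "PartSequence",
    "ReferenceGene",
    "LibraryDesign",
    "AssemblyError",
    "FrameError",
    "expand_degenerate_codon",
    "assemble_parts",
    "expected_mutations_per_gene",
    "additivity_check",
    "round_half_up",
    "cal_a_reference",
    "load_reference",
    "write_reference_config",
]

IUPAC_NUCLEOTIDES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class AssemblyError(ValueError):
    """Junction tags of adjacent parts do not match."""


class FrameError(ValueError):
    """Assembled coding sequence length is not a multiple of 3."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (so 1.27 -> 1.3, 0.25 -> 0.3)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Degenerate codons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonExpansion:
    """All concrete codons of a degenerate triplet and what they encode."""

    triplet: str
    codons: tuple[str, ...]
    amino_acids: frozenset[str]      # one-letter codes, stops excluded
    stop_codons: tuple[str, ...]

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    @property
    def n_amino_acids(self) -> int:
        return len(self.amino_acids)


def expand_degenerate_codon(triplet: str) -> CodonExpansion:
    """Expand an IUPAC-ambiguous codon into concrete codons and amino acids.

    ``NDT`` (N = A/C/G/T, D = A/G/T) expands to 12 codons encoding 12 distinct
    amino acids with no stops, the workhorse of reduced saturation mutagenesis.
    Stop-encoding codons are reported separately, never as amino acids.
    """
    trip = triplet.upper()
    if len(trip) != 3:
        raise ValueError(f"degenerate codon must have 3 letters, got {triplet!r}")
    for letter in trip:
        if letter not in IUPAC_NUCLEOTIDES:
            raise ValueError(f"invalid IUPAC nucleotide code {letter!r} in {triplet!r}")
    codons = tuple(
        a + b + c
        for a in IUPAC_NUCLEOTIDES[trip[0]]
        for b in IUPAC_NUCLEOTIDES[trip[1]]
        for c in IUPAC_NUCLEOTIDES[trip[2]]
    )
    aas: set[str] = set()
    stops: list[str] = []
    for codon in codons:
        aa = str(Seq(codon).translate())
        if aa == "*":
            stops.append(codon)
        else:
            aas.add(aa)
    return CodonExpansion(trip, codons, frozenset(aas), tuple(stops))


# ---------------------------------------------------------------------------
# Parts and the reference gene
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartDesign:
    """One Golden Gate part of the coding sequence.

    ``residue_range`` is the inclusive 1-based protein span the part encodes,
    so the coding span is ``3 * n_residues`` bp.  ``mutagenized_bp`` is the
    length of the segment actually exposed to error-prone PCR, which for
    historical constructs can differ slightly from the coding span (amplicon
    trimming); it is the length used in mutational-load arithmetic.  Junction
    tags are the 4-nt type IIS overhangs validated at assembly time.
    """

    part_id: str
    residue_range: tuple[int, int]
    junction_5: str
    junction_3: str
    mutagenized_bp: int | None = None

    def __post_init__(self) -> None:
        start, end = self.residue_range
        if start < 1 or end < start:
            raise ValueError(f"bad residue range {self.residue_range} for {self.part_id}")

    @property
    def n_residues(self) -> int:
        return self.residue_range[1] - self.residue_range[0] + 1

    @property
    def bp_length(self) -> int:
        """Coding-span length in bp (3 x residues)."""
        return 3 * self.n_residues

    @property
    def load_bp(self) -> int:
        """Length used for mutational-load arithmetic."""
        return self.mutagenized_bp if self.mutagenized_bp is not None else self.bp_length


@dataclass(frozen=True)
class PartSequence:
    """A concrete part sequence carrying its junction overhang tags."""

    part_id: str
    seq: str
    junction_5: str
    junction_3: str


@dataclass
class ReferenceGene:
    """Reference coding sequence partitioned into Golden Gate parts."""

    name: str
    cds: str
    parts: list[PartDesign]
    numbering_offset: int = 0
    catalytic_triad: tuple[int, ...] = ()
    ndt_targets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.cds) % 3 != 0:
            raise FrameError(f"CDS length {len(self.cds)} not divisible by 3")
        if set(self.cds.upper()) - set("ACGT"):
            raise ValueError("CDS contains non-ACGT characters")
        self.cds = self.cds.upper()
        # parts must tile 1..n_residues exactly
        expected = 1
        for part in self.parts:
            if part.residue_range[0] != expected:
                raise ValueError(
                    f"part {part.part_id} starts at residue {part.residue_range[0]}, "
                    f"expected {expected} (parts must tile with no gaps/overlaps)"
                )
            expected = part.residue_range[1] + 1
        if expected - 1 != self.n_residues:
            raise ValueError(
                f"parts cover residues 1..{expected - 1} but CDS encodes {self.n_residues}"
            )

    @property
    def n_residues(self) -> int:
        return len(self.cds) // 3

    @property
    def protein(self) -> str:
        return str(Seq(self.cds).translate())

    def codon(self, residue: int) -> str:
        """Codon for a structure residue number (1-based, offset-corrected)."""
        idx = residue - self.numbering_offset
        if not 1 <= idx <= self.n_residues:
            raise IndexError(f"residue {residue} outside 1..{self.n_residues}")
        return self.cds[3 * (idx - 1): 3 * idx]

    def part_of(self, residue: int) -> str:
        idx = residue - self.numbering_offset
        for part in self.parts:
            if part.residue_range[0] <= idx <= part.residue_range[1]:
                return part.part_id
        raise IndexError(f"residue {residue} not covered by any part")

    def part(self, part_id: str) -> PartDesign:
        for part in self.parts:
            if part.part_id == part_id:
                return part
        raise KeyError(part_id)

    def cds_span(self, part_id: str) -> tuple[int, int]:
        """Half-open 0-based bp span of a part's coding region in the CDS."""
        part = self.part(part_id)
        start, end = part.residue_range
        return 3 * (start - 1), 3 * end

    def part_sequences(self) -> list[PartSequence]:
        """Slice the reference CDS into tagged part sequences."""
        out = []
        for part in self.parts:
            lo, hi = self.cds_span(part.part_id)
            out.append(PartSequence(part.part_id, self.cds[lo:hi],
                                    part.junction_5, part.junction_3))
        return out

    def geometry_warnings(self) -> list[str]:
        """Report parts whose mutagenized segment length differs from the coding span."""
        notes = []
        for part in self.parts:
            if part.mutagenized_bp is not None and part.mutagenized_bp != part.bp_length:
                notes.append(
                    f"{part.part_id}: mutagenized segment {part.mutagenized_bp} bp "
                    f"vs coding span {part.bp_length} bp ({part.n_residues} residues)"
                )
        return notes


@dataclass(frozen=True)
class LibraryDesign:
    """How one library was diversified.

    ``mode='random'`` is error-prone PCR over the mutated parts at
    ``rate_per_kb`` expected DNA substitutions per kb; ``mode='ndt_saturation'``
    replaces one of ``target_positions`` per clone with a random NDT codon.
    ``mutated_parts`` may be the sentinel ``("full_gene",)``.
    """

    library_id: str
    mutated_parts: tuple[str, ...]
    mode: str = "random"
    rate_per_kb: float | None = None
    target_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("random", "ndt_saturation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "random":
            if self.rate_per_kb is None or self.rate_per_kb < 0:
                raise ValueError("random mode requires rate_per_kb >= 0")
        else:
            if not self.target_positions:
                raise ValueError("ndt_saturation mode requires target_positions")

    @property
    def full_gene(self) -> bool:
        return self.mutated_parts == ("full_gene",)

    def mutated_load_bp(self, gene: ReferenceGene) -> int:
        """Mutagenized-segment bp total used in load arithmetic."""
        if self.full_gene:
            return sum(p.load_bp for p in gene.parts)
        return sum(gene.part(pid).load_bp for pid in self.mutated_parts)

    def mutated_coding_bp_spans(self, gene: ReferenceGene) -> list[tuple[int, int]]:
        """Half-open CDS bp spans actually subject to mutation."""
        if self.full_gene:
            return [(0, len(gene.cds))]
        return [gene.cds_span(pid) for pid in self.mutated_parts]


# ---------------------------------------------------------------------------
# Assembly and load arithmetic
# ---------------------------------------------------------------------------

def assemble_parts(parts: Sequence[PartSequence]) -> str:
    """Reassemble tagged parts into a full CDS (junction-validated concatenation).

    Type IIS digestion/ligation is abstracted to exact string matching of the
    declared overhang tags: part i's 3' tag must equal part i+1's 5' tag.  The
    frame check applies to the assembled product (historical part amplicons
    need not individually be codon multiples).
    """
    if not parts:
        raise ValueError("no parts to assemble")
    for left, right in zip(parts, parts[1:]):
        if left.junction_3 != right.junction_5:
            raise AssemblyError(
                f"junction mismatch between {left.part_id} (3' {left.junction_3}) "
                f"and {right.part_id} (5' {right.junction_5})"
            )
    cds = "".join(p.seq for p in parts)
    if len(cds) % 3 != 0:
        raise FrameError(f"assembled length {len(cds)} bp is not a codon multiple")
    return cds


def expected_mutations_per_gene(design: LibraryDesign, gene: ReferenceGene,
                                rounded: bool = True) -> float:
    """Expected DNA substitutions per reassembled gene for a random library.

    rate_per_kb x mutagenized bp / 1000, additive over disjoint mutated
    regions.  Reported to one decimal (half-up) to match how library QC
    tables are conventionally printed.
    """
    if design.mode != "random":
        raise ValueError("expected load is defined for random-mode designs only")
    load = design.rate_per_kb * design.mutated_load_bp(gene) / 1000.0
    return round_half_up(load, 1) if rounded else load


def additivity_check(per_part_loads: Iterable[float], ndigits: int = 1) -> float:
    """Sum reported per-part mutational loads (the recombined-library check).

    A library recombined from independently mutagenized parts should carry a
    load essentially equal to the sum of the parts' loads.
    """
    return round_half_up(float(sum(per_part_loads)), ndigits)


# ---------------------------------------------------------------------------
# Default Cal-A geometry and synthetic reference sequence
# ---------------------------------------------------------------------------

# Part geometry of the Cal-A construct: 446 residues split at 210/350, with
# the printed mutagenized-segment lengths of the historical amplicons.
_CAL_A_PARTS = [
    PartDesign("Part1", (1, 210), junction_5="AATG", junction_3="CCTA", mutagenized_bp=605),
    PartDesign("Part2", (211, 350), junction_5="CCTA", junction_3="GGAT", mutagenized_bp=420),
    PartDesign("Part3", (351, 446), junction_5="GGAT", junction_3="TTCG", mutagenized_bp=286),
]

CAL_A_CATALYTIC_TRIAD = (184, 334, 366)     # Ser184, Asp334, His366
CAL_A_NDT_TARGETS = (93, 183, 431)          # Tyr93, Tyr183, Phe431
CAL_A_SHORT_HOTSPOT = (217, 245)            # helix-loop-helix lid motif

# Residue identities the analysis refers to by name, pinned in the synthetic
# reference so positional vocabulary (Tyr93, Gly237, ...) is meaningful.
_PINNED_CODONS = {
    84: "CCT",   # Pro
    93: "TAT",   # Tyr
    183: "TAT",  # Tyr
    184: "TCT",  # Ser (catalytic)
    222: "TTT",  # Phe
    225: "CTT",  # Leu
    232: "GGT",  # Gly
    237: "GGT",  # Gly
    240: "GGT",  # Gly
    244: "GCT",  # Ala
    334: "GAT",  # Asp (catalytic)
    359: "TCT",  # Ser
    366: "CAT",  # His (catalytic)
    431: "TTT",  # Phe
}

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if str(Seq(a + b + c).translate()) != "*"
)


def cal_a_reference(name: str = "CalA") -> ReferenceGene:
    """Default Cal-A gene model with a synthetic coding sequence.

    The part geometry, catalytic triad and saturation-target annotations are
    the real construct's; the DNA itself is a synthetic stand-in (the actual
    coding sequence is not redistributed), generated deterministically from
    sense codons with the named residues pinned to their true identities.
    Substitution calls, load arithmetic and structure mapping depend only on
    geometry and the pinned identities, not on the remaining codons.
    """
    rng = np.random.default_rng(1311)
    codons = [str(c) for c in rng.choice(_SENSE_CODONS, size=446)]
    for residue, codon in _PINNED_CODONS.items():
        codons[residue - 1] = codon
    return ReferenceGene(
        name=name,
        cds="".join(codons),
        parts=list(_CAL_A_PARTS),
        numbering_offset=0,
        catalytic_triad=CAL_A_CATALYTIC_TRIAD,
        ndt_targets=CAL_A_NDT_TARGETS,
    )


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def write_reference_config(gene: ReferenceGene, cfg_path: str | Path,
                           fasta_path: str | Path | None = None) -> None:
    """Write the gene's geometry as an INI config (and optionally its FASTA)."""
    cp = configparser.ConfigParser()
    cp["gene"] = {
        "name": gene.name,
        "numbering_offset": str(gene.numbering_offset),
        "catalytic_triad": ",".join(map(str, gene.catalytic_triad)),
        "ndt_targets": ",".join(map(str, gene.ndt_targets)),
    }
    for part in gene.parts:
        sec = f"part:{part.part_id}"
        cp[sec] = {
            "residues": f"{part.residue_range[0]}-{part.residue_range[1]}",
            "junction_5": part.junction_5,
            "junction_3": part.junction_3,
        }
        if part.mutagenized_bp is not None:
            cp[sec]["mutagenized_bp"] = str(part.mutagenized_bp)
    with open(cfg_path, "w") as fh:
        cp.write(fh)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            fh.write(f">{gene.name}\n")
            for i in range(0, len(gene.cds), 60):
                fh.write(gene.cds[i:i + 60] + "\n")


def load_reference(fasta_path: str | Path, cfg_path: str | Path) -> ReferenceGene:
    """Load a reference gene from a CDS FASTA plus an INI geometry config."""
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    cp = configparser.ConfigParser()
    read = cp.read(str(cfg_path))
    if not read:
        raise FileNotFoundError(cfg_path)
    g = cp["gene"]
    parts = []
    for sec in cp.sections():
        if not sec.startswith("part:"):
            continue
        lo, hi = cp[sec]["residues"].split("-")
        mbp = cp[sec].get("mutagenized_bp")
        parts.append(PartDesign(
            part_id=sec.split(":", 1)[1],
            residue_range=(int(lo), int(hi)),
            junction_5=cp[sec]["junction_5"],
            junction_3=cp[sec]["junction_3"],
            mutagenized_bp=int(mbp) if mbp else None,
        ))
    parts.sort(key=lambda p: p.residue_range[0])

    def _ints(key: str) -> tuple[int, ...]:
        raw = g.get(key, "").strip()
        return tuple(int(x) for x in raw.split(",") if x) if raw else ()

    return ReferenceGene(
        name=g.get("name", record.id),
        cds=str(record.seq),
        parts=parts,
        numbering_offset=int(g.get("numbering_offset", "0")),
        catalytic_triad=_ints("catalytic_triad"),
        ndt_targets=_ints("ndt_targets"),
    )
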