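"""Per-residue hot-spot aggregation and PDB B-factor painting.

Substitution calls are joined with whole-clone phenotype calls and aggregated
per residue: activity values take the maximum over supporting variants (a
position substituted in several variants is shown at its best), and each
residue gets a discrimination category — short, long, or *both* when distinct
variants of opposite discriminative phenotype substitute it.  Multi-
substitution variants are not deconvoluted: every residue they substitute
inherits the whole variant's phenotype; unambiguous single-substitution
support is tracked separately.

Aggregates are written into the B-factor column (fixed-width columns 61-66)
of a standard PDB file, leaving every other byte untouched, so any molecular
viewer can color the structure by phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .calling import VariantRecord
from .phenotype import PhenotypeCall
from .reference import ReferenceGene

__all__ = [
    "CATEGORY_CODES",
    "ResidueEntry",
    "ResidueMap",
    "PartEnrichment",
    "MalformedPDBError",
    "build_residue_map",
    "part_enrichment",
    "write_bfactor_pdb",
    "read_bfactors",
    "residue_map_table",
]

# Numeric encoding of the discrimination category channel for B-factors.
CATEGORY_CODES = {"none": 0.0, "short": 1.0, "long": 2.0, "both": 3.0}

DEFAULT_WINDOW = 29   # residues; the width of the 217-245 lid motif


class MalformedPDBError(ValueError):
    pass


@dataclass
class ResidueEntry:
    activity_short: int = 0
    activity_long: int = 0
    n_supporting_variants: int = 0
    n_single_sub_variants: int = 0
    _short: bool = False
    _long: bool = False

    @property
    def category(self) -> str:
        if self._short and self._long:
            return "both"
        if self._short:
            return "short"
        if self._long:
            return "long"
        return "none"


@dataclass
class ResidueMap:
    entries: dict[int, ResidueEntry] = field(default_factory=dict)
    background_value: float = 0.0

    def value(self, residue: int, channel: str) -> float:
        entry = self.entries.get(residue)
        if entry is None:
            return self.background_value
        if channel == "short":
            return float(entry.activity_short)
        if channel == "long":
            return float(entry.activity_long)
        if channel == "category":
            return CATEGORY_CODES[entry.category]
        raise ValueError(f"unknown channel {channel!r}")

    def positions(self, category: str, include_both: bool = True) -> list[int]:
        """Residues carrying a discrimination category (optionally counting 'both')."""
        wanted = {category} | ({"both"} if include_both and category in ("short", "long") else set())
        return sorted(r for r, e in self.entries.items() if e.category in wanted)


@dataclass
class PartEnrichment:
    """Distinct substituted positions per part per discrimination class."""

    counts: dict[str, dict[str, int]]                 # part_id -> class -> n positions
    top_windows: dict[str, tuple[int, int, int]]      # class -> (start, end, count)
    window_width: int = DEFAULT_WINDOW


def build_residue_map(records: list[VariantRecord], calls: list[PhenotypeCall],
                      background_value: float = 0.0) -> ResidueMap:
    """Aggregate per-residue activity and discrimination from variant evidence.

    Every record must have a matching phenotype call (by clone_id) and be QC
    ok.  Aggregation is order-independent: max for activity values, set union
    for categories.
    """
    call_by_id = {c.clone_id: c for c in calls}
    rmap = ResidueMap(background_value=background_value)
    for rec in records:
        if rec.qc_status != "ok":
            raise ValueError(f"clone {rec.clone_id}: qc_status {rec.qc_status!r}, "
                             "only ok records can be mapped")
        call = call_by_id.get(rec.clone_id)
        if call is None:
            raise KeyError(f"clone {rec.clone_id} has no phenotype call")
        single = len(rec.substitutions) == 1
        for sub in rec.substitutions:
            entry = rmap.entries.setdefault(sub.residue_position, ResidueEntry())
            entry.activity_short = max(entry.activity_short, call.rating_short)
            entry.activity_long = max(entry.activity_long, call.rating_long)
            entry.n_supporting_variants += 1
            if single:
                entry.n_single_sub_variants += 1
            if call.discrimination == "short":
                entry._short = True
            elif call.discrimination == "long":
                entry._long = True
    return rmap


def part_enrichment(rmap: ResidueMap, gene: ReferenceGene,
                    window_width: int = DEFAULT_WINDOW) -> PartEnrichment:
    """Count distinct discriminative positions per part and scan for the top window.

    Window scans count positions of the class (including 'both') inside every
    ``window_width``-residue interval; ties break to the leftmost start.
    """
    classes = ("short", "long", "both")
    counts = {p.part_id: {cls: 0 for cls in classes} for p in gene.parts}
    for residue, entry in rmap.entries.items():
        if entry.category == "none":
            continue
        counts[gene.part_of(residue)][entry.category] += 1

    top: dict[str, tuple[int, int, int]] = {}
    n_res = gene.n_residues
    for cls in ("short", "long"):
        positions = set(rmap.positions(cls, include_both=True))
        best = (1, window_width, 0)
        for start in range(1, n_res - window_width + 2):
            n = sum(1 for p in positions if start <= p <= start + window_width - 1)
            if n > best[2]:
                best = (start, start + window_width - 1, n)
        top[cls] = best
    return PartEnrichment(counts=counts, top_windows=top, window_width=window_width)


# ---------------------------------------------------------------------------
# PDB B-factor writer
# ---------------------------------------------------------------------------

def write_bfactor_pdb(pdb_text: str, rmap: ResidueMap, channel: str = "short",
                      chain: str | None = None) -> str:
    """Set B-factors (columns 61-66) of ATOM/HETATM records from a residue map.

    Atoms of mapped residues (on the selected chain) get the channel value,
    everything else the map's background value; all other bytes are preserved.
    Multi-chain structures require an explicit chain selector; insertion codes
    are rejected.
    """
    lines = pdb_text.splitlines(keepends=True)
    atom_chains = {ln[21] for ln in lines if ln.startswith(("ATOM  ", "HETATM")) and len(ln) >= 27}
    if chain is None and len(atom_chains) > 1:
        raise ValueError(
            f"structure has chains {sorted(atom_chains)}; residue numbers may "
            "collide across chains — pass an explicit chain selector"
        )
    out = []
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            out.append(line)
            continue
        body = line.rstrip("\r\n")
        eol = line[len(body):]
        if len(body) < 66:
            raise MalformedPDBError(
                f"line {lineno}: fixed-width record too short ({len(body)} < 66 columns)")
        if body[26] != " ":
            raise MalformedPDBError(
                f"line {lineno}: insertion code {body[26]!r} unsupported")
        try:
            resseq = int(body[22:26])
        except ValueError as exc:
            raise MalformedPDBError(f"line {lineno}: bad residue number field "
                                    f"{body[22:26]!r}") from exc
        on_chain = chain is None or body[21] == chain
        value = rmap.value(resseq, channel) if on_chain else rmap.background_value
        out.append(body[:60] + f"{value:6.2f}" + body[66:] + eol)
    return "".join(out)


def read_bfactors(pdb_text: str) -> dict[tuple[str, int], set[float]]:
    """Parse B-factor values per (chain, residue) from PDB text."""
    values: dict[tuple[str, int], set[float]] = {}
    for line in pdb_text.splitlines():
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66:
            key = (line[21], int(line[22:26]))
            values.setdefault(key, set()).add(float(line[60:66]))
    return values


def residue_map_table(rmap: ResidueMap) -> pd.DataFrame:
    rows = [
        {"residue": residue,
         "activity_short": e.activity_short,
         "activity_long": e.activity_long,
         "category": e.category,
         "n_supporting_variants": e.n_supporting_variants,
         "n_single_sub_variants": e.n_single_sub_variants}
        for residue, e in sorted(rmap.entries.items())
    ]
    return pd.DataFrame(rows)
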