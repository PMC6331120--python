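"""Seeded synthetic libraries, phenotypes and kinetic traces.

Everything downstream of the wet lab is testable against this generator: it
emulates error-prone-PCR libraries at a stated per-kb substitution rate
confined to designated parts, NDT point-saturation variants, triplicate
ordinal halo ratings driven by a ground-truth model (a short-chain hotspot
interval, long-chain positions, and catalytic-triad knockouts), and linear
absorbance time courses for the chromogenic ester assay.

Defaults mirror the Cal-A study conditions: hotspot 217-245 (the
helix-loop-helix lid), long-chain positions {84, 93, 232, 359}, knockout at
the Ser184/Asp334/His366 triad, wild-type rating 3, and per-library clone
counts / mutation rates as in the library-quality table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import KineticAssay
from .reference import (LibraryDesign, ReferenceGene, cal_a_reference,
                        expand_degenerate_codon, round_half_up)
from .phenotype import HaloObservation, RATING_MAX, RATING_MIN

__all__ = [
    "GroundTruthModel",
    "SimulatedClone",
    "simulate_library",
    "simulate_phenotype",
    "simulate_halo_observations",
    "simulate_kinetic_trace",
    "simulate_campaign",
    "write_campaign",
    "reference_screen_fixture",
    "toy_pdb",
    "CAL_A_LIBRARY_DESIGNS",
    "CAL_A_CLONES_SCREENED",
]

_NDT_CODONS = expand_degenerate_codon("NDT").codons

# Study-condition library designs (mutation rates per kb as reported for the
# five Cal-A libraries) and the number of clones screened per library.
CAL_A_LIBRARY_DESIGNS: dict[str, LibraryDesign] = {
    "Random1": LibraryDesign("Random1", ("Part1",), "random", rate_per_kb=2.1),
    "Random2": LibraryDesign("Random2", ("Part2",), "random", rate_per_kb=4.1),
    "Random3": LibraryDesign("Random3", ("Part3",), "random", rate_per_kb=3.3),
    "RandomRec": LibraryDesign("RandomRec", ("Part1", "Part2", "Part3"), "random",
                               rate_per_kb=3.0),
    "RandomTot": LibraryDesign("RandomTot", ("full_gene",), "random", rate_per_kb=4.2),
}

CAL_A_CLONES_SCREENED = {"Random1": 384, "Random2": 384, "Random3": 384,
                         "RandomRec": 768, "RandomTot": 768}


@dataclass(frozen=True)
class GroundTruthModel:
    """Genotype -> phenotype ground truth used by the simulator.

    ``hotspot_short`` is the residue interval whose substitution confers
    strong short-chain discrimination; ``long_positions`` confer long-chain
    discrimination; ``knockout_positions`` abolish activity on both
    substrates.  Replicate ratings shift by +/-1 with ``noise_prob`` and are
    clipped to the ordinal scale.
    """

    hotspot_short: tuple[int, int] = (217, 245)
    long_positions: frozenset[int] = frozenset({84, 93, 232, 359})
    knockout_positions: frozenset[int] = frozenset({184, 334, 366})
    noise_prob: float = 0.1
    wt_rating: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_prob <= 1.0:
            raise ValueError("noise_prob must be in [0, 1]")
        if not RATING_MIN <= self.wt_rating <= RATING_MAX:
            raise ValueError("wt_rating outside the ordinal rating scale")

    def effect(self, position: int) -> tuple[int, int]:
        """Core (tributyrin, olive-oil) rating effect of one substitution.

        Knockouts dominate; long-chain positions are checked before the short
        hotspot because the sets may overlap (e.g. residue 232 sits inside the
        217-245 lid yet drives long-chain discrimination).
        """
        if position in self.knockout_positions:
            return (0, 0)
        if position in self.long_positions:
            return (0, 4)
        if self.hotspot_short[0] <= position <= self.hotspot_short[1]:
            return (4, 0)
        return (self.wt_rating, self.wt_rating)


@dataclass
class SimulatedClone:
    clone_id: str
    library_id: str
    dna: str
    true_substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    true_phenotype: tuple[int, int] | None = None


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

def simulate_library(design: LibraryDesign, gene: ReferenceGene, n_clones: int,
                     seed: int | np.random.Generator,
                     frameshift_prob: float = 0.0) -> list[SimulatedClone]:
    """Draw ``n_clones`` variant CDSs under a library design.

    Random mode: per-clone substitution count ~ Poisson(rate_per_kb x
    mutated_coding_bp / 1000), positions uniform without replacement within
    the mutated coding region, substituted base uniform over the three
    alternatives.  NDT mode: one uniformly chosen target codon per clone is
    replaced by a uniformly drawn NDT codon.  ``frameshift_prob`` optionally
    injects a single-base insertion to exercise QC failure paths.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from Bio.Seq import Seq  # local: avoid import cost at module load for numpy-only users

    ref = gene.cds
    clones: list[SimulatedClone] = []
    if design.mode == "random":
        spans = design.mutated_coding_bp_spans(gene)
        positions = np.concatenate([np.arange(lo, hi) for lo, hi in spans])
        lam = design.rate_per_kb * len(positions) / 1000.0
    for i in range(n_clones):
        clone_id = f"{design.library_id}_{i + 1:04d}"
        dna = list(ref)
        if design.mode == "random":
            k = min(int(rng.poisson(lam)), len(positions))
            hit = rng.choice(positions, size=k, replace=False) if k else np.array([], int)
            for pos in sorted(int(p) for p in hit):
                alternatives = [b for b in "ACGT" if b != ref[pos]]
                dna[pos] = alternatives[int(rng.integers(3))]
        else:
            target = int(design.target_positions[int(rng.integers(len(design.target_positions)))])
            codon = _NDT_CODONS[int(rng.integers(len(_NDT_CODONS)))]
            idx = target - 1 - gene.numbering_offset
            dna[3 * idx: 3 * idx + 3] = list(codon)
        variant = "".join(dna)

        subs: list[tuple[int, str, str]] = []
        for r in range(gene.n_residues):
            wt_codon, mut_codon = ref[3 * r: 3 * r + 3], variant[3 * r: 3 * r + 3]
            if wt_codon == mut_codon:
                continue
            wt_aa, mut_aa = str(Seq(wt_codon).translate()), str(Seq(mut_codon).translate())
            if wt_aa != mut_aa:
                subs.append((r + 1 + gene.numbering_offset, wt_aa, mut_aa))

        if frameshift_prob > 0 and rng.random() < frameshift_prob:
            at = int(rng.integers(len(variant)))
            variant = variant[:at] + "ACGT"[int(rng.integers(4))] + variant[at:]
        clones.append(SimulatedClone(clone_id, design.library_id, variant, subs))
    return clones


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

def true_ratings(substitutions: list[tuple[int, str, str]],
                 truth: GroundTruthModel) -> tuple[int, int]:
    """Noise-free (tributyrin, olive-oil) ratings of a substitution set.

    Per-substitution effects combine per substrate by dominance of loss: any
    effect below wild type pins the substrate to the minimum; otherwise the
    maximum gain applies.  Frameshifted/truncated genotypes are handled
    upstream as QC failures, not here.
    """
    wt = truth.wt_rating
    if not substitutions:
        return (wt, wt)
    effects = [truth.effect(pos) for pos, _, _ in substitutions]
    out = []
    for channel in (0, 1):
        vals = [e[channel] for e in effects]
        out.append(min(vals) if min(vals) < wt else max(vals))
    return (out[0], out[1])


def simulate_phenotype(clone: SimulatedClone, truth: GroundTruthModel,
                       seed: int | np.random.Generator) -> dict[str, tuple[int, int, int]]:
    """Triplicate halo ratings per substrate for one clone (seeded noise)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    core = true_ratings(clone.true_substitutions, truth)
    clone.true_phenotype = core
    out: dict[str, tuple[int, int, int]] = {}
    for substrate, base in zip(("tributyrin", "olive_oil"), core):
        reps = []
        for _ in range(3):
            r = base
            if truth.noise_prob > 0 and rng.random() < truth.noise_prob:
                r += int(rng.choice((-1, 1)))
            reps.append(int(np.clip(r, RATING_MIN, RATING_MAX)))
        out[substrate] = tuple(reps)
    return out


def simulate_halo_observations(clones: list[SimulatedClone], truth: GroundTruthModel,
                               seed: int | np.random.Generator) -> list[HaloObservation]:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs: list[HaloObservation] = []
    for clone in clones:
        ratings = simulate_phenotype(clone, truth, rng)
        for substrate in ("tributyrin", "olive_oil"):
            obs.append(HaloObservation(clone.clone_id, substrate, ratings[substrate]))
    return obs


# ---------------------------------------------------------------------------
# Kinetic traces
# ---------------------------------------------------------------------------

def simulate_kinetic_trace(sa_true: float, assay: KineticAssay, n_points: int = 31,
                           dt_min: float = 1.0, noise_sd: float = 0.0,
                           seed: int | np.random.Generator | None = None,
                           a0: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Linear absorbance time course A(t) = A0 + slope*t + N(0, noise_sd).

    The slope is the exact inverse of the specific-activity formula, so a
    noiseless trace round-trips through slope fitting to ``sa_true``.
    Returns (times_min, absorbance).
    """
    if sa_true < 0:
        raise ValueError("sa_true must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    slope = (sa_true * assay.protein_conc * assay.epsilon * assay.path_length
             * assay.v_enzyme / assay.v_total)
    t = np.arange(n_points, dtype=float) * dt_min
    a = a0 + slope * t
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=n_points)
    return t, a


# ---------------------------------------------------------------------------
# Whole campaigns
# ---------------------------------------------------------------------------

def simulate_campaign(designs: dict[str, LibraryDesign] | None = None,
                      n_clones: dict[str, int] | int | None = None,
                      gene: ReferenceGene | None = None,
                      truth: GroundTruthModel | None = None,
                      seed: int = 0) -> tuple[ReferenceGene, GroundTruthModel,
                                              dict[str, list[SimulatedClone]],
                                              list[HaloObservation]]:
    """Simulate a multi-library screening campaign under one master seed."""
    gene = gene or cal_a_reference()
    truth = truth or GroundTruthModel()
    designs = designs or CAL_A_LIBRARY_DESIGNS
    master = np.random.default_rng(seed)
    libraries: dict[str, list[SimulatedClone]] = {}
    observations: list[HaloObservation] = []
    for lib_id, design in designs.items():
        if isinstance(n_clones, dict):
            n = n_clones.get(lib_id, CAL_A_CLONES_SCREENED.get(lib_id, 384))
        elif isinstance(n_clones, int):
            n = n_clones
        else:
            n = CAL_A_CLONES_SCREENED.get(lib_id, 384)
        clones = simulate_library(design, gene, n, master)
        libraries[lib_id] = clones
        observations.extend(simulate_halo_observations(clones, truth, master))
    return gene, truth, libraries, observations


def write_campaign(out_dir: str | Path, gene: ReferenceGene,
                   libraries: dict[str, list[SimulatedClone]],
                   observations: list[HaloObservation], seed: int,
                   truth: GroundTruthModel | None = None) -> None:
    """Write clone FASTAs, the ratings table, truth table and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for lib_id, clones in libraries.items():
        with open(out / f"{lib_id}.fasta", "w") as fh:
            for clone in clones:
                fh.write(f">{clone.clone_id}\n")
                for i in range(0, len(clone.dna), 60):
                    fh.write(clone.dna[i:i + 60] + "\n")
    pd.DataFrame(
        [{"clone_id": o.clone_id, "substrate": o.substrate,
          "rep1": o.ratings[0], "rep2": o.ratings[1], "rep3": o.ratings[2]}
         for o in observations]
    ).to_csv(out / "ratings.tsv", sep="\t", index=False)
    truth_rows = [
        {"clone_id": c.clone_id, "library_id": c.library_id,
         "substitutions": ";".join(f"{w}{p}{m}" for p, w, m in c.true_substitutions),
         "true_short": c.true_phenotype[0] if c.true_phenotype else "",
         "true_long": c.true_phenotype[1] if c.true_phenotype else ""}
        for clones in libraries.values() for c in clones
    ]
    pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False)
    manifest = {
        "seed": seed,
        "gene": gene.name,
        "n_clones": {k: len(v) for k, v in libraries.items()},
        "truth": None if truth is None else {
            "hotspot_short": list(truth.hotspot_short),
            "long_positions": sorted(truth.long_positions),
            "knockout_positions": sorted(truth.knockout_positions),
            "noise_prob": truth.noise_prob,
            "wt_rating": truth.wt_rating,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Screen fixture with the study's reported marginals
# ---------------------------------------------------------------------------

# Reported screening marginals per library: (clones screened, % active,
# n short-discriminative, n long-discriminative).
_SCREEN_MARGINALS = {
    "Random1": (384, 89, 0, 0),
    "Random2": (384, 66, 18, 3),
    "Random3": (384, 89, 0, 0),
    "RandomRec": (768, 41, 12, 6),
    "RandomTot": (768, 23, 10, 4),
}


def reference_screen_fixture() -> dict[str, list[HaloObservation]]:
    """Deterministic noise-free observations reproducing the reported screen marginals.

    For each library, discriminative clones are encoded as (4,0) or (0,4)
    rating pairs, remaining actives as wild-type-like (3,3), and the rest as
    (0,0); the active count is the smallest one matching the printed percent.
    """
    fixture: dict[str, list[HaloObservation]] = {}
    for lib_id, (n, pct, n_short, n_long) in _SCREEN_MARGINALS.items():
        n_active = next(k for k in range(n + 1)
                        if int(round_half_up(100.0 * k / n, 0)) == pct)
        pairs = ([(4, 0)] * n_short + [(0, 4)] * n_long
                 + [(3, 3)] * (n_active - n_short - n_long)
                 + [(0, 0)] * (n - n_active))
        obs = []
        for i, (rs, rl) in enumerate(pairs):
            cid = f"{lib_id}_{i + 1:04d}"
            obs.append(HaloObservation(cid, "tributyrin", (rs, rs, rs)))
            obs.append(HaloObservation(cid, "olive_oil", (rl, rl, rl)))
        fixture[lib_id] = obs
    return fixture


# ---------------------------------------------------------------------------
# Toy PDB structure
# ---------------------------------------------------------------------------

def toy_pdb(n_residues: int = 3, chain: str = "A", b_factor: float = 0.0,
            extra_chain: str | None = None) -> str:
    """Minimal synthetic PDB text (N, CA, C per residue on a straight line).

    A stand-in for real coordinates in structure-painting tests; geometry is
    arbitrary but the fixed-width record layout is standard.
    """
    lines = ["HEADER    SYNTHETIC TOY STRUCTURE"]
    serial = 1
    chains = [chain] + ([extra_chain] if extra_chain else [])
    for ch in chains:
        for resi in range(1, n_residues + 1):
            x = 3.8 * resi
            for atom, dy in (("N", -0.5), ("CA", 0.0), ("C", 0.5)):
                lines.append(
                    f"ATOM  {serial:5d} {atom:^4s} ALA {ch}{resi:4d}    "
                    f"{x:8.3f}{dy:8.3f}{0.0:8.3f}{1.00:6.2f}{b_factor:6.2f}"
                    f"          {atom[0]:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      ALA {ch}{n_residues:4d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
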