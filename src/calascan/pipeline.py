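"""End-to-end campaign orchestration.

``run_pipeline`` chains the stages — simulate (or ingest) clone sequences,
call substitutions, consolidate and classify halo phenotypes, aggregate
per-residue hot-spots onto a structure, and quantify specific activities —
through their declared tabular/FASTA/PDB interfaces only, and records seeds
and parameters in a manifest so a rerun is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calling import call_fasta, call_substitutions, library_qc, qc_table, substitution_table
from .kinetics import KineticAssay, activity_table, fit_slope
from .mapping import (build_residue_map, part_enrichment, residue_map_table,
                      write_bfactor_pdb)
from .phenotype import Thresholds, call_phenotypes, calls_table, read_ratings, \
    summarize_screen, summary_table
from .reference import LibraryDesign, ReferenceGene, cal_a_reference, load_reference
from .synth import (CAL_A_CLONES_SCREENED, CAL_A_LIBRARY_DESIGNS,
                    GroundTruthModel, simulate_halo_observations,
                    simulate_kinetic_trace, simulate_library, toy_pdb,
                    write_campaign)

__all__ = ["CampaignConfig", "run_pipeline"]

log = logging.getLogger("calascan")


@dataclass
class CampaignConfig:
    """Validated configuration of one campaign run."""

    out_dir: Path
    seed: int = 0
    reference_fasta: Path | None = None
    reference_config: Path | None = None
    designs: dict[str, LibraryDesign] = field(default_factory=dict)
    n_clones: dict[str, int] = field(default_factory=dict)
    truth: GroundTruthModel = field(default_factory=GroundTruthModel)
    thresholds: Thresholds = field(default_factory=Thresholds)
    variants_fasta: dict[str, Path] = field(default_factory=dict)   # ingest mode
    ratings_file: Path | None = None
    pdb_file: Path | None = None
    kinetics_reference_sa: float = 0.4    # U/mg, reference-clone activity
    kinetics_noise_sd: float = 0.002
    kinetics_max_variants: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None,
                  out_dir: str | Path | None = None) -> "CampaignConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ref = raw.get("reference", {}) or {}
        for key in ("fasta", "config"):
            if key in ref and not Path(ref[key]).exists():
                raise FileNotFoundError(f"reference {key} file not found: {ref[key]}")
        designs = {}
        n_clones = {}
        for lib_id, spec in (raw.get("designs") or {}).items():
            designs[lib_id] = LibraryDesign(
                library_id=lib_id,
                mutated_parts=tuple(spec.get("mutated_parts", ("full_gene",))),
                mode=spec.get("mode", "random"),
                rate_per_kb=spec.get("rate_per_kb"),
                target_positions=tuple(spec.get("target_positions", ())),
            )
            if "n_clones" in spec:
                n_clones[lib_id] = int(spec["n_clones"])
        truth_raw = raw.get("truth", {}) or {}
        truth = GroundTruthModel(
            hotspot_short=tuple(truth_raw.get("hotspot_short", (217, 245))),
            long_positions=frozenset(truth_raw.get("long_positions", (84, 93, 232, 359))),
            knockout_positions=frozenset(truth_raw.get("knockout_positions", (184, 334, 366))),
            noise_prob=float(truth_raw.get("noise_prob", 0.1)),
            wt_rating=int(truth_raw.get("wt_rating", 3)),
        )
        thr_raw = raw.get("thresholds", {}) or {}
        thresholds = Thresholds(**thr_raw)
        kin = raw.get("kinetics", {}) or {}
        return cls(
            out_dir=Path(out_dir or raw.get("out_dir", "campaign_out")),
            seed=int(seed if seed is not None else raw.get("seed", 0)),
            reference_fasta=Path(ref["fasta"]) if "fasta" in ref else None,
            reference_config=Path(ref["config"]) if "config" in ref else None,
            designs=designs,
            n_clones=n_clones,
            truth=truth,
            thresholds=thresholds,
            variants_fasta={k: Path(v) for k, v in (raw.get("variants") or {}).items()},
            ratings_file=Path(raw["ratings"]) if raw.get("ratings") else None,
            pdb_file=Path(raw["pdb"]) if raw.get("pdb") else None,
            kinetics_reference_sa=float(kin.get("reference_sa", 0.4)),
            kinetics_noise_sd=float(kin.get("noise_sd", 0.002)),
            kinetics_max_variants=int(kin.get("max_variants", 5)),
        )

    def gene(self) -> ReferenceGene:
        if self.reference_fasta and self.reference_config:
            return load_reference(self.reference_fasta, self.reference_config)
        if self.reference_fasta or self.reference_config:
            raise ValueError("reference requires both fasta and config paths")
        return cal_a_reference()


def run_pipeline(config: CampaignConfig) -> dict[str, Path]:
    """Run a full campaign; returns paths of the emitted artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene = config.gene()
    designs = config.designs or dict(CAL_A_LIBRARY_DESIGNS)
    rng = np.random.default_rng(config.seed)

    # --- stage 1: obtain clone sequences and halo ratings -------------------
    simulated = not config.variants_fasta
    records_by_lib = {}
    if simulated:
        libraries = {}
        observations = []
        for lib_id, design in designs.items():
            n = config.n_clones.get(lib_id, CAL_A_CLONES_SCREENED.get(lib_id, 384))
            clones = simulate_library(design, gene, n, rng)
            libraries[lib_id] = clones
            observations.extend(simulate_halo_observations(clones, config.truth, rng))
        write_campaign(out / "simulated_inputs", gene, libraries, observations,
                       config.seed, config.truth)
        log.info("simulated %d libraries, %d clones total",
                 len(libraries), sum(map(len, libraries.values())))
        for lib_id, clones in libraries.items():
            records_by_lib[lib_id] = [
                call_substitutions(c.dna, gene, clone_id=c.clone_id, library_id=lib_id)
                for c in clones
            ]
    else:
        if config.ratings_file is None:
            raise ValueError("ingest mode requires a ratings file")
        observations = read_ratings(config.ratings_file)
        for lib_id, fasta in config.variants_fasta.items():
            records_by_lib[lib_id] = call_fasta(fasta, gene, library_id=lib_id)

    # --- stage 2: variant calling QC ----------------------------------------
    qcs = []
    for lib_id, records in records_by_lib.items():
        design = designs.get(lib_id)
        region_bp = design.mutated_load_bp(gene) if design else len(gene.cds)
        n_failed = sum(1 for r in records if r.qc_status != "ok")
        log.info("library %s: %d clones, %d QC failures", lib_id, len(records), n_failed)
        qcs.append(library_qc([r for r in records], gene, region_bp, library_id=lib_id))
    all_records = [r for recs in records_by_lib.values() for r in recs]
    artifacts = {}
    qc_df = qc_table(qcs)
    artifacts["qc_table"] = out / "qc_table.tsv"
    qc_df.to_csv(artifacts["qc_table"], sep="\t", index=False)
    sub_df = substitution_table(all_records)
    artifacts["substitutions"] = out / "substitutions.tsv"
    sub_df.to_csv(artifacts["substitutions"], sep="\t", index=False)

    # --- stage 3: phenotyping ------------------------------------------------
    calls = call_phenotypes(observations, config.thresholds)
    call_by_id = {c.clone_id: c for c in calls}
    summaries = []
    for lib_id, records in records_by_lib.items():
        lib_calls = [call_by_id[r.clone_id] for r in records if r.clone_id in call_by_id]
        if lib_calls:
            summaries.append(summarize_screen(lib_calls, lib_id))
    artifacts["phenotype_calls"] = out / "phenotype_calls.tsv"
    calls_table(calls).to_csv(artifacts["phenotype_calls"], sep="\t", index=False)
    artifacts["screen_summary"] = out / "screen_summary.tsv"
    summary_table(summaries).to_csv(artifacts["screen_summary"], sep="\t", index=False)

    # --- stage 4: hot-spot mapping onto the structure ------------------------
    ok_records = [r for r in all_records
                  if r.qc_status == "ok" and r.clone_id in call_by_id]
    rmap = build_residue_map(ok_records, [call_by_id[r.clone_id] for r in ok_records])
    enr = part_enrichment(rmap, gene)
    artifacts["residue_map"] = out / "residue_map.tsv"
    residue_map_table(rmap).to_csv(artifacts["residue_map"], sep="\t", index=False)
    enrichment_rows = [
        {"part_id": pid, **cls_counts} for pid, cls_counts in enr.counts.items()
    ]
    for cls, (start, end, count) in enr.top_windows.items():
        enrichment_rows.append({"part_id": f"top_window_{cls}", "short": "",
                                "long": "", "both": "",
                                "window": f"{start}-{end}", "count": count})
    import pandas as pd
    artifacts["enrichment"] = out / "enrichment.tsv"
    pd.DataFrame(enrichment_rows).to_csv(artifacts["enrichment"], sep="\t", index=False)

    pdb_text = (Path(config.pdb_file).read_text() if config.pdb_file
                else toy_pdb(n_residues=gene.n_residues))
    for channel in ("short", "long", "category"):
        painted = write_bfactor_pdb(pdb_text, rmap, channel=channel)
        path = out / f"structure_{channel}.pdb"
        path.write_text(painted)
        artifacts[f"structure_{channel}"] = path

    # --- stage 5: kinetics ----------------------------------------------------
    chosen = [r for r in ok_records
              if call_by_id[r.clone_id].discrimination != "none"]
    chosen = chosen[: config.kinetics_max_variants]
    assays = []
    wt_rating = config.truth.wt_rating if simulated else 3
    panel = [("WT", wt_rating, wt_rating)] + [
        (r.clone_id, call_by_id[r.clone_id].rating_short, call_by_id[r.clone_id].rating_long)
        for r in chosen
    ]
    for clone_id, rating_short, rating_long in panel:
        for substrate, rating in (("C4_butyrate", rating_short),
                                  ("C16_palmitate", rating_long)):
            # generator convention: S.A. scales linearly with the ordinal
            # rating, anchored at the reference activity for the WT rating
            sa_true = config.kinetics_reference_sa * rating / wt_rating
            proto = KineticAssay(clone_id=clone_id, substrate=substrate)
            t, a = simulate_kinetic_trace(sa_true, proto,
                                          noise_sd=config.kinetics_noise_sd, seed=rng)
            slope, _ = fit_slope(t, a)
            assays.append(KineticAssay(clone_id=clone_id, substrate=substrate,
                                       slope=max(slope, 0.0)))
    kin_df = activity_table(assays, reference_clone="WT", reference_substrate="C4_butyrate")
    artifacts["kinetics"] = out / "kinetics.tsv"
    kin_df.round(6).to_csv(artifacts["kinetics"], sep="\t", index=False)

    # --- manifest -------------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "simulated": simulated,
        "gene": gene.name,
        "libraries": {lib_id: len(records) for lib_id, records in records_by_lib.items()},
        "thresholds": config.thresholds.__dict__,
        "truth": {
            "hotspot_short": list(config.truth.hotspot_short),
            "long_positions": sorted(config.truth.long_positions),
            "knockout_positions": sorted(config.truth.knockout_positions),
            "noise_prob": config.truth.noise_prob,
            "wt_rating": config.truth.wt_rating,
        } if simulated else None,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    artifacts["manifest"] = out / "manifest.json"
    with open(artifacts["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return artifacts
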