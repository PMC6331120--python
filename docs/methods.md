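# Methods

## The problem

Cal-A (Candida antarctica lipase A) hydrolyzes triglycerides with little
discrimination between short-chain (tributyrin, C4) and long-chain (olive
oil, mostly C18/C16) substrates. A part-wise engineering campaign splits the
1.3-kb coding sequence into three Golden Gate parts (residues 1–210,
211–350, 351–446), mutagenizes each part independently — error-prone PCR at
a tunable per-kb rate, or NDT saturation at chosen codons — recombines parts
into full-length genes, screens colonies on emulsified-substrate plates for
halo formation, and maps the substitutions of discriminative clones onto the
protein structure to find the hot-spot that governs chain-length
recognition. `calascan` implements the computational side of that campaign
end to end, plus a synthetic-data generator so every stage runs and is
testable with no external data.

## Reference model

`ReferenceGene` stores the CDS, its part decomposition, the catalytic triad
(Ser184, Asp334, His366) and the NDT saturation targets (Tyr93, Tyr183,
Phe431). Parts must tile the protein exactly on codon boundaries. Each
`PartDesign` carries two lengths: the coding span (3 × residues) and the
mutagenized-segment length of the historical amplicon (605 / 420 / 286 bp
for Parts 1–3), which is what mutational-load arithmetic uses. The two
disagree for Parts 1 and 3 (630 and 288 bp coding); the model stores both
and reports the discrepancy through `geometry_warnings()` rather than
reconciling it.

Because the construct's actual DNA is not redistributable, the default gene
(`cal_a_reference()`) carries a synthetic CDS: 446 sense codons drawn from a
fixed-seed generator, with every residue the analysis names pinned to its
true identity (so Tyr93, Gly237 etc. are meaningful). Nothing downstream
depends on the unpinned codons.

Golden Gate assembly is abstracted to junction-tag-validated concatenation:
part i's 3′ overhang tag must equal part i+1's 5′ tag, and the frame check
applies to the assembled product (the printed amplicon lengths are not
individually codon multiples). Type IIS recognition-site scanning is out of
scope — assembly correctness here is positional, not enzymatic.

Expected mutational load is `rate_per_kb × mutagenized_bp / 1000`, additive
over disjoint mutated regions, reported to one decimal with half-up rounding
(1.27 → 1.3). `additivity_check` sums reported per-part loads to verify that
a part-recombined library carries the sum of its parts' loads.

## Synthetic data generator

`simulate_library` draws, per clone, a Poisson number of DNA substitutions
with mean `rate_per_kb × mutated_coding_bp / 1000`, at uniform positions
within the mutated parts' coding spans, each substituted base uniform over
the three alternatives. The error model is substitution-only; a
`frameshift_prob` flag injects single-base insertions to exercise QC
failure paths. NDT mode replaces one uniformly chosen target codon per clone
with a uniformly drawn NDT codon. Default designs and clone counts are the
five study libraries (Random 1/2/3 at 2.1/4.1/3.3 per kb over one part,
Random Rec at 3.0 per kb over all three parts, Random Tot at 4.2 per kb over
the full gene; 384 or 768 clones each).

`GroundTruthModel` encodes the genotype→phenotype convention:

- catalytic-triad substitution → (0, 0): dead on both substrates;
- a long-chain position (default {84, 93, 232, 359}) → (0, 4);
- a substitution inside the short-chain hotspot interval (default 217–245,
  the helix-loop-helix lid) → (4, 0);
- anything else is neutral, (3, 3) with wild type = 3.

Residue 232 belongs to both the long-position set and the hotspot interval;
the lookup checks knockout, then long positions, then the hotspot, so 232
acts as a long-chain discriminator (matching the behaviour of Gly232Cys).
Effects of multiple substitutions combine per substrate by dominance of
loss: if any effect falls below wild type the substrate takes the minimum,
otherwise the maximum gain applies. This is a deliberate no-epistasis
convention (real campaigns show context-dependent cases); triplicate
ratings add ±1 with probability `noise_prob` (default 0.1) and clip to 0..4,
reflecting that replicate halo calls rarely differ by more than one shade.

The generator does **not** emulate polymerase mutational spectra
(transition/transversion bias), expression-level variation, plate-position
effects, or genuine epistasis. Passing recovery tests therefore shows the
pipeline's logic is sound under its stated statistical assumptions, not that
those assumptions hold for any particular wet-lab dataset.

There is no quantitative halo-size model to calibrate against; the ordinal
encoding above is this package's convention. Likewise
`reference_screen_fixture()` reconstructs per-library rating sets that
reproduce the reported screen marginals (percent active, counts of short-
and long-discriminative clones) using the smallest active count consistent
with each printed percentage — it is a tabulation fixture, not clone-level
data.

## Variant calling and library QC

Equal-length variants are compared codon-wise against the reference (the
fast path, exhaustively verified against a brute-force per-codon oracle);
length mismatches are globally aligned (affine gaps, leftmost placement) and
any gap marks the clone `frameshift` with no substitution calls; a premature
stop marks it `truncated`. DNA mutation counts are nucleotide-level and
include synonymous changes; amino-acid substitution lists exclude them.
Positions are 1-based protein coordinates (codon index + numbering offset).

`library_qc` reports two rate estimators, reflecting a genuine ambiguity in
how such tables are normalized: per total bp sequenced (primary) and per
designed mutated-region length; they coincide when sequencing covers exactly
the mutagenized segment (the default assumption). Mutations per reassembled
gene is the region-rate × region length, i.e. the mean per-clone count.
Frameshift and low-quality clones are excluded from QC; truncated clones are
**included** — a nonsense change is still a countable nucleotide
substitution, and conditioning on "no premature stop" would preferentially
drop high-count clones and bias the rate estimate low (≈ 0.1 mutations/gene
at a 1.7-mutation load). Truncated clones are still excluded from phenotype
mapping.

## Phenotyping

Triplicate ratings consolidate by median; a replicate range > 1 warns but
does not reject. Classification thresholds (config-exposed, defaults in
`Thresholds`): active ⇔ rating ≥ 2 ("unequivocal" halo made numeric);
strong discrimination ⇔ preferred substrate ≥ 3 and the other ≤ 1; weak ⇔
preferred = 2 and the other ≤ 1; otherwise none. The rule is monotone
(raising the preferred rating never removes a call, raising the other never
creates one) and assigns at most one direction. Screen summaries count
actives (either substrate) and discriminative calls per direction, with
percent active rounded to a whole percent.

## Hot-spot mapping

Substitution calls join whole-clone phenotype calls; per residue, activity
values take the maximum over supporting variants and the discrimination
category is the union of supporting calls (`both` when distinct variants of
opposite phenotype substitute the same residue). Multi-substitution variants
are not deconvoluted — every residue they substitute inherits the whole
variant's phenotype — but single-substitution support is counted separately
(`n_single_sub_variants`) to flag unambiguous attributions. Aggregation is
order-independent by construction (max/union).

`part_enrichment` counts distinct discriminative positions per part and
scans a sliding window (default width 29 residues, the length of the
217–245 lid motif) for the densest interval per direction, counting `both`
positions for each direction and breaking ties to the leftmost start.

`write_bfactor_pdb` edits fixed-width PDB text directly: only columns 61–66
of ATOM/HETATM records change (`%6.2f`), every other byte is preserved —
which is why the writer is hand-rolled rather than delegated to a structure
library that would re-serialize records. Channels: per-residue short or long
activity value, or the category code (none = 0, short = 1, long = 2,
both = 3; the numeric encoding is this package's convention chosen to give a
four-colour scheme in any viewer). Unmapped residues get the map's
background value (default 0). Multi-chain files require an explicit chain
selector (residue numbers may collide); insertion codes are rejected. The
construct-to-structure numbering offset defaults to 0 and is config-exposed,
since signal-peptide offsets vary between constructs and deposited
coordinates.

## Kinetics

Specific activity from an initial-rate absorbance slope of p-NO2-phenyl
ester hydrolysis:

    S.A. [U/mg] = slope / (l × ε) × (Vt / Ve) × 1 / [Ce]

with ε(p-NO2-phenolate) = 18.1 mM⁻¹ cm⁻¹, path length l in cm, volumes in
mL, protein in mg/mL; 1 U = 1 µmol/min (45 °C reference). Slopes are fit by
ordinary least squares over a configurable linear window; negative fits clip
to zero with a warning. Relative activity is a percentage of a named
reference; selectivity is the activity ratio between two substrates.
Background-hydrolysis blank subtraction is available but off by default.
The assay wavelength is recorded as metadata only; the formula is agnostic
to it. Michaelis–Menten fitting is out of scope.

## Pipeline

`run_pipeline` chains simulate/ingest → call → phenotype → map → kinetics
through the declared tabular/FASTA/PDB interfaces only, funnels all
randomness through one generator seeded from the config, and writes a
manifest (seed, parameters, versions) sufficient to reproduce every output
byte-identically. In simulated runs the kinetics panel uses a generator
convention tying the ordinal ratings to activities: S.A. = reference
activity (default 0.4 U/mg) × rating / wild-type rating, for a C4 and a C16
ester channel. When no structure is supplied, painting targets a synthetic
toy structure of matching length so the artifact set is complete.

## Problem sizes in tests

The bundled test and acceptance runs use the study's screening scale where
it matters (384-clone Part-2 campaigns, 20 independent seeds for hot-spot
recovery; 2000 clones for the library-QC rate check) and smaller sizes
(25–400 clones) for unit-level properties. Oracle-equivalence checks run
1000 random mutants against the brute-force caller.

## Known limitations

- The ordinal phenotype generator and the numeric classification thresholds
  are declared conventions; only their categorical consequences are
  validated against the reported screen tables.
- No indel calling beyond frameshift rejection; no sequencing-quality model.
- PDB fixed-width only (no mmCIF), single conformer, no insertion codes.
- Selectivity analysis assumes activities measured under identical assay
  geometry; no temperature or pH corrections.
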