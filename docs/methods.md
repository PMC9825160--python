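# Methods

## Overview

`ribodesign` implements the dry-lab half of a computationally guided
ribosomal-RNA mutagenesis loop: pose an identity-design problem against a
rigid structural scaffold, search the variant space by Monte Carlo under an
energy score, select candidates by that score, and analyze the activity
screens and conservation data that come back from the wet lab.  The
production workflow scores candidates with an all-atom stepwise Monte Carlo
structure calculation; that score function is deliberately outside this
package.  It enters either through score files (`design.read_scorefile`,
Rosetta-compatible `SCORE:` dialect) or through any `EnergyModel` subclass.
The bundled `ToyEnergyModel` is a stand-in with the same contract, not an
approximation of the all-atom score; every number it produces is in its own
arbitrary energy units.

## Structural context

A design problem is defined by a set of designable residues in a reference
structure (PDB or mmCIF, parsed by gemmi; author numbering preserved so
large-subunit rRNA positions like 2225 or 2552 survive round-trips).  The
context is the set of residues with at least one heavy atom within a
distance sphere of any heavy atom of a designed residue; the default radius
is 25.0 Å, enough for several shells of indirect interactions.  Decisions
that the distance criterion leaves open were fixed as follows:

* residue-level inclusion by **any heavy atom** (hydrogens excluded) rather
  than centroids — the conservative structural convention;
* ties at exactly the radius are **included** (`<=`), so the boundary set is
  reproducible;
* ions and proteins inside the sphere are kept as rigid context;
* the *native* model holds designed + neighbor residues, the *starting*
  model neighbors only; both are written as fixed-width PDB v3.3;
* FASTA export writes RNA lowercase and protein uppercase, one record per
  contiguously numbered chain segment, headers carrying `chain:start-end`;
* the minimize-adjacent list is the primary-sequence flanks (n−1, n+1) of
  every designed residue, deduplicated, excluding designed residues — these
  stay energy-minimizable next to the flexible designed region.

## Libraries

The standard library style excludes the wild-type base at every designed
position, written with IUPAC codes b/d/h/v ("not a/c/g/u"); an 8-position
library therefore spans 3^8 = 6561 variants.  Enumeration is exhaustive in
lexicographic order (a<c<g<u) when the space fits under a cap, otherwise a
seeded uniform sample without replacement.  Combinatorial constructs are
the Cartesian product over per-region option sets {WT} ∪ variants — a
(2,2,2,1)-variant menu over four regions yields 3·3·3·2 = 54 constructs
including the all-WT control.  Applying a construct to a reference sequence
checks that the reference base at every library position matches the
recorded wild type, which guards against numbering drift.

## Monte Carlo design and forward folding

`design_trajectory` is a Metropolis walk over identity space: each cycle
mutates one uniformly chosen position to a uniformly chosen allowed base,
scores the proposal through the model's noise channel, accepts downhill
always and uphill with probability exp(−Δ/T) at T = 1.0 energy unit, and
records the lowest-scoring frame seen.  The backbone add/delete moves of
the production sampler are abstracted into a zero-mean Gaussian noise
channel of width σ per evaluation (default 1.0 for simulation studies):
that single knob reproduces the statistics that matter downstream —
variable best-frame frequencies across trajectories, and the need for
equal-budget re-scoring.  Default cycle counts follow the production
recipe: 1000 for simple helices, 2000 for structurally complex regions.
Campaigns run independent trajectories (production ≥ 10 000; desk scale
hundreds — the identity space at desk scale is covered many times over and
every evaluation is cheap), with per-trajectory seeds spawned from one
campaign seed, so all results are bit-reproducible.  Ties are broken
lexicographically everywhere.

Forward folding re-scores *fixed* sequences under an equal sampling budget
(default 500 cycles × 400 models per sequence, applied to the top 200
campaign sequences): each model is the best of n_cycles noisy evaluations
and the per-sequence score is the minimum over models.  Equal budgets make
best scores comparable across sequences, which a design campaign's variable
sampling frequencies cannot guarantee.

The toy energy scores a duplex position-wise: −3.0 per Watson–Crick pair
(au/ua/cg/gc), −1.5 per wobble (gu/ug), +1.0 per other pair, and −0.5 for
each intra-strand adjacent position pair whose members both sit in WC
pairs.  The constants are package defaults chosen so WC-rich, stacked
helices score best; they are configurable and carry no physical meaning.

## Selection protocols

* **Spanning** (default n = 50): evenly spaced score quantiles by the
  nearest-rank rule (rank = ⌈q·N⌉), stepping over already-used ranks, so
  both extremes are always included.  The even-quantile rule is a declared
  convention — the spacing of the original spanning panel is not specified.
* **Top fraction** (defaults 30%, n = 14): rank-based — eligible rows are
  the first ⌈f·N⌉ of the ranking, of which the best n return.  "Top 30%"
  is read as a fraction of sequences, not of the score range.
* **Randomized controls**: n distinct variants drawn uniformly over the
  *fully* randomized space (alphabet n = all four bases), because
  randomized primers can re-draw the wild-type base — unlike the designed
  library's anything-but-WT exclusion.

## Screen analytics

Activities are normalized per batch as A_rel = mean(replicate maxima) /
mean(WT replicate maxima); mean-of-replicates is used rather than
per-replicate normalization (the two differ only by replicate pairing, and
mean-of-replicates is the simpler estimator).  Replicate SD is propagated
as sd/WT-mean for reporting only.  Negative raw values clip to zero with a
warning.

The score–activity relationship is summarized by the Pearson correlation
with a two-sided t-test and an OLS fit line with pointwise 95% confidence
band (statsmodels).  Pearson with a linear fit matches how the
relationship is usually displayed; Spearman is not computed.

Epistasis between regions is measured against a multiplicative null:
for a combination, expected A_rel = Π constituent single-region A_rel, and
the deviation D = observed − expected.  Positive D flags synergistic
rescue (e.g. an inactive double rescued to 0.43 by a third region gives
D = +0.43), negative D incompatibility (two above-WT singles combining to
zero give D = −(1.1·1.05) = −1.155).  The multiplicative null is the
natural choice for WT-relative ratios; D is a package-defined statistic
and is labelled as such in outputs.

Viability concordance: among constructs whose in-vitro activity exceeds a
threshold (default 1/3 of WT), the fraction that support life in a cell
whose only ribosomes are the mutant, with the full 2×2 table.  The
threshold is the screen-to-cell heuristic and is configurable.

## Conservation

Conservation of an alignment column is 100 × (modal-base count)/(non-gap,
unambiguous letter count); ambiguity letters are excluded from both counts,
all-gap columns are missing.  An alternative metric (`metric="reference"`)
scores agreement with the reference row's base instead of the modal base.
Columns map to reference numbering by walking the degapped reference row
(1-based plus an offset).  Region summaries are unweighted arithmetic
means plus counts strictly above supplied thresholds (91% and 95% by
default).

## Synthetic data

The fixtures module generates every external input class at test scale:

* **Ideal A-form duplex** — rise 2.81 Å, twist 32.7°/bp, three
  pseudo-atoms per residue (P at radius 9.2 Å, C1′ at 9.4 Å, base centroid
  at 3.5 Å; inter-strand phase 67.2° so paired C1′–C1′ ≈ 10.4 Å and
  consecutive P–P ≈ 5.9 Å).  Coarse residues are sufficient for every
  geometric operation in scope and keep fixtures dependency-free; they do
  not support clash checking or base-level geometry, which are out of
  scope.
* **Simulated screens** — construct activities follow
  A_rel = max(0, α + β·score + ε), ε ~ N(0, σ), scores uniform over a
  stated range.  Defaults (α = 0.26, β = −1/19, range −15..4) place
  activities between ≈1.05 at the best toy-energy score and ≈0.05 at the
  worst, with σ = 0.385 giving an implied correlation near −0.6 — the
  regime of the benchmark helix screen.  `ScreenSimSpec.from_target_rho`
  calibrates σ by bisection against a fixed internal seed set, because
  zero-clipping biases the analytic no-clip formula slightly.
* **Simulated alignments** — each column's modal base planted at a target
  frequency (remaining mass uniform over the other three bases, so targets
  ≤ 25% are rejected), independent gap draws, an ungapped reference row
  spelling the modal bases.

What passing tests show — and do not show — about real data: the
generators plant exactly the structure the analyses look for (a linear
score–activity link, independent per-column conservation, threshold-driven
viability).  Real screens have batch effects, real energy landscapes are
not linear in activity, and real alignments have phylogenetic correlation
between rows; recovering the planted parameters validates the estimators
and the pipeline plumbing, not those biological assumptions.

## Benchmark pipeline and problem sizes

`pipeline.run_benchmark` chains the whole loop at desk scale: a 300 ×
150-cycle campaign over the 8-position benchmark duplex library (6561
variants), forward folding of the top 200 sequences at the full 500 × 400
budget, top-30%/n=14 selection, 14 randomized controls, simulated screens,
and planted viability.  These sizes cover the toy space exhaustively many
times over; the production recipe's larger numbers compensate for a vastly
more expensive, noisier score function, not a larger identity space.  One
quirk of the toy energy is a degenerate optimum (81 sequences share the
global minimum −15.0), so the deterministic scores of a campaign's top
sequences carry no spread; the spanning screen panel is therefore emulated
directly by the generator's uniform score distribution, which is also what
"scores spanning the energy range" describes.

## Known limitations

* The toy energy has no notion of 3D conformation, non-canonical pairs
  beyond the wobble class, or context interactions; scores from it must
  never be compared with all-atom scores.
* Sphere selection is O(designed-atoms × structure-atoms) per residue —
  fine up to ribosome-sized structures but not optimized with spatial
  indexing.
* mmCIF is accepted on input only; all structural output is PDB v3.3.
* The epistasis statistic assumes constituent effects are independent and
  multiplicative; it flags interactions, it does not model them.
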