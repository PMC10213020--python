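# Methods

## Coordinate model and geometry

Structures are chains of residues with explicit atom records; all geometry
downstream of parsing uses 1-based author residue numbering and inclusive
region bounds, matching the UniProt P04637 convention for the p53 C-terminal
region (301–393). PDB and mmCIF parsing is delegated to gemmi; alternate
locations resolve to the highest-occupancy copy (ties keep the first
encountered) so parsing is deterministic. PDB output is plain ATOM-record
formatting with occupancy 1.00 and an optional per-residue score in the
B-factor column.

**Radius of gyration.** Rg = √(Σ wᵢ‖rᵢ − r̄‖² / Σ wᵢ). The default mode is
`ca_only` (unit weights): the refiner and the synthetic generators are
Cα-coarse-grained, so an all-atom mass weighting would only re-weight the
same trace. `all_atom_mass_weighted` is available for full-atom inputs.
For the coarse-grained conformers compared here the two modes differ by
far less than the ensemble spread, so the choice does not affect rankings.

**SASA.** Shrake–Rupley with a deterministic golden-spiral lattice of 960
points per atom and probe radius 1.4 Å. Van-der-Waals radii come from a
built-in element table (C 1.7, N 1.55, O 1.52, S 1.8, H 1.2 Å; unknown
elements configurable: error or 1.8 Å with warning). The fixed point set
makes areas exactly reproducible across runs and platforms; at 960 points
the isolated-sphere error is below 2 %. Relative side-chain SASA divides
the summed side-chain atom areas by an approximate per-amino-acid maximum
(extended Gly-X-Gly context). That reference table is approximate by
nature — published maxima differ by a few Å² between sources — which is
acceptable here because relative SASA is only consumed through coarse
class bounds (see scoring). Synthetic residues carry a single
pseudo-side-chain sphere and normalize to its isolated area instead, so
their relative values are exact.

## Restraints and the ensemble plan

Interpeptide cross-links become Cα–Cα upper-bound restraints with mean 15 Å
and SD 5 Å, one per unique unordered residue pair, applied to every chain of
the homotetramer symmetrically. The restraint potential is a flat-bottom
quadratic: 0 for d ≤ mean, ((d − mean)/sd)² above. The exact functional
form behind an "upper bound with a standard deviation" is not uniquely
determined; the flat-bottom quadratic is the conventional reading and is
flagged as an interpretation.

Three strategies: `all` (every restraint, every chain), `reduced` (a uniform
6-of-12 subset drawn independently per chain, giving asymmetric tetramers),
`random` (restraints between uniformly drawn distinct residues in 301–393;
duplicate pairs across a set are allowed by default, a flag enforces
distinctness). The default plan is 12,000 `all` models plus 100 sets × 20
models each for `reduced` and `random` — 16,000 models. Every manifest
entry carries a seed derived deterministically from (master seed, strategy,
set index) via `numpy.random.SeedSequence`, and each model's seed derives
from its entry seed and model index, so any single model is re-derivable in
isolation. A `scale_down` factor divides the totals uniformly (factor 100
gives 120 + 20 + 20 = 160) for desk-scale runs.

## Refinement

The refiner is a coarse-grained stand-in with the same contract as a
restraint-driven comparative-modeling refinement (template + upper-bound
restraints → conformers): Metropolis Monte-Carlo over Cα coordinates.

Energy terms (reduced units):

* restraint: the flat-bottom quadratic above, summed over chains and
  restraints;
* pseudo-bond: ((d − 3.8)/0.2)² on consecutive Cα — stiff enough that
  accepted moves keep the chain chain-like;
* clash: max(0, 4.0 − d)² on all non-bonded pairs (|i−j| > 1 within a
  chain; every inter-chain pair);
* core (optional): w·Σ‖rᵢ − rᵢ^template‖² over a residue window, default
  weight 3 per residue per Å², which holds an ordered core within ~2 Å RMSD
  of the template while tails relocate freely.

Moves: pivot (rotate a chain segment about a random axis through a pivot
residue), crankshaft (rotate interior residues about the axis between two
fixed residues) and single-residue perturbation. Pivot and crankshaft are
rigid rotations about axes through chain atoms, so they preserve every
pseudo-bond exactly; local perturbations that would stretch a bond beyond
±0.5 Å are rejected outright. Energy updates are incremental: only terms
touching moved atoms are recomputed, which keeps a step at O(moved × total)
distances.

The temperature schedule is geometric from 2.0 to 0.05 over the run
(default 20,000 steps); at temperature → 0 the acceptance rule reduces to
pure descent. Moves producing non-finite energies are rejected. The
sampler tracks the best-seen conformer and returns it, so the final energy
never exceeds the template's; a guard re-checks this against float drift in
the accumulated energy. Everything is deterministic given the seed.

Desk-scale settings used by the acceptance tests: scale-down factor 100
(160 models) and 2,000 MC steps per model. Two thousand steps do not fully
converge a 4×93-residue system — they are chosen as the point where the
ensemble already separates cleanly by strategy and compaction, which is
what the acceptance properties measure.

## Scoring and ranking

Cross-links: per link, one distance per chain policy — default
`min_over_chains`, because in a homotetramer of identical chains an
intramolecular link is satisfied if *any* protomer satisfies it. Distance
bands: satisfied ≤ threshold (BS²G 25 Å, DSBU 30 Å), tolerated within a
further 10 Å flexibility band, violated beyond. Points 1 / 0.5 / 0,
averaged into an xl score in [0, 1]. Averaging (rather than summing) makes
models with different numbers of resolvable links comparable; whether
tolerated links should incur a distance-dependent rather than constant
penalty is left configurable through the points map.

Footprinting: the predicted accessibility class comes from relative
side-chain SASA with bounds buried ≤ 0.2 < partial ≤ 0.4 < accessible; the
observed class from labeling yields (buried < 5 %, partial 5–10 %,
accessible ≥ 10 %, resolved as the exhaustive partition [0,5), [5,10),
[10,100]). Match/adjacent/opposite score 1 / 0.5 / 0, averaged. The
stepwise matrices and class bounds are explicit defaults in the
`ScoringMatrix` and freely overridable; they preserve the
stepwise-with-penalized-outliers structure without hidden constants.

Lysine pKa: a burial-shift heuristic, pKa = 10.4 − 2·(1 − rel SASA)
clamped to [8.4, 10.4] — monotone non-increasing in burial, overridden
verbatim by an external per-residue table when supplied. pKa is reported
but excluded from the default combined score: for IDR lysines the side
chain is rarely locked into the interaction networks that shift pKa, so
the value does not discriminate between conformers.

Ranking: combined = xl + footprint score; ties break by higher xl score,
then model id. A Pareto front over the two score axes is available for
selection plots. The compaction statistic is the Spearman rank correlation
between combined score and Rg over an ensemble; negative values mean
compact models score better.

## Quantitative isotope-pair analysis

Monoisotopic masses come from a built-in table (C 12 exactly, H 1.00782503,
D 2.01410178, O 15.99491462, N 14.00307401, S 31.97207117); the mass of a
composition is the weighted sum, verified in tests against an independent
proteomics mass calculator.

A pair ratio is D₄/D₀ for forward labeling and D₀/D₄ for the label-swap
replicates, so the ratio always reads bound/free. Zero denominators are
missing values, excluded and counted. Per link, ratios aggregate in log
space (the geometric mean treats enrichment and depletion symmetrically);
links with fewer than 2 usable ratios out of the 6-replicate design are
dropped. Significance is a two-sided one-sample t-test of log2 ratios
against zero — the natural minimal test for this design. A link is called
enriched only when p < 0.05 *and* |log2FC| ≥ 1; the fold-change threshold
is a configurable default (1 log2 unit), and no multiple-testing
correction is applied by default (Benjamini–Hochberg is available via a
flag).

## HDX

Corrected fraction = (m_t − m_undeuterated)/(m_control − m_undeuterated),
clamped to [0, 1.05] with a flag; the control is the protein equilibrated
in 80 % D₂O, so the fraction is control-relative rather than absolute.
This cancels back-exchange and calibration offsets exactly (adding any
constant to all three masses leaves the fraction unchanged). An absolute
conversion would additionally need the effective labeling D₂O fraction
(nominally 90 % at 10-fold dilution ≈ 81 %); it is not needed for
control-relative comparisons. Exchangeable amides per peptide = length − 1
− prolines after the first position (N-terminal amine and prolyl nitrogens
do not report). Validation is the Spearman correlation between corrected
uptake and per-peptide mean relative side-chain SASA at a chosen time
point; default time grid 30/60/120 s, arbitrary grids accepted.

## Synthetic data

The generators exist so that every stage runs against data with known
ground truth, offline.

* **Toy tetramer**: the ordered core (326–356) is an ideal-helix bundle —
  four Cα helices (2.3 Å radius, 100°/residue, rise solved so consecutive
  Cα sit exactly 3.8 Å apart) on a 6.5 Å circle, alternating up/down;
  identical for every seed. Tails grow as self-avoiding 3.8 Å random
  walks (minimum separation 3.5 Å) with a bias term: compact mode holds
  tails in a shell around the core (attracted beyond 24 Å from the core
  centroid, repelled inside 11 Å), extended mode pushes them outward.
  Dead ends backtrack up to three steps and re-try; a persistently stuck
  chain regrows with an incremented sub-seed. Every third tail residue is
  designated lysine (echoing the lysine-rich CTD), core residues are
  leucine, the rest serine.
* **Pseudo side chains**: Cα-only models get one 2.3 Å sphere placed 2.5 Å
  along the local chain normal per residue. This gives a burial-sensitive
  side-chain SASA signal without building side chains; relative SASA
  normalizes to the isolated pseudo-sphere area.
* **Cross-links**: n unique lysine pairs whose Cα–Cα distance in at least
  one chain of the ground-truth conformer is within the linker threshold —
  every simulated link is satisfied by construction in its source model.
* **Footprinting**: mean yield = 2 + 28 × relative side-chain SASA
  (the ~2–30 % range of real dead-end data), multiplicative log-normal
  noise of given CV (mean-corrected), identical means in both states by
  default — the null of accessibility unchanged upon DNA binding.
* **Quant**: per-replicate intensities log-normal around a true ratio, the
  last half of replicates with swapped label roles.
* **HDX**: peptides tile the region (default length 8, half-overlapping);
  the target corrected fraction is mean relative SASA × a saturation
  factor (0.6/0.8/0.9 at 30/60/120 s), centroid masses are back-computed
  from the target so the correction inverts the construction exactly at
  zero noise.

What the generators do *not* emulate: realistic disorder statistics (no
Flory scaling), residue-specific cross-linker reactivity, peptide
misidentification, spectral interference, DNA. Passing the recovery and
compaction tests therefore shows the pipeline's statistics behave correctly
under their stated assumptions — monotone accessibility signals, distance-
bounded links — not that they would rank real p53 ensembles identically.

## Numerical and degenerate-input choices

* SASA point set and all samplers are seed-deterministic; no global RNG.
* Constant score or Rg vectors give a flagged NaN correlation rather than
  an error; fewer than 3 points is an error.
* Relative SASA above 1 is reported up to 1.2 with a clamp flag.
* A differential link whose ratios are all exactly 1 gets p = 1; identical
  non-unity ratios (zero variance) are treated as maximally consistent.
* Dead-end links are rejected as distance restraints with an explanatory
  message; out-of-region cross-links are skipped with a warning and
  reported in the per-link detail.
* Refinement of single-residue chains returns the input with a warning.

## Known limitations

* The refiner is a minimal-physics sampler, not a replacement for a
  force-field refinement; its purpose is to produce restraint-consistent,
  chain-like conformers whose *scoring* can be studied.
* The pKa heuristic captures only the burial shift, not interaction
  networks.
* Footprinting class bounds (0.2/0.4 relative SASA) and the labeling-yield
  map are calibrated to the synthetic generator's scale; real data may
  need different bounds, which is why they live in the `ScoringMatrix`.
* Residue-level HDX deconvolution from overlapping peptides is out of
  scope; the correlation operates at peptide resolution.
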