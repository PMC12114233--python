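# Methods

## The classification problem

Docking a ligand library into one or more structures of a target yields
a score matrix (compounds × structures) in which lower (more negative)
scores mean stronger predicted binding, with failed docks as missing
entries. Activity ground truth is a pChEMBL value per compound
(−log10 molar IC50/Ki); the binary label is active iff pChEMBL > 8
(strictly — a value exactly at 8 is inactive). Compounds whose multiple
activity measurements straddle the cutoff get conflicting labels and are
removed at labeling; after merging duplicate entries by compound id, all
remaining multi-valued compounds are removed as a second filtering stage
so every modelled compound carries exactly one activity value.

## Threshold Method

Each class's score distribution is estimated with a Gaussian-kernel KDE
using Scott's bandwidth rule, fitted independently per class (scipy's
`gaussian_kde`). The decision cutoff is the crossing point of the two
density curves: at the crossing the misclassified density mass is
balanced, penalising false negatives and false positives equally — a
deliberately liberal screening cutoff compared with strategies that
minimise false positives first.

Numerical procedure: the density difference is evaluated on a 2048-point
grid spanning the pooled score range padded by 3 bandwidths on each
side; crossings are located by sign change with linear interpolation.
KDE tails can produce spurious crossings, so among multiple crossings
the one lying between the two class means and nearest their midpoint is
chosen. Orientation is inferred from the class means, never hard-coded:
raw docking scores put actives *below* the cutoff, calibrated
(pChEMBL-approximating) scores put them *above*. A score exactly at the
threshold is classified inactive; this boundary convention is arbitrary
but fixed and documented. Degenerate inputs (constant score vectors, or
densities that never cross inside the grid) raise errors rather than
returning a silent cutoff.

On two equal-variance Gaussian classes the intersection converges to the
midpoint of the means; the test suite checks recovery of −9.0 from
N(−10,1) vs N(−8,1) at 5000 draws per class within ±0.1.

## Ensemble docking (rank-by-number)

All subsets of the structure panel with 2 ≤ size ≤ K are enumerated
(26 subsets for K = 5). A compound's ensemble score is the arithmetic
mean of its scores over the subset's members — the rank-by-number
consensus; rank-by-rank and voting variants are deliberately out of
scope. A compound missing a score in *any* member structure is excluded
from that ensemble rather than averaged over the available subset: an
available-case mean would mix compounds whose scores average different
structure panels and bias the comparison. Each subset's threshold model
is fitted and evaluated on its own retained compound set, and subsets
are ranked by MCC (ties: smaller subset, then lexicographic members).

## Similarity-weighted calibration

The calibration corrects a query docking score by the
similarity-weighted mean of the reference ligands' activity/score
ratios (formula in the README). Design choices:

- **ΔG on the pChEMBL scale.** The reference activity entering the
  ratio is the pChEMBL value, not a kcal/mol binding energy; calibrated
  scores then approximate pChEMBL values, which is why the fitted
  thresholds land near the labeling cutoff of 8 and why classification
  of calibrated scores uses the higher-is-active orientation.
- **Fingerprints.** MACCS keys (166 structural keys; the unused
  leading bit of the 167-bit RDKit vector is dropped), Morgan circular
  (radius 2, 2048 bits), and the RDKit path fingerprint (paths up to 7
  bonds, 2048 bits). These parameters are pinned explicitly for
  reproducibility. Similarity is Tanimoto; a pair of empty fingerprints
  is defined as similarity 0 with a warning.
- **Exponent grid.** p ∈ {4, 12, 20, 28, 36, 44, 52, 60}. Higher p
  concentrates weight on the nearest structural neighbours; the weight
  fraction of the uniquely most-similar reference is strictly
  increasing in p (tested). Ties on mean MCC resolve to the smaller p,
  the choice least dependent on the similarity model.
- **Cross-validation.** Stratified 5-fold: per-class shuffle under one
  integer seed, then round-robin assignment, which guarantees per-fold
  class counts differ by at most one (sklearn's splitter is used as a
  cross-check in tests, not as the implementation). Each fold is the
  query set once, calibrated against the union of the other folds, so a
  query never appears in its own reference set. The reported model
  score is the mean fold MCC at the best p; the final cutoff is the
  mean of that p's fold thresholds.
- **Degenerate cases.** Reference ligands with a docking score of 0 are
  excluded before calibration (the ratio divides by the score). A query
  whose total similarity weight ω underflows to 0 is returned
  uncalibrated and flagged.
- **External set.** The external evaluation set is a stratified 20%
  hold-out taken before cross-validation, calibrated against the full
  training set at the selected p and classified at the mean fold
  threshold.

## Paired stereochemistry comparison

`invert_stereocenter` flips the tetrahedral parity of one atom and
returns the canonical SMILES (an involution, tested as such), which is
how an epimerised library is built from an R-configured one. The score
comparison is a classical paired t-test on d = S − R over index-paired
compounds (compounds docked in both libraries), two-sided p from the t
distribution with n−1 df and a 95% CI of mean(d); zero-variance
differences raise a degenerate-case error reporting the constant. The
interaction analysis subtracts per-column bit sums of two binary
ligand × (residue, interaction-type) matrices; columns losing strictly
more than `min_loss` (default 5) interactions are reported with a loss
fraction whose denominator defaults to the S-library's docked ligand
count but is configurable, since the natural denominator (full library
vs docked subset) is ambiguous in practice. Columns that *gain*
occupancy are listed separately; total losses minus gains always equals
the difference of the matrix totals (a conservation identity, tested).

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical shape of a docking campaign,
not docking physics:

- **Two-class score tables** (`simulate_scores`): class-conditional
  Gaussians per structure (the simplest family matching unimodal score
  densities), with a shared latent affinity term so that any two
  structures' scores correlate at ρ; missing entries i.i.d. at a
  dropout rate. Defaults: 500/500 compounds at means −10/−8, σ = 1,
  5 structures, ρ = 0.5.
- **Gliflozin-like library** (`simulate_library_smiles`): combinatorial
  chemistry — one glucose-like C-aryl core with two aryl substituents
  drawn from a 16-fragment pool — rather than random graphs, so
  fingerprint similarity has interpretable structure. Each fragment
  carries a latent activity contribution (SD 0.7 pChEMBL units per
  position) plus residual noise (SD 0.2), giving compounds that share
  substituents correlated activities: the neighborhood signal the
  calibration exploits. Base activity 7.9 puts the library roughly
  astride the pChEMBL 8 cutoff.
- **Full campaign** (`simulate_classification_dataset`): docking scores
  track activity linearly (0.85 score units per pChEMBL unit, negative
  orientation) distorted by (i) a fragment-linked systematic bias
  (SD 0.7 per position) shared by structurally similar compounds,
  (ii) a compound-level error shared across structures, and (iii)
  independent per-structure noise, with σ = 0.8 split ρ = 0.5 between
  (ii) and (iii), and 4% dropout. This decomposition is what makes the
  three methodologies separable: ensemble averaging cancels only (iii),
  similarity calibration can additionally correct (i), and (ii) bounds
  everyone. Default library size 1197 compounds × 5 structures.
- **Paired stereo libraries**: S-scores are R-scores plus a
  Normal(δ, σ_pair²) shift; defaults 291 pairs, δ = 0.26 score units,
  σ_pair = 0.65, R-library at N(−9.5, 0.8²).
- **Interaction matrices**: Bernoulli occupancy with per-column loss
  probabilities applied to set bits.

Passing tests on these generators shows the pipeline's statistical
machinery is correct and that the methodology ordering (calibrated ≥
best ensemble ≥ single structure, checked as a 25-seed median at 400
compounds) follows from the assumed error decomposition. It does not
validate docking accuracy on real chemistry: real score distributions
are skewed and multimodal, real similarity–activity landscapes contain
activity cliffs, and real docking failures are not i.i.d. Problem sizes
in the test suite (120–800 compounds, 5–500 seeds per property) and the
acceptance script (1197 compounds) are the package's own choices
balancing statistical resolution against turnaround.

## Known limitations

- The KDE grid resolution (2048 points) bounds threshold precision at
  roughly the grid spacing; the recorded model stores grid and
  bandwidths so results are exactly reproducible.
- The enrichment-factor top-set uses ceiling(fraction · N) with stable
  sort order at ties; other EF variants differ in tie handling.
- MCC returns 0 with a warning when a denominator factor is zero.
- `run_full_comparison` drives only the synthetic generator; real-data
  runs compose the same library functions directly (reading CSV score
  tables, SMILES/SDF molecules, and activity CSVs).
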