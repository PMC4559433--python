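# Methods

This note documents the statistical models and procedures implemented by
`macrobench`, the defaults it ships with, the numerical choices made where a
definition was genuinely open, and what the synthetic-data generators do and
do not emulate.

## Stability ΔΔG evaluation (`ddg_eval`)

Predictions of the stability change on point mutation are compared to
experimental values with three complementary metrics:

- **Pearson's r** — linear correlation, invariant to the scale of the
  predictions (predicted energies are in the scoring method's own units,
  experiments in kcal/mol). Zero-variance inputs raise an explicit
  undefined-metric error rather than propagating NaN, and reports record the
  gap with its reason.
- **MAE** — mean absolute error, scale-sensitive; the relevant quantity for
  judging confidence in individual design decisions.
- **Fraction correct** — agreement of the three-way stabilizing / neutral /
  destabilizing classification. The neutral band is the *closed* interval
  |ΔΔG| ≤ 1 (boundary values are neutral) on both axes by default; an
  asymmetric predicted band such as the historical [−3, 1.1] convention is
  available via `pred_bounds`. Positive ΔΔG is destabilizing throughout.

**Ensemble aggregation.** When an engine emits an ensemble of scored
wild-type and mutant models, the predicted ΔΔG is the mean of the 3
best-scoring (lowest) mutant models minus the mean of the 3 best-scoring
wild-type models. The mean rather than the sum keeps the value on the
per-model score scale, so MAE against per-mutation experiments stays
comparable; a difference of sums would be 3× larger.

**Alanine-scanning ΔΔG of binding** is assembled from six ΔG-of-folding
terms:

    ΔΔG_bind = (ΔG_complex^MUT − ΔG_A^MUT − ΔG_B^MUT)
             − (ΔG_complex^WT  − ΔG_A^WT  − ΔG_B^WT)

**Curation filters.** Thermostability datasets drawn from literature
compilations are filtered by: (i) an X-ray structure of resolution ≤ 2.5 Å
must exist (non-X-ray methods, missing resolutions, and worse resolutions
are all rejected under the same reason code — a missing resolution is
unverifiable); (ii) when replicate measurements of one mutation (same PDB,
chain, residue, wild-type and mutant amino acid) span more than 2.5 kcal/mol,
*all* records of that mutation are rejected — the spread is max − min, the
strictest reading when more than two replicates exist, and whole groups are
removed rather than averaged, which is what makes the filter idempotent;
(iii) transmembrane proteins are excluded. Kept ∪ rejected always equals the
input, and each rejection carries a machine-readable reason.

## Design evaluation (`design_eval`)

**Sequence recovery** is percent identity between a designed and the native
sequence, optionally over a position subset; a gap never matches anything
but still counts as a scored position.

**Profiles.** Column distributions exclude gaps and unknowns and
renormalize; an all-gap column is flagged empty and excluded from averages.
Entropies are in bits (log₂), which makes the perfectly coupled two-symbol
case below come out to exactly 1.

**Profile similarity.** For column distributions p (natural) and q
(designed), with r = (p+q)/2 and background P₀:

    S(p, q) = ½ (1 − D_JS[p‖q]) (1 + D_JS[r‖P₀])

D_JS is the Jensen–Shannon divergence in base 2 (in [0, 1]). The first
factor rewards agreement between the profiles, the second rewards their
joint divergence from background: matching the background exactly scores
0.5, a shared informative profile approaches 1. D_JS[r‖P₀] is always
well-defined because its mixture argument has support wherever r does, so no
restriction on P₀'s support is needed (zero background entries are
legitimate and occur in the maximal-similarity case). The default P₀ is
uniform (1/20); a user composition can be supplied — natural databases have
a mildly non-uniform composition and results are reported against the
background actually used.

**Covariation.** For columns i, j the plug-in mutual information is
MI_ij = H_i + H_j − H_ij in bits, computed from the rows that are non-gap at
*both* columns so the three entropies share a sample space (this also keeps
MI ≥ 0 exactly). The average-product correction removes shared-ancestry and
noise background:

    MIp_ij = MI_ij − (MĪ_i · MĪ_j) / MĪ

with column means MĪ_i and grand mean MĪ taken over off-diagonal entries
(when MĪ = 0 — an exactly zero MI matrix — the correction term vanishes and
MIp = MI). MIp is standardized per column against its off-diagonal mean and
*population* standard deviation, the two z-scores multiplied, and the signed
square root taken:

    Z_ij = z_i(MIp_ij) · z_j(MIp_ij),   Zpx_ij = sign(Z_ij) √|Z_ij|

The second factor standardizes against column j's statistics; anything else
would make Zpx asymmetric, contradicting its use as a pair score. A column
whose off-diagonal MIp values have zero spread has no defined z-score; its
pairs are reported NaN with a warning and skipped by downstream selection.

No sequence weighting or pseudocounts are applied by default — the plug-in
estimator is the definition being tested — but both matter for real,
redundancy-biased family alignments and are the first thing to add when
feeding such data.

**High covariation and overlap.** Highly covarying pairs are off-diagonal
upper-triangle entries strictly above mean + 2 SD. "Percent overlap" between
natural and designed covariation uses recovery semantics — 100 · |HC(nat) ∩
HC(des)| / |HC(nat)| — since the designed set's job is to recover the
natural pairs; a Jaccard denominator is available where a symmetric measure
is wanted. The metric is undefined (explicit error, reported as a null with
reason) when the reference set is empty.

**Burial.** A residue's neighbors are the other residues whose Cβ lies
within 8 Å of its own Cβ (Cα stands in for glycine and for residues missing
Cβ — the standard convention). Buried: > 14 neighbors (strictly); exposed:
≤ 8; intermediate otherwise. Count 14 is therefore intermediate, not buried.

**Composition** percentages are reported per amino acid or per polarity
category (nonpolar CGAVLIMFWP, polar STYNQ, charged HRKDE); categories must
partition the alphabet, so percentages total 100 by construction.

## Specificity evaluation (`specificity_eval`)

The predicted PWM from a scored designed-sequence set weights each sequence
by exp(−E/kT); the minimum energy is subtracted before exponentiation, an
overflow guard that leaves normalized weights unchanged and gives exact
invariance to a common energy shift. kT defaults to 1.0 score unit and is
exposed everywhere — it is an analysis temperature, separate from any
sampling temperature used to generate the sequences. kT → 0 recovers the
one-hot of the single best sequence; kT → ∞ the unweighted frequencies.

Comparison metrics between experimental frequencies E and predictions P:
AAD = (1/N) Σ|E_i − P_i|; Frobenius = √Σ(E_i − P_i)²; rank-based AUC where
amino acids with experimental frequency ≥ 0.1 form the positive class and P
is the score (midranks, so ties contribute 0.5 — the Wilcoxon/Mann–Whitney
form); and rank-top, the competition rank of the experimentally most
frequent amino acid within P (ties in P share the best rank; ties in E
resolve to the first amino acid in alphabet order). The AUC label
construction (threshold on experimental frequency, per position) is an
implementation choice, as is per-position computation with macro-averaging;
flattened matrix-level AAD/Frobenius variants are also returned. Degenerate
label sets (no positives or no negatives at the threshold) make AUC
undefined for that position and it is excluded from the macro average.

## Loop evaluation (`loop_eval`)

A model is scored in two fixed steps: (1) least-squares (Kabsch, proper
rotation via SVD sign correction) superposition onto the native using the
backbone atoms of all *non*-loop residues — side chains are excluded because
repacking within ~10 Å of the loop would contaminate the frame; (2) RMSD
over the loop backbone heavy atoms with no further fitting. Backbone heavy
atoms default to {N, CA, C, O} — the carbonyl O is part of the backbone —
and {N, CA, C} is available for comparison with three-atom conventions.

Per case: RMSD of the lowest-energy model (energy ties broken by input
order, documented and deterministic); minimum RMSD among the 5 lowest-energy
models (undefined below 5 models — reported as an explicit gap, less
susceptible to stochastic fluctuation than the single-best variant); and the
percentage of models strictly below 1.0 Å ("sub-angstrom"). Benchmark level:
medians over cases, with the even-length median defined as the mean of the
two central values.

The crystal-contact curation rule for long loops counts loop residues with
any heavy atom within 6.0 Å (inclusive at the boundary) of any
symmetry-mate heavy atom; a case passes with at most 5 contact residues.
Generating the symmetry mates (space-group expansion) is the caller's
responsibility — full crystallographic symmetry support is orthogonal to the
metric and heavy; an empty mate set passes trivially with a warning.

## Synthetic fixtures (`synthetic_fixtures`)

Each generator takes an explicit seed and owns its `numpy.random.Generator`;
identical seeds give bit-identical output. Noise is Gaussian throughout so
every expectation is closed-form.

- **ΔΔG datasets**: experimental values N(1.0, 2.0²) kcal/mol — a realistic
  center and spread for single point mutations, which are mostly mildly
  destabilizing; predictions are the experimental value plus independent
  noise with SD σ = 2.0·√(1/r² − 1), giving population correlation r and
  expected MAE σ√(2/π). Planted curation violations (one resolution, one
  transmembrane, one discrepant replicate pair) occupy the last four records
  on request.
- **Alignments**: background columns i.i.d. uniform over the 20 amino acids;
  a planted pair copies its partner column per row with probability equal to
  the coupling strength, so coupling 1 gives MI equal to the column entropy
  exactly and coupling 0 reduces to background.
- **Scored sequences**: sequences are drawn *uniformly* over the alphabet
  and assigned E = −kT Σ log p_truth(s_i), so the Boltzmann weight equals
  Π p_truth and the importance identity makes the weighted frequencies an
  unbiased estimator of the truth PWM. (Sampling from the truth itself and
  using the same energies would concentrate the recovered PWM onto
  p²-normalized columns — the uniform proposal is what makes exact recovery
  possible.) Truth PWMs must be strictly positive.
- **Loop ensembles**: loop atoms are displaced by i.i.d. per-coordinate
  Gaussian offsets with the frame untouched, so the true RMSD is the
  root-mean-square displacement, recorded as ground truth; pseudo-energies
  correlate with the true RMSD at a stated level (1.0 makes the
  lowest-energy model the most accurate by construction).
- **Structures**: `line` and `cluster` packings give analytically known
  neighbor counts for burial tests; `simulate_backbone_structure` emits a
  complete N/CA/C/O backbone with ~3.8 Å CA spacing for superposition tests.
  None of these are physically realistic protein geometry.

Because the generators use i.i.d. columns, additive Gaussian noise, and
idealised geometry, passing tests demonstrate correctness of the *metrics* —
not performance claims about real modeling engines, whose score landscapes,
alignment redundancy, and crystal environments are far from these
assumptions.

## Problem sizes

The verification suite sizes were chosen so each check is decisive but
cheap: 50 alignments of 10×8 for oracle equivalence (exhaustive enough to
hit gap/tie paths), 10 000 records for correlation recovery (Fisher
sampling error ≈ 0.006, well inside the ±0.02 assertion band), 20 seeds ×
500 sequences for covariation power, 100 000 sequences for PWM recovery
(sup-norm sampling error ≈ 0.004 against the 0.01 bound), 10 000 random
rotations × 20 point clouds for superposition optimality, and a 45-case
ensemble for the median oracle.

## Known limitations

- No sequence weighting/pseudocounts by default (see above); plug-in MI is
  biased upward at low depth, which cancels only partially in MIp.
- The discrepancy filter keys replicates on exact (PDB, chain, residue,
  wt, mut) identity; cross-PDB duplicates of the same protein are not
  unified.
- PDB reading keeps altloc ' '/'A' only and the first MODEL by default;
  mmCIF and multi-model NMR statistics are out of scope.
- Symmetry-mate generation and loop-sampling protocols are inputs, not
  features.
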