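# Methods

## The model

`sdscore` treats a missense substitution as a small perturbation of a
folded protein and asks how many independent structural liabilities it
carries.  Each variant is reduced to seven boolean deleterious-direction
indicators — sequence-consensus deleteriousness, physico-chemical
magnitude of the change, glycine/proline involvement, burial, conserved
surface-patch membership, domain membership, and predicted
destabilization — and the structural disruption score (SDS) is simply
their count.  The underlying assumption is additive and deliberately
crude: no weighting, no interaction terms.  That makes the score robust
to the very small cohorts (tens of case variants) this method targets,
where fitting weights would overfit immediately, and keeps every point of
the score interpretable as a named mechanism.

The indicator set is not arbitrary: on a labelled cohort the package
tests every candidate feature with a one-tailed Fisher's exact test
(positive = known causal, negative = known neutral variants in the same
proteins) and reports which are significantly enriched in the causal
direction.  The seven canonical flags are those that replicate across
cohorts; the score is always computed over these seven even when a
particular cohort's significant set differs, because a score with a
data-dependent maximum is not comparable across studies.  Enrichment
output is reported alongside so a user can opt into a different set
deliberately.  Site conservation (3/3 conservation calls) is never
scored: its enrichment direction is cohort-dependent, so it is only
reported.

## Inputs and their provenance

The pipeline consumes external predictor outputs as columns of a
tab-separated annotation table — six deleteriousness calls, three
conservation calls, ΔΔG (kcal/mol, positive destabilizing), the sequence
non-optimality Γ (the sum of stabilizing ΔΔG values over all mutations at
the site; strongly negative values mark residues optimized for function
rather than stability), normalized B-factor and RMSF, a conformational
flexibility probability P(Flexible), surface-patch and domain membership,
and the gene-level residual variation intolerance score (RVIS).  It
never calls the upstream services.  Calls are consumed as categories;
raw-score dichotomization rules (e.g. SIFT ≤ 0.05) can be supplied in the
config and are applied, with logging, only where the call column is
absent.

What the package computes itself, given a PDB structure: relative
solvent accessibility, stabilization-center membership, and
disulfide-bond geometry (Sγ–Sγ < 2.5 Å).  Protein positions are 1-based
UniProt coordinates; PDB numbering is used verbatim and a per-chain
offset in the config aligns the two, mirroring the manual mapping step
such studies perform.

## Thresholds and their defaults

| parameter | default | note |
|---|---|---|
| deleterious count | ≥ 4 of 6 | missing calls count 0; coverage is reported separately |
| Grantham distance | ≥ 100 | published matrix, see below |
| RSA buried | ≤ 20 % | boundary inclusive |
| ΔΔG bands | (−0.5, 0.5) no change; (−2, −0.5] mild and ≤ −2 strong stabilizing; [0.5, 4) mild and ≥ 4 strong destabilizing | kcal/mol; the ≥ 0.5 bound is the scored flag |
| Γ non-optimal | ≤ −5 kcal/mol | reported, not scored |
| B-factor / P(Flexible) tails | 2.5 / 97.5 percentiles | RMSF uses 0.5 / 99.5 |
| fixed fallback cutoffs | B-factor (−0.537, 1.17); RMSF (−0.607, 1.195); P(Flexible) (0.158, 0.860) | used when < 40 pooled values |
| priority threshold | SDS ≥ 4 | |

Dynamics/flexibility cutoffs are empirical percentiles of the score
distribution pooled over *all rows given to the scoring call* (linear
interpolation between order statistics).  Published fixed cutoffs are
shipped as fallbacks because percentiles derived from a handful of
variants are meaningless; the crossover is 40 values.  All threshold
comparisons are boundary-inclusive exactly as written above.

## Grantham distance

The published 20×20 integer matrix is primary; the
composition/polarity/volume formula (α = 1.833, β = 0.1018, γ = 0.000399,
global scale fixed so the 190-pair mean is 100) is implemented as a
cross-check.  The two agree to integer rounding for 188 of 190 pairs;
Asn–Glu differs by 1.1 and Asp–Trp by ~10 *in the original publication
itself*, so the matrix — which is what downstream annotation tools cite —
is treated as ground truth and the property test excludes exactly the
Asp–Trp pair.

## Solvent accessibility

SASA is Shrake–Rupley with probe radius 1.4 Å, 2000 sphere points per
atom, and per-element van der Waals radii C 1.70, N 1.55, O 1.52,
S 1.80 Å (others 1.70 Å).  RSA normalizes a residue's SASA by the
maximal accessibility of its type, defined as the central-residue SASA of
an extended Ala-X-Ala tripeptide.  That reference is computed once per
residue type by the package's own peptide builder (ideal backbone
geometry at φ = ψ = 180°, full heavy-atom side chains from the chemical
component dictionary superimposed via the N/CA/C triad) with the same
probe and radii as the production SASA — so RSA = 100 means exactly "as
exposed as the reference conformation" and the normalization cannot drift
from the radii table.  A user-supplied per-residue reference table is
accepted in the config (`max_asa_overrides`).  Values are reported
uncapped; unusual conformations can exceed 100 %.  Tests require
agreement within 2 % per residue against an independent 20000-point
Monte-Carlo estimator.

## Stabilization centers

A residue pair is a long-range stabilization-center candidate iff the two
residues are ≥ 10 apart in sequence within one chain and some heavy-atom
pair between them lies closer than the sum of the van der Waals radii
plus 1.0 Å.  (The contact criterion is sometimes abbreviated in print as
"sum of van der Waals radii < 1 Å", which read literally is physically
impossible; the +1.0 Å margin is the original definition.)  The full
mutual-contact-fraction refinement and the conservation requirement of
the upstream tools are not implemented; a precomputed membership column
is accepted instead.  Note that an ideal α-helix (1.5 Å rise per
residue) cannot contain such pairs — any ≥ 10-separated pair is ≥ 15 Å
apart — so helices are a guaranteed-empty test case and non-empty checks
use a folded two-strand fixture.

## Statistics

Fisher tests are exact one-tailed hypergeometric probabilities with the
direction declared a priori per feature (causal-direction features tested
for enrichment in positives, neutral-direction in negatives).  No
multiple-testing correction is applied by default — the feature count is
seven and α = 0.05 is per feature; a Bonferroni flag exists.  Continuous
measures are compared with pooled-variance (not Welch) two-sample
t-tests, df = n₁ + n₂ − 2, which is the form the reported degrees of
freedom imply.  The leave-one-component-out analysis regresses an
external composite deleteriousness score on the SDS (ordinary least
squares; R² and the two-tailed p of the slope), then repeats after
removing one flag at a time, also reporting how many variants' scores
the removal changed.

## Priority-list rules

Filtering order is fixed: threshold (SDS ≥ 4), tolerance partition,
flexible-site exclusion, curated inclusion.  RVIS > 0 is high tolerance,
< 0 low; exactly 0 means "as expected" and is classed high (logged),
since low tolerance denotes *fewer* variants than expected.  Exclusion
removes priority variants whose site is conformationally flexible — the
one feature enriched among neutral variants — and never touches
non-priority records.  Low-tolerance variants need an explicit "likely"
disease-curation value to enter the final list; the package does no
literature mining, so reproducing a curated final list requires supplying
that column.  Missing upstream values yield missing flags, which count as
false in the score; the number of missing components is carried per
record (`n_missing_features`) so low-coverage variants can be dropped by
the user.  A substitution always yields its Grantham and Gly/Pro flags
(they depend only on the amino-acid pair), so an otherwise unannotated
variant has 5, not 7, missing components.

## Synthetic cohorts

The generator emulates the class-conditional contrasts the method
assumes, with defaults matching the study conditions of a structural
subset of an exome cohort: 30 case / 1674 negative / 100 positive
variants.  Causal-like variants carry each planted deleterious-direction
flag with probability 0.5, neutral-like with 0.1.  Where a flag is
thresholded from a continuous measure the continuous value is drawn and
the flag derived from it: ΔΔG ~ N(1.5, 1) kcal/mol for causal-like and
N(0.3, 1) for neutral-like (so the destabilizing-flag rates, ≈ 0.84 and
≈ 0.42, follow from the distributions rather than the generic flag
probability); RSA is a buried/exposed uniform mixture matched to the flag
probability; P(Flexible) ~ Beta(1, b) with b solved so the mass above the
0.860 cutoff is 0.01 (causal-like) or 0.08 (neutral-like).  Gene-level
RVIS ~ N(0, 0.5).  Case variants are causal-like with probability 0.3,
emulating a cohort in which a minority of candidates are functional.
Values are rounded before flags are derived so the emitted table and the
truth table can never disagree at a boundary.

What the generator does **not** emulate: correlations among predictors
(real deleteriousness calls are strongly correlated; here they are
conditionally independent given the class), realistic protein folds,
gene-level clustering of variants, or allele-frequency structure.
Passing recovery tests therefore demonstrates that the pipeline detects
planted marginal enrichment at realistic sample sizes — not that the
features are independent in real data.

## Problem sizes and numerical choices

The parameter-recovery check runs 100 seeded cohorts of 200 positives vs
2000 negatives and requires all seven features recovered at α = 0.05 in
≥ 95 runs, and a mean SDS separation ≥ 2 between classes equally often.
Fisher p-values are verified against brute-force tail enumeration over
all 2×2 tables with row margins ≤ 12; t-test null calibration uses 2000
simulated tests at n = 50 per group (Kolmogorov–Smirnov < 0.05).  Ties
in the ranked output are broken by gene symbol then position, making all
table output byte-deterministic.  Degenerate statistical inputs are
defined rather than erroring: an all-zero 2×2 table gives p = 1, a
zero-variance equal-mean t-test gives t = 0, p = 1, and a constant score
vector in the leave-one-out regression yields an undefined (NaN) R²,
logged.

## Known limitations

Missingness handling (missing flag = false) biases scores of poorly
annotated variants downward by design; filter on `n_missing_features`
when coverage varies.  The dichotomization of raw predictor scores is
left to the config because the upstream defaults are not standardized.
The RSA reference uses idealized extended tripeptides, not
conformer-maximized accessibility, so RSA is relative to the extended
reference and can exceed 100 %.  Stabilization-center detection omits the
conservation and contact-fraction refinements of the dedicated servers.
The final-list curation column encodes expert judgment the package cannot
produce.
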