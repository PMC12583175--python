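# Methods

## Mass arithmetic

Monoisotopic masses use the most-abundant-isotope table (C = 12 exactly,
H = 1.0078250319, O = 15.9949146221, N = 14.0030740052, S = 31.97207069 Da);
the element set is CHNOS with a registration hook for others, since every
compound in scope is CHO(N). Protonation adds the proton mass
1.0072765 Da — the H-atom mass minus the electron mass — rather than the
H-atom mass. At the 2-decimal precision of printed ion values the two
conventions are indistinguishable, but full-precision library matching at
10 ppm (≈ 0.002 Da at m/z 200) is sensitive to the ~0.0005 Da electron
mass, so the physically correct constant is used throughout. Report
values are rounded half-up to 2 decimals; internal computation always
keeps full precision.

Two default tolerances apply. Precursor-level matching uses 10 ppm
(relative). Fragment-level matching uses the wider of 20 ppm and 0.01 Da,
mirroring the 2-decimal precision at which fragment ions are reported;
the absolute floor matters below ~m/z 500 where 20 ppm alone would be
narrower than the reporting precision. Tolerance windows are evaluated at
the midpoint of the two m/z values being compared, which makes the
within-tolerance predicate exactly symmetric.

## Neutral-loss ladders and diagnostic sets

The default loss catalog is CH3 (radical, 15.02348 Da), CHO (29.00274),
CO (27.99491), CO2 (43.98983), C2H2 (26.01565), H2O (18.01056) and CH2
(14.01565); every mass is recomputed from the loss's elemental
composition and validated to 1e-6 Da. The engine tracks m/z only:
radical losses produce odd-electron ions, but annotation works on mass
differences, not electron parity.

A candidate compound's diagnostic-ion set is the union of the rungs of
its class-expected loss ladders generated from its own [M+H]+ — not a
fixed global ion list — because characteristic ions are derived
compound-by-compound. Coumarins get four parallel channels
(CH3→CHO→CO2→CO, CH3→CO2→C2H2→CO, H2O→CO→C2H2→CO, CO→C2H2→CO2; 14
distinct rungs after merging duplicates), cinnamic acids three
(H2O→CO, CO→C2H2, H2O→CO→CO), and methoxylated members of any class add
CH3-initial channels. Loss detection accepts both precursor-to-fragment
and fragment-to-fragment differences, since real spectra show sequential
multi-step ladders whose intermediate ions are themselves observed.

Some published coumarin fragment annotations sit ≈ 1.008 Da below the
mass their loss labels imply (an unannotated extra hydrogen loss). The
ladder engine therefore supports an optional single-H loss step
(`LossCatalog.with_hydrogen()`), off by default; such ions are never
used as reference values.

## Screening pipeline and tiers

Per node: (1) precursor match against the library at 10 ppm — all
isomeric hits are kept; (2) class calls from detected losses (coumarin
requires CH3 and CO; cinnamic acid requires H2O and CO, with the
[M+H−H2O]+ > [M+H−CO]+ intensity ordering as rank-only soft evidence);
(3) per-candidate diagnostic score = fraction of the candidate's ladder
rungs present; a candidate passes only when the score is **strictly**
above the 0.6 threshold ("over 60%" read literally); (4) if no direct
hit passes, modification inference searches combinations (with
repetition) of up to two catalog shifts whose sum matches
precursor − base [M+H]+ within the precursor tolerance, and the base
must itself pass the diagnostic-score gate on its aglycone/core ladder;
(5) tier assignment: `library_confirmed` → `class_plus_modification` →
`class_only` → `unassigned`. Nodes matching two or more library entries
(isomers) are reported in full and flagged `needs_manual_review`; the
pipeline never auto-resolves ties. The two-step cap on modifications
bounds the combinatorics; deeper assemblies are left to manual review.
An external structural-unit resolver can be plugged in for unassigned
nodes, but the shipped pipeline performs no network calls and the hook
is disabled by default.

The screening score threshold and the candidate-likelihood threshold
are numerically identical in the source workflow; they are treated as a
single knob (`score_threshold`).

## Molecular networking

Modified cosine uses square-root intensity weighting and one-to-one peak
matching; candidate pairs match directly or offset by the precursor mass
difference, and the pairing is solved exactly as a maximum-weight
assignment (`scipy.optimize.linear_sum_assignment`). A greedy
approximation is available behind a flag for very dense spectra and is a
documented lower bound, never the default. Edges require cosine strictly
above 0.6 ("above") and at least 5 matched peaks ("at least"); optional
top-K neighbor pruning keeps an edge only when it ranks in the top K for
both endpoints. All comparisons are node-vs-node; no consensus library
spectra are involved.

## Dimer-linkage calls

For precursors at or above the 300 m/z dimer gate (configurable; there
is no established mass gate, 300 safely exceeds any single protonated
simple coumarin), two fragmentation regimes are scored by the fraction
of total intensity they explain: the C–O regime (every cumulative
combination of CH3/CH2/CO2 losses from the precursor) and the C–C
regime (monomer-like ladders anchored at supplied monomer [M+H]+
values). A regime claiming more than 50% of the intensity wins;
"dominates" is a qualitative description in the source chemistry, and
the 50% operationalization is this package's choice. Neither regime
dominating yields `undetermined`.

## Differential statistics

PCA and PLS-DA operate on samples × features matrices, mean-centered
and unit-variance scaled by default (pareto and no scaling available);
constant features pass through unscaled rather than dividing by zero,
and an all-constant matrix raises "no variance". PLS-DA fits NIPALS
PLS2 (scikit-learn's `PLSRegression`) against the one-hot group matrix;
VIP_j = sqrt(p · Σ_a SSY_a w²_ja / Σ_a SSY_a) with SSY_a =
(tᵀa t_a)(qᵀa q_a). Because the weight columns are unit-norm, the mean
of VIP² is identically 1 — an algebraic identity the tests verify to
1e-9.

Volcano analysis defines FC as the ratio of arithmetic group means of
raw areas and takes two-sided Welch t-tests on log areas. Welch is the
default (robust to unequal variances; for two groups the pooled t-test
coincides with one-way ANOVA, and both behaviours are reachable through
the p-value machinery). Zeros are handled by adding half the smallest
positive area in the two groups before log and ratio. "FC ≥ 2" is
inclusive, applied as max(FC, 1/FC) ≥ 2 with direction from the ratio's
side; p-values are raw by default with Benjamini–Hochberg behind a
flag. The joint selection is volcano-significant ∩ VIP > 1. Before
heatmap-style summaries, features mapping to the same annotated
compound (adduct redundancy) can be collapsed to the highest-total-area
feature.

## Synthetic data: what it emulates, what it does not

The spectrum generator builds a compound's spectrum from its own
class-expected ladders: rung intensities decay geometrically down each
channel (earlier rungs more intense, decay 0.75), a residual precursor
peak at half the base intensity is included by default, m/z jitter is
uniform within ±ppm (a bounded mass-accuracy model), each fragment rung
is dropped independently with the dropout probability, and noise peaks
are uniform over [50, precursor − 1] m/z with intensities below the
10th percentile of the signal rungs. The feature-table generator uses
per-feature log-normal baselines (ln-mean 11.5 ≈ 1e5 area units,
ln-sd 1.0), multiplicative log-normal noise at the requested CV, and
fold multipliers planted per (feature, group). Everything is
integer-seeded with no time-based entropy.

The benchmark conditions are fixed: 50 synthetic coumarin-like library
compounds ([M+H]+ spaced ≥ 0.05 Da so precursor matches are
unambiguous), 150 structurally unrelated decoys, 5 ppm jitter, 20% peak
dropout, 6 noise peaks; and for statistics 1000 features, 30 planted
8-fold effects, 10% CV, 3 samples per group. These are the conditions
under which recovery is assessed; they emulate clean Orbitrap-class
data. What they do *not* emulate: chromatographic co-elution and
in-source fragmentation, isotope envelopes, multiply charged species,
correlated (structured) noise, intensity-dependent mass error, and
real isomer diversity at the same nominal mass. Passing the benchmarks
therefore demonstrates the pipeline's logic is correct under its stated
model, not that real-data sensitivity will reach the same numbers.

## Numerical and degenerate-input choices

- Duplicate peak m/z within 1e-6 are merged by intensity summation at
  spectrum construction; peaks are always stored sorted.
- Ties among equally good library matches are ordered by score, then
  |Δppm|, then name (deterministic output).
- Empty spectra are retained, flagged, and screen to `unassigned`;
  `screen_spectrum` never raises on a valid spectrum.
- Corpus screening is order-independent and byte-deterministic given
  identical inputs and configuration.
- A score exactly equal to the threshold fails (strict inequality);
  the public-library admission score is likewise strict (> 0.9).
- The pathway graph is shipped as packaged data; the one hydroxylation
  step whose enzyme the source figure leaves unlabeled carries
  `enzyme=None` with `authenticated=false`. The bicoumarin formulas in
  the starter library (chimsalicifoliusins, biisofraxidins) were
  inferred from their reported protonated masses, not from a structure
  database, and are marked as such in the library module.

## Problem sizes

The shipped benchmarks run in seconds: 200 spectra in the screening
benchmark, 1000 × 6 feature tables, 1000 random spectrum pairs (≤ 8
peaks) for the assignment oracle. These sizes were chosen because the
statistical conclusions (recovery rates, identities, monotonicity) are
already stable there; all generators scale to larger corpora by
argument.

## Known limitations

- Class rules cover coumarins and cinnamic acids (plus generic
  fallbacks); flavonoid/alkaloid/terpenoid rules would need their own
  loss signatures.
- Only singly charged positive-mode adducts are modeled ([M+H]+ by
  default; Na+/NH4+ available for library arithmetic), no isotope
  patterns.
- Modification inference reports mass-consistent hypotheses; it cannot
  distinguish positional isomers or rule out alternative assemblies —
  hence the manual-review flags.
- The modified cosine's exact assignment is O(n³) in matched-peak
  candidates; the greedy flag exists for unusually dense spectra.
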