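# Methods

## Model and descriptor

The endpoint model is a simple regression `pIC50 = C0 + C1·DCW`, with all
of the flexibility living in the descriptor.  `DCW` is the sum of learned
correlation weights over a molecule's structural attributes, counted with
multiplicity: an attribute occurring k times contributes k·CW.  It splits
additively into a SMILES part and a graph part; the split is exact by
construction (attribute families are disjoint) and is checked to 1e−12.

Only the product C1·CW is identified — rescaling all weights is absorbed
by the slope, and adding a constant to a weight carried by every compound
is absorbed by the intercept.  Fitted slopes may therefore come out with
either sign between runs; interpretation must read the *probe-consistent
sign of CW itself* (see Interpretation) or prediction differences between
structures, never the raw magnitude of a single weight.

### SMILES attributes

The tokenizer treats the string verbatim: one token per character except
two-letter elements (Cl, Br, Si), bracket-atom blocks kept whole, and
`%nn` ring closures.  Stereo slashes are ordinary tokens; `@` contributes
to the BOND code only.  Local fragments of one/two/three adjacent tokens
(Sk/SSk/SSSk) are direction-normalized (a fragment and its reversal map to
one key, rendered as the lexicographically smaller reading) and printed in
fixed-width dot-padded slots (`O...=...(...`) so weight tables diff
cleanly.  Global codes record presence of `=`/`#`/`@` (BOND), N/O/S/P
(NOSP), F/Cl/Br/I (HALO), their pairwise and three-way associations
(PAIR, HARD), and the integer censuses: ring count (Cmax, counted as
matched ring-closure label pairs, robust to digit reuse) and N/O/S atom
counts.

Aromaticity is taken at face value from lowercase symbols — there is no
valence model or canonicalization.  This is deliberate: the descriptor is
defined on the string as deposited, and equivalent SMILES written
differently are different inputs for the string half (the graph half is
writing-invariant, which a test enforces).

### Graph attributes

The hydrogen-suppressed graph is the heavy-atom skeleton; bond orders are
ignored (double bonds influence only the string attributes).  Per vertex:
EC0 = degree and EC1 = sum of neighbour degrees (two Morgan orders — the
lowest two, since exactly two connectivity terms enter the descriptor);
pt2/pt3 = counts of simple paths (visited-set DFS, not walks, so rings are
not double-counted); S2/S3 = sums of degrees over the shells at shortest
distance exactly 2 and 3 (degree sums, not vertex counts — a nitrogen
shell value of 8 is natural as a degree sum and unreachable as a count at
typical branching); the nearest-neighbour code (total, carbon, non-carbon
neighbours — a carbonyl carbon reads 321); and the six sum/absolute
difference combinations of the three invariant pairs.  Ring codes cover
5-/6-membered rings of a networkx minimum cycle basis, flagged aromatic
only when every member atom is aromatic, with their heteroatom count.
Keys embed the element symbol and the invariant value, so each distinct
value is its own learnable attribute.

## Registry and threshold

The registry counts, per attribute, the compounds containing it
(presence) and its total occurrences in each subset.  An attribute is
active when present in ≥ T compounds of TRN ∪ iTRN — both subsets drive
the optimization, so both define rarity.  Blocked attributes have their
weight pinned to zero permanently; attributes confined to calibration or
validation data are blocked regardless of T.  At prediction time unknown
attributes contribute zero to DCW but count as absent (defect 1) in the
applicability domain, which is what makes new chemistry detectable rather
than silently extrapolated.

## Monte-Carlo optimization

Coordinate-wise stochastic ascent: each epoch visits every active
attribute once in seeded-random order, proposes an additive perturbation
drawn uniformly from ±`perturbation_range`, re-derives C0/C1 by
closed-form least squares on TRN, and accepts the move when the target
function does not decrease.  Plateau moves are accepted so flat regions
can be crossed; the per-epoch best target value is non-decreasing by
construction.  Everything is driven by one `numpy` Generator, so a seed
fixes the result bit-for-bit.

Defaults and why:

| parameter            | default | rationale |
|----------------------|---------|-----------|
| c (TF1 penalty)      | 0.1     | the customary small penalty on the train/invisible-train correlation gap |
| w_IIC (TF2)          | 0.2     | the weight at which the IIC term is known to improve calibration/validation behaviour |
| T (threshold)        | 1       | attributes seen even once in training carry signal with ~190 compounds |
| N (epochs)           | 15      | enough for the coordinate ascent to converge at the default proposal width |
| perturbation_range   | 2.0     | weights are O(1) with initialization U(0.5, 1.5); narrow proposals (±0.3) left the 15-epoch climb visibly unconverged (training r ≈ 0.78 on synthetic data), ±2.0 converges within budget; a decaying schedule gave no consistent gain |
| n_probes             | 3       | promoter classification needs independent runs; three give a usable consistency vote |

The strictly positive initialization avoids starting from a dead
all-zero descriptor.  The IIC residual-class means divide by the size of
each sign class (Δ ≥ 0 counts as positive), making the damping factor a
ratio in (0, 1]; an empty sign class gives 0, and an exactly zero
residual vector is treated as the ideal symmetric fit (factor 1).  A
training set with constant activity aborts with a diagnostic — the
correlation target is undefined there.

## Validation battery

R² is reported in two forms: the explained-variance form 1 − SSE/SST
(which can be negative externally) and the squared observed–calculated
Pearson correlation, which is the form conventionally printed for
external sets in this family of models (it exceeds the external Q² for a
well-behaved model, which is the pattern in published tables).  Q² is
leave-one-out on the set the regression was fit to (via the PRESS/leverage
identity for simple regression, tested against explicit refits) and the
training-mean-referenced external form elsewhere.  Q²F1/F2/F3 follow
their standard definitions (F3 scales the residual and reference sums by
the external and training sizes); CCC is Lin's concordance (biased /n
form); rm² uses the squared correlation and the through-origin
determination of predicted on observed (that direction only);
s uses the n − 2 denominator.  Y-scrambling reports
cRp² = R·√(R² − R̄r²) over seeded activity permutations, clipped at zero.
The > 3S outlier rule is a single pass: fit on all pre-split data, drop
|residual| > 3s, refit once.

## Applicability domain

Attribute defect = |P_TRN − P_CAL| / (N_TRN + N_CAL), with presence
fractions in the numerator and total occurrence counts in the denominator
(the occurrence-based reading of the defect definition); absent from both
reference sets → defect 1.  Molecular defect sums attribute defects with
multiplicity over active attributes of the defect table, plus 1 per
occurrence of any attribute outside it.  The threshold is exactly twice
the mean training-set molecular defect; equality stays in-domain (the
exclusion inequality is strict).

## Interpretation

An attribute is an increase (decrease) promoter when its weight is
strictly positive (negative) in every probe; an exact zero in any probe
asserts no sign and the attribute is excluded as inconsistent.  For
recovery checks against the synthetic ground truth the package does not
read single weights (which are only identified in colinear groups) but
predicts the parent chalcone with and without a fragment and compares the
sign of the activity difference — the direct structure–activity reading
of the model.

## Synthetic data generator

The generator emulates a chalcone-derivative library: the enone core
`O=C(C=C Ar_B) Ar_A` decorated at para/meta positions from a grammar of
nine common substituents (H, OCH3, OH, F, Cl, Br, NO2, NMe2, CH3) with
heteroaryl B-ring options (thienyl, furyl, thiazolyl, pyridyl).  Activity
is base 5.3 plus additive fragment effects plus Gaussian noise
(SD 0.15 by default), clipped to [3.5, 7.0] — the spread of measured
chalcone pIC50 values against HT-29.  Default size 190 and split
fractions 0.27/0.27/0.23/0.23 mirror the study geometry.  The default
effect map plants a strong deactivating NMe2 (−1.2, matching the
observation that dimethylamino chalcones are the least active), moderate
activators (OCH3 +0.4, OH +0.3, F +0.25, Cl +0.2) and deactivators
(NO2 −0.5, thiazolyl −0.6).

What the generator does *not* emulate: assay noise heteroscedasticity,
non-additive substituent interactions, scaffold diversity beyond the
single enone core, and activity cliffs.  Passing the recovery tests
therefore shows the machinery can extract an additive fragment signal at
realistic noise, not that real chalcone SAR is additive.

## Problem sizes and numerics

Tests and the acceptance script run the full pipeline at the study
geometry (190 compounds, ~460 active attributes, 15 epochs, 3 probes; a
few seconds per fit) and the graph-invariant equivalence check at 200
random graphs of ≤ 8 vertices, where exhaustive enumeration is still
exact.  Correlations on constant vectors are defined as 0 inside the
optimizer (a proposal that flattens a subset is simply rejected);
degenerate designs (constant descriptor, constant activity) raise.
Descriptor linear algebra is dense `float64`; all randomness flows from
explicit `numpy.random.default_rng` seeds.

## Known limitations

* The string half of the descriptor is representation-dependent by
  design; datasets should deposit one consistent SMILES writing.
* Ring perception uses a minimum cycle basis; fused-ring systems with
  ambiguous bases may code differently between equivalent writings in
  pathological cases (none occur in the chalcone grammar).
* The reproduction checks against the published chalcone/HT-29 dataset
  run only when the deposited supplementary table is placed under
  `data/`; the repository ships no third-party data.
* Promoter classification is a sign-consistency vote, not an inferential
  procedure; colinear attributes share an effect and individual weights
  have no standalone meaning.
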