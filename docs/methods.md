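# Methods

This note documents the models, procedures and numerical choices behind
`librank`, in the spirit of a statistical-software methods appendix. It
states nothing empirical that the test suite or `scripts/acceptance.py` do
not themselves compute.

## Problem setting

Given several candidate compound screening libraries (SDF or SMILES files),
the package scores each library on a set of per-library criteria and
aggregates the scores into a single ranking, so that a group planning a
(typically phenotypic) screening campaign can pick the library with the
most balanced profile. The criteria are: data quality after curation,
ADME/T profile (Lipinski, Veber, predicted blood-brain-barrier permeation),
the fraction of promiscuous binders / frequent HTS hitters, internal
diversity in fingerprint space, and — optionally — similarity to known
active compounds and overlap with an in-house collection.

## Curation

Each record passes through: (1) salt stripping — a multi-fragment record is
reduced to its largest fragment when every other fragment is a recognised
counter-ion (shipped list, `data/counterions.smi`) or small (≤ 6 heavy
atoms) with zero or opposite net charge; a tie in fragment size means the
record is not a salt; (2) classification, checked in the order inorganic →
mixture → bad valence, first match wins. A parent fragment is inorganic
when it has no carbon or contains an element outside
{C, H, N, O, S, P, F, Cl, Br, I, B, Se}; a mixture when more than one
fragment survives stripping; bad-valence when any atom violates the
standard organic valence model (the toolkit's sanitization rules);
(3) standardization — functional-group normalization, one canonical
tautomer from a deterministic tautomer canonicalizer with fixed scoring,
then rule-based (de)protonation at pH 7.4; (4) de-duplication on the
canonical SMILES of the standardized parent, keeping first occurrences in
input order.

Protonation uses the shipped rule table `data/pka_rules.tsv` (carboxylic,
sulfonic, sulfinic and phosphonic acids deprotonated; aliphatic amines and
amidines/guanidines protonated), with literature-typical pKa values. Each
SMARTS is written so the transformed group no longer matches its own
pattern, which makes the standardization pass idempotent — a property the
suite checks. A rule table was chosen over a full pKa predictor because it
is deterministic, auditable and editable; the cost is that unusual
ionizable groups (tetrazoles, phenols near the pH boundary, zwitterion
subtleties) keep their input protonation state.

Unparseable records are counted and logged, never fatal: vendor files
contain occasional junk, and removal rates are themselves a reported
statistic. Structures that fail only the valence check are parsed leniently
and counted in their own category rather than as parse failures.

## ADME/T profile

Lipinski violations count strict inequalities among {HBD > 5, MW > 500,
CLogP > 5, HBA > 10}; a compound fails the filter only with more than one
violation. Veber is rotatable bonds ≤ 10 AND (TPSA ≤ 140 Å² OR
HBD + HBA ≤ 12); the H-bond count reading follows the original rule. The
Lipinski H-bond counts use the classic N/O-based definitions; CLogP is the
same atom-contribution (Crippen) logP used for AlogP98 below.

The blood-brain-barrier model predicts logBB (log brain/blood
concentration ratio) as

    logBB = 1.2827 + 0.17977·AlogP98 − 0.0033777·DPSA1
            − 0.18676·Num_H_Acceptors + 0.1557·S_sssN
            − 0.022135·⟨4.6743 − S_ssCH2⟩

with ⟨x⟩ = max(0, x), the truncated-power spline basis of GFA models —
the only reading of the angle bracket that keeps the term bounded. A
compound with logBB ≥ 0 is classed permeable (boundary inclusive), < 0
impermeable; the workflow consumes only the impermeable percentage per
library. The model ships as a plain-text parameter file
(`data/logbb_model.txt`) so the equation is auditable, and any model
produced by the GFA module can be dropped in its place.

Descriptor implementations are open-source reconstructions: AlogP98 ≈
Crippen atom-contribution logP; DPSA1 = (partial-positive − partial-negative)
solvent-accessible surface area from Gasteiger charges and FreeSASA on a
single ETKDG conformer embedded with a fixed seed (1987) — deterministic by
construction; Num_H_Acceptors uses the toolkit's standard acceptor
definition; S_sssN and S_ssCH2 sum Kier–Hall E-state indices over >N− and
−CH2− atom types, zero when no such atom exists. Because the original
descriptor engine is proprietary, absolute logBB values for a given
molecule are not expected to agree implementation-to-implementation; the
classification behaviour and the equation's exact arithmetic are what the
package guarantees (checked to 1e-9). Conformer-embedding failures flag the
record and exclude it from the BBB statistic only, with a logged count.

## Promiscuity alerts

Alert catalogs are plain text, `name<TAB>SMARTS`. The shipped default
(`data/alerts_default.smarts`) is a hand-written catalog of PAINS-style
frequent-hitter chemotypes — catechols, hydroquinones, quinones, rhodanines
and ene-rhodanines, open-chain Michael-acceptor enones, alkyl halides, azo
compounds, nitro-aromatics, isothiazolones, acyl hydrazones, thioureas,
aromatic aldehydes. The suite cross-checks four of these classes against
the independently curated PAINS filter collection bundled with RDKit. The
workflow flags compounds and reports the flagged percentage per library; it
never deletes compounds, since the unit of selection is the whole library.

## Fingerprints

Three families, all 25 dialect tags the diversity/similarity protocols
iterate over:

* **ECFP_n / FCFP_n** (n = 2, 4, 6): sparse extended-connectivity count
  fingerprints of diameter n, with element/connectivity (ECFP) or
  functional-class (FCFP) atom invariants. Feature identifiers are
  canonical environment hashes, stable across runs and platforms, and no
  bit folding is applied — so the diameter-2 feature set is nested inside
  diameters 4 and 6, a property the suite asserts for every molecule it
  touches.
* **MDL public keys**: the standard 166-key structural dictionary, binary.
* **PH{F,PF,RF}{P,C}_n** (n = 2, 3, 4): topological n-point pharmacophore
  fingerprints. Features are canonical (sorted) tuples of pharmacophoric
  types plus binned shortest-path distances between the feature atoms.
  Feature definitions (donor, acceptor, positive/negative ionizable,
  aromatic ring, hydrophobe, halogen) are shipped SMARTS
  (`data/pharmacophore_features.smarts`). The palette letter selects the
  type set: F = the full six-type palette; PF = a coarse three-type palette
  (ionizables merged into donor/acceptor, aromatic merged into hydrophobe);
  RF = a fine palette that also separates halogens. The final letter
  selects binary (P) or count (C) form. Aromatic features are per-ring and
  carry the whole ring's atom set; inter-feature distance is the minimum
  over the atom sets, which keeps fingerprints invariant to atom numbering.
  Distance bins are {1, 2, 3, 4, 5, 6–7, 8–10, >10}: fully resolved at
  short range so positional isomers (e.g. para- vs meta-substitution,
  donor–donor distances 5 vs 4 bonds) map to different features; a coarser
  binning that merges distances 4–6 cannot distinguish them. Molecules
  with fewer pharmacophoric features than the point count yield an empty,
  flagged fingerprint and are excluded from that metric only — mirroring
  how reference databases drop compounds whose descriptors cannot be
  calculated.

Tanimoto similarity is |A∩B|/|A∪B| for binary fingerprints and
Σmin/Σmax over the feature union for count fingerprints; distance is
1 − similarity. Two empty fingerprints compare as 0 with a warning.

## Diversity, similarity and overlap

**Internal diversity** is the mean pairwise Tanimoto over all unordered
pairs (lower = more diverse). Above a configurable pair budget
(default 20 000) an unbiased uniform sample of pairs, seeded, estimates the
mean; on a 200-molecule fixture the sampled estimate at 5 000 pairs is
within 0.02 of the exhaustive mean (checked).

**MaxMin selection** greedily adds the candidate maximizing its minimum
distance to the selected set; ties break by input order. The default first
pick is the record with maximal mean distance to all others (deterministic);
a seed or explicit index can override it, since diverse-picker components
in commercial platforms do not document their seeding. Greedy prefixes are
nested, so coverage curves from one run are monotone in subset size; the
suite verifies each pick against brute force on 10-molecule sets.

**Coverage curves** report the percentage of distinct labels (targets or
indications) covered by MaxMin subsets of increasing size, with a
random-selection baseline averaged over 10 seeded replicates by default.
Labeled-set preprocessing drops multi-label records and labels below a
member minimum (parameter, default 2).

**Similarity ranking** orders a library by descending Tanimoto to a
reference compound, stably, with tied blocks marked. The **enrichment
curve** plots cumulative % actives recovered vs % library screened; a tied
block contributes a single point, so the drawn curve is the straight line
across the block (beyond the point where the coefficient levels off there
is no way to order compounds). The averaged-coverage scalar is the
trapezoid-rule area under the curve on the unit square: 0.5 for a random
or fully tied ordering, 1 for perfect early recovery. The trapezoid rule
was chosen because "average coverage over the entire curve" has no unique
formula; it is exact for the piecewise-linear curves produced here.

**Threshold search** returns records with Tanimoto ≥ t (inclusive);
**substructure search** accepts queries with one variable atom — a template
with a `{X}` placeholder expands to one SMARTS per allowed element and a
record matches if any expansion matches. **Cross-library overlap** counts
candidate compounds whose best Tanimoto against the in-house library
reaches 0.7 (ECFP_4 by default), reported as a percentage of the candidate
to one decimal; it is deliberately asymmetric and computed exactly over
all pairs.

## Consensus ranking

Each criterion dense-ranks the libraries: best value 1, ties share a rank,
next distinct value gets the previous rank + 1. A block of criteria sums
the (optionally weighted, default equal) ranks per library and dense-ranks
the sums; blocks combine the same way into grand totals and final ranks.
An overlap criterion can be folded into an existing final ranking as
combined = prior final rank + dense rank of overlap %, re-dense-ranked.
Dense ranking at both levels is the package's tie rule: it is the unique
simple rule that exactly reproduces the published nine-library rank tables
from their printed percentage inputs, which the acceptance suite checks
cell for cell. Ranks depend only on value orderings, so any strictly
monotone transform of a criterion leaves all downstream ranks unchanged
(property-tested).

Directions: failure %, promiscuity %, mean similarity and overlap % are
lower-better; similar-to-active counts are higher-better. Library size is
reported but never ranked — screening capacity is a resource decision, not
a quality criterion.

## GFA model building

The QSAR module evolves linear-plus-spline models with a genetic
algorithm: individuals are term lists (linear x, ⟨knot − x⟩, ⟨x − knot⟩),
crossover exchanges term sublists, mutation adds/removes/replaces a term or
re-draws a spline knot, coefficients come from least squares, and fitness
is Friedman's lack-of-fit

    LOF = (SSE/m) / (1 − (c + d·p)/m)²

with m samples, c terms, p parameters and smoothness factor d (default
1.0). LOF is the canonical GFA fitness; it reduces to SSE/m when c = p = 0
and grows monotonically with term count at fixed SSE. Knots are drawn from
the 5th–95th observed quantiles of each descriptor so spline hinges stay
inside data support; a planted hinge outside that range is unidentifiable
(nearly linear over the data), which is why the synthetic spline-recovery
fixtures widen the descriptor distribution to place the knot well inside
support. Rank-deficient least-squares systems get infinite LOF rather than
aborting the run. Defaults: population 80, generations 40, 1–5 terms,
crossover 0.7, mutation 0.35, tournament size 3, elitism 2 — small enough
to finish in under a second on the synthetic problems used here and
sufficient for reliable recovery of planted 2-term models at n = 200.

Support steps: a kNN outlier filter (z-score of the mean Euclidean
distance to the k nearest neighbours in standardized descriptor space;
published workflows cite bespoke outlier algorithms without printing them,
so this documented approximation is used); random or diversity (MaxMin in
descriptor space) train/test splits; and Y-scrambling — refitting on
permuted training responses n times (default 10) and reporting mean ± sd
of train/test R², which should collapse toward zero for an honest model.
Everything is deterministic under a fixed seed.

## Synthetic data

The fixture generator is first-class, tested code; it emulates the inputs
the workflow consumes without any download:

* **Fixture libraries**: drug-like "clean" molecules enumerated from
  scaffold × substituent vocabularies (chosen to be inert under the default
  alert catalog and pKa rules), plus planted salt forms, inorganics,
  mixtures, duplicate pairs (parent + salt of the same compound) and
  alert-matching compounds, with a ground-truth manifest. Pure function of
  (spec, seed).
* **Labeled clusters**: up to 10 large, mutually dissimilar scaffolds, each
  decorated with small substituents — within-cluster circular-fingerprint
  similarity exceeds any cross-cluster similarity by construction, so the
  clusters behave as well-separated targets for coverage protocols.
* **Planted analogues**: a reference amide template whose analogues differ
  only in O-alkyl chain length, keeping ECFP_4 similarity to the reference
  above 0.7 for the first ~6 homologs while typical decoys stay below 0.3
  (verified by direct computation in the suite).
* **Planted regression data**: iid normal descriptors with a known linear
  (and optionally spline) response plus Gaussian noise.

What the synthetic data does *not* emulate: real vendor libraries' size
(tens of thousands of compounds), their scaffold frequency distributions,
stereochemistry-rich structures, and the messiness of real target/
indication annotations. Passing tests therefore demonstrate correctness of
the algorithms and bookkeeping under controlled conditions — planted
categories recovered, ranks reproduced, estimators unbiased — not
field performance on any particular vendor's catalog.

## Problem sizes and tolerances

The suite and the acceptance script run on one CPU in well under a minute
total, using: fixture libraries of 10–30 molecules for curation/ADME/T/
alerts; 80–200 molecules for diversity, enrichment and sampling checks;
n = 200, 10 descriptors for GFA recovery; 200 permutations for the
random-enrichment check (tolerance ±0.05 around 0.5); 5–10 Y-scrambling
repeats. Exact reconstructions (consensus tables, logBB arithmetic) are
asserted cell-for-cell or to 1e-9; stochastic checks use the tolerances
stated inline above.

## Known limitations

* Absolute descriptor values (AlogP98, DPSA1, E-state sums) differ from
  proprietary implementations; only the shipped equation's arithmetic and
  the downstream classification bookkeeping are exact.
* The tautomer canonicalizer and normalization rules are the toolkit's;
  a different toolkit version may choose a different (still deterministic)
  canonical tautomer.
* The pKa rule table covers the common ionizable groups only.
* The vendor semantics of the pharmacophore dialect families are not
  public; the palettes here are documented analogues and keep all 25
  dialect tags available.
* MaxMin is greedy, not optimal; the diversity criterion inherits its
  usual bias toward outliers.
* The alert catalog is a small PAINS-style stand-in; real screening
  operations should load their own full catalog.
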