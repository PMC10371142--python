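# Methods

## The screening problem

Organophosphate anticholinesterases phosphylate the active-site serine of
acetylcholinesterase (AChE). An effective antidote must both reactivate
the inhibited enzyme — across chemically different OPs, since the
threat spans G-series, V-series and GV-series agents plus insecticide
oxons — and reach the brain, which the permanently charged pyridinium of
classical oximes largely prevents. The package screens the substituted
phenoxyalkyl pyridinium oxime (SPPO) chemotype for both properties at
once, entirely in descriptor space: no docking, conformers or quantum
chemistry.

## Scaffolds and decomposition

The scaffold registry holds three cores: the positional isomers of the
pyridinium aldoxime with the oxime at ring position 2, 3 or 4 (`S2`,
`S3`, `S4`), each carrying an N-alkyl linker of n carbons to a phenyl
ether. The phenoxy ring positions are labeled R1/R5 (ortho to the ether
oxygen), R2/R4 (meta) and R3 (para).

`decompose` matches each core (per linker length, in-rule lengths 3–5
first, then 1–8 with an `in_rule=False` flag) as a substructure, requires
every non-core atom to hang off an R position, kekulizes, cuts the
attachment bonds and collects the fragments with position labels.
Fragments cut at two adjacent positions are "special" fused-ring
fragments. The phenoxy ring is symmetric, so several equivalent
assignments can exist; the lexicographically smallest (by position,
fragment canonical SMILES) that reassembles to the input is returned,
making decomposition deterministic. `reassemble` rebuilds the molecule
with RDKit `molzip` from atom-mapped dummies; `reassemble ∘ decompose` is
the identity on canonical SMILES and is asserted inside `decompose`
itself.

Scaffold priority is the fixed registry order S2, S3, S4 — the three
cores are the same size, so "largest first" does not discriminate; a
molecule matching two cores (not observed in practice) is assigned to the
first.

## Enumeration rules

Candidates are every (scaffold, n, assignment) with n ∈ {3, 4, 5}, R3
drawn from the whitelist of fragments observed at R3, and R1/R2/R4/R5
drawn from the union of fragments observed at any of those positions
("union" swap semantics; a "positional" mode restricting each position to
its own observed set is available). Hydrogen is always in every swap
pool. Special fragments participate at their observed paired positions
and consume the R3 slot (configurable). Duplicates are removed by
canonical SMILES and input structures are excluded by default, so the
library contains only new variations. The enumerator streams; only the
dedup key set is held in memory.

`rules_from_decompositions(max_swap_fragments=k)` optionally keeps only
the k most frequently observed swap fragments — the same
computational-feasibility rationale as the three rules themselves. The
default test/acceptance runs use k = 2, giving libraries of ~8,000
candidates; the unconstrained pools reproduce the tens-of-thousands scale
at proportionally higher cost.

## Featurization

The descriptor battery is the full RDKit 2D list for the pinned toolkit
version (210 under RDKit 2024.09.2) plus an oxime-group count
(`[CX3]=[NX2][OX2H1]` matches). The battery size is a function of the
toolkit version and is recorded in output manifests, never asserted. A
descriptor that raises or returns a non-finite value is an error naming
the descriptor and molecule.

Pair features for SPPO:OP samples are the concatenation
`[sppo__*, op__*]` (length 2 × battery). Exactly-constant columns are
dropped (variance threshold 0 by default; the threshold is a knob since
"low variance" admits degrees), then min–max scaling maps each column to
[0, 1]. Scaling is fit on the training rows only and applied to test or
screening rows with clipping into [0, 1] — fitting on everything would
leak test information into the transform. Constant columns map to 0. One
exception: the k-means clustering that *stratifies* the split needs
scaled features before the split exists, so clustering uses a provisional
all-rows scaling that is discarded afterwards; the model's scaler is
refit on the training rows.

## Classifier construction

Both tasks use XGBoost (`tree_method="hist"`, single-threaded,
seed-pinned).

**Split.** k-means (k = 3 × number of classes, configurable) clusters
the scaled features; the global 20% test quota is apportioned across
(cluster × class) cells by largest remainder, capped at all-but-one per
multi-member cell, and drawn with a seeded RNG. This guarantees every
pocket of descriptor space and every class feeds both partitions where
size permits.

**Reduced-set selection.** A model trained on the full feature set ranks
features by permutation importance (5 repeats). Nested top-m subsets over
the size grid {4, 6, 9, 14, 20, 30, 50, full} are scored by 5-fold
cross-validated macro F1; the best wins, ties to the smaller set.
Permutation importance is the default because the battery is highly
collinear and split-gain importance dilutes credit across correlated
descriptors — on fixtures with planted rules, gain ranking missed the
causal descriptors that permutation ranking recovers. Gain ranking and a
recursive-elimination mode (re-rank within survivors at each size) remain
available.

**Hyperparameters.** Grid search (5-fold CV, accuracy scoring) over tree
count {200, 600} × depth {2, 4} × learning rate {0.05, 0.2}, refit on all
training rows. The grid includes shallow/slow configurations because both
tasks have smooth, low-dimensional decision structure that deep trees
overfit.

**Deployment.** The evaluation report always comes from the held-out
test set. The model used for screening is, by default, refit with the
selected subset and tuned hyperparameters on *all* labeled rows
(`deploy_on_full`): the split exists to estimate quality, the deployed
model should use every sample. A flag keeps the split model instead.

**Metrics.** Per class (one-vs-rest): sensitivity (recall), selectivity
(reported as specificity — because "selectivity" is ambiguous in the
field, precision is always reported alongside), F1; plus overall accuracy
and a row-normalized confusion matrix. Zero-denominator ratios report 0.

## Class conventions

- Reactivation: |percent| ≤ 0.5 points → No ("about 0%" must tolerate
  assay noise; exact-zero matching would misclassify near-zero
  replicates); 0.5 < percent ≤ 40 → Low; > 40 → High (the 40% boundary
  itself is Low — High is strictly greater). Raw values accepted in
  [−10, 110]; negatives beyond the zero tolerance are rejected, not
  silently binned. Replicate rows are averaged; duplicate pairs with
  conflicting classes are an error listing the conflicts.
- logBB: > 0 → BBB+, ≤ 0 → BBB− (the boundary is conservatively not
  claimed as brain-penetrant). The threshold is a parameter; 0 is the
  default.
- Broad-spectrum: predicted High for **every** OP in the panel
  {PIMP, NEMP, PXN, DFP, GV}. GV is encoded from its IUPAC name
  (2-[dimethylamino(fluoro)phosphoryl]oxy-N,N-dimethylethanamine) and is
  prediction-only — no training data exists for it anywhere in the
  workflow.

## Synthetic fixtures: what they emulate, what they do not

`generate_sppo_fixture` assembles (default) 84 distinct SPPOs from the
registry scaffolds, 19 R3 fragments (all guaranteed observed, matching
the para-position diversity of the platform), an 8-fragment swap pool and
occasional fused-ring specials. Each of the 336 pairs with the 4-OP
training panel gets a class from a planted rule — a linear score on
(sppo MolLogP, sppo TPSA, op TPSA) with weights (1.0, −0.05, 0.012), cut
at the population score quantiles 0.436/0.815 so class proportions match
the 44/38/19% balance of the in vitro platform. The challenge weight is
deliberately small: it modulates pair scores by well under one class band
across the panel, so a minority of reactivators is High against every
challenge — the qualitative structure a broad-spectrum screen needs.
Labels flip with probability 0.05 (configurable, in [0, 0.5)); percent
values are then drawn class-conditionally: No ~ N(0, 0.3) truncated to
±0.45, Low ~ U(5, 38), High ~ U(45, 95) — away from bin boundaries except
in dedicated boundary tests. A ledger records true class, emitted class
and flip flag per pair.

`generate_logbb_fixture` decorates a built-in list of 46 drug-like
scaffolds with up to two substituents to (default) 1058 distinct
molecules and assigns logBB = 0.62 + 0.24·MolLogP − 0.024·TPSA −
0.13·NumHDonors − 0.0008·MolWt + N(0, 0.3). The term structure follows
the classic TPSA/logP brain-penetration relationship; the magnitudes are
scaled so the population dispersion (sd ≈ 0.8, range ≈ −2.5 to +1.5)
matches curated experimental logBB compilations — with realistic spread
the 0-threshold task has an irreducible error of ~11%, so the ≥85%
accuracy the tests demand is attainable but not trivial.

What passing tests show: the machinery — decomposition, featurization,
splitting, selection, training, screening — recovers planted structure at
realistic noise and scale. What they do not show: chemical validity of
any real reactivation SAR. The fixtures validate machinery, not
chemistry.

## Screening funnel

Stages run in the order enumerate → broad-spectrum → BBB →
synthesizability (configurable; the filters commute logically). Survivor
counts are reported with fractions ("44 of 698 (6.3%)" style). Every
record carries its terminal stage, per-OP classes, BBB class and backend
verdict; later-stage fields stay unset for candidates that exited
earlier. Outputs embed the config hash, toolkit version and seed.

Synthesizability is an interface, not an implementation: route-search
tools depend on building-block catalogs and change results with their
stock files, so the package ships an external-command adapter (JSON
stdin/stdout contract, failures are explicit errors) and a deliberately
simple heuristic stub (pass iff BertzCT ≤ 1500 and ring count ≤ 6) that
orders easy before hard chemistry and nothing more.

## Problem sizes and determinism

Default study conditions: 84 SPPOs × 4 OPs = 336 pairs; 1058 logBB
molecules; acceptance funnel ~8,000 candidates (swap pool capped at the 2
most frequent fragments). The acceptance script runs in a few minutes on
one CPU; unconstrained pools scale the library (and descriptor cost)
by an order of magnitude. All randomness — fixture assembly, k-means,
quota draws, CV shuffles, XGBoost — flows from one seed; repeated runs
are bit-identical.

## Known limitations

- Reactivation classes rest on in vitro percent reactivation; no
  pharmacokinetics beyond the BBB class, no dose or efficacy.
- No docking or 3D: ligand–enzyme fit enters only through 2D size/shape
  descriptors.
- The three-scaffold registry covers the pyridinium-aldoxime positional
  isomers; SPPOs outside it fail decomposition loudly rather than being
  forced.
- The heuristic synthesizability stub is a placeholder ordering, not a
  route search; quantitative synthesizability claims require the external
  backend.
- Classifier thresholds (40%, logBB 0) shift the survivor counts when
  changed; the ranking of top candidates is more stable than the counts.
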