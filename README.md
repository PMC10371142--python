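# oximescreen

In silico discovery of broad-spectrum antidotes for organophosphate (OP)
poisoning. Organophosphate anticholinesterases — nerve agents and potent
insecticides — inhibit acetylcholinesterase (AChE); oxime antidotes
reactivate the phosphylated enzyme, but the standard of care (2-PAM)
barely crosses the blood-brain barrier (BBB). Substituted phenoxyalkyl
pyridinium oximes (SPPOs) are a chemotype with evidence of brain
penetration: a pyridinium aldoxime joined by an alkyl linker of *n*
carbons to a substituted phenoxy ring carrying R-groups R1–R5.

`oximescreen` is for computational and medicinal chemists prioritizing
SPPO candidates for synthesis. It implements a complete screening
framework:

1. **R-group decomposition and enumeration** — input SPPOs are factored
   into shared scaffolds + positioned fragments; a virtual library is
   generated combinatorially under three rules: *n* ∈ {3, 4, 5}; R3 (the
   para position, the most variable in practice) restricted to fragments
   observed there; fragments at R1/R2/R4/R5 free to swap among those
   positions. "Special" fragments spanning two adjacent positions
   (R2&R3 or R3&R4) form rings fused to the phenoxy ring.
2. **AChE reactivation classifier** — in vitro percent reactivation of
   SPPO:OP pairs is binned into classes (No: ≈0%, Low: ≤40%, High: >40%)
   and modeled with extreme gradient boosting (XGBoost) on paired RDKit
   descriptor vectors `[x_SPPO, x_OP]`, after min–max scaling to [0, 1]
   and variance filtering. Features are reduced to an *optimal reduced
   set* (RS) by importance ranking + cross-validated macro-F1 over nested
   subset sizes. Train/test splitting is stratified by k-means clusters in
   descriptor space (20% test).
3. **BBB classifier** — molecules with measured logBB (log10 brain/blood
   ratio) are labeled BBB+ (logBB > 0) or BBB− and modeled with the same
   machinery on single-molecule descriptors.
4. **Screening funnel** — every candidate is screened for *broad-spectrum*
   reactivation (predicted High against all five challenges: PIMP, NEMP,
   paraoxon, DFP and GV), then BBB permeability, then synthesizability via
   a pluggable backend (external retrosynthesis tool over a JSON contract,
   or a documented complexity heuristic).

A synthetic-fixture module generates download-free stand-ins for all
inputs — SPPO structures assembled from the scaffold registry, percent
reactivation from a planted descriptor rule with label noise, and logBB
from a planted linear model — with ground-truth ledgers, so the whole
pipeline is testable offline.

## Worked example

```python
from oximescreen import (FixtureSpec, generate_sppo_fixture, generate_logbb_fixture,
                         assemble_reactivation_dataset, assemble_bbb_dataset,
                         train_reactivation_model, train_bbb_model)

fx = generate_sppo_fixture(FixtureSpec(seed=1))         # 84 SPPOs x 4 OPs
ds = assemble_reactivation_dataset(fx.measurements, fx.sppos, fx.ops)
print(dict(ds.tallies))
res = train_reactivation_model(ds, seed=1)
print(f"accuracy {res.report.overall_accuracy:.3f}  macro F1 {res.report.macro_f1:.3f}")
print("reduced set:", res.subset.names)
```

prints (RDKit 2024.09.2, XGBoost 3.0.5):

```
{'Low': 131, 'No': 139, 'High': 66}
accuracy 0.866  macro F1 0.856
reduced set: ('sppo__MolLogP', 'op__MaxAbsEStateIndex', 'sppo__TPSA', 'op__qed')
```

336 pairs are binned into the three reactivation classes; the classifier
reaches 86.6% held-out accuracy, and the optimal reduced set recovers the
reactivator lipophilicity (MolLogP) and polar surface area (TPSA) that the
fixture's planted rule actually uses, plus two challenge descriptors that
proxy its OP term — i.e. the workflow identifies the descriptors that
drive the label. The same pattern holds for the BBB model (TPSA, logP
among the RS).

The full funnel is one call (or `oxime-screen run --config config.yaml`):

```python
from oximescreen import PipelineConfig, run_pipeline
config = PipelineConfig(seed=1, output_dir="out", max_swap_fragments=2)
records, summary = run_pipeline(config, fx.sppos, res.model, bbb.model)
print(summary["funnel"]["broad_spectrum_of_library"])   # e.g. "306 of 8163 (3.7%)"
```

Outputs (`library.smi.gz`, `screening_records.jsonl`, `summary.json`,
`rgroup_summary.csv`) carry full provenance: each surviving target is
reconstructible down to its scaffold, linker length and fragment
assignment.

## Using published datasets

The ingesters accept the published experimental tables directly when you
have them:

- `data/table_s1.csv` — in vitro pair measurements, columns
  `sppo_id, op_id, reactivation_percent` (optional `replicate`);
- `data/b3db_regression.csv` — experimental logBB compilation with a
  `logBB` column (`assemble_bbb_dataset(..., column_map=...)` maps other
  headers).

The acceptance tests automatically switch to these files when present.

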