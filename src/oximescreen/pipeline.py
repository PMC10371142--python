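"""End-to-end screening funnel: enumerate -> reactivation -> BBB -> synthesizability.

The pipeline decomposes the input reactivator set, derives enumeration
rules, builds the virtual library, and pushes every candidate through the
sequence of filters, recording the terminal stage each one reaches.  The
per-stage survivor counts are reported with fractions in the style
``"44 of 698 (6.3%)"``.  Outputs carry full provenance: each final target
can be reconstructed (scaffold, linker, fragment assignment, per-OP
classes, BBB class, backend verdict) from the output files alone.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .compounds import CompoundRecord, op_panel
from .descriptors import TOOLKIT_VERSION
from .enumeration import (
    CandidateLibrary,
    enumerate_candidates,
    rules_from_decompositions,
    write_library,
)
from .scaffolds import Decomposition, decompose
from .synthesis import make_backend
from .tasks import TaskModel, predict_broad_spectrum

STAGES = ("enumerated", "broad_spectrum", "bbb_pass", "final")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything a screening run needs; hashed into the outputs for audit."""

    seed: int = 0
    output_dir: str = "screening_output"
    op_panel: tuple[str, ...] = ("PIMP", "NEMP", "PXN", "DFP", "GV")
    n_values: tuple[int, ...] = (3, 4, 5)
    include_special: bool = True
    exclude_inputs: bool = True
    max_swap_fragments: int | None = None
    library_limit: int | None = None
    synthesizability_backend: str = "heuristic-stub"
    backend_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("op_panel", "n_values"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ScreeningRecord:
    candidate_id: str
    smiles: str
    scaffold_id: str
    n: int
    assignment: dict
    per_op_class: dict | None = None
    broad_spectrum: bool | None = None
    bbb_class: str | None = None
    synthesizable: bool | None = None
    stage_reached: str = "enumerated"

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _fraction(part: int, whole: int) -> str:
    pct = 100.0 * part / whole if whole else 0.0
    return f"{part} of {whole} ({pct:.1f}%)"


def screen_library(
    library: CandidateLibrary,
    reactivation_model: TaskModel,
    bbb_model: TaskModel,
    op_names: Sequence[str],
    backend_name: str = "heuristic-stub",
    backend_params: dict | None = None,
) -> tuple[list[ScreeningRecord], dict]:
    """Run the three screening stages over an enumerated library."""
    if not len(library):
        raise PipelineError("screening stage received an empty library")
    if not op_names:
        raise PipelineError("empty OP panel")
    ops = op_panel(op_names)
    records = {
        c.record.id: ScreeningRecord(
            candidate_id=c.record.id,
            smiles=c.record.smiles,
            scaffold_id=c.scaffold_id,
            n=c.n,
            assignment=c.provenance()["assignment"],
        )
        for c in library.records
    }
    order = [c.record.id for c in library.records]
    smiles_of = {c.record.id: c.record.smiles for c in library.records}

    # stage 1: broad-spectrum reactivation
    unique_smiles = list(dict.fromkeys(smiles_of.values()))
    bs = predict_broad_spectrum(reactivation_model, unique_smiles, ops)
    survivors: list[str] = []
    for cid in order:
        row = bs.loc[smiles_of[cid]]
        rec = records[cid]
        rec.per_op_class = {op: row[op] for op in bs.columns if op != "broad_spectrum"}
        rec.broad_spectrum = bool(row["broad_spectrum"])
        if rec.broad_spectrum:
            rec.stage_reached = "broad_spectrum"
            survivors.append(cid)
    n_broad = len(survivors)

    # stage 2: BBB permeability
    if survivors:
        bbb_classes = bbb_model.predict_molecules([smiles_of[c] for c in survivors])
        next_survivors = []
        for cid, cls in zip(survivors, bbb_classes):
            records[cid].bbb_class = cls
            if cls == "BBB+":
                records[cid].stage_reached = "bbb_pass"
                next_survivors.append(cid)
        survivors = next_survivors
    n_bbb = len(survivors)

    # stage 3: synthesizability
    if survivors:
        backend = make_backend(backend_name, **(backend_params or {}))
        verdicts = backend.assess([smiles_of[c] for c in survivors])
        final = []
        for cid, verdict in zip(survivors, verdicts):
            records[cid].synthesizable = bool(verdict)
            if verdict:
                records[cid].stage_reached = "final"
                final.append(cid)
        survivors = final
    n_final = len(survivors)

    total = len(order)
    summary = {
        "library_size": total,
        "broad_spectrum": n_broad,
        "bbb_pass": n_bbb,
        "final": n_final,
        "broad_spectrum_of_library": _fraction(n_broad, total),
        "bbb_pass_of_broad_spectrum": _fraction(n_bbb, n_broad),
        "final_of_bbb_pass": _fraction(n_final, n_bbb),
        "synthesizability_backend": backend_name,
    }
    return [records[cid] for cid in order], summary


def run_pipeline(
    config: PipelineConfig,
    input_sppos: Sequence[CompoundRecord],
    reactivation_model: TaskModel,
    bbb_model: TaskModel,
    decompositions: Sequence[Decomposition] | None = None,
) -> tuple[list[ScreeningRecord], dict]:
    """Full funnel from input structures to final targets, with outputs on disk."""
    if not input_sppos:
        raise PipelineError("enumeration stage received no input structures")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if decompositions is None:
        decompositions = [decompose(rec) for rec in input_sppos]
    rules = rules_from_decompositions(
        decompositions,
        max_swap_fragments=config.max_swap_fragments,
        n_values=config.n_values,
        include_special=config.include_special,
        exclude_inputs=config.exclude_inputs,
    )
    library = enumerate_candidates(
        rules,
        input_smiles=[r.smiles for r in input_sppos],
        limit=config.library_limit,
    )
    if not len(library):
        raise PipelineError("enumeration produced an empty library")
    write_library(library, outdir / "library.smi.gz", outdir / "library_provenance.jsonl")

    records, funnel = screen_library(
        library,
        reactivation_model,
        bbb_model,
        config.op_panel,
        config.synthesizability_backend,
        config.backend_params,
    )

    with open(outdir / "screening_records.jsonl", "w") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")
    finals = [r for r in records if r.stage_reached == "final"]
    import gzip

    with gzip.open(outdir / "survivors.smi.gz", "wt") as fh:
        for rec in finals:
            fh.write(f"{rec.smiles}\t{rec.candidate_id}\n")
    summary = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "toolkit_version": TOOLKIT_VERSION,
        "enumeration_stats": library.stats,
        "funnel": funnel,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    if finals:
        rg = rgroup_summary_from_records(finals)
        rg.to_csv(outdir / "rgroup_summary.csv", index=False)
    return records, summary


def rgroup_summary_from_records(targets: Sequence[ScreeningRecord]) -> pd.DataFrame:
    """Per-position fragment frequencies among surviving candidates.

    Uses the enumeration provenance carried by each record; counts are
    sorted descending within each position.
    """
    if not targets:
        raise PipelineError("empty survivor set")
    counts: dict[str, Counter] = {}
    for rec in targets:
        for pos_label, frag in rec.assignment.items():
            counts.setdefault(pos_label, Counter())[frag] += 1
    rows = []
    for pos_label in sorted(counts):
        for frag, cnt in counts[pos_label].most_common():
            rows.append((pos_label, frag, cnt))
    return pd.DataFrame(rows, columns=["position", "fragment", "count"])


def rgroup_summary(targets: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Like :func:`rgroup_summary_from_records` but from structures alone.

    Every target must decompose against the scaffold registry; a survivor
    that fails to decompose is a hard error (it cannot have been enumerated
    from the scaffolds).
    """
    if not targets:
        raise PipelineError("empty survivor set")
    counts: dict[str, Counter] = {}
    for rec in targets:
        d = decompose(rec)
        for positions, frag in d.assignment.items():
            label = "+".join(f"R{p}" for p in positions)
            counts.setdefault(label, Counter())[frag.pool_key] += 1
    rows = []
    for pos_label in sorted(counts):
        for frag, cnt in counts[pos_label].most_common():
            rows.append((pos_label, frag, cnt))
    return pd.DataFrame(rows, columns=["position", "fragment", "count"])
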