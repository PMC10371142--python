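"""Pluggable synthesizability screening backends.

Retrosynthetic route search is deliberately out of scope here: the filter
is an interface.  Three backends ship:

* ``always-pass`` — accepts everything (useful to disable the stage);
* ``heuristic-stub`` — a documented fragment-complexity rule: a candidate
  passes when its Bertz graph complexity and SSSR ring count both fall
  under configurable caps.  This is a coarse stand-in that orders easy
  before hard chemistry, nothing more;
* ``external-command`` — shells out to a user-installed retrosynthesis
  tool with a JSON contract: the tool reads ``{"smiles": [...]}`` on stdin
  and must print ``{"synthesizable": [true/false, ...]}`` (same order) on
  stdout.  An unavailable or failing tool is an explicit error, never a
  silent pass.
"""

from __future__ import annotations

import json
import shlex
import subprocess
from dataclasses import dataclass
from typing import Protocol, Sequence

from rdkit import Chem
from rdkit.Chem import GraphDescriptors


class SynthesizabilityError(RuntimeError):
    pass


class SynthesizabilityBackend(Protocol):
    name: str

    def assess(self, smiles: Sequence[str]) -> list[bool]: ...


@dataclass
class AlwaysPassBackend:
    name: str = "always-pass"

    def assess(self, smiles: Sequence[str]) -> list[bool]:
        return [True] * len(smiles)


@dataclass
class HeuristicStubBackend:
    """Pass iff BertzCT <= max_bertz and ring count <= max_rings."""

    max_bertz: float = 1500.0
    max_rings: int = 6
    name: str = "heuristic-stub"

    def assess(self, smiles: Sequence[str]) -> list[bool]:
        verdicts = []
        for smi in smiles:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise SynthesizabilityError(f"unparseable candidate: {smi!r}")
            complexity = GraphDescriptors.BertzCT(mol)
            rings = mol.GetRingInfo().NumRings()
            verdicts.append(complexity <= self.max_bertz and rings <= self.max_rings)
        return verdicts


@dataclass
class ExternalCommandBackend:
    """Adapter for a user-installed retrosynthesis tool (JSON stdin/stdout)."""

    command: str
    timeout: float = 3600.0
    name: str = "external-command"

    def assess(self, smiles: Sequence[str]) -> list[bool]:
        payload = json.dumps({"smiles": list(smiles)})
        try:
            proc = subprocess.run(
                shlex.split(self.command),
                input=payload,
                capture_output=True,
                text=True,
                timeout=self.timeout,
                check=False,
            )
        except FileNotFoundError as exc:
            raise SynthesizabilityError(f"backend command not found: {self.command!r}") from exc
        except subprocess.TimeoutExpired as exc:
            raise SynthesizabilityError(f"backend timed out: {self.command!r}") from exc
        if proc.returncode != 0:
            raise SynthesizabilityError(
                f"backend failed (exit {proc.returncode}): {proc.stderr.strip()[:500]}"
            )
        try:
            verdicts = json.loads(proc.stdout)["synthesizable"]
        except (json.JSONDecodeError, KeyError) as exc:
            raise SynthesizabilityError("backend returned malformed JSON") from exc
        if len(verdicts) != len(smiles) or not all(isinstance(v, bool) for v in verdicts):
            raise SynthesizabilityError("backend verdict list does not match input")
        return list(verdicts)


def make_backend(name: str, **params) -> SynthesizabilityBackend:
    if name == "always-pass":
        return AlwaysPassBackend()
    if name == "heuristic-stub":
        return HeuristicStubBackend(**params)
    if name == "external-command":
        return ExternalCommandBackend(**params)
    raise SynthesizabilityError(f"unknown synthesizability backend {name!r}")
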