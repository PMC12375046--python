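"""Chemical-logic rule library: SMARTS-encoded bond form/break templates and
the enumeration of concrete active atom pairs on a structure.

A rule names two mapped atoms in a SMARTS pattern and whether the event between
them forms or breaks a bond.  Applied to a structure, every substructure match
projects the mapped pair onto concrete atom indices; repeated and symmetric
matches are merged so each distinct (i, j, action) proposal appears once, with
the set of rules that produced it.

The rule files are ordinary YAML (see ``data/general_rules.yaml``); the
``provenance`` field records whether an entry is general literature logic or
system-specific logic supplied by an external generator.  ``load_rule_library``
is deliberately agnostic about where a file came from — it is the adapter
surface for externally (e.g. language-model) generated rule sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml
from rdkit import Chem

from .potentials.species import connectivity
from .potentials.structure import Structure

VALID_ACTIONS = ("form", "break")
VALID_PROVENANCE = ("general", "system_specific")

#: minimum graph distance (bonds) for an intramolecular form proposal; shorter
#: separations would just re-propose existing bonds or angles.
MIN_INTRAMOLECULAR_FORM_DISTANCE = 3


class RuleError(ValueError):
    pass


@dataclass
class ReactionRule:
    rule_id: str
    name: str
    smarts: str
    action: str
    mapped_pair: tuple[int, int]
    provenance: str = "general"
    notes: str = ""
    pattern: Chem.Mol = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.action not in VALID_ACTIONS:
            raise RuleError(f"rule {self.rule_id!r}: action must be one of {VALID_ACTIONS}")
        if self.provenance not in VALID_PROVENANCE:
            raise RuleError(f"rule {self.rule_id!r}: provenance must be one of {VALID_PROVENANCE}")
        if self.pattern is None:
            self.pattern = Chem.MolFromSmarts(self.smarts)
        if self.pattern is None:
            raise RuleError(f"rule {self.rule_id!r}: unparsable SMARTS {self.smarts!r}")
        maps = {a.GetAtomMapNum(): a.GetIdx() for a in self.pattern.GetAtoms() if a.GetAtomMapNum()}
        self.mapped_pair = (int(self.mapped_pair[0]), int(self.mapped_pair[1]))
        missing = [m for m in self.mapped_pair if m not in maps]
        if missing:
            raise RuleError(
                f"rule {self.rule_id!r}: mapped_pair atom-map number(s) {missing} "
                f"absent from SMARTS {self.smarts!r}"
            )
        if self.mapped_pair[0] == self.mapped_pair[1]:
            raise RuleError(f"rule {self.rule_id!r}: mapped_pair atoms must differ")
        self._map_to_idx = maps


@dataclass
class RuleLibrary:
    rules: list[ReactionRule] = field(default_factory=list)
    version: str = "0"

    def __post_init__(self):
        seen = set()
        for r in self.rules:
            if r.rule_id in seen:
                raise RuleError(f"duplicate rule_id {r.rule_id!r}")
            seen.add(r.rule_id)

    def __len__(self):
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


@dataclass(frozen=True)
class ActivePair:
    """A concrete bond form/break proposal between atoms i < j of a structure."""

    i: int
    j: int
    action: str
    rule_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.i == self.j:
            raise RuleError("active pair atoms must differ")
        if self.i > self.j:
            lo, hi = self.j, self.i
            object.__setattr__(self, "i", lo)
            object.__setattr__(self, "j", hi)

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.i, self.j, self.action)


def load_rule_library(path: str | Path) -> RuleLibrary:
    """Load and validate a YAML rule file; rules keep file order."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise RuleError(f"{path}: rule file must be a mapping with a 'rules' list")
    entries = doc.get("rules") or []
    rules = []
    for entry in entries:
        try:
            rules.append(ReactionRule(
                rule_id=str(entry["rule_id"]),
                name=str(entry.get("name", entry["rule_id"])),
                smarts=str(entry["smarts"]),
                action=str(entry["action"]),
                mapped_pair=tuple(entry["mapped_pair"]),
                provenance=str(entry.get("provenance", "general")),
                notes=str(entry.get("notes", "")),
            ))
        except KeyError as exc:
            raise RuleError(f"{path}: rule entry missing field {exc}") from None
    return RuleLibrary(rules=rules, version=str(doc.get("version", "0")))


def save_rule_library(lib: RuleLibrary, path: str | Path) -> None:
    doc = {"version": lib.version, "rules": [
        {"rule_id": r.rule_id, "name": r.name, "smarts": r.smarts, "action": r.action,
         "mapped_pair": list(r.mapped_pair), "provenance": r.provenance, "notes": r.notes}
        for r in lib.rules]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def mol_from_structure(s: Structure, graph: nx.Graph | None = None) -> Chem.Mol:
    """RDKit molecule over the covalent connectivity graph (all single bonds).

    Bond orders are not perceived: patterns intended for mid-exploration
    structures should use generic (``~``) or unspecified bonds and connectivity
    primitives (``X<n>``) rather than bond-order primitives.
    """
    g = graph if graph is not None else connectivity(s)
    rw = Chem.RWMol()
    for el in s.elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j in g.edges:
        rw.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return mol


def enumerate_active_pairs(
    s: Structure,
    lib: RuleLibrary,
    graph: nx.Graph | None = None,
) -> list[ActivePair]:
    """All deduplicated active pairs of every rule in the library on one structure.

    Matches are projected onto each rule's mapped pair; proposals are screened
    against the connectivity graph (break needs an existing bond, form needs its
    absence; intramolecular form additionally needs a graph separation of at
    least ``MIN_INTRAMOLECULAR_FORM_DISTANCE`` bonds), then merged on
    (i, j, action) accumulating the contributing rule ids.
    """
    g = graph if graph is not None else connectivity(s)
    mol = mol_from_structure(s, g)
    merged: dict[tuple[int, int, str], set[str]] = {}
    for rule in lib:
        pi = rule._map_to_idx[rule.mapped_pair[0]]
        pj = rule._map_to_idx[rule.mapped_pair[1]]
        for match in mol.GetSubstructMatches(rule.pattern, uniquify=False, maxMatches=100000):
            i, j = match[pi], match[pj]
            if i == j:
                continue
            a, b = (i, j) if i < j else (j, i)
            bonded = g.has_edge(a, b)
            if rule.action == "break" and not bonded:
                continue
            if rule.action == "form":
                if bonded:
                    continue
                if nx.has_path(g, a, b):  # intramolecular
                    if nx.shortest_path_length(g, a, b) < MIN_INTRAMOLECULAR_FORM_DISTANCE:
                        continue
            merged.setdefault((a, b, rule.action), set()).add(rule.rule_id)
    return [ActivePair(i=k[0], j=k[1], action=k[2], rule_ids=frozenset(v))
            for k, v in sorted(merged.items())]


def default_rule_library() -> RuleLibrary:
    """The bundled library of general organic chemical logic."""
    return load_rule_library(Path(__file__).parent / "data" / "general_rules.yaml")
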