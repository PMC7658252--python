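"""Declarative reaction rules with ADD/SUBTRACT/KILL scoring semantics.

A rule (here called a *transform*, following expert-system usage) couples two
reactant roles, described by SMARTS patterns, to a single product through a
SMIRKS template, and carries an ordered list of scoring clauses.  Clauses
inspect either reactant or the raw product and adjust an integer score:
``ADD`` raises it, ``SUBTRACT`` lowers it, and ``KILL`` vetoes the reaction
outright.  ADD/SUBTRACT values are qualitative expert judgements expressed in
increments of five, conventionally between 5 and 30.

Rule files are YAML documents (see ``data/rule_schema.json`` for the published
schema); the loader performs full validation itself and reports offending rule
ids and fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional

import yaml
from rdkit import Chem
from rdkit.Chem import rdChemReactions

__all__ = [
    "ScoringClause",
    "Transform",
    "RuleLoadError",
    "load_rules",
    "serialize_rules",
    "validate_transform",
    "validate_ruleset",
    "clause_matches",
]

ACTIONS = ("ADD", "SUBTRACT", "KILL")
SCOPES = ("reactant_a", "reactant_b", "product")

#: closed vocabulary of named property predicates available to clauses
PROPERTY_PREDICATES = ("heavy_atoms", "ring_count", "net_charge")
PROPERTY_OPS = ("gt", "ge", "lt", "le", "eq", "ne")

_OP_FUNCS = {
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
}


class RuleLoadError(ValueError):
    """Raised when a rule file violates the schema or contains a bad pattern."""


@lru_cache(maxsize=512)
def _compile_smarts(smarts: str) -> Optional[Chem.Mol]:
    return Chem.MolFromSmarts(smarts)


@lru_cache(maxsize=64)
def _compile_reaction(smirks: str) -> Optional[rdChemReactions.ChemicalReaction]:
    try:
        rxn = rdChemReactions.ReactionFromSmarts(smirks)
    except Exception:
        return None
    return rxn


@dataclass(frozen=True)
class ScoringClause:
    """One ADD/SUBTRACT/KILL statement.

    The predicate is either a SMARTS substructure test (``smarts``) or a named
    property comparison (``prop``/``op``/``threshold``) from a closed
    vocabulary.  KILL clauses carry no value.
    """

    scope: str
    action: str
    value: Optional[int] = None
    smarts: Optional[str] = None
    prop: Optional[str] = None
    op: Optional[str] = None
    threshold: Optional[float] = None

    def signed_value(self) -> int:
        if self.action == "ADD":
            return int(self.value)
        if self.action == "SUBTRACT":
            return -int(self.value)
        return 0


def clause_matches(clause: ScoringClause, mol: Chem.Mol) -> bool:
    """Evaluate a clause predicate against a molecule (scope already resolved)."""
    if clause.smarts is not None:
        patt = _compile_smarts(clause.smarts)
        if patt is None:
            raise RuleLoadError(f"unparseable clause SMARTS: {clause.smarts!r}")
        return mol.HasSubstructMatch(patt)
    if clause.prop == "heavy_atoms":
        observed = mol.GetNumHeavyAtoms()
    elif clause.prop == "ring_count":
        observed = Chem.rdMolDescriptors.CalcNumRings(mol)
    elif clause.prop == "net_charge":
        observed = Chem.GetFormalCharge(mol)
    else:  # pragma: no cover - loader rejects unknown predicates
        raise RuleLoadError(f"unknown property predicate: {clause.prop!r}")
    return _OP_FUNCS[clause.op](observed, clause.threshold)


@dataclass
class Transform:
    """One reaction rule: role patterns, product template, scoring clauses."""

    id: int
    name: str
    role_a_pattern: str
    role_b_pattern: str
    product_template: str
    leaving_groups: list[str] = field(default_factory=list)
    ring_forming: bool = False
    clauses: list[ScoringClause] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def role_a(self) -> Chem.Mol:
        return _compile_smarts(self.role_a_pattern)

    @property
    def role_b(self) -> Chem.Mol:
        return _compile_smarts(self.role_b_pattern)

    @property
    def reaction(self) -> rdChemReactions.ChemicalReaction:
        return _compile_reaction(self.product_template)

    def leaving_group_heavy_atoms(self) -> int:
        """Total heavy atoms across the declared leaving-group fragments."""
        total = 0
        for smi in self.leaving_groups:
            frag = Chem.MolFromSmiles(smi)
            if frag is None:
                raise RuleLoadError(
                    f"rule {self.id}: unparseable leaving group {smi!r}"
                )
            total += frag.GetNumHeavyAtoms()
        return total


# ---------------------------------------------------------------------------
# loading / serialization


def _clause_from_mapping(raw: dict, rule_id, idx: int, permissive: bool) -> ScoringClause:
    where = f"rule {rule_id}, clause {idx}"
    if not isinstance(raw, dict):
        raise RuleLoadError(f"{where}: clause must be a mapping")
    scope = raw.get("scope")
    if scope not in SCOPES:
        raise RuleLoadError(f"{where}: field 'scope' must be one of {SCOPES}, got {scope!r}")
    action = raw.get("action")
    if action not in ACTIONS:
        raise RuleLoadError(f"{where}: field 'action' must be one of {ACTIONS}, got {action!r}")

    smarts = raw.get("smarts")
    prop = raw.get("property")
    if (smarts is None) == (prop is None):
        raise RuleLoadError(f"{where}: exactly one of 'smarts' or 'property' is required")
    op = raw.get("op")
    threshold = raw.get("threshold")
    if smarts is not None:
        if _compile_smarts(str(smarts)) is None:
            raise RuleLoadError(f"{where}: unparseable SMARTS pattern {smarts!r}")
        op = threshold = None
    else:
        if prop not in PROPERTY_PREDICATES:
            raise RuleLoadError(
                f"{where}: field 'property' must be one of {PROPERTY_PREDICATES}, got {prop!r}"
            )
        if op not in PROPERTY_OPS:
            raise RuleLoadError(f"{where}: field 'op' must be one of {PROPERTY_OPS}, got {op!r}")
        if not isinstance(threshold, (int, float)):
            raise RuleLoadError(f"{where}: field 'threshold' must be numeric")

    value = raw.get("value")
    if action == "KILL":
        if value is not None:
            raise RuleLoadError(f"{where}: KILL clauses carry no 'value'")
    else:
        if not isinstance(value, int):
            raise RuleLoadError(f"{where}: field 'value' must be an integer")
        if not permissive and (value % 5 != 0 or not 5 <= value <= 30):
            raise RuleLoadError(
                f"{where}: field 'value' must be a multiple of 5 in [5, 30], got {value}"
            )
        if permissive and value <= 0:
            raise RuleLoadError(f"{where}: field 'value' must be positive")

    return ScoringClause(
        scope=scope,
        action=action,
        value=value,
        smarts=None if smarts is None else str(smarts),
        prop=prop,
        op=op,
        threshold=threshold,
    )


def _transform_from_mapping(raw: dict, permissive: bool) -> Transform:
    if not isinstance(raw, dict):
        raise RuleLoadError("each transform must be a mapping")
    rule_id = raw.get("id")
    if not isinstance(rule_id, int):
        raise RuleLoadError(f"transform field 'id' must be an integer, got {rule_id!r}")
    where = f"rule {rule_id}"

    name = raw.get("name")
    if not isinstance(name, str) or not name:
        raise RuleLoadError(f"{where}: field 'name' must be non-empty text")

    for key in ("role_a", "role_b"):
        patt = raw.get(key)
        if not isinstance(patt, str) or _compile_smarts(patt) is None:
            raise RuleLoadError(f"{where}: field '{key}' has unparseable pattern {patt!r}")

    template = raw.get("product_template")
    if not isinstance(template, str) or _compile_reaction(template) is None:
        raise RuleLoadError(
            f"{where}: field 'product_template' has unparseable template {template!r}"
        )

    leaving = raw.get("leaving_groups", [])
    if not isinstance(leaving, list) or not all(isinstance(x, str) for x in leaving):
        raise RuleLoadError(f"{where}: field 'leaving_groups' must be a list of SMILES")
    for smi in leaving:
        if Chem.MolFromSmiles(smi) is None:
            raise RuleLoadError(f"{where}: field 'leaving_groups' has unparseable SMILES {smi!r}")

    ring_forming = raw.get("ring_forming", False)
    if not isinstance(ring_forming, bool):
        raise RuleLoadError(f"{where}: field 'ring_forming' must be boolean")

    clauses_raw = raw.get("clauses", [])
    if not isinstance(clauses_raw, list):
        raise RuleLoadError(f"{where}: field 'clauses' must be a list")
    clauses = [
        _clause_from_mapping(c, rule_id, i, permissive) for i, c in enumerate(clauses_raw)
    ]

    metadata = raw.get("metadata", {}) or {}
    if not isinstance(metadata, dict):
        raise RuleLoadError(f"{where}: field 'metadata' must be a mapping")

    return Transform(
        id=rule_id,
        name=name,
        role_a_pattern=raw["role_a"],
        role_b_pattern=raw["role_b"],
        product_template=template,
        leaving_groups=list(leaving),
        ring_forming=ring_forming,
        clauses=clauses,
        metadata=dict(metadata),
    )


def load_rules(path, permissive: bool = False) -> list[Transform]:
    """Load and validate a YAML rule file.

    Parameters
    ----------
    path : str or pathlib.Path
        Rule file; top level is a mapping with a ``transforms`` list (an empty
        or absent list yields an empty result).
    permissive : bool
        If set, ADD/SUBTRACT values only need to be positive integers rather
        than multiples of 5 in [5, 30].
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return []
    if not isinstance(doc, dict) or not isinstance(doc.get("transforms", []), list):
        raise RuleLoadError("rule file must be a mapping with a 'transforms' list")
    transforms = [
        _transform_from_mapping(raw, permissive) for raw in doc.get("transforms", [])
    ]
    dup = validate_ruleset(transforms)
    if dup:
        raise RuleLoadError("; ".join(dup))
    return transforms


def serialize_rules(transforms: Iterable[Transform], path) -> None:
    """Write transforms back to YAML, preserving clause order and values."""
    out = {"transforms": []}
    for t in transforms:
        clauses = []
        for c in t.clauses:
            entry = {"scope": c.scope, "action": c.action}
            if c.smarts is not None:
                entry["smarts"] = c.smarts
            else:
                entry.update({"property": c.prop, "op": c.op, "threshold": c.threshold})
            if c.value is not None:
                entry["value"] = c.value
            clauses.append(entry)
        out["transforms"].append(
            {
                "id": t.id,
                "name": t.name,
                "role_a": t.role_a_pattern,
                "role_b": t.role_b_pattern,
                "product_template": t.product_template,
                "leaving_groups": list(t.leaving_groups),
                "ring_forming": t.ring_forming,
                "clauses": clauses,
                "metadata": dict(t.metadata),
            }
        )
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# validation diagnostics


def _template_dropped_heavy_atoms(rxn: rdChemReactions.ChemicalReaction) -> int:
    """Heavy atoms on the reactant side of a template that do not reach the product.

    Unmapped reactant-template atoms, and mapped atoms whose map number is
    absent from the product side, are both dropped by template application and
    must be accounted for by declared leaving groups.
    """
    product_maps = set()
    for i in range(rxn.GetNumProductTemplates()):
        for atom in rxn.GetProductTemplate(i).GetAtoms():
            if atom.GetAtomMapNum():
                product_maps.add(atom.GetAtomMapNum())
    dropped = 0
    for i in range(rxn.GetNumReactantTemplates()):
        for atom in rxn.GetReactantTemplate(i).GetAtoms():
            if atom.GetAtomicNum() == 1:
                continue
            if atom.GetAtomMapNum() not in product_maps:
                dropped += 1
    return dropped


def validate_transform(t: Transform) -> list[str]:
    """Return human-readable diagnostics; empty iff the transform is well formed."""
    diags: list[str] = []
    if t.role_a is None:
        diags.append(f"rule {t.id}: role_a pattern does not parse: {t.role_a_pattern!r}")
    if t.role_b is None:
        diags.append(f"rule {t.id}: role_b pattern does not parse: {t.role_b_pattern!r}")
    rxn = t.reaction
    if rxn is None:
        diags.append(f"rule {t.id}: product template does not parse")
        return diags
    if rxn.GetNumReactantTemplates() != 2:
        diags.append(
            f"rule {t.id}: product template must take exactly two reactants, "
            f"has {rxn.GetNumReactantTemplates()}"
        )
    if rxn.GetNumProductTemplates() != 1:
        diags.append(
            f"rule {t.id}: product template must yield exactly one product, "
            f"has {rxn.GetNumProductTemplates()}"
        )
    try:
        declared = t.leaving_group_heavy_atoms()
    except RuleLoadError as exc:
        diags.append(str(exc))
    else:
        dropped = _template_dropped_heavy_atoms(rxn)
        if dropped != declared:
            diags.append(
                f"rule {t.id}: template drops {dropped} heavy atom(s) but leaving_groups "
                f"declare {declared}"
            )
    seen = set()
    for i, c in enumerate(t.clauses):
        key = (c.scope, c.action, c.value, c.smarts, c.prop, c.op, c.threshold)
        if key in seen:
            diags.append(f"rule {t.id}: clause {i} duplicates an earlier clause")
        seen.add(key)
        if c.action == "KILL" and c.value is not None:
            diags.append(f"rule {t.id}: clause {i} is KILL but carries a value")
    return diags


def validate_ruleset(transforms: list[Transform]) -> list[str]:
    """Cross-rule diagnostics (currently: id uniqueness)."""
    diags = []
    seen: dict[int, int] = {}
    for t in transforms:
        if t.id in seen:
            diags.append(f"rule id {t.id} appears more than once")
        seen[t.id] = 1
    return diags
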