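"""Protecting-group detection and removal.

Seven protecting groups are handled, mirroring the standard set used in
building-block catalogs: Boc, Fmoc and Cbz on amines; tert-butyl and benzyl
esters on carboxyls; tert-butyl ether and benzoate on hydroxyls.  Products are
stored deprotected; the product id carries a ``-DP`` suffix when anything was
removed and ``-UN`` otherwise.

Definitions ship as a YAML data file (label, detection SMARTS, removal SMIRKS,
attachment class) so the set can be extended without code changes.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import yaml
from rdkit import Chem
from rdkit.Chem import rdChemReactions

__all__ = [
    "ProtectingGroup",
    "load_protecting_groups",
    "default_protecting_groups",
    "detect_pgs",
    "deprotect",
    "suffix_id",
    "DeprotectionError",
]

_MAX_REMOVAL_PASSES = 50


class DeprotectionError(RuntimeError):
    """A removal template produced an invalid structure (a bug signal)."""


@dataclass(frozen=True)
class ProtectingGroup:
    label: str
    attach_class: str  # amine | carboxyl | hydroxyl
    match_pattern: str  # SMARTS; attach_index names the substrate-side atom
    removal_template: str  # SMIRKS restoring the free functional group
    attach_index: int = 0

    @property
    def pattern(self) -> Chem.Mol:
        return _smarts(self.match_pattern)

    @property
    def removal(self) -> rdChemReactions.ChemicalReaction:
        return _reaction(self.removal_template)


@functools.lru_cache(maxsize=128)
def _smarts(s: str) -> Chem.Mol:
    patt = Chem.MolFromSmarts(s)
    if patt is None:
        raise ValueError(f"unparseable protecting-group SMARTS: {s!r}")
    return patt


@functools.lru_cache(maxsize=128)
def _reaction(s: str) -> rdChemReactions.ChemicalReaction:
    return rdChemReactions.ReactionFromSmarts(s)


def load_protecting_groups(path) -> list[ProtectingGroup]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    groups = []
    for raw in doc["protecting_groups"]:
        groups.append(
            ProtectingGroup(
                label=raw["label"],
                attach_class=raw["attach_class"],
                match_pattern=raw["smarts"],
                removal_template=raw["removal"],
                attach_index=raw.get("attach_index", 0),
            )
        )
    return groups


@functools.lru_cache(maxsize=1)
def default_protecting_groups() -> tuple[ProtectingGroup, ...]:
    ref = resources.files("synforge.data") / "protecting_groups.yaml"
    with resources.as_file(ref) as path:
        return tuple(load_protecting_groups(path))


def _as_mol(mol_or_smiles) -> Chem.Mol:
    if isinstance(mol_or_smiles, Chem.Mol):
        return mol_or_smiles
    mol = Chem.MolFromSmiles(mol_or_smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {mol_or_smiles!r}")
    return mol


def detect_pgs(mol_or_smiles, groups=None) -> list[tuple[str, int]]:
    """Report every protecting-group occurrence as (label, attachment atom index).

    Matches are uniquified by atom set, so symmetric patterns report each
    physical occurrence once.
    """
    mol = _as_mol(mol_or_smiles)
    groups = default_protecting_groups() if groups is None else groups
    hits: list[tuple[str, int]] = []
    for pg in groups:
        seen: set[frozenset] = set()
        for match in mol.GetSubstructMatches(pg.pattern, uniquify=True):
            key = frozenset(match)
            if key in seen:
                continue
            seen.add(key)
            hits.append((pg.label, match[pg.attach_index]))
    return hits


def deprotect(mol_or_smiles, groups=None) -> tuple[str, list[str]]:
    """Strip all protecting groups, returning (free canonical SMILES, removed labels).

    Removal templates are applied one occurrence at a time until no group is
    detected; on a PG-free input this is the identity.
    """
    mol = _as_mol(mol_or_smiles)
    groups = default_protecting_groups() if groups is None else groups
    removed: list[str] = []
    for _ in range(_MAX_REMOVAL_PASSES):
        hit = None
        for pg in groups:
            if mol.HasSubstructMatch(pg.pattern):
                hit = pg
                break
        if hit is None:
            return Chem.MolToSmiles(mol), removed
        products = hit.removal.RunReactants((mol,))
        if not products:
            raise DeprotectionError(
                f"{hit.label}: pattern matched but removal template did not apply "
                f"on {Chem.MolToSmiles(mol)}"
            )
        cand = products[0][0]
        try:
            cand = Chem.RemoveHs(cand)
            Chem.SanitizeMol(cand)
        except Exception as exc:
            raise DeprotectionError(
                f"{hit.label}: removal produced an invalid structure "
                f"from {Chem.MolToSmiles(mol)}: {exc}"
            ) from exc
        mol = cand
        removed.append(hit.label)
    raise DeprotectionError("removal did not terminate; cyclic protecting-group match?")


def suffix_id(base_id: str, removed: list[str]) -> str:
    """Append ``-DP`` if any group was removed from the product, else ``-UN``."""
    if not base_id:
        raise ValueError("base_id must be non-empty")
    return f"{base_id}-DP" if removed else f"{base_id}-UN"
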