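"""Building-block standardization, filtering, deduplication, and role assignment.

Raw catalog SMILES are reduced to their largest organic fragment, normalized
and neutralized; each record gets a stereo-sensitive but tautomer-insensitive
unique key (canonical tautomer, isomeric canonical SMILES) used for
deduplication and product uniqueness.  Filters reject isotopically labelled
atoms, metals, and overly complex structures (Bertz complexity above a
configurable cutoff).

Role assignment matches the prepared blocks against a transform's two reactant
patterns and applies two exclusions to keep products unambiguous:

* a block matching *both* roles is excluded from both sets (it would
  oligomerize);
* a block matching one role at more than one symmetry-distinct site is
  excluded from that set (it would yield product mixtures).

Dual-role exclusion is applied first.  Match sites are uniquified by atom set,
so a pattern matching the same atoms in two orientations counts as one site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from rdkit import Chem
from rdkit.Chem import GraphDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .deprotect import detect_pgs

__all__ = [
    "BuildingBlock",
    "RoleSet",
    "FilterConfig",
    "standardize",
    "filter_bb",
    "deduplicate",
    "assign_roles",
    "count_match_sites",
    "unique_key",
    "prepare",
]

#: elements tolerated in building blocks; B and Si stay because boronates and
#: silanes are required coupling partners, Se because selenophenes occur in
#: catalog stock.
DEFAULT_ALLOWED_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the building-block filters."""

    complexity_cutoff: float = 1000.0  # Bertz CT units; catalog blocks sit well below
    allowed_elements: frozenset = DEFAULT_ALLOWED_ELEMENTS


@dataclass
class BuildingBlock:
    bb_id: str
    smiles_raw: str
    smiles_std: Optional[str] = None
    unique_key: Optional[str] = None
    protecting_groups: list[str] = field(default_factory=list)
    complexity: float = 0.0
    rejected: Optional[str] = None

    def mol(self) -> Optional[Chem.Mol]:
        if self.smiles_std is None:
            return None
        return Chem.MolFromSmiles(self.smiles_std)


@dataclass
class RoleSet:
    transform_id: int
    role: str  # "A" or "B"
    members: list[str] = field(default_factory=list)
    excluded_dual_role: list[str] = field(default_factory=list)
    excluded_multi_site: list[str] = field(default_factory=list)


# one shared set of standardization tools; construction is not free
_LARGEST = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def _tautomer_enumerator() -> rdMolStandardize.TautomerEnumerator:
    # stereo must survive tautomer canonicalization: enantiomers keep
    # distinct keys while keto/enol pairs merge
    params = rdMolStandardize.CleanupParameters()
    params.tautomerRemoveSp3Stereo = False
    params.tautomerRemoveBondStereo = False
    params.tautomerRemoveIsotopicHs = False
    return rdMolStandardize.TautomerEnumerator(params)


_TAUTOMER = _tautomer_enumerator()


def unique_key(mol: Chem.Mol) -> str:
    """Stereo-sensitive, tautomer-insensitive canonical identifier."""
    canon = _TAUTOMER.Canonicalize(mol)
    return Chem.MolToSmiles(canon)


def standardize(smiles_raw: str, bb_id: str = "") -> BuildingBlock:
    """Largest organic fragment, normalized, neutralized; PGs detected."""
    bb = BuildingBlock(bb_id=bb_id, smiles_raw=smiles_raw)
    if not smiles_raw or not smiles_raw.strip():
        bb.rejected = "parse_error"
        return bb
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        bb.rejected = "parse_error"
        return bb
    mol = rdMolStandardize.Cleanup(mol)
    mol = _LARGEST.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    bb.smiles_std = Chem.MolToSmiles(mol)
    bb.unique_key = unique_key(mol)
    bb.protecting_groups = sorted({label for label, _ in detect_pgs(mol)})
    bb.complexity = float(GraphDescriptors.BertzCT(mol))
    return bb


def filter_bb(bb: BuildingBlock, config: FilterConfig = FilterConfig()) -> BuildingBlock:
    """Set ``rejected`` to isotope/metal/complexity (first hit wins) or leave None."""
    if bb.rejected is not None:
        return bb
    mol = bb.mol()
    if mol is None:  # pragma: no cover - standardize() already rejected
        bb.rejected = "parse_error"
        return bb
    if any(atom.GetIsotope() != 0 for atom in mol.GetAtoms()):
        bb.rejected = "isotope"
        return bb
    if any(atom.GetSymbol() not in config.allowed_elements for atom in mol.GetAtoms()):
        bb.rejected = "metal"
        return bb
    if bb.complexity > config.complexity_cutoff:
        bb.rejected = "complexity"
        return bb
    return bb


def deduplicate(bbs: Iterable[BuildingBlock]) -> list[BuildingBlock]:
    """One record per unique key; first occurrence wins. Rejected records pass through."""
    seen: set[str] = set()
    out: list[BuildingBlock] = []
    for bb in bbs:
        if bb.unique_key is None:
            out.append(bb)
            continue
        if bb.unique_key in seen:
            continue
        seen.add(bb.unique_key)
        out.append(bb)
    return out


def count_match_sites(mol: Chem.Mol, pattern: Chem.Mol) -> int:
    """Symmetry-distinct substructure sites: matches uniquified by atom set."""
    matches = mol.GetSubstructMatches(pattern, uniquify=True)
    return len({frozenset(m) for m in matches})


def assign_roles(transform, bbs: Iterable[BuildingBlock]) -> tuple[RoleSet, RoleSet]:
    """Partition accepted blocks into role members and exclusion lists.

    Every block matching a role lands in exactly one of that role's
    {members, excluded_dual_role, excluded_multi_site}.
    """
    role_a = RoleSet(transform_id=transform.id, role="A")
    role_b = RoleSet(transform_id=transform.id, role="B")
    patt_a, patt_b = transform.role_a, transform.role_b
    for bb in bbs:
        if bb.rejected is not None:
            continue
        mol = bb.mol()
        if mol is None:
            continue
        sites_a = count_match_sites(mol, patt_a)
        sites_b = count_match_sites(mol, patt_b)
        if sites_a and sites_b:
            role_a.excluded_dual_role.append(bb.bb_id)
            role_b.excluded_dual_role.append(bb.bb_id)
            continue
        if sites_a:
            (role_a.members if sites_a == 1 else role_a.excluded_multi_site).append(bb.bb_id)
        if sites_b:
            (role_b.members if sites_b == 1 else role_b.excluded_multi_site).append(bb.bb_id)
    for rs in (role_a, role_b):
        rs.members.sort()
        rs.excluded_dual_role.sort()
        rs.excluded_multi_site.sort()
    return role_a, role_b


def prepare(
    smiles_records: Iterable[tuple[str, str]],
    config: FilterConfig = FilterConfig(),
) -> list[BuildingBlock]:
    """Standardize, filter and deduplicate (id, smiles) records in one pass."""
    bbs = [filter_bb(standardize(smi, bb_id), config) for bb_id, smi in smiles_records]
    accepted = deduplicate([bb for bb in bbs if bb.rejected is None])
    rejected = [bb for bb in bbs if bb.rejected is not None]
    return accepted + rejected
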