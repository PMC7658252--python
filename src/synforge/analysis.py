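"""Library-level bookkeeping: class distributions, closed-form estimates,
ring-system census, and database overlap.

The closed-form estimates follow the combinatorial accounting of two-reactant
library generation: with N building blocks and T transforms of the form
A + B -> C, the theoretical product maximum is (1/2) N^2 T (unordered pairs);
the overall success ratio is that maximum divided by the saved-reaction count;
and each saved product's expected number of SAR neighbors (products sharing
one building block) is N times the fill fraction of the triangular N x N
matrix.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import pandas as pd
import yaml
from rdkit import Chem

__all__ = [
    "RingSystemCensus",
    "class_distribution",
    "class_distribution_from_counts",
    "kill_loss_rate",
    "theoretical_max",
    "success_ratio",
    "round_sig",
    "sar_neighbors",
    "ring_systems",
    "ring_system_census",
    "overlap",
    "load_reference_run",
]

CLASS_ORDER = ("Plus", "Neg0", "Neg10", "Neg20", "Neg30")


@dataclass
class RingSystemCensus:
    """Unique ring systems with per-system frequencies.

    A ring system is one connected component of ring atoms and ring bonds;
    fused and spiro-joined rings form a single system, isolated rings separate
    ones.  Systems are identified by the canonical SMILES of the extracted
    ring-only substructure.
    """

    counts: Counter = field(default_factory=Counter)

    @property
    def systems(self) -> set:
        return set(self.counts)

    def overlap_with(self, other: "RingSystemCensus") -> tuple[int, int, int]:
        common = self.systems & other.systems
        return len(common), len(self.systems - common), len(other.systems - common)


# ---------------------------------------------------------------------------
# class bookkeeping


def class_distribution_from_counts(counts: dict) -> pd.DataFrame:
    """Distribution table from per-class counts.

    ``counts`` maps class label to either a saved count or a
    ``(saved, unique)`` pair.  Percentages are saved/total*100 rounded to two
    decimals; an all-zero input yields an empty table.
    """
    norm: dict[str, tuple[int, Optional[int]]] = {}
    for label, val in counts.items():
        if isinstance(val, (tuple, list)):
            norm[label] = (int(val[0]), int(val[1]))
        else:
            norm[label] = (int(val), None)
    total = sum(saved for saved, _ in norm.values())
    if total == 0:
        return pd.DataFrame(columns=["class", "saved", "unique", "percent"])
    rows = []
    for label in sorted(norm, key=lambda c: CLASS_ORDER.index(c) if c in CLASS_ORDER else 99):
        saved, uniq = norm[label]
        rows.append(
            {
                "class": label,
                "saved": saved,
                "unique": uniq,
                "percent": round(saved / total * 100, 2),
            }
        )
    return pd.DataFrame(rows)


def class_distribution(records) -> pd.DataFrame:
    """Distribution table from saved reaction records."""
    saved = Counter(rec.class_label for rec in records)
    uniq: dict[str, set] = {}
    for rec in records:
        uniq.setdefault(rec.class_label, set()).add(rec.product_key)
    return class_distribution_from_counts(
        {label: (saved[label], len(uniq[label])) for label in saved}
    )


def kill_loss_rate(tested_pairs: float, saved: float) -> float:
    """Fraction of tested pairs lost, 1 - saved/tested."""
    if tested_pairs <= 0:
        raise ValueError("tested_pairs must be positive")
    return 1.0 - saved / tested_pairs


# ---------------------------------------------------------------------------
# closed-form estimates


def theoretical_max(n_bb: int, n_transforms: int) -> float:
    """Upper bound on products: (1/2) * n_bb^2 * n_transforms (unordered pairs)."""
    if n_bb < 0 or n_transforms < 0:
        raise ValueError("counts must be non-negative")
    return 0.5 * n_bb**2 * n_transforms


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report-display convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def success_ratio(theoretical_maximum: float, total_saved: int) -> Optional[float]:
    """Reciprocal success ratio, theoretical max / saved; None when saved is 0."""
    if total_saved == 0:
        return None
    return theoretical_maximum / total_saved


def sar_neighbors(n_bb: int, total_saved: int) -> tuple[float, float]:
    """(fill fraction, mean SAR-neighbor estimate).

    fill = saved / ((1/2) n_bb^2) is the occupancy of the triangular reactant
    matrix; a saved product then has about n_bb * fill neighbors sharing one
    of its two building blocks.
    """
    if n_bb <= 0:
        raise ValueError("n_bb must be positive")
    fill = total_saved / (0.5 * n_bb**2)
    return fill, n_bb * fill


# ---------------------------------------------------------------------------
# ring systems


def ring_systems(mol_or_smiles, include_exocyclic_double: bool = False) -> list[str]:
    """Canonical SMILES of each ring system instance in a molecule.

    By default only ring atoms and ring bonds enter the system; with
    ``include_exocyclic_double`` atoms double-bonded to a ring atom (e.g. a
    carbonyl oxygen on a ring) are pulled in as well.
    """
    mol = mol_or_smiles
    if not isinstance(mol, Chem.Mol):
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {mol_or_smiles!r}")
    ri = mol.GetRingInfo()
    ring_bonds = [b.GetIdx() for b in mol.GetBonds() if ri.NumBondRings(b.GetIdx())]
    if not ring_bonds:
        return []
    # union-find over ring bonds sharing an atom -> connected ring components
    parent = list(range(mol.GetNumAtoms()))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for bidx in ring_bonds:
        bond = mol.GetBondWithIdx(bidx)
        union(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())

    components: dict[int, list[int]] = {}
    for bidx in ring_bonds:
        root = find(mol.GetBondWithIdx(bidx).GetBeginAtomIdx())
        components.setdefault(root, []).append(bidx)

    out = []
    for bond_ids in components.values():
        bond_ids = list(bond_ids)
        if include_exocyclic_double:
            comp_atoms = set()
            for bidx in bond_ids:
                bond = mol.GetBondWithIdx(bidx)
                comp_atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
            for bond in mol.GetBonds():
                if ri.NumBondRings(bond.GetIdx()):
                    continue
                if bond.GetBondType() != Chem.BondType.DOUBLE:
                    continue
                a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
                if a in comp_atoms or b in comp_atoms:
                    bond_ids.append(bond.GetIdx())
        sub = Chem.PathToSubmol(mol, bond_ids)
        out.append(Chem.MolToSmiles(sub))
    return sorted(out)


def ring_system_census(
    products: Iterable, include_exocyclic_double: bool = False
) -> RingSystemCensus:
    """Census over an iterable of SMILES (or mols): unique systems + frequencies."""
    census = RingSystemCensus()
    for item in products:
        for system in ring_systems(item, include_exocyclic_double):
            census.counts[system] += 1
    return census


# ---------------------------------------------------------------------------
# overlap


def overlap(set_a: Iterable, set_b: Iterable) -> tuple[int, int, int]:
    """(|a n b|, |a only|, |b only|) on unique keys from one canonicalization scheme."""
    a, b = set(set_a), set(set_b)
    common = a & b
    return len(common), len(a - common), len(b - common)


# ---------------------------------------------------------------------------
# shipped production-scale bookkeeping table


def load_reference_run() -> dict:
    """Bookkeeping numbers of the production-scale release run (shipped data).

    Keys: ``class_counts`` (label -> {saved, unique}), ``accepted_bbs``,
    ``matched_bbs``, ``n_transforms``, ``tested_pairs``.  These are inputs to
    the formatter and estimate formulas, not computed results.
    """
    ref = resources.files("synforge.data") / "reference_run.yaml"
    with resources.as_file(ref) as path:
        with open(path) as fh:
            return yaml.safe_load(fh)
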