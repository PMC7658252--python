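"""Per-product drug-design descriptors.

Each product is annotated with the standard medicinal-chemistry block:
molecular weight, computed logP (Crippen atom-contribution method), TPSA,
fraction of sp3 carbons, rotatable bonds, H-bond donors/acceptors, rule-of-five
and rule-of-three violation counts, PAINS matches, QED, and an additive
demerit score over substructure alert rules (lower is better; the conventional
cutoffs are <100 strict and <160 loose).

All descriptors are pure functions of the canonical structure.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, FilterCatalog, Lipinski, QED, rdMolDescriptors

__all__ = [
    "ProductAnnotation",
    "DemeritRule",
    "AnnotationError",
    "annotate",
    "ro5_violations",
    "ro3_violations",
    "pains_count",
    "demerit_score",
    "demerit_flags",
    "qed_score",
    "load_demerit_rules",
    "default_demerit_rules",
    "annotation_table",
]

DEMERIT_STRICT_LIMIT = 100
DEMERIT_LOOSE_LIMIT = 160

#: method names recorded in output metadata
DESCRIPTOR_METHODS = {
    "logp": "Crippen atom contribution",
    "tpsa": "topological polar surface area (Ertl)",
    "rotatable_bonds": "strict non-ring single bonds",
    "qed": "QED, mean-weighted desirability (published weights)",
}


class AnnotationError(ValueError):
    """Carried in the record when a product cannot be annotated; runs continue."""


@dataclass(frozen=True)
class ProductAnnotation:
    mw: float
    logp: float
    tpsa: float
    fsp3: float
    rotatable_bonds: int
    hbd: int
    hba: int
    ro5_violations: int
    ro3_violations: int
    pains_count: int
    qed: float
    demerits: int
    demerit_rule_ids: tuple = ()
    demerit_strict_pass: bool = True
    demerit_loose_pass: bool = True


@dataclass(frozen=True)
class DemeritRule:
    rule_id: str
    smarts: str
    demerits: int
    description: str = ""

    @property
    def pattern(self) -> Chem.Mol:
        return _smarts(self.smarts)


@functools.lru_cache(maxsize=512)
def _smarts(s: str) -> Chem.Mol:
    patt = Chem.MolFromSmarts(s)
    if patt is None:
        raise ValueError(f"unparseable demerit SMARTS: {s!r}")
    return patt


@functools.lru_cache(maxsize=1)
def _pains_catalog() -> FilterCatalog.FilterCatalog:
    params = FilterCatalog.FilterCatalogParams()
    params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
    return FilterCatalog.FilterCatalog(params)


def _as_mol(mol_or_smiles) -> Chem.Mol:
    if isinstance(mol_or_smiles, Chem.Mol):
        return mol_or_smiles
    mol = Chem.MolFromSmiles(mol_or_smiles)
    if mol is None:
        raise AnnotationError(f"unparseable SMILES: {mol_or_smiles!r}")
    return mol


def ro5_violations(mw: float, logp: float, hbd: int, hba: int) -> int:
    """Lipinski rule-of-five exceedance count (0-4)."""
    return sum([mw > 500, logp > 5, hbd > 5, hba > 10])


def ro3_violations(mw: float, logp: float, hbd: int, rotatable_bonds: int, tpsa: float) -> int:
    """Fragment rule-of-three exceedance count (0-5)."""
    return sum([mw > 300, logp > 3, hbd > 3, rotatable_bonds > 3, tpsa > 60])


def pains_count(mol_or_smiles) -> int:
    """Number of distinct PAINS alert patterns matched."""
    mol = _as_mol(mol_or_smiles)
    return len(_pains_catalog().GetMatches(mol))


def qed_score(mol_or_smiles) -> float:
    """Quantitative estimate of drug-likeness, in (0, 1]."""
    return float(QED.qed(_as_mol(mol_or_smiles)))


def load_demerit_rules(path) -> list[DemeritRule]:
    """Load a demerit rule file (any size; users may drop in a full set)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    rules = []
    for raw in doc.get("rules", []):
        rule = DemeritRule(
            rule_id=str(raw["id"]),
            smarts=raw["smarts"],
            demerits=int(raw["demerits"]),
            description=raw.get("description", ""),
        )
        _ = rule.pattern  # validate eagerly
        if rule.demerits < 0:
            raise ValueError(f"demerit rule {rule.rule_id}: negative demerit value")
        rules.append(rule)
    return rules


@functools.lru_cache(maxsize=1)
def default_demerit_rules() -> tuple[DemeritRule, ...]:
    ref = resources.files("synforge.data") / "demerit_rules.yaml"
    with resources.as_file(ref) as path:
        return tuple(load_demerit_rules(path))


def demerit_score(mol_or_smiles, rules=None) -> tuple[int, list[str]]:
    """Additive demerit total plus the matched rule ids."""
    mol = _as_mol(mol_or_smiles)
    rules = default_demerit_rules() if rules is None else rules
    total = 0
    matched: list[str] = []
    for rule in rules:
        if mol.HasSubstructMatch(rule.pattern):
            total += rule.demerits
            matched.append(rule.rule_id)
    return total, matched


def demerit_flags(total: int) -> tuple[bool, bool]:
    """(strict pass, loose pass) under the <100 / <160 conventions."""
    return total < DEMERIT_STRICT_LIMIT, total < DEMERIT_LOOSE_LIMIT


def annotate(mol_or_smiles, demerit_rules=None) -> ProductAnnotation:
    """Compute the full annotation block for one product.

    The input is re-canonicalized first so annotations are exact functions of
    the canonical structure (atom-order and SMILES-spelling invariant).
    """
    mol = _as_mol(mol_or_smiles)
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    mw = float(Descriptors.MolWt(mol))
    logp = float(Crippen.MolLogP(mol))
    tpsa = float(rdMolDescriptors.CalcTPSA(mol))
    fsp3 = float(rdMolDescriptors.CalcFractionCSP3(mol))
    rotb = int(rdMolDescriptors.CalcNumRotatableBonds(mol))
    hbd = int(Lipinski.NumHDonors(mol))
    hba = int(Lipinski.NumHAcceptors(mol))
    demerits, matched = demerit_score(mol, demerit_rules)
    strict, loose = demerit_flags(demerits)
    return ProductAnnotation(
        mw=mw,
        logp=logp,
        tpsa=tpsa,
        fsp3=fsp3,
        rotatable_bonds=rotb,
        hbd=hbd,
        hba=hba,
        ro5_violations=ro5_violations(mw, logp, hbd, hba),
        ro3_violations=ro3_violations(mw, logp, hbd, rotb, tpsa),
        pains_count=pains_count(mol),
        qed=qed_score(mol),
        demerits=demerits,
        demerit_rule_ids=tuple(matched),
        demerit_strict_pass=strict,
        demerit_loose_pass=loose,
    )


def annotation_table(records, demerit_rules=None):
    """Annotate a list of reaction records into a pandas DataFrame keyed by product id."""
    import pandas as pd

    rows = []
    for rec in records:
        try:
            ann = annotate(rec.product_smiles, demerit_rules)
        except AnnotationError as exc:
            rows.append({"product_id": rec.product_id, "error": str(exc)})
            continue
        row = {"product_id": rec.product_id, "smiles": rec.product_smiles, "error": None}
        row.update(
            {
                k: getattr(ann, k)
                for k in (
                    "mw",
                    "logp",
                    "tpsa",
                    "fsp3",
                    "rotatable_bonds",
                    "hbd",
                    "hba",
                    "ro5_violations",
                    "ro3_violations",
                    "pains_count",
                    "qed",
                    "demerits",
                )
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def plot_property_panels(annotations, out_path):
    """Histogram panels (MW, logP, TPSA, FSP3, rotatable bonds, QED, PAINS, demerits).

    Plumbing for visual inspection only; requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [
        ("mw", "Molecular weight"),
        ("logp", "logP"),
        ("tpsa", "TPSA (A^2)"),
        ("fsp3", "Fraction sp3 carbons"),
        ("rotatable_bonds", "Rotatable bonds"),
        ("qed", "QED"),
        ("pains_count", "PAINS matches"),
        ("demerits", "Demerit score"),
    ]
    fig, axes = plt.subplots(2, 4, figsize=(16, 7))
    for ax, (col, title) in zip(axes.ravel(), panels):
        ax.hist(annotations[col].dropna(), bins=30, color="#4878d0")
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
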