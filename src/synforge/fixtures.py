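"""Seeded generator of toy building-block libraries.

Emulates a purchasable building-block pool at desk scale: every requested
functional-group class (acids, amines, aryl bromides, boronic acids, azides,
terminal alkynes, alcohols, sulfonyl chlorides, alkyl bromides, 1,4-diketones)
is represented by a requested number of valid structures, built by decorating
a fixed pool of inert tails onto per-class scaffold templates.  Randomness
only selects decorations, so every molecule is valid by construction and runs
are byte-identical for a given seed.

Optionally planted records provide ground truth for the preparation and
role-assignment stages: a dual-role block (amino acid), a multi-site block
(diamine), KILL-clause exercisers (thiol amine, aminophenol, amino alcohol,
hindered amines), and deliberate rejects (isotope label, organometallic,
over-complex structure).  Protected variants carry real protecting groups and
keep a second free functional group so deprotected (-DP) products arise in
pipeline runs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem

__all__ = ["LibrarySpec", "GeneratedBB", "generate_library", "write_library", "DEFAULT_SPEC"]

#: inert decorations: no N-H, O-H, acid, halide, boron, azide, alkyne,
#: sulfonyl chloride, 1,4-dione or protecting-group motif
_TAILS = [
    "C", "CC", "CCC", "CCCC", "CCCCC", "CC(C)C", "CC(C)CC", "CCOC", "CCCOC",
    "CCOCC", "CCN(C)C", "CCCN(C)C", "CCSC", "Cc9ccccc9", "CCc9ccccc9",
    "Cc9ccc(F)cc9", "Cc9ccc(Cl)cc9", "Cc9ccc(OC)cc9", "Cc9ccc(C)cc9",
    "Cc9ccncc9", "Cc9cccs9", "CC9CCCC9", "CC9CCCCC9", "Cc9cc(C)cc(C)c9",
]

# per-class scaffold templates; {t} takes a tail
_CLASS_TEMPLATES: dict[str, list[str]] = {
    "acids": ["OC(=O){t}", "OC(=O)c1ccc({t})cc1", "OC(=O)C{t}"],
    "primary_amines": ["NC{t}", "Nc1ccc({t})cc1", "NCC{t}"],
    "secondary_amines": ["CNC{t}", "CCNC{t}"],
    "aryl_bromides": ["Brc1ccc({t})cc1", "Brc1c({t})cccc1", "Brc1cccc({t})c1"],
    "boronic_acids": ["OB(O)c1ccc({t})cc1", "OB(O)c1c({t})cccc1"],
    "azides": ["N(=[N+]=[N-])C{t}", "N(=[N+]=[N-])c1ccc({t})cc1"],
    "alkynes": ["C#CC{t}", "C#Cc1ccc({t})cc1"],
    "alcohols": ["OCC{t}", "OC(C){t}", "OCCC{t}"],
    "sulfonyl_chlorides": ["O=S(=O)(Cl)c1ccc({t})cc1", "O=S(=O)(Cl)c1cccc({t})c1"],
    "alkyl_bromides": ["BrC{t}", "BrCc1ccc({t})cc1"],
    "diketones": ["CC(=O)CCC(=O){t}", "CC(=O)CCC(=O)C{t}"],
}

_DECOYS = [
    "CCOCC", "CCCCCC", "CCN(CC)CC", "COc1ccccc1", "Cc1ccccc1", "CCSCC",
    "CC(C)OC(C)C", "c1ccc2ccccc2c1", "CN1CCOCC1", "CCOc1ccccc1",
    "c1ccc(-c2ccccc2)cc1", "CCCOCCC", "CN(C)c1ccccc1", "Cc1cccnc1",
]

# protected variants keep a second, free reacting group so -DP products arise
_PROTECTED_TEMPLATES: dict[str, str] = {
    "primary_amines": "CC(C)(C)OC(=O)NC{t}",            # Boc amine (masked)
    "acids": "OC(=O)C{link}NC(=O)OC(C)(C)C",            # Boc-amino acid, free COOH
    "alcohols": "OCC{link}COC(=O)c1ccccc1",             # benzoate diol, free OH
    "aryl_bromides": "Brc1ccc(C{link}C(=O)OC(C)(C)C)cc1",  # tBu ester, free ArBr
}
_PROTECTED_PG: dict[str, str] = {
    "primary_amines": "Boc",
    "acids": "Boc",
    "alcohols": "Bz_O",
    "aryl_bromides": "tBu_ester",
}

# planted ground-truth cases
_SPECIAL = [
    ("Nc1ccc(C(=O)O)cc1", "dual_role"),      # amino acid: matches acid and amine roles
    ("Nc1cccc(N)c1", "multi_site"),          # two symmetry-distinct amine sites
    ("NCCS", "kill_thiol"),                  # thiol amine: KILL in couplings
    ("Nc1ccc(O)cc1", "kill_phenol"),         # aminophenol: KILL in sulfonamide rule
    ("NCCO", "amino_alcohol"),               # amine penalty / Williamson KILL
    ("NC(C)(C)C", "hindered_amine"),         # severe-hindrance SUBTRACT
    ("NC(C)(C)CC", "hindered_amine"),
    ("OC(=O)c1c(C)cccc1C", "ortho_acid"),    # ortho-disubstituted benzoic acid
]
_REJECTS = [
    ("[13CH3]c1ccc(C(=O)O)cc1", "isotope"),
    ("CC[Sn](CC)CC", "metal"),
    # densely fused polycycle: Bertz complexity far above the default cutoff
    ("OC(=O)C1CC2CC3C4CC5C6CC(C1)C2C1C3C(C4C5C61)C1CC2CC3CC1C2C3C1CC2CC3CC1C2C3", "complexity"),
]


@dataclass(frozen=True)
class LibrarySpec:
    """Composition of a generated toy library; all counts >= 0, fractions in [0, 1]."""

    counts: dict = field(
        default_factory=lambda: {
            "acids": 30,
            "primary_amines": 25,
            "secondary_amines": 10,
            "aryl_bromides": 25,
            "boronic_acids": 20,
            "azides": 15,
            "alkynes": 15,
            "alcohols": 25,
            "sulfonyl_chlorides": 10,
            "alkyl_bromides": 10,
            "diketones": 10,
            "decoys": 10,
        }
    )
    fraction_protected: dict = field(
        default_factory=lambda: {
            "acids": 0.2,
            "primary_amines": 0.2,
            "alcohols": 0.2,
            "aryl_bromides": 0.2,
        }
    )
    plant_special: bool = True
    plant_rejects: bool = True
    seed: int = 0


DEFAULT_SPEC = LibrarySpec()


@dataclass(frozen=True)
class GeneratedBB:
    bb_id: str
    smiles: str
    bb_class: str
    planted_pg: str = ""
    planted_case: str = ""


def _validate_spec(spec: LibrarySpec) -> None:
    for cls, n in spec.counts.items():
        if cls != "decoys" and cls not in _CLASS_TEMPLATES:
            raise ValueError(f"unknown building-block class: {cls!r}")
        if not isinstance(n, int) or n < 0:
            raise ValueError(f"count for {cls!r} must be a non-negative integer")
    for cls, frac in spec.fraction_protected.items():
        if cls not in _PROTECTED_TEMPLATES:
            raise ValueError(f"no protected variant defined for class {cls!r}")
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction_protected[{cls!r}] must be in [0, 1]")


def _canonical(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - templates are valid by construction
        raise ValueError(f"generated invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def generate_library(spec: LibrarySpec = DEFAULT_SPEC) -> list[GeneratedBB]:
    """Deterministic toy library for the given spec (same seed, same output)."""
    _validate_spec(spec)
    rng = random.Random(spec.seed)
    out: list[GeneratedBB] = []
    seen: set[str] = set()

    def emit(smiles: str, bb_class: str, pg: str = "", case: str = "") -> bool:
        canon = _canonical(smiles)
        if canon in seen:
            return False
        seen.add(canon)
        out.append(
            GeneratedBB(
                bb_id=f"BB{len(out) + 1:04d}",
                smiles=canon,
                bb_class=bb_class,
                planted_pg=pg,
                planted_case=case,
            )
        )
        return True

    for cls in sorted(spec.counts):
        n = spec.counts[cls]
        if n == 0:
            continue
        if cls == "decoys":
            for i in range(n):
                if not emit(_DECOYS[i % len(_DECOYS)], cls):
                    raise ValueError(f"decoy pool exhausted at {n} decoys")
            continue
        n_protected = round(spec.fraction_protected.get(cls, 0.0) * n)
        templates = _CLASS_TEMPLATES[cls]
        for i in range(n):
            protected = i < n_protected
            for attempt in range(200):
                tail = rng.choice(_TAILS)
                if protected:
                    tmpl = _PROTECTED_TEMPLATES[cls]
                    smiles = tmpl.format(t=tail, link="C" * (attempt % 6 + 1))
                else:
                    smiles = templates[(i + attempt) % len(templates)].format(t=tail)
                if emit(smiles, cls, pg=_PROTECTED_PG[cls] if protected else ""):
                    break
            else:  # pragma: no cover
                raise ValueError(f"could not generate a fresh {cls} block")

    if spec.plant_special:
        for smiles, case in _SPECIAL:
            emit(smiles, "special", case=case)
    if spec.plant_rejects:
        for smiles, case in _REJECTS:
            emit(smiles, "reject", case=f"reject_{case}")
    return out


def write_library(spec: LibrarySpec, outdir) -> tuple[Path, Path]:
    """Write the library as a .smi file plus a ground-truth CSV; returns both paths."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = generate_library(spec)
    smi_path = outdir / "building_blocks.smi"
    with open(smi_path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles} {rec.bb_id}\n")
    truth_path = outdir / "ground_truth.csv"
    pd.DataFrame(records).to_csv(truth_path, index=False)
    return smi_path, truth_path
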