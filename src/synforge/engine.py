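"""Pair enumeration, transform application, clause scoring, and classification.

The workflow mirrors forward-synthetic library generation: for each transform,
all A x B reactant pairs from the (exclusion-filtered) role sets are
enumerated; the product template is applied at the unique match site of each
reactant; the candidate product is then subjected to the transform's scoring
clauses.  A matched KILL vetoes the reaction (recorded only in the audit log);
otherwise the ADD/SUBTRACT deltas are summed and the reaction is saved with a
synthesizability class:

* ``Plus``  - net delta > 0
* ``Neg n`` - penalized by at least n, for n in {0, 10, 20, 30}

Saved products are stored deprotected; the id suffix records whether any
protecting group was removed (``-DP``) or not (``-UN``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from rdkit import Chem

from .deprotect import DeprotectionError, deprotect, suffix_id
from .bbs import BuildingBlock, RoleSet, assign_roles, unique_key
from .rules import Transform, clause_matches

__all__ = [
    "ReactantPair",
    "ReactionRecord",
    "LibraryStats",
    "LibraryRunResult",
    "EngineConfig",
    "KILLED",
    "CLASS_LABELS",
    "enumerate_pairs",
    "apply_transform",
    "score_reaction",
    "classify_score",
    "run_library",
]

CLASS_LABELS = ("Plus", "Neg0", "Neg10", "Neg20", "Neg30")

#: sentinel returned by score_reaction when a KILL clause matched
KILLED = object()


@dataclass(frozen=True)
class ReactantPair:
    transform_id: int
    bb_a: str
    bb_b: str


@dataclass
class ReactionRecord:
    product_id: str  # carries the -UN / -DP suffix
    transform_id: int
    bb_a: str
    bb_b: str
    product_smiles: str  # deprotected, canonical
    product_key: str  # tautomer-insensitive unique key of the deprotected product
    product_protected_smiles: Optional[str]  # as generated, if a PG was removed
    delta: int
    clause_trace: list[tuple[int, str, int]]  # (clause index, action, signed value)
    class_label: str
    killed: bool = False


@dataclass
class LibraryStats:
    per_transform: dict = field(default_factory=dict)
    totals: dict = field(default_factory=dict)
    estimates: dict = field(default_factory=dict)


@dataclass
class LibraryRunResult:
    records: list[ReactionRecord]
    stats: LibraryStats
    audit: list[dict]
    role_sets: dict


@dataclass(frozen=True)
class EngineConfig:
    id_prefix: str = "P"


def enumerate_pairs(role_a: RoleSet, role_b: RoleSet) -> Iterator[ReactantPair]:
    """Yield all |A| x |B| member pairs once, in sorted-id order."""
    for bb_a, bb_b in itertools.product(sorted(role_a.members), sorted(role_b.members)):
        # dual-role blocks were excluded upstream, so self-pairing is impossible
        assert bb_a != bb_b, f"self-pairing of {bb_a}; dual-role exclusion missed it"
        yield ReactantPair(transform_id=role_a.transform_id, bb_a=bb_a, bb_b=bb_b)


def apply_transform(
    t: Transform, mol_a: Chem.Mol, mol_b: Chem.Mol
) -> tuple[Optional[str], Optional[str]]:
    """Apply the product template to one reactant pair.

    Returns ``(product_smiles, None)`` on success or ``(None, reason)`` where
    reason is one of ``template_mismatch``, ``sanitization_failed``,
    ``ambiguous_product``.  Multi-site reactants are excluded upstream, so at
    most one distinct product is expected; symmetric template matches that
    produce the same structure collapse to it.
    """
    product_sets = t.reaction.RunReactants((mol_a, mol_b))
    if not product_sets:
        return None, "template_mismatch"
    products: set[str] = set()
    any_valid = False
    for (mol,) in product_sets:
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        any_valid = True
        products.add(Chem.MolToSmiles(mol))
    if not any_valid:
        return None, "sanitization_failed"
    if len(products) > 1:
        return None, "ambiguous_product"
    return products.pop(), None


def score_reaction(t: Transform, mol_a: Chem.Mol, mol_b: Chem.Mol, product: Chem.Mol):
    """Evaluate all clauses; returns ``(delta, trace)`` or the ``KILLED`` sentinel.

    The trace lists every matched clause as (index, action, signed value) in
    file order; order never changes the delta (a pure sum) but keeps runs
    reproducible and auditable.
    """
    scope_mols = {"reactant_a": mol_a, "reactant_b": mol_b, "product": product}
    delta = 0
    trace: list[tuple[int, str, int]] = []
    for idx, clause in enumerate(t.clauses):
        if not clause_matches(clause, scope_mols[clause.scope]):
            continue
        if clause.action == "KILL":
            trace.append((idx, "KILL", 0))
            return KILLED, trace
        signed = clause.signed_value()
        delta += signed
        trace.append((idx, clause.action, signed))
    return delta, trace


def classify_score(delta: int) -> str:
    """Synthesizability class from the net clause delta.

    Positive deltas are ``Plus``; otherwise the class is ``Neg n`` with the
    largest n in {0, 10, 20, 30} not exceeding |delta| (0 and -5 -> Neg0,
    -10/-15 -> Neg10, -20/-25 -> Neg20, -30 and below -> Neg30).
    """
    if delta > 0:
        return "Plus"
    return f"Neg{min(30, (abs(delta) // 10) * 10)}"


def run_library(
    transforms: Iterable[Transform],
    bbs: list[BuildingBlock],
    config: EngineConfig = EngineConfig(),
) -> LibraryRunResult:
    """Run every transform over the prepared blocks; deterministic end to end.

    Any single-reaction failure is written to the audit log and never aborts
    the run.  Killed reactions are retained in the audit (with the triggering
    clause) because computationally failed reactions remain useful data, e.g.
    for model training.
    """
    transforms = sorted(transforms, key=lambda t: t.id)
    accepted = [bb for bb in bbs if bb.rejected is None]
    mols = {bb.bb_id: bb.mol() for bb in accepted}

    records: list[ReactionRecord] = []
    audit: list[dict] = []
    role_sets: dict = {}
    per_transform: dict = {}
    seq = 0

    for t in transforms:
        role_a, role_b = assign_roles(t, accepted)
        role_sets[t.id] = (role_a, role_b)
        tested = killed = saved = 0
        class_hist = {label: 0 for label in CLASS_LABELS}
        for pair in enumerate_pairs(role_a, role_b):
            tested += 1
            mol_a, mol_b = mols[pair.bb_a], mols[pair.bb_b]
            product_smiles, reason = apply_transform(t, mol_a, mol_b)
            if product_smiles is None:
                audit.append(
                    {
                        "transform_id": t.id,
                        "bb_a": pair.bb_a,
                        "bb_b": pair.bb_b,
                        "outcome": reason,
                    }
                )
                continue
            product_mol = Chem.MolFromSmiles(product_smiles)
            outcome = score_reaction(t, mol_a, mol_b, product_mol)
            if outcome[0] is KILLED:
                killed += 1
                audit.append(
                    {
                        "transform_id": t.id,
                        "bb_a": pair.bb_a,
                        "bb_b": pair.bb_b,
                        "outcome": "killed",
                        "clause_trace": outcome[1],
                    }
                )
                continue
            delta, trace = outcome
            try:
                free_smiles, removed = deprotect(product_mol)
            except DeprotectionError as exc:
                audit.append(
                    {
                        "transform_id": t.id,
                        "bb_a": pair.bb_a,
                        "bb_b": pair.bb_b,
                        "outcome": "deprotection_failed",
                        "detail": str(exc),
                    }
                )
                continue
            seq += 1
            saved += 1
            label = classify_score(delta)
            class_hist[label] += 1
            records.append(
                ReactionRecord(
                    product_id=suffix_id(f"{config.id_prefix}{seq:07d}", removed),
                    transform_id=t.id,
                    bb_a=pair.bb_a,
                    bb_b=pair.bb_b,
                    product_smiles=free_smiles,
                    product_key=unique_key(Chem.MolFromSmiles(free_smiles)),
                    product_protected_smiles=product_smiles if removed else None,
                    delta=delta,
                    clause_trace=trace,
                    class_label=label,
                )
            )
        per_transform[t.id] = {
            "name": t.name,
            "tested_pairs": tested,
            "killed": killed,
            "saved": saved,
            "success_rate": (saved / tested) if tested else 0.0,
            "class_hist": class_hist,
        }

    stats = _build_stats(per_transform, records, accepted, role_sets, transforms)
    return LibraryRunResult(records=records, stats=stats, audit=audit, role_sets=role_sets)


def _build_stats(per_transform, records, accepted, role_sets, transforms) -> LibraryStats:
    # imported here: analysis depends on engine record shapes, not vice versa
    from .analysis import sar_neighbors, success_ratio, theoretical_max

    total_saved = len(records)
    class_counts = {label: 0 for label in CLASS_LABELS}
    class_keys: dict[str, set] = {label: set() for label in CLASS_LABELS}
    all_keys: set = set()
    for rec in records:
        class_counts[rec.class_label] += 1
        class_keys[rec.class_label].add(rec.product_key)
        all_keys.add(rec.product_key)

    matched_bb_ids = set()
    for role_a, role_b in role_sets.values():
        matched_bb_ids.update(role_a.members, role_b.members)

    n_bb = len(accepted)
    n_transforms = len(list(transforms))
    t_max = theoretical_max(n_bb, n_transforms)
    estimates = {
        "n_accepted_bbs": n_bb,
        "n_matched_bbs": len(matched_bb_ids),
        "theoretical_max": t_max,
        "success_ratio": success_ratio(t_max, total_saved) if total_saved else None,
    }
    if len(matched_bb_ids):
        fill, mean = sar_neighbors(len(matched_bb_ids), total_saved)
        estimates["sar_fill_fraction"] = fill
        estimates["sar_neighbors_mean"] = mean

    totals = {
        "tested_pairs": sum(pt["tested_pairs"] for pt in per_transform.values()),
        "killed": sum(pt["killed"] for pt in per_transform.values()),
        "saved": total_saved,
        "unique_combined": len(all_keys),
        "class_counts": class_counts,
        "class_unique": {label: len(class_keys[label]) for label in CLASS_LABELS},
    }
    return LibraryStats(per_transform=per_transform, totals=totals, estimates=estimates)
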