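"""File formats and run configuration.

Flat-file persistence between pipeline stages: SMILES (.smi) for structures,
CSV for tabular records (prepared blocks, products, annotations, rejections),
JSON for stats and role sets, JSON-lines for the audit trail and the stage
log, SDF (V2000) with namespaced ``SF_*`` data fields for product export, and
an optional single-file SQLite sink.  Re-running a stage on unchanged inputs
reproduces byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from rdkit import Chem

from .bbs import BuildingBlock, FilterConfig
from .engine import LibraryStats, ReactionRecord

__all__ = [
    "RunConfig",
    "read_smiles_file",
    "write_smiles_file",
    "write_prepared_bbs",
    "read_prepared_bbs",
    "write_rejection_report",
    "write_products_csv",
    "read_products_csv",
    "write_products_sdf",
    "write_audit_jsonl",
    "write_stats_json",
    "write_role_sets_json",
    "write_products_sqlite",
    "StageLog",
]

#: SDF data fields written per product, in order
SDF_FIELDS = (
    "SF_PRODUCT_ID",
    "SF_TRANSFORM_ID",
    "SF_BB_A",
    "SF_BB_B",
    "SF_DELTA",
    "SF_CLASS",
    "SF_PROTECTED_SMILES",
)


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips through YAML."""

    rule_path: Optional[str] = None
    bb_path: Optional[str] = None
    outdir: str = "."
    complexity_cutoff: float = 1000.0
    id_prefix: str = "P"
    seed: int = 0
    processes: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(complexity_cutoff=self.complexity_cutoff)


class StageLog:
    """JSON-lines log of per-stage counts (read, rejected, matched, saved...)."""

    def __init__(self, path=None):
        self.path = Path(path) if path else None
        self.entries: list[dict] = []

    def record(self, stage: str, **counts) -> None:
        entry = {"stage": stage, **counts}
        self.entries.append(entry)
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# SMILES


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a .smi file: one record per line, SMILES plus optional id."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            smiles = parts[0]
            bb_id = parts[1] if len(parts) > 1 else f"L{lineno:05d}"
            records.append((bb_id, smiles))
    return records


def write_smiles_file(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for bb_id, smiles in records:
            fh.write(f"{smiles} {bb_id}\n")


# ---------------------------------------------------------------------------
# building blocks


def write_prepared_bbs(bbs: list[BuildingBlock], path) -> None:
    rows = [
        {
            "bb_id": bb.bb_id,
            "smiles_raw": bb.smiles_raw,
            "smiles_std": bb.smiles_std,
            "unique_key": bb.unique_key,
            "protecting_groups": ";".join(bb.protecting_groups),
            "complexity": round(bb.complexity, 4),
            "rejected": bb.rejected or "",
        }
        for bb in bbs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_prepared_bbs(path) -> list[BuildingBlock]:
    df = pd.read_csv(path, keep_default_na=False)
    bbs = []
    for row in df.itertuples(index=False):
        bbs.append(
            BuildingBlock(
                bb_id=str(row.bb_id),
                smiles_raw=row.smiles_raw,
                smiles_std=row.smiles_std or None,
                unique_key=row.unique_key or None,
                protecting_groups=[p for p in str(row.protecting_groups).split(";") if p],
                complexity=float(row.complexity),
                rejected=row.rejected or None,
            )
        )
    return bbs


def write_rejection_report(bbs: list[BuildingBlock], path) -> None:
    rows = [
        {"bb_id": bb.bb_id, "reason": bb.rejected}
        for bb in bbs
        if bb.rejected is not None
    ]
    pd.DataFrame(rows, columns=["bb_id", "reason"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# products


def _record_row(rec: ReactionRecord) -> dict:
    return {
        "product_id": rec.product_id,
        "product_smiles": rec.product_smiles,
        "product_key": rec.product_key,
        "transform_id": rec.transform_id,
        "bb_a": rec.bb_a,
        "bb_b": rec.bb_b,
        "delta": rec.delta,
        "class": rec.class_label,
        "product_protected_smiles": rec.product_protected_smiles or "",
        "clause_trace": json.dumps(rec.clause_trace),
    }


def write_products_csv(records: list[ReactionRecord], path) -> None:
    pd.DataFrame([_record_row(r) for r in records]).to_csv(path, index=False)


def read_products_csv(path) -> list[ReactionRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    records = []
    for row in df.to_dict(orient="records"):
        records.append(
            ReactionRecord(
                product_id=row["product_id"],
                transform_id=int(row["transform_id"]),
                bb_a=str(row["bb_a"]),
                bb_b=str(row["bb_b"]),
                product_smiles=row["product_smiles"],
                product_key=row["product_key"],
                product_protected_smiles=row["product_protected_smiles"] or None,
                delta=int(row["delta"]),
                clause_trace=[tuple(t) for t in json.loads(row["clause_trace"])],
                class_label=row["class"],
            )
        )
    return records


def write_products_sdf(records: list[ReactionRecord], path) -> None:
    """V2000 SDF with one SF_* data field per record attribute."""
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            mol = Chem.MolFromSmiles(rec.product_smiles)
            if mol is None:
                continue
            mol.SetProp("_Name", rec.product_id)
            mol.SetProp("SF_PRODUCT_ID", rec.product_id)
            mol.SetProp("SF_TRANSFORM_ID", str(rec.transform_id))
            mol.SetProp("SF_BB_A", rec.bb_a)
            mol.SetProp("SF_BB_B", rec.bb_b)
            mol.SetProp("SF_DELTA", str(rec.delta))
            mol.SetProp("SF_CLASS", rec.class_label)
            if rec.product_protected_smiles:
                mol.SetProp("SF_PROTECTED_SMILES", rec.product_protected_smiles)
            writer.write(mol)
    finally:
        writer.close()


def write_audit_jsonl(audit: list[dict], path) -> None:
    with open(path, "w") as fh:
        for entry in audit:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


def write_stats_json(stats: LibraryStats, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "per_transform": stats.per_transform,
                "totals": stats.totals,
                "estimates": stats.estimates,
            },
            fh,
            indent=2,
            sort_keys=True,
        )


def write_role_sets_json(role_sets: dict, path) -> None:
    doc = {}
    for tid, (role_a, role_b) in role_sets.items():
        doc[str(tid)] = {
            role.role: {
                "members": role.members,
                "excluded_dual_role": role.excluded_dual_role,
                "excluded_multi_site": role.excluded_multi_site,
            }
            for role in (role_a, role_b)
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)


def write_products_sqlite(records: list[ReactionRecord], path) -> None:
    """Optional single-file SQLite sink mirroring the product CSV."""
    con = sqlite3.connect(str(path))
    try:
        con.execute(
            """CREATE TABLE IF NOT EXISTS products (
                product_id TEXT PRIMARY KEY, product_smiles TEXT, product_key TEXT,
                transform_id INTEGER, bb_a TEXT, bb_b TEXT, delta INTEGER,
                class TEXT, product_protected_smiles TEXT, clause_trace TEXT)"""
        )
        con.executemany(
            "INSERT OR REPLACE INTO products VALUES (?,?,?,?,?,?,?,?,?,?)",
            [
                (
                    r.product_id,
                    r.product_smiles,
                    r.product_key,
                    r.transform_id,
                    r.bb_a,
                    r.bb_b,
                    r.delta,
                    r.class_label,
                    r.product_protected_smiles,
                    json.dumps(r.clause_trace),
                )
                for r in records
            ],
        )
        con.commit()
    finally:
        con.close()
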