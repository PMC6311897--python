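"""Readers and writers for compound datasets and fingerprints.

Two input formats: a tab-separated SMILES table (``id<TAB>smiles[<TAB>label]``,
``#`` comments) and SDF (V2000; molecule title as id, binary activity read
from a named property).  Output files are UTF-8, Unix newlines, floats with
full round-trip precision, and every writer is lossless under its paired
reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)


class DatasetError(ValueError):
    pass


@dataclass
class CompoundRecord:
    id: str
    smiles: str
    label: int | None = None
    source: str = ""


def _parse_label(text: str, where: str) -> int:
    if text not in ("0", "1"):
        raise DatasetError(f"{where}: label must be 0 or 1, got {text!r}")
    return int(text)


def read_compounds(path, format: str | None = None, strict: bool = False,
                   label_property: str = "label") -> list[CompoundRecord]:
    """Load compounds; format inferred from the extension when not given."""
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "smiles-tsv"
    if format == "smiles-tsv":
        records = _read_smiles_tsv(path, strict)
    elif format == "sdf":
        records = _read_sdf(path, strict, label_property)
    else:
        raise DatasetError(f"unknown format {format!r}")
    if not records:
        raise DatasetError(f"{path}: no valid records")
    seen = set()
    for r in records:
        if r.id in seen:
            raise DatasetError(f"{r.source}: duplicate compound id {r.id!r}")
        seen.add(r.id)
    return records


def _read_smiles_tsv(path: Path, strict: bool) -> list[CompoundRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            where = f"{path}:{lineno}"
            parts = line.split("\t")
            try:
                if len(parts) not in (2, 3):
                    raise DatasetError(f"{where}: expected 2 or 3 tab-separated fields, got {len(parts)}")
                label = _parse_label(parts[2], where) if len(parts) == 3 else None
                records.append(CompoundRecord(parts[0], parts[1], label, where))
            except DatasetError:
                if strict:
                    raise
                logger.warning("skipping malformed line %s", where)
    return records


def _read_sdf(path: Path, strict: bool, label_property: str) -> list[CompoundRecord]:
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        where = f"{path}#mol{i}"
        if mol is None:
            if strict:
                raise DatasetError(f"{where}: unreadable molecule")
            logger.warning("skipping unreadable molecule %s", where)
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        label = None
        if mol.HasProp(label_property):
            try:
                label = _parse_label(mol.GetProp(label_property).strip(), where)
            except DatasetError:
                if strict:
                    raise
                logger.warning("skipping bad label on %s", where)
        records.append(CompoundRecord(cid, Chem.MolToSmiles(mol), label, where))
    return records


def write_compounds(path, records: list[CompoundRecord], format: str | None = None,
                    label_property: str = "label"):
    path = Path(path)
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "smiles-tsv"
    if format == "smiles-tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("# id\tsmiles\tlabel\n")
            for r in records:
                fh.write(f"{r.id}\t{r.smiles}" + (f"\t{r.label}" if r.label is not None else "") + "\n")
    elif format == "sdf":
        writer = Chem.SDWriter(str(path))
        for r in records:
            mol = Chem.MolFromSmiles(r.smiles)
            if mol is None:
                raise DatasetError(f"unwritable SMILES for {r.id!r}")
            mol.SetProp("_Name", r.id)
            if r.label is not None:
                mol.SetProp(label_property, str(r.label))
            writer.write(mol)
        writer.close()
    else:
        raise DatasetError(f"unknown format {format!r}")


def write_fingerprints(path, ids, scfp_matrix):
    """Tab-separated fingerprint table: id, scfp_0..scfp_{d-1}."""
    scfp_matrix = np.asarray(scfp_matrix)
    ids = list(ids)
    if scfp_matrix.ndim != 2 and not (scfp_matrix.size == 0 and len(ids) == 0):
        raise DatasetError("fingerprint matrix must be 2-D")
    if scfp_matrix.ndim == 2 and len(ids) != scfp_matrix.shape[0]:
        raise DatasetError(f"{len(ids)} ids but {scfp_matrix.shape[0]} fingerprint rows")
    d = scfp_matrix.shape[1] if scfp_matrix.ndim == 2 else 64
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\t" + "\t".join(f"scfp_{j}" for j in range(d)) + "\n")
        for cid, row in zip(ids, scfp_matrix):
            fh.write(cid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_fingerprints(path):
    """Inverse of :func:`write_fingerprints`: returns (ids, matrix)."""
    ids, rows = [], []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "id":
            raise DatasetError(f"{path}: not a fingerprint file")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    d = len(header) - 1
    return ids, np.asarray(rows, dtype=float).reshape(len(ids), d)
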