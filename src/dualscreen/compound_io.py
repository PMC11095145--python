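"""Reading, validating, filtering and writing compound datasets.

A dataset is a delimited text table (CSV, UTF-8, header row) with a
``compound_id`` column, a ``smiles`` column, up to 10 binary attribute
label columns (``1`` = active, ``0`` = inactive, blank = inconclusive /
unlabeled) and an optional ``toxic`` flag column.  Attribute names, their
model path (``tabular`` vs ``graph``) and their screening role
(``bbb_gate`` vs ``activity``) live in a small key-value schema file.

Inconclusive labels are carried as ``None`` and dropped per attribute at
training time, so a compound with a missing label for one attribute still
contributes to the others.
"""

from __future__ import annotations

import configparser
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.rdBase import BlockLogs

VALID_PATHS = ("tabular", "graph")
VALID_ROLES = ("bbb_gate", "activity")
EXCLUSION_REASONS = ("parse_failure", "multi_fragment_salt", "duplicate_id")

_MISSING_TOKENS = {"", "na", "nan", "none"}


class ValidationError(ValueError):
    """Input violates a dataset or schema contract."""


@dataclass(frozen=True)
class Attribute:
    attribute_id: str
    display_name: str
    path: str
    role: str = "activity"

    def __post_init__(self) -> None:
        if not self.attribute_id:
            raise ValidationError("attribute_id must be nonempty")
        if self.path not in VALID_PATHS:
            raise ValidationError(
                f"attribute {self.attribute_id!r}: path must be one of {VALID_PATHS}, got {self.path!r}"
            )
        if self.role not in VALID_ROLES:
            raise ValidationError(
                f"attribute {self.attribute_id!r}: role must be one of {VALID_ROLES}, got {self.role!r}"
            )


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered panel of up to 10 binary attributes, exactly one of which
    is the blood-brain-barrier gate."""

    attributes: tuple[Attribute, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.attributes) <= 10:
            raise ValidationError(f"schema must have 1..10 attributes, got {len(self.attributes)}")
        ids = [a.attribute_id for a in self.attributes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate attribute_ids in schema: {dupes}")
        n_gate = sum(a.role == "bbb_gate" for a in self.attributes)
        if n_gate != 1:
            raise ValidationError(f"schema must have exactly one bbb_gate attribute, got {n_gate}")

    def __len__(self) -> int:
        return len(self.attributes)

    def __iter__(self) -> Iterator[Attribute]:
        return iter(self.attributes)

    @property
    def attribute_ids(self) -> list[str]:
        return [a.attribute_id for a in self.attributes]

    @property
    def gate_attribute(self) -> Attribute:
        return next(a for a in self.attributes if a.role == "bbb_gate")

    @property
    def activity_attributes(self) -> list[Attribute]:
        return [a for a in self.attributes if a.role == "activity"]

    def attribute(self, attribute_id: str) -> Attribute:
        for a in self.attributes:
            if a.attribute_id == attribute_id:
                return a
        raise KeyError(attribute_id)


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str
    labels: tuple[Optional[int], ...]
    toxic: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be nonempty")
        for v in self.labels:
            if v not in (0, 1, None):
                raise ValidationError(f"label values must be 0, 1 or None, got {v!r}")


@dataclass(frozen=True)
class ExclusionEntry:
    compound_id: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise ValidationError(f"unknown exclusion reason {self.reason!r}")


@dataclass
class ExclusionLog:
    entries: list[ExclusionEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, compound_id: str, reason: str) -> None:
        self.entries.append(ExclusionEntry(compound_id, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.compound_id, e.reason) for e in self.entries],
            columns=["compound_id", "reason"],
        )


@dataclass
class CompoundDataset:
    """An ordered collection of :class:`CompoundRecord` aligned to a schema."""

    schema: AttributeSchema
    records: list[CompoundRecord]

    def __post_init__(self) -> None:
        n = len(self.schema)
        for r in self.records:
            if len(r.labels) != n:
                raise ValidationError(
                    f"compound {r.compound_id!r}: {len(r.labels)} labels for a {n}-attribute schema"
                )
        counts = Counter(r.compound_id for r in self.records)
        dupes = sorted(i for i, c in counts.items() if c > 1)
        if dupes:
            raise ValidationError(f"duplicate compound_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    @property
    def compound_ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    def labels_for(self, attribute_id: str) -> list[Optional[int]]:
        j = self.schema.attribute_ids.index(attribute_id)
        return [r.labels[j] for r in self.records]


# ---------------------------------------------------------------------------
# schema files


def read_schema(path: str | Path) -> AttributeSchema:
    """Parse a key-value schema file (one section per attribute, in order)."""
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise IOError(f"cannot read schema file {path}")
    attrs = []
    for section in parser.sections():
        sec = parser[section]
        attrs.append(
            Attribute(
                attribute_id=section,
                display_name=sec.get("display_name", section),
                path=sec.get("path", "tabular"),
                role=sec.get("role", "activity"),
            )
        )
    return AttributeSchema(tuple(attrs))


def write_schema(schema: AttributeSchema, path: str | Path) -> None:
    parser = configparser.ConfigParser()
    for a in schema:
        parser[a.attribute_id] = {
            "display_name": a.display_name,
            "path": a.path,
            "role": a.role,
        }
    with open(path, "w", encoding="utf-8") as fh:
        parser.write(fh)


# ---------------------------------------------------------------------------
# dataset files


def _parse_label(cell: str, row: int, column: str) -> Optional[int]:
    s = cell.strip()
    if s.lower() in _MISSING_TOKENS:
        return None
    if s in ("0", "1"):
        return int(s)
    raise ValidationError(f"row {row}, column {column!r}: label must be 0, 1 or blank, got {cell!r}")


def _parse_toxic(cell: str, row: int) -> Optional[bool]:
    s = cell.strip().lower()
    if s in _MISSING_TOKENS:
        return None
    if s in ("1", "true"):
        return True
    if s in ("0", "false"):
        return False
    raise ValidationError(f"row {row}, column 'toxic': flag must be 0/1/true/false/blank, got {cell!r}")


def read_dataset(path: str | Path, schema: AttributeSchema) -> CompoundDataset:
    """Read a compound CSV against a schema.

    Attribute columns absent from the file yield all-missing labels; label
    cells outside {0, 1, blank} are rejected with the offending row and
    column named.  Duplicate compound_ids are an error.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise IOError(f"cannot read dataset {path}: {exc}") from exc
    for required in ("compound_id", "smiles"):
        if required not in frame.columns:
            raise ValidationError(f"dataset {path} is missing required column {required!r}")
    present = [a for a in schema.attribute_ids if a in frame.columns]
    has_toxic = "toxic" in frame.columns

    records = []
    for row, rec in enumerate(frame.itertuples(index=False)):
        data = dict(zip(frame.columns, rec))
        labels = tuple(
            _parse_label(data[a], row, a) if a in present else None for a in schema.attribute_ids
        )
        toxic = _parse_toxic(data["toxic"], row) if has_toxic else None
        records.append(
            CompoundRecord(
                compound_id=data["compound_id"].strip(),
                smiles=data["smiles"].strip(),
                labels=labels,
                toxic=toxic,
            )
        )
    return CompoundDataset(schema, records)


def write_table(dataset: CompoundDataset, path: str | Path) -> None:
    """Write a dataset as CSV; ``read_dataset(write_table(d))`` round-trips
    field-for-field (missing labels become blank cells)."""
    cols: dict[str, list] = {
        "compound_id": [r.compound_id for r in dataset],
        "smiles": [r.smiles for r in dataset],
    }
    for j, a in enumerate(dataset.schema.attribute_ids):
        cols[a] = ["" if r.labels[j] is None else str(r.labels[j]) for r in dataset]
    if any(r.toxic is not None for r in dataset):
        cols["toxic"] = ["" if r.toxic is None else str(int(r.toxic)) for r in dataset]
    frame = pd.DataFrame(cols, dtype=str)
    try:
        frame.to_csv(path, index=False, lineterminator="\n")
    except OSError as exc:
        raise IOError(f"cannot write table {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# validation / filtering


def parse_single_fragment(smiles: str) -> Optional[Chem.Mol]:
    """Parse a SMILES, returning None on failure (RDKit warnings silenced)."""
    with BlockLogs():
        return Chem.MolFromSmiles(smiles)


def num_fragments(mol: Chem.Mol) -> int:
    return len(Chem.GetMolFrags(mol))


def validate_and_filter(
    dataset: CompoundDataset, exclude_salts: bool = True
) -> tuple[CompoundDataset, ExclusionLog]:
    """Drop records whose SMILES fails to parse and, when ``exclude_salts``,
    records whose parsed structure has more than one disconnected fragment
    (the operational definition of a salt here).

    Survivor order is preserved and ``len(survivors) + len(log) == len(input)``.
    """
    survivors: list[CompoundRecord] = []
    log = ExclusionLog()
    seen: set[str] = set()
    for rec in dataset:
        if rec.compound_id in seen:
            log.add(rec.compound_id, "duplicate_id")
            continue
        seen.add(rec.compound_id)
        mol = parse_single_fragment(rec.smiles)
        if mol is None:
            log.add(rec.compound_id, "parse_failure")
            continue
        if exclude_salts and num_fragments(mol) > 1:
            log.add(rec.compound_id, "multi_fragment_salt")
            continue
        survivors.append(rec)
    return CompoundDataset(dataset.schema, survivors), log
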