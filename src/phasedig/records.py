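"""Read, write, validate and query PhDat JSON datasets.

A PhDat file is a JSON object mapping a record-index string (``"81"``) to
one record per digitized source diagram.  Each record carries the compound
metadata (SMILES, name, citation, figure locator, purity, measurement
method codes A-F, charge type, solvent) plus the gridded data: ``keys``
names the columns (temperature, composition, then phase states) and
``values`` holds one equal-length list per key.  Compositions are wt%
surfactant in [0, 100]; phase-state probabilities are stored as percentages
summing to 100 per grid point.  The ``U`` (unknown) column may only appear
in records whose diagram state is ``"incomplete"``.  SMILES strings are
stored verbatim and must not be assumed unique across records: the same
compound may have several source diagrams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .vocab import UNKNOWN_CODE, Vocabulary, load_vocabulary

__all__ = [
    "PhDatRecord",
    "PhDatDataset",
    "ValidationReport",
    "write_record",
    "record_to_json",
    "read_dataset",
    "read_dataset_file",
    "write_dataset",
    "validate",
    "query",
]

_MANDATORY_META = ("smiles", "state", "name", "source", "figure", "method", "type")
_STATES = ("complete", "incomplete")
_TYPES = ("nonionic", "anionic", "cationic", "zwitterionic", "mixed")
_METHOD_CODES = set("ABCDEF")
_META_ORDER = (
    "smiles",
    "state",
    "name",
    "source",
    "figure",
    "purity",
    "method",
    "type",
    "solvent",
    "labels",
    "keys",
    "values",
)


@dataclass(frozen=True)
class PhDatRecord:
    """One source diagram's metadata and probability grid."""

    smiles: str
    state: str
    name: str
    source: str
    figure: str
    method: str
    type: str
    solvent: str = "water"
    purity: str | None = None
    labels: tuple[tuple[str, str], ...] = ()
    keys: tuple[str, ...] = ()
    values: tuple[tuple[float, ...], ...] = ()

    def to_dict(self) -> dict:
        out: dict = {}
        for key in _META_ORDER:
            if key == "purity":
                if self.purity is not None:
                    out["purity"] = self.purity
            elif key == "labels":
                out["labels"] = [list(pair) for pair in self.labels]
            elif key == "keys":
                out["keys"] = list(self.keys)
            elif key == "values":
                out["values"] = [list(col) for col in self.values]
            else:
                out[key] = getattr(self, key)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PhDatRecord":
        missing = [k for k in _MANDATORY_META if k not in d]
        if missing:
            raise SchemaError(f"record missing mandatory field(s): {missing}")
        if "keys" not in d or "values" not in d:
            raise SchemaError("record missing keys/values data block")
        return cls(
            smiles=str(d["smiles"]),
            state=str(d["state"]),
            name=str(d["name"]),
            source=str(d["source"]),
            figure=str(d["figure"]),
            method=str(d["method"]),
            type=str(d["type"]),
            solvent=str(d.get("solvent", "water")),
            purity=None if d.get("purity") is None else str(d["purity"]),
            labels=tuple((str(a), str(b)) for a, b in d.get("labels", [])),
            keys=tuple(str(k) for k in d["keys"]),
            values=tuple(tuple(float(v) for v in col) for col in d["values"]),
        )

    # -- data access -------------------------------------------------------

    @property
    def state_columns(self) -> tuple[str, ...]:
        return self.keys[2:]

    def table(self, fractions: bool = False) -> pd.DataFrame:
        """The data block as a DataFrame (percentages by default)."""
        df = pd.DataFrame({k: list(v) for k, v in zip(self.keys, self.values)})
        if fractions and len(self.keys) > 2:
            df[list(self.state_columns)] = df[list(self.state_columns)] / 100.0
        return df


class PhDatDataset(dict):
    """Mapping from record-index string to :class:`PhDatRecord`."""

    def to_dict(self) -> dict:
        return {idx: rec.to_dict() for idx, rec in self.items()}


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_record(meta: dict, table: pd.DataFrame) -> PhDatRecord:
    """Assemble a record from metadata and a fractional probability table.

    *table* must have ``temperature`` and ``composition`` columns followed by
    one fractional probability column per phase state; probabilities are
    converted to percentages for storage.
    """
    missing = [k for k in _MANDATORY_META if k not in meta]
    if missing:
        raise SchemaError(f"metadata missing mandatory field(s): {missing}")
    cols = list(table.columns)
    if cols[:2] != ["temperature", "composition"]:
        raise SchemaError(
            "table must start with temperature and composition columns"
        )
    states = cols[2:]
    keys = tuple(cols)
    values = [tuple(float(v) for v in table[c]) for c in cols[:2]]
    for s in states:
        values.append(tuple(float(v) * 100.0 for v in table[s]))
    return PhDatRecord(
        smiles=str(meta["smiles"]),
        state=str(meta["state"]),
        name=str(meta["name"]),
        source=str(meta["source"]),
        figure=str(meta["figure"]),
        method=str(meta["method"]),
        type=str(meta["type"]),
        solvent=str(meta.get("solvent", "water")),
        purity=meta.get("purity"),
        labels=tuple((str(a), str(b)) for a, b in meta.get("labels", [])),
        keys=keys,
        values=tuple(values),
    )


def record_to_json(record: PhDatRecord) -> str:
    """Deterministic JSON text for one record."""
    return json.dumps(record.to_dict(), indent=1, ensure_ascii=False)


def write_dataset(dataset: PhDatDataset, path: str | Path | None = None) -> str:
    """Serialize a dataset to JSON text (and optionally a file).

    Record indices are emitted in numeric order when they are all numeric,
    otherwise lexicographic, so serialization is deterministic.
    """
    def sort_key(idx: str):
        return (0, int(idx)) if idx.isdigit() else (1, idx)

    doc = {idx: dataset[idx].to_dict() for idx in sorted(dataset, key=sort_key)}
    text = json.dumps(doc, indent=1, ensure_ascii=False)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def read_dataset(text: str) -> tuple[PhDatDataset, list[tuple[str, str]]]:
    """Parse PhDat JSON text.

    Accepts either the index-keyed map form or a list of records carrying
    explicit ``index`` fields.  Malformed records are collected into the
    returned error list (index, message) instead of aborting the load.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    items: list[tuple[str, dict]]
    if isinstance(doc, dict):
        items = [(str(k), v) for k, v in doc.items()]
    elif isinstance(doc, list):
        items = []
        for pos, entry in enumerate(doc):
            if not isinstance(entry, dict):
                raise SchemaError(f"list entry {pos} is not a record object")
            items.append((str(entry.get("index", pos)), entry))
    else:
        raise SchemaError("top level must be a record map or a record list")
    dataset = PhDatDataset()
    errors: list[tuple[str, str]] = []
    for idx, raw in items:
        if not isinstance(raw, dict):
            errors.append((idx, "record is not an object"))
            continue
        try:
            dataset[idx] = PhDatRecord.from_dict(raw)
        except (SchemaError, ValueError, TypeError) as exc:
            errors.append((idx, str(exc)))
    return dataset, errors


def read_dataset_file(path: str | Path) -> tuple[PhDatDataset, list[tuple[str, str]]]:
    return read_dataset(Path(path).read_text())


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Per-record rule violations; empty means the dataset is valid."""

    violations: list[tuple[str, str]] = field(default_factory=list)

    def add(self, idx: str, message: str) -> None:
        self.violations.append((idx, message))

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "dataset valid: no violations"
        lines = [f"record {i}: {m}" for i, m in self.violations]
        return "\n".join(lines)


def validate(
    dataset: PhDatDataset,
    vocabulary: Vocabulary | None = None,
    sum_tol: float = 1e-6,
) -> ValidationReport:
    """Check every record against the PhDat contract.

    Flags: value-list length mismatches, compositions outside [0, 100] wt%,
    per-point percentage sums away from 100 (beyond *sum_tol* x 100), phase
    columns not in the controlled vocabulary, ``U`` columns in records whose
    diagram state is ``"complete"``, and malformed metadata enums.
    """
    vocab = vocabulary or load_vocabulary()
    report = ValidationReport()
    for idx, rec in dataset.items():
        if rec.state not in _STATES:
            report.add(idx, f"unknown diagram state {rec.state!r}")
        if rec.type not in _TYPES:
            report.add(idx, f"unknown surfactant type {rec.type!r}")
        if not rec.method or not set(rec.method) <= _METHOD_CODES:
            report.add(idx, f"method {rec.method!r} not drawn from codes A-F")
        if len(rec.keys) != len(rec.values):
            report.add(idx, "keys and values have different lengths")
            continue
        if len(rec.keys) < 2:
            report.add(idx, "record needs temperature and composition columns")
            continue
        lengths = {len(col) for col in rec.values}
        if len(lengths) > 1:
            report.add(idx, f"value lists have unequal lengths {sorted(lengths)}")
            continue
        comp = np.asarray(rec.values[1], dtype=float)
        if comp.size and (comp.min() < 0.0 or comp.max() > 100.0):
            report.add(idx, "composition outside [0, 100] wt%")
        allow_u = rec.state == "incomplete"
        for col in rec.state_columns:
            if col == UNKNOWN_CODE:
                if not allow_u:
                    report.add(idx, "'U' column in a complete diagram")
            elif not vocab.is_valid_state(col):
                report.add(idx, f"unknown phase-state column {col!r}")
        if rec.state_columns and lengths and lengths != {0}:
            probs = np.asarray(rec.values[2:], dtype=float)
            sums = probs.sum(axis=0)
            bad = np.abs(sums - 100.0) > sum_tol * 100.0
            if np.any(bad):
                where = int(np.argmax(bad))
                report.add(
                    idx,
                    f"row {where} probabilities sum to {sums[where]:g}%, not 100%",
                )
            if probs.size and (probs.min() < 0.0 or probs.max() > 100.0):
                report.add(idx, "probability outside [0, 100]%")
    return report


# ---------------------------------------------------------------------------
# querying
# ---------------------------------------------------------------------------

_RECORD_FILTERS = {"smiles", "type", "state"}
_POINT_FILTERS = {"temperature_range", "composition_range", "drop_u"}


def query(dataset: PhDatDataset, **filters):
    """Filter a dataset; never mutates its input.

    Record-level filters (``smiles=``, ``type=``, ``state=``) return a new
    sub-:class:`PhDatDataset` and compose order-independently.  Point-level
    filters (``temperature_range=(lo, hi)``, ``composition_range=(lo, hi)``,
    ``drop_u=True``) return a tidy wide table instead: one row per surviving
    grid point with ``record``, ``temperature``, ``composition`` and the
    union of phase-state percentage columns.
    """
    unknown = set(filters) - _RECORD_FILTERS - _POINT_FILTERS
    if unknown:
        raise ValueError(
            f"unknown filter key(s) {sorted(unknown)}; allowed: "
            f"{sorted(_RECORD_FILTERS | _POINT_FILTERS)}"
        )
    subset = PhDatDataset(dataset)
    for key in _RECORD_FILTERS & set(filters):
        want = filters[key]
        subset = PhDatDataset(
            (idx, rec)
            for idx, rec in subset.items()
            if getattr(rec, key) == want
        )
    if not _POINT_FILTERS & set(filters):
        return subset

    frames = []
    for idx, rec in subset.items():
        df = rec.table()
        df.insert(0, "record", idx)
        frames.append(df)
    if frames:
        table = pd.concat(frames, ignore_index=True).fillna(0.0)
    else:
        table = pd.DataFrame(columns=["record", "temperature", "composition"])
    if "temperature_range" in filters:
        lo, hi = filters["temperature_range"]
        table = table[(table["temperature"] >= lo) & (table["temperature"] <= hi)]
    if "composition_range" in filters:
        lo, hi = filters["composition_range"]
        table = table[(table["composition"] >= lo) & (table["composition"] <= hi)]
    if filters.get("drop_u") and UNKNOWN_CODE in table.columns:
        table = table[table[UNKNOWN_CODE] == 0.0]
        table = table.drop(columns=[UNKNOWN_CODE])
    return table.reset_index(drop=True)
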