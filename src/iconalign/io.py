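"""Tab-delimited readers and writers for all pipeline tables.

All tables are UTF-8 TSV with a header row, no quoting dialect (tabs are
forbidden inside labels) and ``|`` as the in-cell list separator. Readers
reject duplicate primary keys and report the offending line number.

Formats
-------
``components.tsv``   component_id, name, required(0/1), multi_valued(0/1)
``primitives.tsv``   primitive_id, label, component_id, parent_id (ROOT for tops)
``icons.tsv``        icon_id, component_id, primitive_id  (long: one row per occurrence)
``concepts.tsv``     terminology_id, code, label, parents, cross_ids (pipe-separated)
``alignments.tsv``   terminology_id, code, icon_id, provenance(manual|automatic)
``sim_fixture.tsv``  primitive_a, primitive_b, similarity (symmetric closure on load)
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .icon_model import Component, Icon, Primitive

_CSV_KW = dict(delimiter="\t", quoting=csv.QUOTE_NONE, quotechar=None)


class TableError(ValueError):
    """Raised for malformed tables; messages name the file and line."""


def _read_rows(path, required_cols: Sequence[str]) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise TableError(f"{path}: file not found")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, **_CSV_KW)
        if reader.fieldnames is None:
            raise TableError(f"{path}: empty file (missing header)")
        missing = [c for c in required_cols if c not in reader.fieldnames]
        if missing:
            raise TableError(f"{path}: missing columns {missing}")
        rows = []
        for row in reader:
            if any(v is None for v in row.values()):
                raise TableError(f"{path} line {reader.line_num}: short row")
            row = {k: (v or "").strip() for k, v in row.items() if k is not None}
            row["__line__"] = reader.line_num
            rows.append(row)
    return rows


def _check_unique(rows: list[dict], key_cols: Sequence[str], path) -> None:
    seen: dict[tuple, int] = {}
    for row in rows:
        key = tuple(row[c] for c in key_cols)
        if key in seen:
            raise TableError(
                f"{path} line {row['__line__']}: duplicate key {key} "
                f"(first seen on line {seen[key]})"
            )
        seen[key] = row["__line__"]


def _write_rows(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, **_CSV_KW)
        writer.writerow(header)
        for row in rows:
            for cell in row:
                if "\t" in str(cell):
                    raise TableError(f"{path}: tab character inside cell {cell!r}")
            writer.writerow(row)


def _parse_flag(value: str, path, line) -> bool:
    if value in ("0", "1"):
        return value == "1"
    raise TableError(f"{path} line {line}: flag must be 0 or 1, got {value!r}")


# -- components ---------------------------------------------------------

def read_components(path) -> dict[str, Component]:
    rows = _read_rows(path, ["component_id", "name", "required", "multi_valued"])
    _check_unique(rows, ["component_id"], path)
    return {
        r["component_id"]: Component(
            id=r["component_id"],
            name=r["name"],
            required=_parse_flag(r["required"], path, r["__line__"]),
            multi_valued=_parse_flag(r["multi_valued"], path, r["__line__"]),
        )
        for r in rows
    }


def write_components(components: Mapping[str, Component] | Iterable[Component], path) -> None:
    comps = components.values() if isinstance(components, Mapping) else components
    _write_rows(
        path,
        ["component_id", "name", "required", "multi_valued"],
        [
            (c.id, c.name, int(c.required), int(c.multi_valued))
            for c in sorted(comps, key=lambda c: c.id)
        ],
    )


# -- primitives ---------------------------------------------------------

def read_primitives(path) -> list[Primitive]:
    rows = _read_rows(path, ["primitive_id", "label", "component_id", "parent_id"])
    _check_unique(rows, ["primitive_id"], path)
    return [
        Primitive(
            id=r["primitive_id"],
            label=r["label"],
            component=r["component_id"],
            parent=r["parent_id"],
        )
        for r in rows
    ]


def write_primitives(primitives: Iterable[Primitive], path) -> None:
    _write_rows(
        path,
        ["primitive_id", "label", "component_id", "parent_id"],
        [
            (p.id, p.label, p.component, p.parent)
            for p in sorted(primitives, key=lambda p: p.id)
        ],
    )


# -- icons (long format) ------------------------------------------------

def read_icons(path) -> dict[str, Icon]:
    rows = _read_rows(path, ["icon_id", "component_id", "primitive_id"])
    _check_unique(rows, ["icon_id", "component_id", "primitive_id"], path)
    assignments: dict[str, dict[str, set[str]]] = {}
    for r in rows:
        assignments.setdefault(r["icon_id"], {}).setdefault(
            r["component_id"], set()
        ).add(r["primitive_id"])
    return {icon_id: Icon(icon_id, assign) for icon_id, assign in assignments.items()}


def write_icons(icons: Mapping[str, Icon] | Iterable[Icon], path) -> None:
    items = icons.values() if isinstance(icons, Mapping) else icons
    rows = []
    for icon in sorted(items, key=lambda i: i.id):
        for comp, prims in sorted(icon.assignment.items()):
            for pid in sorted(prims):
                rows.append((icon.id, comp, pid))
    _write_rows(path, ["icon_id", "component_id", "primitive_id"], rows)


# -- concepts / alignments ----------------------------------------------

def read_concept_rows(path) -> list[dict]:
    rows = _read_rows(path, ["terminology_id", "code", "label", "parents", "cross_ids"])
    _check_unique(rows, ["terminology_id", "code"], path)
    return rows


def write_concepts(concepts: Iterable, path) -> None:
    """Write Concept objects (possibly from several terminologies)."""
    rows = []
    for c in sorted(concepts, key=lambda c: (c.terminology, c.code)):
        rows.append(
            (
                c.terminology,
                c.code,
                c.label,
                "|".join(sorted(c.parents)),
                "|".join(sorted(c.cross_ids)),
            )
        )
    _write_rows(path, ["terminology_id", "code", "label", "parents", "cross_ids"], rows)


def read_alignment_rows(path) -> list[dict]:
    rows = _read_rows(path, ["terminology_id", "code", "icon_id", "provenance"])
    _check_unique(rows, ["terminology_id", "code", "icon_id"], path)
    return rows


def write_alignments(records: Iterable[tuple[str, object]], path) -> None:
    """Write (terminology_id, AlignmentRecord) pairs."""
    rows = [
        (tid, rec.concept, rec.icon, rec.provenance)
        for tid, rec in sorted(
            records, key=lambda tr: (tr[0], tr[1].concept, tr[1].icon)
        )
    ]
    _write_rows(path, ["terminology_id", "code", "icon_id", "provenance"], rows)


# -- similarity fixture -------------------------------------------------

def read_sim_fixture(path) -> dict[tuple[str, str], float]:
    rows = _read_rows(path, ["primitive_a", "primitive_b", "similarity"])
    table: dict[tuple[str, str], float] = {}
    for r in rows:
        try:
            s = float(r["similarity"])
        except ValueError:
            raise TableError(
                f"{path} line {r['__line__']}: bad similarity {r['similarity']!r}"
            ) from None
        if not 0.0 <= s <= 1.0:
            raise TableError(f"{path} line {r['__line__']}: similarity {s} out of [0,1]")
        a, b = r["primitive_a"], r["primitive_b"]
        for key in ((a, b), (b, a)):
            if key in table and table[key] != s:
                raise TableError(
                    f"{path} line {r['__line__']}: conflicting similarity for {key}"
                )
            table[key] = s
    return table


def write_sim_fixture(table: Mapping[tuple[str, str], float], path) -> None:
    seen = set()
    rows = []
    for (a, b), s in sorted(table.items()):
        key = (a, b) if a <= b else (b, a)
        if key in seen:
            continue
        seen.add(key)
        rows.append((key[0], key[1], repr(float(s))))
    _write_rows(path, ["primitive_a", "primitive_b", "similarity"], rows)
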