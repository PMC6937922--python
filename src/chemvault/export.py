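"""Field-selection export: SDF and tab-delimited writers.

The selected fields determine not only the columns but the row semantics:
if every field is compound-level there is one row per compound; as soon
as any container-level field (including a biodata aggregate) appears,
there is one row per container, with the compound-level values repeated
on each of its rows. A compound without containers contributes no rows in
container mode.

Biodata aggregate columns (``biodata.count:<method>`` etc.) are statistics
over one container's assay entries for a given method — the
structure-activity view grouped by batch.
"""
from __future__ import annotations

import csv
import io
import re
from typing import Optional, Union

from pydantic import BaseModel

from . import chem
from .model import BiodataSrv, CompoundSrv
from .query import FIELDS
from .result import Result
from .store import DataTree


class ExportErr(Exception):
    def __init__(self, code: str, detail: str):
        super().__init__(f"{code}: {detail}")
        self.code = code
        self.detail = detail


class BiodataStats(BaseModel):
    """Summary of one method's assay values on one container."""

    method: int
    count: int
    mean: float
    min: float
    max: float


def aggregate_biodata(entries: list[BiodataSrv], method: int) -> Optional[BiodataStats]:
    """Stats over the entries of one assay method; ``None`` when the
    method has no entries in the list."""
    values = [e.value for e in entries if e.method == method]
    if not values:
        return None
    return BiodataStats(
        method=method,
        count=len(values),
        mean=sum(values) / len(values),
        min=min(values),
        max=max(values),
    )


_AGG_RE = re.compile(r"^biodata\.(count|mean|min|max):(\d+)$")

Cell = Union[str, float, int, None]


class ExportSpec(BaseModel):
    """Ordered field selection plus output format (``sdf`` or ``csv``)."""

    fields: list[str]
    format: str = "csv"

    def model_post_init(self, __context) -> None:
        if not self.fields:
            raise ExportErr("bad_spec", "field selection must be nonempty")
        if self.format not in ("sdf", "csv"):
            raise ExportErr("bad_spec", f"unknown format {self.format!r}")
        for f in self.fields:
            _field_level(f)


def _field_level(field: str) -> str:
    if _AGG_RE.match(field):
        return "container"  # aggregates are per-container (grouped by batch)
    fdef = FIELDS.get(field)
    if fdef is None or fdef.kind == "structure" or fdef.level not in ("compound", "container"):
        raise ExportErr("unknown_field", field)
    return fdef.level


def _cell(field: str, compound: CompoundSrv, container, tree: DataTree) -> Cell:
    m = _AGG_RE.match(field)
    if m:
        stat, method = m.group(1), int(m.group(2))
        entries = [
            b
            for bid in container.biodata
            if (b := tree.entity("biodata", bid)) is not None
        ]
        stats = aggregate_biodata(entries, method)
        return None if stats is None else getattr(stats, stat)
    fdef = FIELDS[field]
    return fdef.get(compound if fdef.level == "compound" else container)  # type: ignore[return-value]


def build_rows(
    compounds: list[CompoundSrv], tree: DataTree, spec: ExportSpec
) -> Result[list[list[Cell]], ExportErr]:
    """Explode a (visibility-filtered) hitset into export rows under the
    compound-mode / container-mode rule. Each row carries exactly one cell
    per selected field, in selection order."""
    try:
        levels = [_field_level(f) for f in spec.fields]
    except ExportErr as exc:
        return Result.err(exc)
    container_mode = any(lv == "container" for lv in levels)
    rows: list[list[Cell]] = []
    for c in compounds:
        if not container_mode:
            rows.append([_cell(f, c, None, tree) for f in spec.fields])
            continue
        for kid in c.containers:
            k = tree.entity("container", kid)
            if k is None:
                continue
            rows.append([_cell(f, c, k, tree) for f in spec.fields])
    return Result.ok(rows)


def _fmt(v: Cell) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return f"{v:g}"
    return str(v)


def write_csv(rows: list[list[Cell]], spec: ExportSpec) -> str:
    """Tab-delimited UTF-8 text: header of field labels in selection
    order, one line per row; cells containing tab/newline/quote are
    quoted so the table round-trips."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n", quoting=csv.QUOTE_MINIMAL)
    writer.writerow(spec.fields)
    for row in rows:
        writer.writerow([_fmt(v) for v in row])
    return buf.getvalue()


def read_csv(text: str) -> list[list[str]]:
    """Inverse of :func:`write_csv` (header included)."""
    return list(csv.reader(io.StringIO(text), delimiter="\t"))


def write_sdf(
    compounds: list[CompoundSrv], tree: DataTree, spec: ExportSpec
) -> Result[str, ExportErr]:
    """SDF text: per row a kekulized V2000 mol block, the selected fields
    as ``> <label>`` data items in order, then the ``$$$$`` terminator.
    Structure-less compounds emit a zero-atom mol block."""
    rows_res = build_rows(compounds, tree, spec)
    if rows_res.is_err:
        return Result.err(rows_res.error)
    levels = [_field_level(f) for f in spec.fields]
    container_mode = any(lv == "container" for lv in levels)

    # one structure per row, aligned with build_rows' enumeration order
    structures: list[Optional[str]] = []
    for c in compounds:
        n_rows = 1
        if container_mode:
            n_rows = sum(1 for kid in c.containers if tree.entity("container", kid) is not None)
        structures.extend([c.structure] * n_rows)

    out: list[str] = []
    for molfile, row in zip(structures, rows_res.value):
        if molfile is None:
            block = chem.empty_molblock()
        else:
            parsed = chem.parse_molfile(molfile)
            if parsed.is_err:
                return Result.err(ExportErr("bad_structure", str(parsed.error)))
            written = chem.to_molblock(parsed.value)
            if written.is_err:
                return Result.err(ExportErr("bad_structure", str(written.error)))
            block = written.value
        out.append(block.rstrip("\n") + "\n")
        for label, value in zip(spec.fields, row):
            out.append(f"> <{label}>\n{_fmt(value)}\n\n")
        out.append("$$$$\n")
    return Result.ok("".join(out))


def read_sdf(text: str) -> list[tuple[str, dict[str, str]]]:
    """Split SDF text back into (mol block, data items) records; the
    parse-back half of the export round-trip."""
    records = []
    for chunk in text.split("$$$$\n"):
        if not chunk.strip():
            continue
        if "\n> <" in chunk:
            mol, rest = chunk.split("\n> <", 1)
            mol += "\n"
            items: dict[str, str] = {}
            for item in ("> <" + rest).split("\n\n"):
                item = item.strip("\n")
                if not item:
                    continue
                header, _, value = item.partition("\n")
                label = header[len("> <") : header.index(">", 3)]
                items[label] = value
        else:
            mol, items = chunk, {}
        records.append((mol, items))
    return records
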