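"""Event-sourced persistence: append-only change log and its replay.

The dataset on disk is a newline-delimited JSON file of
:class:`ChangeRecord`s — one timestamped, user-attributed mutation per
line, sequence numbers contiguous from 1. The in-memory
:class:`DataTree` is a left fold of ``apply_record`` over the log; the
server reconstructs it from the log at startup, and any prefix of a valid
log is itself a valid log (crash consistency).

``DataTree`` is persistent in the functional sense: ``apply_record``
returns a new tree sharing unchanged structure with the old one, so
readers can keep using a snapshot while a writer advances the head.

Linked files and per-user settings live outside the history in an
embedded SQLite database (:class:`BlobStore`, :class:`SettingsStore`);
they are deliberately not event-sourced.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import sqlite3
import threading
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Iterator, Optional

from pydantic import BaseModel

from . import model
from .result import Result

log = logging.getLogger("chemvault.store")

OPS = ("add", "mod", "del")


class StoreErr(Exception):
    """Failure in the persistence layer (codes: seq_conflict, corrupt_log,
    not_found, missing_ref, validation, conflict)."""

    def __init__(self, code: str, detail: str, seq: Optional[int] = None):
        super().__init__(f"{code}: {detail}")
        self.code = code
        self.detail = detail
        self.seq = seq


@dataclass(frozen=True)
class DecodeErr:
    """Mandatory fields without defaults that were missing from a JSON tree."""

    missing: tuple[str, ...]
    detail: str


class ChangeRecord(BaseModel):
    """One mutation in the append-only log."""

    seq: int
    ts: int
    user: int
    family: str
    id: int
    op: str
    payload: dict[str, Any] = {}

    def meta(self) -> model.EditMeta:
        return model.EditMeta(ts=self.ts, user=self.user)


# --------------------------------------------------------------------------
# Schema-tolerant decoding
# --------------------------------------------------------------------------


def decode_with_defaults(
    raw: dict[str, Any], family: str, variant: str
) -> Result[BaseModel, DecodeErr]:
    """Decode a stored JSON object against today's schema.

    Fields added to the schema after the record was written are absent
    from the JSON: optional ones decode as absent, ones with declared
    defaults take the default. Unknown fields (removed from the schema,
    or written by a newer version) are ignored with a warning. Only a
    mandatory field without a default is an error, reported by name.
    """
    cls = model.FAMILIES[family][variant]
    if cls is None:
        return Result.err(DecodeErr((), f"{family} has no {variant} variant"))
    extras = set(raw) - set(cls.model_fields)
    if extras:
        log.warning("ignoring unknown fields %s in %s.%s record", sorted(extras), family, variant)
    try:
        return Result.ok(cls.model_validate(raw))
    except Exception as exc:
        missing = tuple(
            ".".join(str(p) for p in e["loc"])
            for e in getattr(exc, "errors", lambda: [])()
            if e.get("type") == "missing"
        )
        return Result.err(DecodeErr(missing, str(exc)))


# --------------------------------------------------------------------------
# The data tree
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Node:
    """A stored entity plus its audit trail; deletion is a flag, never
    physical removal — the history stays reviewable."""

    entity: BaseModel
    deleted: bool = False
    history: tuple[int, ...] = ()


@dataclass(frozen=True)
class DataTree:
    """Id-keyed map per family; a fold over the change log."""

    families: dict[str, dict[int, Node]] = field(
        default_factory=lambda: {f: {} for f in model.FAMILIES}
    )

    def node(self, family: str, ident: int) -> Optional[Node]:
        return self.families[family].get(ident)

    def entity(self, family: str, ident: int) -> Optional[BaseModel]:
        n = self.node(family, ident)
        return None if n is None or n.deleted else n.entity

    def alive(self, family: str) -> Iterator[BaseModel]:
        for n in self.families[family].values():
            if not n.deleted:
                yield n.entity

    def next_id(self, family: str) -> int:
        fam = self.families[family]
        return max(fam, default=0) + 1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DataTree):
            return NotImplemented
        return self.families == other.families


_PARENT_LINK = {child: (parent, link, coll) for child, parent, link, coll in model.CHILD_LINKS}
#: link field -> referenced family, checked for referential integrity on add
_REF_FIELDS = {
    "compound": {"project": "project"},
    "container": {"project": "project", "location": "location", "supplier": "supplier"},
    "biodata": {"project": "project", "method": "method"},
    "file": {"project": "project"},
}


def _with_node(tree: DataTree, family: str, ident: int, node: Node) -> DataTree:
    fams = dict(tree.families)
    fam = dict(fams[family])
    fam[ident] = node
    fams[family] = fam
    return DataTree(families=fams)


def _check_refs(tree: DataTree, family: str, data: BaseModel) -> Optional[StoreErr]:
    for fld, target in _REF_FIELDS.get(family, {}).items():
        ref = getattr(data, fld, None)
        if ref is not None and tree.entity(target, ref) is None:
            return StoreErr("missing_ref", f"{family}.{fld} -> {target} {ref} does not exist")
    if family in _PARENT_LINK:
        parent_family, link, _ = _PARENT_LINK[family]
        pid = getattr(data, link, None)  # Mod variants have no parent link
        if pid is not None and tree.entity(parent_family, pid) is None:
            return StoreErr("missing_ref", f"{family}.{link} -> {parent_family} {pid} does not exist")
    if family == "file" and hasattr(data, "parent_family"):
        pf, pid = data.parent_family, data.parent_id  # type: ignore[attr-defined]
        if pf not in ("compound", "container", "biodata"):
            return StoreErr("missing_ref", f"file parent family {pf!r} cannot hold files")
        if tree.entity(pf, pid) is None:
            return StoreErr("missing_ref", f"file parent {pf} {pid} does not exist")
    return None


def _attach_child(tree: DataTree, child_family: str, child: BaseModel) -> DataTree:
    """Append the new child's id to its parent's child-id collection."""
    if child_family in _PARENT_LINK:
        parent_family, link, coll = _PARENT_LINK[child_family]
    elif child_family == "file":
        parent_family, link, coll = child.parent_family, "parent_id", "files"  # type: ignore[attr-defined]
    else:
        return tree
    pid = getattr(child, link)
    pnode = tree.node(parent_family, pid)
    assert pnode is not None  # ref-checked upstream
    ids = list(getattr(pnode.entity, coll))
    ids.append(child.id)  # type: ignore[attr-defined]
    new_parent = pnode.entity.model_copy(update={coll: ids})
    return _with_node(tree, parent_family, pid, replace(pnode, entity=new_parent))


def apply_record(tree: DataTree, rec: ChangeRecord) -> Result[DataTree, StoreErr]:
    """Apply one change record; the single transition function used both
    for replay and for live mutations (so the two can never diverge)."""
    if rec.op not in OPS:
        return Result.err(StoreErr("corrupt_log", f"unknown op {rec.op!r}", rec.seq))
    if rec.family not in model.FAMILIES:
        return Result.err(StoreErr("corrupt_log", f"unknown family {rec.family!r}", rec.seq))
    node = tree.node(rec.family, rec.id)

    if rec.op == "add":
        if node is not None:
            return Result.err(StoreErr("conflict", f"{rec.family} {rec.id} already exists", rec.seq))
        decoded = decode_with_defaults(rec.payload, rec.family, "add")
        if decoded.is_err:
            return Result.err(StoreErr("validation", decoded.error.detail, rec.seq))
        err = _check_refs(tree, rec.family, decoded.value)
        if err is not None:
            err.seq = rec.seq
            return Result.err(err)
        made = model.mk_srv(rec.family, rec.id, decoded.value, rec.meta())
        if made.is_err:
            return Result.err(StoreErr("validation", made.error.detail, rec.seq))
        out = _with_node(tree, rec.family, rec.id, Node(made.value, history=(rec.seq,)))
        return Result.ok(_attach_child(out, rec.family, made.value))

    if node is None or node.deleted:
        return Result.err(StoreErr("not_found", f"{rec.family} {rec.id} not live", rec.seq))

    if rec.op == "mod":
        decoded = decode_with_defaults(rec.payload, rec.family, "mod")
        if decoded.is_err:
            return Result.err(StoreErr("validation", decoded.error.detail, rec.seq))
        err = _check_refs(tree, rec.family, decoded.value)
        if err is not None:
            err.seq = rec.seq
            return Result.err(err)
        merged = model.apply_mod(node.entity, decoded.value, rec.family)
        if merged.is_err:
            return Result.err(StoreErr("validation", merged.error.detail, rec.seq))
        return Result.ok(
            _with_node(
                tree, rec.family, rec.id,
                Node(merged.value, history=node.history + (rec.seq,)),
            )
        )

    # del: soft — flag, keep entity and history
    return Result.ok(
        _with_node(
            tree, rec.family, rec.id,
            replace(node, deleted=True, history=node.history + (rec.seq,)),
        )
    )


def replay(records: Iterable[ChangeRecord]) -> Result[DataTree, StoreErr]:
    """Left fold of the log in sequence order; fails fast at the first
    corrupt record, reporting its sequence number."""
    tree = DataTree()
    expected = 1
    for rec in records:
        if rec.seq != expected:
            return Result.err(
                StoreErr("corrupt_log", f"expected seq {expected}, found {rec.seq}", rec.seq)
            )
        applied = apply_record(tree, rec)
        if applied.is_err:
            e = applied.error
            return Result.err(StoreErr("corrupt_log", f"seq {rec.seq}: {e.detail}", rec.seq))
        tree = applied.value
        expected += 1
    return Result.ok(tree)


def history(
    records: Iterable[ChangeRecord], tree: DataTree, family: str, ident: int
) -> Result[list[ChangeRecord], StoreErr]:
    """Every change record that touched an entity, oldest first; served
    for deleted entities too."""
    node = tree.node(family, ident)
    if node is None:
        return Result.err(StoreErr("not_found", f"{family} {ident} was never created"))
    wanted = set(node.history)
    return Result.ok([r for r in records if r.seq in wanted])


# --------------------------------------------------------------------------
# The NDJSON change log
# --------------------------------------------------------------------------


class ChangeLog:
    """Append-only NDJSON log; one ChangeRecord per line, UTF-8.

    A record is durable (flushed and fsynced) before ``append`` returns.
    Without a path the log is memory-only, which the tests use freely.
    """

    def __init__(self, path: Optional[str | os.PathLike] = None):
        self.path = Path(path) if path is not None else None
        self.records: list[ChangeRecord] = []
        if self.path is not None and self.path.exists():
            loaded = load_log(self.path)
            if loaded.is_err:
                raise loaded.error
            self.records = loaded.value

    @property
    def last_seq(self) -> int:
        return self.records[-1].seq if self.records else 0

    def append(self, rec: ChangeRecord) -> Result[None, StoreErr]:
        if rec.seq != self.last_seq + 1:
            return Result.err(
                StoreErr("seq_conflict", f"expected seq {self.last_seq + 1}, got {rec.seq}", rec.seq)
            )
        line = json.dumps(rec.model_dump(mode="json"), ensure_ascii=False, sort_keys=True)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(line + "\n")
                fh.flush()
                os.fsync(fh.fileno())
        self.records.append(rec)
        return Result.ok(None)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ChangeRecord]:
        return iter(self.records)


def load_log(path: str | os.PathLike) -> Result[list[ChangeRecord], StoreErr]:
    """Parse an NDJSON change-log file; fail fast on the first bad line."""
    records: list[ChangeRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                records.append(ChangeRecord.model_validate(json.loads(line)))
            except Exception as exc:
                return Result.err(
                    StoreErr("corrupt_log", f"line {lineno}: {exc}", seq=lineno)
                )
    return Result.ok(records)


# --------------------------------------------------------------------------
# Side stores (not historized)
# --------------------------------------------------------------------------


class _Sqlite:
    def __init__(self, path: str | os.PathLike = ":memory:"):
        self._conn = sqlite3.connect(str(path), check_same_thread=False)
        self._lock = threading.Lock()


class BlobStore(_Sqlite):
    """Content-addressed binary store for linked files. Files are large
    and change rarely; keeping their update history would cost much and
    buy nothing, so they live outside the event log."""

    def __init__(self, path: str | os.PathLike = ":memory:"):
        super().__init__(path)
        with self._lock:
            self._conn.execute(
                "CREATE TABLE IF NOT EXISTS blobs"
                " (id TEXT PRIMARY KEY, name TEXT, mime TEXT, data BLOB)"
            )
            self._conn.commit()

    def put(self, data: bytes, name: str = "", mime: str = "application/octet-stream") -> str:
        blob_id = hashlib.sha256(data).hexdigest()
        with self._lock:
            self._conn.execute(
                "INSERT OR REPLACE INTO blobs (id, name, mime, data) VALUES (?, ?, ?, ?)",
                (blob_id, name, mime, sqlite3.Binary(data)),
            )
            self._conn.commit()
        return blob_id

    def get(self, blob_id: str) -> Optional[tuple[bytes, str, str]]:
        with self._lock:
            row = self._conn.execute(
                "SELECT data, name, mime FROM blobs WHERE id = ?", (blob_id,)
            ).fetchone()
        return None if row is None else (bytes(row[0]), row[1], row[2])


class SettingsStore(_Sqlite):
    """Per-user settings (column layouts, named stored queries);
    last-write-wins, not historized — they change with nearly every
    client interaction."""

    def __init__(self, path: str | os.PathLike = ":memory:"):
        super().__init__(path)
        with self._lock:
            self._conn.execute(
                "CREATE TABLE IF NOT EXISTS settings (user_id INTEGER PRIMARY KEY, doc TEXT)"
            )
            self._conn.commit()

    def put(self, user_id: int, settings: dict[str, Any]) -> None:
        with self._lock:
            self._conn.execute(
                "INSERT OR REPLACE INTO settings (user_id, doc) VALUES (?, ?)",
                (user_id, json.dumps(settings, ensure_ascii=False, sort_keys=True)),
            )
            self._conn.commit()

    def get(self, user_id: int) -> Optional[dict[str, Any]]:
        with self._lock:
            row = self._conn.execute(
                "SELECT doc FROM settings WHERE user_id = ?", (user_id,)
            ).fetchone()
        return None if row is None else json.loads(row[0])
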