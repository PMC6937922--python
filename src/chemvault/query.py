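"""Quick-search dispatch and combined predicate-tree queries.

A combined query is a finite tree: leaves pair a registered field with a
predicate, interior nodes are ``And``/``Or`` connectives. The backend
compiles the tree into a single predicate over stored compounds;
container-, biodata- and file-level leaves match a compound iff *any*
visible child of that kind satisfies the leaf (each leaf quantifies
independently — two container leaves under an ``And`` need not be
satisfied by the same container).

Quick search dispatches on the shape of the search string: a list of
integers is an id set, a CAS-shaped string a CAS lookup, anything else a
case-insensitive regular expression matched against every textual field
in the compound's subtree.

Visibility is applied *before* any predicate runs: queries are evaluated
against the user's visible subtree only, so a hit can never mention data
from an inaccessible project.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Literal, Optional, Union

from pydantic import BaseModel

from . import auth, chem, model
from .model import CompoundSrv, UserSrv
from .result import Result
from .store import DataTree

DEFAULT_PAGE_LIMIT = 64
MAX_PAGE_LIMIT = 256


class QueryErr(Exception):
    """codes: unknown_field, bad_regex, bad_structure, bad_predicate,
    unsortable_field, bad_paging"""

    def __init__(self, code: str, detail: str):
        super().__init__(f"{code}: {detail}")
        self.code = code
        self.detail = detail


# --------------------------------------------------------------------------
# Field registry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldDef:
    level: str  # compound | container | biodata | file
    kind: str  # numeric | text | link | structure
    get: Callable[[BaseModel], object]


@lru_cache(maxsize=4096)
def _mass_of(molfile: str) -> Optional[float]:
    parsed = chem.parse_molfile(molfile)
    if parsed.is_err:
        return None
    props = chem.compute_properties(parsed.value)
    return None if props.is_err else props.value["mass"]


def _compound_mass(c: BaseModel) -> Optional[float]:
    return None if c.structure is None else _mass_of(c.structure)  # type: ignore[attr-defined]


FIELDS: dict[str, FieldDef] = {
    "compound.id": FieldDef("compound", "numeric", lambda e: e.id),
    "compound.name": FieldDef("compound", "text", lambda e: e.name),
    "compound.casNr": FieldDef("compound", "text", lambda e: e.casNr),
    "compound.mass": FieldDef("compound", "numeric", _compound_mass),
    "compound.project": FieldDef("compound", "link", lambda e: e.project),
    "compound.structure": FieldDef("compound", "structure", lambda e: e.structure),
    "container.batch": FieldDef("container", "text", lambda e: e.batch),
    "container.amount": FieldDef("container", "numeric", lambda e: e.amount),
    "container.purity": FieldDef("container", "numeric", lambda e: e.purity),
    "container.location": FieldDef("container", "link", lambda e: e.location),
    "container.supplier": FieldDef("container", "link", lambda e: e.supplier),
    "container.project": FieldDef("container", "link", lambda e: e.project),
    "biodata.value": FieldDef("biodata", "numeric", lambda e: e.value),
    "biodata.method": FieldDef("biodata", "link", lambda e: e.method),
    "file.name": FieldDef("file", "text", lambda e: e.name),
}

SORTABLE = {f: d for f, d in FIELDS.items() if d.level == "compound" and d.kind in ("numeric", "text")}


# --------------------------------------------------------------------------
# Query AST
# --------------------------------------------------------------------------

CMP_FNS: dict[str, Callable[[float, float], bool]] = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    "==": lambda a, b: a == b,
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
}


@dataclass(frozen=True)
class NumericPred:
    clauses: tuple[tuple[str, float], ...]  # conjunction of (cmp, value)


@dataclass(frozen=True)
class TextPred:
    mode: Literal["exact", "contains", "regex"]
    s: str


@dataclass(frozen=True)
class LinkPred:
    allowed: frozenset[int]


@dataclass(frozen=True)
class StructurePred:
    kind: Literal["substructure", "similarity"]
    molfile: str
    threshold: Optional[float] = None  # similarity only, in (0, 1]


PredicateSpec = Union[NumericPred, TextPred, LinkPred, StructurePred]


@dataclass(frozen=True)
class Leaf:
    field: str
    pred: PredicateSpec


@dataclass(frozen=True)
class And:
    children: tuple["QueryTree", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["QueryTree", ...]


QueryTree = Union[Leaf, And, Or]


@dataclass(frozen=True)
class IdSet:
    ids: frozenset[int]


@dataclass(frozen=True)
class CasQuery:
    cas: str


@dataclass(frozen=True)
class RegexQuery:
    pattern: str


QuickQuery = Union[IdSet, CasQuery, RegexQuery]


@dataclass(frozen=True)
class SortSpec:
    field: str
    ascending: bool = True


@dataclass(frozen=True)
class Paging:
    offset: int = 0
    limit: int = DEFAULT_PAGE_LIMIT

    def __post_init__(self) -> None:
        if self.offset < 0 or not (1 <= self.limit <= MAX_PAGE_LIMIT):
            raise QueryErr("bad_paging", f"offset={self.offset} limit={self.limit}")


# --------------------------------------------------------------------------
# Quick search
# --------------------------------------------------------------------------

_INT_TOKENS = re.compile(r"^\s*\d+(\s+\d+)*\s*$")
_CAS_SHAPE = re.compile(r"^\s*\d{2,7}-\d{2}-\d\s*$")


def parse_quick(s: str) -> Result[QuickQuery, QueryErr]:
    """Dispatch precedence: integer tokens → id set, CAS shape → CAS
    lookup, anything else → regular expression."""
    if not s or not s.strip():
        return Result.err(QueryErr("bad_regex", "empty quick-search string"))
    if _INT_TOKENS.match(s):
        return Result.ok(IdSet(frozenset(int(t) for t in s.split())))
    if _CAS_SHAPE.match(s):
        return Result.ok(CasQuery(s.strip()))
    try:
        re.compile(s)
    except re.error as exc:
        return Result.err(QueryErr("bad_regex", f"{s!r}: {exc}"))
    return Result.ok(RegexQuery(s))


def _subtree_texts(c: CompoundSrv, tree: DataTree) -> list[str]:
    out = [c.name]
    if c.casNr:
        out.append(c.casNr)
    for fid in c.files:
        f = tree.entity("file", fid)
        if f is not None:
            out.append(f.name)  # type: ignore[attr-defined]
    for kid in c.containers:
        k = tree.entity("container", kid)
        if k is None:
            continue
        out.append(k.batch)  # type: ignore[attr-defined]
        for fid in k.files:  # type: ignore[attr-defined]
            f = tree.entity("file", fid)
            if f is not None:
                out.append(f.name)  # type: ignore[attr-defined]
    return out


# --------------------------------------------------------------------------
# Structure-query support (cached per molfile text)
# --------------------------------------------------------------------------


@lru_cache(maxsize=4096)
def _search_ready(molfile: str) -> Optional[chem.Molecule]:
    parsed = chem.parse_molfile(molfile)
    if parsed.is_err:
        return None
    norm = chem.normalize(parsed.value, chem.MolState.SEARCH_READY)
    return None if norm.is_err else norm.value


@lru_cache(maxsize=4096)
def _fingerprint(molfile: str) -> Optional[chem.Fingerprint]:
    m = _search_ready(molfile)
    if m is None:
        return None
    fp = chem.morgan_fingerprint(m)
    return None if fp.is_err else fp.value


# --------------------------------------------------------------------------
# Compilation
# --------------------------------------------------------------------------

CompiledPred = Callable[[CompoundSrv, DataTree], bool]


def _compile_value_pred(fdef: FieldDef, pred: PredicateSpec) -> Callable[[object], bool]:
    if isinstance(pred, NumericPred):
        if fdef.kind != "numeric":
            raise QueryErr("bad_predicate", f"numeric predicate on {fdef.kind} field")
        clauses = [(CMP_FNS[c], v) for c, v in pred.clauses]

        def num(v: object) -> bool:
            return v is not None and all(fn(float(v), ref) for fn, ref in clauses)  # type: ignore[arg-type]

        return num
    if isinstance(pred, TextPred):
        if fdef.kind != "text":
            raise QueryErr("bad_predicate", f"text predicate on {fdef.kind} field")
        if pred.mode == "regex":
            try:
                rx = re.compile(pred.s)
            except re.error as exc:
                raise QueryErr("bad_regex", f"{pred.s!r}: {exc}")
            return lambda v: v is not None and rx.search(str(v)) is not None
        if pred.mode == "exact":
            return lambda v: v == pred.s
        if pred.mode == "contains":
            return lambda v: v is not None and pred.s.lower() in str(v).lower()
        raise QueryErr("bad_predicate", f"unknown text mode {pred.mode!r}")
    if isinstance(pred, LinkPred):
        if fdef.kind != "link":
            raise QueryErr("bad_predicate", f"link predicate on {fdef.kind} field")
        return lambda v: v in pred.allowed
    raise QueryErr("bad_predicate", f"predicate {type(pred).__name__} not applicable here")


def _compile_structure(pred: StructurePred) -> Callable[[Optional[str]], bool]:
    qmol = _search_ready(pred.molfile)
    if qmol is None:
        raise QueryErr("bad_structure", "query molfile does not parse")
    if pred.kind == "similarity":
        if pred.threshold is None or not (0 < pred.threshold <= 1):
            raise QueryErr("bad_predicate", "similarity requires threshold in (0, 1]")
        qfp = _fingerprint(pred.molfile)

        def sim(molfile: Optional[str]) -> bool:
            if molfile is None or qfp is None:
                return False
            tfp = _fingerprint(molfile)
            return tfp is not None and chem.tanimoto_similarity(qfp, tfp) >= pred.threshold

        return sim

    def sub(molfile: Optional[str]) -> bool:
        if molfile is None:
            return False
        tmol = _search_ready(molfile)
        if tmol is None:
            return False
        res = chem.substructure_match(qmol, tmol)
        return res.is_ok and res.value

    return sub


def _children_of(c: CompoundSrv, tree: DataTree, level: str):
    if level == "container":
        for kid in c.containers:
            k = tree.entity("container", kid)
            if k is not None:
                yield k
    elif level == "biodata":
        for kid in c.containers:
            k = tree.entity("container", kid)
            if k is None:
                continue
            for bid in k.biodata:  # type: ignore[attr-defined]
                b = tree.entity("biodata", bid)
                if b is not None:
                    yield b
    elif level == "file":
        ids = list(c.files)
        for kid in c.containers:
            k = tree.entity("container", kid)
            if k is None:
                continue
            ids.extend(k.files)  # type: ignore[attr-defined]
            for bid in k.biodata:  # type: ignore[attr-defined]
                b = tree.entity("biodata", bid)
                if b is not None:
                    ids.extend(b.files)  # type: ignore[attr-defined]
        for fid in ids:
            f = tree.entity("file", fid)
            if f is not None:
                yield f


def compile_tree(tree: QueryTree) -> Result[CompiledPred, QueryErr]:
    """Compile a predicate tree into a total function over stored
    compounds. Empty connectives take their neutral element: an empty
    ``And`` matches everything, an empty ``Or`` nothing."""
    try:
        return Result.ok(_compile_node(tree))
    except QueryErr as exc:
        return Result.err(exc)


def _compile_node(node: QueryTree) -> CompiledPred:
    if isinstance(node, And):
        kids = [_compile_node(k) for k in node.children]
        return lambda c, t: all(k(c, t) for k in kids)
    if isinstance(node, Or):
        kids = [_compile_node(k) for k in node.children]
        return lambda c, t: any(k(c, t) for k in kids)
    if not isinstance(node, Leaf):
        raise QueryErr("bad_predicate", f"unknown node {type(node).__name__}")
    fdef = FIELDS.get(node.field)
    if fdef is None:
        raise QueryErr("unknown_field", node.field)

    if isinstance(node.pred, StructurePred):
        if fdef.kind != "structure":
            raise QueryErr("bad_predicate", f"structure predicate on {fdef.kind} field")
        match = _compile_structure(node.pred)
        return lambda c, t: match(fdef.get(c))  # type: ignore[arg-type]

    value_ok = _compile_value_pred(fdef, node.pred)
    if fdef.level == "compound":
        return lambda c, t: value_ok(fdef.get(c))
    level = fdef.level
    return lambda c, t: any(value_ok(fdef.get(child)) for child in _children_of(c, t, level))


# --------------------------------------------------------------------------
# Execution
# --------------------------------------------------------------------------


def query_hits(
    tree: DataTree, user: UserSrv, q: Union[QueryTree, QuickQuery, None]
) -> Result[list[CompoundSrv], QueryErr]:
    """Visible compounds matching ``q`` (``None`` = match all), in stored
    id order. Visibility filtering happens before any predicate runs."""
    visible = auth.visible_subtree(user, tree)
    compounds = sorted(visible.alive("compound"), key=lambda c: c.id)
    if q is None:
        return Result.ok(compounds)
    if isinstance(q, IdSet):
        return Result.ok([c for c in compounds if c.id in q.ids])
    if isinstance(q, CasQuery):
        return Result.ok([c for c in compounds if c.casNr == q.cas])
    if isinstance(q, RegexQuery):
        try:
            rx = re.compile(q.pattern, re.IGNORECASE)
        except re.error as exc:
            return Result.err(QueryErr("bad_regex", f"{q.pattern!r}: {exc}"))
        return Result.ok(
            [c for c in compounds if any(rx.search(t) for t in _subtree_texts(c, visible))]
        )
    compiled = compile_tree(q)
    if compiled.is_err:
        return Result.err(compiled.error)
    pred = compiled.value
    return Result.ok([c for c in compounds if pred(c, visible)])


def sort_hits(hits: list[CompoundSrv], sort: SortSpec) -> Result[list[CompoundSrv], QueryErr]:
    """Stable sort on a compound-level field; entities lacking the field
    go last regardless of direction."""
    fdef = SORTABLE.get(sort.field)
    if fdef is None:
        return Result.err(QueryErr("unsortable_field", sort.field))
    present = [h for h in hits if fdef.get(h) is not None]
    missing = [h for h in hits if fdef.get(h) is None]
    present.sort(key=fdef.get, reverse=not sort.ascending)  # type: ignore[arg-type]
    return Result.ok(present + missing)


@dataclass(frozen=True)
class Page:
    items: list
    total: int
    offset: int
    limit: int


def paginate(hits: list, page: Paging) -> Page:
    """Slice ``hits[offset : offset+limit]``; out-of-range offsets yield an
    empty slice, and consecutive pages concatenate back to ``hits``."""
    return Page(
        items=hits[page.offset : page.offset + page.limit],
        total=len(hits),
        offset=page.offset,
        limit=page.limit,
    )


# --------------------------------------------------------------------------
# Client-view assembly
# --------------------------------------------------------------------------


@lru_cache(maxsize=1024)
def _svg_of(molfile: str) -> Optional[str]:
    parsed = chem.parse_molfile(molfile)
    if parsed.is_err:
        return None
    svg = chem.render_svg(parsed.value)
    return None if svg.is_err else svg.value


def make_resolver(tree: DataTree) -> model.ResolveFn:
    def resolve(family: str, ident: int) -> str:
        e = tree.entity(family, ident)
        if e is None:
            return f"{family}#{ident}"
        return getattr(e, "name", None) or getattr(e, "alias", f"{family}#{ident}")

    return resolve


def compound_to_cli(c: CompoundSrv, visible: DataTree, user: UserSrv) -> model.CompoundCli:
    """Assemble the nested client view; every node demands an access proof
    obtained from ``auth.has_access`` for its own project."""
    resolve = make_resolver(visible)

    def file_cli(fid: int):
        f = visible.entity("file", fid)
        if f is None:
            return None
        proof = auth.has_access(user, f.project)  # type: ignore[attr-defined]
        return model.to_cli(f, "file", proof, resolve)

    containers = []
    for kid in c.containers:
        k = visible.entity("container", kid)
        if k is None:
            continue
        biodata = []
        for bid in k.biodata:  # type: ignore[attr-defined]
            b = visible.entity("biodata", bid)
            if b is None:
                continue
            bproof = auth.has_access(user, b.project)  # type: ignore[attr-defined]
            bfiles = [x for x in (file_cli(f) for f in b.files) if x is not None]  # type: ignore[attr-defined]
            biodata.append(model.to_cli(b, "biodata", bproof, resolve, files=bfiles))
        kproof = auth.has_access(user, k.project)  # type: ignore[attr-defined]
        kfiles = [x for x in (file_cli(f) for f in k.files) if x is not None]  # type: ignore[attr-defined]
        containers.append(
            model.to_cli(k, "container", kproof, resolve, biodata=biodata, files=kfiles)
        )
    proof = auth.has_access(user, c.project)
    cfiles = [x for x in (file_cli(f) for f in c.files) if x is not None]
    svg = _svg_of(c.structure) if c.structure else None
    return model.to_cli(
        c, "compound", proof, resolve, svg=svg, containers=containers, files=cfiles
    )


def run_query(
    tree: DataTree,
    user: UserSrv,
    q: Union[QueryTree, QuickQuery, None],
    sort: Optional[SortSpec] = None,
    page: Optional[Paging] = None,
) -> Result[Page, QueryErr]:
    """Full pipeline: visibility filter → predicate → sort → page → client
    views. Only the returned slice is converted (and rendered) — large
    hitsets stay cheap, the client lazily pages through them."""
    hits = query_hits(tree, user, q)
    if hits.is_err:
        return Result.err(hits.error)
    ordered = hits.value
    if sort is not None:
        sorted_res = sort_hits(ordered, sort)
        if sorted_res.is_err:
            return Result.err(sorted_res.error)
        ordered = sorted_res.value
    pg = paginate(ordered, page or Paging())
    visible = auth.visible_subtree(user, tree)
    items = [compound_to_cli(c, visible, user) for c in pg.items]
    return Result.ok(Page(items=items, total=pg.total, offset=pg.offset, limit=pg.limit))


# --------------------------------------------------------------------------
# Wire schema (shared with the HTTP layer)
# --------------------------------------------------------------------------


def pred_from_json(raw: dict) -> PredicateSpec:
    kind = raw.get("type")
    if kind == "numeric":
        return NumericPred(tuple((c, float(v)) for c, v in raw["clauses"]))
    if kind == "text":
        return TextPred(raw["mode"], raw["s"])
    if kind == "link":
        return LinkPred(frozenset(int(i) for i in raw["allowed"]))
    if kind == "structure":
        return StructurePred(raw["kind"], raw["molfile"], raw.get("threshold"))
    raise QueryErr("bad_predicate", f"unknown predicate type {kind!r}")


def tree_from_json(raw: dict) -> QueryTree:
    if "and" in raw:
        return And(tuple(tree_from_json(k) for k in raw["and"]))
    if "or" in raw:
        return Or(tuple(tree_from_json(k) for k in raw["or"]))
    if "field" in raw:
        return Leaf(raw["field"], pred_from_json(raw["pred"]))
    raise QueryErr("bad_predicate", f"unknown query node {sorted(raw)}")


def pred_to_json(p: PredicateSpec) -> dict:
    if isinstance(p, NumericPred):
        return {"type": "numeric", "clauses": [list(c) for c in p.clauses]}
    if isinstance(p, TextPred):
        return {"type": "text", "mode": p.mode, "s": p.s}
    if isinstance(p, LinkPred):
        return {"type": "link", "allowed": sorted(p.allowed)}
    return {"type": "structure", "kind": p.kind, "molfile": p.molfile, "threshold": p.threshold}


def tree_to_json(t: QueryTree) -> dict:
    if isinstance(t, And):
        return {"and": [tree_to_json(k) for k in t.children]}
    if isinstance(t, Or):
        return {"or": [tree_to_json(k) for k in t.children]}
    return {"field": t.field, "pred": pred_to_json(t.pred)}
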