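"""Entity families and their four systematic shape variants.

Every entity family (compound, container, biodata entry, project, user,
supplier, location, method, file reference) exists in four shapes:

``Srv``
    the stored server record: id present, child collections present as id
    lists, structure kept as validated molfile source.
``Add``
    a creation request: no id (the server allocates ids), no child
    collections, structure as raw molfile text.
``Mod``
    an update request: every user-editable field optional; an absent field
    means "unchanged", an explicit null clears an optional field.
``Cli``
    the outgoing client view: links resolved to ``(id, display name)``
    pairs, the structure replaced by an SVG depiction, and sensitive
    fields (password hashes, molfile source) absent altogether.

The JSON encoding of each variant is the pydantic dump with stable field
names; ``encode``/``decode`` below are the single codec used by the wire
layer and the change log alike.
"""
from __future__ import annotations

import enum
import re
from typing import Any, Callable, Optional

from pydantic import BaseModel, ConfigDict, Field, field_serializer, field_validator

from . import chem
from .result import Result


class ValidationErr(Exception):
    """A rejected field value; carries a machine code and human detail."""

    def __init__(self, code: str, detail: str):
        super().__init__(f"{code}: {detail}")
        self.code = code
        self.detail = detail


class Role(str, enum.Enum):
    """User roles, totally ordered guest < common < superuser < admin."""

    GUEST = "guest"
    COMMON = "common"
    SUPERUSER = "superuser"
    ADMIN = "admin"

    @property
    def rank(self) -> int:
        return _ROLE_ORDER.index(self)

    def __lt__(self, other: "Role") -> bool:  # type: ignore[override]
        return self.rank < other.rank

    def __le__(self, other: "Role") -> bool:  # type: ignore[override]
        return self.rank <= other.rank


_ROLE_ORDER = [Role.GUEST, Role.COMMON, Role.SUPERUSER, Role.ADMIN]


# --------------------------------------------------------------------------
# CAS registry numbers
# --------------------------------------------------------------------------

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")


def cas_check_digit(digits: str) -> int:
    """Mod-10 positional checksum over the digits left of the check digit,
    weighted by position counted from the right."""
    return sum(int(d) * w for w, d in enumerate(reversed(digits), start=1)) % 10


def validate_cas(s: str) -> Result[str, ValidationErr]:
    """Accept a CAS number iff the D{2,7}-DD-D format and check digit hold."""
    m = _CAS_RE.match(s or "")
    if not m:
        return Result.err(ValidationErr("bad_format", f"not a CAS number: {s!r}"))
    body = m.group(1) + m.group(2)
    if cas_check_digit(body) != int(m.group(3)):
        return Result.err(
            ValidationErr(
                "bad_check_digit",
                f"{s!r}: expected check digit {cas_check_digit(body)}",
            )
        )
    return Result.ok(s)


# --------------------------------------------------------------------------
# Shared pieces
# --------------------------------------------------------------------------


class _Base(BaseModel):
    model_config = ConfigDict(extra="ignore", validate_assignment=True)


class EditMeta(_Base):
    """Timestamp (ms since epoch, UTC) and author of a mutation."""

    ts: int
    user: int


class LinkView(_Base):
    """A resolved link: target id plus its display name."""

    id: int
    name: str


def _check_cas(v: Optional[str]) -> Optional[str]:
    if v is None:
        return v
    res = validate_cas(v)
    if res.is_err:
        raise ValueError(str(res.error))
    return v


def _check_purity(v: Optional[float]) -> Optional[float]:
    if v is not None and not (0 < v <= 100):
        raise ValueError(f"purity must be in (0, 100], got {v}")
    return v


# --------------------------------------------------------------------------
# Compound
# --------------------------------------------------------------------------


class CompoundSrv(_Base):
    id: int
    name: str = Field(min_length=1)
    casNr: Optional[str] = None
    structure: Optional[str] = None  # validated molfile source
    project: int
    created: EditMeta
    containers: list[int] = Field(default_factory=list)
    files: list[int] = Field(default_factory=list)

    _cas = field_validator("casNr")(_check_cas)


class CompoundAdd(_Base):
    name: str = Field(min_length=1)
    casNr: Optional[str] = None
    structure: Optional[str] = None
    project: int

    _cas = field_validator("casNr")(_check_cas)


class CompoundMod(_Base):
    name: Optional[str] = Field(default=None, min_length=1)
    casNr: Optional[str] = None
    structure: Optional[str] = None
    project: Optional[int] = None

    _cas = field_validator("casNr")(_check_cas)


class FileRefCli(_Base):
    id: int
    name: str
    mime: str
    project: LinkView


class BiodataCli(_Base):
    id: int
    method: LinkView
    value: float
    unit: str
    project: LinkView
    files: list[FileRefCli] = Field(default_factory=list)


class ContainerCli(_Base):
    id: int
    batch: str
    location: LinkView
    supplier: LinkView
    amount: Optional[float] = None
    purity: Optional[float] = None
    project: LinkView
    biodata: list[BiodataCli] = Field(default_factory=list)
    files: list[FileRefCli] = Field(default_factory=list)


class CompoundCli(_Base):
    id: int
    name: str
    casNr: Optional[str] = None
    svg: Optional[str] = None  # replaces the molfile source
    project: LinkView
    created: EditMeta
    containers: list[ContainerCli] = Field(default_factory=list)
    files: list[FileRefCli] = Field(default_factory=list)


# --------------------------------------------------------------------------
# Container
# --------------------------------------------------------------------------


class ContainerSrv(_Base):
    id: int
    compound: int
    batch: str = ""
    location: int
    supplier: int
    amount: Optional[float] = None  # grams
    purity: Optional[float] = None  # percent, (0, 100]
    project: int
    created: EditMeta
    biodata: list[int] = Field(default_factory=list)
    files: list[int] = Field(default_factory=list)

    _purity = field_validator("purity")(_check_purity)


class ContainerAdd(_Base):
    compound: int
    batch: str = ""
    location: int
    supplier: int
    amount: Optional[float] = None
    purity: Optional[float] = None
    project: int

    _purity = field_validator("purity")(_check_purity)


class ContainerMod(_Base):
    batch: Optional[str] = None
    location: Optional[int] = None
    supplier: Optional[int] = None
    amount: Optional[float] = None
    purity: Optional[float] = None
    project: Optional[int] = None

    _purity = field_validator("purity")(_check_purity)


# --------------------------------------------------------------------------
# Biodata
# --------------------------------------------------------------------------


class BiodataSrv(_Base):
    id: int
    container: int
    method: int
    value: float
    unit: str = ""
    project: int
    created: EditMeta
    files: list[int] = Field(default_factory=list)


class BiodataAdd(_Base):
    container: int
    method: int
    value: float
    unit: str = ""
    project: int


class BiodataMod(_Base):
    method: Optional[int] = None
    value: Optional[float] = None
    unit: Optional[str] = None
    project: Optional[int] = None


# --------------------------------------------------------------------------
# Project / User / Supplier / Location / Method / FileRef
# --------------------------------------------------------------------------


class ProjectSrv(_Base):
    id: int
    name: str = Field(min_length=1)
    owner: int
    created: EditMeta


class ProjectAdd(_Base):
    name: str = Field(min_length=1)
    owner: int


class ProjectMod(_Base):
    name: Optional[str] = Field(default=None, min_length=1)
    owner: Optional[int] = None


class ProjectCli(_Base):
    id: int
    name: str
    owner: LinkView


class UserSrv(_Base):
    id: int
    alias: str = Field(min_length=1)
    password_hash: str
    role: Role = Role.COMMON
    projects: set[int] = Field(default_factory=set)
    created: EditMeta

    @field_serializer("projects")
    def _sorted_projects(self, v: set[int]) -> list[int]:
        return sorted(v)  # stable wire form regardless of set order


class UserAdd(_Base):
    alias: str = Field(min_length=1)
    password_hash: str
    role: Role = Role.COMMON
    projects: set[int] = Field(default_factory=set)

    @field_serializer("projects")
    def _sorted_projects(self, v: set[int]) -> list[int]:
        return sorted(v)


class UserMod(_Base):
    alias: Optional[str] = Field(default=None, min_length=1)
    password_hash: Optional[str] = None
    role: Optional[Role] = None
    projects: Optional[set[int]] = None

    @field_serializer("projects")
    def _sorted_projects(self, v: Optional[set[int]]) -> Optional[list[int]]:
        return None if v is None else sorted(v)


class UserCli(_Base):
    """Client view of a user account; the password hash never appears."""

    id: int
    alias: str
    role: Role
    projects: list[int] = Field(default_factory=list)


class _NamedSrv(_Base):
    id: int
    name: str = Field(min_length=1)
    created: EditMeta


class _NamedAdd(_Base):
    name: str = Field(min_length=1)


class _NamedMod(_Base):
    name: Optional[str] = Field(default=None, min_length=1)


class _NamedCli(_Base):
    id: int
    name: str


class SupplierSrv(_NamedSrv):
    pass


class SupplierAdd(_NamedAdd):
    pass


class SupplierMod(_NamedMod):
    pass


class SupplierCli(_NamedCli):
    pass


class LocationSrv(_NamedSrv):
    pass


class LocationAdd(_NamedAdd):
    pass


class LocationMod(_NamedMod):
    pass


class LocationCli(_NamedCli):
    pass


class MethodSrv(_NamedSrv):
    pass


class MethodAdd(_NamedAdd):
    pass


class MethodMod(_NamedMod):
    pass


class MethodCli(_NamedCli):
    pass


class FileRefSrv(_Base):
    id: int
    name: str = Field(min_length=1)
    mime: str = "application/octet-stream"
    blob_id: str
    parent_family: str
    parent_id: int
    project: int
    created: EditMeta


class FileRefAdd(_Base):
    name: str = Field(min_length=1)
    mime: str = "application/octet-stream"
    blob_id: str
    parent_family: str
    parent_id: int
    project: int


class FileRefMod(_Base):
    name: Optional[str] = Field(default=None, min_length=1)
    mime: Optional[str] = None
    project: Optional[int] = None


# --------------------------------------------------------------------------
# Family registry
# --------------------------------------------------------------------------

FAMILIES: dict[str, dict[str, type[BaseModel] | None]] = {
    "compound": {"srv": CompoundSrv, "add": CompoundAdd, "mod": CompoundMod, "cli": CompoundCli},
    "container": {"srv": ContainerSrv, "add": ContainerAdd, "mod": ContainerMod, "cli": ContainerCli},
    "biodata": {"srv": BiodataSrv, "add": BiodataAdd, "mod": BiodataMod, "cli": BiodataCli},
    "project": {"srv": ProjectSrv, "add": ProjectAdd, "mod": ProjectMod, "cli": ProjectCli},
    "user": {"srv": UserSrv, "add": UserAdd, "mod": UserMod, "cli": UserCli},
    "supplier": {"srv": SupplierSrv, "add": SupplierAdd, "mod": SupplierMod, "cli": SupplierCli},
    "location": {"srv": LocationSrv, "add": LocationAdd, "mod": LocationMod, "cli": LocationCli},
    "method": {"srv": MethodSrv, "add": MethodAdd, "mod": MethodMod, "cli": MethodCli},
    "file": {"srv": FileRefSrv, "add": FileRefAdd, "mod": FileRefMod, "cli": FileRefCli},
}

#: families whose records carry a project link and are therefore subject
#: to project-scoped visibility filtering
PROJECT_SCOPED = ("compound", "container", "biodata", "file")

#: (child family, parent family, parent-link field, child-list field on parent)
CHILD_LINKS = (
    ("container", "compound", "compound", "containers"),
    ("biodata", "container", "container", "biodata"),
)

#: fields a client is never allowed to dictate or receive raw
SENSITIVE_FIELDS = ("password_hash", "structure", "blob_id")


def encode(entity: BaseModel, *, variant: str = "srv") -> dict[str, Any]:
    """JSON-ready dict for any variant; Mod dumps only the fields that
    were explicitly set (absent = unchanged)."""
    if variant == "mod":
        return entity.model_dump(mode="json", exclude_unset=True)
    return entity.model_dump(mode="json")


def decode(family: str, variant: str, raw: dict[str, Any]) -> BaseModel:
    """Inverse of :func:`encode`; raises pydantic ``ValidationError`` on
    missing mandatory fields (see ``store.decode_with_defaults`` for the
    schema-tolerant wrapper)."""
    cls = FAMILIES[family][variant]
    if cls is None:
        raise KeyError(f"{family} has no {variant} variant")
    return cls.model_validate(raw)


# --------------------------------------------------------------------------
# Creation and merge semantics
# --------------------------------------------------------------------------

ParseFn = Callable[[str], Result[chem.Molecule, chem.ChemErr]]


def mk_srv(
    family: str,
    next_id: int,
    add: BaseModel,
    meta: EditMeta,
    parse: ParseFn = chem.parse_molfile,
) -> Result[BaseModel, ValidationErr]:
    """Build a stored record from a creation request.

    The server owns id allocation: ``next_id`` comes from the store, never
    from the client. Child collections start empty. A compound structure
    is accepted only if ``parse`` succeeds on the molfile text; the
    validated source text is what gets stored.
    """
    data = add.model_dump()
    structure = data.get("structure")
    if family == "compound" and structure is not None:
        parsed = parse(structure)
        if parsed.is_err:
            err = parsed.error
            return Result.err(ValidationErr(err.code.value, err.detail))
    data["id"] = next_id
    data["created"] = meta.model_dump()
    try:
        srv = FAMILIES[family]["srv"].model_validate(data)  # type: ignore[union-attr]
    except Exception as exc:
        return Result.err(ValidationErr("invalid_field", str(exc)))
    return Result.ok(srv)


ResolveFn = Callable[[str, int], str]


def to_cli(
    e: BaseModel,
    family: str,
    proof: Any,
    resolve: ResolveFn,
    *,
    svg: Optional[str] = None,
    containers: list[ContainerCli] | None = None,
    biodata: list[BiodataCli] | None = None,
    files: list[FileRefCli] | None = None,
) -> BaseModel:
    """Build the outgoing client view of a stored record.

    For project-scoped families this is callable only with an access proof
    matching the record's project — the proof is constructed exclusively by
    ``auth.has_access``, so a Cli view existing at all certifies that the
    authorization check ran. Link fields are resolved to (id, name) pairs
    via ``resolve``; sensitive fields (molfile source, password hash,
    blob id) never appear in the output.
    """
    if family in PROJECT_SCOPED:
        if proof is None or getattr(proof, "project", None) != getattr(e, "project"):
            raise PermissionError(
                f"no access proof for project {getattr(e, 'project', None)} ({family} {getattr(e, 'id', '?')})"
            )

    def link(fam: str, ident: int) -> LinkView:
        return LinkView(id=ident, name=resolve(fam, ident))

    if family == "compound":
        c: CompoundSrv = e  # type: ignore[assignment]
        return CompoundCli(
            id=c.id, name=c.name, casNr=c.casNr, svg=svg,
            project=link("project", c.project), created=c.created,
            containers=containers or [], files=files or [],
        )
    if family == "container":
        k: ContainerSrv = e  # type: ignore[assignment]
        return ContainerCli(
            id=k.id, batch=k.batch, location=link("location", k.location),
            supplier=link("supplier", k.supplier), amount=k.amount,
            purity=k.purity, project=link("project", k.project),
            biodata=biodata or [], files=files or [],
        )
    if family == "biodata":
        b: BiodataSrv = e  # type: ignore[assignment]
        return BiodataCli(
            id=b.id, method=link("method", b.method), value=b.value,
            unit=b.unit, project=link("project", b.project), files=files or [],
        )
    if family == "file":
        f: FileRefSrv = e  # type: ignore[assignment]
        return FileRefCli(id=f.id, name=f.name, mime=f.mime, project=link("project", f.project))
    if family == "project":
        p: ProjectSrv = e  # type: ignore[assignment]
        return ProjectCli(id=p.id, name=p.name, owner=link("user", p.owner))
    if family == "user":
        u: UserSrv = e  # type: ignore[assignment]
        return UserCli(id=u.id, alias=u.alias, role=u.role, projects=sorted(u.projects))
    if family in ("supplier", "location", "method"):
        return FAMILIES[family]["cli"](id=e.id, name=e.name)  # type: ignore[union-attr, attr-defined]
    raise KeyError(f"unknown family {family!r}")


def apply_mod(
    cur: BaseModel,
    mod: BaseModel,
    family: str,
    parse: ParseFn = chem.parse_molfile,
) -> Result[BaseModel, ValidationErr]:
    """Merge an update request into a stored record, atomically.

    Only fields explicitly present in the request are touched; the id is
    immutable. Any present-but-invalid field rejects the whole request and
    leaves the record untouched.
    """
    changes = mod.model_dump(exclude_unset=True)
    if not changes:
        return Result.ok(cur)
    if "structure" in changes and changes["structure"] is not None:
        parsed = parse(changes["structure"])
        if parsed.is_err:
            err = parsed.error
            return Result.err(ValidationErr(err.code.value, err.detail))
    merged = {**cur.model_dump(), **changes}
    merged["id"] = getattr(cur, "id")
    try:
        new = type(cur).model_validate(merged)
    except Exception as exc:
        return Result.err(ValidationErr("invalid_field", str(exc)))
    return Result.ok(new)
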