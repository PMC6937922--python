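"""Authentication, roles, and project-scoped visibility.

The central object is :class:`AccessProof`: a tiny token whose existence
certifies that :func:`has_access` checked a user against a project before
any data left the server. Client views can only be built from a proof
(``model.to_cli`` demands one), so the authorization check cannot be
forgotten on any code path — the Scala original enforces this at compile
time with a private constructor; here the constructor is module-private
and the invariant is additionally property-tested.

Visibility is per node, not per subtree root: a user who may see a
compound but not one of its containers gets the compound with that
container stripped.
"""
from __future__ import annotations

import hashlib
import hmac
import os
import secrets
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .model import Role, UserSrv, PROJECT_SCOPED
from .result import Result
from .store import DataTree, Node

_KDF_ITERATIONS = 60_000


class AuthErr(Exception):
    """Single failure shape for login: unknown alias and wrong password are
    deliberately indistinguishable (no user enumeration)."""

    def __init__(self) -> None:
        super().__init__("invalid credentials")


@dataclass(frozen=True)
class Credentials:
    alias: str
    password: str = field(repr=False)  # never logged, never serialized


@dataclass(frozen=True)
class AccessProof:
    """Evidence that access to ``project`` was granted.

    Do not construct directly — :func:`has_access` is the only sanctioned
    constructor; everything downstream (client views, exports) demands a
    proof rather than re-checking project membership.
    """

    project: int


def hash_password(
    password: str, *, iterations: int = _KDF_ITERATIONS, salt: Optional[bytes] = None
) -> str:
    """Salted PBKDF2-HMAC-SHA256, encoded ``pbkdf2$iters$salt$hash``.

    ``salt`` defaults to 16 random bytes; passing one explicitly is for
    deterministic fixture generation only.
    """
    if salt is None:
        salt = secrets.token_bytes(16)
    digest = hashlib.pbkdf2_hmac("sha256", password.encode("utf-8"), salt, iterations)
    return f"pbkdf2${iterations}${salt.hex()}${digest.hex()}"


def verify_password(password: str, stored: str) -> bool:
    try:
        scheme, iters, salt_hex, digest_hex = stored.split("$")
        if scheme != "pbkdf2":
            return False
        digest = hashlib.pbkdf2_hmac(
            "sha256", password.encode("utf-8"), bytes.fromhex(salt_hex), int(iters)
        )
        return hmac.compare_digest(digest.hex(), digest_hex)
    except (ValueError, AttributeError):
        return False


# a syntactically valid hash verified against when the alias is unknown, so
# the two failure modes take comparable time
_DUMMY_HASH = hash_password("*")


def authenticate(c: Credentials, users: Iterable[UserSrv]) -> Result[UserSrv, AuthErr]:
    """Look up the alias and verify the password against the stored KDF
    hash; both failure modes yield the identical :class:`AuthErr`."""
    found = next((u for u in users if u.alias == c.alias), None)
    if found is None:
        verify_password(c.password, _DUMMY_HASH)
        return Result.err(AuthErr())
    if not verify_password(c.password, found.password_hash):
        return Result.err(AuthErr())
    return Result.ok(found)


def has_access(u: UserSrv, project: int) -> Optional[AccessProof]:
    """The sole constructor of :class:`AccessProof`.

    A proof exists iff the project is in the user's grant set, or the user
    is an administrator (admins review all changes, hence see everything).
    Absence of access is the ``None`` result, not an error.
    """
    if u.role is Role.ADMIN or project in u.projects:
        return AccessProof(project=project)
    return None


def visible_subtree(u: UserSrv, tree: DataTree) -> DataTree:
    """Strip every node linked to a project the user holds no proof for.

    Project-scoped families are filtered per node; the projects family
    itself is reduced to the accessible ones (dropdowns must only offer
    valid options); global families (suppliers, locations, methods, users)
    pass through. Child-id collections are pruned to surviving children.
    """
    if u.role is Role.ADMIN:
        return tree

    def ok(project: int) -> bool:
        return has_access(u, project) is not None

    fams = dict(tree.families)
    kept: dict[str, dict[int, Node]] = {}
    for family in PROJECT_SCOPED:
        kept[family] = {
            i: n for i, n in fams[family].items() if ok(n.entity.project)  # type: ignore[attr-defined]
        }
        fams[family] = kept[family]
    fams["project"] = {i: n for i, n in fams["project"].items() if ok(i)}

    # prune dangling child ids (accessible parent, stripped child)
    def prune(family: str, coll: str, child_family: str) -> None:
        out: dict[int, Node] = {}
        for i, n in fams[family].items():
            ids = [c for c in getattr(n.entity, coll) if c in kept[child_family]]
            if len(ids) != len(getattr(n.entity, coll)):
                n = replace(n, entity=n.entity.model_copy(update={coll: ids}))
            out[i] = n
        fams[family] = out

    prune("compound", "containers", "container")
    prune("compound", "files", "file")
    prune("container", "biodata", "biodata")
    prune("container", "files", "file")
    prune("biodata", "files", "file")
    return DataTree(families=fams)


#: families only administrators may touch
_ADMIN_FAMILIES = ("user", "project")


def can_edit(u: UserSrv, project: Optional[int], family: str, op: str) -> bool:
    """Server-side edit permission (the client's edit master switch is
    advisory only; this check always runs).

    Guests never write. User and project administration is admin-only.
    Common users and superusers may mutate entities in projects they hold
    a proof for. Admins may do anything.
    """
    if u.role is Role.GUEST:
        return False
    if u.role is Role.ADMIN:
        return True
    if family in _ADMIN_FAMILIES:
        return False
    if project is None:
        # global families (supplier, location, method) are shared
        # infrastructure any writer may extend
        return family in ("supplier", "location", "method")
    return has_access(u, project) is not None
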