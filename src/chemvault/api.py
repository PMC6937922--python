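"""Request handling: pure handlers, serialized mutations, one error channel.

The read path is a pure function :func:`handle` over an immutable
:class:`Env` (parsed request + data-tree snapshot + authenticated user)
and an opaque query state :class:`QSt`: identical inputs give identical
outputs, and the caller decides what to do with the returned state. Every
failure on any path is a :class:`DataErr` — serialized to the client and
written to the log, never an unhandled exception.

Mutations go through :meth:`Server.mutate`: validate, append to the
change log, advance the in-memory tree — atomically under a single writer
lock. The tree is persistent (copy on write), so any number of readers
can keep querying their snapshot while a writer advances the head; a
concurrent reader sees either the pre- or the post-state, never a torn
one.

Transport is deliberately thin: :class:`Request`/:class:`Response` are
plain values, so the whole surface is exercisable in-process. Routes:

    POST  /login                       -> {token, user}
    POST  /query                       -> page of compound client views
    GET   /{family}/{id}               -> client view
    GET   /{family}/{id}/history       -> change records
    POST  /{family}                    -> create (server assigns the id)
    PATCH /{family}/{id}               -> partial update
    DELETE /{family}/{id}              -> soft delete
    POST  /export                      -> SDF / tab-delimited text
    PUT   /file                        -> upload blob + file entity
    GET   /file/{id}/content           -> blob bytes (base64)
    GET/PUT /settings                  -> per-user settings
"""
from __future__ import annotations

import base64
import binascii
import enum
import json
import logging
import secrets
import threading
import time
from dataclasses import dataclass, field
from typing import Any, Optional

from . import auth, export, model, query, store
from .result import Result

log = logging.getLogger("chemvault.api")

MUTATION_RETRIES = 16
SESSION_TTL_S = 8 * 3600


class ErrCode(str, enum.Enum):
    UNAUTHORIZED = "unauthorized"
    NOT_FOUND = "not_found"
    VALIDATION = "validation"
    PARSE = "parse"
    QUERY = "query"
    CONFLICT = "conflict"
    INTERNAL = "internal"


_STATUS = {
    ErrCode.UNAUTHORIZED: 403,
    ErrCode.NOT_FOUND: 404,
    ErrCode.VALIDATION: 422,
    ErrCode.PARSE: 400,
    ErrCode.QUERY: 400,
    ErrCode.CONFLICT: 409,
    ErrCode.INTERNAL: 500,
}


@dataclass(frozen=True)
class DataErr:
    code: ErrCode
    detail: Any

    def to_json(self) -> dict:
        return {"code": self.code.value, "detail": self.detail}


@dataclass(frozen=True)
class Request:
    method: str
    path: str
    body: Any = None
    params: dict[str, str] = field(default_factory=dict)
    token: Optional[str] = None


@dataclass(frozen=True)
class Response:
    status: int
    body: Any

    @property
    def ok(self) -> bool:
        return 200 <= self.status < 300

    def to_bytes(self) -> bytes:
        return json.dumps(self.body, ensure_ascii=False, sort_keys=True).encode("utf-8")


@dataclass(frozen=True)
class Env:
    """Everything a read handler may look at, frozen for the call."""

    request: Request
    tree: store.DataTree
    user: model.UserSrv


@dataclass(frozen=True)
class QSt:
    """Opaque per-server query state. Reserved for caching query results;
    handlers return it (possibly replaced), the caller owns its fate."""

    version: int = 0
    cache: Any = None


@dataclass(frozen=True)
class HandlerResult:
    logs: tuple[str, ...]
    errors: tuple[DataErr, ...]  # nonempty means failure
    response: Any = None
    state: Optional[QSt] = None


def _fail(code: ErrCode, detail: Any, *logs: str) -> HandlerResult:
    return HandlerResult(logs=tuple(logs) + (f"{code.value}: {detail}",), errors=(DataErr(code, detail),))


def _ok(response: Any, st: QSt, *logs: str) -> HandlerResult:
    return HandlerResult(logs=tuple(logs), errors=(), response=response, state=st)


def _map_query_err(e: query.QueryErr) -> DataErr:
    code = ErrCode.NOT_FOUND if e.code == "unknown_field" else ErrCode.QUERY
    return DataErr(code, f"{e.code}: {e.detail}")


def _parse_query_body(body: Any):
    if body is None:
        return None, None, None
    if not isinstance(body, dict):
        raise query.QueryErr("bad_predicate", "query body must be an object")
    q = None
    if "quick" in body:
        parsed = query.parse_quick(body["quick"])
        if parsed.is_err:
            raise parsed.error
        q = parsed.value
    elif "tree" in body:
        q = query.tree_from_json(body["tree"])
    sort = None
    if body.get("sort"):
        sort = query.SortSpec(
            field=body["sort"]["field"], ascending=bool(body["sort"].get("ascending", True))
        )
    paging = None
    if body.get("paging"):
        paging = query.Paging(
            offset=int(body["paging"].get("offset", 0)),
            limit=int(body["paging"].get("limit", query.DEFAULT_PAGE_LIMIT)),
        )
    return q, sort, paging


# --------------------------------------------------------------------------
# Pure read handlers
# --------------------------------------------------------------------------


def handle(env: Env, st: QSt) -> HandlerResult:
    """Dispatch a read-only request. Pure: no global mutation, identical
    (env, state) pairs produce identical results."""
    try:
        return _handle(env, st)
    except Exception as exc:  # total: every failure is a DataErr
        return _fail(ErrCode.INTERNAL, f"{type(exc).__name__}: {exc}")


def _handle(env: Env, st: QSt) -> HandlerResult:
    req = env.request
    parts = [p for p in req.path.split("/") if p]

    if req.method == "POST" and parts == ["query"]:
        return _handle_query(env, st)
    if req.method == "POST" and parts == ["export"]:
        return _handle_export(env, st)
    if req.method == "GET" and len(parts) == 3 and parts[0] == "file" and parts[2] == "content":
        return _fail(ErrCode.INTERNAL, "file content is served by the Server, not the pure handler")
    if req.method == "GET" and parts == ["settings"]:
        return _fail(ErrCode.INTERNAL, "settings are served by the Server, not the pure handler")
    if req.method == "GET" and len(parts) == 2 and parts[0] in model.FAMILIES:
        return _handle_get_entity(env, st, parts[0], parts[1])
    if req.method == "GET" and len(parts) == 3 and parts[2] == "history" and parts[0] in model.FAMILIES:
        return _fail(ErrCode.INTERNAL, "history needs the log; served by the Server")
    return _fail(ErrCode.NOT_FOUND, f"no route {req.method} {req.path}")


def _handle_query(env: Env, st: QSt) -> HandlerResult:
    try:
        q, sort, paging = _parse_query_body(env.request.body)
    except query.QueryErr as exc:
        return HandlerResult(logs=(str(exc),), errors=(_map_query_err(exc),))
    res = query.run_query(env.tree, env.user, q, sort, paging)
    if res.is_err:
        return HandlerResult(logs=(str(res.error),), errors=(_map_query_err(res.error),))
    page = res.value
    body = {
        "items": [model.encode(c) for c in page.items],
        "total": page.total,
        "offset": page.offset,
        "limit": page.limit,
    }
    return _ok(body, st, f"query: {page.total} hits for user {env.user.id}")


def _handle_export(env: Env, st: QSt) -> HandlerResult:
    body = env.request.body or {}
    if not isinstance(body, dict) or "spec" not in body:
        return _fail(ErrCode.VALIDATION, "export body needs a 'spec' object")
    try:
        spec = export.ExportSpec(
            fields=body["spec"].get("fields", []), format=body["spec"].get("format", "csv")
        )
    except export.ExportErr as exc:
        return _fail(ErrCode.VALIDATION, str(exc))
    except Exception as exc:
        cause = getattr(exc, "__cause__", None)
        return _fail(ErrCode.VALIDATION, str(cause or exc))
    try:
        q, _, _ = _parse_query_body(body.get("query"))
    except query.QueryErr as exc:
        return HandlerResult(logs=(str(exc),), errors=(_map_query_err(exc),))
    hits = query.query_hits(env.tree, env.user, q)
    if hits.is_err:
        return HandlerResult(logs=(str(hits.error),), errors=(_map_query_err(hits.error),))
    visible = auth.visible_subtree(env.user, env.tree)
    if spec.format == "sdf":
        text = export.write_sdf(hits.value, visible, spec)
        if text.is_err:
            return _fail(ErrCode.VALIDATION, str(text.error))
        content = text.value
    else:
        rows = export.build_rows(hits.value, visible, spec)
        if rows.is_err:
            return _fail(ErrCode.VALIDATION, str(rows.error))
        content = export.write_csv(rows.value, spec)
    return _ok({"format": spec.format, "content": content}, st, f"export: {len(hits.value)} hits")


def _handle_get_entity(env: Env, st: QSt, family: str, raw_id: str) -> HandlerResult:
    try:
        ident = int(raw_id)
    except ValueError:
        return _fail(ErrCode.PARSE, f"bad id {raw_id!r}")
    visible = auth.visible_subtree(env.user, env.tree)
    entity = visible.entity(family, ident)
    if entity is None:
        # inaccessible and nonexistent are indistinguishable on purpose
        return _fail(ErrCode.NOT_FOUND, f"{family} {ident}")
    if family == "user" and env.user.role is not model.Role.ADMIN and env.user.id != ident:
        return _fail(ErrCode.UNAUTHORIZED, "user records are admin-only")
    if family == "compound":
        cli = query.compound_to_cli(entity, visible, env.user)  # type: ignore[arg-type]
    else:
        proof = None
        if family in model.PROJECT_SCOPED:
            proof = auth.has_access(env.user, entity.project)  # type: ignore[attr-defined]
        cli = model.to_cli(entity, family, proof, query.make_resolver(visible))
    return _ok(model.encode(cli), st)


# --------------------------------------------------------------------------
# The server: sessions, routing, serialized mutations
# --------------------------------------------------------------------------


class Server:
    """In-process application server over one change log.

    Readers take the current tree snapshot without locking (the tree is
    immutable); all mutations serialize through one lock, mirroring the
    binary-semaphore discipline of the original design.
    """

    def __init__(
        self,
        log_path: Optional[str] = None,
        blob_path: str = ":memory:",
        settings_path: str = ":memory:",
    ):
        self.log = store.ChangeLog(log_path)
        replayed = store.replay(self.log.records)
        if replayed.is_err:
            raise replayed.error
        self.tree: store.DataTree = replayed.value
        self.blobs = store.BlobStore(blob_path)
        self.settings = store.SettingsStore(settings_path)
        self.state = QSt()
        self._write_lock = threading.Lock()
        self._sessions: dict[str, tuple[int, float]] = {}

    @classmethod
    def from_records(cls, records: list[store.ChangeRecord], **kwargs) -> "Server":
        """A server over an in-memory log seeded with existing records."""
        srv = cls(**kwargs)
        srv.log.records = list(records)
        replayed = store.replay(srv.log.records)
        if replayed.is_err:
            raise replayed.error
        srv.tree = replayed.value
        return srv

    # -- bootstrap ---------------------------------------------------------

    def bootstrap_admin(self, alias: str, password: str) -> model.UserSrv:
        """Create the first (admin) account on an empty dataset."""
        if any(True for _ in self.tree.alive("user")):
            raise store.StoreErr("conflict", "dataset already has users")
        add = model.UserAdd(
            alias=alias, password_hash=auth.hash_password(password), role=model.Role.ADMIN
        )
        meta = model.EditMeta(ts=int(time.time() * 1000), user=0)
        res = self._commit("user", "add", None, add.model_dump(mode="json"), meta)
        if res.is_err:
            raise res.error
        return self.tree.entity("user", res.value)  # type: ignore[return-value]

    # -- sessions ----------------------------------------------------------

    def login(self, alias: str, password: str) -> Optional[str]:
        res = auth.authenticate(
            auth.Credentials(alias=alias, password=password), self.tree.alive("user")
        )
        if res.is_err:
            return None
        token = secrets.token_hex(16)
        self._sessions[token] = (res.value.id, time.time() + SESSION_TTL_S)
        return token

    def _user_for(self, token: Optional[str]) -> Optional[model.UserSrv]:
        if token is None or token not in self._sessions:
            return None
        uid, expiry = self._sessions[token]
        if expiry < time.time():
            del self._sessions[token]
            return None
        return self.tree.entity("user", uid)  # type: ignore[return-value]

    # -- mutation (single writer) ------------------------------------------

    def _commit(
        self,
        family: str,
        op: str,
        ident: Optional[int],
        payload: dict,
        meta: model.EditMeta,
    ) -> Result[int, store.StoreErr]:
        """Append one validated change and advance the tree, atomically.

        Sequence races with a concurrent writer are retried a bounded
        number of times; validation failures leave log and tree untouched.
        """
        for _ in range(MUTATION_RETRIES):
            with self._write_lock:
                seq = self.log.last_seq + 1
                assigned = ident if ident is not None else self.tree.next_id(family)
                rec = store.ChangeRecord(
                    seq=seq, ts=meta.ts, user=meta.user,
                    family=family, id=assigned, op=op, payload=payload,
                )
                applied = store.apply_record(self.tree, rec)
                if applied.is_err:
                    return Result.err(applied.error)
                appended = self.log.append(rec)
                if appended.is_err and appended.error.code == "seq_conflict":
                    continue  # lost a race against an external appender
                if appended.is_err:
                    return Result.err(appended.error)
                self.tree = applied.value  # atomic reference swap
                return Result.ok(assigned)
        return Result.err(store.StoreErr("conflict", "sequence race retry budget exhausted"))

    def mutate(
        self, user: model.UserSrv, family: str, op: str, ident: Optional[int], payload: dict
    ) -> Result[dict, DataErr]:
        """Permission-checked mutation; returns the client view of the
        touched entity (or a deletion receipt)."""
        if family not in model.FAMILIES:
            return Result.err(DataErr(ErrCode.NOT_FOUND, f"unknown family {family!r}"))
        if op == "add" and "id" in payload:
            # the server owns id allocation; a forged id is rejected, not honored
            return Result.err(DataErr(ErrCode.VALIDATION, "ids are assigned by the server"))

        project: Optional[int] = None
        if op == "add":
            project = payload.get("project") if family in model.PROJECT_SCOPED else None
        else:
            if ident is None:
                return Result.err(DataErr(ErrCode.PARSE, "missing entity id"))
            visible = auth.visible_subtree(user, self.tree)
            existing = visible.entity(family, ident)
            if existing is None:
                return Result.err(DataErr(ErrCode.NOT_FOUND, f"{family} {ident}"))
            project = getattr(existing, "project", None)

        if not auth.can_edit(user, project, family, op):
            return Result.err(DataErr(ErrCode.UNAUTHORIZED, f"{user.alias} may not {op} {family}"))
        if op == "add" and family in model.PROJECT_SCOPED:
            if project is None or auth.has_access(user, project) is None:
                return Result.err(DataErr(ErrCode.UNAUTHORIZED, f"no access to project {project}"))

        meta = model.EditMeta(ts=int(time.time() * 1000), user=user.id)
        committed = self._commit(family, op, ident if op != "add" else None, payload, meta)
        if committed.is_err:
            e = committed.error
            code = {
                "validation": ErrCode.VALIDATION,
                "missing_ref": ErrCode.VALIDATION,
                "not_found": ErrCode.NOT_FOUND,
                "conflict": ErrCode.CONFLICT,
            }.get(e.code, ErrCode.INTERNAL)
            return Result.err(DataErr(code, e.detail))
        assigned = committed.value
        if op == "del":
            return Result.ok({"deleted": {"family": family, "id": assigned}})
        snapshot = self.tree
        entity = snapshot.entity(family, assigned)
        visible = auth.visible_subtree(user, snapshot)
        if family == "compound":
            cli = query.compound_to_cli(entity, visible, user)  # type: ignore[arg-type]
        else:
            proof = None
            if family in model.PROJECT_SCOPED:
                proof = auth.has_access(user, entity.project)  # type: ignore[attr-defined]
            cli = model.to_cli(entity, family, proof, query.make_resolver(visible))
        return Result.ok(model.encode(cli))

    # -- dispatch ----------------------------------------------------------

    def request(
        self,
        method: str,
        path: str,
        body: Any = None,
        *,
        raw_body: Optional[str] = None,
        token: Optional[str] = None,
        params: Optional[dict[str, str]] = None,
    ) -> Response:
        """Single entry point; never raises, never returns a stack trace."""
        try:
            if raw_body is not None:
                try:
                    body = json.loads(raw_body)
                except (json.JSONDecodeError, UnicodeDecodeError) as exc:
                    return _err_response(DataErr(ErrCode.PARSE, f"malformed JSON body: {exc}"))
            req = Request(method=method.upper(), path=path, body=body,
                          params=params or {}, token=token)
            return self._dispatch(req)
        except Exception as exc:  # pragma: no cover - belt and braces
            log.exception("internal error")
            return _err_response(DataErr(ErrCode.INTERNAL, f"{type(exc).__name__}: {exc}"))

    def _dispatch(self, req: Request) -> Response:
        parts = [p for p in req.path.split("/") if p]

        if req.method == "POST" and parts == ["login"]:
            body = req.body if isinstance(req.body, dict) else {}
            alias, password = body.get("alias"), body.get("password")
            if not isinstance(alias, str) or not isinstance(password, str):
                return _err_response(DataErr(ErrCode.PARSE, "login needs alias and password"))
            token = self.login(alias, password)
            if token is None:
                return _err_response(DataErr(ErrCode.UNAUTHORIZED, "invalid credentials"))
            return Response(200, {"token": token})

        user = self._user_for(req.token)
        if user is None:
            return _err_response(DataErr(ErrCode.UNAUTHORIZED, "missing or expired session"))

        # impure routes (log, side stores, mutations) handled here;
        # read-only routes delegate to the pure handler
        if req.method == "GET" and parts == ["settings"]:
            return Response(200, {"settings": self.settings.get(user.id) or {}})
        if req.method == "PUT" and parts == ["settings"]:
            if not isinstance(req.body, dict):
                return _err_response(DataErr(ErrCode.PARSE, "settings body must be an object"))
            self.settings.put(user.id, req.body)
            return Response(200, {"settings": req.body})
        if req.method == "GET" and len(parts) == 3 and parts[2] == "history":
            return self._serve_history(user, parts[0], parts[1])
        if req.method == "GET" and len(parts) == 3 and parts[0] == "file" and parts[2] == "content":
            return self._serve_file(user, parts[1])
        if req.method == "PUT" and parts == ["file"]:
            return self._upload_file(user, req.body)
        if req.method == "POST" and len(parts) == 1 and parts[0] in model.FAMILIES:
            body = req.body if isinstance(req.body, dict) else None
            if body is None:
                return _err_response(DataErr(ErrCode.PARSE, "creation body must be an object"))
            return _result_response(self.mutate(user, parts[0], "add", None, body))
        if req.method == "PATCH" and len(parts) == 2 and parts[0] in model.FAMILIES:
            body = req.body if isinstance(req.body, dict) else None
            if body is None:
                return _err_response(DataErr(ErrCode.PARSE, "update body must be an object"))
            ident = _int_or_none(parts[1])
            if ident is None:
                return _err_response(DataErr(ErrCode.PARSE, f"bad id {parts[1]!r}"))
            return _result_response(self.mutate(user, parts[0], "mod", ident, body))
        if req.method == "DELETE" and len(parts) == 2 and parts[0] in model.FAMILIES:
            ident = _int_or_none(parts[1])
            if ident is None:
                return _err_response(DataErr(ErrCode.PARSE, f"bad id {parts[1]!r}"))
            return _result_response(self.mutate(user, parts[0], "del", ident, {}))

        env = Env(request=req, tree=self.tree, user=user)
        result = handle(env, self.state)
        for line in result.logs:
            log.info("%s", line)
        if result.errors:
            return _err_response(*result.errors)
        if result.state is not None:
            self.state = result.state
        return Response(200, result.response)

    # -- impure reads ------------------------------------------------------

    def _serve_history(self, user: model.UserSrv, family: str, raw_id: str) -> Response:
        ident = _int_or_none(raw_id)
        if family not in model.FAMILIES or ident is None:
            return _err_response(DataErr(ErrCode.NOT_FOUND, f"{family}/{raw_id}"))
        node = self.tree.node(family, ident)
        if node is None:
            return _err_response(DataErr(ErrCode.NOT_FOUND, f"{family} {ident} was never created"))
        if family in model.PROJECT_SCOPED and user.role is not model.Role.ADMIN:
            if auth.has_access(user, node.entity.project) is None:  # type: ignore[attr-defined]
                # indistinguishable from a nonexistent entity
                return _err_response(DataErr(ErrCode.NOT_FOUND, f"{family} {ident} was never created"))
        if family == "user" and user.role is not model.Role.ADMIN and user.id != ident:
            return _err_response(DataErr(ErrCode.NOT_FOUND, f"{family} {ident} was never created"))
        recs = store.history(self.log.records, self.tree, family, ident)
        if recs.is_err:
            return _err_response(DataErr(ErrCode.NOT_FOUND, recs.error.detail))
        dumped = []
        for r in recs.value:
            d = r.model_dump(mode="json")
            if "password_hash" in d.get("payload", {}):
                d["payload"]["password_hash"] = "<redacted>"  # never serve KDF hashes
            dumped.append(d)
        return Response(200, {"history": dumped, "deleted": node.deleted})

    def _serve_file(self, user: model.UserSrv, raw_id: str) -> Response:
        ident = _int_or_none(raw_id)
        visible = auth.visible_subtree(user, self.tree)
        entity = visible.entity("file", ident) if ident is not None else None
        if entity is None:
            return _err_response(DataErr(ErrCode.NOT_FOUND, f"file {raw_id}"))
        blob = self.blobs.get(entity.blob_id)  # type: ignore[attr-defined]
        if blob is None:
            return _err_response(DataErr(ErrCode.NOT_FOUND, f"blob for file {ident}"))
        data, name, mime = blob
        return Response(
            200, {"name": name, "mime": mime, "data": base64.b64encode(data).decode("ascii")}
        )

    def _upload_file(self, user: model.UserSrv, body: Any) -> Response:
        if not isinstance(body, dict):
            return _err_response(DataErr(ErrCode.PARSE, "file upload body must be an object"))
        try:
            data = base64.b64decode(body.get("data", ""), validate=True)
        except (binascii.Error, ValueError) as exc:
            return _err_response(DataErr(ErrCode.PARSE, f"bad base64 payload: {exc}"))
        name = body.get("name", "")
        mime = body.get("mime", "application/octet-stream")
        blob_id = self.blobs.put(data, name=name, mime=mime)
        payload = {
            "name": name, "mime": mime, "blob_id": blob_id,
            "parent_family": body.get("parent_family"),
            "parent_id": body.get("parent_id"),
            "project": body.get("project"),
        }
        return _result_response(self.mutate(user, "file", "add", None, payload))


def _int_or_none(raw: str) -> Optional[int]:
    try:
        return int(raw)
    except (TypeError, ValueError):
        return None


def _err_response(*errors: DataErr) -> Response:
    for e in errors:
        log.warning("request failed: %s: %s", e.code.value, e.detail)
    status = max(_STATUS[e.code] for e in errors)
    return Response(status, {"errors": [e.to_json() for e in errors]})


def _result_response(res: Result) -> Response:
    if res.is_err:
        return _err_response(res.error)
    return Response(200, res.value)
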