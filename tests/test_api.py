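"""HTTP-shaped handler layer: purity, error totality, serialized writes."""
import base64
import json
import threading

import pytest

from chemvault import api, auth, fixtures, store
from chemvault.api import Env, QSt, Request, Server, handle

from conftest import login, molblock


@pytest.fixture()
def admin_token(server, small_dataset):
    return login(server, small_dataset.passwords, "admin")[1]


@pytest.fixture()
def guest_token(server, small_dataset):
    return login(server, small_dataset.passwords, "guest")[1]


class TestLogin:
    def test_good_credentials_yield_token(self, server, small_dataset):
        alias = next(iter(small_dataset.passwords))
        r = server.request("POST", "/login", {"alias": alias, "password": small_dataset.passwords[alias]})
        assert r.status == 200 and r.body["token"]

    def test_bad_credentials_rejected_uniformly(self, server, small_dataset):
        alias = next(iter(small_dataset.passwords))
        wrong_pw = server.request("POST", "/login", {"alias": alias, "password": "nope"})
        ghost = server.request("POST", "/login", {"alias": "ghost", "password": "nope"})
        assert wrong_pw.status == ghost.status == 403
        assert wrong_pw.body == ghost.body

    def test_no_token_means_unauthorized(self, server):
        assert server.request("POST", "/query", {}).status == 403


class TestPurity:
    def test_identical_env_and_state_give_identical_bytes(self, server, small_dataset):
        user = next(u for u in server.tree.alive("user") if u.role.value == "admin")
        env = Env(
            request=Request("POST", "/query", {"paging": {"limit": 10}}),
            tree=server.tree,
            user=user,
        )
        st = QSt()
        r1, r2 = handle(env, st), handle(env, st)
        assert r1.errors == r2.errors == ()
        assert json.dumps(r1.response, sort_keys=True) == json.dumps(r2.response, sort_keys=True)

    def test_query_leaves_log_untouched(self, server, admin_token):
        before = len(server.log)
        server.request("POST", "/query", {}, token=admin_token)
        assert len(server.log) == before


class TestMutations:
    def test_add_assigns_consecutive_ids(self, server, admin_token):
        r1 = server.request("POST", "/supplier", {"name": "Acme"}, token=admin_token)
        r2 = server.request("POST", "/supplier", {"name": "Bane"}, token=admin_token)
        assert r2.body["id"] == r1.body["id"] + 1

    def test_client_supplied_id_rejected(self, server, admin_token):
        r = server.request("POST", "/supplier", {"id": 999, "name": "Forged"}, token=admin_token)
        assert r.status == 422

    def test_guest_mutation_unauthorized_and_logged(self, server, guest_token, caplog):
        import logging
        before = len(server.log)
        with caplog.at_level(logging.WARNING, logger="chemvault.api"):
            r = server.request("POST", "/compound", {"name": "x", "project": 1}, token=guest_token)
        assert r.status == 403
        assert r.body["errors"][0]["code"] == "unauthorized"
        assert len(server.log) == before
        assert any("unauthorized" in m for m in caplog.messages)

    def test_failed_validation_persists_nothing(self, server, admin_token):
        before = len(server.log)
        r = server.request(
            "POST", "/compound",
            {"name": "bad", "casNr": "71-43-3", "project": 1}, token=admin_token,
        )
        assert r.status == 422
        assert len(server.log) == before

    def test_add_mod_del_lifecycle(self, server, admin_token):
        r = server.request(
            "POST", "/compound",
            {"name": "lifecycle", "structure": molblock("CCO"), "project": 1},
            token=admin_token,
        )
        assert r.status == 200
        cid = r.body["id"]
        r2 = server.request("PATCH", f"/compound/{cid}", {"casNr": "64-17-5"}, token=admin_token)
        assert r2.status == 200 and r2.body["casNr"] == "64-17-5"
        r3 = server.request("DELETE", f"/compound/{cid}", token=admin_token)
        assert r3.status == 200
        assert server.request("GET", f"/compound/{cid}", token=admin_token).status == 404
        hist = server.request("GET", f"/compound/{cid}/history", token=admin_token)
        assert hist.status == 200 and len(hist.body["history"]) == 3 and hist.body["deleted"]

    def test_mutation_outside_granted_project_rejected(self, server, small_dataset):
        data = small_dataset
        alias = next(
            a for a in data.passwords if "common" in a or "superuser" in a
        )
        u = next(x for x in server.tree.alive("user") if x.alias == alias)
        hidden = next(p.id for p in server.tree.alive("project") if p.id not in u.projects)
        token = login(server, data.passwords, alias)[1]
        r = server.request("POST", "/compound", {"name": "spy", "project": hidden}, token=token)
        assert r.status == 403


class TestErrorTotality:
    @pytest.mark.parametrize(
        "method,path,raw",
        [
            ("POST", "/query", "{not json"),
            ("POST", "/query", '"just a string"'),
            ("POST", "/compound", "[1,2,3]"),
            ("PATCH", "/compound/zzz", "{}"),
            ("GET", "/compound/NaN", None),
            ("POST", "/nosuchroute", "{}"),
            ("PUT", "/file", '{"data": "%%%not-base64%%%"}'),
            ("POST", "/export", '{"spec": {"fields": []}}'),
            ("POST", "/export", '{"spec": {"fields": ["compound.nope"]}}'),
        ],
    )
    def test_malformed_requests_yield_dataerr_never_traceback(
        self, server, admin_token, method, path, raw
    ):
        r = server.request(method, path, raw_body=raw, token=admin_token)
        assert 400 <= r.status < 500 or r.status == 500
        assert "errors" in r.body
        for e in r.body["errors"]:
            assert e["code"] in {c.value for c in api.ErrCode}
            assert "Traceback" not in json.dumps(r.body)

    def test_unknown_query_field_maps_to_clean_error(self, server, admin_token):
        r = server.request(
            "POST", "/query",
            {"tree": {"field": "compound.colour", "pred": {"type": "text", "mode": "exact", "s": "x"}}},
            token=admin_token,
        )
        assert not r.ok and r.body["errors"][0]["code"] in ("not_found", "query")


class TestFilesAndSettings:
    def test_file_upload_download_round_trip(self, server, admin_token):
        payload = b"\x00\x01binary spectrum\xff"
        cid = next(c.id for c in server.tree.alive("compound"))
        project = server.tree.entity("compound", cid).project
        up = server.request(
            "PUT", "/file",
            {
                "name": "spec.bin", "mime": "application/octet-stream",
                "data": base64.b64encode(payload).decode(),
                "parent_family": "compound", "parent_id": cid, "project": project,
            },
            token=admin_token,
        )
        assert up.status == 200
        down = server.request("GET", f"/file/{up.body['id']}/content", token=admin_token)
        assert base64.b64decode(down.body["data"]) == payload

    def test_settings_round_trip(self, server, admin_token):
        doc = {"columns": ["compound.name", "compound.mass"], "queries": {"aromatics": {}}}
        assert server.request("PUT", "/settings", doc, token=admin_token).status == 200
        got = server.request("GET", "/settings", token=admin_token)
        assert got.body["settings"] == doc


class TestConcurrency:
    def test_concurrent_writers_produce_gap_free_log(self, small_dataset):
        server = Server.from_records(small_dataset.records)
        alias, token = None, None
        admin_alias = next(a for a in small_dataset.passwords if "admin" in a)
        token = server.request(
            "POST", "/login",
            {"alias": admin_alias, "password": small_dataset.passwords[admin_alias]},
        ).body["token"]

        errors = []

        def writer(wid):
            for i in range(10):
                r = server.request(
                    "POST", "/supplier", {"name": f"w{wid}-s{i}"}, token=token
                )
                if r.status != 200:
                    errors.append(r.body)

        threads = [threading.Thread(target=writer, args=(w,)) for w in range(6)]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        assert not errors
        seqs = [r.seq for r in server.log.records]
        assert seqs == list(range(1, len(seqs) + 1))
        # in-memory head equals replay of the full log (no torn state)
        assert store.replay(server.log.records).value == server.tree


class TestBootstrap:
    def test_bootstrap_admin_then_login(self, tmp_path):
        server = Server(log_path=str(tmp_path / "log.ndjson"))
        server.bootstrap_admin("root", "hunter2")
        token = server.request("POST", "/login", {"alias": "root", "password": "hunter2"})
        assert token.status == 200
        with pytest.raises(store.StoreErr):
            server.bootstrap_admin("root2", "x")
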