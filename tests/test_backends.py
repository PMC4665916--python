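"""Backend services: authentication, RBAC, CRUD audit, temp ids, encryption."""

import pytest

from pseudokit.backends import (
    AuthenticationError,
    AuthorizationError,
    BackendService,
    ChildrenExistError,
    ConfigError,
    MappingService,
    MemoryStore,
    NotFoundError,
    SqliteStore,
    DocumentNode,
)
from pseudokit.model import Namespace
from pseudokit.tokens import ReplayError, TokenPayload, generate_keypair, seal_token
import random


def make_backend(component_id="svc", ns="ns-svc", seed=1, **kw):
    kp = generate_keypair(component_id, random.Random(seed))
    b = BackendService(component_id, Namespace(ns), kp, seed=seed, **kw)
    b.add_user("phys1", "pw-p1", "physician", "site-01")
    b.add_user("phys2", "pw-p2", "physician", "site-02")
    b.add_user("mon1", "pw-m1", "monitor", "site-01")
    b.add_user("adm1", "pw-a1", "administrator", "site-01")
    b.add_user("lab1", "pw-l1", "lab", "site-01")
    return b


@pytest.fixture()
def backend():
    return make_backend()


class TestAuthentication:
    def test_login_issues_session_and_audits(self, backend):
        sid = backend.authenticate("phys1", "pw-p1")
        assert sid in backend.sessions
        assert backend.audit[-1].operation == "login"
        assert backend.audit[-1].outcome == "ok"

    def test_wrong_secret_denied_and_audited(self, backend):
        with pytest.raises(AuthenticationError) as e1:
            backend.authenticate("phys1", "wrong")
        assert backend.audit[-1].outcome == "denied"
        with pytest.raises(AuthenticationError) as e2:
            backend.authenticate("nobody", "wrong")
        # unknown user indistinguishable from bad secret
        assert str(e1.value) == str(e2.value)

    def test_sessions_are_unique(self, backend):
        sids = {backend.authenticate("phys1", "pw-p1") for _ in range(1000)}
        assert len(sids) == 1000


class TestAuthorization:
    def test_monitor_reads_but_never_mutates_clinical(self, backend):
        assert backend.authorize("mon1", "read", "clinical", "site-01")
        assert not backend.authorize("mon1", "update", "clinical", "site-01")
        assert not backend.authorize("mon1", "create", "clinical", "site-01")

    def test_administrator_has_no_research_data_access(self, backend):
        for dclass in ("master", "clinical", "specimen"):
            assert not backend.authorize("adm1", "read", dclass, "site-01")
        assert backend.authorize("adm1", "create", "account", None)

    def test_cross_site_physician_denied(self, backend):
        assert backend.authorize("phys1", "read", "master", "site-01")
        assert not backend.authorize("phys1", "read", "master", "site-02")

    def test_denial_is_audited(self, backend):
        n = len(backend.audit)
        backend.authorize("mon1", "delete", "clinical", "site-01")
        assert len(backend.audit) == n + 1
        assert backend.audit[-1].outcome == "denied"


class TestCrud:
    def test_create_then_read_roundtrip(self, backend):
        sid = backend.authenticate("phys1", "pw-p1")
        node = backend.crud(sid, "create", doc_type="master",
                            content={"name": "Alba"}, site="site-01")
        got = backend.crud(sid, "read", node_id=node.node_id)
        assert got.content == {"name": "Alba"}

    def test_mutations_audited_one_to_one(self, backend):
        sid = backend.authenticate("phys1", "pw-p1")
        before = backend.mutation_audit_count()
        n1 = backend.crud(sid, "create", doc_type="master", content={}, site="site-01")
        backend.crud(sid, "update", node_id=n1.node_id, content={"x": "1"})
        backend.crud(sid, "delete", node_id=n1.node_id)
        assert backend.mutation_audit_count() - before == 3

    def test_delete_unknown_id_is_error_without_state_change(self, backend):
        sid = backend.authenticate("phys1", "pw-p1")
        before = backend.store.all()
        with pytest.raises(NotFoundError):
            backend.crud(sid, "delete", node_id="missing")
        assert backend.store.all() == before
        assert backend.audit[-1].outcome == "error"

    def test_root_delete_requires_cascade(self, backend):
        sid = backend.authenticate("phys1", "pw-p1")
        root = backend.crud(sid, "create", doc_type="master", content={}, site="site-01")
        backend.crud(sid, "create", parent=root.node_id, doc_type="baseline_visit",
                     content={}, site="site-01")
        with pytest.raises(ChildrenExistError):
            backend.crud(sid, "delete", node_id=root.node_id)
        backend.crud(sid, "delete", node_id=root.node_id, cascade=True)
        assert backend.store.all() == []

    def test_fresh_pseudonyms_assigned_on_create(self, backend):
        sid = backend.authenticate("phys1", "pw-p1")
        ids = {
            backend.crud(sid, "create", doc_type="master", content={},
                         site="site-01").node_id
            for _ in range(20)
        }
        assert len(ids) == 20

    def test_unauthorized_crud_raises_and_audits_denial(self, backend):
        sid = backend.authenticate("mon1", "pw-m1")
        with pytest.raises(AuthorizationError):
            backend.crud(sid, "create", doc_type="master", content={}, site="site-01")
        assert backend.audit[-1].outcome == "denied"


class TestTempIds:
    def test_temp_ids_never_equal_internal_pseudonyms(self, backend):
        internal = [backend.fresh_pseudonym() for _ in range(30)]
        temp, pairs = backend.issue_temp_ids(internal, mode="indirect")
        assert set(temp).isdisjoint(internal)
        assert [p[1] for p in pairs] == internal

    def test_indirect_mode_leaves_server_stateless(self, backend):
        backend.issue_temp_ids([backend.fresh_pseudonym()], mode="indirect")
        assert backend.temp_map == {}

    def test_direct_mode_persists_one_entry_per_id(self, backend):
        ids = [backend.fresh_pseudonym() for _ in range(3)]
        temp, _ = backend.issue_temp_ids(ids, mode="direct")
        assert len(backend.temp_map) == 3
        assert backend.resolve_persisted_temp(temp[0]) == ids[0]

    def test_retired_mapping_cannot_resolve_again(self, backend):
        ids = [backend.fresh_pseudonym()]
        temp, _ = backend.issue_temp_ids(ids, mode="direct")
        backend.resolve_persisted_temp(temp[0])
        from pseudokit.backends import TempMappingError

        with pytest.raises(TempMappingError):
            backend.resolve_persisted_temp(temp[0])


class TestMappingService:
    def make_pair(self, seed=3):
        rng = random.Random(seed)
        kp_b1 = generate_keypair("b1", random.Random(rng.getrandbits(31)))
        kp_ms = generate_keypair("ms", random.Random(rng.getrandbits(31)))
        kp_b2 = generate_keypair("b2", random.Random(rng.getrandbits(31)))
        b1 = BackendService("b1", Namespace("ns-a"), kp_b1, seed=1)
        b2 = BackendService("b2", Namespace("ns-b"), kp_b2, seed=2)
        ms = MappingService("ms", kp_ms, Namespace("ns-a"), Namespace("ns-b"), seed=3)
        for svc in (b1, b2, ms):
            svc.register_peer("b1", kp_b1.public_part)
            svc.register_peer("ms", kp_ms.public_part)
            svc.register_peer("b2", kp_b2.public_part)
            svc.add_user("phys1", "pw", "physician", "site-01")
        return b1, ms, b2

    def test_translate_maps_temp_to_secondary_namespace(self):
        b1, ms, b2 = self.make_pair()
        a, b = b1.fresh_pseudonym(), b2.fresh_pseudonym()
        ms.add_pair(a, b)
        token = b1.seal_for("ms", "phys1", "pw",
                            {"op": "translate", "id_pairs": [["t-x", a]]})
        out = ms.translate(token, "b2")
        got = b2.open_incoming(out)
        assert got.payload["id_pairs"] == [["t-x", b]]
        assert ms.audit[-1].operation == "translate"

    def test_missing_pair_becomes_marker_not_failure(self):
        b1, ms, b2 = self.make_pair()
        token = b1.seal_for("ms", "phys1", "pw",
                            {"op": "translate", "id_pairs": [["t-x", "unmapped"]]})
        got = b2.open_incoming(ms.translate(token, "b2"))
        assert got.payload["id_pairs"] == [["t-x", None]]

    def test_replayed_translation_token_rejected(self):
        b1, ms, b2 = self.make_pair()
        token = b1.seal_for("ms", "phys1", "pw",
                            {"op": "translate", "id_pairs": []})
        ms.translate(token, "b2")
        with pytest.raises(ReplayError):
            ms.translate(token, "b2")

    def test_mapping_service_state_holds_no_attributes(self):
        b1, ms, b2 = self.make_pair()
        ms.add_pair(b1.fresh_pseudonym(), b2.fresh_pseudonym())
        state = ms.exposed_state()
        assert state["identifying"] == {} and state["payload"] == {}
        assert len(state["links"]) == 1


class TestEncryptionAtRest:
    def test_missing_key_refused_at_startup(self):
        kp = generate_keypair("p", random.Random(0))
        with pytest.raises(ConfigError):
            BackendService("p", Namespace("ns"), kp, encrypt_master=True)

    @pytest.mark.parametrize("store_cls", [MemoryStore, SqliteStore])
    def test_store_bytes_hide_identifying_values(self, store_cls):
        backend = make_backend(encrypt_master=True,
                               master_data_key=b"k" * 32, store=store_cls())
        sid = backend.authenticate("phys1", "pw-p1")
        node = backend.crud(sid, "create", doc_type="master",
                            content={"name": "Cathi Fernsby"}, site="site-01")
        raw = backend.store.dump_bytes()
        assert b"Cathi Fernsby" not in raw
        got = backend.crud(sid, "read", node_id=node.node_id)
        assert got.content == {"name": "Cathi Fernsby"}

    def test_payload_documents_unaffected_by_master_encryption(self):
        backend = make_backend(encrypt_master=True, master_data_key=b"k" * 32)
        sid = backend.authenticate("phys1", "pw-p1")
        root = backend.crud(sid, "create", doc_type="master", content={}, site="site-01")
        backend.crud(sid, "create", parent=root.node_id, doc_type="baseline_visit",
                     content={"severity_score": "42"}, site="site-01")
        assert b"42" in backend.store.dump_bytes()


class TestSqliteStore:
    def test_persist_and_reload_from_file(self, tmp_path):
        path = str(tmp_path / "store.db")
        store = SqliteStore(path)
        store.put(DocumentNode("n1", None, "master", {"a": "1"}, "site-01", "master"))
        store2 = SqliteStore(path)
        assert store2.get("n1").content == {"a": "1"}
        assert len(store2.all()) == 1
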