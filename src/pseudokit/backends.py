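"""Stateful parties: primary service, secondary service, mapping service.

The primary service owns the master-data namespace and stores one root node
per subject (identifying attributes, optionally encrypted at rest).  The
secondary service owns the payload namespace and stores document nodes
(eCRF instances) grouped under a per-subject payload pseudonym.  The
mapping service stores bare pseudonym pairs linking the two namespaces and
nothing else.

Every component authenticates every request itself (non-delegated: user
credentials travel inside sealed tokens and are re-verified at each hop),
applies its own role-based access control with a site filter, and keeps an
append-only, gapless audit trail of every operation.
"""

from __future__ import annotations

import hashlib
import hmac
import json
import random
import secrets
import sqlite3
from abc import ABC, abstractmethod
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

from .hybridcrypto import aead_open, aead_seal
from .model import MappingTable, Namespace, Pseudonym, new_pseudonym
from .tokens import (
    KeyPair,
    KeyRing,
    ReplayState,
    SealedToken,
    TokenPayload,
    open_token,
    seal_token,
)

ROLES = ("administrator", "monitor", "physician", "lab")
OPERATIONS = ("create", "read", "update", "delete")
DATA_CLASSES = ("master", "clinical", "specimen", "account")

# Default role x data-class x operation matrix:
#   administrators manage accounts but have no access to research data;
#   monitors read clinical/master/specimen data for quality assurance;
#   physicians have full CRUD on master and clinical data at their site;
#   lab personnel manage specimen documents at their site.
DEFAULT_RBAC: dict[str, dict[str, frozenset[str]]] = {
    "administrator": {"account": frozenset(OPERATIONS)},
    "monitor": {
        "master": frozenset({"read"}),
        "clinical": frozenset({"read"}),
        "specimen": frozenset({"read"}),
    },
    "physician": {
        "master": frozenset(OPERATIONS),
        "clinical": frozenset(OPERATIONS),
        "specimen": frozenset({"read"}),
    },
    "lab": {"specimen": frozenset(OPERATIONS)},
}

# Physicians and lab personnel see only their own institution's subjects;
# monitors audit across sites (configurable).
DEFAULT_SITE_RESTRICTED = frozenset({"physician", "lab"})

DOC_TYPE_CLASSES: dict[str, str] = {"specimen_registration": "specimen"}

PBKDF2_ITERATIONS = 50_000
TEMP_ID_PREFIX = "t-"


class BackendError(Exception):
    pass


class AuthenticationError(BackendError):
    """Bad credentials or unknown user (indistinguishable by design)."""


class AuthorizationError(BackendError):
    """Operation denied by the RBAC matrix or the site filter."""


class NotFoundError(BackendError):
    pass


class ChildrenExistError(BackendError):
    """Deleting a root that still has children requires an explicit cascade."""


class TempMappingError(BackendError):
    """Temporary-identifier mapping expired, retired or never persisted."""


class ConfigError(BackendError):
    pass


@dataclass(frozen=True)
class UserAccount:
    username: str
    secret_hash: bytes = field(repr=False)
    salt: bytes = field(repr=False)
    role: str
    site: str


@dataclass
class DocumentNode:
    node_id: str
    parent: str | None
    doc_type: str
    content: dict[str, str]
    site: str
    label: str = ""  # stable display label, e.g. "baseline_visit#0"


@dataclass(frozen=True)
class AuditEvent:
    seq: int
    actor: str
    operation: str  # create | read | update | delete | login | translate
    target: str
    backend: str
    outcome: str  # ok | denied | error


@dataclass
class TempIdEntry:
    temp_id: str
    internal: str
    issued_seq: int
    status: str = "active"  # active | retired


@dataclass
class Session:
    session_id: str
    username: str
    # Kept in memory only, never at rest: needed to embed credentials into
    # outgoing tokens (non-delegated authentication at every hop).
    secret: str = field(repr=False)


def hash_secret(secret: str, salt: bytes) -> bytes:
    return hashlib.pbkdf2_hmac("sha256", secret.encode(), salt, PBKDF2_ITERATIONS)


def data_class_of(doc_type: str, is_root: bool) -> str:
    if is_root:
        return "master"
    return DOC_TYPE_CLASSES.get(doc_type, "clinical")


# ---------------------------------------------------------------------------
# Storage: contract plus an in-memory and an embedded-SQL implementation
# ---------------------------------------------------------------------------


class DocumentStore(ABC):
    """Minimal persistent-store contract for document nodes."""

    @abstractmethod
    def put(self, node: DocumentNode) -> None: ...

    @abstractmethod
    def get(self, node_id: str) -> DocumentNode | None: ...

    @abstractmethod
    def delete(self, node_id: str) -> None: ...

    @abstractmethod
    def all(self) -> list[DocumentNode]: ...

    def children(self, parent: str) -> list[DocumentNode]:
        return [n for n in self.all() if n.parent == parent]

    @abstractmethod
    def dump_bytes(self) -> bytes:
        """Serialized persistent state, as an adversary reading the store
        medium would see it."""


class MemoryStore(DocumentStore):
    def __init__(self) -> None:
        self._nodes: dict[str, DocumentNode] = {}

    def put(self, node: DocumentNode) -> None:
        self._nodes[node.node_id] = node

    def get(self, node_id: str) -> DocumentNode | None:
        return self._nodes.get(node_id)

    def delete(self, node_id: str) -> None:
        self._nodes.pop(node_id, None)

    def all(self) -> list[DocumentNode]:
        return list(self._nodes.values())

    def dump_bytes(self) -> bytes:
        rows = [
            {
                "node_id": n.node_id,
                "parent": n.parent,
                "doc_type": n.doc_type,
                "content": n.content,
                "site": n.site,
                "label": n.label,
            }
            for n in sorted(self._nodes.values(), key=lambda n: n.node_id)
        ]
        return json.dumps(rows, sort_keys=True).encode()


class SqliteStore(DocumentStore):
    """Single-file embedded-SQL store (stdlib sqlite3)."""

    def __init__(self, path: str = ":memory:") -> None:
        self.path = path
        self._conn = sqlite3.connect(path)
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS nodes ("
            "node_id TEXT PRIMARY KEY, parent TEXT, doc_type TEXT, "
            "content TEXT, site TEXT, label TEXT)"
        )
        self._conn.commit()

    def put(self, node: DocumentNode) -> None:
        self._conn.execute(
            "INSERT OR REPLACE INTO nodes VALUES (?,?,?,?,?,?)",
            (
                node.node_id,
                node.parent,
                node.doc_type,
                json.dumps(node.content, sort_keys=True),
                node.site,
                node.label,
            ),
        )
        self._conn.commit()

    def get(self, node_id: str) -> DocumentNode | None:
        row = self._conn.execute(
            "SELECT node_id, parent, doc_type, content, site, label "
            "FROM nodes WHERE node_id = ?",
            (node_id,),
        ).fetchone()
        if row is None:
            return None
        return DocumentNode(row[0], row[1], row[2], json.loads(row[3]), row[4], row[5])

    def delete(self, node_id: str) -> None:
        self._conn.execute("DELETE FROM nodes WHERE node_id = ?", (node_id,))
        self._conn.commit()

    def all(self) -> list[DocumentNode]:
        rows = self._conn.execute(
            "SELECT node_id, parent, doc_type, content, site, label FROM nodes"
        ).fetchall()
        return [
            DocumentNode(r[0], r[1], r[2], json.loads(r[3]), r[4], r[5]) for r in rows
        ]

    def dump_bytes(self) -> bytes:
        return "\n".join(self._conn.iterdump()).encode()


# ---------------------------------------------------------------------------
# Backend service
# ---------------------------------------------------------------------------


class BackendService:
    """One stateful data-holding party (primary or secondary service)."""

    def __init__(
        self,
        component_id: str,
        namespace: Namespace,
        keypair: KeyPair,
        *,
        store: DocumentStore | None = None,
        rbac: Mapping[str, Mapping[str, frozenset[str]]] | None = None,
        site_restricted_roles: frozenset[str] = DEFAULT_SITE_RESTRICTED,
        encrypt_master: bool = False,
        master_data_key: bytes | None = None,
        seed: int | None = None,
    ) -> None:
        if encrypt_master and master_data_key is None:
            raise ConfigError(
                f"{component_id}: master-data encryption enabled without a key"
            )
        self.component_id = component_id
        self.namespace = namespace
        self.ring = KeyRing(own=keypair)
        self.store = store or MemoryStore()
        self.rbac = {r: dict(m) for r, m in (rbac or DEFAULT_RBAC).items()}
        self.site_restricted_roles = site_restricted_roles
        self.encrypt_master = encrypt_master
        self.master_data_key = master_data_key
        self.users: dict[str, UserAccount] = {}
        self.sessions: dict[str, Session] = {}
        self.replay = ReplayState()
        self.audit: list[AuditEvent] = []
        self.temp_map: dict[str, TempIdEntry] = {}
        self.temp_map_single_use = True
        # Test hook: disabling substitution leaks internal pseudonyms to the
        # client; the verifier must catch this.
        self.substitute_temp_ids = True
        self._rng = random.Random(seed) if seed is not None else random.Random()
        self._send_counters: dict[str, int] = {}
        self._taken_pseudonyms: set[str] = set()
        self._verified_cache: set[bytes] = set()

    # -- key topology -------------------------------------------------------

    def register_peer(self, component_id: str, public_key: bytes) -> None:
        self.ring.peers[component_id] = public_key

    # -- audit --------------------------------------------------------------

    def _audit(self, actor: str, operation: str, target: str, outcome: str) -> None:
        self.audit.append(
            AuditEvent(
                seq=len(self.audit),
                actor=actor,
                operation=operation,
                target=target,
                backend=self.component_id,
                outcome=outcome,
            )
        )

    def mutation_audit_count(self) -> int:
        return sum(
            1
            for e in self.audit
            if e.operation in ("create", "update", "delete") and e.outcome == "ok"
        )

    # -- users and authentication -------------------------------------------

    def add_user(self, username: str, secret: str, role: str, site: str) -> None:
        if role not in self.rbac:
            raise ConfigError(f"unknown role {role!r}")
        salt = self._rng.getrandbits(128).to_bytes(16, "big")
        self.users[username] = UserAccount(
            username=username,
            secret_hash=hash_secret(secret, salt),
            salt=salt,
            role=role,
            site=site,
        )

    def _verify_credentials(self, username: str, secret: str) -> bool:
        account = self.users.get(username)
        if account is None:
            # Burn comparable work so unknown users are indistinguishable.
            hash_secret(secret, b"\x00" * 16)
            return False
        cache_key = hashlib.sha256(
            account.salt + username.encode() + b"\x00" + secret.encode()
        ).digest()
        if cache_key in self._verified_cache:
            return True
        ok = hmac.compare_digest(account.secret_hash, hash_secret(secret, account.salt))
        if ok:
            self._verified_cache.add(cache_key)
        return ok

    def authenticate(self, username: str, secret: str) -> str:
        """Interactive login; returns a fresh random session id."""
        if not self._verify_credentials(username, secret):
            self._audit(username, "login", "-", "denied")
            raise AuthenticationError("invalid username or password")
        session_id = secrets.token_hex(16)
        self.sessions[session_id] = Session(session_id, username, secret)
        self._audit(username, "login", "-", "ok")
        return session_id

    def _session(self, session_id: str) -> Session:
        try:
            return self.sessions[session_id]
        except KeyError:
            raise AuthenticationError("unknown or expired session") from None

    # -- authorization ------------------------------------------------------

    def authorize(
        self,
        username: str,
        operation: str,
        data_class: str,
        target_site: str | None = None,
        *,
        audit_denial: bool = True,
    ) -> bool:
        """RBAC decision; deny is a value and is audited, never raised."""
        account = self.users.get(username)
        allowed = False
        if account is not None and operation in self.rbac.get(account.role, {}).get(
            data_class, frozenset()
        ):
            allowed = True
            if (
                account.role in self.site_restricted_roles
                and target_site is not None
                and target_site != account.site
            ):
                allowed = False
        if not allowed and audit_denial:
            self._audit(username, operation, f"{data_class}:{target_site}", "denied")
        return allowed

    # -- master-data encryption at rest --------------------------------------

    def _store_content(self, node: DocumentNode) -> DocumentNode:
        if self.encrypt_master and node.parent is None:
            raw = json.dumps(node.content, sort_keys=True).encode()
            sealed = aead_seal(self.master_data_key, raw, aad=node.node_id.encode())
            return replace(node, content={"_sealed": sealed.hex()})
        return node

    def _load_content(self, node: DocumentNode) -> DocumentNode:
        if self.encrypt_master and node.parent is None and "_sealed" in node.content:
            raw = aead_open(
                self.master_data_key,
                bytes.fromhex(node.content["_sealed"]),
                aad=node.node_id.encode(),
            )
            return replace(node, content=json.loads(raw))
        return node

    # -- CRUD ----------------------------------------------------------------

    def fresh_pseudonym(self) -> str:
        return new_pseudonym(self.namespace, self._rng, self._taken_pseudonyms).value

    def crud(
        self,
        session_id: str,
        operation: str,
        *,
        node_id: str | None = None,
        parent: str | None = None,
        doc_type: str = "",
        content: Mapping[str, str] | None = None,
        site: str = "",
        label: str = "",
        cascade: bool = False,
    ) -> DocumentNode | None:
        """Create/read/update/delete one document node.

        Every executed mutation appends exactly one audit event per node
        touched; denials and failures are audited with their outcome.
        """
        session = self._session(session_id)
        account = self.users[session.username]

        if operation == "create":
            dclass = data_class_of(doc_type, is_root=parent is None)
            if not self.authorize(session.username, "create", dclass, site):
                raise AuthorizationError(f"{account.role} may not create {dclass}")
            nid = node_id or self.fresh_pseudonym()
            node = DocumentNode(
                node_id=nid,
                parent=parent,
                doc_type=doc_type,
                content=dict(content or {}),
                site=site,
                label=label or doc_type,
            )
            self.store.put(self._store_content(node))
            self._audit(session.username, "create", nid, "ok")
            return node

        if node_id is None:
            raise NotFoundError("node_id required")
        stored = self.store.get(node_id)
        if operation == "read":
            if stored is None:
                self._audit(session.username, "read", node_id, "error")
                raise NotFoundError(node_id)
            dclass = data_class_of(stored.doc_type, stored.parent is None)
            if not self.authorize(session.username, "read", dclass, stored.site):
                raise AuthorizationError(f"{account.role} may not read {dclass}")
            self._audit(session.username, "read", node_id, "ok")
            return self._load_content(stored)

        if operation == "update":
            if stored is None:
                self._audit(session.username, "update", node_id, "error")
                raise NotFoundError(node_id)
            dclass = data_class_of(stored.doc_type, stored.parent is None)
            if not self.authorize(session.username, "update", dclass, stored.site):
                raise AuthorizationError(f"{account.role} may not update {dclass}")
            node = replace(stored, content=dict(content or {}))
            self.store.put(self._store_content(node) if stored.parent is None else node)
            self._audit(session.username, "update", node_id, "ok")
            return node

        if operation == "delete":
            if stored is None:
                self._audit(session.username, "delete", node_id, "error")
                raise NotFoundError(node_id)
            dclass = data_class_of(stored.doc_type, stored.parent is None)
            if not self.authorize(session.username, "delete", dclass, stored.site):
                raise AuthorizationError(f"{account.role} may not delete {dclass}")
            children = self.store.children(node_id)
            if children and not cascade:
                self._audit(session.username, "delete", node_id, "error")
                raise ChildrenExistError(
                    f"node {node_id} has {len(children)} children; pass cascade=True"
                )
            for child in children:
                self.store.delete(child.node_id)
                self._audit(session.username, "delete", child.node_id, "ok")
            self.store.delete(node_id)
            self._audit(session.username, "delete", node_id, "ok")
            return None

        raise BackendError(f"unknown operation {operation!r}")

    # -- sealed-token plumbing ----------------------------------------------

    def next_counter(self, receiver_id: str) -> int:
        self._send_counters[receiver_id] = self._send_counters.get(receiver_id, 0) + 1
        return self._send_counters[receiver_id]

    def seal_for(
        self, receiver_id: str, username: str, secret: str, payload: dict[str, Any]
    ) -> SealedToken:
        return seal_token(
            self.ring,
            receiver_id,
            TokenPayload(
                username=username,
                password=secret,
                counter=self.next_counter(receiver_id),
                payload=payload,
            ),
        )

    def open_incoming(self, token: SealedToken) -> TokenPayload:
        """Open a token and re-authenticate the user it carries."""
        payload = open_token(self.ring, token, self.replay)
        if not self._verify_credentials(payload.username, payload.password):
            self._audit(payload.username, "login", "-", "denied")
            raise AuthenticationError("token credentials rejected")
        return payload

    # -- temporary identifiers ----------------------------------------------

    def _fresh_temp_id(self) -> str:
        # The prefix guarantees a temp id never collides with an internal
        # 32-hex-character pseudonym.
        return TEMP_ID_PREFIX + format(self._rng.getrandbits(96), "024x")

    def issue_temp_ids(
        self, internal_ids: Sequence[str], *, mode: str
    ) -> tuple[list[str], list[list[str]]]:
        """Substitute internal pseudonyms with fresh temporary identifiers.

        Returns (temp_ids, id_pairs).  In ``indirect`` mode the association
        lives only in the returned pairs (to be sealed into a token) and no
        server state changes; in ``direct`` mode it is persisted in the
        temp-id map for later peer resolution.
        """
        if not self.substitute_temp_ids:
            pairs = [[i, i] for i in internal_ids]
            return list(internal_ids), pairs
        temp_ids = [self._fresh_temp_id() for _ in internal_ids]
        pairs = [[t, i] for t, i in zip(temp_ids, internal_ids)]
        if mode == "direct":
            for t, i in zip(temp_ids, internal_ids):
                self.temp_map[t] = TempIdEntry(
                    temp_id=t, internal=i, issued_seq=len(self.audit)
                )
        elif mode != "indirect":
            raise ConfigError(f"unknown mode {mode!r}")
        return temp_ids, pairs

    def resolve_persisted_temp(self, temp_id: str) -> str:
        """Direct mode: look up a persisted temp mapping, retiring it on use."""
        entry = self.temp_map.get(temp_id)
        if entry is None or entry.status != "active":
            raise TempMappingError(f"no active temporary mapping for {temp_id!r}")
        if self.temp_map_single_use:
            entry.status = "retired"
        return entry.internal

    # -- adversary view ------------------------------------------------------

    def exposed_state(self) -> dict[str, Any]:
        """Everything an adversary holding this party's disks would get."""
        identifying: dict[str, dict[str, str]] = {}
        payload: dict[str, dict[str, str]] = {}
        for node in self.store.all():
            loaded = self._load_content(node)
            if node.parent is None:
                identifying[node.node_id] = dict(loaded.content)
            else:
                payload[node.node_id] = dict(loaded.content)
        return {"identifying": identifying, "payload": payload, "links": []}


class MappingService:
    """Trusted third party holding bare pseudonym pairs."""

    def __init__(
        self,
        component_id: str,
        keypair: KeyPair,
        ns_a: Namespace,
        ns_b: Namespace,
        seed: int | None = None,
    ) -> None:
        self.component_id = component_id
        self.ns_a = ns_a
        self.ns_b = ns_b
        self.ring = KeyRing(own=keypair)
        self.table = MappingTable()
        self.replay = ReplayState()
        self.audit: list[AuditEvent] = []
        self.users: dict[str, UserAccount] = {}
        self._rng = random.Random(seed) if seed is not None else random.Random()
        self._send_counters: dict[str, int] = {}
        self._taken: set[str] = set()
        self._verified_cache: set[bytes] = set()

    def register_peer(self, component_id: str, public_key: bytes) -> None:
        self.ring.peers[component_id] = public_key

    def _audit(self, actor: str, operation: str, target: str, outcome: str) -> None:
        self.audit.append(
            AuditEvent(
                seq=len(self.audit),
                actor=actor,
                operation=operation,
                target=target,
                backend=self.component_id,
                outcome=outcome,
            )
        )

    def add_user(self, username: str, secret: str, role: str, site: str) -> None:
        salt = self._rng.getrandbits(128).to_bytes(16, "big")
        self.users[username] = UserAccount(
            username, hash_secret(secret, salt), salt, role, site
        )

    def _verify_credentials(self, username: str, secret: str) -> bool:
        account = self.users.get(username)
        if account is None:
            hash_secret(secret, b"\x00" * 16)
            return False
        cache_key = hashlib.sha256(
            account.salt + username.encode() + b"\x00" + secret.encode()
        ).digest()
        if cache_key in self._verified_cache:
            return True
        ok = hmac.compare_digest(account.secret_hash, hash_secret(secret, account.salt))
        if ok:
            self._verified_cache.add(cache_key)
        return ok

    def add_pair(self, a_value: str, b_value: str) -> None:
        self.table.add(Pseudonym(self.ns_a, a_value), Pseudonym(self.ns_b, b_value))

    def next_counter(self, receiver_id: str) -> int:
        self._send_counters[receiver_id] = self._send_counters.get(receiver_id, 0) + 1
        return self._send_counters[receiver_id]

    def translate(
        self, token: SealedToken, receiver_id: str, *, create_missing: bool = False
    ) -> SealedToken:
        """Translate (temp_id, ns_a pseudonym) pairs into (temp_id, ns_b).

        Pairs with no mapping become dangling-link markers (``null``), not a
        hard failure, unless ``create_missing`` asks for a fresh ns_b
        pseudonym plus a new table pair (used when a first payload document
        is created for a subject).  The result is sealed for the receiver;
        the user's credentials are carried forward for the next hop's own
        authentication.
        """
        payload = open_token(self.ring, token, self.replay)
        if not self._verify_credentials(payload.username, payload.password):
            self._audit(payload.username, "login", "-", "denied")
            raise AuthenticationError("token credentials rejected")
        out_pairs: list[list[str | None]] = []
        for temp_id, a_value in payload.payload.get("id_pairs", []):
            mapped = self.table.lookup_a(a_value)
            if mapped is None and create_missing:
                b = new_pseudonym(self.ns_b, self._rng, self._taken)
                self.table.add(Pseudonym(self.ns_a, a_value), b)
                mapped = b
            out_pairs.append([temp_id, mapped.value if mapped else None])
            self._audit(
                payload.username,
                "translate",
                temp_id,
                "ok" if mapped else "error",
            )
        out_payload = dict(payload.payload)
        out_payload["id_pairs"] = out_pairs
        return seal_token(
            self.ring,
            receiver_id,
            TokenPayload(
                username=payload.username,
                password=payload.password,
                counter=self.next_counter(receiver_id),
                payload=out_payload,
            ),
        )

    def forward(self, token: SealedToken, receiver_id: str) -> SealedToken:
        """Direct mode: route an answer from one backend to another.

        The mapping service is the mandated relay; it re-seals the content
        for the final receiver after translating namespaces.
        """
        return self.translate(token, receiver_id)

    def exposed_state(self) -> dict[str, Any]:
        return {
            "identifying": {},
            "payload": {},
            "links": [(pa.value, pb.value) for pa, pb in self.table.pairs],
        }
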