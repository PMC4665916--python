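"""Client-orchestrated join and creation protocols with verifiable transcripts.

The logical global record only ever exists at the client: backends deliver
their shares keyed by *temporary* identifiers, the mapping service
translates between namespaces inside sealed tokens, and the client joins
the shares locally.  Two channel styles exist:

* **indirect** — every message is routed via the client (all transcript
  messages are client-visible); backends stay stateless with respect to
  temporary identifiers, which travel only inside sealed tokens.  A
  single-record join takes exactly six enumerated steps.
* **direct** — backends synchronize temporary identifiers directly; the
  primary persists the temp association and the answer is routed through
  the mapping service.  A single-record join takes nine enumerated steps
  of which at least seven are message exchanges.

Transcripts record every step (message or local action) with a digest of
the body; client-visible bodies are retained so confidentiality scans can
assert that no internal pseudonym ever reaches the client.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

from .backends import AuthorizationError, BackendService, MappingService, NotFoundError
from .tokens import SealedToken, decode_request_line, encode_request_line

CLIENT = "client"


@dataclass(frozen=True)
class Message:
    step_no: int
    frm: str
    to: str
    kind: str  # request | response
    visible_to_client: bool
    body_text: str = field(repr=False)

    @property
    def body_digest(self) -> str:
        return hashlib.sha256(self.body_text.encode()).hexdigest()


@dataclass(frozen=True)
class LocalAction:
    step_no: int
    at: str
    description: str


@dataclass
class Transcript:
    """Ordered protocol trace; message exchanges vs local steps."""

    steps: list[Message | LocalAction] = field(default_factory=list)

    def _next(self) -> int:
        return len(self.steps) + 1

    def message(
        self, frm: str, to: str, kind: str, body: Mapping[str, Any], visible: bool
    ) -> dict[str, Any]:
        body = dict(body)
        self.steps.append(
            Message(
                step_no=self._next(),
                frm=frm,
                to=to,
                kind=kind,
                visible_to_client=visible,
                body_text=json.dumps(body, sort_keys=True),
            )
        )
        return body

    def local(self, at: str, description: str) -> None:
        self.steps.append(LocalAction(self._next(), at, description))

    @property
    def message_count(self) -> int:
        return sum(1 for s in self.steps if isinstance(s, Message))

    @property
    def step_count(self) -> int:
        return len(self.steps)

    def client_visible_text(self) -> str:
        return "\n".join(
            s.body_text
            for s in self.steps
            if isinstance(s, Message) and s.visible_to_client
        )

    def to_jsonl(self) -> str:
        lines = []
        for s in self.steps:
            if isinstance(s, Message):
                lines.append(
                    json.dumps(
                        {
                            "step_no": s.step_no,
                            "from": s.frm,
                            "to": s.to,
                            "kind": s.kind,
                            "visible_to_client": s.visible_to_client,
                            "body_digest": s.body_digest,
                        },
                        sort_keys=True,
                    )
                )
            else:
                lines.append(
                    json.dumps(
                        {"step_no": s.step_no, "at": s.at, "local": s.description},
                        sort_keys=True,
                    )
                )
        return "\n".join(lines) + ("\n" if lines else "")


@dataclass
class IntegratedView:
    """Client-side reconstruction: rows keyed by temporary identifiers."""

    rows: list[dict[str, Any]] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)

    def to_dataset(self):
        from .model import (
            IDENTIFYING,
            PAYLOAD,
            AttributeValue,
            IntegratedDataset,
            IntegratedRecord,
        )

        records = []
        for row in self.rows:
            attrs = tuple(
                [
                    AttributeValue(n, v, IDENTIFYING)
                    for n, v in sorted(row["master"].items())
                ]
                + [
                    AttributeValue(n, v, PAYLOAD)
                    for n, v in sorted(row.get("payload", {}).items())
                ]
            )
            records.append(IntegratedRecord(subject_key=row["temp_id"], attributes=attrs))
        return IntegratedDataset(records=records, degenerate=True)


@dataclass
class ConfidentialityReport:
    violations: list[tuple[str, str]] = field(default_factory=list)  # (namespace, value)

    @property
    def ok(self) -> bool:
        return not self.violations


def assert_confidential(
    transcript: Transcript, namespaces: Mapping[str, Iterable[str]]
) -> ConfidentialityReport:
    """Scan all client-visible message bodies for internal pseudonyms.

    ``namespaces`` maps a namespace id to the internal pseudonym values it
    owns.  An empty violation list certifies the run leaked none of them.
    """
    report = ConfidentialityReport()
    visible = transcript.client_visible_text()
    for ns_id, values in namespaces.items():
        for value in values:
            if value and value in visible:
                report.violations.append((ns_id, value))
    return report


# ---------------------------------------------------------------------------
# Server-side request handlers (the application layer of each backend)
# ---------------------------------------------------------------------------


def _flatten_docs(docs) -> dict[str, str]:
    out: dict[str, str] = {}
    for doc in docs:
        for fname, fval in doc.content.items():
            out[f"{doc.label}.{fname}"] = fval
    return out


def _primary_select_roots(
    primary: BackendService, session_id: str, selector: Mapping[str, Any] | None
) -> list:
    """Resolve a selector to the readable master roots, applying RBAC/site."""
    session = primary.sessions[session_id]
    roots = sorted(
        (n for n in primary.store.all() if n.parent is None), key=lambda n: n.node_id
    )
    readable = [
        n
        for n in roots
        if primary.authorize(
            session.username, "read", "master", n.site, audit_denial=False
        )
    ]
    if selector and "subject_index" in selector:
        idx = selector["subject_index"]
        if idx < 0 or idx >= len(readable):
            raise NotFoundError(f"no readable subject at index {idx}")
        readable = [readable[idx]]
    return readable


def _primary_rows_and_pairs(
    primary: BackendService, session_id: str, roots, mode: str
) -> tuple[list[dict[str, Any]], list[list[str]]]:
    temp_ids, pairs = primary.issue_temp_ids([n.node_id for n in roots], mode=mode)
    rows = []
    for temp_id, node in zip(temp_ids, roots):
        loaded = primary.crud(session_id, "read", node_id=node.node_id)
        rows.append({"temp_id": temp_id, "master": dict(loaded.content)})
    return rows, pairs


def _secondary_fetch(
    secondary: BackendService, username: str, id_pairs
) -> tuple[list[dict[str, Any]], list[str]]:
    """Look up payload documents per (temp_id, ns_b pseudonym) pair."""
    results = []
    unmatched = []
    for temp_id, b_value in id_pairs:
        if b_value is None:
            unmatched.append(temp_id)
            continue
        docs = secondary.store.children(b_value)
        if not docs and secondary.store.get(b_value) is None:
            # Fresh pair with no documents yet is an empty (not missing) set
            # only if the subject group is known; otherwise report unmatched.
            unmatched.append(temp_id)
            continue
        allowed_docs = []
        for doc in docs:
            from .backends import data_class_of

            dclass = data_class_of(doc.doc_type, is_root=False)
            if secondary.authorize(username, "read", dclass, doc.site):
                secondary._audit(username, "read", doc.node_id, "ok")
                allowed_docs.append(doc)
        results.append({"temp_id": temp_id, "payload": _flatten_docs(allowed_docs)})
    return results, unmatched


# ---------------------------------------------------------------------------
# Client
# ---------------------------------------------------------------------------


class Client:
    """Client-side orchestrator: holds per-endpoint sessions, joins locally.

    The client never sees internal pseudonyms (it receives temporary
    identifiers and opaque sealed tokens) and submits interactive
    credentials exactly once per session; all further hops authenticate via
    the credentials sealed inside tokens.
    """

    def __init__(self, system, username: str, secret: str) -> None:
        self.system = system
        self.username = username
        self._secret = secret
        self.sessions: dict[str, str] = {}  # endpoint -> session id
        self.credential_submissions = 0

    # -- session management --------------------------------------------------

    def login(self) -> str:
        """Interactive login at the primary service (once per session)."""
        primary = self.system.primary
        if primary.component_id not in self.sessions:
            self.credential_submissions += 1
            self.sessions[primary.component_id] = primary.authenticate(
                self.username, self._secret
            )
        return self.sessions[primary.component_id]

    # -- indirect single-record join (six steps, all via the client) ---------

    def join_indirect_single(
        self, selector: Mapping[str, Any]
    ) -> tuple[IntegratedView, Transcript]:
        system = self.system
        if system.mode != "indirect":
            raise AuthorizationError("system is not in indirect mode")
        session_id = self.login()
        primary, ms, secondary = system.primary, system.mapping_service, system.secondary
        t = Transcript()

        # Step 1: client requests the data item from the primary service.
        t.message(CLIENT, primary.component_id, "request",
                  {"op": "join", "selector": dict(selector)}, visible=True)
        roots = _primary_select_roots(primary, session_id, selector)
        rows, pairs = _primary_rows_and_pairs(primary, session_id, roots, "indirect")
        session = primary.sessions[session_id]
        token_ms = primary.seal_for(
            ms.component_id, session.username, session.secret,
            {"op": "translate", "id_pairs": pairs},
        )
        # Step 2: response with substituted identifiers plus a sealed token.
        t.message(primary.component_id, CLIENT, "response",
                  {"rows": rows, "token": encode_request_line(token_ms)}, visible=True)

        # Step 3: client forwards the token to the mapping service.
        t.message(CLIENT, ms.component_id, "request",
                  {"op": "translate", "token": encode_request_line(token_ms)},
                  visible=True)
        token_b2 = ms.translate(token_ms, secondary.component_id)
        # Step 4: mapping service returns a token for the secondary service.
        t.message(ms.component_id, CLIENT, "response",
                  {"token": encode_request_line(token_b2)}, visible=True)

        # Step 5: client forwards that token to the secondary service.
        t.message(CLIENT, secondary.component_id, "request",
                  {"op": "fetch", "token": encode_request_line(token_b2)},
                  visible=True)
        payload_in = secondary.open_incoming(token_b2)
        results, unmatched = _secondary_fetch(
            secondary, payload_in.username, payload_in.payload["id_pairs"]
        )
        # Step 6: secondary returns the data keyed by temporary identifiers.
        t.message(secondary.component_id, CLIENT, "response",
                  {"results": results, "unmatched": unmatched}, visible=True)

        view = self._join(rows, results, unmatched)
        return view, t

    # -- direct single-record join (nine steps, server-to-server sync) -------

    def join_direct_single(
        self, selector: Mapping[str, Any]
    ) -> tuple[IntegratedView, Transcript]:
        system = self.system
        if system.mode != "direct":
            raise AuthorizationError("system is not in direct mode")
        session_id = self.login()
        primary, ms, secondary = system.primary, system.mapping_service, system.secondary
        t = Transcript()

        # Step 1: client requests the data item from the primary service.
        t.message(CLIENT, primary.component_id, "request",
                  {"op": "join", "selector": dict(selector)}, visible=True)
        roots = _primary_select_roots(primary, session_id, selector)
        rows, pairs = _primary_rows_and_pairs(primary, session_id, roots, "direct")
        # Step 2: the primary persists the temp-id association (local).
        t.local(primary.component_id, "persist temporary identifier mapping")
        session = primary.sessions[session_id]
        sso = primary.seal_for(
            secondary.component_id, session.username, session.secret, {"op": "sso"}
        )
        # Step 3: response to the client with substituted identifiers.
        t.message(primary.component_id, CLIENT, "response",
                  {"rows": rows, "sso": encode_request_line(sso)}, visible=True)

        temp_id = rows[0]["temp_id"]
        # Step 4: client requests the payload item by temporary identifier.
        t.message(CLIENT, secondary.component_id, "request",
                  {"op": "fetch_direct", "temp_id": temp_id,
                   "sso": encode_request_line(sso)}, visible=True)
        sso_payload = secondary.open_incoming(sso)
        # Step 5: the secondary asks the primary to resolve the temp id
        # (direct server-to-server message, not visible to the client).
        resolve_req = secondary.seal_for(
            primary.component_id, sso_payload.username, sso_payload.password,
            {"op": "resolve_temp", "ids": [temp_id]},
        )
        t.message(secondary.component_id, primary.component_id, "request",
                  {"token": encode_request_line(resolve_req)}, visible=False)
        req_payload = primary.open_incoming(resolve_req)
        # Step 6: the primary resolves from its persisted mappings (local).
        internal = primary.resolve_persisted_temp(req_payload.payload["ids"][0])
        t.local(primary.component_id, "resolve persisted temporary mapping")
        # Steps 7-8: the answer is routed through the mapping service.
        answer = primary.seal_for(
            ms.component_id, req_payload.username, req_payload.password,
            {"op": "translate", "id_pairs": [[temp_id, internal]]},
        )
        t.message(primary.component_id, ms.component_id, "response",
                  {"token": encode_request_line(answer)}, visible=False)
        forwarded = ms.forward(answer, secondary.component_id)
        t.message(ms.component_id, secondary.component_id, "response",
                  {"token": encode_request_line(forwarded)}, visible=False)
        fwd_payload = secondary.open_incoming(forwarded)
        results, unmatched = _secondary_fetch(
            secondary, fwd_payload.username, fwd_payload.payload["id_pairs"]
        )
        # Step 9: the secondary delivers the data entry to the client.
        t.message(secondary.component_id, CLIENT, "response",
                  {"results": results, "unmatched": unmatched}, visible=True)

        view = self._join(rows, results, unmatched)
        return view, t

    # -- batch list view (three message rounds) -------------------------------

    def list_view(
        self, selector: Mapping[str, Any] | None = None
    ) -> tuple[IntegratedView, Transcript]:
        system = self.system
        session_id = self.login()
        primary, ms, secondary = system.primary, system.mapping_service, system.secondary
        t = Transcript()

        t.message(CLIENT, primary.component_id, "request",
                  {"op": "list", "selector": dict(selector or {})}, visible=True)
        roots = _primary_select_roots(primary, session_id, selector)
        rows, pairs = _primary_rows_and_pairs(primary, session_id, roots, "indirect")
        if not rows:
            t.message(primary.component_id, CLIENT, "response",
                      {"rows": [], "token": None}, visible=True)
            return IntegratedView(rows=[], unmatched=[]), t
        session = primary.sessions[session_id]
        token_ms = primary.seal_for(
            ms.component_id, session.username, session.secret,
            {"op": "translate", "id_pairs": pairs},
        )
        t.message(primary.component_id, CLIENT, "response",
                  {"rows": rows, "token": encode_request_line(token_ms)}, visible=True)

        t.message(CLIENT, ms.component_id, "request",
                  {"op": "translate", "token": encode_request_line(token_ms)},
                  visible=True)
        token_b2 = ms.translate(token_ms, secondary.component_id)
        t.message(ms.component_id, CLIENT, "response",
                  {"token": encode_request_line(token_b2)}, visible=True)

        t.message(CLIENT, secondary.component_id, "request",
                  {"op": "fetch", "token": encode_request_line(token_b2)},
                  visible=True)
        payload_in = secondary.open_incoming(token_b2)
        results, unmatched = _secondary_fetch(
            secondary, payload_in.username, payload_in.payload["id_pairs"]
        )
        t.message(secondary.component_id, CLIENT, "response",
                  {"results": results, "unmatched": unmatched}, visible=True)

        view = self._join(rows, results, unmatched)
        return view, t

    # -- eCRF creation cascade (single sign-on) --------------------------------

    def create_ecrf(
        self,
        selector: Mapping[str, Any],
        doc_type: str,
        content: Mapping[str, str],
    ) -> tuple[str, Transcript]:
        """Create a payload document for a subject across the cascade.

        The first request carries the interactive credentials; every later
        hop authenticates via credentials sealed inside tokens (single
        sign-on).  Document content travels client -> secondary directly and
        never through the mapping service.
        """
        system = self.system
        primary, ms, secondary = system.primary, system.mapping_service, system.secondary
        t = Transcript()

        # Step 1: first request, carrying credentials (interactive login).
        self.credential_submissions += 1
        t.message(CLIENT, primary.component_id, "request",
                  {"op": "create_ecrf", "selector": dict(selector),
                   "doc_type": doc_type, "username": self.username,
                   "password": self._secret}, visible=True)
        session_id = primary.authenticate(self.username, self._secret)
        self.sessions[primary.component_id] = session_id
        roots = _primary_select_roots(primary, session_id, selector)
        if not roots:
            raise NotFoundError("subject not found")
        node = roots[0]
        from .backends import data_class_of

        dclass = data_class_of(doc_type, is_root=False)
        if not primary.authorize(self.username, "create", dclass, node.site):
            raise AuthorizationError(
                f"creation of {dclass} documents denied at the primary service"
            )
        temp_ids, pairs = primary.issue_temp_ids([node.node_id], mode="indirect")
        token_ms = primary.seal_for(
            ms.component_id, self.username, self._secret,
            {"op": "create_doc", "id_pairs": pairs, "doc_type": doc_type,
             "site": node.site},
        )
        # Step 2: token for the mapping service.
        t.message(primary.component_id, CLIENT, "response",
                  {"temp_id": temp_ids[0], "token": encode_request_line(token_ms)},
                  visible=True)

        # Steps 3-4: namespace translation (creates the pair if missing).
        t.message(CLIENT, ms.component_id, "request",
                  {"op": "create_doc", "token": encode_request_line(token_ms)},
                  visible=True)
        token_b2 = ms.translate(token_ms, secondary.component_id, create_missing=True)
        t.message(ms.component_id, CLIENT, "response",
                  {"token": encode_request_line(token_b2)}, visible=True)

        # Step 5: token plus document content to the secondary service.
        t.message(CLIENT, secondary.component_id, "request",
                  {"op": "create_doc", "token": encode_request_line(token_b2),
                   "content": dict(content)}, visible=True)
        payload_in = secondary.open_incoming(token_b2)
        (temp_id, b_value), = payload_in.payload["id_pairs"]
        site = payload_in.payload["site"]
        if not secondary.authorize(payload_in.username, "create", dclass, site):
            raise AuthorizationError(
                f"creation of {dclass} documents denied at the secondary service"
            )
        siblings = secondary.store.children(b_value)
        ordinal = sum(1 for d in siblings if d.doc_type == doc_type)
        sid = secondary.authenticate(payload_in.username, payload_in.password)
        new_node = secondary.crud(
            sid, "create", parent=b_value, doc_type=doc_type,
            content=dict(content), site=site, label=f"{doc_type}#{ordinal}",
        )
        doc_temp_refs, _ = secondary.issue_temp_ids([new_node.node_id], mode="indirect")
        # Step 6: response with the new document's temporary reference.
        t.message(secondary.component_id, CLIENT, "response",
                  {"temp_id": temp_id, "doc_temp_ref": doc_temp_refs[0]},
                  visible=True)
        return doc_temp_refs[0], t

    # -- client-side join ------------------------------------------------------

    @staticmethod
    def _join(rows, results, unmatched) -> IntegratedView:
        by_temp = {r["temp_id"]: r.get("payload", {}) for r in results}
        joined = []
        missing = list(unmatched)
        for row in rows:
            tid = row["temp_id"]
            if tid in by_temp:
                joined.append(
                    {"temp_id": tid, "master": row["master"], "payload": by_temp[tid]}
                )
            elif tid not in missing:
                missing.append(tid)
        return IntegratedView(rows=joined, unmatched=missing)
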