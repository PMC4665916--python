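"""System-level invariant suite.

Four classes of checks certify a deployed system and a set of protocol
transcripts:

* **separation** — an adversary holding any *single* party's persistent
  state (including its keys) cannot produce a single (identifying, payload)
  attribute pairing: the data pools hold one category each and the mapping
  service holds links but no attributes;
* **confidentiality** — the concatenation of all client-visible transcript
  bytes contains no internal pseudonym of any namespace;
* **audit completeness** — audit sequences are gapless and every executed
  mutation produced exactly one audit event;
* **RBAC soundness** — randomized operation fuzzing never yields an allow
  outside the declared role matrix.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

from .backends import (
    AuthorizationError,
    BackendService,
    ChildrenExistError,
    NotFoundError,
    data_class_of,
)
from .protocols import Transcript, assert_confidential
from .synth import Registry


def adversary_join(exposed: Mapping[str, Any]) -> list[tuple[str, str]]:
    """Attempt the identifying x payload join from one party's state alone.

    Returns every (identifying attrs, payload attrs) pairing derivable from
    that state: via shared keys (one-tier style) or via link pairs held by
    the same party.  A compliant deployment yields zero pairings for every
    single party.
    """
    identifying = exposed["identifying"]
    payload = exposed["payload"]
    links = exposed["links"]
    pairs: list[tuple[str, str]] = []
    for key in set(identifying) & set(payload):
        pairs.append((key, key))
    for a, b in links:
        if a in identifying and b in payload:
            pairs.append((a, b))
    return pairs


def separation_violations(system) -> dict[str, int]:
    """Linked-pair count per party; all must be zero."""
    return {
        party.component_id: len(adversary_join(party.exposed_state()))
        for party in system.services()
    }


def confidentiality_violations(
    system, transcripts: Iterable[Transcript]
) -> list[tuple[str, str]]:
    internal = system.internal_pseudonym_values()
    violations: list[tuple[str, str]] = []
    for transcript in transcripts:
        violations.extend(assert_confidential(transcript, internal).violations)
    return violations


def audit_gapless(service) -> bool:
    return all(event.seq == i for i, event in enumerate(service.audit))


@dataclass
class FuzzReport:
    operations: int = 0
    allowed: int = 0
    denied: int = 0
    matrix_violations: list[str] = field(default_factory=list)
    mutations_executed: dict[str, int] = field(default_factory=dict)
    mutation_audit_events: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.matrix_violations and (
            self.mutations_executed == self.mutation_audit_events
        )


def rbac_fuzz(system, registry: Registry, n_ops: int, seed: int) -> FuzzReport:
    """Fuzz CRUD operations with random users against both data backends.

    Every allow outcome is cross-checked against the declared role matrix
    (including the site filter); executed mutations are tallied per backend
    and compared with the audit trail's mutation events.
    """
    rng = random.Random(seed)
    report = FuzzReport()
    backends: list[BackendService] = [system.primary, system.secondary]
    sessions: dict[tuple[str, str], str] = {}
    baseline = {b.component_id: b.mutation_audit_count() for b in backends}
    executed = {b.component_id: 0 for b in backends}
    users = registry.users

    for _ in range(n_ops):
        backend = rng.choice(backends)
        user = rng.choice(users)
        op = rng.choice(["create", "read", "update", "delete"])
        key = (backend.component_id, user.username)
        if key not in sessions:
            sessions[key] = backend.authenticate(user.username, user.secret)
        session_id = sessions[key]

        nodes = backend.store.all()
        target = rng.choice(nodes) if nodes else None
        if op == "create":
            is_primary = backend is system.primary
            doc_type = "master" if is_primary else rng.choice(
                ["baseline_visit", "specimen_registration"]
            )
            parent = None if is_primary else (target.parent if target else None)
            site = rng.choice(registry.sites)
            dclass = data_class_of(doc_type, is_root=parent is None)
            expected = _matrix_allows(backend, user, "create", dclass, site)
            report.operations += 1
            try:
                backend.crud(
                    session_id, "create", parent=parent, doc_type=doc_type,
                    content={"k": "v"}, site=site,
                )
                outcome_allowed = True
                executed[backend.component_id] += 1
            except AuthorizationError:
                outcome_allowed = False
            _tally(report, backend, user, op, dclass, site, expected, outcome_allowed)
            continue

        if target is None:
            continue
        dclass = data_class_of(target.doc_type, target.parent is None)
        expected = _matrix_allows(backend, user, op, dclass, target.site)
        report.operations += 1
        outcome_allowed = False
        try:
            if op == "read":
                backend.crud(session_id, "read", node_id=target.node_id)
                outcome_allowed = True
            elif op == "update":
                backend.crud(
                    session_id, "update", node_id=target.node_id,
                    content={"k": f"v{rng.randrange(100)}"},
                )
                outcome_allowed = True
                executed[backend.component_id] += 1
            else:
                # cascade=False: succeeds only on leaf nodes, one audit event
                backend.crud(session_id, "delete", node_id=target.node_id)
                outcome_allowed = True
                executed[backend.component_id] += 1
        except AuthorizationError:
            outcome_allowed = False
        except (NotFoundError, ChildrenExistError):
            # Authorized but inapplicable: not a matrix decision.
            report.operations -= 1
            continue
        _tally(report, backend, user, op, dclass, target.site, expected, outcome_allowed)

    report.mutations_executed = executed
    report.mutation_audit_events = {
        b.component_id: b.mutation_audit_count() - baseline[b.component_id]
        for b in backends
    }
    return report


def _matrix_allows(backend: BackendService, user, op: str, dclass: str, site: str) -> bool:
    allowed = op in backend.rbac.get(user.role, {}).get(dclass, frozenset())
    if allowed and user.role in backend.site_restricted_roles and site != user.site:
        allowed = False
    return allowed


def _tally(report, backend, user, op, dclass, site, expected, outcome_allowed) -> None:
    if outcome_allowed:
        report.allowed += 1
        if not expected:
            report.matrix_violations.append(
                f"{backend.component_id}: {user.role} {user.username} allowed "
                f"{op} on {dclass}@{site} outside the matrix"
            )
    else:
        report.denied += 1
        if expected:
            report.matrix_violations.append(
                f"{backend.component_id}: {user.role} {user.username} denied "
                f"{op} on {dclass}@{site} inside the matrix"
            )


def run_invariant_suite(
    system,
    transcripts: Iterable[Transcript],
    registry: Registry | None = None,
    fuzz_ops: int = 500,
    seed: int = 0,
) -> dict[str, bool]:
    """Run all invariants; returns a pass/fail map per invariant name."""
    results: dict[str, bool] = {}
    results["separation"] = all(
        v == 0 for v in separation_violations(system).values()
    )
    results["confidentiality"] = not confidentiality_violations(system, transcripts)
    results["audit_gapless"] = all(audit_gapless(s) for s in system.services())
    if registry is not None:
        report = rbac_fuzz(system, registry, fuzz_ops, seed)
        results["rbac_soundness"] = not report.matrix_violations
        results["audit_completeness"] = (
            report.mutations_executed == report.mutation_audit_events
        )
    return results
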