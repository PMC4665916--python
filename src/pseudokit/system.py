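"""Wiring: build the three-party system from a generated registry.

``deploy`` provisions the primary service (master-data roots), the
secondary service (payload document nodes grouped per subject) and the
mapping service (bare pseudonym pairs), registers every user at every
component (non-delegated authentication requires local directories), and
exchanges public keys peer-to-peer.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .backends import BackendService, DocumentNode, DocumentStore, MappingService
from .model import Namespace
from .synth import Registry
from .tokens import generate_keypair

PRIMARY_ID = "primary"
SECONDARY_ID = "secondary"
MAPPING_ID = "mapping"


@dataclass
class System:
    primary: BackendService
    secondary: BackendService
    mapping_service: MappingService
    mode: str
    ns_a: Namespace
    ns_b: Namespace
    sites: list[str] = field(default_factory=list)

    def services(self):
        return (self.primary, self.secondary, self.mapping_service)

    def internal_pseudonym_values(self) -> dict[str, set[str]]:
        """All internal pseudonyms per namespace, for confidentiality scans."""
        ns_a_values: set[str] = set()
        ns_b_values: set[str] = set()
        for node in self.primary.store.all():
            ns_a_values.add(node.node_id)
        for node in self.secondary.store.all():
            ns_b_values.add(node.node_id)
            if node.parent:
                ns_b_values.add(node.parent)
        for pa, pb in self.mapping_service.table.pairs:
            ns_a_values.add(pa.value)
            ns_b_values.add(pb.value)
        return {self.ns_a.id: ns_a_values, self.ns_b.id: ns_b_values}


def deploy(
    registry: Registry,
    *,
    mode: str = "indirect",
    seed: int = 0,
    store_factory=None,
    encrypt_master: bool = True,
    rbac=None,
    site_restricted_roles=None,
) -> System:
    """Provision a running three-party system from a synthetic registry."""
    if mode not in ("indirect", "direct"):
        raise ValueError(f"mode must be 'direct' or 'indirect', got {mode!r}")
    backend_kw = {}
    if rbac is not None:
        backend_kw["rbac"] = rbac
    if site_restricted_roles is not None:
        backend_kw["site_restricted_roles"] = frozenset(site_restricted_roles)
    rng = random.Random(seed)
    ns_a = Namespace("ns-primary")
    ns_b = Namespace("ns-secondary")

    kp_primary = generate_keypair(PRIMARY_ID, random.Random(rng.getrandbits(31)))
    kp_secondary = generate_keypair(SECONDARY_ID, random.Random(rng.getrandbits(31)))
    kp_mapping = generate_keypair(MAPPING_ID, random.Random(rng.getrandbits(31)))

    master_key = rng.getrandbits(256).to_bytes(32, "big")
    primary = BackendService(
        PRIMARY_ID,
        ns_a,
        kp_primary,
        store=store_factory() if store_factory else None,
        encrypt_master=encrypt_master,
        master_data_key=master_key if encrypt_master else None,
        seed=rng.getrandbits(31),
        **backend_kw,
    )
    secondary = BackendService(
        SECONDARY_ID,
        ns_b,
        kp_secondary,
        store=store_factory() if store_factory else None,
        seed=rng.getrandbits(31),
        **backend_kw,
    )
    mapping = MappingService(
        MAPPING_ID, kp_mapping, ns_a, ns_b, seed=rng.getrandbits(31)
    )

    for service in (primary, secondary, mapping):
        for peer in (primary, secondary, mapping):
            if peer.component_id != service.component_id:
                service.register_peer(peer.component_id, peer.ring.own.public_part)

    for user in registry.users:
        primary.add_user(user.username, user.secret, user.role, user.site)
        secondary.add_user(user.username, user.secret, user.role, user.site)
        mapping.add_user(user.username, user.secret, user.role, user.site)

    # Initial provisioning is an out-of-band load, not a user operation: it
    # writes the stores directly and is not audited.
    for subject in registry.subjects:
        a_value = primary.fresh_pseudonym()
        root = DocumentNode(
            node_id=a_value,
            parent=None,
            doc_type="master",
            content=dict(subject.identifying),
            site=subject.site,
            label="master",
        )
        primary.store.put(primary._store_content(root))
        b_value = secondary.fresh_pseudonym()
        mapping.add_pair(a_value, b_value)
        counters: dict[str, int] = {}
        for doc in subject.documents:
            ordinal = counters.get(doc.doc_type, 0)
            counters[doc.doc_type] = ordinal + 1
            secondary.store.put(
                DocumentNode(
                    node_id=secondary.fresh_pseudonym(),
                    parent=b_value,
                    doc_type=doc.doc_type,
                    content=dict(doc.content),
                    site=subject.site,
                    label=f"{doc.doc_type}#{ordinal}",
                )
            )

    return System(
        primary=primary,
        secondary=secondary,
        mapping_service=mapping,
        mode=mode,
        ns_a=ns_a,
        ns_b=ns_b,
        sites=list(registry.sites),
    )
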