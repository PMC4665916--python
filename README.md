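# pseudokit

Two-tier pseudonymized data management for multi-site biomedical
registries, as a testable Python framework.

Data protection law and standards for health research (e.g. ISO 25237)
require that personally **identifying** data be kept separate from
substantive **payload** data, linked only through arbitrary codes
(pseudonyms). `pseudokit` implements the full machinery this requires for
a prospective research registry, for people who build or evaluate such
systems:

* **Data-layer separation** — an integrated per-subject record is split
  into a *master-data pool* (identifying attributes) and a *payload pool*
  (clinical/document attributes). In **one-tier** pseudonymization both
  pools share one pseudonym per record; in **two-tier** pseudonymization
  each pool lives in its own namespace and a dedicated *mapping service*
  holds the only link — a table of bare pseudonym pairs
  (psn<sub>A</sub>, psn<sub>B</sub>).
* **Three separated parties** — a primary service (master data, encrypted
  at rest), a secondary service (payload documents / eCRFs) and the
  mapping service, each with its own namespace, user directory,
  non-delegated authentication, role-based access control with a
  site-based view, and a gapless append-only audit trail.
* **Sealed access tokens** — server-to-server traffic is routed *via the
  client* inside two-component hybrid-encrypted tokens: component 1 is a
  fresh symmetric key K₁ encrypted for the receiver's public key K₂,
  E<sub>K₂</sub>(K₁); component 2 is
  E<sub>K₁</sub>(username, password, counter, P). A strictly increasing
  per-channel counter defeats replay; tokens double as the single-sign-on
  mechanism. Long request lines are fragmented under the classic
  2083-character URL limit and reassembled losslessly.
* **Client-side recombination** — the integrated view is reconstructed
  only at the client, keyed by *temporary identifiers*, so no server ever
  holds the joined data and the client never learns an internal
  pseudonym. The indirect single-record join takes exactly 6 enumerated
  steps; the direct variant takes 9 steps with at least 7 message
  exchanges and routes its answer through the mapping service.

A deterministic synthetic-registry generator supplies all fixtures, so
everything is testable without any real data.

## Worked example

```bash
pseudokit demo --seed 0
```

```
{"event": "demo.separation", "mapping_pairs": 3, "master_pool": 3, "payload_pool": 3, "records": 3, "reintegrated": 3, "unmatched": 0}
{"event": "demo.join_indirect", "messages": 6, "rows": 1, "steps": 6}
{"event": "demo.join_direct", "messages": 7, "rows": 1, "steps": 9}
```

The first line is the canonical three-record dataset (identifying values
A, B, C; payload values D, E, F): two-tier separation produces two
3-entry pools plus 3 mapping pairs, and de-pseudonymization reconstructs
all 3 records with nothing unmatched. The next lines run both join
protocols end to end on a 10-subject synthetic registry: the indirect
join completes in 6 steps (all messages via the client), the direct join
in 9 steps with 7 message exchanges.

The same from the library:

```python
import pseudokit as pk

ds = pk.example_three_subjects()
master, payload, mapping = pk.pseudonymize_two_tier(
    ds, pk.Namespace("ns-a"), pk.Namespace("ns-b"), rng_seed=0)
result = pk.integrate(master, payload, mapping)
assert pk.datasets_equivalent(result.dataset, ds)

registry = pk.generate_registry(pk.GeneratorSpec(n_subjects=10, seed=42))
system = pk.deploy(registry, mode="indirect", seed=1)
user = next(u for u in registry.users if u.role == "physician")
client = pk.Client(system, user.username, user.secret)
view, transcript = client.list_view()      # 4 rows: site-based view
report = pk.assert_confidential(transcript, system.internal_pseudonym_values())
assert report.ok                           # no internal pseudonym leaked
```

Other CLI subcommands: `gen-data` (write a registry as CSV + schema),
`run` (execute a protocol, dump transcript and view files), `verify`
(full invariant suite; exit code 1 on any failure), `audit-dump`.

## Layout

```
src/pseudokit/
  model.py        data-layer separation and de-pseudonymization
  hybridcrypto.py KEM + AEAD primitives (named cipher suite)
  tokens.py       sealed tokens, replay state, URL encoding, fragmentation
  backends.py     primary/secondary/mapping services, RBAC, audit, stores
  protocols.py    client-orchestrated joins, transcripts, confidentiality
  synth.py        deterministic synthetic registry generator
  system.py       deployment wiring
  verify.py       invariant suite (separation, confidentiality, fuzzing)
  cli.py          command-line scenarios
docs/methods.md   design and methods notes
```
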