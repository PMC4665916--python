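# Methods and design notes

## The model

A registry record is modelled as an *integrated record*: a subject key
plus attributes, each declared `identifying` or `payload` at dataset
definition time. Which attributes of a real dataset are identifying is a
governance decision with no technical answer (diagnosis codes, for
instance, can re-identify); the package therefore refuses to infer
categories and requires an explicit schema. Two categories are modelled;
finer typologies (e.g. separating biospecimen-management data) reduce to
additional payload document types.

Separation produces pseudonym-keyed pools. Pseudonyms are 128-bit values
from a seedable RNG, rendered as 32 lowercase hex characters — never
derived from record content, so pseudonyms generated under different
seeds for identical data share nothing. In two-tier separation the two
pools draw from disjoint value sets and the mapping table of bare
(psn_A, psn_B) pairs is the unique linking artifact: deleting it reduces
the exhaustive join to zero records. The mapping service stores bare
pairs only — no timestamps, no attributes — keeping its breach surface
minimal; if operational metadata is ever needed it belongs in the audit
trail, not the table.

De-pseudonymization (`integrate`) is deliberately total: entries without
a partner and pairs pointing at absent entries are returned in a side
report rather than raised, because partial joins are legitimate in
exception workflows. Reconstructed records are keyed by the master-pool
pseudonym; source subject keys are unrecoverable by design, so record
equality throughout the package is order- and key-insensitive comparison
of attribute multisets.

## Token infrastructure

Tokens are the secure server-to-server channel routed via the client and
simultaneously the single-sign-on mechanism. Each token has exactly two
components: a key encapsulation of a fresh symmetric key K1 for the
receiver, and the payload (username, password, counter, structured
content P) authenticated-encrypted under K1. Payloads are canonically
serialized (sorted-key JSON, fixed separators) before encryption so
integrity checks are deterministic.

The default cipher suite, `dhies-modp2048-hs256`, is DHIES-style hybrid
encryption: ephemeral–static finite-field Diffie-Hellman over the
RFC 3526 2048-bit MODP group (short 256-bit exponents, 128-bit security
level) with HKDF-SHA256 key derivation, and encrypt-then-MAC AEAD built
from an HMAC-SHA256 counter-mode keystream plus an HMAC-SHA256 tag over
(aad, nonce, ciphertext). Both components are integrity protected, and
the routing metadata (sender, receiver, suite) is bound into the AAD so
a re-addressed token fails authentication. Tags are verified before any
plaintext is released: every single-byte corruption surfaces as an
integrity error, never as garbled output, which the exhaustive byte-flip
suite confirms structurally rather than statistically. The suite is a
named, registered object so alternative KEM/AEAD pairs can be substituted
without touching the token layer.

Replay protection is a counter scoped **per sender→receiver channel**
with strictly-greater acceptance and no window. A single global counter
across parties would require coordination between components that are
organizationally separated by design; channel scoping preserves the
guarantee (no token is ever accepted twice by any receiver) without it.
The counter is bound to the channel, not to the user session — binding it
to sessions would add nothing, since the credentials inside the payload
are already verified per request. Receivers advance their replay state
only after full integrity verification succeeds.

Transport: tokens encode to unpadded base64url for embedding in an HTTP
request line. Requests longer than the limit (default 2083 characters,
the strictest common browser URL limit) are fragmented; each fragment
carries a request id (16 hex chars derived from the content hash, making
fragmentation deterministic), its index, the total count and a chunk.
Reassembly is order-insensitive, detects missing indices by name and
rejects conflicting duplicates.

## Backends

Each data-holding party stores documents as a tree: the root node of a
subject holds master data (primary service only), non-root nodes hold
payload documents (secondary service only). The storage contract is a
small interface with an in-memory implementation and a single-file
embedded-SQL (sqlite3) implementation; the tests exercise the contract,
not an engine. `dump_bytes()` exposes the serialized store as an
adversary reading the medium would see it, which is how the
encryption-at-rest check works: with master-data encryption enabled
(refused at startup without a key), identifying values are
AEAD-encrypted per node before hitting the store and transparently
decrypted on read; payload backends are unaffected.

Authentication is non-delegated: every component verifies credentials
itself, on login and again on every token hop. Secrets rest as
PBKDF2-HMAC-SHA256 hashes (50,000 iterations, per-user salt); a per
service in-memory cache of successfully verified credentials keeps
re-verification cheap without changing the protocol. Unknown users and
wrong passwords are indistinguishable, and failed verifications burn
comparable work. Sessions are random ids held by the client in an
endpoint→session map (the cookie equivalent); session objects keep the
cleartext secret in memory only, because outgoing tokens must embed the
user's credentials for the next hop's own verification. The mapping
service authenticates end users as well as peers — the stricter of the
two defensible choices; authenticating only peer components would let
any authenticated component translate on behalf of anyone.

Authorization is a static role × data-class × operation matrix with four
default roles: administrators manage accounts and have no access to any
research data; monitors read master/clinical/specimen data across all
sites (quality assurance; site-restricting them is a config switch);
physicians have full CRUD on master and clinical data restricted to
their own institution; lab personnel manage specimen documents at their
site. Denials are values, not exceptions, and are audited, so fuzzing
can count them. Audit trails are append-only with gapless per-backend
sequence numbers; every executed mutation appends exactly one event per
node touched.

Temporary identifiers carry a `t-` prefix so they can never collide with
internal 32-hex pseudonyms. In indirect mode the temp↔internal
association exists only inside sealed tokens (backends stay stateless);
in direct mode it is persisted and retired on first successful
resolution (delete-on-use), because no clean deletion point exists
otherwise without transactional protocols across parties.

## Protocols

All flows are driven by the client over an in-process synchronous
message bus; the protocols are defined by message content and routing,
not by browser machinery, so presentation-layer mechanics (framesets,
script-tag transport, same-origin policy) are abstracted into the single
constraint they impose: joining happens client-side only. Transcripts
record every step as either a message (with direction, client visibility
and a body digest) or a local action.

* *Indirect single-record join* — 6 steps, all messages via the client:
  client→primary; primary→client (master row keyed by a temp id, plus a
  sealed token for the mapping service); client→mapping; mapping→client
  (token for the secondary, ids translated); client→secondary;
  secondary→client (payload keyed by the temp id).
* *Direct single-record join* — 9 steps, 7 of them messages: the primary
  persists the temp association (local step), the secondary requests
  resolution directly from the primary, the primary resolves from its
  persisted map (local step), and the answer routes
  primary→mapping→secondary, never primary-to-secondary directly. The
  resolution *request* travels secondary→primary directly while only the
  *answer* is relayed — the enumerated step structure fixes this reading,
  though routing the request through the mapping service as well would
  be a defensible alternative. The client authenticates at the secondary
  with an SSO token minted by the primary, so one interactive credential
  submission still suffices.
* *Batch list view* — three message rounds regardless of batch size
  (primary, mapping, secondary, each handling all subjects at once),
  short-circuiting after the first round when no row is visible.
* *eCRF creation cascade* — the first request carries the interactive
  credentials; every later hop authenticates via token. The mapping
  service creates the subject's ns_B pseudonym and table pair if missing
  (so the table grows by at most one pair). Document content travels
  client→secondary directly and never through the mapping service, which
  accordingly never handles attribute values even in transit.

Confidentiality is checked, not assumed: `assert_confidential` scans the
concatenation of all client-visible message bodies for every internal
pseudonym of every namespace. Sealed tokens appear in those bodies as
base64url text, so a leak of a 32-hex pseudonym is detectable by plain
substring scan; the test hook that disables temp-id substitution
produces exactly the leak class the verifier must catch.

## Synthetic data

The generator emulates a small multi-site observational rare-disease
registry: identifying attributes (synthetic name from a bundled invented
word list, birth date, institution), 1–3 structured payload documents
per subject drawn from three eCRF schemas (baseline visit, follow-up
visit, specimen registration), subjects assigned to sites round-robin,
and a user directory with one administrator, one monitor and a
physician/lab pair per site. Defaults are 10 subjects, 3 sites, 2
documents per subject. Output is byte-deterministic under the seed.

What it does **not** model: realistic clinical value distributions,
missingness, record-linkage noise, or free text. Passing tests therefore
demonstrate the correctness of separation, token security and protocol
logic — not that any particular real dataset's payload pool is safe
against statistical re-identification, which is an open problem outside
this package's scope.

## Problem sizes and numerical choices

The oracle-equivalence suite runs 100 seeded registries of 10–200
subjects: each registry is fully reconstructed through the batch
indirect join and compared record-for-record against the data-layer
`integrate` oracle, and the single-record direct protocol is verified on
three subjects per registry (first, middle, last) against their oracle
records; exhaustive per-subject direct-join coverage is additionally
proven on 10-subject registries in the unit suite. Replay rejection is
measured over 1,000 randomized attempts, tamper detection over an
exhaustive single-byte-flip loop (~450 flips on a short token), RBAC
soundness over 10,000 fuzzed operations. All randomness flows from
explicit seeds; hypothesis-based property tests are bounded and
deadline-free for determinism.

## Known limitations

* The HTTP shim is notional: the bus models request/response semantics
  1:1 but no network transport ships in the package.
* Pure-Python 2048-bit modular exponentiation makes token operations
  cost a few milliseconds each — fine for a reference implementation,
  not a production throughput target.
* Two-factor authentication, TLS deployment, IP filtering and other
  operational hardening are explicitly out of scope.
* One mapping service is wired; the data model (namespaces, pair tables)
  would support chains of more than two tiers, but no flow exercises
  that.
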