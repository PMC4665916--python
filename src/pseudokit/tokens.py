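"""Sealed two-component access tokens.

A token is the secure server-to-server channel of the system: it is created
by one component, carried by the client (which can neither read nor modify
it), and opened by exactly one receiving component.  It is built of two
encrypted components:

1. a fresh symmetric key ``K1``, asymmetrically encrypted and integrity
   protected under the receiver's public key;
2. the token payload — username, password, replay counter and structured
   content ``P`` — symmetrically encrypted and integrity protected under
   ``K1``.

Replay protection is a per sender→receiver counter: a receiver accepts a
token only if its counter is strictly greater than the highest counter it
has accepted from that sender before.

The module also provides the transport helpers: URL-safe request-line
encoding (base64url, unpadded) and request fragmentation under a maximum
request-line length (default 2083 characters, the strictest common browser
URL limit), with order-insensitive lossless reassembly.
"""

from __future__ import annotations

import base64
import binascii
import hashlib
import json
import random
import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

from .hybridcrypto import (
    DEFAULT_SUITE,
    SUITES,
    CipherSuite,
    IntegrityError,
    aead_open,
    aead_seal,
)

DEFAULT_MAX_REQUEST_LINE = 2083


class TokenError(Exception):
    """Base class for token failures."""


class UnknownPeerError(TokenError, KeyError):
    """No public key on the ring for the requested receiver."""


class TokenIntegrityError(TokenError):
    """Decryption/integrity failure: tampered bytes or wrong receiver key."""


class ReplayError(TokenError):
    """Counter not strictly greater than the last accepted one."""


class TokenDecodeError(TokenError):
    """Malformed request-line encoding."""


class FragmentError(TokenError):
    """Fragmentation framing violated (gap, conflict, mixed request ids)."""


@dataclass(frozen=True)
class KeyPair:
    component_id: str
    public_part: bytes
    private_part: bytes = field(repr=False)


@dataclass
class KeyRing:
    """Peer-to-peer key topology: every component knows every peer's public key."""

    own: KeyPair
    peers: dict[str, bytes] = field(default_factory=dict)
    suite: CipherSuite = DEFAULT_SUITE

    def public_key_of(self, component_id: str) -> bytes:
        if component_id == self.own.component_id:
            return self.own.public_part
        try:
            return self.peers[component_id]
        except KeyError:
            raise UnknownPeerError(
                f"no public key for component {component_id!r}"
            ) from None


def generate_keypair(
    component_id: str, rng: random.Random | None = None, suite: CipherSuite = DEFAULT_SUITE
) -> KeyPair:
    private, public = suite.generate_keypair(rng)
    return KeyPair(component_id=component_id, public_part=public, private_part=private)


@dataclass(frozen=True)
class TokenPayload:
    """Cleartext token content: credentials, replay counter, structured P."""

    username: str
    password: str
    counter: int
    payload: dict[str, Any] = field(default_factory=dict)

    def to_bytes(self) -> bytes:
        # Canonical encoding (sorted keys, fixed separators) so that
        # integrity checks are deterministic.
        return json.dumps(
            {
                "username": self.username,
                "password": self.password,
                "counter": self.counter,
                "payload": self.payload,
            },
            sort_keys=True,
            separators=(",", ":"),
        ).encode("utf-8")

    @classmethod
    def from_bytes(cls, raw: bytes) -> "TokenPayload":
        obj = json.loads(raw.decode("utf-8"))
        return cls(
            username=obj["username"],
            password=obj["password"],
            counter=int(obj["counter"]),
            payload=obj["payload"],
        )


@dataclass(frozen=True)
class SealedToken:
    """The two-component encrypted token plus routing metadata."""

    sender_id: str
    receiver_id: str
    suite: str
    component_1: bytes  # E_K2(K1): key encapsulation for the receiver
    component_2: bytes  # E_K1(username, password, counter, P)

    @property
    def components(self) -> tuple[bytes, bytes]:
        return (self.component_1, self.component_2)


@dataclass
class ReplayState:
    """Highest accepted counter per sender; monotonically non-decreasing."""

    last_accepted: dict[str, int] = field(default_factory=dict)

    def check_and_update(self, sender_id: str, counter: int) -> None:
        last = self.last_accepted.get(sender_id, -1)
        if counter <= last:
            raise ReplayError(
                f"counter {counter} from {sender_id!r} not greater than "
                f"last accepted {last}"
            )
        self.last_accepted[sender_id] = counter


def _aad(sender_id: str, receiver_id: str, suite: str) -> bytes:
    # Binds routing metadata to both components: re-addressing a token
    # invalidates it.
    return json.dumps([sender_id, receiver_id, suite]).encode("utf-8")


def seal_token(
    ring: KeyRing,
    receiver_id: str,
    payload: TokenPayload,
    rng_seed: int | None = None,
) -> SealedToken:
    """Seal a payload for one receiver with a fresh symmetric key K1.

    Even identical payloads seal to byte-distinct tokens because K1 and the
    nonces are fresh per call.
    """
    receiver_pub = ring.public_key_of(receiver_id)
    rng = random.Random(rng_seed) if rng_seed is not None else None
    if rng is None:
        import secrets

        k1 = secrets.token_bytes(32)
    else:
        k1 = rng.getrandbits(256).to_bytes(32, "big")
    aad = _aad(ring.own.component_id, receiver_id, ring.suite.name)
    component_1 = ring.suite.encapsulate(receiver_pub, k1, rng)
    component_2 = aead_seal(k1, payload.to_bytes(), aad=aad, rng=rng)
    return SealedToken(
        sender_id=ring.own.component_id,
        receiver_id=receiver_id,
        suite=ring.suite.name,
        component_1=component_1,
        component_2=component_2,
    )


def open_token(ring: KeyRing, token: SealedToken, replay: ReplayState) -> TokenPayload:
    """Open a token addressed to this ring's component.

    Order of checks: key decapsulation and payload integrity first (any
    tampering or misaddressing raises :class:`TokenIntegrityError`), then
    the replay counter (:class:`ReplayError`, a distinct condition).  The
    replay state is only advanced on full success.
    """
    suite = SUITES.get(token.suite)
    if suite is None:
        raise TokenIntegrityError(f"unknown cipher suite {token.suite!r}")
    try:
        k1 = suite.decapsulate(ring.own.private_part, token.component_1)
        aad = _aad(token.sender_id, token.receiver_id, token.suite)
        raw = aead_open(k1, token.component_2, aad=aad)
    except IntegrityError as exc:
        raise TokenIntegrityError(str(exc)) from exc
    if token.receiver_id != ring.own.component_id:
        # Decryption would normally already have failed; this guards the
        # degenerate case of components sharing key material.
        raise TokenIntegrityError("token not addressed to this component")
    try:
        payload = TokenPayload.from_bytes(raw)
    except (ValueError, KeyError) as exc:  # pragma: no cover - defensive
        raise TokenIntegrityError(f"payload malformed after decrypt: {exc}") from exc
    replay.check_and_update(token.sender_id, payload.counter)
    return payload


# ---------------------------------------------------------------------------
# Request-line transport
# ---------------------------------------------------------------------------

_B64 = dict(altchars=b"-_")


def _b64e(raw: bytes) -> str:
    return base64.b64encode(raw, **_B64).rstrip(b"=").decode("ascii")


def _b64d(text: str) -> bytes:
    pad = -len(text) % 4
    try:
        return base64.b64decode(text + "=" * pad, validate=True, **_B64)
    except (binascii.Error, ValueError) as exc:
        raise TokenDecodeError(f"invalid base64url: {exc}") from exc


URL_SAFE_RE = re.compile(r"^[A-Za-z0-9_.~-]*$")


def encode_request_line(token: SealedToken) -> str:
    """Encode a sealed token as a URL-safe request-line parameter value."""
    blob = json.dumps(
        {
            "s": token.sender_id,
            "r": token.receiver_id,
            "u": token.suite,
            "c1": _b64e(token.component_1),
            "c2": _b64e(token.component_2),
        },
        sort_keys=True,
        separators=(",", ":"),
    ).encode("utf-8")
    return _b64e(blob)


def decode_request_line(text: str) -> SealedToken:
    if not URL_SAFE_RE.match(text or "") or text == "":
        raise TokenDecodeError("request line is not URL-safe base64url text")
    try:
        obj = json.loads(_b64d(text).decode("utf-8"))
        return SealedToken(
            sender_id=obj["s"],
            receiver_id=obj["r"],
            suite=obj["u"],
            component_1=_b64d(obj["c1"]),
            component_2=_b64d(obj["c2"]),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise TokenDecodeError(f"malformed token encoding: {exc}") from exc


# ---------------------------------------------------------------------------
# Fragmentation: split a long encoded request over several request lines
# ---------------------------------------------------------------------------

_FRAG_TEMPLATE = "/f?rid={rid}&idx={idx}&tot={tot}&c={chunk}"
_FRAG_RE = re.compile(r"^/f\?rid=([0-9a-f]{16})&idx=(\d+)&tot=(\d+)&c=([A-Za-z0-9_.~-]*)$")


def fragment_request(encoded: str, max_len: int = DEFAULT_MAX_REQUEST_LINE) -> list[str]:
    """Split an encoded request into sub-requests each fitting in max_len.

    Framing per fragment: a request id (16 hex chars, derived from the
    content so fragmentation is deterministic), the fragment index, the
    total count, and the chunk.  Reassembly tolerates arbitrary reordering.
    """
    rid = hashlib.sha256(encoded.encode("ascii")).hexdigest()[:16]
    # Iterate: a larger total may need more digits, shrinking the chunk size.
    tot = 1
    while True:
        digits_idx = len(str(max(tot - 1, 0)))
        worst = len(_FRAG_TEMPLATE.format(rid=rid, idx="9" * digits_idx, tot=tot, chunk=""))
        chunk_size = max_len - worst
        if chunk_size < 1:
            raise FragmentError(
                f"max_len={max_len} cannot carry framing plus one payload character"
            )
        needed = max(1, -(-len(encoded) // chunk_size))
        if needed <= tot:
            break
        tot = needed

    digits_idx = len(str(max(tot - 1, 0)))
    worst = len(_FRAG_TEMPLATE.format(rid=rid, idx="9" * digits_idx, tot=tot, chunk=""))
    chunk_size = max_len - worst
    fragments = []
    for idx in range(tot):
        chunk = encoded[idx * chunk_size : (idx + 1) * chunk_size]
        fragments.append(_FRAG_TEMPLATE.format(rid=rid, idx=idx, tot=tot, chunk=chunk))
    return fragments


def reassemble_request(fragments: Iterable[str]) -> str:
    """Reassemble sub-requests (any order) into the original encoded text.

    Detects missing fragments (naming the gap), conflicting duplicates and
    mixed request ids.
    """
    seen: dict[int, str] = {}
    rid: str | None = None
    tot: int | None = None
    for frag in fragments:
        m = _FRAG_RE.match(frag)
        if not m:
            raise FragmentError(f"malformed fragment: {frag[:80]!r}")
        frid, idx_s, tot_s, chunk = m.groups()
        idx, ftot = int(idx_s), int(tot_s)
        if rid is None:
            rid, tot = frid, ftot
        elif frid != rid:
            raise FragmentError(f"mixed request ids: {rid} vs {frid}")
        elif ftot != tot:
            raise FragmentError(f"inconsistent totals: {tot} vs {ftot}")
        if idx >= ftot:
            raise FragmentError(f"fragment index {idx} out of range (total {ftot})")
        if idx in seen and seen[idx] != chunk:
            raise FragmentError(f"conflicting content for fragment index {idx}")
        seen[idx] = chunk
    if tot is None:
        raise FragmentError("no fragments supplied")
    missing = [i for i in range(tot) if i not in seen]
    if missing:
        raise FragmentError(f"missing fragment indices: {missing}")
    return "".join(seen[i] for i in range(tot))
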