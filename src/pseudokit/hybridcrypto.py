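"""Hybrid public-key encryption primitives for sealed tokens.

The scheme is DHIES-style hybrid encryption, assembled from stdlib
``hashlib``/``hmac`` primitives:

* **Key encapsulation** — finite-field Diffie-Hellman over the RFC 3526
  2048-bit MODP group (group 14), ephemeral-static: the sender draws an
  ephemeral exponent per message, the receiver holds a static key pair.
  The shared secret is hashed through HKDF into a wrap key.
* **Data encapsulation** — encrypt-then-MAC with a 256-bit key: an
  HMAC-SHA256 counter-mode keystream for confidentiality and an
  HMAC-SHA256 tag over (aad, nonce, ciphertext) for integrity.  The tag is
  verified before any plaintext is released, so every corruption surfaces
  as an integrity error, never as garbled output.

The suite is named (``dhies-modp2048-hs256``) and registered in ``SUITES``
so that alternative KEM/AEAD pairs can be plugged in without touching the
token layer.

Randomness: callers may pass a seeded ``random.Random`` for reproducible
test vectors; production paths use ``secrets``.
"""

from __future__ import annotations

import hashlib
import hmac
import random
import secrets
from dataclasses import dataclass

# RFC 3526 group 14: 2048-bit MODP prime, generator 2.
MODP2048_P = int(
    "FFFFFFFFFFFFFFFFC90FDAA22168C234C4C6628B80DC1CD129024E088A67CC74"
    "020BBEA63B139B22514A08798E3404DDEF9519B3CD3A431B302B0A6DF25F1437"
    "4FE1356D6D51C245E485B576625E7EC6F44C42E9A637ED6B0BFF5CB6F406B7ED"
    "EE386BFB5A899FA5AE9F24117C4B1FE649286651ECE45B3DC2007CB8A163BF05"
    "98DA48361C55D39A69163FA8FD24CF5F83655D23DCA3AD961C62F356208552BB"
    "9ED529077096966D670C354E4ABC9804F1746C08CA18217C32905E462E36CE3B"
    "E39E772C180E86039B2783A2EC07A28FB5C55DF06F4C52C9DE2BCBF695581718"
    "3995497CEA956AE515D2261898FA051015728E5A8AACAA68FFFFFFFFFFFFFFFF",
    16,
)
MODP2048_G = 2
GROUP_BYTES = 256  # serialized field-element size
EXPONENT_BITS = 256  # short-exponent DH: 128-bit security level
KEY_BYTES = 32
NONCE_BYTES = 16
TAG_BYTES = 32


class CryptoError(Exception):
    """Base class for cryptographic failures."""


class IntegrityError(CryptoError):
    """Authentication tag mismatch: the message was tampered with or is
    not addressed to this key."""


def _randbits(bits: int, rng: random.Random | None) -> int:
    if rng is None:
        return secrets.randbits(bits)
    return rng.getrandbits(bits)


def _randbytes(n: int, rng: random.Random | None) -> bytes:
    if rng is None:
        return secrets.token_bytes(n)
    return rng.getrandbits(8 * n).to_bytes(n, "big")


def hkdf_sha256(ikm: bytes, info: bytes, length: int, salt: bytes = b"") -> bytes:
    """HKDF (extract-then-expand) with SHA-256."""
    prk = hmac.new(salt or b"\x00" * 32, ikm, hashlib.sha256).digest()
    out = b""
    block = b""
    counter = 1
    while len(out) < length:
        block = hmac.new(prk, block + info + bytes([counter]), hashlib.sha256).digest()
        out += block
        counter += 1
    return out[:length]


def _keystream_xor(key: bytes, nonce: bytes, data: bytes) -> bytes:
    out = bytearray(len(data))
    block_index = 0
    offset = 0
    while offset < len(data):
        block = hmac.new(
            key, nonce + block_index.to_bytes(8, "big"), hashlib.sha256
        ).digest()
        chunk = data[offset : offset + len(block)]
        for i, byte in enumerate(chunk):
            out[offset + i] = byte ^ block[i]
        offset += len(chunk)
        block_index += 1
    return bytes(out)


def _subkeys(key: bytes) -> tuple[bytes, bytes]:
    material = hkdf_sha256(key, b"pseudokit.aead.v1", 2 * KEY_BYTES)
    return material[:KEY_BYTES], material[KEY_BYTES:]


def _tag(mac_key: bytes, aad: bytes, nonce: bytes, ciphertext: bytes) -> bytes:
    h = hmac.new(mac_key, digestmod=hashlib.sha256)
    h.update(len(aad).to_bytes(8, "big"))
    h.update(aad)
    h.update(nonce)
    h.update(ciphertext)
    return h.digest()


def aead_seal(
    key: bytes, plaintext: bytes, aad: bytes = b"", rng: random.Random | None = None
) -> bytes:
    """Authenticated encryption: returns nonce || ciphertext || tag."""
    enc_key, mac_key = _subkeys(key)
    nonce = _randbytes(NONCE_BYTES, rng)
    ciphertext = _keystream_xor(enc_key, nonce, plaintext)
    return nonce + ciphertext + _tag(mac_key, aad, nonce, ciphertext)


def aead_open(key: bytes, sealed: bytes, aad: bytes = b"") -> bytes:
    """Verify the tag, then decrypt.  Raises IntegrityError on any mismatch."""
    if len(sealed) < NONCE_BYTES + TAG_BYTES:
        raise IntegrityError("sealed blob too short")
    enc_key, mac_key = _subkeys(key)
    nonce = sealed[:NONCE_BYTES]
    ciphertext = sealed[NONCE_BYTES:-TAG_BYTES]
    tag = sealed[-TAG_BYTES:]
    if not hmac.compare_digest(tag, _tag(mac_key, aad, nonce, ciphertext)):
        raise IntegrityError("authentication tag mismatch")
    return _keystream_xor(enc_key, nonce, ciphertext)


from functools import lru_cache


@lru_cache(maxsize=64)
def _public_of(private: bytes) -> bytes:
    x = int.from_bytes(private, "big")
    return pow(MODP2048_G, x, MODP2048_P).to_bytes(GROUP_BYTES, "big")


@dataclass(frozen=True)
class CipherSuite:
    """A named KEM + AEAD pairing; the default is DH-2048 with HMAC-SHA256."""

    name: str

    def generate_keypair(self, rng: random.Random | None = None) -> tuple[bytes, bytes]:
        """Returns (private, public) as fixed-size big-endian byte strings."""
        x = _randbits(EXPONENT_BITS, rng) | (1 << (EXPONENT_BITS - 1))
        pub = pow(MODP2048_G, x, MODP2048_P)
        return (
            x.to_bytes(EXPONENT_BITS // 8, "big"),
            pub.to_bytes(GROUP_BYTES, "big"),
        )

    def _wrap_key(self, shared: int, eph_pub: bytes, receiver_pub: bytes) -> bytes:
        return hkdf_sha256(
            shared.to_bytes(GROUP_BYTES, "big"),
            b"pseudokit.kem.v1" + eph_pub + receiver_pub,
            KEY_BYTES,
        )

    def encapsulate(
        self, receiver_public: bytes, key: bytes, rng: random.Random | None = None
    ) -> bytes:
        """Wrap a fresh symmetric key for the receiver.

        Returns eph_pub || aead(wrap_key, key): the asymmetric, integrity
        protected first token component.
        """
        y = _randbits(EXPONENT_BITS, rng) | (1 << (EXPONENT_BITS - 1))
        eph_pub = pow(MODP2048_G, y, MODP2048_P).to_bytes(GROUP_BYTES, "big")
        shared = pow(int.from_bytes(receiver_public, "big"), y, MODP2048_P)
        wrap = self._wrap_key(shared, eph_pub, receiver_public)
        return eph_pub + aead_seal(wrap, key, aad=b"kem", rng=rng)

    def decapsulate(self, receiver_private: bytes, wrapped: bytes) -> bytes:
        """Recover the symmetric key; IntegrityError if tampered or misaddressed."""
        if len(wrapped) < GROUP_BYTES + NONCE_BYTES + TAG_BYTES:
            raise IntegrityError("wrapped key too short")
        eph_pub = wrapped[:GROUP_BYTES]
        x = int.from_bytes(receiver_private, "big")
        receiver_pub = _public_of(receiver_private)
        shared = pow(int.from_bytes(eph_pub, "big"), x, MODP2048_P)
        wrap = self._wrap_key(shared, eph_pub, receiver_pub)
        return aead_open(wrap, wrapped[GROUP_BYTES:], aad=b"kem")


DEFAULT_SUITE = CipherSuite(name="dhies-modp2048-hs256")
SUITES: dict[str, CipherSuite] = {DEFAULT_SUITE.name: DEFAULT_SUITE}
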