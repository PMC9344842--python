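"""Canonical serialization shared by every hashing site.

Every node in a consortium must hash identical content to identical
digests, so all digests in the package are taken over one canonical
byte form: UTF-8 JSON with lexicographically sorted keys and no
insignificant whitespace.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any


def canonical_json(obj: Any) -> bytes:
    """Serialize ``obj`` to canonical JSON bytes (sorted keys, compact)."""
    return json.dumps(
        obj, sort_keys=True, separators=(",", ":"), ensure_ascii=False
    ).encode("utf-8")


def sha256_hex(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def digest_json(obj: Any) -> str:
    """SHA-256 hex digest of the canonical JSON form of ``obj``."""
    return sha256_hex(canonical_json(obj))


ZERO_DIGEST = "0" * 64


def is_hex_digest(value: str, length: int = 64) -> bool:
    if not isinstance(value, str) or len(value) != length:
        return False
    return all(c in "0123456789abcdef" for c in value)
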