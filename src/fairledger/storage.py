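"""Content-addressed object store over an MDS erasure code in GF(2⁸).

A payload is zero-padded to a multiple of *k*, split into *k* equal
data stripes, and extended with *m* parity stripes computed from a
Cauchy generator matrix over GF(2⁸) (reducing polynomial 0x11D).  The
code is systematic and maximum-distance-separable: any *k* of the
*N = k + m* shards reconstruct the payload, so with the default
*k = m = N/2* the system tolerates the loss of half of the storage
devices.  Setting *k = 1* degenerates to plain replication.

Shards are placed round-robin across organizations so that no single
organization concentrates more than ``ceil(N / #orgs)`` shards of one
object.  Shards are screened by digest on retrieval: a corrupt shard is
excluded, never trusted (error-locating decoding is out of scope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._canon import sha256_hex
from .errors import (
    ConfigError,
    DataUnavailableError,
    InsufficientShardsError,
    PlacementError,
)

# ---------------------------------------------------------------------------
# GF(2^8) arithmetic, reducing polynomial x^8+x^4+x^3+x^2+1 (0x11D)

_POLY = 0x11D


def gf_mul(a: int, b: int) -> int:
    """Multiply two field elements by carry-less (peasant) multiplication
    with on-the-fly reduction.  This is the defining primitive; the
    log/antilog tables used elsewhere are derived from it."""
    if not (0 <= a <= 255 and 0 <= b <= 255):
        raise ValueError("GF(256) elements must be in [0, 255]")
    r = 0
    while b:
        if b & 1:
            r ^= a
        a <<= 1
        if a & 0x100:
            a ^= _POLY
        b >>= 1
    return r


def _build_tables() -> tuple[list[int], list[int]]:
    # 2 is primitive for 0x11D, so powers of 2 enumerate all 255 nonzero elements
    exp = [0] * 512
    log = [0] * 256
    x = 1
    for i in range(255):
        exp[i] = x
        log[x] = i
        x = gf_mul(x, 2)
    for i in range(255, 512):
        exp[i] = exp[i - 255]
    return exp, log


_EXP, _LOG = _build_tables()


def _mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[_LOG[a] + _LOG[b]]


def gf_inv(a: int) -> int:
    if a == 0:
        raise ZeroDivisionError("0 has no inverse in GF(256)")
    return _EXP[255 - _LOG[a]]


def _mul_row(c: int) -> bytes:
    """Translation table for multiplying a whole byte string by c."""
    return bytes(_mul(c, b) for b in range(256))


def _addmul(acc: bytearray, c: int, vec: bytes) -> None:
    """acc ^= c * vec, elementwise over GF(256)."""
    if c == 0:
        return
    table = _mul_row(c)
    for i, b in enumerate(vec):
        acc[i] ^= table[b]


# ---------------------------------------------------------------------------
# configuration and shard containers


@dataclass(frozen=True)
class StorageConfig:
    """Erasure-code geometry: N = k + m shards, reconstruction threshold k."""

    data_shards: int
    parity_shards: int

    def __post_init__(self) -> None:
        if self.data_shards < 1:
            raise ConfigError("data_shards (k) must be >= 1")
        if self.parity_shards < 0:
            raise ConfigError("parity_shards (m) must be >= 0")
        if self.total_shards > 256:
            raise ConfigError("at most 256 shards are supported over GF(256)")

    @property
    def total_shards(self) -> int:
        return self.data_shards + self.parity_shards

    @classmethod
    def default(cls, total: int = 8) -> "StorageConfig":
        """k = m = N/2 — tolerates losing half of the devices."""
        if total < 2 or total % 2:
            raise ConfigError("default geometry needs an even N >= 2")
        return cls(data_shards=total // 2, parity_shards=total // 2)


@dataclass(frozen=True)
class Shard:
    object_id: str
    shard_index: int
    payload: bytes
    shard_digest: str

    @classmethod
    def make(cls, object_id: str, shard_index: int, payload: bytes) -> "Shard":
        return cls(object_id, shard_index, bytes(payload), sha256_hex(payload))


@dataclass(frozen=True)
class ObjectManifest:
    """Everything needed to locate and verify the shards of one object."""

    object_id: str  # digest of the original payload
    size: int  # true payload length for unpadding
    config: StorageConfig
    shard_digests: tuple[str, ...]
    placement: dict[int, str]  # shard_index -> storage node id

    def to_dict(self) -> dict:
        return {
            "object_id": self.object_id,
            "size": self.size,
            "data_shards": self.config.data_shards,
            "parity_shards": self.config.parity_shards,
            "shard_digests": list(self.shard_digests),
            "placement": {str(i): n for i, n in self.placement.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ObjectManifest":
        return cls(
            object_id=d["object_id"],
            size=int(d["size"]),
            config=StorageConfig(int(d["data_shards"]), int(d["parity_shards"])),
            shard_digests=tuple(d["shard_digests"]),
            placement={int(i): n for i, n in d["placement"].items()},
        )


# ---------------------------------------------------------------------------
# encoding / reconstruction


def _generator_row(j: int, k: int) -> list[int]:
    """Parity row j of the Cauchy construction: x_i = i, y_j = k + j;
    entry i is 1/(x_i XOR y_j).  Guarantees every k×k submatrix of the
    stacked [I; C] generator is invertible for N <= 256."""
    return [gf_inv(i ^ (k + j)) for i in range(k)]


def encode(payload: bytes, config: StorageConfig) -> tuple[list[Shard], ObjectManifest]:
    """Split a payload into N systematic shards and build its manifest.

    Shards 0..k-1 are the zero-padded payload split into k stripes;
    shards k..N-1 are parity.  The manifest records the true size and
    leaves placement empty (filled by :func:`plan_placement`).
    """
    if not payload:
        raise ConfigError("payload must be nonempty")
    k, m = config.data_shards, config.parity_shards
    object_id = sha256_hex(payload)
    stripe_len = max(1, math.ceil(len(payload) / k))
    padded = payload.ljust(k * stripe_len, b"\0")
    stripes = [padded[i * stripe_len : (i + 1) * stripe_len] for i in range(k)]
    shards = [Shard.make(object_id, i, stripes[i]) for i in range(k)]
    for j in range(m):
        row = _generator_row(j, k)
        acc = bytearray(stripe_len)
        for i in range(k):
            _addmul(acc, row[i], stripes[i])
        shards.append(Shard.make(object_id, k + j, bytes(acc)))
    manifest = ObjectManifest(
        object_id=object_id,
        size=len(payload),
        config=config,
        shard_digests=tuple(s.shard_digest for s in shards),
        placement={},
    )
    return shards, manifest


def _solve(rows: list[list[int]], rhs: list[bytearray]) -> list[bytearray]:
    """Gaussian elimination over GF(256): solve M X = V for the stripes."""
    k = len(rows)
    m = [row[:] for row in rows]
    v = [bytearray(r) for r in rhs]
    for col in range(k):
        pivot = next((r for r in range(col, k) if m[r][col] != 0), None)
        if pivot is None:
            raise InsufficientShardsError(have=0, need=k)  # rank-deficient
        m[col], m[pivot] = m[pivot], m[col]
        v[col], v[pivot] = v[pivot], v[col]
        inv = gf_inv(m[col][col])
        m[col] = [_mul(inv, x) for x in m[col]]
        scaled = bytearray(_mul_row(inv)[b] for b in v[col])
        v[col] = scaled
        for r in range(k):
            if r != col and m[r][col]:
                c = m[r][col]
                m[r] = [m[r][i] ^ _mul(c, m[col][i]) for i in range(k)]
                _addmul(v[r], c, bytes(v[col]))
    return v


def reconstruct(shards: Iterable[Shard], manifest: ObjectManifest) -> bytes:
    """Recover the payload from any >= k valid shards.

    Shards whose digest does not match the manifest are dropped before
    decoding.  Succeeds iff at least k distinct valid shards remain;
    the output always re-verifies against the manifest's object_id.
    """
    k = manifest.config.data_shards
    valid: dict[int, bytes] = {}
    for s in shards:
        idx = s.shard_index
        if 0 <= idx < manifest.config.total_shards and (
            sha256_hex(s.payload) == manifest.shard_digests[idx] == s.shard_digest
        ):
            valid.setdefault(idx, s.payload)
    if len(valid) < k:
        raise InsufficientShardsError(have=len(valid), need=k)
    chosen = sorted(valid)[:k]
    if all(i < k for i in chosen):
        stripes = [valid[i] for i in chosen]
    else:
        rows, rhs = [], []
        for idx in chosen:
            if idx < k:
                rows.append([1 if c == idx else 0 for c in range(k)])
            else:
                rows.append(_generator_row(idx - k, k))
            rhs.append(bytearray(valid[idx]))
        stripes = [bytes(s) for s in _solve(rows, rhs)]
    payload = b"".join(stripes)[: manifest.size]
    if sha256_hex(payload) != manifest.object_id:
        raise DataUnavailableError("reconstructed payload fails its digest check")
    return payload


# ---------------------------------------------------------------------------
# simulated storage nodes and object-level operations


@dataclass
class StorageNode:
    """One simulated storage device; a failed node serves nothing."""

    node_id: str
    org_id: str
    status: str = "online"  # online | failed
    store: dict[tuple[str, int], Shard] = field(default_factory=dict)
    staging: dict[tuple[str, int], Shard] = field(default_factory=dict)

    @property
    def online(self) -> bool:
        return self.status == "online"

    def fail(self) -> None:
        self.status = "failed"

    def restore(self) -> None:
        self.status = "online"


def plan_placement(
    config: StorageConfig, nodes: Sequence[StorageNode]
) -> dict[int, str]:
    """Assign each shard index to a distinct online node, round-robin
    across organizations, honoring the ceil(N/#orgs) per-org cap."""
    online = [n for n in nodes if n.online]
    by_org: dict[str, list[StorageNode]] = {}
    for n in sorted(online, key=lambda n: n.node_id):
        by_org.setdefault(n.org_id, []).append(n)
    if not by_org:
        raise PlacementError("no online storage nodes")
    n_total = config.total_shards
    if len(online) < n_total:
        raise PlacementError(
            f"need {n_total} online storage nodes, have {len(online)}"
        )
    orgs = sorted(by_org)
    cap = math.ceil(n_total / len(orgs))
    placement: dict[int, str] = {}
    used_per_org = {o: 0 for o in orgs}
    org_cursor = 0
    for shard_index in range(n_total):
        placed = False
        for attempt in range(len(orgs)):
            org = orgs[(org_cursor + attempt) % len(orgs)]
            if used_per_org[org] < cap and by_org[org]:
                node = by_org[org].pop(0)
                placement[shard_index] = node.node_id
                used_per_org[org] += 1
                org_cursor = (org_cursor + attempt + 1) % len(orgs)
                placed = True
                break
        if not placed:
            raise PlacementError("placement infeasible under the per-organization cap")
    return placement


def stage_object(
    payload: bytes, nodes: Sequence[StorageNode], config: StorageConfig
) -> ObjectManifest:
    """Encode and write shards to the nodes' staging area (not yet visible)."""
    shards, manifest = encode(payload, config)
    placement = plan_placement(config, nodes)
    manifest = ObjectManifest(
        object_id=manifest.object_id,
        size=manifest.size,
        config=manifest.config,
        shard_digests=manifest.shard_digests,
        placement=placement,
    )
    index = {n.node_id: n for n in nodes}
    for shard in shards:
        index[placement[shard.shard_index]].staging[
            (manifest.object_id, shard.shard_index)
        ] = shard
    return manifest


def promote_object(object_id: str, nodes: Sequence[StorageNode]) -> None:
    """Move an object's staged shards into the visible store."""
    for node in nodes:
        staged = [key for key in node.staging if key[0] == object_id]
        for key in staged:
            node.store[key] = node.staging.pop(key)


def discard_staged(object_id: str, nodes: Sequence[StorageNode]) -> None:
    for node in nodes:
        for key in [k for k in node.staging if k[0] == object_id]:
            del node.staging[key]


def put_object(
    payload: bytes, nodes: Sequence[StorageNode], config: StorageConfig
) -> ObjectManifest:
    """Encode, place and store a payload in one step (no staging)."""
    manifest = stage_object(payload, nodes, config)
    promote_object(manifest.object_id, nodes)
    return manifest


def get_object(manifest: ObjectManifest, nodes: Sequence[StorageNode]) -> bytes:
    """Gather reachable shards per the manifest, screen digests, reconstruct.

    Raises :class:`DataUnavailableError` when fewer than k valid shards
    are reachable (failed nodes serve nothing; corrupt shards are
    excluded).  Metadata resolution is unaffected — see the platform's
    purge semantics.
    """
    index = {n.node_id: n for n in nodes}
    available: list[Shard] = []
    for shard_index, node_id in manifest.placement.items():
        node = index.get(node_id)
        if node is None or not node.online:
            continue
        shard = node.store.get((manifest.object_id, shard_index))
        if shard is not None:
            available.append(shard)
    try:
        return reconstruct(available, manifest)
    except InsufficientShardsError as exc:
        raise DataUnavailableError(
            f"only {exc.have} of the required {exc.need} valid shards are reachable"
        ) from exc


def purge_object(object_id: str, nodes: Sequence[StorageNode]) -> int:
    """Delete every stored and staged shard of an object; returns the count."""
    removed = 0
    for node in nodes:
        for store in (node.store, node.staging):
            for key in [k for k in store if k[0] == object_id]:
                del store[key]
                removed += 1
    return removed
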