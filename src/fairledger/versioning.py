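"""Version control over the (meta)data duple.

Every submission mints a stable Data ID (DID) binding the metadata to
an immutable payload.  Metadata updates re-run the full endorsement
lifecycle and, on commit, append a new version to the chain — the data
digest never changes, so every metadata version points at the same
data.  History is reconstructed purely by scanning the ledger: no side
index is authoritative, and a deleted index can always be rebuilt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from ._canon import is_hex_digest, sha256_hex
from .errors import NotFoundError
from .ledger import Ledger
from .schema import MetadataRecord

DID_LENGTH = 32


def mint_did(data_digest: str, metadata_digest: str) -> str:
    """Derive the DID for a submission: the first 32 hex characters of
    SHA-256 over the concatenated data and initial-metadata digests.

    Content-based, hence deterministic: the same (data, metadata) pair
    always yields the same DID, and distinct initial metadata over the
    same data yields distinct DIDs.
    """
    for name, digest in (("data_digest", data_digest), ("metadata_digest", metadata_digest)):
        if not is_hex_digest(digest):
            raise ValueError(f"{name} must be a 64-character lowercase hex digest")
    return sha256_hex((data_digest + metadata_digest).encode("ascii"))[:DID_LENGTH]


class VersionEntry(NamedTuple):
    version: int
    block_index: int
    position: int
    metadata_digest: str


@dataclass(frozen=True)
class VersionChain:
    """Per-DID ordered version list, all bound to one data digest."""

    did: str
    entries: tuple[VersionEntry, ...]
    data_digest: str

    @property
    def latest_version(self) -> int:
        return self.entries[-1].version


def history(chain_ledger: Ledger, did: str) -> VersionChain:
    """Reconstruct a DID's version chain by scanning the ledger."""
    entries: list[VersionEntry] = []
    data_digest = None
    for block_index, position, tx in chain_ledger.transactions():
        if tx.did == did:
            entries.append(
                VersionEntry(tx.version, block_index, position, tx.metadata_digest)
            )
            data_digest = tx.data_digest
    if not entries:
        raise NotFoundError(f"unknown DID {did!r}")
    return VersionChain(did=did, entries=tuple(entries), data_digest=data_digest)


def get_version(chain_ledger: Ledger, did: str, version: int) -> MetadataRecord:
    """Return one committed metadata version exactly as stored."""
    found = False
    for _, _, tx in chain_ledger.transactions():
        if tx.did == did:
            found = True
            if tx.version == version:
                return tx.record
    if not found:
        raise NotFoundError(f"unknown DID {did!r}")
    raise NotFoundError(f"DID {did!r} has no version {version}")


def latest(chain_ledger: Ledger, did: str):
    """The highest committed transaction for a DID."""
    best = None
    for _, _, tx in chain_ledger.transactions():
        if tx.did == did and (best is None or tx.version > best.version):
            best = tx
    if best is None:
        raise NotFoundError(f"unknown DID {did!r}")
    return best
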