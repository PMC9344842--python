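"""Append-only hash-chained block store doubling as the metadata database.

Each block carries an ordered transaction list; a transaction is one
validated metadata version bound to a Data ID (DID), the digest of the
payload it describes, its submitter and the endorsements that approved
it.  Blocks chain through SHA-256: block *i* stores the hash of block
*i-1*, so any retroactive edit breaks a recomputable link.  The
serialized form of every block additionally carries its own hash, which
:func:`verify_chain` recomputes — this binds the chain tip's header,
which no successor link covers.

Timestamps are supplied by the orderer (a logical clock), never read
from the wall clock here, so independent replicas fed the same block
sequence are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple

from ._canon import ZERO_DIGEST, canonical_json, digest_json, sha256_hex
from .errors import LedgerAppendError
from .schema import MetadataRecord, record_digest

GENESIS_TIMESTAMP = "1970-01-01T00:00:00Z"


@dataclass(frozen=True)
class Transaction:
    """One committed metadata version, the unit stored in blocks."""

    did: str
    version: int
    record: MetadataRecord
    metadata_digest: str
    data_digest: str
    submitter: str
    template_id: str
    endorsements: tuple[tuple[str, str], ...] = ()  # (node_id, signature hex)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "endorsements", tuple((n, s) for n, s in self.endorsements)
        )

    def proposal_dict(self) -> dict:
        """The endorsement-free content every node signs and validates."""
        return {
            "did": self.did,
            "version": self.version,
            "record": self.record.to_dict(),
            "metadata_digest": self.metadata_digest,
            "data_digest": self.data_digest,
            "submitter": self.submitter,
            "template_id": self.template_id,
        }

    @property
    def proposal_digest(self) -> str:
        return digest_json(self.proposal_dict())

    def to_dict(self) -> dict:
        d = self.proposal_dict()
        d["endorsements"] = [list(e) for e in self.endorsements]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Transaction":
        rec = d["record"]
        return cls(
            did=d["did"],
            version=int(d["version"]),
            record=MetadataRecord(template_id=rec["template_id"], values=rec["values"]),
            metadata_digest=d["metadata_digest"],
            data_digest=d["data_digest"],
            submitter=d["submitter"],
            template_id=d["template_id"],
            endorsements=tuple((e[0], e[1]) for e in d.get("endorsements", [])),
        )


@dataclass(frozen=True)
class Block:
    index: int
    previous_hash: str
    payload_hash: str
    timestamp: str
    transactions: tuple[Transaction, ...]
    hash: str  # self-hash as serialized; recomputed during verification

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "previous_hash": self.previous_hash,
            "payload_hash": self.payload_hash,
            "timestamp": self.timestamp,
            "transactions": [t.to_dict() for t in self.transactions],
            "hash": self.hash,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Block":
        return cls(
            index=int(d["index"]),
            previous_hash=d["previous_hash"],
            payload_hash=d["payload_hash"],
            timestamp=d["timestamp"],
            transactions=tuple(Transaction.from_dict(t) for t in d["transactions"]),
            hash=d["hash"],
        )


def payload_hash(transactions: Iterable[Transaction]) -> str:
    """Digest over the canonical serialization of a transaction list."""
    return digest_json([t.to_dict() for t in transactions])


def block_hash(block: Block) -> str:
    """Chaining digest over the block header (excludes the stored self-hash)."""
    return digest_json(
        {
            "index": block.index,
            "previous_hash": block.previous_hash,
            "payload_hash": block.payload_hash,
            "timestamp": block.timestamp,
        }
    )


def make_block(
    index: int, previous_hash: str, transactions: Iterable[Transaction], timestamp: str
) -> Block:
    txs = tuple(transactions)
    ph = payload_hash(txs)
    blk = Block(
        index=index,
        previous_hash=previous_hash,
        payload_hash=ph,
        timestamp=timestamp,
        transactions=txs,
        hash="",
    )
    return replace(blk, hash=block_hash(blk))


def genesis_block(timestamp: str = GENESIS_TIMESTAMP) -> Block:
    """Block 0: zero previous hash, no transactions, fixed epoch timestamp
    so independent deployments of one consortium share a genesis."""
    return make_block(0, ZERO_DIGEST, (), timestamp)


@dataclass
class Ledger:
    """Ordered block list held by one replica."""

    blocks: list[Block] = field(default_factory=list)
    replica_id: str = ""

    @classmethod
    def new(cls, replica_id: str = "", genesis_timestamp: str = GENESIS_TIMESTAMP) -> "Ledger":
        return cls(blocks=[genesis_block(genesis_timestamp)], replica_id=replica_id)

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def tip(self) -> Block:
        return self.blocks[-1]

    def transactions(self) -> Iterable[tuple[int, int, Transaction]]:
        """Yield (block index, position, transaction) in chain order."""
        for blk in self.blocks:
            for pos, tx in enumerate(blk.transactions):
                yield blk.index, pos, tx


def did_state(ledger: Ledger) -> dict[str, tuple[int, str]]:
    """Map DID -> (highest committed version, data digest)."""
    state: dict[str, tuple[int, str]] = {}
    for _, _, tx in ledger.transactions():
        state[tx.did] = (tx.version, tx.data_digest)
    return state


def append_block(
    ledger: Ledger, transactions: Iterable[Transaction], timestamp: str
) -> Ledger:
    """Append one block; rejects any transaction violating chain invariants.

    Enforced per transaction, also across the batch being appended:
    the metadata digest matches the record, versions are contiguous per
    DID (a version n+1 requires a committed version n), and the data
    digest of a DID never changes.  No existing block is ever mutated.
    """
    txs = tuple(transactions)
    if not txs:
        raise LedgerAppendError("cannot append an empty block")
    state = did_state(ledger)
    for tx in txs:
        if tx.version < 1:
            raise LedgerAppendError(f"did {tx.did}: version must be >= 1")
        actual = record_digest(tx.record)
        if tx.metadata_digest != actual:
            raise LedgerAppendError(
                f"did {tx.did}: metadata_digest does not match the record"
            )
        if tx.did in state:
            prev_version, prev_data = state[tx.did]
            if tx.version != prev_version + 1:
                raise LedgerAppendError(
                    f"did {tx.did}: version {tx.version} does not follow "
                    f"committed version {prev_version}"
                )
            if tx.data_digest != prev_data:
                raise LedgerAppendError(
                    f"did {tx.did}: data_digest change rejected — data bound "
                    "to a DID is immutable"
                )
        elif tx.version != 1:
            raise LedgerAppendError(
                f"did {tx.did}: version {tx.version} appended before version 1"
            )
        state[tx.did] = (tx.version, tx.data_digest)
    blk = make_block(len(ledger.blocks), block_hash(ledger.tip), txs, timestamp)
    ledger.blocks.append(blk)
    return ledger


class Finding(NamedTuple):
    block_index: int
    kind: str  # payload-mismatch | broken-link | bad-genesis | bad-index
    message: str


@dataclass(frozen=True)
class TamperReport:
    findings: tuple[Finding, ...] = ()

    @property
    def consistent(self) -> bool:
        return not self.findings


def verify_chain(ledger: Ledger) -> TamperReport:
    """Recompute every payload hash, self-hash and link; report each
    discrepancy at the earliest block where it is detectable."""
    findings: list[Finding] = []
    blocks = ledger.blocks
    if not blocks:
        return TamperReport((Finding(0, "bad-genesis", "ledger has no blocks"),))
    g = blocks[0]
    if g.index != 0:
        findings.append(Finding(0, "bad-genesis", f"genesis index is {g.index}"))
    if g.previous_hash != ZERO_DIGEST:
        findings.append(Finding(0, "bad-genesis", "genesis previous_hash is not all zeros"))
    if g.transactions:
        findings.append(Finding(0, "bad-genesis", "genesis block carries transactions"))
    for i, blk in enumerate(blocks):
        if i > 0 and blk.index != i:
            findings.append(
                Finding(i, "bad-index", f"block at position {i} has index {blk.index}")
            )
        if payload_hash(blk.transactions) != blk.payload_hash:
            findings.append(
                Finding(
                    i,
                    "payload-mismatch",
                    "stored payload_hash does not match the transactions",
                )
            )
        if block_hash(blk) != blk.hash:
            findings.append(
                Finding(i, "broken-link", "stored block hash does not match its header")
            )
        if i > 0 and blk.previous_hash != block_hash(blocks[i - 1]):
            findings.append(
                Finding(
                    i,
                    "broken-link",
                    "previous_hash does not match the recomputed hash of the prior block",
                )
            )
    return TamperReport(tuple(findings))


def search(
    ledger: Ledger, query: Mapping[str, str], latest_only: bool = False
) -> list[Transaction]:
    """Exact, case-insensitive match of all query pairs against record values.

    Results come back in chain order (block index, position); with
    ``latest_only`` only the highest committed version per DID is kept.
    """
    matches: list[Transaction] = []
    for _, _, tx in ledger.transactions():
        values = tx.record.values
        if all(
            name in values and values[name].lower() == str(wanted).lower()
            for name, wanted in query.items()
        ):
            matches.append(tx)
    if latest_only:
        best: dict[str, Transaction] = {}
        order: list[str] = []
        for tx in matches:
            if tx.did not in best:
                order.append(tx.did)
            if tx.did not in best or tx.version > best[tx.did].version:
                best[tx.did] = tx
        matches = [best[did] for did in order]
    return matches


# ---------------------------------------------------------------------------
# persistence: JSON Lines, one block per line, bit-exact across replicas


def to_jsonl(ledger: Ledger) -> str:
    return "".join(
        canonical_json(blk.to_dict()).decode("utf-8") + "\n" for blk in ledger.blocks
    )


def from_jsonl(text: str, replica_id: str = "") -> Ledger:
    import json as _json

    blocks = [
        Block.from_dict(_json.loads(line)) for line in text.splitlines() if line.strip()
    ]
    return Ledger(blocks=blocks, replica_id=replica_id)


def clone(ledger: Ledger, replica_id: str = "") -> Ledger:
    """Deep, serialization-faithful copy (used by replica resync)."""
    return from_jsonl(to_jsonl(ledger), replica_id=replica_id)
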