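"""Hash chaining, append invariants, tamper localization and search."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from fairledger.errors import LedgerAppendError
from fairledger.ledger import (
    Block,
    Ledger,
    Transaction,
    append_block,
    block_hash,
    from_jsonl,
    genesis_block,
    make_block,
    search,
    to_jsonl,
    verify_chain,
)
from fairledger.network import logical_timestamp
from fairledger.schema import MetadataRecord, record_digest
from fairledger.versioning import mint_did

DATA_A = "a" * 64
DATA_B = "b" * 64


def make_tx(seq: int, version: int = 1, data_digest: str = DATA_A, **values) -> Transaction:
    record = MetadataRecord("t", {"Creator": f"group {seq % 3}", "Title": f"rec {seq}", **values})
    md = record_digest(record)
    return Transaction(
        did=mint_did(data_digest, record_digest(MetadataRecord("t", {"seq": str(seq)}))),
        version=version,
        record=record,
        metadata_digest=md,
        data_digest=data_digest,
        submitter="alice",
        template_id="t",
    )


def build_ledger(n_tx: int = 9) -> Ledger:
    chain = Ledger.new(replica_id="fixture")
    for i in range(n_tx):
        append_block(chain, [make_tx(i)], logical_timestamp(i + 1))
    return chain


class TestBlockHash:
    def test_hashing_is_deterministic(self):
        blk = genesis_block()
        assert block_hash(blk) == block_hash(blk)

    def test_timestamp_difference_changes_the_digest(self):
        a = make_block(1, "0" * 64, [make_tx(0)], logical_timestamp(1))
        b = make_block(1, "0" * 64, [make_tx(0)], logical_timestamp(2))
        assert block_hash(a) != block_hash(b)

    def test_independent_ledgers_share_the_canonical_genesis(self):
        assert block_hash(Ledger.new().blocks[0]) == block_hash(Ledger.new().blocks[0])


class TestAppendBlock:
    def test_smallest_append_verifies(self):
        chain = Ledger.new()
        append_block(chain, [make_tx(0)], logical_timestamp(1))
        assert len(chain) == 2
        assert verify_chain(chain).consistent

    def test_data_digest_change_for_existing_did_is_rejected(self):
        chain = Ledger.new()
        v1 = make_tx(0)
        append_block(chain, [v1], logical_timestamp(1))
        v2 = Transaction(
            did=v1.did,
            version=2,
            record=v1.record,
            metadata_digest=v1.metadata_digest,
            data_digest=DATA_B,
            submitter="alice",
            template_id="t",
        )
        with pytest.raises(LedgerAppendError, match="immutable"):
            append_block(chain, [v2], logical_timestamp(2))

    def test_version_gap_is_rejected(self):
        chain = Ledger.new()
        v1 = make_tx(0)
        append_block(chain, [v1], logical_timestamp(1))
        v3 = Transaction(
            did=v1.did,
            version=3,
            record=v1.record,
            metadata_digest=v1.metadata_digest,
            data_digest=v1.data_digest,
            submitter="alice",
            template_id="t",
        )
        with pytest.raises(LedgerAppendError, match="version 3"):
            append_block(chain, [v3], logical_timestamp(2))

    def test_first_version_must_be_one(self):
        chain = Ledger.new()
        with pytest.raises(LedgerAppendError, match="before version 1"):
            append_block(
                chain,
                [
                    Transaction(
                        did="f" * 32,
                        version=2,
                        record=make_tx(0).record,
                        metadata_digest=make_tx(0).metadata_digest,
                        data_digest=DATA_A,
                        submitter="alice",
                        template_id="t",
                    )
                ],
                logical_timestamp(1),
            )

    def test_wrong_metadata_digest_is_rejected(self):
        chain = Ledger.new()
        tx = make_tx(0)
        forged = Transaction(
            did=tx.did,
            version=1,
            record=tx.record,
            metadata_digest="0" * 64,
            data_digest=tx.data_digest,
            submitter="alice",
            template_id="t",
        )
        with pytest.raises(LedgerAppendError, match="metadata_digest"):
            append_block(chain, [forged], logical_timestamp(1))

    def test_empty_block_is_rejected(self):
        with pytest.raises(LedgerAppendError):
            append_block(Ledger.new(), [], logical_timestamp(1))


class TestVerifyChain:
    def test_untouched_ten_block_ledger_is_consistent(self):
        assert verify_chain(build_ledger(9)).consistent

    def test_flipped_record_character_is_localized_to_its_block(self):
        chain = build_ledger(9)
        doc = chain.blocks[4].to_dict()
        title = doc["transactions"][0]["record"]["values"]["Title"]
        doc["transactions"][0]["record"]["values"]["Title"] = "X" + title[1:]
        chain.blocks[4] = Block.from_dict(doc)
        findings = verify_chain(chain).findings
        assert (4, "payload-mismatch") in [(f.block_index, f.kind) for f in findings]

    def test_self_consistent_forgery_breaks_the_next_link(self):
        chain = build_ledger(9)
        original = chain.blocks[4]
        forged = make_block(
            original.index,
            original.previous_hash,
            [make_tx(99)],
            original.timestamp,
        )  # internally valid: hashes recomputed over the forged payload
        chain.blocks[4] = forged
        report = verify_chain(chain)
        kinds = [(f.block_index, f.kind) for f in report.findings]
        assert (5, "broken-link") in kinds
        assert (4, "payload-mismatch") not in kinds

    def test_bad_genesis_is_reported(self):
        chain = build_ledger(2)
        doc = chain.blocks[0].to_dict()
        doc["previous_hash"] = "1" * 64
        chain.blocks[0] = Block.from_dict(doc)
        assert "bad-genesis" in {f.kind for f in verify_chain(chain).findings}

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=0, max_size=8))
    def test_any_ledger_built_by_append_only_is_consistent(self, seqs):
        chain = Ledger.new()
        for t, seq in enumerate(set(seqs)):
            append_block(chain, [make_tx(seq)], logical_timestamp(t + 1))
        assert verify_chain(chain).consistent


class TestSearch:
    def test_empty_query_returns_all_transactions_in_chain_order(self):
        chain = build_ledger(9)
        result = search(chain, {})
        oracle = [tx for _, _, tx in chain.transactions()]
        assert result == oracle
        assert len(result) == 9

    def test_field_query_matches_linear_scan_oracle(self):
        chain = build_ledger(10)
        result = search(chain, {"Creator": "GROUP 1"})  # case-insensitive
        oracle = [
            tx
            for _, _, tx in chain.transactions()
            if tx.record.values["Creator"].lower() == "group 1"
        ]
        assert result == oracle
        assert len(result) == 3  # seqs 1, 4, 7 of 10

    def test_latest_only_keeps_the_highest_version_per_did(self):
        chain = Ledger.new()
        v1 = make_tx(0)
        append_block(chain, [v1], logical_timestamp(1))
        for v in (2, 3):
            record = MetadataRecord("t", {**v1.record.values, "Title": f"edit {v}"})
            append_block(
                chain,
                [
                    Transaction(
                        did=v1.did,
                        version=v,
                        record=record,
                        metadata_digest=record_digest(record),
                        data_digest=v1.data_digest,
                        submitter="alice",
                        template_id="t",
                    )
                ],
                logical_timestamp(v),
            )
        result = search(chain, {}, latest_only=True)
        assert [tx.version for tx in result] == [3]


class TestPersistence:
    def test_jsonl_round_trip_is_byte_identical(self):
        chain = build_ledger(5)
        text = to_jsonl(chain)
        assert to_jsonl(from_jsonl(text)) == text
        assert len(text.splitlines()) == 6  # genesis + 5

    def test_replicas_fed_the_same_blocks_serialize_identically(self):
        a, b = Ledger.new(replica_id="a"), Ledger.new(replica_id="b")
        for i in range(4):
            tx = make_tx(i)
            append_block(a, [tx], logical_timestamp(i + 1))
            append_block(b, [tx], logical_timestamp(i + 1))
        assert to_jsonl(a) == to_jsonl(b)

    def test_jsonl_lines_are_valid_json_objects(self):
        for line in to_jsonl(build_ledger(3)).splitlines():
            assert isinstance(json.loads(line), dict)
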