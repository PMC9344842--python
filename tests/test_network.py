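"""Endorsement lifecycle, quorum arithmetic, fault injection and resync."""

import pytest

from fairledger.errors import (
    ConfigError,
    NotFoundError,
    PermissionDeniedError,
    ProposalRejected,
    ResyncError,
)
from fairledger.ledger import Block, Transaction, to_jsonl
from fairledger.network import (
    HONEST,
    MALICIOUS,
    OFFLINE,
    Endorsement,
    Network,
    decide,
    endorse,
)
from fairledger.schema import MetadataRecord, builtin_registry, record_digest
from fairledger.versioning import mint_did

from conftest import dublin_record


def make_network(n_orgs: int = 3, evc_per_org: int = 2) -> Network:
    net = Network.from_config(
        {
            "consortium": "test-consortium",
            "channel": "ch",
            "organizations": [
                {"org_id": f"org{i}", "evc_nodes": evc_per_org, "storage_nodes": 0}
                for i in range(n_orgs)
            ],
            "users": [{"user_id": "alice", "org_id": "org0"}],
        }
    )
    return net


def proposal_for(record: MetadataRecord, seq: int = 0) -> Transaction:
    md = record_digest(record)
    data = record_digest(MetadataRecord("payload", {"seq": str(seq)}))
    return Transaction(
        did=mint_did(data, md),
        version=1,
        record=record,
        metadata_digest=md,
        data_digest=data,
        submitter="alice",
        template_id=record.template_id,
    )


def valid_record(corpus):
    return next(i.record for i in corpus if i.record.template_id == "fiber-manufacture")


class TestEndorse:
    def test_honest_node_approves_a_valid_record(self, corpus):
        net = make_network()
        node = net.channel_evc_nodes("ch")[0]
        e = endorse(node, proposal_for(valid_record(corpus)), net.templates)
        assert e.verdict is True
        assert decide([e], {node.node_id: node.key}).approvals == 1  # signature verifies

    def test_honest_node_rejects_a_bad_language_record(self):
        net = make_network()
        node = net.channel_evc_nodes("ch")[0]
        record = dublin_record(Language="english")
        assert endorse(node, proposal_for(record), net.templates).verdict is False

    def test_malicious_node_approves_the_same_invalid_record(self):
        net = make_network()
        node = net.channel_evc_nodes("ch")[0]
        node.status = MALICIOUS
        record = dublin_record(Language="english")
        assert endorse(node, proposal_for(record), net.templates).verdict is True

    def test_offline_node_returns_nothing(self, corpus):
        net = make_network()
        node = net.channel_evc_nodes("ch")[0]
        node.status = OFFLINE
        assert endorse(node, proposal_for(valid_record(corpus)), net.templates) is None

    def test_unknown_template_yields_a_false_verdict(self):
        net = make_network()
        node = net.channel_evc_nodes("ch")[0]
        record = MetadataRecord("no-such-template", {"A": "x"})
        assert endorse(node, proposal_for(record), net.templates).verdict is False


class TestDecide:
    def _endorsements(self, net, record, n_true, n_false=0):
        nodes = net.channel_evc_nodes("ch")
        out = []
        proposal = proposal_for(record)
        digest = proposal.proposal_digest
        for node in nodes[:n_true]:
            out.append(Endorsement(node.node_id, digest, True, node.sign(digest, True)))
        for node in nodes[n_true : n_true + n_false]:
            out.append(Endorsement(node.node_id, digest, False, node.sign(digest, False)))
        return out

    def test_four_of_six_commits(self, corpus):
        net = make_network(3, 2)
        d = decide(self._endorsements(net, valid_record(corpus), 4), net.electorate_keys("ch"))
        assert d.commit and d.approvals == 4 and d.electorate == 6

    def test_three_of_six_is_not_a_strict_majority(self, corpus):
        net = make_network(3, 2)
        d = decide(self._endorsements(net, valid_record(corpus), 3, 3), net.electorate_keys("ch"))
        assert not d.commit

    def test_singleton_electorate_commits_on_its_own_vote(self, corpus):
        net = make_network(1, 1)
        d = decide(self._endorsements(net, valid_record(corpus), 1), net.electorate_keys("ch"))
        assert d.commit

    def test_tampered_signature_never_counts(self, corpus):
        net = make_network(3, 2)
        endorsements = self._endorsements(net, valid_record(corpus), 4)
        good = endorsements[0]
        endorsements[0] = Endorsement(
            good.node_id, good.proposal_digest, good.verdict, "0" * 64
        )
        d = decide(endorsements, net.electorate_keys("ch"))
        assert d.approvals == 3 and not d.commit

    def test_duplicate_endorsements_count_once(self, corpus):
        net = make_network(3, 2)
        endorsements = self._endorsements(net, valid_record(corpus), 3)
        d = decide(endorsements + endorsements, net.electorate_keys("ch"))
        assert d.approvals == 3 and not d.commit

    def test_empty_electorate_is_a_configuration_error(self):
        with pytest.raises(ConfigError):
            decide([], {})


class TestSubmitProposal:
    def test_commit_grows_all_six_replicas_identically(self, corpus):
        net = make_network(3, 2)
        block = net.submit_proposal(proposal_for(valid_record(corpus)))
        replicas = [n.replica for n in net.channel_evc_nodes("ch")]
        assert len(replicas) == 6
        assert all(len(r) == 2 for r in replicas)
        assert len({to_jsonl(r) for r in replicas}) == 1
        assert isinstance(block, Block)

    def test_rejected_proposal_leaves_no_trace(self):
        net = make_network(3, 2)
        with pytest.raises(ProposalRejected) as err:
            net.submit_proposal(proposal_for(dublin_record(Language="english")))
        assert any(v[1] == "bad-language-code" for v in err.value.violations)
        assert all(len(n.replica) == 1 for n in net.channel_evc_nodes("ch"))
        assert len(net.ledgers["ch"]) == 1

    def test_quorum_boundary_three_offline_rejects_then_four_online_commits(self, corpus):
        net = make_network(3, 2)
        nodes = net.channel_evc_nodes("ch")
        for node in nodes[:3]:
            net.inject_fault(node.node_id, OFFLINE)
        with pytest.raises(ProposalRejected):
            net.submit_proposal(proposal_for(valid_record(corpus), seq=1))
        net.restore(nodes[0].node_id)  # 4 of 6 online: 4 > 3
        net.submit_proposal(proposal_for(valid_record(corpus), seq=1))
        assert len(net.ledgers["ch"]) == 2

    def test_non_member_submitter_is_refused(self, corpus):
        net = make_network(3, 2)
        proposal = proposal_for(valid_record(corpus))
        outsider = Transaction(
            did=proposal.did,
            version=1,
            record=proposal.record,
            metadata_digest=proposal.metadata_digest,
            data_digest=proposal.data_digest,
            submitter="mallory",
            template_id=proposal.template_id,
        )
        with pytest.raises(PermissionDeniedError):
            net.submit_proposal(outsider)


class TestFaultInjection:
    def test_offline_then_restore_is_an_involution(self, corpus):
        net = make_network()
        node = net.channel_evc_nodes("ch")[0]
        net.inject_fault(node.node_id, OFFLINE)
        net.inject_fault(node.node_id, OFFLINE)  # idempotent
        assert node.status == OFFLINE
        net.restore(node.node_id)
        assert node.status == HONEST
        assert endorse(node, proposal_for(valid_record(corpus)), net.templates).verdict

    def test_all_nodes_offline_rejects_every_proposal(self, corpus):
        net = make_network()
        for node in net.channel_evc_nodes("ch"):
            net.inject_fault(node.node_id, OFFLINE)
        with pytest.raises(ProposalRejected):
            net.submit_proposal(proposal_for(valid_record(corpus)))

    def test_minority_of_malicious_nodes_cannot_commit_invalid_metadata(self):
        net = make_network(3, 2)  # E = 6, ceil(E/2) - 1 = 2 malicious
        nodes = net.channel_evc_nodes("ch")
        for node in nodes[:2]:
            net.inject_fault(node.node_id, MALICIOUS)
        with pytest.raises(ProposalRejected):
            net.submit_proposal(proposal_for(dublin_record(Language="english")))

    def test_unknown_node_raises(self):
        with pytest.raises(NotFoundError):
            make_network().inject_fault("ghost", OFFLINE)


class TestResync:
    def test_node_offline_during_three_commits_catches_up_byte_identically(self, corpus):
        net = make_network(3, 2)
        lagger = net.channel_evc_nodes("ch")[5]
        net.inject_fault(lagger.node_id, OFFLINE)
        for seq in range(3):
            net.submit_proposal(proposal_for(valid_record(corpus), seq=seq))
        assert len(lagger.replica) == 1
        net.restore(lagger.node_id)
        gained = net.resync(lagger.node_id)
        assert gained == 3
        peer = net.channel_evc_nodes("ch")[0]
        assert to_jsonl(lagger.replica) == to_jsonl(peer.replica)

    def test_resync_with_nothing_missed_is_a_noop(self, corpus):
        net = make_network(3, 2)
        net.submit_proposal(proposal_for(valid_record(corpus)))
        node = net.channel_evc_nodes("ch")[0]
        before = to_jsonl(node.replica)
        assert net.resync(node.node_id) == 0
        assert to_jsonl(node.replica) == before

    def test_tampered_candidates_are_refused(self, corpus):
        net = make_network(3, 2)
        lagger = net.channel_evc_nodes("ch")[5]
        net.inject_fault(lagger.node_id, OFFLINE)
        net.submit_proposal(proposal_for(valid_record(corpus)))
        # corrupt every peer replica so no trustworthy candidate remains
        for peer in net.channel_evc_nodes("ch")[:5]:
            doc = peer.replica.blocks[1].to_dict()
            doc["transactions"][0]["record"]["values"]["Title"] = "forged"
            peer.replica.blocks[1] = Block.from_dict(doc)
        net.restore(lagger.node_id)
        with pytest.raises(ResyncError) as err:
            net.resync(lagger.node_id)
        assert err.value.reports  # the refusal carries the tamper evidence
        assert len(lagger.replica) == 1  # nothing adopted
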