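"""Simulated permissioned consortium and the majority-endorsement lifecycle.

Organizations contribute endorser-validator-committer (EVC) nodes and
storage nodes; organizations sharing a channel form a consortium with
one logical ledger, replicated on every member EVC node.  A proposal is
broadcast to all channel EVC nodes, each of which validates the record
against the registered template and returns a signed verdict; the
proposal commits only when strictly more than half of ALL registered
EVC nodes return a verifying, positive endorsement (proof-of-authority
style).  Offline nodes return nothing and therefore count against the
quorum; malicious nodes endorse everything; endorsements with bad
signatures are discarded before counting.

All actors are in-process.  Node keys are HMAC-SHA256 secrets derived
deterministically from the consortium and node ids and registered with
the channel — a stand-in for a membership service provider, which keeps
the signature discipline (a tampered signature never counts) without a
PKI.
"""

from __future__ import annotations

import hashlib
import hmac
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timedelta, timezone
from typing import Mapping

import yaml

from .errors import ConfigError, NotFoundError, PermissionDeniedError, ProposalRejected, ResyncError
from .ledger import Block, Ledger, Transaction, append_block, block_hash, clone, verify_chain
from .schema import TemplateRegistry, builtin_registry, validate_record
from .storage import StorageNode

_EPOCH = datetime(1970, 1, 1, tzinfo=timezone.utc)


def logical_timestamp(tick: int) -> str:
    """Orderer timestamps: a logical clock rendered as UTC instants."""
    return (_EPOCH + timedelta(seconds=tick)).strftime("%Y-%m-%dT%H:%M:%SZ")


HONEST = "honest-online"
OFFLINE = "offline"
MALICIOUS = "malicious"
NODE_STATUSES = (HONEST, OFFLINE, MALICIOUS)


def derive_node_key(consortium_id: str, node_id: str) -> bytes:
    """Deterministic per-node signing secret (simulated enrollment)."""
    return hashlib.sha256(f"evc-key:{consortium_id}:{node_id}".encode()).digest()


@dataclass
class EVCNode:
    """Endorser-validator-committer peer holding one ledger replica."""

    node_id: str
    org_id: str
    key: bytes
    status: str = HONEST
    replica: Ledger = dc_field(default_factory=Ledger.new)

    def sign(self, proposal_digest: str, verdict: bool) -> str:
        msg = f"{proposal_digest}:{int(verdict)}".encode()
        return hmac.new(self.key, msg, hashlib.sha256).hexdigest()


@dataclass(frozen=True)
class Endorsement:
    node_id: str
    proposal_digest: str
    verdict: bool
    signature: str


def verify_endorsement(endorsement: Endorsement, key: bytes) -> bool:
    msg = f"{endorsement.proposal_digest}:{int(endorsement.verdict)}".encode()
    expected = hmac.new(key, msg, hashlib.sha256).hexdigest()
    return hmac.compare_digest(expected, endorsement.signature)


@dataclass
class Organization:
    org_id: str
    domain_name: str
    evc_node_ids: list[str] = dc_field(default_factory=list)
    storage_node_ids: list[str] = dc_field(default_factory=list)


@dataclass
class Channel:
    channel_id: str
    member_org_ids: set[str] = dc_field(default_factory=set)


@dataclass
class Consortium:
    consortium_id: str
    channel_ids: set[str] = dc_field(default_factory=set)
    users: dict[str, str] = dc_field(default_factory=dict)  # user id -> org id


@dataclass
class Orderer:
    """Sequences endorsed proposals and packages blocks, FIFO, one
    transaction per block, stamping each block from a logical clock."""

    orderer_id: str
    channel_id: str
    clock: int = 0

    def next_timestamp(self) -> str:
        self.clock += 1
        return logical_timestamp(self.clock)


def endorse(
    node: EVCNode, proposal: Transaction, templates: TemplateRegistry
) -> Endorsement | None:
    """One node's endorsement of a proposal; ``None`` when offline.

    Honest nodes validate the record against the registered template
    (an unregistered template is an unknown-template failure) and sign
    their true verdict; malicious nodes sign an approval regardless.
    """
    if node.status == OFFLINE:
        return None
    digest = proposal.proposal_digest
    if node.status == MALICIOUS:
        verdict = True
    else:
        template = templates.get(proposal.template_id)
        if template is None:
            verdict = False
        else:
            verdict = validate_record(proposal.record, template).valid
    return Endorsement(node.node_id, digest, verdict, node.sign(digest, verdict))


@dataclass(frozen=True)
class Decision:
    commit: bool
    approvals: int
    electorate: int
    reason: str


def decide(
    endorsements: list[Endorsement],
    electorate_keys: Mapping[str, bytes],
) -> Decision:
    """Strict-majority quorum over ALL registered channel EVC nodes.

    Commit iff the count of verifying, verdict-true endorsements from
    distinct registered nodes is strictly greater than E/2.  Absent
    (offline) nodes simply contribute nothing, which counts against the
    quorum; forged or tampered signatures are discarded before counting.
    """
    electorate = len(electorate_keys)
    if electorate < 1:
        raise ConfigError("channel has no registered EVC nodes")
    approvals = 0
    seen: set[str] = set()
    for e in endorsements:
        key = electorate_keys.get(e.node_id)
        if key is None or e.node_id in seen:
            continue
        if not verify_endorsement(e, key):
            continue
        seen.add(e.node_id)
        if e.verdict:
            approvals += 1
    commit = approvals * 2 > electorate
    reason = (
        f"{approvals} of {electorate} registered nodes endorsed"
        + ("" if commit else " — not a strict majority")
    )
    return Decision(commit=commit, approvals=approvals, electorate=electorate, reason=reason)


class Network:
    """The whole simulated consortium: topology, keys, replicas, orderer."""

    def __init__(
        self,
        consortium: Consortium,
        channels: dict[str, Channel],
        organizations: dict[str, Organization],
        evc_nodes: dict[str, EVCNode],
        storage_nodes: dict[str, StorageNode],
        templates: TemplateRegistry | None = None,
    ):
        self.consortium = consortium
        self.channels = channels
        self.organizations = organizations
        self.evc_nodes = evc_nodes
        self.storage_nodes = storage_nodes
        self.templates = templates if templates is not None else builtin_registry()
        self.orderers = {
            cid: Orderer(orderer_id=f"orderer-{cid}", channel_id=cid) for cid in channels
        }
        # the orderer's committed view of each channel's ledger
        self.ledgers = {cid: Ledger.new(replica_id=f"channel:{cid}") for cid in channels}
        for node in evc_nodes.values():
            node.replica = Ledger.new(replica_id=node.node_id)

    # -- topology ----------------------------------------------------------

    @classmethod
    def from_config(cls, config: Mapping) -> "Network":
        try:
            consortium_id = config["consortium"]
            channel_id = config.get("channel", "channel1")
            org_docs = config["organizations"]
        except KeyError as exc:
            raise ConfigError(f"topology config missing key {exc}") from exc
        consortium = Consortium(consortium_id=consortium_id, channel_ids={channel_id})
        channel = Channel(channel_id=channel_id)
        organizations: dict[str, Organization] = {}
        evc_nodes: dict[str, EVCNode] = {}
        storage_nodes: dict[str, StorageNode] = {}
        for doc in org_docs:
            org_id = doc["org_id"]
            org = Organization(org_id=org_id, domain_name=doc.get("domain", f"{org_id}.example.org"))
            for i in range(int(doc.get("evc_nodes", 2))):
                node_id = f"{org_id}-evc{i}"
                org.evc_node_ids.append(node_id)
                evc_nodes[node_id] = EVCNode(
                    node_id=node_id,
                    org_id=org_id,
                    key=derive_node_key(consortium_id, node_id),
                )
            for i in range(int(doc.get("storage_nodes", 3))):
                node_id = f"{org_id}-store{i}"
                org.storage_node_ids.append(node_id)
                storage_nodes[node_id] = StorageNode(node_id=node_id, org_id=org_id)
            organizations[org_id] = org
            if doc.get("member", True):
                channel.member_org_ids.add(org_id)
        for user in config.get("users", []):
            consortium.users[user["user_id"]] = user["org_id"]
        return cls(
            consortium=consortium,
            channels={channel_id: channel},
            organizations=organizations,
            evc_nodes=evc_nodes,
            storage_nodes=storage_nodes,
        )

    @classmethod
    def from_topology_file(cls, path) -> "Network":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_config(yaml.safe_load(fh))

    @property
    def default_channel_id(self) -> str:
        return next(iter(sorted(self.channels)))

    def channel_evc_nodes(self, channel_id: str) -> list[EVCNode]:
        channel = self.channels[channel_id]
        return [
            self.evc_nodes[nid]
            for org_id in sorted(channel.member_org_ids)
            for nid in self.organizations[org_id].evc_node_ids
        ]

    def channel_storage_nodes(self, channel_id: str) -> list[StorageNode]:
        channel = self.channels[channel_id]
        return [
            self.storage_nodes[nid]
            for org_id in sorted(channel.member_org_ids)
            for nid in self.organizations[org_id].storage_node_ids
        ]

    def electorate_keys(self, channel_id: str) -> dict[str, bytes]:
        return {n.node_id: n.key for n in self.channel_evc_nodes(channel_id)}

    def user_org(self, user_id: str) -> str:
        try:
            return self.consortium.users[user_id]
        except KeyError as exc:
            raise PermissionDeniedError(f"unknown user {user_id!r}") from exc

    def is_member(self, user_id: str, channel_id: str | None = None) -> bool:
        cid = channel_id or self.default_channel_id
        org = self.consortium.users.get(user_id)
        return org is not None and org in self.channels[cid].member_org_ids

    # -- lifecycle ---------------------------------------------------------

    def submit_proposal(
        self, proposal: Transaction, channel_id: str | None = None
    ) -> Block:
        """Run the full endorse → decide → order → commit lifecycle.

        On commit the orderer stamps one block carrying the transaction
        (with its collected endorsements) and appends it to the channel
        ledger and every online member replica; offline replicas catch
        up at :meth:`resync`.  On rejection nothing changes anywhere and
        :class:`ProposalRejected` carries the violation list from an
        honest validation pass.
        """
        cid = channel_id or self.default_channel_id
        channel = self.channels[cid]
        submitter_org = self.consortium.users.get(proposal.submitter)
        if submitter_org is None or submitter_org not in channel.member_org_ids:
            raise PermissionDeniedError(
                f"submitter {proposal.submitter!r} is not a registered user of a member organization"
            )
        nodes = self.channel_evc_nodes(cid)
        endorsements = [
            e for e in (endorse(n, proposal, self.templates) for n in nodes) if e is not None
        ]
        decision = decide(endorsements, self.electorate_keys(cid))
        if not decision.commit:
            template = self.templates.get(proposal.template_id)
            if template is None:
                violations = (("template_id", "unknown-template", "template not registered"),)
            else:
                violations = tuple(validate_record(proposal.record, template).violations)
            raise ProposalRejected(decision.reason, violations=violations)

        committed = Transaction(
            did=proposal.did,
            version=proposal.version,
            record=proposal.record,
            metadata_digest=proposal.metadata_digest,
            data_digest=proposal.data_digest,
            submitter=proposal.submitter,
            template_id=proposal.template_id,
            endorsements=tuple((e.node_id, e.signature) for e in endorsements),
        )
        timestamp = self.orderers[cid].next_timestamp()
        try:
            append_block(self.ledgers[cid], [committed], timestamp)
        except Exception:
            self.orderers[cid].clock -= 1
            raise
        block = self.ledgers[cid].tip
        for node in nodes:
            if node.status != OFFLINE:
                node.replica.blocks.append(block)
        return block

    # -- fault injection and recovery --------------------------------------

    def inject_fault(self, node_id: str, status: str) -> None:
        """Replace a node's status (idempotent)."""
        if status not in NODE_STATUSES:
            raise ConfigError(f"unknown node status {status!r}")
        try:
            self.evc_nodes[node_id].status = status
        except KeyError as exc:
            raise NotFoundError(f"unknown EVC node {node_id!r}") from exc

    def restore(self, node_id: str) -> None:
        self.inject_fault(node_id, HONEST)

    def resync(self, node_id: str, channel_id: str | None = None) -> int:
        """Adopt the longest verified-consistent replica in the channel.

        Candidate replicas are checked with verify_chain before
        adoption; if every longer candidate is inconsistent, resync
        fails loudly rather than silently adopting a tampered chain.
        Returns the number of blocks gained.
        """
        cid = channel_id or self.default_channel_id
        try:
            node = self.evc_nodes[node_id]
        except KeyError as exc:
            raise NotFoundError(f"unknown EVC node {node_id!r}") from exc
        peers = [n for n in self.channel_evc_nodes(cid) if n.node_id != node_id]
        candidates = sorted(
            (p.replica for p in peers), key=len, reverse=True
        )
        before = len(node.replica)
        reports = {}
        for candidate in candidates:
            if len(candidate) <= before:
                break  # no longer candidates remain
            report = verify_chain(candidate)
            if report.consistent:
                node.replica = clone(candidate, replica_id=node_id)
                return len(node.replica) - before
            reports[candidate.replica_id] = report
        if reports:
            raise ResyncError(
                "every longer peer replica failed chain verification", reports=reports
            )
        return 0

    def status(self) -> dict:
        """Human-oriented summary used by the CLI."""
        return {
            "consortium": self.consortium.consortium_id,
            "channels": {
                cid: {
                    "members": sorted(ch.member_org_ids),
                    "ledger_blocks": len(self.ledgers[cid]),
                }
                for cid, ch in self.channels.items()
            },
            "evc_nodes": {
                nid: {"org": n.org_id, "status": n.status, "replica_blocks": len(n.replica)}
                for nid, n in sorted(self.evc_nodes.items())
            },
            "storage_nodes": {
                nid: {"org": n.org_id, "status": n.status, "shards": len(n.store)}
                for nid, n in sorted(self.storage_nodes.items())
            },
        }
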