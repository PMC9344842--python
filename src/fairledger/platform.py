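"""Platform facade tying the (meta)data lifecycle together.

Upload: validate → endorse → commit → store.  Shards are written to a
staging namespace first; the transaction is committed to the ledger and
only then is staging promoted, so a rejected or crashed upload leaves
neither metadata nor shards behind.  Download: search/resolve the
ledger, then gather and reconstruct shards.  Access is permissioned:
users authenticate with a salted-hash credential and must belong to an
organization of the consortium's channel; data purge requires admin
rights and leaves the ledger untouched — metadata then points at
non-existing data, reported as an explicit data-missing status.

Payloads are deduplicated by content address: two DIDs describing the
same bytes share one stored object, and a purge therefore reports every
affected DID.
"""

from __future__ import annotations

import hashlib
import json
import secrets
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from ._canon import sha256_hex
from .errors import (
    AuthenticationError,
    ConfigError,
    DataUnavailableError,
    NotFoundError,
    PermissionDeniedError,
)
from .ledger import Ledger, Transaction, append_block, from_jsonl, to_jsonl, verify_chain
from .network import Network, logical_timestamp
from .schema import MetadataRecord, record_digest
from .storage import (
    ObjectManifest,
    StorageConfig,
    discard_staged,
    get_object,
    promote_object,
    purge_object,
    stage_object,
)
from .versioning import VersionChain, get_version, history, latest, mint_did


@dataclass
class User:
    user_id: str
    org_id: str
    salt: str
    secret_hash: str
    admin: bool = False

    @classmethod
    def create(cls, user_id: str, org_id: str, secret: str, admin: bool = False) -> "User":
        salt = secrets.token_hex(8)
        return cls(user_id, org_id, salt, _hash_secret(salt, secret), admin)

    def check(self, secret: str) -> bool:
        return secrets.compare_digest(self.secret_hash, _hash_secret(self.salt, secret))


def _hash_secret(salt: str, secret: str) -> str:
    return hashlib.sha256(f"{salt}:{secret}".encode()).hexdigest()


@dataclass(frozen=True)
class UploadResult:
    did: str
    version: int
    object_id: str
    deduplicated: bool


@dataclass(frozen=True)
class DownloadResult:
    did: str
    version: int
    record: MetadataRecord
    payload: bytes | None
    data_available: bool


@dataclass(frozen=True)
class PurgeReport:
    object_id: str
    removed_shards: int
    affected_dids: tuple[str, ...]


class Platform:
    """One consortium deployment: network + storage + user registry."""

    def __init__(self, network: Network, storage_config: StorageConfig | None = None):
        self.network = network
        self.storage_config = storage_config or StorageConfig.default(8)
        self.users: dict[str, User] = {}
        self.manifests: dict[str, ObjectManifest] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_config(cls, config: Mapping) -> "Platform":
        network = Network.from_config(config)
        st = config.get("storage", {})
        storage_config = StorageConfig(
            data_shards=int(st.get("data_shards", 4)),
            parity_shards=int(st.get("parity_shards", 4)),
        )
        platform = cls(network, storage_config)
        for doc in config.get("users", []):
            platform.register_user(
                doc["user_id"], doc["org_id"], doc["secret"], admin=bool(doc.get("admin"))
            )
        return platform

    @classmethod
    def from_topology_file(cls, path) -> "Platform":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_config(yaml.safe_load(fh))

    def register_user(self, user_id: str, org_id: str, secret: str, admin: bool = False) -> User:
        if org_id not in self.network.organizations:
            raise ConfigError(f"unknown organization {org_id!r} for user {user_id!r}")
        user = User.create(user_id, org_id, secret, admin)
        self.users[user_id] = user
        self.network.consortium.users[user_id] = org_id
        return user

    # -- auth --------------------------------------------------------------

    def authenticate(self, user_id: str, secret: str) -> User:
        user = self.users.get(user_id)
        if user is None or not user.check(secret):
            raise AuthenticationError("unknown user or wrong credential")
        return user

    def _authorize_member(self, user: User, channel_id: str | None = None) -> None:
        cid = channel_id or self.network.default_channel_id
        if user.org_id not in self.network.channels[cid].member_org_ids:
            raise PermissionDeniedError(
                f"user {user.user_id!r} belongs to {user.org_id!r}, "
                f"not a member organization of channel {cid!r}"
            )

    # -- ledger access -----------------------------------------------------

    @property
    def ledger(self) -> Ledger:
        return self.network.ledgers[self.network.default_channel_id]

    def history(self, did: str) -> VersionChain:
        return history(self.ledger, did)

    def search(self, query: Mapping[str, str], latest_only: bool = False):
        from .ledger import search as ledger_search

        return ledger_search(self.ledger, query, latest_only=latest_only)

    def verify(self) -> dict:
        """Verify the channel ledger and every member replica."""
        reports = {"channel": verify_chain(self.ledger)}
        cid = self.network.default_channel_id
        for node in self.network.channel_evc_nodes(cid):
            reports[node.node_id] = verify_chain(node.replica)
        return reports

    # -- lifecycle ---------------------------------------------------------

    def upload(
        self, user_id: str, secret: str, record: MetadataRecord, payload: bytes
    ) -> UploadResult:
        """Metadata-first upload with staged data promotion.

        The shards are staged before endorsement, the transaction is
        committed, then staging is promoted; any rejection discards the
        staging so no shard outlives a failed upload.
        """
        user = self.authenticate(user_id, secret)
        self._authorize_member(user)
        nodes = self.network.channel_storage_nodes(self.network.default_channel_id)
        object_id = sha256_hex(payload)
        deduplicated = object_id in self.manifests
        if not deduplicated:
            manifest = stage_object(payload, nodes, self.storage_config)
        else:
            manifest = self.manifests[object_id]
        metadata_digest = record_digest(record)
        did = mint_did(object_id, metadata_digest)
        proposal = Transaction(
            did=did,
            version=1,
            record=record,
            metadata_digest=metadata_digest,
            data_digest=object_id,
            submitter=user_id,
            template_id=record.template_id,
        )
        try:
            self.network.submit_proposal(proposal)
        except Exception:
            if not deduplicated:
                discard_staged(object_id, nodes)
            raise
        if not deduplicated:
            promote_object(object_id, nodes)
            self.manifests[object_id] = manifest
        return UploadResult(did=did, version=1, object_id=object_id, deduplicated=deduplicated)

    def update(
        self, user_id: str, secret: str, did: str, new_record: MetadataRecord
    ) -> int:
        """Re-validate an updated record as if it were a new entry and,
        on commit, append version n+1 bound to the unchanged data."""
        user = self.authenticate(user_id, secret)
        self._authorize_member(user)
        current = latest(self.ledger, did)
        proposal = Transaction(
            did=did,
            version=current.version + 1,
            record=new_record,
            metadata_digest=record_digest(new_record),
            data_digest=current.data_digest,
            submitter=user_id,
            template_id=new_record.template_id,
        )
        self.network.submit_proposal(proposal)
        return current.version + 1

    def download(
        self, user_id: str, secret: str, did: str, version: int | None = None
    ) -> DownloadResult:
        """Resolve a metadata version and reconstruct its payload.

        Purged or unreachable data is reported as an explicit
        data-missing status alongside the metadata, never as an opaque
        failure.
        """
        user = self.authenticate(user_id, secret)
        self._authorize_member(user)
        chain = history(self.ledger, did)
        v = version if version is not None else chain.latest_version
        record = get_version(self.ledger, did, v)
        manifest = self.manifests.get(chain.data_digest)
        payload: bytes | None = None
        if manifest is not None:
            nodes = self.network.channel_storage_nodes(self.network.default_channel_id)
            try:
                payload = get_object(manifest, nodes)
            except DataUnavailableError:
                payload = None
        return DownloadResult(
            did=did,
            version=v,
            record=record,
            payload=payload,
            data_available=payload is not None,
        )

    def purge_data(self, user_id: str, secret: str, did: str) -> PurgeReport:
        """Delete every shard of the DID's object; the ledger is untouched.

        Requires admin rights.  Because storage is deduplicated by
        content, the report names every DID whose data disappears with
        the shared object.  Idempotent.
        """
        user = self.authenticate(user_id, secret)
        if not user.admin:
            raise PermissionDeniedError("purge requires admin privileges")
        chain = history(self.ledger, did)  # raises NotFoundError for unknown DIDs
        object_id = chain.data_digest
        nodes = self.network.channel_storage_nodes(self.network.default_channel_id)
        removed = purge_object(object_id, nodes)
        affected = sorted(
            {tx.did for _, _, tx in self.ledger.transactions() if tx.data_digest == object_id}
        )
        return PurgeReport(
            object_id=object_id, removed_shards=removed, affected_dids=tuple(affected)
        )

    def export_open_ledger(self, dids: set[str] | list[str]) -> Ledger:
        """Re-package all versions of the selected DIDs into a fresh chain.

        Records are NOT re-validated against templates (that already
        happened at original submission), but every hash is recomputed
        because block order changes; the result is a new, internally
        consistent public chain with its own genesis.
        """
        wanted = set(dids)
        known = {tx.did for _, _, tx in self.ledger.transactions()}
        missing = sorted(wanted - known)
        if missing:
            raise NotFoundError(f"unknown DIDs: {', '.join(missing)}")
        # continue the logical clock past the source tip so the exported
        # chain never collides with the private one, deterministically
        tick = len(self.ledger.blocks) + 1
        exported = Ledger.new(
            replica_id="open-export", genesis_timestamp=logical_timestamp(tick)
        )
        for _, _, tx in self.ledger.transactions():
            if tx.did in wanted:
                tick += 1
                append_block(exported, [tx], logical_timestamp(tick))
        return exported

    # -- persistence -------------------------------------------------------

    def save(self, state_dir) -> None:
        root = Path(state_dir)
        root.mkdir(parents=True, exist_ok=True)
        (root / "ledger.jsonl").write_text(to_jsonl(self.ledger), encoding="utf-8")
        state = {
            "storage": {
                "data_shards": self.storage_config.data_shards,
                "parity_shards": self.storage_config.parity_shards,
            },
            "consortium": self.network.consortium.consortium_id,
            "channel": self.network.default_channel_id,
            "organizations": [
                {
                    "org_id": org.org_id,
                    "domain": org.domain_name,
                    "evc_nodes": len(org.evc_node_ids),
                    "storage_nodes": len(org.storage_node_ids),
                    "member": org.org_id
                    in self.network.channels[self.network.default_channel_id].member_org_ids,
                }
                for org in self.network.organizations.values()
            ],
            "users": [
                {
                    "user_id": u.user_id,
                    "org_id": u.org_id,
                    "salt": u.salt,
                    "secret_hash": u.secret_hash,
                    "admin": u.admin,
                }
                for u in self.users.values()
            ],
            "node_status": {n.node_id: n.status for n in self.network.evc_nodes.values()},
            "storage_status": {
                n.node_id: n.status for n in self.network.storage_nodes.values()
            },
            "orderer_clock": self.network.orderers[self.network.default_channel_id].clock,
            "manifests": {oid: m.to_dict() for oid, m in self.manifests.items()},
        }
        (root / "state.json").write_text(json.dumps(state, indent=1), encoding="utf-8")
        shard_root = root / "nodes"
        for node in self.network.storage_nodes.values():
            node_dir = shard_root / node.node_id
            node_dir.mkdir(parents=True, exist_ok=True)
            kept = set()
            for (object_id, idx), shard in node.store.items():
                name = f"{object_id}.{idx}"
                kept.add(name)
                (node_dir / name).write_bytes(shard.payload)
            for existing in node_dir.iterdir():
                if existing.name not in kept:
                    existing.unlink()

    @classmethod
    def load(cls, state_dir) -> "Platform":
        root = Path(state_dir)
        state = json.loads((root / "state.json").read_text(encoding="utf-8"))
        network = Network.from_config(
            {
                "consortium": state["consortium"],
                "channel": state["channel"],
                "organizations": state["organizations"],
            }
        )
        platform = cls(
            network,
            StorageConfig(
                data_shards=state["storage"]["data_shards"],
                parity_shards=state["storage"]["parity_shards"],
            ),
        )
        for doc in state["users"]:
            user = User(
                user_id=doc["user_id"],
                org_id=doc["org_id"],
                salt=doc["salt"],
                secret_hash=doc["secret_hash"],
                admin=doc["admin"],
            )
            platform.users[user.user_id] = user
            network.consortium.users[user.user_id] = user.org_id
        chain = from_jsonl(
            (root / "ledger.jsonl").read_text(encoding="utf-8"),
            replica_id=f"channel:{state['channel']}",
        )
        network.ledgers[state["channel"]] = chain
        for node in network.evc_nodes.values():
            node.replica = from_jsonl(to_jsonl(chain), replica_id=node.node_id)
            node.status = state["node_status"].get(node.node_id, node.status)
        for node_id, status in state.get("storage_status", {}).items():
            if node_id in network.storage_nodes:
                network.storage_nodes[node_id].status = status
        network.orderers[state["channel"]].clock = int(state["orderer_clock"])
        platform.manifests = {
            oid: ObjectManifest.from_dict(d) for oid, d in state["manifests"].items()
        }
        from .storage import Shard

        shard_root = root / "nodes"
        if shard_root.exists():
            for node_dir in shard_root.iterdir():
                node = network.storage_nodes.get(node_dir.name)
                if node is None:
                    continue
                for shard_file in node_dir.iterdir():
                    object_id, _, idx = shard_file.name.rpartition(".")
                    node.store[(object_id, int(idx))] = Shard.make(
                        object_id, int(idx), shard_file.read_bytes()
                    )
        return platform
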