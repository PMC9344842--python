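# fairledger

Cross-disciplinary research collaborations need to share heterogeneous
experimental data with some guarantee of FAIRness — findable,
accessible, interoperable, reusable — without handing control of the
data to a single central host.  `fairledger` is a self-contained,
desk-scale implementation of a consortium data platform built on three
ideas:

1. **Metadata quality control by majority endorsement.**  Every
   metadata record is validated against a registered template
   (Dublin Core base + experiment extensions) by the consortium's
   endorser-validator-committer (EVC) nodes; a submission commits only
   when a strict majority of all registered nodes approves, so no
   single participant decides what counts as valid metadata and the
   system stays live while > 50 % of nodes are honest and online.
2. **A tamper-evident ledger that *is* the metadata database.**
   Committed transactions live in SHA-256 hash-chained blocks
   replicated on every member node; any retroactive edit produces
   identifiable inconsistencies that `verify_chain` localizes to a
   block.
3. **Erasure-coded storage with immutable data and versioned
   metadata.**  Payloads are split into N = k + m systematic
   Reed–Solomon shards over GF(2⁸) (default k = m = N/2), spread across
   organizations, and recoverable from any k shards — losing half the
   devices loses nothing.  Each submission mints a stable Data ID
   (DID); metadata updates are re-validated and appended as new
   versions that all point at the same immutable payload.

Everything — organizations, channels, EVC nodes, the orderer, storage
devices — is an in-process simulated actor, which makes the whole
platform deterministic and exhaustively testable.  It is intended for
people studying or prototyping FAIR data-sharing infrastructure, not as
a production service.

## The core mechanisms

*Quorum.*  A channel with E registered EVC nodes commits a proposal iff
the number of verifying, positive endorsements a > E/2.  Offline nodes
contribute nothing and therefore count against the quorum: on a
100-node channel the commit boundary sits exactly at a = 51.

*Chaining.*  Block *i* stores `previous_hash = H(header_{i-1})` and a
payload hash over its canonically serialized transactions; each
serialized block also carries its own header hash so the chain tip is
bound too.  Verification recomputes all three per block.

*Erasure code.*  Data stripes `d_0..d_{k-1}` are extended with parity
`p_j = Σ_i c_{ji} d_i` over GF(2⁸), `c_{ji} = (i ⊕ (k+j))^{-1}` (a
Cauchy construction), giving a maximum-distance-separable code: any k
of the N shards reconstruct, any k−1 do not.

## Worked example

```
$ fairledger init --config topology.yaml --state state      # 3 orgs × 2 EVC + 9 storage nodes
$ fairledger fixtures --seed 42 -n 2 --out corpus
$ fairledger upload --state state --user alice --secret alginate-fiber \
      --meta corpus/record_000.json --data corpus/payload_000.bin
{"did": "c751fc59a12fbf9c66fb4329d1f96898", "version": 1,
 "object_id": "cf65b7045dfcf7fdd77ed3d866f70148ba38e1b99f407353fb3e188067609d42",
 "deduplicated": false}
```

The upload was endorsed by all six EVC nodes, committed as block 1 on
every replica, and the 1 KiB payload was split into 8 shards across the
three organizations.  `did` is the stable Data ID linking metadata and
data; `object_id` is the content address (SHA-256) of the payload.

```
$ fairledger download --state state --user bob --secret collagen-gel \
      -o restored.bin c751fc59a12fbf9c66fb4329d1f96898
{"did": "c751fc59a12fbf9c66fb4329d1f96898", "version": 1,
 "record": {"template_id": "fiber-manufacture", "values": {...}},
 "data_available": true, "bytes": 1024}
$ cmp restored.bin corpus/payload_000.bin && echo PAYLOAD-IDENTICAL
PAYLOAD-IDENTICAL
```

A user of another member organization retrieves the latest metadata
version and the byte-identical payload.  History and chain verification:

```
$ fairledger history --state state c751fc59a12fbf9c66fb4329d1f96898
{"did": "c751fc59a12fbf9c66fb4329d1f96898",
 "data_digest": "cf65b7045dfcf7fdd77ed3d866f70148ba38e1b99f407353fb3e188067609d42",
 "versions": [{"version": 1, "block": 1, "metadata_digest": "2cfd6a99..."}]}
$ fairledger verify --state state
{"channel": {"consistent": true, "findings": []}, ...}
```

`update` appends re-validated metadata versions (the data digest never
changes), `purge` deletes every shard of a DID's object while the
metadata keeps resolving with an explicit data-missing status, and
`export` re-packages selected DIDs into a fresh, internally consistent
open ledger.  The same operations are available as a Python API:

```python
from fairledger import Platform
platform = Platform.from_topology_file("topology.yaml")
result = platform.upload("alice", "alginate-fiber", record, payload)
platform.download("bob", "collagen-gel", result.did)
```

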