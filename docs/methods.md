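# Methods

`fairledger` simulates, in a single process, a permissioned consortium
that enforces metadata quality before data ever reaches storage.  This
note records the models behind each component, the parameters that
matter, the numerical and design choices that were genuinely open, and
what the simulation does and does not show about a real deployment.

## Metadata model and validation

Metadata is a flat map of field name → text value, validated against a
named, versioned template.  The base template is the 15-element Dublin
Core standard; experiment templates extend it (the packaged fiber
manufacture template adds 6 wet-lab fields, the measurement template
adds 8 characterization fields).  Seven field kinds cover every rule
the platform enforces: free text, controlled vocabulary, ISO 639-1
language codes, ISO 8601 calendar dates, integers, decimals and opaque
identifiers.

Decisions taken where the requirements were open:

* **Language codes** are checked syntactically — exactly two ASCII
  letters, case-insensitive.  An allowlist of assigned ISO 639-1 codes
  is built in but off by default (`enforce_iso639_codes=True` turns it
  on), because syntax is the only rule the platform promises and an
  allowlist drifts with the standard's registry.
* **Dates** follow ISO 8601 calendar form `YYYY-MM-DD`, the least
  ambiguous convention for a multi-national consortium.
* **Empty string counts as missing** for required fields: a form that
  submits `Title: ""` has not supplied a title.
* Numbers are stored as text (metadata is text) and parsed by kind;
  scientific notation such as `1e8` is a valid decimal, since cell
  densities are naturally written that way.  Units live in field names
  (`collagen_concentration_mg_per_ml`) and are documentation only —
  semantic unit checking is out of scope.

Every record hashes through a canonical byte form: UTF-8 JSON with
lexicographically sorted keys and no insignificant whitespace.  This
makes the digest a pure function of the key→value map, independent of
insertion order, so every node in the consortium derives the same
metadata digest — a precondition for replicas ever being byte-identical.

## Ledger

Blocks chain through SHA-256 (ubiquitous, deterministic, no parameter
choices).  A block stores its header (index, previous hash, payload
hash, timestamp), the transaction list, and — in serialized form — its
own header hash.  `verify_chain` recomputes three things per block: the
payload hash over the transactions, the self-hash over the header, and
the link `previous_hash == hash(block[i-1])`.  The stored self-hash is
what makes tampering with the *tip* block's header detectable: no
successor link covers it.  A "self-consistent forgery" (a replacement
block whose internal hashes are recomputed) is caught at the next
block's broken link, which is also the earliest position where it is
detectable.

The genesis block is fixed: index 0, all-zero previous hash, empty
transaction list and the epoch timestamp `1970-01-01T00:00:00Z`, so
independent deployments of the same consortium configuration share a
genesis.  All other timestamps come from the orderer's logical clock
(one tick per committed block), never from the wall clock — determinism
is what lets tests assert byte-identical replicas.

Append enforces the versioning invariants at the door: a transaction's
metadata digest must match its record, versions per DID must be
contiguous (no version 3 before version 2), and the data digest of a
DID can never change.  Search is exact-match and case-insensitive over
record values; free-text ranking is out of scope.

## Consensus

The consortium model follows the permissioned-blockchain vocabulary:
organizations contribute endorser-validator-committer (EVC) nodes, a
channel binds member organizations to one shared ledger, and a single
orderer per channel sequences commits FIFO, one transaction per block.

Endorsement is proof-of-authority style.  Each EVC node validates the
proposed record against the registered template and signs its verdict.
The decision rule is a **strict majority of all registered nodes**:
commit iff verifying, positive endorsements from distinct registered
nodes exceed E/2.  Counting the denominator over registered rather than
responding nodes means an offline node is a vote lost, which gives the
fault-tolerance phase boundary its sharp location: on a 100-node
channel a valid proposal commits exactly when ≥ 51 nodes are honest and
online (the acceptance sweep measures this boundary end to end).

The adversary model is deliberately minimal: a *malicious* node
endorses everything (approving invalid metadata), an *offline* node
returns nothing.  Equivocation and forged blocks are represented by the
ledger tamper tests rather than by live Byzantine actors.  Orderer
failure is out of scope — there is one orderer per channel.

Signatures are HMAC-SHA256 tags over `(proposal digest, verdict)` with
per-node keys derived deterministically from the consortium and node
ids and registered with the channel.  This simulated enrollment plays
the role a membership service provider would play in a production
permissioned network; it preserves the property the tests rely on —
a tampered or forged endorsement never counts toward quorum — without
dragging a PKI into an in-process simulation.  It is *not*
publicly-verifiable cryptography: anyone holding the registry could
forge tags, which is acceptable only because all actors live in one
process.

A node returning from downtime resynchronizes by adopting the longest
peer replica **that passes full chain verification**; if every longer
candidate fails verification, resync refuses and surfaces the tamper
reports rather than silently adopting a forged chain.

## Storage

Payloads are erasure-coded over GF(2⁸) with reducing polynomial 0x11D.
The code is systematic Reed–Solomon: the payload, zero-padded to a
multiple of k (true length kept in the manifest), forms k data stripes;
m parity stripes are produced by a Cauchy generator with x_i = i,
y_j = k + j, which guarantees every k×k submatrix of the stacked
generator is invertible for N ≤ 256.  Decoding solves the k×k system by
Gaussian elimination over the field.  The defaults k = m = N/2 with
N = 8 give the headline property: any half of the devices suffices, so
the tolerated loss fraction is exactly 0.5.  k = 1 degenerates to plain
replication.

Objects are content-addressed (object id = SHA-256 of the payload), so
identical payloads deduplicate to one stored object.  Placement is
round-robin across organizations with a per-organization cap of
⌈N/#orgs⌉ shards per object, so no single organization's failure can
destroy recoverability once there are ≥ 2 organizations and N ≥ 4.
Corrupt shards are detected by digest comparison against the manifest
and excluded; error-locating decoding of silently corrupted symbols is
out of scope.

`gf_mul` is implemented as the carry-less peasant multiplication — the
defining primitive — and the log/antilog tables used for speed are
derived from it at import.  The test suite cross-checks the full 256×256
multiplication table and the encoder output against an independently
written log/antilog implementation.

## Versioning

A submission mints a DID: the first 32 hex characters of SHA-256 over
the concatenated data digest and initial metadata digest.  Content-based
derivation (rather than a UUID) makes every test deterministic; the
platform only requires uniqueness, which holds except for the identical
(data, metadata) resubmission — and that duplicate is exactly the case
the ledger rejects as a replayed version 1.

An update is re-validated through the full endorsement lifecycle as if
it were a new entry; on commit it becomes version n+1 bound to the
unchanged data digest.  Full records are stored per version (no deltas
— blocks are tiny at this scale, and retrieval of any version stays a
pure ledger scan).  History is *derived*, never stored: the version
index can be deleted and rebuilt from the ledger with identical
results.  Concurrent updates are linearized by the orderer's FIFO
order; there is no branching or merging.

## Platform lifecycle

Upload is metadata-first with staged storage: shards are written to a
staging namespace, the transaction is endorsed and committed, and only
then is staging promoted to the visible store.  A rejection (or a crash
before promotion) therefore leaves neither committed metadata pointing
at never-stored data nor orphaned visible shards.  Download resolves
the requested (default latest) metadata version from the ledger and
reconstructs the payload from any k reachable valid shards.

Authentication is a salted-hash credential check; authorization is
consortium membership only (users of non-member organizations can
neither submit nor download).  Purging data removes every shard of the
object from every node while leaving the ledger untouched — the
metadata then points at non-existing data, reported as an explicit
data-missing status, and the purge report names every DID sharing the
deduplicated object.  Export re-packages all versions of selected DIDs
into a fresh open chain: records are not re-validated (that already
happened at submission), but every hash is recomputed because block
order changes; the exported chain's clock continues past the source
tip, so its hashes never collide with the private chain's.

## Fixture generator

The generator emulates the two-phase fiber workflow the platform was
built around.  Manufacture records carry the documented fabrication
conditions — HEK293 cells, 4 mg/ml collagen, 1 × 10⁸ cells/ml, 200
µl/min alginate flow, 100 mM CaCl₂, incubation at 37 °C (flow jittered
across 180/200/220 µl/min to vary the corpus) — and measurement records
carry inner/outer diameters at three points (90–130 µm and 180–260 µm)
from at least five microscope images.  Payloads are seeded pseudo-random
bytes, 1 KiB by default, standing in for instrument output.  Corruption
modes each plant exactly one violation (dropped required field, bad
language code, off-vocabulary cell type, malformed date, non-numeric
value) on odd-indexed records, so validator tests can assert the exact
violation kind.  The same seed always reproduces a byte-identical
corpus.

What the generator does **not** emulate: realistic payload content,
heterogeneous or nested metadata, schema drift over time, clock skew,
network partitions or concurrent submitters.  Passing tests show the
control and data planes behave correctly under the stated fault models
at desk scale; they say nothing about throughput, real network
adversaries or the ergonomics of real instrument metadata.

## Problem sizes and numerical notes

Tests run the exhaustive sweeps at sizes where exhaustion is exact and
fast: the full 2⁸ shard-availability sweep at N = 8 (163 reconstructable
subsets, tolerated loss exactly 0.5), the 0–100 availability sweep on a
100-node channel (boundary at 51), every single-character corruption of
a 10-block ledger (> 2000 mutations, all detected), 200-operation random
API sequences against one DID, and the complete 256×256 field
multiplication table against the independent oracle.  Gaussian
elimination over GF(2⁸) is exact integer arithmetic — there are no
tolerances anywhere in the package; every assertion is equality.

## Known limitations

* One orderer per channel; its failure halts commits (no Raft).
* HMAC endorsements are not publicly verifiable (see above).
* The quorum rule counts nodes, not stake or organizations: a single
  organization contributing > E/2 nodes could commit alone.
* Search is a linear scan; fine at desk scale, no indexing.
* Purge removes shards but cannot prove remote erasure — in a real
  deployment that guarantee is organizational, not technical.
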