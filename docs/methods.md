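# Methods

This note records the engine's design: the models and procedures it
implements, the parameters that matter, what the synthetic data does and
does not emulate, and the choices made where the design was genuinely
open.

## Event-sourced persistence

The dataset is defined as a left fold over an append-only log of change
records. A record is `(seq, ts, user, family, id, op, payload)` with
`op ∈ {add, mod, del}`; sequence numbers are contiguous from 1 and a
record is fsynced before the append is acknowledged. The fold function
(`store.apply_record`) is the *single* transition used both for startup
replay and for live mutations, so the two paths cannot diverge; tests
still check the equality over serialized round trips, because the NDJSON
encode/decode step is only on the replay path.

Consequences of this design:

- any prefix of a valid log is a valid dataset (crash consistency);
- the complete history of every entity is the subsequence of records
  carrying its id (each record is indexed exactly once, so history
  lengths sum to the log length);
- deletion is a flag (`del` keeps the entity and its history) — the
  review requirement forbids physical removal;
- ids are allocated server-side per family as `max existing + 1`.

The in-memory tree is persistent (copy-on-write): applying a record
builds a new tree sharing unmodified family maps with the old one.
Readers therefore never lock — they hold a snapshot — and all writers
serialize through one lock (validate → append → swap the tree
reference). A reader concurrent with a writer sees exactly the state
after some log prefix, which is the property the concurrency tests
assert.

Referential integrity is enforced on apply for project links, structural
parents (container→compound, biodata→container, file→parent), and
vocabulary links (location, supplier, method). `project.owner` and
`user.projects` are deliberately *not* enforced: users and projects
reference each other cyclically and are weakly linked; a dangling grant
is harmless (it grants nothing).

Binary attachments and per-user settings live in an embedded SQLite
database outside the history: files are large and immutable in practice
(the blob store is content-addressed by SHA-256), and settings change
with nearly every client interaction, so historizing either would cost
much and buy nothing.

### Schema evolution

Stored JSON is decoded tolerantly: fields missing from old records
decode as absent (optional fields) or take their declared defaults;
unknown fields are ignored with a warning. Only a missing mandatory
field without a default is an error, reported by name. This lets the
schema grow without touching data on disk.

## Shape variants and codecs

Every entity family has four variants with systematic properties — Srv
(id present, child-id collections present, molfile source validated),
Add (no id, no children), Mod (every field optional; absent = unchanged,
explicit null = clear), Cli (links resolved to `(id, name)` pairs,
structure replaced by SVG, sensitive fields absent). The JSON codec is
the pydantic dump with stable field names; Mod dumps only explicitly-set
fields. Project grant sets serialize sorted so encodings are
byte-stable. `decode(encode(x)) == x` is property-tested over random
instances of every variant.

One representational choice: the spec-level idea of "the stored record
holds the molecule" is realized as *validated molfile source text* in
the Srv record — creation fails unless the molfile parses — with the
parsed, state-tagged `Molecule` derived on demand behind an LRU cache.
The text is the canonical codec form; the cache makes repeated structure
queries cheap (a dataset has few distinct structures relative to query
volume).

## Chemistry facade

All chemistry goes through one module wrapping RDKit, with two rules:

1. **Totality** — every fallible operation returns a `Result` carrying a
   `ChemErr` (`parse_err`, `empty_molecule`, `state_err`, `render_err`)
   with input context; nothing raises for any byte-string input. This is
   fuzz-tested.
2. **Truthful state tags** — a `Molecule` is `(graph, state)` with
   `state ∈ {kekulized, aromatized, search_ready}`. Parsing yields
   `kekulized`; `normalize` moves between states and is idempotent
   (re-aromatizing an aromatized molecule is a no-op, which prevents the
   double-aromatization class of bugs while keeping the API total);
   matching demands `search_ready` from both arguments and fails with
   `state_err` otherwise, rather than silently coercing.

`search_ready` means: aromatized representation with explicit hydrogens
attached. Substructure matching, however, compares the *heavy-atom*
skeleta under element/bond-order/aromaticity compatibility: explicit
hydrogens are not themselves match constraints. With hydrogens as hard
constraints, a benzene query could never hit toluene (six ring H cannot
inject into five), which contradicts both chemical intent and the
standard semantics of substructure search; the matching contract is
stated in terms of heavy atoms throughout.

Only the V2000 molfile dialect is accepted; V3000 input is rejected with
a parse error naming the dialect (smallest faithful surface; the SDF
writer emits V2000 too). Reactions, 3D conformers, InChI and
stereo-aware matching beyond the toolkit default are out of scope.

Fingerprints are Morgan (circular), radius 2, folded to 2048 bits — the
de-facto default where no scheme is otherwise prescribed — and
similarity is the Tanimoto coefficient over bit sets, with the
convention that two *empty* fingerprints score 1.0 (identity: two
featureless objects are indistinguishable). The coefficient and scheme
are isolated behind the chem module so either can be swapped.

SVG rendering computes 2D coordinates deterministically, so identical
molecules render to byte-identical documents (responses stay pure).

## Query interpretation

A combined query is a finite tree: `Leaf(field, predicate)` under
`And`/`Or` connectives. Compilation walks the tree once, resolving each
leaf against a closed field registry (unknown fields are rejected, so no
case can be silently missed) and precompiling regexes, parsed query
molecules and fingerprints; the result is a total predicate over stored
compounds. Semantics:

- child-level leaves (container, biodata, file fields) match a compound
  iff **any** visible child satisfies the leaf; each leaf quantifies
  independently, so a conjunction of two container leaves does *not*
  require one container to satisfy both (each row of a query form is a
  predicate against one field);
- empty connectives take neutral elements: `And(())` matches all,
  `Or(())` matches none;
- structure leaves skip structure-less compounds rather than erroring;
  similarity thresholds are inclusive (≥) and must lie in (0, 1];
- there is no negation node; negation is expressible per-leaf where a
  mode provides it (kept minimal deliberately).

Quick search dispatches on the string's shape: all-integer tokens → id
set; `D{2,7}-DD-D` → CAS lookup; otherwise a case-insensitive regular
expression matched against every textual field in the compound's subtree
(name, CAS, batches, file names). Python's `re` dialect is used.

Sorting is stable, on compound-level numeric/text fields; entities
lacking the field sort last regardless of direction (missing data is
"worst" either way). Pagination is offset/limit (default page 64,
maximum 256); pages are disjoint, exhaustive and order-preserving, and
the reported total is page-invariant. Only the returned slice is
converted to client views (and rendered), so large hitsets cost little
until paged through.

## Authorization

Roles are totally ordered: guest < common < superuser < admin. Guests
never write. Common users and superusers write within projects they
hold grants for (superusers differ in review duties, not reach — they
see their own projects only). Admins review all changes and therefore
implicitly access every project; user and project administration is
admin-only. The client-side "editing enabled" switch is advisory; the
server checks every mutation.

The central mechanism is the `AccessProof`: a value constructed only by
`auth.has_access(user, project)` and demanded by every client-view
constructor. The original design enforces this with a compile-time
private constructor; Python cannot, so the constructor is module-private
by convention and the guarantee is property-tested instead: serialized
responses of every endpoint are scanned for names of inaccessible
entities, for password hashes, and for raw molfile text, over many
random (dataset, user) pairs.

Visibility filtering is per node and runs before predicate evaluation:
an accessible compound with some containers in an inaccessible project
is served with those containers stripped; the projects list itself is
reduced to the accessible ones (dropdowns must only offer valid
options). Enlarging a user's grant set never shrinks their visible tree.

Authentication is by alias + password against salted PBKDF2-HMAC-SHA256
(60 000 iterations by default); unknown alias and wrong password produce
the identical error (no user enumeration), and the unknown-alias path
still runs one KDF verification so the two failures take comparable
time. Sessions are opaque random tokens with an 8-hour expiry.

## Export

The field selection determines row semantics: compound-only fields give
one row per compound; any container-level field switches to one row per
container with compound values repeated. A compound without containers
contributes no rows in container mode — the row *is* the container under
this rule; padding a blank row was the documented alternative and was
rejected as inventing a container that does not exist. Per-container
biodata statistics (count, mean, min, max per assay method) are
container-level columns, matching the structure–activity view grouped by
batch.

SDF output is one kekulized V2000 mol block per row, `> <label>` data
items in selection order, `$$$$` terminators; structure-less rows emit a
zero-atom mol block. Tab-delimited output quotes cells containing
tabs/newlines/quotes so the table round-trips. ODT output is out of
scope (spreadsheet use is covered by the tab-delimited format).

## Request handling

Read handlers are pure functions of an immutable environment (request +
tree snapshot + authenticated user) and an opaque query state the caller
owns: identical inputs give identical outputs, which is tested at the
byte level. Every failure path maps to one structured error code
(`unauthorized`, `not_found`, `validation`, `parse`, `query`,
`conflict`, `internal`), serialized to the client and written to the
log; malformed input can never surface a stack trace. Mutations follow
validate → append → swap under the single writer lock; a failed
validation leaves log and tree untouched. History responses redact
password hashes, and user-family records are visible only to admins and
the account owner.

The transport is an in-process `Request`/`Response` pair rather than a
bound socket: the handler contract is transport-agnostic, the whole
surface is exercisable (and fuzzable) without a network, and mounting it
on any HTTP framework is a thin adapter.

## Synthetic data: what it does and does not emulate

The generator is fully deterministic in its seed (fixture password
salts included). It emulates the *structure* of a working registry:
every entity family populated, all four roles present, per-user project
grants that always leave at least one project inaccessible, compounds
with and without structures (~10% structure-less), checksum-valid CAS
numbers, container/biodata fan-out in configurable ranges, a fraction of
mods (default 0.2) and a few soft deletes. Molecules come from a curated
table of ~55 small structures with known substructure relations
(benzene ⊂ toluene; benzene ⊄ cyclohexane pinned in every draw), not
random graphs — chemical validity and known oracle answers matter more
than variety.

It does **not** emulate: realistic assay-value distributions (values are
uniform noise), realistic molecule-size distributions (everything is
drug-like-small, ≤ ~15 heavy atoms), file contents (blob ids may dangle
unless uploaded through the API), clock skew (timestamps are an evenly
spaced synthetic clock), or adversarial inputs beyond what the fuzz
tests inject. Passing tests therefore demonstrate the engine's logical
guarantees — fold/replay equivalence, codec identity, oracle agreement,
leak-freedom, export laws — on datasets of this shape, not performance
or chemistry coverage on production-scale registries.

Problem sizes used by the default suite and the acceptance script: 20
replay logs of ~1000 operations; 10⁴ codec instances per variant; 100
query trees (depth ≤ 3) over 200 compounds; all ~2600 substructure pairs
with ≤ 12 heavy atoms; 100+ (dataset, user) leak-scan pairs; 8 writer +
32 reader threads. These are desk-scale sizes chosen so the full suite
runs in well under a minute of compute per group while still exercising
every code path at property-testing volume.

## Numerical and encoding choices

- Timestamps: integer milliseconds UTC (total order across records).
- Molecular mass: standard atomic weights including implicit/explicit
  hydrogens; formulas in Hill order. Tests compare to 0.01 g/mol.
- Numeric query comparisons are exact floating-point comparisons — the
  engine filters stored values, it does not do arithmetic on them.
- NDJSON lines are UTF-8, one record per line, keys sorted (bit-stable).
- The log fails fast on the first corrupt record, reporting its sequence
  number, rather than skipping.

## Known limitations

- The access-proof constructor is private by convention, not by the
  language; the leak-freedom property tests are the enforcement.
- No log compaction: startup replay is linear in total history.
- Single-process writer lock: no multi-node replication story.
- Per-leaf any-quantification cannot express "the same container
  satisfies both predicates"; that would need a dedicated correlated
  node.
- Quick-search regexes run over a bounded set of textual fields; fields
  added to the registry must be added there explicitly.
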