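# chemvault

An event-sourced chemical data-management engine for medicinal-chemistry
and organic-synthesis groups: a searchable compound registry and lab
inventory with a full audit trail, substructure/similarity search,
project-scoped confidentiality, and SDF/tabular export.

## Who it is for, and what it does

Research groups in drug discovery need to register compounds, track the
physical containers (batches) holding them, attach bioassay results and
files, and later ask questions like *"all compounds containing this
aromatic scaffold, with IC50 below 10 µM, from projects I'm allowed to
see"*. chemvault is the backend engine for that workflow:

- **Data model** — a heterogeneous tree: `Compound` → `Container` →
  `BiodataEntry`, each node linked to a `Project`, plus global
  vocabularies (`Supplier`, `Location`, `Method`) and `FileRef`s to
  binary attachments. Every entity family has four shape variants:
  `Srv` (stored record), `Add` (creation request — the server assigns
  ids), `Mod` (partial update — absent field means unchanged), and
  `Cli` (outgoing view — links resolved to names, structures rendered to
  SVG, sensitive fields withheld).
- **Persistence** — an append-only NDJSON change log. Every mutation is
  one timestamped, user-attributed record; the in-memory dataset is a
  left fold (replay) over the log, so the complete edit history of every
  entity is always available and any log prefix is a consistent state.
  Binary files and per-user settings live in an embedded SQLite side
  store, outside the history.
- **Queries** — quick search (id list / CAS number / regular expression,
  dispatched on the string's shape) and combined queries: a tree of
  typed predicates over registered fields (numeric comparators, text
  modes, link sets, substructure and Tanimoto-similarity leaves),
  compiled and interpreted server-side, with stable sorting and offset
  pagination for lazy result loading.
- **Authorization** — users hold roles (guest < common < superuser <
  admin) and per-project grants. Visibility filtering runs *before* any
  predicate: an `AccessProof` object, constructible only by
  `auth.has_access`, is required to build any outgoing client view, so
  the authorization check cannot be skipped on any code path.
- **Chemistry** — a safe facade over RDKit. Molecules carry an explicit
  normalization-state tag (`kekulized → aromatized → search_ready`);
  state-sensitive operations enforce their preconditions, and every
  fallible operation returns a `Result` value instead of raising.
  Similarity is the Tanimoto coefficient |A∩B|/|A∪B| over Morgan
  (radius-2) fingerprints folded to 2048 bits.
- **Export** — field-selection export to SDF (kekulized V2000 blocks +
  data items) and tab-delimited text. Selected fields determine row
  semantics: compound-level fields give one row per compound; any
  container-level field (including per-container biodata statistics)
  gives one row per container.

CAS registry numbers are validated structurally: format `D{2,7}-DD-D`
with the standard mod-10 positional check digit
(Σ digitᵢ · positionᵢ-from-right ≡ check digit, mod 10).

## Worked example

Everything below runs against synthetic data — no external services or
downloads. The fixture generator is deterministic in its seed.

```python
from chemvault import fixtures
from chemvault.api import Server
from chemvault.fixtures import FixtureSpec

data = fixtures.gen_dataset(FixtureSpec(seed=42, n_compounds=30))
print(f"generated {len(data.records)} change records")

server = Server.from_records(data.records)
alias = next(a for a in data.passwords if "admin" in a)
token = server.request("POST", "/login",
                       {"alias": alias, "password": data.passwords[alias]}).body["token"]

benzene = fixtures.gen_molecules(0, 1).value[0][1]   # a V2000 molfile
q = {
    "tree": {"and": [
        {"field": "compound.structure",
         "pred": {"type": "structure", "kind": "substructure", "molfile": benzene}},
        {"field": "compound.mass",
         "pred": {"type": "numeric", "clauses": [["<=", 120.0]]}},
    ]},
    "sort": {"field": "compound.mass", "ascending": True},
    "paging": {"offset": 0, "limit": 5},
}
page = server.request("POST", "/query", q, token=token).body
print(f"{page['total']} aromatic compounds with mass <= 120 g/mol; first page:")
for item in page["items"]:
    print(f"  #{item['id']:>3} {item['name']}  (project {item['project']['name']}, "
          f"{len(item['containers'])} containers)")
```

prints

```
generated 129 change records
9 aromatic compounds with mass <= 120 g/mol; first page:
  #  1 CMP-0000-876f  (project Project-0-3900, 2 containers)
  #  2 CMP-0001-579f  (project Project-2-8cd0, 1 containers)
  # 23 CMP-0022-de7f  (project Project-1-0cce, 1 containers)
  # 16 CMP-0015-36cd  (project Project-2-8cd0, 1 containers)
  # 11 CMP-0010-4f41  (project Project-0-3900, 0 containers)
```

Nine of the thirty registered compounds carry a benzene substructure and
have molecular mass ≤ 120 g/mol; the page lists the five lightest, each
as a client view with its project link resolved to a display name (the
raw molfile never appears in client payloads — views carry an SVG
depiction instead). The same query drives an export; selecting a
container-level field switches to one-row-per-container semantics:

```python
exp = server.request("POST", "/export",
                     {"query": q,
                      "spec": {"fields": ["compound.name", "container.batch",
                                          "container.amount"], "format": "csv"}},
                     token=token).body
print("\n".join(exp["content"].splitlines()[:3]))
```

```
compound.name	container.batch	container.amount
CMP-0000-876f	B0000-b928	176.146
CMP-0000-876f	B0000-7730	69.501
```

A fixture dataset can also be written to disk from the shell:

```bash
chemvault fixtures generate --seed 1 --out ./fixture-data
```

which emits the NDJSON change log plus the referenced molfiles.

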