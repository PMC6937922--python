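"""Deterministic synthetic data: molecules, datasets, queries.

Everything the engine consumes can be generated here from a seed, so the
full stack is testable without any external data. Molecules come from a
curated table of small drug-like and solvent structures (chemically valid
by construction, with known substructure relations: benzene ⊂ toluene,
benzene ⊄ cyclohexane), not from random graph generation.

Datasets are emitted as change-log records: a block of adds covering every
entity family, followed by a configurable fraction of mods and a few soft
deletes. The expected tree is built by folding the same records, so
``replay(log) == expected`` is a dual-construction check, not a tautology
of one code path.

Synthetic realism caveats: assay values are uniform noise, user passwords
derive from aliases, and the password KDF runs at a deliberately low work
factor — fixture accounts are not real credentials.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field

from rdkit import Chem

from . import auth, store
from .model import Role, cas_check_digit
from .query import (
    And, Leaf, LinkPred, NumericPred, Or, QueryTree, StructurePred, TextPred,
)
from .result import Result

_FIXTURE_KDF_ITERATIONS = 1_000  # weak on purpose: synthetic accounts only

# name -> SMILES; the first three entries are pinned so that every
# generated set of >= 3 molecules contains an aromatic/aliphatic pair
# (benzene / cyclohexane) and a substructure pair (benzene / toluene).
MOLECULE_TABLE: tuple[tuple[str, str], ...] = (
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("cyclohexane", "C1CCCCC1"),
    ("phenol", "Oc1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("styrene", "C=Cc1ccccc1"),
    ("anisole", "COc1ccccc1"),
    ("benzaldehyde", "O=Cc1ccccc1"),
    ("benzoic acid", "OC(=O)c1ccccc1"),
    ("benzamide", "NC(=O)c1ccccc1"),
    ("benzonitrile", "N#Cc1ccccc1"),
    ("nitrobenzene", "O=[N+]([O-])c1ccccc1"),
    ("chlorobenzene", "Clc1ccccc1"),
    ("fluorobenzene", "Fc1ccccc1"),
    ("bromobenzene", "Brc1ccccc1"),
    ("p-xylene", "Cc1ccc(C)cc1"),
    ("mesitylene", "Cc1cc(C)cc(C)c1"),
    ("acetophenone", "CC(=O)c1ccccc1"),
    ("furan", "c1ccoc1"),
    ("thiophene", "c1ccsc1"),
    ("pyrrole", "c1cc[nH]c1"),
    ("imidazole", "c1c[nH]cn1"),
    ("pyrazole", "c1cc[nH]n1"),
    ("oxazole", "c1cnco1"),
    ("thiazole", "c1cncs1"),
    ("pyrimidine", "c1cncnc1"),
    ("pyrazine", "c1cnccn1"),
    ("indole", "c1ccc2[nH]ccc2c1"),
    ("quinoline", "c1ccc2ncccc2c1"),
    ("benzofuran", "c1ccc2occc2c1"),
    ("methane", "C"),
    ("ethanol", "CCO"),
    ("acetone", "CC(C)=O"),
    ("acetic acid", "CC(O)=O"),
    ("acetonitrile", "CC#N"),
    ("dimethyl sulfoxide", "CS(C)=O"),
    ("tetrahydrofuran", "C1CCOC1"),
    ("dioxane", "C1COCCO1"),
    ("piperidine", "C1CCNCC1"),
    ("piperazine", "C1CNCCN1"),
    ("morpholine", "C1COCCN1"),
    ("cyclopentane", "C1CCCC1"),
    ("cyclopropane", "C1CC1"),
    ("n-hexane", "CCCCCC"),
    ("isobutane", "CC(C)C"),
    ("urea", "NC(N)=O"),
    ("glycine", "NCC(O)=O"),
    ("alanine", "CC(N)C(O)=O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("aspirin", "CC(=O)Oc1ccccc1C(O)=O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(O)=O"),
)


class FixtureErr(Exception):
    def __init__(self, code: str, detail: str):
        super().__init__(f"{code}: {detail}")
        self.code = code
        self.detail = detail


def _molblock(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - table is curated
        raise FixtureErr("bad_table", f"table SMILES does not parse: {smiles}")
    return Chem.MolToMolBlock(mol, kekulize=True)


def gen_molecules(seed: int, n: int) -> Result[list[tuple[str, str]], FixtureErr]:
    """``n`` (name, molfile) pairs from the curated table, deterministic in
    ``seed``. The pinned benzene/toluene/cyclohexane trio always leads."""
    if n > len(MOLECULE_TABLE):
        return Result.err(
            FixtureErr("n_too_large", f"{n} > table size {len(MOLECULE_TABLE)}")
        )
    rng = random.Random(seed)
    rest = list(MOLECULE_TABLE[3:])
    rng.shuffle(rest)
    picked = (list(MOLECULE_TABLE[:3]) + rest)[:n]
    return Result.ok([(name, _molblock(smi)) for name, smi in picked])


def gen_cas(rng: random.Random) -> str:
    """A checksum-valid CAS registry number."""
    body = str(rng.randint(10, 9_999_999)) + f"{rng.randint(0, 99):02d}"
    return f"{body[:-2]}-{body[-2:]}-{cas_check_digit(body)}"


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a generated dataset; identical specs yield identical logs."""

    seed: int
    n_compounds: int = 50
    n_projects: int = 3
    n_users: int = 6
    n_suppliers: int = 3
    n_locations: int = 3
    n_methods: int = 3
    containers_per_compound: tuple[int, int] = (0, 3)
    biodata_per_container: tuple[int, int] = (0, 2)
    file_fraction: float = 0.1
    mod_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_projects < 2:
            raise FixtureErr("bad_spec", "need >= 2 projects to exercise inaccessibility")
        if not (0 <= self.mod_fraction <= 1):
            raise FixtureErr("bad_spec", "mod_fraction must be in [0, 1]")


@dataclass
class FixtureData:
    records: list[store.ChangeRecord]
    tree: store.DataTree
    #: alias -> clear-text password for the synthetic accounts
    passwords: dict[str, str] = field(default_factory=dict)


_ROLE_CYCLE = (Role.ADMIN, Role.SUPERUSER, Role.COMMON, Role.GUEST)


def gen_dataset(spec: FixtureSpec) -> FixtureData:
    """A full synthetic dataset as change-log records plus the expected
    tree (built by folding the same records one by one)."""
    rng = random.Random(spec.seed)
    tag = lambda: f"{rng.randrange(16**4):04x}"  # noqa: E731 - distinctive token

    records: list[store.ChangeRecord] = []
    tree = store.DataTree()

    def emit(family: str, op: str, ident: int, payload: dict, user: int = 1) -> None:
        nonlocal tree
        rec = store.ChangeRecord(
            seq=len(records) + 1,
            ts=1_700_000_000_000 + len(records) * 1_000,
            user=user,
            family=family,
            id=ident,
            op=op,
            payload=payload,
        )
        applied = store.apply_record(tree, rec)
        if applied.is_err:  # pragma: no cover - generator emits valid data
            raise applied.error
        tree = applied.value
        records.append(rec)

    def add(family: str, payload: dict, user: int = 1) -> int:
        ident = tree.next_id(family)
        emit(family, "add", ident, payload, user)
        return ident

    # projects first (owner links are not referentially enforced)
    project_ids = [
        add("project", {"name": f"Project-{i}-{tag()}", "owner": 1})
        for i in range(spec.n_projects)
    ]

    passwords: dict[str, str] = {}
    user_ids: list[int] = []
    for i in range(spec.n_users):
        role = _ROLE_CYCLE[i % len(_ROLE_CYCLE)]
        alias = f"user{i}-{role.value}"
        password = f"pw-{alias}"
        passwords[alias] = password
        if role is Role.ADMIN:
            projects: list[int] = []
        else:
            # always a *proper* subset: at least one project stays hidden
            k = rng.randint(1, spec.n_projects - 1)
            projects = rng.sample(project_ids, k)
        user_ids.append(
            add(
                "user",
                {
                    "alias": alias,
                    "password_hash": auth.hash_password(
                        password,
                        iterations=_FIXTURE_KDF_ITERATIONS,
                        salt=rng.randbytes(16),  # deterministic fixture salt
                    ),
                    "role": role.value,
                    "projects": projects,
                },
            )
        )

    supplier_ids = [add("supplier", {"name": f"Supplier-{i}-{tag()}"}) for i in range(spec.n_suppliers)]
    location_ids = [add("location", {"name": f"Shelf-{i}-{tag()}"}) for i in range(spec.n_locations)]
    method_ids = [add("method", {"name": f"Assay-{i}-{tag()}"}) for i in range(spec.n_methods)]

    mols = gen_molecules(spec.seed, min(spec.n_compounds, len(MOLECULE_TABLE)))
    molfiles = mols.value if mols.is_ok else []

    writers = [u for u in user_ids if tree.entity("user", u).role is not Role.GUEST]  # type: ignore[union-attr]

    compound_ids: list[int] = []
    container_ids: list[int] = []
    for i in range(spec.n_compounds):
        payload: dict = {
            "name": f"CMP-{i:04d}-{tag()}",
            "project": rng.choice(project_ids),
        }
        if molfiles and rng.random() > 0.1:  # ~10% structure-less compounds
            payload["structure"] = molfiles[i % len(molfiles)][1]
        if rng.random() < 0.6:
            payload["casNr"] = gen_cas(rng)
        cid = add("compound", payload, user=rng.choice(writers))
        compound_ids.append(cid)

        for _ in range(rng.randint(*spec.containers_per_compound)):
            kid = add(
                "container",
                {
                    "compound": cid,
                    "batch": f"B{i:04d}-{tag()}",
                    "location": rng.choice(location_ids),
                    "supplier": rng.choice(supplier_ids),
                    "amount": round(rng.uniform(0.01, 250.0), 3),
                    "purity": round(rng.uniform(50.0, 100.0), 1),
                    "project": rng.choice(project_ids),
                },
                user=rng.choice(writers),
            )
            container_ids.append(kid)
            for _ in range(rng.randint(*spec.biodata_per_container)):
                add(
                    "biodata",
                    {
                        "container": kid,
                        "method": rng.choice(method_ids),
                        "value": round(rng.uniform(0.001, 100.0), 4),
                        "unit": "uM",
                        "project": rng.choice(project_ids),
                    },
                    user=rng.choice(writers),
                )

    for cid in compound_ids:
        if rng.random() < spec.file_fraction:
            add(
                "file",
                {
                    "name": f"spectrum-{cid}-{tag()}.pdf",
                    "mime": "application/pdf",
                    "blob_id": f"{rng.getrandbits(256):064x}",
                    "parent_family": "compound",
                    "parent_id": cid,
                    "project": tree.entity("compound", cid).project,  # type: ignore[union-attr]
                },
                user=rng.choice(writers),
            )

    # mods: rename / re-CAS / batch edits, all valid by construction
    n_mods = int(spec.mod_fraction * spec.n_compounds)
    for cid in rng.sample(compound_ids, min(n_mods, len(compound_ids))):
        choice = rng.random()
        if choice < 0.5:
            payload = {"name": f"CMP-renamed-{cid}-{tag()}"}
        elif choice < 0.8:
            payload = {"casNr": gen_cas(rng)}
        else:
            payload = {"project": rng.choice(project_ids)}
        emit("compound", "mod", cid, payload, user=rng.choice(writers))
    for kid in rng.sample(container_ids, min(n_mods // 2, len(container_ids))):
        emit(
            "container", "mod", kid,
            {"amount": round(rng.uniform(0.01, 250.0), 3)},
            user=rng.choice(writers),
        )

    # a few soft deletes, never the pinned first compound
    for kid in rng.sample(container_ids, min(2, len(container_ids))):
        emit("container", "del", kid, {}, user=rng.choice(writers))

    return FixtureData(records=records, tree=tree, passwords=passwords)


# --------------------------------------------------------------------------
# Random query trees
# --------------------------------------------------------------------------


def gen_query(
    seed: int,
    depth: int,
    n_projects: int = 3,
    n_suppliers: int = 3,
    n_methods: int = 3,
) -> QueryTree:
    """A random predicate tree of the given depth; always compiles against
    the standard field registry."""
    rng = random.Random(seed)
    return _gen_node(rng, depth, n_projects, n_suppliers, n_methods)


def _gen_leaf(rng: random.Random, n_projects: int, n_suppliers: int, n_methods: int) -> Leaf:
    kind = rng.choice(["numeric", "text", "link", "structure"])
    if kind == "numeric":
        fld = rng.choice(["compound.mass", "container.amount", "container.purity", "biodata.value"])
        hi = {"compound.mass": 400.0, "container.amount": 250.0,
              "container.purity": 100.0, "biodata.value": 100.0}[fld]
        cmp_op = rng.choice(["<", "<=", ">=", ">", "=="])
        return Leaf(fld, NumericPred(((cmp_op, round(rng.uniform(0.0, hi), 2)),)))
    if kind == "text":
        fld = rng.choice(["compound.name", "container.batch", "compound.casNr"])
        mode = rng.choice(["contains", "regex", "exact"])
        s = {
            "contains": rng.choice(["CMP", "B0", "ol", "-1", "renamed"]),
            "regex": rng.choice([r"CMP-\d+", r"B\d{4}", r"[0-9]-[0-9]"]),
            "exact": rng.choice(["CMP-0000", "nothing-matches-this"]),
        }[mode]
        return Leaf(fld, TextPred(mode, s))
    if kind == "link":
        fld, pool = rng.choice(
            [
                ("compound.project", range(1, n_projects + 1)),
                ("container.supplier", range(1, n_suppliers + 1)),
                ("biodata.method", range(1, n_methods + 1)),
            ]
        )
        k = rng.randint(1, len(pool))
        return Leaf(fld, LinkPred(frozenset(rng.sample(list(pool), k))))
    name, molfile = rng.choice(
        [(n, _molblock(s)) for n, s in MOLECULE_TABLE[:6]]
    )
    if rng.random() < 0.5:
        return Leaf("compound.structure", StructurePred("substructure", molfile))
    return Leaf(
        "compound.structure",
        StructurePred("similarity", molfile, threshold=round(rng.uniform(0.2, 0.9), 2)),
    )


def _gen_node(
    rng: random.Random, depth: int, n_projects: int, n_suppliers: int, n_methods: int
) -> QueryTree:
    if depth <= 1:
        return _gen_leaf(rng, n_projects, n_suppliers, n_methods)
    kids = tuple(
        _gen_node(rng, rng.randint(1, depth - 1), n_projects, n_suppliers, n_methods)
        for _ in range(rng.randint(2, 3))
    )
    return And(kids) if rng.random() < 0.5 else Or(kids)
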