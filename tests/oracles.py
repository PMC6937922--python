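"""Independent oracles the test suite checks the engine against.

Each oracle deliberately takes a different route from the implementation:
subgraph matching goes through networkx's VF2 matcher on a plain-data
graph, query trees are evaluated by a naive per-record interpreter with
its own field access, and random entity instances are built directly from
field lists rather than through the model's constructors.
"""
from __future__ import annotations

import random
import re
import string
from typing import Optional

import networkx as nx
from networkx.algorithms import isomorphism

from chemvault import chem, fixtures, model, query
from chemvault.store import DataTree

# --------------------------------------------------------------------------
# Brute-force subgraph isomorphism (substructure oracle)
# --------------------------------------------------------------------------


def _to_nx(m: chem.Molecule) -> nx.Graph:
    atoms, bonds = chem.heavy_atom_graph(m)
    g = nx.Graph()
    for idx, elem, _arom in atoms:
        g.add_node(idx, elem=elem)
    for i, j, order, arom in bonds:
        g.add_edge(i, j, order=order, arom=arom)
    return g


def subgraph_oracle(query_mol: chem.Molecule, target_mol: chem.Molecule) -> bool:
    """Subgraph monomorphism under element / bond-order / aromaticity
    compatibility, via VF2 on the heavy-atom graphs."""
    gm = isomorphism.GraphMatcher(
        _to_nx(target_mol),
        _to_nx(query_mol),
        node_match=lambda a, b: a["elem"] == b["elem"],
        edge_match=lambda a, b: a["order"] == b["order"] and a["arom"] == b["arom"],
    )
    return gm.subgraph_is_monomorphic()


# --------------------------------------------------------------------------
# Naive combined-query evaluator (query oracle)
# --------------------------------------------------------------------------


def _naive_mass(c) -> Optional[float]:
    if c.structure is None:
        return None
    parsed = chem.parse_molfile(c.structure)
    if parsed.is_err:
        return None
    return chem.compute_properties(parsed.value).value["mass"]


def _naive_field(level_entity, field: str):
    attr = field.split(".", 1)[1]
    if field == "compound.mass":
        return _naive_mass(level_entity)
    return getattr(level_entity, attr)


def _naive_value_match(pred, value) -> bool:
    if isinstance(pred, query.NumericPred):
        if value is None:
            return False
        ops = {"<": float.__lt__, "<=": float.__le__, "==": float.__eq__,
               ">=": float.__ge__, ">": float.__gt__}
        return all(ops[c](float(value), v) for c, v in pred.clauses)
    if isinstance(pred, query.TextPred):
        if value is None:
            return False
        if pred.mode == "exact":
            return value == pred.s
        if pred.mode == "contains":
            return pred.s.lower() in str(value).lower()
        return re.search(pred.s, str(value)) is not None
    if isinstance(pred, query.LinkPred):
        return value in pred.allowed
    raise AssertionError(f"unexpected predicate {pred}")


def _naive_structure_match(pred: query.StructurePred, molfile: Optional[str]) -> bool:
    if molfile is None:
        return False
    q = chem.normalize(chem.parse_molfile(pred.molfile).value, chem.MolState.SEARCH_READY).value
    t = chem.normalize(chem.parse_molfile(molfile).value, chem.MolState.SEARCH_READY).value
    if pred.kind == "substructure":
        return subgraph_oracle(q, t)
    qfp = chem.morgan_fingerprint(q).value
    tfp = chem.morgan_fingerprint(t).value
    return chem.tanimoto_similarity(qfp, tfp) >= pred.threshold


def _naive_children(c, tree: DataTree, level: str):
    containers = [k for k in (tree.entity("container", i) for i in c.containers) if k is not None]
    if level == "container":
        return containers
    if level == "biodata":
        return [
            b
            for k in containers
            for b in (tree.entity("biodata", i) for i in k.biodata)
            if b is not None
        ]
    if level == "file":
        fids = list(c.files)
        for k in containers:
            fids.extend(k.files)
            for b in (tree.entity("biodata", i) for i in k.biodata):
                if b is not None:
                    fids.extend(b.files)
        return [f for f in (tree.entity("file", i) for i in fids) if f is not None]
    raise AssertionError(level)


def naive_eval(node, c, tree: DataTree) -> bool:
    """Evaluate a query tree on one compound record by direct recursion —
    no compilation, no shared code with the engine's interpreter."""
    if isinstance(node, query.And):
        return all(naive_eval(k, c, tree) for k in node.children)
    if isinstance(node, query.Or):
        return any(naive_eval(k, c, tree) for k in node.children)
    level = node.field.split(".", 1)[0]
    if isinstance(node.pred, query.StructurePred):
        return _naive_structure_match(node.pred, c.structure)
    if level == "compound":
        return _naive_value_match(node.pred, _naive_field(c, node.field))
    return any(
        _naive_value_match(node.pred, _naive_field(child, node.field))
        for child in _naive_children(c, tree, level)
    )


def naive_hitset(tree_q, compounds, tree: DataTree) -> set[int]:
    return {c.id for c in compounds if naive_eval(tree_q, c, tree)}


# --------------------------------------------------------------------------
# Random entity instances (codec oracle input)
# --------------------------------------------------------------------------


def _rand_text(rng: random.Random, allow_weird: bool = True) -> str:
    alphabet = string.ascii_letters + string.digits + (" \t\nüé€-_." if allow_weird else "-")
    return "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 24))).strip() or "x"


def _meta(rng: random.Random) -> dict:
    return {"ts": rng.randint(0, 2**41), "user": rng.randint(1, 99)}


_BENZENE_MOLFILE = fixtures._molblock("c1ccccc1")


def random_instance(family: str, variant: str, rng: random.Random):
    """A valid random instance of any entity variant."""
    opt = lambda v: v if rng.random() < 0.7 else None  # noqa: E731
    base: dict = {}
    if family == "compound":
        base = {
            "name": _rand_text(rng),
            "casNr": opt(fixtures.gen_cas(rng)),
            "structure": opt(_BENZENE_MOLFILE),
            "project": rng.randint(1, 9),
        }
        srv_extra = {"containers": [rng.randint(1, 50) for _ in range(rng.randint(0, 3))],
                     "files": [rng.randint(1, 50) for _ in range(rng.randint(0, 2))]}
    elif family == "container":
        base = {
            "compound": rng.randint(1, 99),
            "batch": _rand_text(rng),
            "location": rng.randint(1, 9),
            "supplier": rng.randint(1, 9),
            "amount": opt(round(rng.uniform(0.001, 500), 4)),
            "purity": opt(round(rng.uniform(0.1, 100), 2)),
            "project": rng.randint(1, 9),
        }
        srv_extra = {"biodata": [], "files": []}
    elif family == "biodata":
        base = {
            "container": rng.randint(1, 99),
            "method": rng.randint(1, 9),
            "value": rng.uniform(-1e6, 1e6),
            "unit": rng.choice(["uM", "nM", "%", ""]),
            "project": rng.randint(1, 9),
        }
        srv_extra = {"files": []}
    elif family == "project":
        base = {"name": _rand_text(rng), "owner": rng.randint(1, 9)}
        srv_extra = {}
    elif family == "user":
        base = {
            "alias": _rand_text(rng),
            "password_hash": f"pbkdf2$1000${rng.getrandbits(64):016x}${rng.getrandbits(128):032x}",
            "role": rng.choice(list(model.Role)).value,
            "projects": sorted({rng.randint(1, 9) for _ in range(rng.randint(0, 4))}),
        }
        srv_extra = {}
    elif family in ("supplier", "location", "method"):
        base = {"name": _rand_text(rng)}
        srv_extra = {}
    elif family == "file":
        base = {
            "name": _rand_text(rng),
            "mime": rng.choice(["application/pdf", "image/png", "text/plain"]),
            "blob_id": f"{rng.getrandbits(256):064x}",
            "parent_family": rng.choice(["compound", "container", "biodata"]),
            "parent_id": rng.randint(1, 99),
            "project": rng.randint(1, 9),
        }
        srv_extra = {}
    else:
        raise AssertionError(family)

    if variant == "add":
        return model.decode(family, "add", base)
    if variant == "srv":
        return model.decode(
            family, "srv", {**base, **srv_extra, "id": rng.randint(1, 10**6), "created": _meta(rng)}
        )
    if variant == "mod":
        mod_cls = model.FAMILIES[family]["mod"]
        keys = [k for k in base if k in mod_cls.model_fields]
        chosen = rng.sample(keys, rng.randint(0, len(keys)))
        return model.decode(family, "mod", {k: base[k] for k in chosen})
    if variant == "cli":
        link = lambda: {"id": rng.randint(1, 99), "name": _rand_text(rng)}  # noqa: E731
        if family == "compound":
            raw = {"id": rng.randint(1, 9999), "name": base["name"], "casNr": base["casNr"],
                   "svg": opt("<svg xmlns='http://www.w3.org/2000/svg'/>"),
                   "project": link(), "created": _meta(rng), "containers": [], "files": []}
        elif family == "container":
            raw = {"id": rng.randint(1, 9999), "batch": base["batch"], "location": link(),
                   "supplier": link(), "amount": base["amount"], "purity": base["purity"],
                   "project": link(), "biodata": [], "files": []}
        elif family == "biodata":
            raw = {"id": rng.randint(1, 9999), "method": link(), "value": base["value"],
                   "unit": base["unit"], "project": link(), "files": []}
        elif family == "project":
            raw = {"id": rng.randint(1, 9999), "name": base["name"], "owner": link()}
        elif family == "user":
            raw = {"id": rng.randint(1, 9999), "alias": base["alias"], "role": base["role"],
                   "projects": base["projects"]}
        elif family == "file":
            raw = {"id": rng.randint(1, 9999), "name": base["name"], "mime": base["mime"],
                   "project": link()}
        else:
            raw = {"id": rng.randint(1, 9999), "name": base["name"]}
        return model.decode(family, "cli", raw)
    raise AssertionError(variant)


ALL_VARIANTS = [
    (family, variant)
    for family in model.FAMILIES
    for variant in ("srv", "add", "mod", "cli")
]
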