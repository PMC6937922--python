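"""Safe, error-explicit facade over RDKit.

Every operation that can fail returns a :class:`~chemvault.result.Result`
with a :class:`ChemErr`; nothing raises through this module for any text
input. Molecules carry an explicit normalization-state tag so that
state-sensitive operations (aromatization, substructure matching) can
enforce their preconditions at run time instead of silently coercing.

State machine::

    kekulized  --aromatize-->  aromatized  --add explicit H-->  search_ready

All transitions are re-derivable from the underlying graph, so
``normalize`` accepts any (state, target) pair and is idempotent.
"""
from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Tuple
from xml.etree import ElementTree

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Descriptors, rdMolDescriptors
from rdkit.Chem.Draw import rdMolDraw2D

from .result import Result

# RDKit reports parse problems on stderr; the facade reports them as values.
RDLogger.DisableLog("rdApp.*")

FP_SIZE = 2048
_MORGAN_RADIUS = 2


class MolState(enum.Enum):
    """Normalization state of a molecule's in-memory representation."""

    KEKULIZED = "kekulized"
    AROMATIZED = "aromatized"
    SEARCH_READY = "search_ready"


class ChemErrCode(enum.Enum):
    PARSE_ERR = "parse_err"
    EMPTY_MOLECULE = "empty_molecule"
    STATE_ERR = "state_err"
    RENDER_ERR = "render_err"


@dataclass(frozen=True)
class ChemErr:
    code: ChemErrCode
    detail: str

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.code.value}: {self.detail}"


@dataclass(frozen=True)
class Molecule:
    """A parsed chemical graph plus a truthful state tag.

    The wrapped RDKit mol is treated as immutable: every transition works
    on a copy, so sharing a `Molecule` between threads is safe.
    """

    rdmol: Chem.Mol = field(repr=False)
    state: MolState

    @property
    def num_heavy_atoms(self) -> int:
        return sum(1 for a in self.rdmol.GetAtoms() if a.GetAtomicNum() > 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Molecule):
            return NotImplemented
        return self.state is other.state and Chem.MolToSmiles(
            self.rdmol
        ) == Chem.MolToSmiles(other.rdmol)

    def __hash__(self) -> int:
        return hash((self.state, Chem.MolToSmiles(self.rdmol)))


@dataclass(frozen=True)
class Fingerprint:
    """Sparse bit set over a fixed universe, for Tanimoto similarity."""

    bits: frozenset[int]
    size: int = FP_SIZE

    def __post_init__(self) -> None:
        if any(b < 0 or b >= self.size for b in self.bits):
            raise ValueError("fingerprint bit index out of range")


_V3000_RE = re.compile(r"[Vv]3000")


def parse_molfile(src: str) -> Result[Molecule, ChemErr]:
    """Parse V2000 molfile text into a kekulized molecule.

    Total over arbitrary input: malformed text yields ``parse_err`` with
    the offending context, a structure with zero atoms yields
    ``empty_molecule``. The V3000 dialect is rejected explicitly.
    """
    if not isinstance(src, str) or not src.strip():
        return Result.err(ChemErr(ChemErrCode.PARSE_ERR, "empty molfile input"))
    lines = src.splitlines()
    if len(lines) >= 4 and _V3000_RE.search(lines[3]):
        return Result.err(
            ChemErr(ChemErrCode.PARSE_ERR, "V3000 molfiles are not supported, only V2000")
        )
    try:
        raw = Chem.MolFromMolBlock(src, sanitize=True, removeHs=True)
    except Exception as exc:  # RDKit can raise on pathological input
        return Result.err(
            ChemErr(ChemErrCode.PARSE_ERR, f"toolkit rejected input: {exc}; head={src[:80]!r}")
        )
    if raw is None:
        return Result.err(
            ChemErr(ChemErrCode.PARSE_ERR, f"malformed molfile; head={src[:80]!r}")
        )
    if raw.GetNumAtoms() == 0:
        return Result.err(ChemErr(ChemErrCode.EMPTY_MOLECULE, "molfile declares zero atoms"))
    try:
        kek = Chem.Mol(raw)
        Chem.Kekulize(kek, clearAromaticFlags=True)
    except Exception as exc:
        return Result.err(ChemErr(ChemErrCode.PARSE_ERR, f"kekulization failed: {exc}"))
    return Result.ok(Molecule(rdmol=kek, state=MolState.KEKULIZED))


def _to_aromatized(m: Chem.Mol) -> Chem.Mol:
    out = Chem.Mol(m)
    out = Chem.RemoveHs(out)
    Chem.SanitizeMol(out)
    Chem.SetAromaticity(out)
    return out


def normalize(m: Molecule, target: MolState) -> Result[Molecule, ChemErr]:
    """Bring a molecule into ``target`` state; idempotent.

    ``search_ready`` means: aromatized representation with explicit
    hydrogens attached, the form expected by the matching and fingerprint
    operations.
    """
    if m.state is target:
        return Result.ok(m)
    try:
        if target is MolState.AROMATIZED:
            return Result.ok(Molecule(_to_aromatized(m.rdmol), MolState.AROMATIZED))
        if target is MolState.SEARCH_READY:
            arom = _to_aromatized(m.rdmol)
            return Result.ok(Molecule(Chem.AddHs(arom), MolState.SEARCH_READY))
        if target is MolState.KEKULIZED:
            out = Chem.RemoveHs(Chem.Mol(m.rdmol))
            Chem.Kekulize(out, clearAromaticFlags=True)
            return Result.ok(Molecule(out, MolState.KEKULIZED))
    except Exception as exc:
        return Result.err(
            ChemErr(
                ChemErrCode.STATE_ERR,
                f"no {m.state.value} -> {target.value} transition for this input: {exc}",
            )
        )
    return Result.err(
        ChemErr(ChemErrCode.STATE_ERR, f"unknown target state {target!r}")
    )  # pragma: no cover


def compute_properties(m: Molecule) -> Result[dict, ChemErr]:
    """Molecular mass (g/mol, standard atomic weights, implicit and
    explicit H included) and Hill-order molecular formula."""
    if m.rdmol.GetNumAtoms() == 0:
        return Result.err(ChemErr(ChemErrCode.EMPTY_MOLECULE, "no atoms"))
    try:
        mass = Descriptors.MolWt(m.rdmol)
        formula = rdMolDescriptors.CalcMolFormula(m.rdmol)
    except Exception as exc:
        return Result.err(ChemErr(ChemErrCode.STATE_ERR, f"property computation failed: {exc}"))
    return Result.ok({"mass": mass, "formula": formula})


def _require_search_ready(m: Molecule, which: str) -> ChemErr | None:
    if m.state is not MolState.SEARCH_READY:
        return ChemErr(
            ChemErrCode.STATE_ERR,
            f"{which} molecule is {m.state.value}, substructure matching requires search_ready",
        )
    return None


def substructure_match(query: Molecule, target: Molecule) -> Result[bool, ChemErr]:
    """True iff ``query`` is subgraph-isomorphic to ``target``.

    Compatibility is element + bond order + aromaticity on the heavy-atom
    skeleton; explicit hydrogens carried by search-ready molecules are not
    themselves match constraints (a ring CH in the query may land on a
    substituted ring carbon of the target). Both arguments must be
    ``search_ready``; anything else is a ``state_err``.
    """
    for m, which in ((query, "query"), (target, "target")):
        err = _require_search_ready(m, which)
        if err is not None:
            return Result.err(err)
    try:
        q = Chem.RemoveHs(Chem.Mol(query.rdmol))
        t = Chem.RemoveHs(Chem.Mol(target.rdmol))
        return Result.ok(bool(t.HasSubstructMatch(q)))
    except Exception as exc:
        return Result.err(ChemErr(ChemErrCode.STATE_ERR, f"match failed: {exc}"))


def morgan_fingerprint(m: Molecule, size: int = FP_SIZE) -> Result[Fingerprint, ChemErr]:
    """Circular (Morgan, radius 2) fingerprint folded to ``size`` bits."""
    if m.rdmol.GetNumAtoms() == 0:
        return Result.err(ChemErr(ChemErrCode.EMPTY_MOLECULE, "no atoms"))
    try:
        heavy = Chem.RemoveHs(Chem.Mol(m.rdmol))
        bv = AllChem.GetMorganFingerprintAsBitVect(heavy, _MORGAN_RADIUS, nBits=size)
        return Result.ok(Fingerprint(bits=frozenset(bv.GetOnBits()), size=size))
    except Exception as exc:
        return Result.err(ChemErr(ChemErrCode.STATE_ERR, f"fingerprint failed: {exc}"))


def tanimoto_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """|a ∩ b| / |a ∪ b|; two empty fingerprints count as identical (1.0)."""
    if a.size != b.size:
        raise ValueError(f"fingerprint universes differ: {a.size} vs {b.size}")
    union = a.bits | b.bits
    if not union:
        return 1.0
    return len(a.bits & b.bits) / len(union)


def render_svg(m: Molecule, width: int = 300, height: int = 300) -> Result[str, ChemErr]:
    """Deterministic 2D depiction as an SVG 1.1 document."""
    if m.rdmol.GetNumAtoms() == 0:
        return Result.err(ChemErr(ChemErrCode.EMPTY_MOLECULE, "no atoms to draw"))
    try:
        draw = Chem.RemoveHs(Chem.Mol(m.rdmol))
        AllChem.Compute2DCoords(draw)
        drawer = rdMolDraw2D.MolDraw2DSVG(width, height)
        rdMolDraw2D.PrepareAndDrawMolecule(drawer, draw)
        drawer.FinishDrawing()
        svg = drawer.GetDrawingText()
        ElementTree.fromstring(svg)  # well-formedness guarantee
        return Result.ok(svg)
    except Exception as exc:
        return Result.err(ChemErr(ChemErrCode.RENDER_ERR, f"rendering failed: {exc}"))


def to_molblock(m: Molecule) -> Result[str, ChemErr]:
    """Serialize as a kekulized V2000 mol block (the SDF building block)."""
    try:
        out = Chem.RemoveHs(Chem.Mol(m.rdmol))
        return Result.ok(Chem.MolToMolBlock(out, kekulize=True))
    except Exception as exc:
        return Result.err(ChemErr(ChemErrCode.STATE_ERR, f"cannot kekulize for export: {exc}"))


def empty_molblock() -> str:
    """A V2000 mol block with zero atoms, used for structure-less records
    in SDF export."""
    return Chem.MolToMolBlock(Chem.RWMol())


def graph_signature(m: Molecule) -> str:
    """Canonical SMILES of the heavy-atom graph; equal iff graphs are
    isomorphic under the toolkit's canonical ordering."""
    return Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(m.rdmol)))


def heavy_atom_graph(m: Molecule) -> Tuple[list[tuple[int, str, bool]], list[tuple[int, int, float, bool]]]:
    """Plain-data view of the heavy-atom graph for external oracles.

    Returns ``(atoms, bonds)`` with atoms ``(index, element, aromatic)``
    and bonds ``(i, j, order, aromatic)``.
    """
    g = Chem.RemoveHs(Chem.Mol(m.rdmol))
    atoms = [(a.GetIdx(), a.GetSymbol(), a.GetIsAromatic()) for a in g.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble(), b.GetIsAromatic())
        for b in g.GetBonds()
    ]
    return atoms, bonds
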