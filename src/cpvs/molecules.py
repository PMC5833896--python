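"""Heavy-atom molecular graphs and SMILES/SDF input/output.

The unit flowing through the whole pipeline is :class:`MoleculeGraph`: a
graph of heavy atoms (hydrogens stay implicit) with integer bond orders and
a stable molecule id. SMILES and SDF parsing/writing is delegated to RDKit;
the contract of this module is the graph produced, not RDKit's richer
chemistry model. Charges, isotopes and stereochemistry are dropped on input
(with a warning) because nothing downstream uses them; aromatic input is
kekulized so bond orders are always integers.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from rdkit import Chem, RDLogger

from .errors import MoleculeError, ParseError, UnsupportedElementError

# RDKit's own parse diagnostics go through our warnings/errors instead.
RDLogger.DisableLog("rdApp.*")

SUPPORTED_ELEMENTS = frozenset({"C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B"})

#: Upper bound on the sum of bond orders per element; anything above is
#: rejected as structurally invalid (hypervalent S/P allowed).
MAX_VALENCE = {
    "C": 4, "N": 4, "O": 2, "S": 6, "P": 5,
    "F": 1, "Cl": 1, "Br": 1, "I": 1, "B": 3,
}

_BOND_TYPE_TO_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
}
_ORDER_TO_BOND_TYPE = {v: k for k, v in _BOND_TYPE_TO_ORDER.items()}


@dataclass(frozen=True)
class Atom:
    """A heavy atom: 0-based position in its molecule plus element symbol."""

    index: int
    element: str


@dataclass(frozen=True)
class Bond:
    """Undirected bond between atom indices ``a`` and ``b``, order 1-3."""

    a: int
    b: int
    order: int


@dataclass
class MoleculeGraph:
    """Heavy-atom graph with a stable molecule id.

    Atoms are ordered; ``atoms[i].index == i`` always holds. The graph is
    not required to be connected (multi-fragment/salt records are kept),
    but :meth:`is_connected` lets callers flag them.
    """

    id: str
    atoms: list[Atom]
    bonds: list[Bond]

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> list[list[tuple[int, int]]]:
        """Per-atom list of ``(neighbor_index, bond_order)`` pairs."""
        adj: list[list[tuple[int, int]]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.a].append((b.b, b.order))
            adj[b.b].append((b.a, b.order))
        return adj

    def valence(self, index: int) -> int:
        return sum(b.order for b in self.bonds if index in (b.a, b.b))

    def is_connected(self) -> bool:
        if self.n_atoms <= 1:
            return True
        seen = {0}
        stack = [0]
        adj = self.adjacency()
        while stack:
            for nbr, _ in adj[stack.pop()]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return len(seen) == self.n_atoms

    def validate(self) -> None:
        """Raise :class:`MoleculeError` on any structural-invariant breach."""
        n = len(self.atoms)
        for i, atom in enumerate(self.atoms):
            if atom.index != i:
                raise MoleculeError(
                    f"{self.id}: atom at position {i} carries index {atom.index}")
            if atom.element not in SUPPORTED_ELEMENTS:
                raise MoleculeError(
                    f"{self.id}: unsupported element {atom.element!r}")
        seen_pairs = set()
        valences = [0] * n
        for b in self.bonds:
            if b.a == b.b:
                raise MoleculeError(f"{self.id}: self-bond on atom {b.a}")
            if not (0 <= b.a < n and 0 <= b.b < n):
                raise MoleculeError(f"{self.id}: bond endpoint out of range")
            if b.order not in (1, 2, 3):
                raise MoleculeError(f"{self.id}: bond order {b.order} not in 1-3")
            pair = (min(b.a, b.b), max(b.a, b.b))
            if pair in seen_pairs:
                raise MoleculeError(f"{self.id}: duplicate bond {pair}")
            seen_pairs.add(pair)
            valences[b.a] += b.order
            valences[b.b] += b.order
        for i, v in enumerate(valences):
            cap = MAX_VALENCE[self.atoms[i].element]
            if v > cap:
                raise MoleculeError(
                    f"{self.id}: atom {i} ({self.atoms[i].element}) valence {v} > {cap}")

    # -- comparisons used by round-trip tests ------------------------------

    def element_multiset(self) -> Counter:
        return Counter(a.element for a in self.atoms)

    def bond_multiset(self) -> Counter:
        """Bonds as unordered element/order triples, invariant to atom order."""
        items = []
        for b in self.bonds:
            ea, eb = self.atoms[b.a].element, self.atoms[b.b].element
            items.append((min(ea, eb), max(ea, eb), b.order))
        return Counter(items)


@dataclass
class MoleculeLibrary:
    """Ordered collection of molecules with unique ids."""

    molecules: list[MoleculeGraph]
    source: str = ""
    #: (record ordinal or line number, message) for records that failed to parse
    parse_failures: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.molecules]
        if len(set(ids)) != len(ids):
            dup = [i for i, c in Counter(ids).items() if c > 1]
            raise MoleculeError(f"duplicate molecule ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self) -> Iterator[MoleculeGraph]:
        return iter(self.molecules)

    def __getitem__(self, i: int) -> MoleculeGraph:
        return self.molecules[i]

    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]


# ---------------------------------------------------------------------------
# RDKit conversion
# ---------------------------------------------------------------------------

def _from_rdkit(mol: Chem.Mol, mol_id: str) -> MoleculeGraph:
    """Convert a sanitized RDKit mol to a heavy-atom MoleculeGraph."""
    dropped: list[str] = []
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
        kekulized = True
    except Chem.KekulizeException:
        kekulized = False
        warnings.warn(
            f"{mol_id}: kekulization failed; aromatic bonds read as single",
            stacklevel=3)

    index_map: dict[int, int] = {}
    atoms: list[Atom] = []
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 1:  # stray explicit hydrogen
            continue
        symbol = a.GetSymbol()
        if symbol not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(
                f"{mol_id}: unsupported element {symbol!r} at atom {a.GetIdx()}")
        if a.GetFormalCharge():
            dropped.append("charge")
        if a.GetIsotope():
            dropped.append("isotope")
        if a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED:
            dropped.append("stereo")
        index_map[a.GetIdx()] = len(atoms)
        atoms.append(Atom(index=len(atoms), element=symbol))

    bonds: list[Bond] = []
    for b in mol.GetBonds():
        ia, ib = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if ia not in index_map or ib not in index_map:
            continue
        order = _BOND_TYPE_TO_ORDER.get(b.GetBondType())
        if order is None:
            order = 1
            if not kekulized and b.GetBondType() == Chem.BondType.AROMATIC:
                pass  # already warned above
            else:
                dropped.append(f"bond type {b.GetBondType()}")
        if b.GetStereo() != Chem.BondStereo.STEREONONE:
            dropped.append("stereo")
        bonds.append(Bond(index_map[ia], index_map[ib], order))

    if dropped:
        warnings.warn(
            f"{mol_id}: dropped annotations: {sorted(set(dropped))}",
            stacklevel=3)
    graph = MoleculeGraph(id=mol_id, atoms=atoms, bonds=bonds)
    if not graph.is_connected() and graph.n_atoms > 1:
        warnings.warn(f"{mol_id}: disconnected (multi-fragment) record kept",
                      stacklevel=3)
    return graph


def to_rdkit(graph: MoleculeGraph) -> Chem.Mol:
    """Build an RDKit mol (implicit hydrogens) from a MoleculeGraph."""
    rw = Chem.RWMol()
    for atom in graph.atoms:
        rw.AddAtom(Chem.Atom(atom.element))
    for b in graph.bonds:
        rw.AddBond(b.a, b.b, _ORDER_TO_BOND_TYPE[b.order])
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.SanitizeMol(mol, catchErrors=True)
    return mol


# ---------------------------------------------------------------------------
# SMILES
# ---------------------------------------------------------------------------

def parse_smiles(smiles: str, id: str) -> MoleculeGraph:
    """Parse one SMILES string into a heavy-atom graph.

    Stereo/isotope/charge annotations are dropped with a warning; elements
    outside the supported alphabet raise :class:`UnsupportedElementError`.
    """
    if not smiles:
        raise ParseError("empty SMILES string", position=0)
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise ParseError(f"unparsable SMILES {smiles!r}", position=0)
    return _from_rdkit(mol, id)


def graph_to_smiles(graph: MoleculeGraph) -> str:
    return Chem.MolToSmiles(to_rdkit(graph))


def read_smiles_file(path: str | Path,
                     max_failure_fraction: float = 0.5) -> MoleculeLibrary:
    """Read a whitespace-delimited ``SMILES [id]`` line file.

    Per-line failures are collected on ``parse_failures``; the read aborts
    only if more than ``max_failure_fraction`` of non-blank lines fail.
    """
    path = Path(path)
    molecules: list[MoleculeGraph] = []
    failures: list[tuple[int, str]] = []
    seen_ids: set[str] = set()
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            n_lines += 1
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{n_lines}"
            mol_id = _dedup_id(mol_id, seen_ids)
            try:
                molecules.append(parse_smiles(smiles, mol_id))
                seen_ids.add(mol_id)
            except ParseError as exc:
                failures.append((lineno, str(exc)))
    if n_lines and len(failures) / n_lines > max_failure_fraction:
        raise ParseError(
            f"{path}: {len(failures)}/{n_lines} lines failed to parse")
    if not molecules:
        warnings.warn(f"{path}: empty molecule library", stacklevel=2)
    return MoleculeLibrary(molecules, source=str(path), parse_failures=failures)


def write_smiles_file(library: Iterable[MoleculeGraph], path: str | Path) -> None:
    with open(path, "w") as fh:
        for graph in library:
            fh.write(f"{graph_to_smiles(graph)} {graph.id}\n")


# ---------------------------------------------------------------------------
# SDF (V2000)
# ---------------------------------------------------------------------------

def read_sdf(path: str | Path) -> MoleculeLibrary:
    """Read a V2000 SDF file, one MoleculeGraph per ``$$$$``-separated record.

    Ids come from the title line (falling back to ``mol<ordinal>``); a
    duplicate title gets an ``_<k>`` suffix with a warning. Records that
    fail to parse are recorded with their ordinal and skipped. Atom-block
    coordinates are discarded; the descriptor downstream is purely 2D.
    """
    path = Path(path)
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    molecules: list[MoleculeGraph] = []
    failures: list[tuple[int, str]] = []
    seen_ids: set[str] = set()
    for ordinal, mol in enumerate(supplier, start=1):
        if mol is None:
            failures.append((ordinal, f"record {ordinal}: malformed SDF record"))
            warnings.warn(f"{path}: skipping malformed SDF record {ordinal}",
                          stacklevel=2)
            continue
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        mol_id = title.strip() or f"mol{ordinal}"
        mol_id = _dedup_id(mol_id, seen_ids, warn=True)
        try:
            molecules.append(_from_rdkit(mol, mol_id))
            seen_ids.add(mol_id)
        except ParseError as exc:
            failures.append((ordinal, str(exc)))
    if not molecules:
        warnings.warn(f"{path}: empty molecule library", stacklevel=2)
    return MoleculeLibrary(molecules, source=str(path), parse_failures=failures)


def write_sdf(library: Iterable[MoleculeGraph], path: str | Path) -> None:
    """Write molecules as a V2000 SDF (zero-filled coordinates)."""
    with open(path, "w") as fh:
        for graph in library:
            mol = to_rdkit(graph)
            mol.SetProp("_Name", graph.id)
            fh.write(Chem.MolToMolBlock(mol, kekulize=True))
            fh.write("$$$$\n")


def _dedup_id(mol_id: str, seen: set[str], warn: bool = False) -> str:
    if mol_id not in seen:
        return mol_id
    k = 2
    while f"{mol_id}_{k}" in seen:
        k += 1
    if warn:
        warnings.warn(f"duplicate molecule id {mol_id!r}; renamed to "
                      f"{mol_id}_{k}", stacklevel=3)
    return f"{mol_id}_{k}"
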