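"""Hydrogen-suppressed molecular graphs and their matrix machinery.

Molecules enter as SMILES and are reduced to labelled graphs over heavy
atoms: hydrogens are recorded only as per-atom counts, aromatic bonds are
kept as edges of weight 1 in the adjacency/distance matrices (their 1.5
conventional order matters only to bond-order sums).  Everything the
topological descriptors consume — adjacency, topological distance,
Laplacian spectrum, simple and valence vertex degrees — lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "GraphMatrices",
    "ChemGraphError",
    "SmilesParseError",
    "UnsupportedInputError",
    "parse_smiles",
    "to_smiles",
    "distance_matrix",
    "laplacian_spectrum",
    "valence_degrees",
]

EIG_TOL = 1e-9

#: valence electrons (Zv), atomic number (Z) and period for the organic subset
ELEMENT_TABLE: dict[str, tuple[int, int, int]] = {
    "B": (3, 5, 2),
    "C": (4, 6, 2),
    "N": (5, 7, 2),
    "O": (6, 8, 2),
    "F": (7, 9, 2),
    "Si": (4, 14, 3),
    "P": (5, 15, 3),
    "S": (6, 16, 3),
    "Cl": (7, 17, 3),
    "Br": (7, 35, 4),
    "I": (7, 53, 5),
}

#: standard atomic weights (g/mol), used by the constitutional block
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.904,
}


class ChemGraphError(ValueError):
    """Base error for molecular-graph construction and queries."""


class SmilesParseError(ChemGraphError):
    """The SMILES string is syntactically invalid."""


class UnsupportedInputError(ChemGraphError):
    """Structurally valid input outside the supported domain."""


@dataclass(frozen=True)
class Atom:
    element: str
    n_hydrogens: int
    formal_charge: int = 0
    aromatic: bool = False


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: float  # 1, 2, 3 or 1.5 (aromatic)
    in_ring: bool = False

    @property
    def aromatic(self) -> bool:
        return self.order == 1.5


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed, connected, simple molecular graph.

    Attributes
    ----------
    atoms : list of Atom
        Heavy atoms with attached-hydrogen counts and formal charges.
    bonds : list of Bond
        Undirected edges; ``order`` is 1/2/3 or 1.5 for aromatic bonds.
    """

    atoms: list[Atom]
    bonds: list[Bond] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise ChemGraphError("molecular graph needs at least one atom")
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if b.i == b.j:
                raise ChemGraphError(f"self-loop on atom {b.i}")
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ChemGraphError(f"bond ({b.i},{b.j}) out of range")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ChemGraphError(f"duplicate bond {key}")
            seen.add(key)
        if n > 1 and self._n_components() != 1:
            raise UnsupportedInputError(
                "disconnected (multi-fragment) structures are not supported"
            )

    def _n_components(self) -> int:
        return connected_components(csr_matrix(self.adjacency()), directed=False)[0]

    # -- basic invariants ---------------------------------------------------

    @property
    def n(self) -> int:
        """Heavy-atom count."""
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def cyclomatic_number(self) -> int:
        """mu = B - n + 1 for a connected graph."""
        return self.n_bonds - self.n + 1

    def degrees(self) -> np.ndarray:
        delta = np.zeros(self.n, dtype=int)
        for b in self.bonds:
            delta[b.i] += 1
            delta[b.j] += 1
        return delta

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n, self.n), dtype=int)
        for b in self.bonds:
            a[b.i, b.j] = a[b.j, b.i] = 1
        return a

    def matrices(self) -> "GraphMatrices":
        return GraphMatrices.from_graph(self)


@dataclass
class GraphMatrices:
    """Adjacency, topological distance, Laplacian spectrum and degrees."""

    A: np.ndarray
    D: np.ndarray
    L: np.ndarray
    eigenvalues: np.ndarray
    degrees: np.ndarray
    valence_degrees: np.ndarray

    @classmethod
    def from_graph(cls, g: MolecularGraph) -> "GraphMatrices":
        a = g.adjacency()
        d = distance_matrix(g)
        delta = g.degrees()
        lap = np.diag(delta) - a
        eig = np.linalg.eigvalsh(lap.astype(float))
        eig[np.abs(eig) < EIG_TOL] = 0.0
        return cls(
            A=a,
            D=d,
            L=lap,
            eigenvalues=eig,
            degrees=delta,
            valence_degrees=np.array([float(v) for v in valence_degrees(g)]),
        )


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed molecular graph.

    Raises
    ------
    SmilesParseError
        If the string is empty or syntactically invalid.
    UnsupportedInputError
        For multi-fragment inputs (``.`` separated) or atom-free results.
    """
    from rdkit import Chem

    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    if "." in smiles:
        raise UnsupportedInputError(f"multi-fragment SMILES not supported: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise UnsupportedInputError(f"no heavy atoms in {smiles!r}")
    atoms = [
        Atom(
            element=a.GetSymbol(),
            n_hydrogens=a.GetTotalNumHs(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        if b.GetIsAromatic():
            order = 1.5
        else:
            order = float(b.GetBondTypeAsDouble())
            if order not in (1.0, 2.0, 3.0):
                raise UnsupportedInputError(
                    f"unsupported bond order {order} in {smiles!r}"
                )
        bonds.append(
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order, b.IsInRing())
        )
    return MolecularGraph(atoms=atoms, bonds=bonds)


def to_smiles(g: MolecularGraph) -> str:
    """Serialise a molecular graph back to canonical SMILES (via rdkit)."""
    from rdkit import Chem

    mol = Chem.RWMol()
    for atom in g.atoms:
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        a.SetNumExplicitHs(atom.n_hydrogens)
        a.SetNoImplicit(True)
        mol.AddAtom(a)
    order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                 3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
    for b in g.bonds:
        mol.AddBond(b.i, b.j, order_map[float(b.order)])
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def distance_matrix(g: MolecularGraph) -> np.ndarray:
    """All-pairs topological distances (bond counts) via unweighted BFS.

    Returns an ``n x n`` integer matrix; raises for disconnected graphs.
    """
    if g.n == 1:
        return np.zeros((1, 1), dtype=int)
    d = shortest_path(csr_matrix(g.adjacency()), method="BF", directed=False,
                      unweighted=True)
    if np.isinf(d).any():
        raise UnsupportedInputError("distance matrix undefined: graph disconnected")
    return d.astype(int)


def laplacian_spectrum(g: MolecularGraph) -> np.ndarray:
    """Laplacian eigenvalues in ascending order.

    For a connected graph the smallest eigenvalue is 0 (within 1e-9) and
    the second smallest is strictly positive.
    """
    delta = g.degrees()
    lap = (np.diag(delta) - g.adjacency()).astype(float)
    eig = np.linalg.eigvalsh(lap)
    eig[np.abs(eig) < EIG_TOL] = 0.0
    return eig


def valence_degrees(g: MolecularGraph, extra_elements: dict[str, tuple[int, int, int]] | None = None) -> list[Fraction]:
    """Kier-Hall valence degrees, one exact rational per heavy atom.

    For period-2 elements ``deltav = Zv - h + q``; for heavier elements
    ``deltav = (Zv - h + q) / (Z - Zv - 1)`` with Zv valence electrons, Z
    atomic number, h attached hydrogens and q the formal charge.
    """
    table = dict(ELEMENT_TABLE)
    if extra_elements:
        table.update(extra_elements)
    out: list[Fraction] = []
    for idx, atom in enumerate(g.atoms):
        if atom.element not in table:
            raise UnsupportedInputError(
                f"unsupported element {atom.element!r} at atom index {idx}"
            )
        zv, z, period = table[atom.element]
        num = zv - atom.n_hydrogens + atom.formal_charge
        if num <= 0:
            raise ChemGraphError(
                f"non-positive valence degree for atom {idx} ({atom.element})"
            )
        if period == 2:
            out.append(Fraction(num))
        else:
            out.append(Fraction(num, z - zv - 1))
    return out
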