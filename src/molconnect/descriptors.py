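"""Registry-driven molecular descriptor computation.

Four descriptor families are covered — constitutional, topological,
connectivity (Randic-type) indices, and walk/path counts — each computed
from the hydrogen-suppressed molecular graph.  The registry is the unit
of extension: every descriptor is a named entry with a family, a tier
(``core`` descriptors are defined for any connected graph with n >= 2;
``extended`` ones may refuse exotic chemistry) and a compute function.

Core formulas
-------------
Wiener            W      = 1/2 sum_ij D_ij
Zagreb            ZM1    = sum_i delta_i^2 ;  ZM2 = sum_edges delta_i delta_j
                  ZM1V/ZM2V use Kier-Hall valence degrees delta_v
Balaban           J      = B/(mu+1) * sum_edges (s_i s_j)^(-1/2),  s_i = sum_j D_ij
Randic chi        Xk     = sum over k-edge simple paths of (prod delta)^(-1/2)
Schultz           SMTI   = sum_i [(A + D) delta]_i           (SMTIV with delta_v)
Gutman            GMTI   = sum_{i<j} delta_i delta_j D_ij    (GMTIV with delta_v)
Quadratic         Qindex = 3 - 2n + sum_i delta_i^2 / 2
quasi-Wiener      QW     = n * sum_{lambda>0} 1/lambda       (= W on trees)
hyper-distance    HyDp   = sum_{i<j} (D_ij + D_ij^2)/2
walk counts       MWCk   = sum_ij (A^k)_ij
path counts       MPCk   = number of simple paths with k edges
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from sklearn.base import BaseEstimator, TransformerMixin

from .chemgraph import (
    ATOMIC_WEIGHTS,
    ELEMENT_TABLE,
    ChemGraphError,
    GraphMatrices,
    MolecularGraph,
    parse_smiles,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorDef",
    "DescriptorMatrix",
    "DescriptorCalculator",
    "RegistryError",
    "NotComputableError",
    "registry",
    "descriptor_names",
    "compute_descriptor",
    "compute_matrix",
    "remove_constant_descriptors",
    "CONSTANT_VARIANCE_TOL",
]

CONSTANT_VARIANCE_TOL = 1e-12


class RegistryError(KeyError):
    """Unknown descriptor name."""


class NotComputableError(ValueError):
    """A descriptor is undefined for the given molecule (never silent NaN)."""


class DescriptorContext:
    """Per-molecule cache shared by all descriptor functions."""

    def __init__(self, g: MolecularGraph):
        self.g = g
        self.m: GraphMatrices = g.matrices()
        self._paths: dict[int, list[tuple[int, ...]]] = {}

    def simple_paths(self, k: int) -> list[tuple[int, ...]]:
        """All simple paths with exactly ``k`` edges, each counted once."""
        if k not in self._paths:
            adj = [np.flatnonzero(self.m.A[i]).tolist() for i in range(self.g.n)]
            paths: list[tuple[int, ...]] = []

            def extend(path: list[int]) -> None:
                if len(path) == k + 1:
                    if path[0] < path[-1]:
                        paths.append(tuple(path))
                    return
                for nxt in adj[path[-1]]:
                    if nxt not in path:
                        path.append(nxt)
                        extend(path)
                        path.pop()

            if k == 0:
                paths = [(i,) for i in range(self.g.n)]
            else:
                for start in range(self.g.n):
                    extend([start])
            self._paths[k] = paths
        return self._paths[k]


@dataclass(frozen=True)
class DescriptorDef:
    name: str
    family: str  # constitutional | topological | connectivity | walk_path
    compute: Callable[[DescriptorContext], float]
    tier: str = "core"  # core | extended
    doc: str = ""


_REGISTRY: dict[str, DescriptorDef] = {}


def _register(name: str, family: str, tier: str = "core", doc: str = ""):
    def wrap(fn: Callable[[DescriptorContext], float]):
        if name in _REGISTRY:
            raise ValueError(f"duplicate descriptor name {name!r}")
        _REGISTRY[name] = DescriptorDef(name, family, fn, tier, doc)
        return fn

    return wrap


def registry() -> dict[str, DescriptorDef]:
    """The full descriptor registry in deterministic (insertion) order."""
    return dict(_REGISTRY)


def descriptor_names(tier: str = "core") -> list[str]:
    """Names in registry order; ``tier='core+extended'`` for everything."""
    tiers = {"core"} if tier == "core" else {"core", "extended"}
    return [d.name for d in _REGISTRY.values() if d.tier in tiers]


# ---------------------------------------------------------------------------
# constitutional block
# ---------------------------------------------------------------------------

def _element_count(symbol: str):
    def fn(ctx: DescriptorContext) -> float:
        return float(sum(1 for a in ctx.g.atoms if a.element == symbol))

    return fn


_register("nSK", "constitutional", doc="heavy atom count")(
    lambda ctx: float(ctx.g.n))
_register("nBT", "constitutional", doc="bond count")(
    lambda ctx: float(ctx.g.n_bonds))
_register("nCIC", "constitutional", doc="cyclomatic number mu = B - n + 1")(
    lambda ctx: float(ctx.g.cyclomatic_number))
_register("nH", "constitutional", doc="attached hydrogen count")(
    lambda ctx: float(sum(a.n_hydrogens for a in ctx.g.atoms)))
for _sym in ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I"):
    _register(f"n{_sym}", "constitutional", doc=f"{_sym} atom count")(
        _element_count(_sym))
_register("nX", "constitutional", doc="halogen count")(
    lambda ctx: float(sum(1 for a in ctx.g.atoms
                          if a.element in ("F", "Cl", "Br", "I"))))
_register("nDB", "constitutional", doc="double bond count")(
    lambda ctx: float(sum(1 for b in ctx.g.bonds if b.order == 2)))
_register("nTB", "constitutional", doc="triple bond count")(
    lambda ctx: float(sum(1 for b in ctx.g.bonds if b.order == 3)))
_register("nAB", "constitutional", doc="aromatic bond count")(
    lambda ctx: float(sum(1 for b in ctx.g.bonds if b.order == 1.5)))


@_register("AMW", "constitutional", doc="mean atomic weight incl. hydrogens")
def _amw(ctx: DescriptorContext) -> float:
    heavy = 0.0
    n_h = 0
    for a in ctx.g.atoms:
        if a.element not in ATOMIC_WEIGHTS:
            raise NotComputableError(f"no atomic weight for {a.element!r}")
        heavy += ATOMIC_WEIGHTS[a.element]
        n_h += a.n_hydrogens
    return (heavy + n_h * ATOMIC_WEIGHTS["H"]) / (ctx.g.n + n_h)


def rotatable_bond_count(g: MolecularGraph, exclude_amides: bool = True) -> int:
    """Acyclic single bonds with both endpoints of degree >= 2.

    Amide C-N bonds (the carbon double-bonded to an oxygen) are excluded
    by default, the dominant rotatable-bond convention.
    """
    delta = g.degrees()
    double_o_partner = set()
    if exclude_amides:
        for b in g.bonds:
            if b.order == 2:
                for x, y in ((b.i, b.j), (b.j, b.i)):
                    if g.atoms[x].element == "C" and g.atoms[y].element == "O":
                        double_o_partner.add(x)
    count = 0
    for b in g.bonds:
        if b.order != 1 or b.in_ring:
            continue
        if delta[b.i] < 2 or delta[b.j] < 2:
            continue
        if exclude_amides:
            ei, ej = g.atoms[b.i].element, g.atoms[b.j].element
            if {ei, ej} == {"C", "N"}:
                carbon = b.i if ei == "C" else b.j
                if carbon in double_o_partner:
                    continue
        count += 1
    return count


_register("RBN", "constitutional", doc="rotatable bond count")(
    lambda ctx: float(rotatable_bond_count(ctx.g)))


# ---------------------------------------------------------------------------
# topological block
# ---------------------------------------------------------------------------

@_register("W", "topological", doc="Wiener index")
def _wiener(ctx: DescriptorContext) -> float:
    return float(ctx.m.D.sum()) / 2.0


@_register("WA", "topological", doc="mean topological distance")
def _mean_distance(ctx: DescriptorContext) -> float:
    n = ctx.g.n
    if n < 2:
        raise NotComputableError("mean distance needs n >= 2")
    return float(ctx.m.D.sum()) / (n * (n - 1))


_register("ZM1", "topological", doc="first Zagreb index")(
    lambda ctx: float((ctx.m.degrees.astype(float) ** 2).sum()))
_register("ZM2", "topological", doc="second Zagreb index")(
    lambda ctx: float(sum(ctx.m.degrees[b.i] * ctx.m.degrees[b.j]
                          for b in ctx.g.bonds)))
_register("ZM1V", "topological", doc="first Zagreb index, valence degrees")(
    lambda ctx: float((ctx.m.valence_degrees ** 2).sum()))
_register("ZM2V", "topological", doc="second Zagreb index, valence degrees")(
    lambda ctx: float(sum(ctx.m.valence_degrees[b.i] * ctx.m.valence_degrees[b.j]
                          for b in ctx.g.bonds)))


@_register("J", "topological", doc="Balaban distance connectivity index")
def _balaban(ctx: DescriptorContext) -> float:
    g = ctx.g
    if g.n_bonds == 0:
        raise NotComputableError("Balaban J undefined without bonds")
    s = ctx.m.D.sum(axis=1).astype(float)
    mu = g.cyclomatic_number
    total = sum(1.0 / np.sqrt(s[b.i] * s[b.j]) for b in g.bonds)
    return g.n_bonds / (mu + 1.0) * total


@_register("Har", "topological", doc="Harary index (sum of reciprocal distances)")
def _harary(ctx: DescriptorContext) -> float:
    d = ctx.m.D.astype(float)
    iu = np.triu_indices(ctx.g.n, k=1)
    return float((1.0 / d[iu]).sum()) if iu[0].size else 0.0


def _schultz(ctx: DescriptorContext, delta: np.ndarray) -> float:
    return float(((ctx.m.A + ctx.m.D) @ delta).sum())


_register("SMTI", "topological", doc="Schultz molecular topological index")(
    lambda ctx: _schultz(ctx, ctx.m.degrees.astype(float)))
_register("SMTIV", "topological", doc="Schultz MTI with valence degrees")(
    lambda ctx: _schultz(ctx, ctx.m.valence_degrees))


def _gutman(ctx: DescriptorContext, delta: np.ndarray) -> float:
    outer = np.outer(delta, delta) * ctx.m.D
    iu = np.triu_indices(ctx.g.n, k=1)
    return float(outer[iu].sum())


_register("GMTI", "topological", doc="Gutman molecular topological index")(
    lambda ctx: _gutman(ctx, ctx.m.degrees.astype(float)))
_register("GMTIV", "topological", doc="Gutman MTI with valence degrees")(
    lambda ctx: _gutman(ctx, ctx.m.valence_degrees))


@_register("Qindex", "topological", doc="quadratic (normalised Zagreb) index")
def _qindex(ctx: DescriptorContext) -> float:
    return 3.0 - 2.0 * ctx.g.n + float((ctx.m.degrees.astype(float) ** 2).sum()) / 2.0


@_register("QW", "topological", doc="quasi-Wiener (Kirchhoff) index")
def _quasi_wiener(ctx: DescriptorContext) -> float:
    lam = ctx.m.eigenvalues
    positive = lam[lam > 0]
    if positive.size != ctx.g.n - 1:
        raise NotComputableError("quasi-Wiener needs a connected graph")
    return float(ctx.g.n * (1.0 / positive).sum())


@_register("HyDp", "topological", doc="hyper-distance-path (hyper-Wiener) index")
def _hyper_wiener(ctx: DescriptorContext) -> float:
    d = ctx.m.D.astype(float)
    iu = np.triu_indices(ctx.g.n, k=1)
    return float(((d[iu] + d[iu] ** 2) / 2.0).sum())


_register("RAM", "topological", doc="ramification index sum(max(0, delta-2))")(
    lambda ctx: float(np.maximum(ctx.m.degrees - 2, 0).sum()))


@_register("ECC", "topological", doc="eccentricity sum")
def _ecc(ctx: DescriptorContext) -> float:
    return float(ctx.m.D.max(axis=1).sum())


_register("RADIUS", "topological", doc="graph radius")(
    lambda ctx: float(ctx.m.D.max(axis=1).min()))
_register("DIAM", "topological", doc="graph diameter")(
    lambda ctx: float(ctx.m.D.max()))


# ---------------------------------------------------------------------------
# connectivity (Randic chi) block
# ---------------------------------------------------------------------------

def _chi(ctx: DescriptorContext, order: int, delta: np.ndarray) -> float:
    if (delta <= 0).any():
        raise NotComputableError("chi index needs positive degrees")
    if order == 0:
        return float((delta.astype(float) ** -0.5).sum())
    total = 0.0
    for path in ctx.simple_paths(order):
        total += 1.0 / np.sqrt(np.prod(delta[list(path)].astype(float)))
    return total


for _k in range(4):
    _register(f"X{_k}", "connectivity", doc=f"Randic connectivity index order {_k}")(
        (lambda k: lambda ctx: _chi(ctx, k, ctx.m.degrees))(_k))
    _register(f"X{_k}v", "connectivity",
              doc=f"valence connectivity index order {_k}")(
        (lambda k: lambda ctx: _chi(ctx, k, ctx.m.valence_degrees))(_k))


# ---------------------------------------------------------------------------
# walk and path counts
# ---------------------------------------------------------------------------

def molecular_walk_count(g: MolecularGraph, k: int) -> float:
    """MWC_k = sum of all entries of A^k (walks of length k, ordered)."""
    a = g.adjacency().astype(float)
    return float(np.linalg.matrix_power(a, k).sum())


def molecular_path_count(g: MolecularGraph, k: int) -> float:
    """MPC_k = number of simple paths with exactly k edges."""
    return float(len(DescriptorContext(g).simple_paths(k)))


for _k in range(2, 6):
    _register(f"MWC{_k}", "walk_path", doc=f"molecular walk count order {_k}")(
        (lambda k: lambda ctx: float(
            np.linalg.matrix_power(ctx.m.A.astype(float), k).sum()))(_k))
_register("TWC", "walk_path", doc="total walk count, orders 1-5")(
    lambda ctx: float(sum(np.linalg.matrix_power(ctx.m.A.astype(float), k).sum()
                          for k in range(1, 6))))
for _k in range(2, 6):
    _register(f"MPC{_k}", "walk_path", doc=f"molecular path count order {_k}")(
        (lambda k: lambda ctx: float(len(ctx.simple_paths(k))))(_k))


# ---------------------------------------------------------------------------
# extended tier: E-state and heteroatom-weighted indices
# ---------------------------------------------------------------------------

_PERIOD = {sym: row for sym, (_, _, row) in ELEMENT_TABLE.items()}


def _estate_values(ctx: DescriptorContext) -> tuple[np.ndarray, np.ndarray]:
    """Kier-Hall intrinsic states I and field perturbations dI.

    I_i = ((2/L_i)^2 * deltav_i + 1) / delta_i with L the period;
    dI_i = sum_j (I_i - I_j) / (d_ij + 1)^2.
    """
    g = ctx.g
    delta = ctx.m.degrees.astype(float)
    if (delta <= 0).any():
        raise NotComputableError("E-state undefined for isolated atoms")
    periods = []
    for idx, a in enumerate(g.atoms):
        if a.element not in _PERIOD:
            raise NotComputableError(
                f"E-state undefined for element {a.element!r} at atom {idx}")
        periods.append(_PERIOD[a.element])
    L = np.asarray(periods, dtype=float)
    intrinsic = ((2.0 / L) ** 2 * ctx.m.valence_degrees + 1.0) / delta
    r = ctx.m.D.astype(float) + 1.0
    np.fill_diagonal(r, np.inf)
    diff = intrinsic[:, None] - intrinsic[None, :]
    d_i = (diff / r**2).sum(axis=1)
    return intrinsic, d_i


@_register("TIE", "topological", tier="extended",
           doc="E-state topological parameter (sum of atomic E-states)")
def _tie(ctx: DescriptorContext) -> float:
    intrinsic, d_i = _estate_values(ctx)
    return float((intrinsic + d_i).sum())


@_register("MAXDN", "topological", tier="extended",
           doc="maximal electrotopological negative variation")
def _maxdn(ctx: DescriptorContext) -> float:
    _, d_i = _estate_values(ctx)
    return float(max(0.0, -d_i.min()))


@_register("TI1", "topological", tier="extended",
           doc="Laplacian spectral index 4*QW/n^2")
def _ti1(ctx: DescriptorContext) -> float:
    return 4.0 * _quasi_wiener(ctx) / ctx.g.n**2


@_register("TI2", "topological", tier="extended",
           doc="Laplacian spectral index 4/(n*lambda_2)")
def _ti2(ctx: DescriptorContext) -> float:
    lam = ctx.m.eigenvalues
    positive = lam[lam > 0]
    if positive.size == 0:
        raise NotComputableError("algebraic connectivity undefined")
    return 4.0 / (ctx.g.n * float(positive[0]))


@_register("Jhete", "topological", tier="extended",
           doc="Balaban-type index over the electronegativity-weighted "
               "(Barysz) distance matrix")
def _jhete(ctx: DescriptorContext) -> float:
    g = ctx.g
    if g.n_bonds == 0:
        raise NotComputableError("Jhete undefined without bonds")
    z = {}
    for idx, a in enumerate(g.atoms):
        if a.element not in ELEMENT_TABLE:
            raise NotComputableError(
                f"Jhete undefined for element {a.element!r} at atom {idx}")
        z[idx] = ELEMENT_TABLE[a.element][1]
    zc = 6.0
    w = np.zeros((g.n, g.n))
    for b in g.bonds:
        weight = zc * zc / (z[b.i] * z[b.j] * float(b.order))
        w[b.i, b.j] = w[b.j, b.i] = weight
    dw = shortest_path(csr_matrix(w), method="D", directed=False)
    s = dw.sum(axis=1)
    mu = g.cyclomatic_number
    total = sum(1.0 / np.sqrt(s[b.i] * s[b.j]) for b in g.bonds)
    return g.n_bonds / (mu + 1.0) * total


# ---------------------------------------------------------------------------
# matrix-level API
# ---------------------------------------------------------------------------

@dataclass
class DescriptorMatrix:
    """Molecules x descriptors table plus per-descriptor metadata."""

    values: pd.DataFrame  # index: molecule ids, columns: descriptor names
    families: dict[str, str] = field(default_factory=dict)
    tiers: dict[str, str] = field(default_factory=dict)
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, names: Sequence[str]) -> "DescriptorMatrix":
        names = list(names)
        return DescriptorMatrix(
            values=self.values[names].copy(),
            families={k: self.families[k] for k in names},
            tiers={k: self.tiers[k] for k in names},
        )

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="molecule_id")

    def metadata(self) -> dict:
        return {
            name: {"family": self.families[name], "tier": self.tiers[name]}
            for name in self.values.columns
        }


def compute_descriptor(name: str, g: MolecularGraph) -> float:
    """Compute a single named descriptor for one molecule."""
    if name not in _REGISTRY:
        raise RegistryError(f"unknown descriptor {name!r}")
    value = _REGISTRY[name].compute(DescriptorContext(g))
    if not np.isfinite(value):
        raise NotComputableError(f"{name} evaluated to a non-finite value")
    return value


def compute_matrix(
    molecules: Iterable[MolecularGraph | str],
    tier: str = "core",
    molecule_ids: Sequence[str] | None = None,
) -> DescriptorMatrix:
    """Compute the descriptor matrix for a batch of molecules.

    Accepts graphs or SMILES strings.  Molecules on which any descriptor
    fails are dropped with a logged reason (mirroring curation) and
    recorded in ``DescriptorMatrix.dropped``.
    """
    molecules = list(molecules)
    if not molecules:
        raise ValueError("compute_matrix needs at least one molecule")
    names = descriptor_names(tier)
    ids = (list(molecule_ids) if molecule_ids is not None
           else [f"mol{i}" for i in range(len(molecules))])
    if len(ids) != len(molecules):
        raise ValueError("molecule_ids length mismatch")
    rows, kept, dropped = [], [], []
    for mol_id, mol in zip(ids, molecules):
        try:
            g = parse_smiles(mol) if isinstance(mol, str) else mol
            ctx = DescriptorContext(g)
            row = []
            for name in names:
                value = _REGISTRY[name].compute(ctx)
                if not np.isfinite(value):
                    raise NotComputableError(f"{name} non-finite")
                row.append(value)
        except (ChemGraphError, NotComputableError) as exc:
            logger.warning("dropping molecule %s: %s", mol_id, exc)
            dropped.append((mol_id, str(exc)))
            continue
        rows.append(row)
        kept.append(mol_id)
    if not rows:
        raise ValueError("no molecule survived descriptor computation")
    frame = pd.DataFrame(rows, index=kept, columns=names, dtype=float)
    return DescriptorMatrix(
        values=frame,
        families={n: _REGISTRY[n].family for n in names},
        tiers={n: _REGISTRY[n].tier for n in names},
        dropped=dropped,
    )


def remove_constant_descriptors(
    m: DescriptorMatrix, tol: float = CONSTANT_VARIANCE_TOL
) -> tuple[DescriptorMatrix, list[str]]:
    """Drop columns whose sample variance is <= ``tol``.

    Returns a new matrix plus the removed names; the input is untouched.
    Raises if fewer than two molecules or if every column is constant.
    """
    if m.values.shape[0] < 2:
        raise ValueError("constant-descriptor removal needs >= 2 molecules")
    variances = m.values.var(axis=0, ddof=1)
    removed = [name for name in m.values.columns if variances[name] <= tol]
    if len(removed) == len(m.values.columns):
        raise ValueError("degenerate data: every descriptor is constant")
    kept = [n for n in m.values.columns if n not in removed]
    return m.subset(kept), removed


class DescriptorCalculator(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: SMILES/graphs -> descriptor DataFrame.

    Parameters
    ----------
    tier : {"core", "core+extended"}
        Which registry tier to compute.
    drop_constant : bool
        Whether to drop (near-)constant columns after computation.
    """

    def __init__(self, tier: str = "core", drop_constant: bool = False,
                 constant_tol: float = CONSTANT_VARIANCE_TOL):
        self.tier = tier
        self.drop_constant = drop_constant
        self.constant_tol = constant_tol

    def fit(self, X, y=None):
        self.feature_names_ = descriptor_names(self.tier)
        return self

    def transform(self, X) -> pd.DataFrame:
        matrix = compute_matrix(X, tier=self.tier)
        if self.drop_constant and matrix.values.shape[0] >= 2:
            matrix, self.removed_ = remove_constant_descriptors(
                matrix, self.constant_tol)
        return matrix.values

    def get_feature_names_out(self, input_features=None):
        return np.asarray(descriptor_names(self.tier))
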