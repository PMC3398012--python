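"""Descriptor formulas against brute-force graph oracles and invariants."""

import itertools

import numpy as np
import pytest

from molconnect.chemgraph import Atom, Bond, MolecularGraph
from molconnect.descriptors import (
    DescriptorMatrix,
    NotComputableError,
    RegistryError,
    compute_descriptor,
    compute_matrix,
    descriptor_names,
    molecular_path_count,
    molecular_walk_count,
    registry,
    remove_constant_descriptors,
)

from conftest import cycle_graph, path_graph, star_graph


def brute_force_wiener(g: MolecularGraph) -> float:
    """Floyd-Warshall all-pairs half-sum, independent of the BFS path."""
    n = g.n
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for b in g.bonds:
        d[b.i, b.j] = d[b.j, b.i] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return float(d.sum()) / 2.0


def brute_force_walks(g: MolecularGraph, k: int) -> int:
    """Count all vertex sequences of length k+1 along edges."""
    a = g.adjacency()
    count = 0
    for seq in itertools.product(range(g.n), repeat=k + 1):
        if all(a[seq[i], seq[i + 1]] for i in range(k)):
            count += 1
    return count


def brute_force_paths(g: MolecularGraph, k: int) -> int:
    """Count unordered simple paths with k edges by permutation filter."""
    a = g.adjacency()
    count = 0
    for seq in itertools.permutations(range(g.n), k + 1):
        if seq[0] < seq[-1] and all(a[seq[i], seq[i + 1]] for i in range(k)):
            count += 1
    return count


class TestWorkedExamples:
    def test_wiener_butane(self):
        assert compute_descriptor("W", path_graph(4)) == 10.0

    @pytest.mark.parametrize("n", [2, 3, 5, 9])
    def test_qindex_vanishes_on_paths(self, n):
        assert compute_descriptor("Qindex", path_graph(n)) == 0.0

    def test_gutman_p3(self):
        assert compute_descriptor("GMTI", path_graph(3)) == 6.0

    def test_zagreb_star(self):
        assert compute_descriptor("ZM1", star_graph(4)) == 20.0

    def test_randic_chi1_p3(self):
        assert compute_descriptor("X1", path_graph(3)) == pytest.approx(
            np.sqrt(2.0), abs=1e-9)

    def test_balaban_j_matches_direct_formula(self, random_graphs_mixed):
        for g in random_graphs_mixed[:10]:
            if g.n < 2:
                continue
            d = g.matrices().D
            s = d.sum(axis=1)
            expected = g.n_bonds / (g.cyclomatic_number + 1) * sum(
                1.0 / np.sqrt(s[b.i] * s[b.j]) for b in g.bonds)
            assert compute_descriptor("J", g) == pytest.approx(expected)

    def test_unknown_name_raises(self):
        with pytest.raises(RegistryError):
            compute_descriptor("WHIM1", path_graph(3))


class TestOracleEquivalence:
    def test_wiener_brute_force(self, random_graphs_mixed):
        for g in random_graphs_mixed:
            assert compute_descriptor("W", g) == brute_force_wiener(g)

    def test_quasi_wiener_equals_wiener_on_trees(self, random_trees):
        for g in random_trees:
            assert compute_descriptor("QW", g) == pytest.approx(
                compute_descriptor("W", g), rel=1e-9)

    def test_walk_counts_brute_force(self, random_graphs_mixed):
        for g in random_graphs_mixed:
            if g.n > 6:
                continue
            for k in range(2, 5):
                assert molecular_walk_count(g, k) == brute_force_walks(g, k)

    def test_path_counts_brute_force(self, random_graphs_mixed):
        for g in random_graphs_mixed:
            if g.n > 7:
                continue
            for k in range(2, 5):
                assert molecular_path_count(g, k) == brute_force_paths(g, k)


class TestInvariance:
    def relabel(self, g: MolecularGraph, rng) -> MolecularGraph:
        perm = rng.permutation(g.n)
        atoms = [None] * g.n
        for old, new in enumerate(perm):
            atoms[new] = g.atoms[old]
        bonds = [Bond(int(perm[b.i]), int(perm[b.j]), b.order, b.in_ring)
                 for b in g.bonds]
        return MolecularGraph(atoms=atoms, bonds=bonds)

    def test_descriptors_invariant_under_relabelling(self, random_graphs_mixed):
        rng = np.random.default_rng(3)
        names = descriptor_names("core")
        for g in random_graphs_mixed[:8]:
            h = self.relabel(g, rng)
            for name in names:
                assert compute_descriptor(name, g) == pytest.approx(
                    compute_descriptor(name, h), rel=1e-9), name

    def test_pendant_vertex_strictly_increases_indices(self, random_trees):
        rng = np.random.default_rng(4)
        for g in random_trees[:15]:
            degree = g.degrees()
            sites = np.flatnonzero(degree < 4)
            if sites.size == 0 or g.n >= 12:
                continue
            site = int(rng.choice(sites))
            atoms = list(g.atoms) + [Atom("C", 3)]
            bonds = list(g.bonds) + [Bond(site, g.n, 1.0)]
            bigger = MolecularGraph(atoms=atoms, bonds=bonds)
            for name in ("SMTI", "GMTI", "W"):
                assert (compute_descriptor(name, bigger)
                        > compute_descriptor(name, g)), name


class TestMatrix:
    def test_core_matrix_complete_and_deterministic(self, random_trees):
        mols = random_trees[:10]
        m1 = compute_matrix(mols, tier="core")
        m2 = compute_matrix(mols, tier="core")
        assert m1.values.shape == (10, len(descriptor_names("core")))
        assert not m1.values.isna().any().any()
        assert m1.values.equals(m2.values)

    def test_extended_tier_appends_columns(self, random_trees):
        m = compute_matrix(random_trees[:5], tier="core+extended")
        assert "TIE" in m.values.columns and "Jhete" in m.values.columns
        assert m.tiers["TIE"] == "extended"

    def test_registry_order_is_column_order(self, random_trees):
        m = compute_matrix(random_trees[:3])
        assert list(m.values.columns) == descriptor_names("core")

    def test_failing_molecule_dropped_with_reason(self, random_trees):
        m = compute_matrix(["CCC", "C[AsH2]", "CCO"],
                           molecule_ids=["a", "b", "c"])
        assert m.molecule_ids == ["a", "c"]
        assert m.dropped and m.dropped[0][0] == "b"

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            compute_matrix([])

    def test_smiles_accepted_directly(self):
        m = compute_matrix(["CCCC"], molecule_ids=["butane"])
        assert m.values.loc["butane", "W"] == 10.0


class TestConstantRemoval:
    def make(self, array, names):
        import pandas as pd
        frame = pd.DataFrame(array, columns=names)
        return DescriptorMatrix(values=frame,
                                families={n: "topological" for n in names},
                                tiers={n: "core" for n in names})

    def test_constant_column_removed_varying_retained(self):
        m = self.make(np.column_stack([np.ones(5), np.arange(5.0)]),
                      ["const", "vary"])
        cleaned, removed = remove_constant_descriptors(m)
        assert removed == ["const"]
        assert cleaned.descriptor_names == ["vary"]
        assert m.values.shape[1] == 2  # original untouched

    def test_variance_at_tolerance_boundary_removed(self):
        tol = 1e-12
        base = np.zeros(4)
        wiggle = base + np.array([0, 1, 0, 1]) * np.sqrt(tol * 3 / 2)
        m = self.make(np.column_stack([wiggle, np.arange(4.0)]), ["w", "v"])
        assert np.var(wiggle, ddof=1) == pytest.approx(tol)
        _, removed = remove_constant_descriptors(m, tol=tol)
        assert removed == ["w"]

    def test_all_constant_raises(self):
        m = self.make(np.ones((4, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            remove_constant_descriptors(m)

    def test_single_molecule_raises(self):
        m = self.make(np.ones((1, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            remove_constant_descriptors(m)


def test_every_core_descriptor_defined_down_to_two_atoms():
    for g in (path_graph(2), path_graph(3), cycle_graph(3)):
        for name in descriptor_names("core"):
            value = compute_descriptor(name, g)
            assert np.isfinite(value), name


def test_registry_names_unique_with_families():
    reg = registry()
    families = {d.family for d in reg.values()}
    assert families == {"constitutional", "topological", "connectivity",
                        "walk_path"}
    assert len(reg) >= 55
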