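"""Brute-force graph oracles, independent of the library's decomposition code.

These work directly on an adjacency-list view of the heavy-atom graph using
networkx primitives (bridges, minimum cycle bases, connected components),
so they share no logic with the atom-classification routines they check.
Intended for small molecules (<= ~12 heavy atoms).
"""

from __future__ import annotations

import networkx as nx
from rdkit import Chem


def mol_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), z=atom.GetAtomicNum())
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
                   order=bond.GetBondTypeAsDouble())
    return g


def oracle_ring_atoms(g: nx.Graph) -> set[int]:
    """Atoms on some cycle = endpoints of non-bridge edges."""
    bridges = set(frozenset(e) for e in nx.bridges(g))
    atoms = set()
    for u, v in g.edges:
        if frozenset((u, v)) not in bridges:
            atoms.update((u, v))
    return atoms


def oracle_ring_sizes(g: nx.Graph) -> list[int]:
    """Sorted sizes of a minimum cycle basis (SSSR-equivalent sizes)."""
    return sorted(len(c) for c in nx.minimum_cycle_basis(g))


def oracle_linker_atoms(g: nx.Graph) -> set[int]:
    """Non-ring atoms whose removal separates two ring-bearing components."""
    ring_atoms = oracle_ring_atoms(g)
    out = set()
    for node in g.nodes:
        if node in ring_atoms:
            continue
        h = g.copy()
        h.remove_node(node)
        n_ring_comps = sum(1 for comp in nx.connected_components(h) if comp & ring_atoms)
        base = sum(1 for comp in nx.connected_components(g) if comp & ring_atoms)
        if n_ring_comps > base:
            out.add(node)
    return out


def oracle_exo_atoms(g: nx.Graph, framework: set[int]) -> set[int]:
    """Degree-1 atoms multi-bonded to a framework atom."""
    out = set()
    for u, v, data in g.edges(data=True):
        if data["order"] < 2:
            continue
        for term, anchor in ((u, v), (v, u)):
            if g.degree(term) == 1 and term not in framework and anchor in framework:
                out.add(term)
    return out


def oracle_murcko_atoms(g: nx.Graph) -> set[int]:
    ring = oracle_ring_atoms(g)
    if not ring:
        return set()
    linker = oracle_linker_atoms(g)
    core = ring | linker
    return core | oracle_exo_atoms(g, core)


def oracle_ring_assembly_atom_sets(g: nx.Graph) -> list[set[int]]:
    """Delete every bridge edge; keep components that contain a cycle."""
    bridges = set(frozenset(e) for e in nx.bridges(g))
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for u, v in g.edges:
        if frozenset((u, v)) not in bridges:
            h.add_edge(u, v)
    out = []
    for comp in nx.connected_components(h):
        sub = h.subgraph(comp)
        if sub.number_of_edges() >= sub.number_of_nodes():
            out.append(set(comp))
    return out


def oracle_bridge_assembly_atom_sets(g: nx.Graph) -> list[set[int]]:
    """Assemblies where some minimum-cycle-basis ring pair shares >= 2 edges."""
    basis = nx.minimum_cycle_basis(g)
    edge_sets = []
    for cycle in basis:
        sub = g.subgraph(cycle)
        # edges of the cycle: walk it as the induced subgraph's cycle
        edges = {frozenset(e) for e in sub.edges}
        edge_sets.append((set(cycle), edges))
    bridged = set()
    for i in range(len(basis)):
        for j in range(i + 1, len(basis)):
            if len(edge_sets[i][1] & edge_sets[j][1]) >= 2:
                bridged |= edge_sets[i][0] | edge_sets[j][0]
    return [a for a in oracle_ring_assembly_atom_sets(g) if a & bridged]


def oracle_side_chain_atom_sets(g: nx.Graph) -> list[set[int]]:
    murcko = oracle_murcko_atoms(g)
    if not murcko:
        return []
    rest = set(g.nodes) - murcko
    h = g.subgraph(rest)
    return [set(c) for c in nx.connected_components(h)]
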