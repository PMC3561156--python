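"""Structural partition of a molecule into scaffold representations.

A molecule is dissected into:

* **Murcko framework** — the union of all ring systems and the linkers
  connecting them, obtained by pruning terminal side-chain atoms;
* **graph framework** — the Murcko framework with every atom carbon and
  every bond single (pure topology);
* **rings** — individual rings of a smallest set of smallest rings (SSSR);
* **ring assemblies** — contiguous ring systems left after deleting every
  bond not in a ring (fused, spiro and bridged systems stay in one piece);
* **bridge assemblies** — ring assemblies in which some pair of SSSR rings
  shares two or more bonds;
* **linkers** — acyclic atoms on a direct path between two ring systems;
* **side chains** — the remaining acyclic substituents, reported with their
  attachment point marked by a dummy atom.

Terminal atoms attached to a ring or linker atom by a double (or higher
order) bond — a carbonyl oxygen, an exocyclic =NH — are retained with the
framework/assembly rather than treated as side chains.  A direct single
bond between two ring systems is a zero-atom linker: the connection is kept
in the framework but emits no linker fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from rdkit import Chem

from ._mols import canonical_smiles, circuit_rank, ring_bond_sets, sssr_rings, submol


# ---------------------------------------------------------------------------
# atom-level classification
# ---------------------------------------------------------------------------

@dataclass
class AtomPartition:
    """Atom-index view of the partition (the testable substrate)."""

    ring_atoms: set[int]
    linker_atoms: set[int]
    # terminal multi-bonded partners, keyed by the framework atom they hang off
    exo_on_ring: set[int]
    exo_on_linker: set[int]
    side_chain_atoms: set[int]

    @property
    def framework_atoms(self) -> set[int]:
        return self.ring_atoms | self.linker_atoms | self.exo_on_ring | self.exo_on_linker


def classify_atoms(mol: Chem.Mol) -> AtomPartition:
    """Classify every heavy atom as ring / linker / retained-exocyclic / side chain."""
    ring_atoms = {a.GetIdx() for a in mol.GetAtoms() if a.IsInRing()}
    adjacency = {a.GetIdx(): {n.GetIdx() for n in a.GetNeighbors()} for a in mol.GetAtoms()}

    # iteratively prune terminal non-ring atoms: what survives is ring + linker
    keep = set(adjacency)
    changed = True
    while changed:
        changed = False
        for idx in sorted(keep):
            if idx in ring_atoms:
                continue
            if len(adjacency[idx] & keep) <= 1:
                keep.discard(idx)
                changed = True
    linker_atoms = keep - ring_atoms

    exo_on_ring: set[int] = set()
    exo_on_linker: set[int] = set()
    for bond in mol.GetBonds():
        if bond.GetBondTypeAsDouble() < 2.0:
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        for terminal, anchor in ((i, j), (j, i)):
            if terminal in keep or anchor not in keep:
                continue
            if mol.GetAtomWithIdx(terminal).GetDegree() != 1:
                continue
            if anchor in ring_atoms:
                exo_on_ring.add(terminal)
            else:
                exo_on_linker.add(terminal)

    framework = keep | exo_on_ring | exo_on_linker
    side_chain_atoms = set(adjacency) - framework
    return AtomPartition(ring_atoms, linker_atoms, exo_on_ring, exo_on_linker, side_chain_atoms)


def _connected_components(mol: Chem.Mol, atoms: set[int]) -> list[set[int]]:
    """Connected components of the subgraph induced on ``atoms``."""
    remaining = set(atoms)
    comps = []
    while remaining:
        seed = min(remaining)
        comp = {seed}
        frontier = [seed]
        while frontier:
            cur = frontier.pop()
            for nb in mol.GetAtomWithIdx(cur).GetNeighbors():
                idx = nb.GetIdx()
                if idx in remaining and idx not in comp:
                    comp.add(idx)
                    frontier.append(idx)
        comps.append(comp)
        remaining -= comp
    return comps


def _ring_bond_components(mol: Chem.Mol, ring_atoms: set[int]) -> list[set[int]]:
    """Components of ring atoms connected through ring bonds only.

    This is the "delete every bond not in a ring" rule: biphenyl splits in
    two, naphthalene and spiro systems stay whole.
    """
    adjacency: dict[int, set[int]] = {idx: set() for idx in ring_atoms}
    for bond in mol.GetBonds():
        if not bond.IsInRing():
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i].add(j)
        adjacency[j].add(i)
    remaining = set(ring_atoms)
    comps = []
    while remaining:
        seed = min(remaining)
        comp = {seed}
        frontier = [seed]
        while frontier:
            cur = frontier.pop()
            for idx in adjacency[cur]:
                if idx in comp:
                    continue
                comp.add(idx)
                frontier.append(idx)
        comps.append(comp)
        remaining -= comp
    return comps


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def murcko_framework(mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Ring systems plus linkers; ``None`` for acyclic molecules."""
    part = classify_atoms(mol)
    if not part.ring_atoms:
        return None
    return submol(mol, part.framework_atoms)


def graph_framework(scaffold: Chem.Mol) -> Chem.Mol:
    """Relabel every atom carbon and every bond single, then canonicalize."""
    rw = Chem.RWMol(scaffold)
    for atom in rw.GetAtoms():
        atom.SetAtomicNum(6)
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
        atom.SetIsAromatic(False)
        atom.SetNumRadicalElectrons(0)
        atom.SetIsotope(0)
    for bond in rw.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def extract_rings(mol: Chem.Mol) -> list[Chem.Mol]:
    """One structure per SSSR ring; count equals the circuit rank.

    Rings are cut out with aromatic flags intact so a benzo ring of a fused
    aromatic re-perceives as benzene.  Rings that are not independently
    aromatic (e.g. either ring of azulene) fall back to extraction from the
    canonical kekulized parent, which fixes explicit bond orders.
    """
    kekulized = None
    out = []
    for ring in sssr_rings(mol):
        frag = submol(mol, ring)
        if frag is None:
            if kekulized is None:
                kekulized = Chem.Mol(mol)
                Chem.Kekulize(kekulized, clearAromaticFlags=True)
            frag = submol(kekulized, ring)
        if frag is not None:
            out.append(frag)
    return out


def extract_ring_assemblies(mol: Chem.Mol) -> list[Chem.Mol]:
    """Contiguous ring systems (with retained exocyclic multi-bond atoms)."""
    part = classify_atoms(mol)
    if not part.ring_atoms:
        return []
    out = []
    for comp in _ring_bond_components(mol, part.ring_atoms):
        exo = {
            e for e in part.exo_on_ring
            if any(nb.GetIdx() in comp for nb in mol.GetAtomWithIdx(e).GetNeighbors())
        }
        frag = submol(mol, comp | exo)
        if frag is not None:
            out.append(frag)
    return out


def ring_assembly_atom_sets(mol: Chem.Mol) -> list[set[int]]:
    """Atom-index sets of the ring assemblies (without exocyclic partners)."""
    part = classify_atoms(mol)
    if not part.ring_atoms:
        return []
    return _ring_bond_components(mol, part.ring_atoms)


def extract_bridge_assemblies(mol: Chem.Mol) -> list[Chem.Mol]:
    """Ring assemblies in which some SSSR ring pair shares >= 2 bonds."""
    part = classify_atoms(mol)
    if not part.ring_atoms:
        return []
    rings = sssr_rings(mol)
    bond_sets = ring_bond_sets(mol, rings)
    bridged_atoms: set[int] = set()
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            if len(bond_sets[i] & bond_sets[j]) >= 2:
                bridged_atoms.update(rings[i])
                bridged_atoms.update(rings[j])
    out = []
    for comp in _ring_bond_components(mol, part.ring_atoms):
        if not (comp & bridged_atoms):
            continue
        exo = {
            e for e in part.exo_on_ring
            if any(nb.GetIdx() in comp for nb in mol.GetAtomWithIdx(e).GetNeighbors())
        }
        frag = submol(mol, comp | exo)
        if frag is not None:
            out.append(frag)
    return out


def extract_acyclic_parts(mol: Chem.Mol) -> tuple[list[Chem.Mol], list[Chem.Mol]]:
    """Return ``(linkers, side_chains)``.

    Linker fragments are the connected components of linker atoms plus any
    retained exocyclic partner hanging off them.  Side chains are emitted
    with their framework attachment atom replaced by a dummy ``[*]``.
    Acyclic molecules yield neither (the whole molecule is outside the
    partition).
    """
    part = classify_atoms(mol)
    if not part.ring_atoms:
        return [], []

    linkers = []
    for comp in _connected_components(mol, part.linker_atoms | part.exo_on_linker):
        frag = submol(mol, comp)
        if frag is not None:
            linkers.append(frag)

    side_chains = []
    framework = part.framework_atoms
    for comp in _connected_components(mol, part.side_chain_atoms):
        attach = set()
        for idx in comp:
            for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
                if nb.GetIdx() in framework:
                    attach.add(nb.GetIdx())
        # a side chain hangs off exactly one framework atom (tree structure)
        keep = comp | attach
        rw = Chem.RWMol(mol)
        for idx in attach:
            atom = rw.GetAtomWithIdx(idx)
            atom.SetAtomicNum(0)
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(0)
            atom.SetNoImplicit(True)
            atom.SetIsAromatic(False)
        for idx in sorted((a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in keep), reverse=True):
            rw.RemoveAtom(idx)
        frag = rw.GetMol()
        err = Chem.SanitizeMol(frag, catchErrors=True)
        if err == Chem.SanitizeFlags.SANITIZE_NONE:
            side_chains.append(frag)
    return linkers, side_chains


@dataclass
class Decomposition:
    """All scaffold representations of one molecule, as canonical SMILES.

    Multisets are plain lists (per-occurrence counting, duplicates kept).
    """

    murcko: Optional[str]
    graph_framework: Optional[str]
    rings: list[str] = field(default_factory=list)
    ring_assemblies: list[str] = field(default_factory=list)
    bridge_assemblies: list[str] = field(default_factory=list)
    linkers: list[str] = field(default_factory=list)
    side_chains: list[str] = field(default_factory=list)


def decompose(mol: Chem.Mol) -> Decomposition:
    """Full partition of one sanitized molecule."""
    murcko = murcko_framework(mol)
    if murcko is None:
        return Decomposition(murcko=None, graph_framework=None)
    linkers, side_chains = extract_acyclic_parts(mol)
    return Decomposition(
        murcko=canonical_smiles(murcko),
        graph_framework=canonical_smiles(graph_framework(murcko)),
        rings=[canonical_smiles(m) for m in extract_rings(mol)],
        ring_assemblies=[canonical_smiles(m) for m in extract_ring_assemblies(mol)],
        bridge_assemblies=[canonical_smiles(m) for m in extract_bridge_assemblies(mol)],
        linkers=[canonical_smiles(m) for m in linkers],
        side_chains=[canonical_smiles(m) for m in side_chains],
    )


__all__ = [
    "AtomPartition",
    "Decomposition",
    "classify_atoms",
    "decompose",
    "extract_acyclic_parts",
    "extract_bridge_assemblies",
    "extract_ring_assemblies",
    "extract_rings",
    "graph_framework",
    "murcko_framework",
    "ring_assembly_atom_sets",
    "circuit_rank",
]
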