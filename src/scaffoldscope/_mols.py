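"""Shared low-level molecule helpers.

Everything that touches RDKit atom/bond bookkeeping in more than one module
lives here: canonicalization, sub-molecule extraction by atom-index set,
circuit-rank arithmetic, and the aromatic-nitrogen repair needed when ring
fragments are cut out of larger aromatic systems.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")


def canonical_smiles(mol: Chem.Mol) -> str:
    """Stereo-stripped canonical SMILES used as fragment/scaffold identity."""
    return Chem.MolToSmiles(mol, isomericSmiles=False)


def isomeric_smiles(mol: Chem.Mol) -> str:
    """Stereo-bearing canonical SMILES used as *molecule* identity."""
    return Chem.MolToSmiles(mol, isomericSmiles=True)


def circuit_rank(mol: Chem.Mol) -> int:
    """bonds - atoms + connected components of the heavy-atom graph."""
    n_frags = len(Chem.GetMolFrags(mol))
    return mol.GetNumBonds() - mol.GetNumAtoms() + n_frags


def sanitize_with_fixes(mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Sanitize a fragment, repairing under-protonated aromatic nitrogens.

    Cutting a substituent off an aromatic nitrogen (N-methylpyrrole -> pyrrole)
    leaves an aromatic N with two ring bonds and no hydrogen, which fails
    kekulization.  We greedily add one explicit H to such nitrogens (lowest
    atom index first) until the fragment sanitizes.  Returns None when no
    repair works.
    """
    probe = Chem.Mol(mol)
    err = Chem.SanitizeMol(probe, catchErrors=True)
    if err == Chem.SanitizeFlags.SANITIZE_NONE:
        return probe
    candidates = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 7
        and a.GetIsAromatic()
        and a.GetTotalNumHs() == 0
        and a.GetDegree() == 2
        and a.GetFormalCharge() == 0
    ]
    for idx in candidates:
        probe = Chem.Mol(mol)
        probe.GetAtomWithIdx(idx).SetNumExplicitHs(1)
        err = Chem.SanitizeMol(probe, catchErrors=True)
        if err == Chem.SanitizeFlags.SANITIZE_NONE:
            return probe
    return None


def submol(mol: Chem.Mol, atom_ids: Iterable[int]) -> Optional[Chem.Mol]:
    """Extract the induced sub-molecule on ``atom_ids`` and sanitize it.

    Bonds are kept only between retained atoms; aromatic flags are left in
    place so that whole aromatic rings cut from fused systems re-perceive
    correctly (one ring of naphthalene comes out as benzene).
    """
    keep = set(atom_ids)
    rw = Chem.RWMol(mol)
    for idx in sorted((a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in keep), reverse=True):
        rw.RemoveAtom(idx)
    return sanitize_with_fixes(rw.GetMol())


def sssr_rings(mol: Chem.Mol) -> list[tuple[int, ...]]:
    """Smallest set of smallest rings as atom-index tuples (size = circuit rank)."""
    return [tuple(r) for r in Chem.GetSSSR(Chem.Mol(mol))]


def ring_bond_sets(mol: Chem.Mol, rings: Sequence[Sequence[int]]) -> list[frozenset[tuple[int, int]]]:
    """Bond sets (as sorted atom-index pairs) for each SSSR ring."""
    out = []
    for ring in rings:
        bonds = set()
        for i, a in enumerate(ring):
            b = ring[(i + 1) % len(ring)]
            if mol.GetBondBetweenAtoms(a, b) is not None:
                bonds.add((min(a, b), max(a, b)))
        out.append(frozenset(bonds))
    return out


def mol_from_smiles(smiles: str) -> Optional[Chem.Mol]:
    return Chem.MolFromSmiles(smiles)


def element_topology(mol: Chem.Mol) -> Chem.Mol:
    """Element-labeled topology view: every bond single, aromaticity erased.

    Useful for subgraph comparisons across scaffold levels, where pruning a
    fused ring legitimately changes aromaticity and bond orders of what
    remains while preserving atoms, elements and connectivity.
    """
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        atom.SetIsAromatic(False)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(True)
    for bond in rw.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
    out = rw.GetMol()
    out.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(out)
    return out
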