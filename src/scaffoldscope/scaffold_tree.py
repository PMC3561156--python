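"""Hierarchical scaffold chains by prioritized iterative ring removal.

Starting from the Murcko framework, one *peripheral* ring — a basis ring
whose deletion leaves the scaffold connected — is removed per step until a
single ring remains.  The intermediates form the molecule's chain, indexed
Level 0 (one ring) up to Level n-1 (the full Murcko framework), where n is
the framework's circuit rank.

Ring removal prioritization (applied to the set of peripheral rings, first
matching rule wins; the cascade favors discarding peripheral decoration and
retaining the most functionalized core):

1. remove a 3-membered heteroring first;
2. remove the ring whose deletion discards the fewest acyclic bonds;
3. remove the ring with the fewest heteroatoms;
4. remove the larger ring;
5. break remaining ties by the lexicographically smallest canonical SMILES
   of the resulting parent scaffold.

Ring counting uses the circuit rank, so fused and bridged systems descend
one basis ring per level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from rdkit import Chem

from ._mols import canonical_smiles, circuit_rank, sssr_rings, submol
from .decompose import classify_atoms, murcko_framework


@dataclass
class ScaffoldTreeChain:
    """Per-molecule ordered scaffolds, Level 0 ... Level n-1."""

    molecule_id: str
    levels: list[str]          # canonical SMILES, index k = Level k
    level_mols: list[Chem.Mol]

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class _Candidate:
    key: tuple
    parent: Chem.Mol


def _removal_candidates(scaffold: Chem.Mol) -> list["_Candidate"]:
    """Enumerate peripheral-ring removals of a (sanitized) scaffold."""
    rings = sssr_rings(scaffold)
    rank = circuit_rank(scaffold)
    n_acyclic = sum(1 for b in scaffold.GetBonds() if not b.IsInRing())
    part = classify_atoms(scaffold)
    candidates = []
    for ring in rings:
        others = set()
        for other in rings:
            if other is not ring:
                others.update(other)
        exclusive = set(ring) - others
        if not exclusive:
            continue  # fully shared ring cannot be deleted on its own
        # take along terminal exocyclic partners of the deleted atoms
        exo = {
            e for e in part.exo_on_ring | part.exo_on_linker
            if any(nb.GetIdx() in exclusive for nb in scaffold.GetAtomWithIdx(e).GetNeighbors())
        }
        keep = {a.GetIdx() for a in scaffold.GetAtoms()} - exclusive - exo
        if not keep:
            continue
        parent_raw = submol(scaffold, keep)
        if parent_raw is None:
            continue
        if len(Chem.GetMolFrags(parent_raw)) != 1:
            continue  # deleting this ring disconnects the scaffold
        # prune acyclic stubs left behind (e.g. the dangling linker)
        parent_part = classify_atoms(parent_raw)
        if not parent_part.ring_atoms:
            continue
        parent = submol(parent_raw, parent_part.framework_atoms)
        if parent is None:
            continue
        if circuit_rank(parent) != rank - 1:
            continue
        n_acyclic_parent = sum(1 for b in parent.GetBonds() if not b.IsInRing())
        n_acyclic_deleted = n_acyclic - n_acyclic_parent
        n_hetero = sum(1 for idx in ring if scaffold.GetAtomWithIdx(idx).GetAtomicNum() != 6)
        is_3het = len(ring) == 3 and n_hetero > 0
        key = (
            0 if is_3het else 1,
            n_acyclic_deleted,
            n_hetero,
            -len(ring),
            canonical_smiles(parent),
        )
        candidates.append(_Candidate(key=key, parent=parent))
    return candidates


def build_chain(mol: Chem.Mol, molecule_id: str = "") -> Optional[ScaffoldTreeChain]:
    """Build the scaffold chain of one molecule; ``None`` when acyclic."""
    scaffold = murcko_framework(mol)
    if scaffold is None:
        return None
    chain_mols = [scaffold]
    current = scaffold
    while circuit_rank(current) > 1:
        candidates = _removal_candidates(current)
        if not candidates:
            break  # no peripheral ring is removable (pathological topology)
        best = min(candidates, key=lambda c: c.key)
        current = best.parent
        chain_mols.append(current)
    chain_mols.reverse()
    return ScaffoldTreeChain(
        molecule_id=molecule_id,
        levels=[canonical_smiles(m) for m in chain_mols],
        level_mols=chain_mols,
    )


def get_level(chain: ScaffoldTreeChain, k: int) -> Optional[str]:
    """Level-k scaffold SMILES, or ``None`` when the molecule is too simple."""
    if k < 0:
        raise ValueError("scaffold level must be non-negative")
    if k >= chain.n_levels:
        return None
    return chain.levels[k]


def level_census(chains: Iterable[Optional[ScaffoldTreeChain]]) -> pd.DataFrame:
    """Per-level scaffold counts across a library.

    Returns a table with columns ``level``, ``total`` (molecules possessing a
    Level-k scaffold) and ``unique`` (distinct Level-k structures).
    """
    totals: dict[int, int] = {}
    uniques: dict[int, set[str]] = {}
    for chain in chains:
        if chain is None:
            continue
        for k, smi in enumerate(chain.levels):
            totals[k] = totals.get(k, 0) + 1
            uniques.setdefault(k, set()).add(smi)
    rows = [
        {"level": k, "total": totals[k], "unique": len(uniques[k])}
        for k in sorted(totals)
    ]
    return pd.DataFrame(rows, columns=["level", "total", "unique"])


__all__ = ["ScaffoldTreeChain", "build_chain", "get_level", "level_census"]
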