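"""Circular fingerprints, Tanimoto similarity and cross-library overlap.

Scaffold similarity uses extended-connectivity (Morgan) fingerprints of
diameter 6 (radius 3) in their sparse binary form: the feature set is the
union of radius-aware neighborhood hashes over radii 0..3, without folding
to a fixed width, so the "identical fingerprint" row of an overlap table is
free of folding collisions.

An overlap table answers, for an ordered library pair (A, B): how many
unique A-scaffolds have a nearest B-scaffold at or above each similarity
cutoff?  The cutoff-1.0 row uses "= 1" semantics (fingerprint-identical);
all other rows use ">=".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

DEFAULT_CUTOFFS: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.0)

_GENERATORS: dict[int, object] = {}


def _generator(radius: int):
    if radius not in _GENERATORS:
        _GENERATORS[radius] = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    return _GENERATORS[radius]


@dataclass(frozen=True)
class Fingerprint:
    """Sparse binary circular fingerprint (set of neighborhood hash ids)."""

    features: frozenset[int]

    def __post_init__(self):
        if not self.features:
            raise ValueError("fingerprint of an empty structure")


def circular_fingerprint(mol_or_smiles: Chem.Mol | str, diameter: int = 6) -> Fingerprint:
    """Sparse binary Morgan fingerprint of ``diameter`` (radius ``diameter/2``)."""
    if diameter % 2:
        raise ValueError("fingerprint diameter must be even")
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise ValueError(f"unparsable scaffold SMILES: {mol_or_smiles!r}")
    else:
        mol = mol_or_smiles
    if mol.GetNumAtoms() == 0:
        raise ValueError("cannot fingerprint an empty structure")
    fp = _generator(diameter // 2).GetSparseCountFingerprint(mol)
    return Fingerprint(features=frozenset(fp.GetNonzeroElements()))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a ∩ b| / |a ∪ b| on feature sets."""
    inter = len(a.features & b.features)
    union = len(a.features) + len(b.features) - inter
    return inter / union


@dataclass
class OverlapTable:
    """Counts of A-scaffolds matched in B at descending similarity cutoffs."""

    direction: tuple[str, str]
    rows: dict[float, int]

    def to_series(self) -> pd.Series:
        name = f"{self.direction[0]} in {self.direction[1]}"
        return pd.Series(self.rows, name=name)


def max_similarities(set_a: Sequence[str], set_b: Sequence[str],
                     diameter: int = 6) -> list[float]:
    """For each scaffold in A, its maximum Tanimoto similarity to B."""
    fps_b = [circular_fingerprint(s, diameter) for s in set_b]
    out = []
    for smi in set_a:
        fa = circular_fingerprint(smi, diameter)
        best = 0.0
        for fb in fps_b:
            sim = tanimoto(fa, fb)
            if sim > best:
                best = sim
                if best == 1.0:
                    break
        out.append(best)
    return out


def cross_library_overlap(set_a: Sequence[str], set_b: Sequence[str],
                          name_a: str = "A", name_b: str = "B",
                          cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
                          diameter: int = 6) -> OverlapTable:
    """Tabulate, per cutoff, the A-scaffolds whose best B-match meets it.

    ``set_a``/``set_b`` are deduplicated scaffold SMILES.  An empty B yields
    zero counts everywhere except the 0.0 row, which by definition equals
    |A| (every scaffold trivially has similarity >= 0).
    """
    if set_b:
        best = max_similarities(set_a, set_b, diameter)
    else:
        best = []
    rows: dict[float, int] = {}
    for cutoff in cutoffs:
        if cutoff >= 1.0:
            rows[cutoff] = sum(1 for s in best if s == 1.0)
        elif cutoff <= 0.0:
            rows[cutoff] = len(set_a)
        else:
            rows[cutoff] = sum(1 for s in best if s >= cutoff)
    return OverlapTable(direction=(name_a, name_b), rows=rows)


def overlap_frame(tables: Sequence[OverlapTable]) -> pd.DataFrame:
    """Combine ordered-pair overlap tables into one cutoff-by-pair frame."""
    df = pd.concat([t.to_series() for t in tables], axis=1)
    df.index.name = "similarity_cutoff"
    return df.sort_index(ascending=False)


__all__ = [
    "DEFAULT_CUTOFFS",
    "Fingerprint",
    "OverlapTable",
    "circular_fingerprint",
    "cross_library_overlap",
    "max_similarities",
    "overlap_frame",
    "tanimoto",
]
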