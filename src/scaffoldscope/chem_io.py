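"""Library input, standardization, filtering and subsampling.

A *library* is an ordered list of :class:`MoleculeRecord` with unique IDs.
The preparation pipeline mirrors common compound-collection practice:

``read -> standardize -> MW filter (< 600 Da) -> deduplicate -> subsample``

Standardization is deliberately minimal and fully documented: keep the
largest covalently connected fragment, drop records with no carbon atom
(inorganics), clear isotopic labels, and recanonicalize.  Molecule identity
keeps stereochemistry (cis/trans-2-butene are two molecules); scaffold
identity elsewhere strips it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from scipy import stats

from ._mols import circuit_rank, isomeric_smiles

logger = logging.getLogger(__name__)

MW_CUTOFF_DA = 600.0
DEFAULT_MW_BIN_DA = 25.0


@dataclass(frozen=True)
class MoleculeRecord:
    """One standardized library member."""

    id: str
    smiles: str           # stereo-bearing canonical SMILES
    mol: Chem.Mol
    mw: float             # molecular weight, Da (average isotopic)
    n_rings: int          # circuit rank of the heavy-atom graph
    source: str = ""


@dataclass
class LibrarySpec:
    """A named, ordered compound collection."""

    name: str
    records: list[MoleculeRecord] = field(default_factory=list)
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def _record_from_mol(mol: Chem.Mol, rec_id: str, source: str) -> MoleculeRecord:
    return MoleculeRecord(
        id=rec_id,
        smiles=isomeric_smiles(mol),
        mol=mol,
        mw=Descriptors.MolWt(mol),
        n_rings=circuit_rank(mol),
        source=source,
    )


def read_library(path: str | Path, format: str = "smiles", strict: bool = False,
                 name: Optional[str] = None) -> LibrarySpec:
    """Read a SMILES (whitespace-separated SMILES + optional ID) or SDF file.

    Unparsable records are skipped and counted in the log unless ``strict``
    is set, in which case the first failure aborts with the offending record
    named.  Missing files and empty libraries are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"library file not found: {path}")
    lib_name = name or path.stem
    records: list[MoleculeRecord] = []
    n_skipped = 0

    if format == "smiles":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                mol = Chem.MolFromSmiles(parts[0])
                if mol is None:
                    if strict:
                        raise ValueError(f"{path}: unparsable SMILES at line {lineno}: {parts[0]!r}")
                    n_skipped += 1
                    continue
                rec_id = parts[1] if len(parts) > 1 else f"{lib_name}_{lineno}"
                records.append(_record_from_mol(mol, rec_id, lib_name))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                if strict:
                    raise ValueError(f"{path}: unparsable SDF record at index {i}")
                n_skipped += 1
                continue
            rec_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{lib_name}_{i+1}"
            records.append(_record_from_mol(mol, rec_id, lib_name))
    else:
        raise ValueError(f"unknown library format: {format!r}")

    if n_skipped:
        logger.warning("%s: skipped %d unparsable record(s)", path, n_skipped)
    if not records:
        raise ValueError(f"{path}: library is empty (no parsable records)")
    return LibrarySpec(name=lib_name, records=records)


def standardize_record(record: MoleculeRecord) -> Optional[MoleculeRecord]:
    """Largest fragment, carbon required, isotopes cleared, recanonicalized.

    Returns ``None`` for records eliminated entirely (inorganics, or
    fragments that fail sanitization).
    """
    frags = Chem.GetMolFrags(record.mol, asMols=True, sanitizeFrags=False)
    organic = []
    for frag in frags:
        if any(a.GetAtomicNum() == 6 for a in frag.GetAtoms()):
            organic.append(frag)
    if not organic:
        return None
    # largest fragment: most heavy atoms, ties by MW then canonical SMILES
    best = max(
        organic,
        key=lambda m: (m.GetNumAtoms(), Descriptors.MolWt(m), Chem.MolToSmiles(m)),
    )
    rw = Chem.RWMol(best)
    for atom in rw.GetAtoms():
        atom.SetIsotope(0)
    mol = rw.GetMol()
    err = Chem.SanitizeMol(mol, catchErrors=True)
    if err != Chem.SanitizeFlags.SANITIZE_NONE:
        logger.warning("record %s dropped: sanitization failed", record.id)
        return None
    return _record_from_mol(mol, record.id, record.source)


def standardize_library(lib: LibrarySpec) -> LibrarySpec:
    """Apply :func:`standardize_record` to every record, dropping eliminations."""
    out = []
    n_dropped = 0
    for rec in lib.records:
        std = standardize_record(rec)
        if std is None:
            n_dropped += 1
        else:
            out.append(std)
    if n_dropped:
        logger.info("%s: standardization dropped %d record(s)", lib.name, n_dropped)
    return LibrarySpec(name=lib.name, records=out, seed=lib.seed)


def filter_by_mw(lib: LibrarySpec, max_mw: float = MW_CUTOFF_DA) -> LibrarySpec:
    """Retain records with MW strictly below ``max_mw``; order preserved."""
    kept = [r for r in lib.records if r.mw < max_mw]
    return LibrarySpec(name=lib.name, records=kept, seed=lib.seed)


def deduplicate(lib: LibrarySpec) -> LibrarySpec:
    """One record per distinct stereo-bearing canonical SMILES; first wins."""
    seen: set[str] = set()
    kept = []
    for rec in lib.records:
        if rec.smiles in seen:
            continue
        seen.add(rec.smiles)
        kept.append(rec)
    return LibrarySpec(name=lib.name, records=kept, seed=lib.seed)


def subsample_random(lib: LibrarySpec, n: int, seed: int) -> LibrarySpec:
    """Uniform sample without replacement; deterministic given ``seed``."""
    if n > len(lib):
        raise ValueError(f"cannot sample {n} records from a library of {len(lib)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(lib), size=n, replace=False)
    return LibrarySpec(name=lib.name, records=[lib.records[i] for i in idx], seed=seed)


def match_mw_distribution(source: LibrarySpec, target: LibrarySpec, n: int,
                          bin_width: float = DEFAULT_MW_BIN_DA,
                          seed: int = 0) -> tuple[LibrarySpec, float]:
    """Draw ``n`` source records whose MW histogram matches the target's.

    Fixed-width bins over [0, 600); per-bin quotas follow the target's bin
    proportions (largest-remainder rounding), draws within a bin are uniform
    without replacement.  Quotas a bin cannot supply are redistributed to
    adjacent bins (warning logged).  Returns the sample and the achieved
    two-sample Kolmogorov-Smirnov distance between sampled and target MW
    distributions.
    """
    if n > len(source):
        raise ValueError(f"cannot sample {n} records from a source of {len(source)}")
    rng = np.random.default_rng(seed)
    n_bins = int(np.ceil(MW_CUTOFF_DA / bin_width))

    def bin_of(mw: float) -> int:
        return min(int(mw // bin_width), n_bins - 1)

    target_counts = np.zeros(n_bins)
    for rec in target.records:
        target_counts[bin_of(rec.mw)] += 1
    proportions = target_counts / target_counts.sum()

    source_bins: list[list[int]] = [[] for _ in range(n_bins)]
    for i, rec in enumerate(source.records):
        source_bins[bin_of(rec.mw)].append(i)

    # largest-remainder integer quotas
    raw = proportions * n
    quotas = np.floor(raw).astype(int)
    remainder = n - quotas.sum()
    order = np.argsort(-(raw - quotas), kind="stable")
    for b in order[:remainder]:
        quotas[b] += 1

    # truncate infeasible quotas, push shortfall to nearest feasible bins
    available = np.array([len(b) for b in source_bins])
    shortfall = 0
    for b in range(n_bins):
        if quotas[b] > available[b]:
            shortfall += quotas[b] - available[b]
            quotas[b] = available[b]
    if shortfall:
        logger.warning("MW matching: redistributing %d draw(s) to adjacent bins", shortfall)
        # spread outward from the most populous target bins
        by_distance = sorted(range(n_bins), key=lambda b: (-proportions[b], b))
        while shortfall:
            progressed = False
            for b in by_distance:
                for nb in (b - 1, b + 1, b):
                    if 0 <= nb < n_bins and quotas[nb] < available[nb]:
                        quotas[nb] += 1
                        shortfall -= 1
                        progressed = True
                        break
                if not shortfall:
                    break
            if not progressed:
                raise ValueError("source cannot supply the requested sample size")

    chosen: list[int] = []
    for b in range(n_bins):
        if quotas[b] == 0:
            continue
        picks = rng.choice(len(source_bins[b]), size=quotas[b], replace=False)
        chosen.extend(source_bins[b][p] for p in picks)
    chosen.sort()
    sample = LibrarySpec(name=source.name, records=[source.records[i] for i in chosen], seed=seed)

    ks = stats.ks_2samp(
        [r.mw for r in sample.records], [r.mw for r in target.records]
    ).statistic
    return sample, float(ks)


def write_library(lib: LibrarySpec, smiles_path: str | Path,
                  tsv_path: Optional[str | Path] = None) -> None:
    """Emit a library as SMILES plus an optional sidecar TSV."""
    with open(smiles_path, "w") as fh:
        for rec in lib.records:
            fh.write(f"{rec.smiles} {rec.id}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("id\tcanonical_smiles\tmw\tn_rings\tsource\n")
            for rec in lib.records:
                fh.write(f"{rec.id}\t{rec.smiles}\t{rec.mw:.3f}\t{rec.n_rings}\t{rec.source}\n")


def prepare_library(lib: LibrarySpec, max_mw: float = MW_CUTOFF_DA,
                    dedup: bool = True) -> LibrarySpec:
    """standardize -> MW filter -> (optional) deduplicate."""
    out = filter_by_mw(standardize_library(lib), max_mw)
    if dedup:
        out = deduplicate(out)
    return out


__all__ = [
    "LibrarySpec",
    "MoleculeRecord",
    "MW_CUTOFF_DA",
    "deduplicate",
    "filter_by_mw",
    "match_mw_distribution",
    "prepare_library",
    "read_library",
    "standardize_library",
    "standardize_record",
    "subsample_random",
    "write_library",
]
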