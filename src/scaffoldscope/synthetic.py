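"""Synthetic compound libraries with planted, fully known scaffold structure.

The generator emulates the statistical shape of large screening collections
— thousands of organic molecules under 600 Da whose molecules concentrate on
a few frequent scaffolds with a long singleton tail — while recording the
exact ground truth for every molecule, so every pipeline stage can be
checked against a manifest instead of a proprietary database.

Construction model
------------------
A library is built from *blueprints*.  Each blueprint is a ring-bearing
core: either a linear chain of monocyclic ring units joined by linkers, or
a single fused/bridged/spiro ring system drawn from a curated pool.  Each
molecule samples a blueprint under the configured frequency law (Zipf or
uniform) and is decorated with random single-bonded side chains on ring
atoms, which leaves the core — and hence the Murcko framework and the whole
scaffold chain — untouched.  A small fraction of molecules is acyclic,
mirroring the ring-free percentages real collections show.

The per-blueprint scaffold chain (Level 0 ... Level n-1) is derived
*independently of the analysis pipeline*: for unit chains by combinatorial
simulation of the ring-removal priority rules on the unit sequence (interior
units are never peripheral in a linear chain), and for fused/bridged pool
units from hand-derived chains shipped with the pool data.
"""

from __future__ import annotations

import importlib.resources as resources
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from ._mols import canonical_smiles, circuit_rank, isomeric_smiles, submol
from .chem_io import LibrarySpec, MoleculeRecord
from .diversity import FrequencyTable

logger = logging.getLogger(__name__)

_ACYCLIC_TEMPLATES = ["CCCCCC", "CCOCC", "CCCC(C)C", "CCNCC", "CCCCO", "CC(C)CC(C)C",
                      "CCCOCC", "CCCCCN"]


# ---------------------------------------------------------------------------
# pools
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingUnit:
    smiles: str                 # canonical
    name: str
    mol: Chem.Mol
    ring_size: int              # atoms of the (single) ring, monocyclic units
    n_het_ring: int             # ring heteroatoms
    n_exo_bonds: int            # retained exocyclic multi-bond atoms
    n_rings: int                # circuit rank
    chain: tuple[str, ...]      # hand-derived scaffold chain (multi-ring units)
    mw: float


@dataclass(frozen=True)
class LinkerUnit:
    smiles: str                 # "" = direct bond
    name: str
    n_bonds: int                # acyclic bonds a removal of this linker deletes
    mw: float


@dataclass(frozen=True)
class SideChainUnit:
    smiles: str
    name: str
    mw: float


def _load_tsv(name: str) -> list[list[str]]:
    text = resources.files("scaffoldscope.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_ring_pool() -> list[RingUnit]:
    units = []
    for row in _load_tsv("ring_systems.tsv"):
        smi, name, kind = row[0], row[1], row[2]
        chain = tuple(
            canonical_smiles(Chem.MolFromSmiles(c))
            for c in (row[3].split("|") if len(row) > 3 and row[3] else [])
        )
        mol = Chem.MolFromSmiles(smi)
        ring_atoms = [a for a in mol.GetAtoms() if a.IsInRing()]
        units.append(
            RingUnit(
                smiles=canonical_smiles(mol),
                name=name,
                mol=mol,
                ring_size=len(ring_atoms) if kind == "mono" else 0,
                n_het_ring=sum(1 for a in ring_atoms if a.GetAtomicNum() != 6),
                n_exo_bonds=mol.GetNumAtoms() - len(ring_atoms),
                n_rings=circuit_rank(mol),
                chain=chain if kind == "multi" else (canonical_smiles(mol),),
                mw=Descriptors.MolWt(mol),
            )
        )
    return units


def load_linker_pool() -> list[LinkerUnit]:
    units = []
    for row in _load_tsv("linkers.tsv"):
        smi, name = row[0], row[1].strip()
        if smi:
            mol = Chem.MolFromSmiles(smi)
            n_bonds = mol.GetNumAtoms() + 1
            mw = sum(a.GetMass() for a in mol.GetAtoms())
        else:
            n_bonds, mw = 1, 0.0
        units.append(LinkerUnit(smiles=smi, name=name, n_bonds=n_bonds, mw=mw))
    return units


def load_side_chain_pool() -> list[SideChainUnit]:
    return [
        SideChainUnit(smiles=row[0], name=row[1].strip(),
                      mw=sum(a.GetMass() for a in Chem.MolFromSmiles(row[0]).GetAtoms()))
        for row in _load_tsv("side_chains.tsv")
    ]


# ---------------------------------------------------------------------------
# configuration and manifest
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    n_molecules: int = 5000
    n_unique_scaffolds: int = 50
    frequency_law: tuple = ("zipf", 1.2)          # or ("uniform",)
    rings_per_molecule_law: dict[int, float] = field(
        default_factory=lambda: {1: 0.15, 2: 0.30, 3: 0.25, 4: 0.15, 5: 0.10, 6: 0.05}
    )
    fused_fraction: float = 0.35                  # P(single fused/bridged unit | rank feasible)
    acyclic_fraction: float = 0.02
    side_chain_law: dict[int, float] = field(
        default_factory=lambda: {0: 0.20, 1: 0.35, 2: 0.30, 3: 0.15}
    )
    mw_target: Optional[Sequence[float]] = None   # proportions over 25-Da bins in [0, 600)
    seed: int = 0
    name: str = "synthetic"
    # pool overrides (default: curated pools shipped as package data)
    ring_pool: Optional[list[RingUnit]] = None
    linker_pool: Optional[list[LinkerUnit]] = None
    side_chain_pool: Optional[list[SideChainUnit]] = None


@dataclass
class Blueprint:
    blueprint_id: int
    units: list[str]
    linkers: list[str]
    murcko: str
    chain: list[str]            # Level 0 ... Level n-1


@dataclass
class ManifestEntry:
    id: str
    smiles: str
    blueprint_id: Optional[int]   # None for acyclic molecules
    side_chains: list[str]


@dataclass
class GroundTruthManifest:
    blueprints: dict[int, Blueprint]
    molecules: list[ManifestEntry]
    config_seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.config_seed,
                "blueprints": {
                    str(b.blueprint_id): {
                        "units": b.units, "linkers": b.linkers,
                        "murcko": b.murcko, "chain": b.chain,
                    }
                    for b in self.blueprints.values()
                },
                "molecules": [
                    {"id": m.id, "smiles": m.smiles, "blueprint_id": m.blueprint_id,
                     "side_chains": m.side_chains}
                    for m in self.molecules
                ],
            },
            indent=1,
        )


def manifest_census(manifest: GroundTruthManifest, level: int) -> FrequencyTable:
    """Aggregate planted Level-k scaffolds straight from the manifest."""
    counts: dict[str, int] = {}
    for entry in manifest.molecules:
        if entry.blueprint_id is None:
            continue
        chain = manifest.blueprints[entry.blueprint_id].chain
        if level < len(chain):
            smi = chain[level]
            counts[smi] = counts.get(smi, 0) + 1
    return FrequencyTable(representation=f"level{level}", counts=counts,
                          n_molecules=len(manifest.molecules))


def manifest_murcko_census(manifest: GroundTruthManifest) -> FrequencyTable:
    counts: dict[str, int] = {}
    for entry in manifest.molecules:
        if entry.blueprint_id is None:
            continue
        smi = manifest.blueprints[entry.blueprint_id].murcko
        counts[smi] = counts.get(smi, 0) + 1
    return FrequencyTable(representation="murcko", counts=counts,
                          n_molecules=len(manifest.molecules))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _attachable_atoms(mol: Chem.Mol, atom_ids: Sequence[int], ring_only: bool = True) -> list[int]:
    out = []
    for idx in atom_ids:
        atom = mol.GetAtomWithIdx(idx)
        if ring_only and not atom.IsInRing():
            continue
        if atom.GetTotalNumHs() >= 1:
            out.append(idx)
    return out


def _assemble_core(units: list[RingUnit], linkers: list[LinkerUnit],
                   rng: np.random.Generator) -> Optional[tuple[Chem.Mol, list[list[int]], list[list[int]]]]:
    """Join ring units left-to-right with linkers.

    Returns the sanitized core plus per-unit and per-linker atom-index
    provenance, or None when a valence dead-end is hit.
    """
    core = Chem.RWMol(units[0].mol)
    unit_atoms: list[list[int]] = [list(range(core.GetNumAtoms()))]
    linker_atoms: list[list[int]] = []
    prev_attach_pool = _attachable_atoms(core, unit_atoms[0])
    if not prev_attach_pool:
        return None
    for i in range(1, len(units)):
        left_candidates = _attachable_atoms(core, unit_atoms[i - 1])
        if not left_candidates:
            return None
        left = int(rng.choice(left_candidates))
        link = linkers[i - 1]
        offset = core.GetNumAtoms()
        if link.smiles:
            lmol = Chem.MolFromSmiles(link.smiles)
            core.InsertMol(lmol)
            l_ids = list(range(offset, offset + lmol.GetNumAtoms()))
            core.AddBond(left, l_ids[0], Chem.BondType.SINGLE)
            right_anchor = l_ids[-1]
            linker_atoms.append(l_ids)
        else:
            right_anchor = left
            linker_atoms.append([])
        offset = core.GetNumAtoms()
        umol = units[i].mol
        core.InsertMol(umol)
        u_ids = list(range(offset, offset + umol.GetNumAtoms()))
        right_candidates = _attachable_atoms(core, u_ids)
        if not right_candidates:
            return None
        right = int(rng.choice(right_candidates))
        core.AddBond(right_anchor, right, Chem.BondType.SINGLE)
        unit_atoms.append(u_ids)
    mol = core.GetMol()
    err = Chem.SanitizeMol(mol, catchErrors=True)
    if err != Chem.SanitizeFlags.SANITIZE_NONE:
        return None
    return mol, unit_atoms, linker_atoms


def _planted_chain(core: Chem.Mol, units: list[RingUnit], linkers: list[LinkerUnit],
                   unit_atoms: list[list[int]], linker_atoms: list[list[int]]) -> list[str]:
    """Scaffold chain of a monocyclic-unit chain, by unit-level rule simulation.

    In a linear chain only the terminal units are peripheral (removing an
    interior unit disconnects the scaffold).  The removal priority mirrors
    the Scaffold Tree cascade: 3-membered heteroring first, then fewest
    acyclic bonds deleted, fewest ring heteroatoms, larger ring, and finally
    the lexicographically smaller resulting parent scaffold.
    """

    def atoms_of(lo: int, hi: int) -> list[int]:
        out: list[int] = []
        for i in range(lo, hi + 1):
            out.extend(unit_atoms[i])
            if i < hi:
                out.extend(linker_atoms[i])
        return out

    def scaffold_smiles(lo: int, hi: int) -> str:
        frag = submol(core, atoms_of(lo, hi))
        if frag is None:
            raise RuntimeError("planted chain extraction failed to sanitize")
        return canonical_smiles(frag)

    lo, hi = 0, len(units) - 1
    chain = [scaffold_smiles(lo, hi)]
    while hi > lo:
        cands = []
        for end in ("lo", "hi"):
            if end == "lo":
                unit, link = units[lo], linkers[lo]
                parent = (lo + 1, hi)
            else:
                unit, link = units[hi], linkers[hi - 1]
                parent = (lo, hi - 1)
            key = (
                0 if (unit.ring_size == 3 and unit.n_het_ring > 0) else 1,
                link.n_bonds + unit.n_exo_bonds,
                unit.n_het_ring,
                -unit.ring_size,
                scaffold_smiles(*parent),
            )
            cands.append((key, parent))
        key, (lo, hi) = min(cands, key=lambda c: c[0])
        chain.append(key[-1])
    chain.reverse()
    return chain


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sample_law(law: dict[int, float], rng: np.random.Generator) -> int:
    keys = sorted(law)
    probs = np.array([law[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(keys, p=probs))


def _frequency_weights(law: tuple, k: int) -> np.ndarray:
    if law[0] == "zipf":
        s = float(law[1])
        w = np.arange(1, k + 1, dtype=float) ** (-s)
    elif law[0] == "uniform":
        w = np.ones(k)
    else:
        raise ValueError(f"unknown frequency law: {law!r}")
    return w / w.sum()


def _build_blueprints(config: GeneratorConfig, rng: np.random.Generator,
                      ring_pool: list[RingUnit], linker_pool: list[LinkerUnit]) -> dict[int, Blueprint]:
    mono = [u for u in ring_pool if u.ring_size > 0]
    multi_by_rank: dict[int, list[RingUnit]] = {}
    for u in ring_pool:
        if u.ring_size == 0:
            multi_by_rank.setdefault(u.n_rings, []).append(u)

    blueprints: dict[int, Blueprint] = {}
    seen_murcko: set[str] = set()
    bp_id = 0
    attempts = 0
    max_attempts = 200 * config.n_unique_scaffolds
    while len(blueprints) < config.n_unique_scaffolds:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not construct {config.n_unique_scaffolds} unique blueprints "
                f"from the configured pools"
            )
        r = _sample_law(config.rings_per_molecule_law, rng)
        use_multi = (
            r in multi_by_rank
            and rng.random() < config.fused_fraction
        )
        if use_multi:
            unit = multi_by_rank[r][int(rng.integers(len(multi_by_rank[r])))]
            murcko = unit.smiles
            if murcko in seen_murcko:
                continue
            bp = Blueprint(bp_id, units=[unit.smiles], linkers=[], murcko=murcko,
                           chain=list(unit.chain))
        else:
            units = [mono[int(rng.integers(len(mono)))] for _ in range(r)]
            linkers = [linker_pool[int(rng.integers(len(linker_pool)))] for _ in range(r - 1)]
            assembled = _assemble_core(units, linkers, rng)
            if assembled is None:
                continue
            core, unit_atoms, l_atoms = assembled
            murcko = canonical_smiles(core)
            if murcko in seen_murcko:
                continue
            chain = _planted_chain(core, units, linkers, unit_atoms, l_atoms)
            bp = Blueprint(bp_id, units=[u.smiles for u in units],
                           linkers=[l.smiles for l in linkers], murcko=murcko, chain=chain)
        seen_murcko.add(murcko)
        blueprints[bp_id] = bp
        bp_id += 1
    return blueprints


def _decorate(core: Chem.Mol, side_chains: list[SideChainUnit], n_side: int,
              rng: np.random.Generator, mw_budget: float) -> tuple[Chem.Mol, list[str]]:
    good = Chem.Mol(core)
    used: list[str] = []
    for _ in range(n_side):
        candidates = _attachable_atoms(good, range(good.GetNumAtoms()), ring_only=True)
        if not candidates:
            break
        affordable = [sc for sc in side_chains
                      if Descriptors.MolWt(good) + sc.mw <= mw_budget]
        if not affordable:
            break
        sc = affordable[int(rng.integers(len(affordable)))]
        attach = int(rng.choice(candidates))
        rw = Chem.RWMol(good)
        scmol = Chem.MolFromSmiles(sc.smiles)
        offset = rw.GetNumAtoms()
        rw.InsertMol(scmol)
        rw.AddBond(attach, offset, Chem.BondType.SINGLE)
        probe = rw.GetMol()
        if Chem.SanitizeMol(probe, catchErrors=True) != Chem.SanitizeFlags.SANITIZE_NONE:
            break  # valence dead-end: keep the molecule as decorated so far
        good = probe
        used.append(sc.smiles)
    return good, used


def generate_library(config: GeneratorConfig) -> tuple[LibrarySpec, GroundTruthManifest]:
    """Generate a library and its ground-truth manifest; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    ring_pool = config.ring_pool if config.ring_pool is not None else load_ring_pool()
    linker_pool = config.linker_pool if config.linker_pool is not None else load_linker_pool()
    side_pool = config.side_chain_pool if config.side_chain_pool is not None else load_side_chain_pool()

    blueprints = _build_blueprints(config, rng, ring_pool, linker_pool)
    weights = _frequency_weights(config.frequency_law, len(blueprints))
    bp_ids = sorted(blueprints)

    # rebuild each blueprint's core once for decoration
    cores = {bid: Chem.MolFromSmiles(blueprints[bid].murcko) for bid in bp_ids}

    if config.mw_target is not None:
        mw_target = np.asarray(config.mw_target, dtype=float)
        mw_target = mw_target / mw_target.sum()
    else:
        mw_target = None

    records: list[MoleculeRecord] = []
    entries: list[ManifestEntry] = []
    for i in range(config.n_molecules):
        mol_id = f"{config.name}_{i+1:06d}"
        if rng.random() < config.acyclic_fraction:
            smi = _ACYCLIC_TEMPLATES[int(rng.integers(len(_ACYCLIC_TEMPLATES)))]
            mol = Chem.MolFromSmiles(smi)
            entries.append(ManifestEntry(mol_id, isomeric_smiles(mol), None, []))
        else:
            bid = bp_ids[int(rng.choice(len(bp_ids), p=weights))]
            core = cores[bid]
            n_side = _sample_law(config.side_chain_law, rng)
            if mw_target is not None:
                bin_idx = int(rng.choice(len(mw_target), p=mw_target))
                budget = min(25.0 * (bin_idx + 1), 590.0)
                budget = max(budget, Descriptors.MolWt(core))
            else:
                budget = 590.0
            mol, used = _decorate(core, side_pool, n_side, rng, budget)
            entries.append(ManifestEntry(mol_id, isomeric_smiles(mol), bid, used))
        records.append(
            MoleculeRecord(
                id=mol_id,
                smiles=isomeric_smiles(mol),
                mol=mol,
                mw=Descriptors.MolWt(mol),
                n_rings=circuit_rank(mol),
                source=config.name,
            )
        )
    lib = LibrarySpec(name=config.name, records=records, seed=config.seed)
    manifest = GroundTruthManifest(blueprints=blueprints, molecules=entries,
                                   config_seed=config.seed)
    return lib, manifest


__all__ = [
    "Blueprint",
    "GeneratorConfig",
    "GroundTruthManifest",
    "LinkerUnit",
    "ManifestEntry",
    "RingUnit",
    "SideChainUnit",
    "generate_library",
    "load_linker_pool",
    "load_ring_pool",
    "load_side_chain_pool",
    "manifest_census",
    "manifest_murcko_census",
]
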