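"""Shared fixtures: a hand-built small-molecule set and synthetic libraries."""

from __future__ import annotations

import pytest
from rdkit import Chem

from scaffoldscope.scaffold_tree import build_chain
from scaffoldscope.synthetic import GeneratorConfig, generate_library

# Hand-built molecules, <= 12 heavy atoms, spanning every decomposition code
# path: plain aromatics, heteroaromatics, fused/bridged/spiro systems,
# linkers of several kinds, side chains, exocyclic carbonyls, and acyclics.
FIXTURE_SMILES: dict[str, str] = {
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "xylene_o": "Cc1ccccc1C",
    "xylene_p": "Cc1ccc(C)cc1",
    "ethylbenzene": "CCc1ccccc1",
    "styrene": "C=Cc1ccccc1",
    "phenylacetylene": "C#Cc1ccccc1",
    "benzonitrile": "N#Cc1ccccc1",
    "phenol": "Oc1ccccc1",
    "anisole": "COc1ccccc1",
    "aniline": "Nc1ccccc1",
    "benzaldehyde": "O=Cc1ccccc1",
    "acetophenone": "CC(=O)c1ccccc1",
    "benzoic_acid": "O=C(O)c1ccccc1",
    "benzamide": "NC(=O)c1ccccc1",
    "chlorobenzene": "Clc1ccccc1",
    "trifluorotoluene": "FC(F)(F)c1ccccc1",
    "biphenyl": "c1ccc(-c2ccccc2)cc1",
    "4-ethylbiphenyl": "CCc1ccc(-c2ccccc2)cc1",
    "diphenylmethane": "c1ccc(Cc2ccccc2)cc1",
    "bibenzyl": "c1ccc(CCc2ccccc2)cc1",
    "diphenyl_ether": "c1ccc(Oc2ccccc2)cc1",
    "diphenylamine": "c1ccc(Nc2ccccc2)cc1",
    "stilbene": "C(=Cc1ccccc1)c1ccccc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "methylnaphthalene": "Cc1cccc2ccccc12",
    "azulene": "c1ccc2cccc2cc1",
    "indene": "C1=Cc2ccccc2C1",
    "indane": "C1Cc2ccccc2C1",
    "anthracene": "c1ccc2cc3ccccc3cc2c1",
    "pyridine": "c1ccncc1",
    "picoline": "Cc1ccccn1",
    "pyrimidine": "c1cncnc1",
    "pyrrole": "c1cc[nH]c1",
    "n_methylpyrrole": "Cn1cccc1",
    "furan": "c1ccoc1",
    "thiophene": "c1ccsc1",
    "imidazole": "c1c[nH]cn1",
    "indole": "c1ccc2[nH]ccc2c1",
    "quinoline": "c1ccc2ncccc2c1",
    "benzofuran": "c1ccc2occc2c1",
    "purine": "c1ncc2[nH]cnc2n1",
    "n_phenylpyrrole": "c1ccc(-n2cccc2)cc1",
    "phenylpyridine": "c1ccc(-c2ccccn2)cc1",
    "anilinopyridine": "c1ccc(Nc2ccccn2)cc1",
    "cyclopropane": "C1CC1",
    "cyclobutane": "C1CCC1",
    "cyclopentane": "C1CCCC1",
    "cyclohexane": "C1CCCCC1",
    "methylcyclohexane": "CC1CCCCC1",
    "cyclohexene": "C1=CCCCC1",
    "cyclohexanone": "O=C1CCCCC1",
    "cyclohexanol": "OC1CCCCC1",
    "tetrahydrofuran": "C1CCOC1",
    "tetrahydropyran": "C1CCOCC1",
    "piperidine": "C1CCNCC1",
    "piperazine": "C1CNCCN1",
    "morpholine": "C1COCCN1",
    "butyrolactone": "O=C1CCCO1",
    "norbornane": "C1CC2CCC1C2",
    "norbornene": "C1CC2CC1C=C2",
    "bicyclo222octane": "C1CC2CCC1CC2",
    "adamantane": "C1C2CC3CC1CC(C2)C3",
    "cubane": "C12C3C4C1C1C2C3C41",
    "spiro44nonane": "C1CCC2(C1)CCCC2",
    "spiro55undecane": "C1CCC2(CC1)CCCCC2",
    "decalin": "C1CCC2CCCCC2C1",
    "bicyclohexyl": "C1CCC(C2CCCCC2)CC1",
    "cyclohexylbenzene": "c1ccc(C2CCCCC2)cc1",
    "methylenedioxybenzene": "C1Oc2ccccc2O1",
    "butane": "CCCC",
    "isooctane": "CC(C)CC(C)(C)C",
    "diethyl_ether": "CCOCC",
    "hexanol": "CCCCCCO",
}


@pytest.fixture(scope="session")
def fixture_mols() -> dict[str, Chem.Mol]:
    mols = {name: Chem.MolFromSmiles(smi) for name, smi in FIXTURE_SMILES.items()}
    assert all(m is not None for m in mols.values())
    return mols


# --- synthetic study libraries (shared across tests; generation is cheap,
# --- scaffold-chain construction is the expensive part, so both are cached)

REDUNDANT_SEED = 101
DIVERSE_SEED = 202


@pytest.fixture(scope="session")
def redundant_library():
    """n=5000 molecules over 50 planted scaffolds, Zipf(s=1.2)."""
    cfg = GeneratorConfig(n_molecules=5000, n_unique_scaffolds=50,
                          frequency_law=("zipf", 1.2), seed=REDUNDANT_SEED,
                          name="redundant")
    return generate_library(cfg)


@pytest.fixture(scope="session")
def diverse_library():
    """n=5000 molecules over 2000 planted scaffolds, uniform."""
    cfg = GeneratorConfig(n_molecules=5000, n_unique_scaffolds=2000,
                          frequency_law=("uniform",), seed=DIVERSE_SEED,
                          name="diverse")
    return generate_library(cfg)


@pytest.fixture(scope="session")
def redundant_chains(redundant_library):
    lib, _ = redundant_library
    return [build_chain(rec.mol, rec.id) for rec in lib.records]


@pytest.fixture(scope="session")
def diverse_chains(diverse_library):
    lib, _ = diverse_library
    return [build_chain(rec.mol, rec.id) for rec in lib.records]
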