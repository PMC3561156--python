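"""Unit and property tests for the structural partition of molecules."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from scaffoldscope._mols import canonical_smiles, circuit_rank
from scaffoldscope.decompose import (
    decompose,
    extract_acyclic_parts,
    extract_bridge_assemblies,
    extract_ring_assemblies,
    extract_rings,
    graph_framework,
    murcko_framework,
)

from conftest import FIXTURE_SMILES


def mol(smiles: str) -> Chem.Mol:
    return Chem.MolFromSmiles(smiles)


class TestMurckoFramework:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("Cc1ccccc1", "c1ccccc1"),                       # methyl is a side chain
            ("c1ccc(Cc2ccccc2)cc1", "c1ccc(Cc2ccccc2)cc1"),  # linker retained
            ("CC(=O)c1ccccc1", "c1ccccc1"),                  # acyl side chain pruned
            ("O=C1CCCCC1", "O=C1CCCCC1"),                    # ring carbonyl retained
            ("O=C(Nc1ccccc1)c1ccccc1", "O=C(Nc1ccccc1)c1ccccc1"),  # amide linker keeps C=O
        ],
    )
    def test_examples(self, smiles, expected):
        assert canonical_smiles(murcko_framework(mol(smiles))) == Chem.CanonSmiles(expected)

    def test_acyclic_is_none(self):
        assert murcko_framework(mol("CCCC")) is None

    def test_idempotent_on_fixture(self, fixture_mols):
        for name, m in fixture_mols.items():
            once = murcko_framework(m)
            if once is None:
                continue
            twice = murcko_framework(once)
            assert canonical_smiles(twice) == canonical_smiles(once), name

    def test_agrees_with_rdkit_murcko_on_fixture(self, fixture_mols):
        """Independent cross-check against RDKit's own Murcko scaffold code."""
        for name, m in fixture_mols.items():
            ours = murcko_framework(m)
            theirs = MurckoScaffold.GetScaffoldForMol(m)
            if ours is None:
                assert theirs.GetNumAtoms() == 0, name
            else:
                assert canonical_smiles(ours) == Chem.MolToSmiles(theirs, isomericSmiles=False), name


class TestGraphFramework:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("c1ccncc1", "C1CCCCC1"),
            ("c1ccccc1", "C1CCCCC1"),
            ("c1ccc(-c2ccccc2)cc1", "C1CCC(C2CCCCC2)CC1"),
        ],
    )
    def test_examples(self, smiles, expected):
        assert canonical_smiles(graph_framework(mol(smiles))) == Chem.CanonSmiles(expected)

    def test_invariant_under_heteroatom_substitution(self):
        gf = {canonical_smiles(graph_framework(mol(s))) for s in
              ["c1ccncc1", "C1CCNCC1", "C1CCOCC1", "C1CCSCC1", "c1cncnc1"]}
        assert gf == {"C1CCCCC1"}


class TestRingsAndAssemblies:
    def test_naphthalene_two_rings(self):
        assert len(extract_rings(mol("c1ccc2ccccc2c1"))) == 2

    def test_cubane_five_rings(self):
        rings = extract_rings(mol("C12C3C4C1C1C2C3C41"))
        assert len(rings) == 5
        assert all(r.GetNumAtoms() == 4 for r in rings)

    @pytest.mark.parametrize(
        "smiles,n_assemblies,n_bridge",
        [
            ("c1ccc(-c2ccccc2)cc1", 2, 0),   # biphenyl: ring-ring bond not in a ring
            ("c1ccc2ccccc2c1", 1, 0),        # fused rings share one bond
            ("c1ccc(Cc2ccccc2)cc1", 2, 0),   # linker removed
            ("C1CC2CCC1C2", 1, 1),           # norbornane: two bonds shared
            ("C1C2CC3CC1CC(C2)C3", 1, 1),    # adamantane
            ("C1CCC2(C1)CCCC2", 1, 0),       # spiro shares one atom, zero bonds
        ],
    )
    def test_assembly_counts(self, smiles, n_assemblies, n_bridge):
        m = mol(smiles)
        assert len(extract_ring_assemblies(m)) == n_assemblies
        assert len(extract_bridge_assemblies(m)) == n_bridge

    def test_ring_count_equals_circuit_rank_on_fixture(self, fixture_mols):
        for name, m in fixture_mols.items():
            assert len(extract_rings(m)) == circuit_rank(m), name


class TestAcyclicParts:
    @pytest.mark.parametrize(
        "smiles,linkers,side_chains",
        [
            ("c1ccc(Cc2ccccc2)cc1", ["C"], []),
            ("Cc1ccccc1", [], ["*C"]),
            ("CCc1ccc(-c2ccccc2)cc1", [], ["*CC"]),  # direct bond: no linker atoms
            ("CCCC", [], []),                         # acyclic: out of the partition
        ],
    )
    def test_examples(self, smiles, linkers, side_chains):
        got_linkers, got_side = extract_acyclic_parts(mol(smiles))
        assert sorted(canonical_smiles(m) for m in got_linkers) == sorted(linkers)
        assert sorted(canonical_smiles(m) for m in got_side) == \
               sorted(Chem.CanonSmiles(s) for s in side_chains)


def test_full_decomposition_shape():
    d = decompose(mol("CCc1ccc(Cc2ccc(O)nc2)cc1"))
    assert d.murcko == Chem.CanonSmiles("c1ccc(Cc2cccnc2)cc1")
    assert d.graph_framework == Chem.CanonSmiles("C1CCC(CC2CCCCC2)CC1")
    assert len(d.rings) == 2 and len(d.ring_assemblies) == 2
    assert d.linkers == ["C"]
    assert sorted(d.side_chains) == sorted([Chem.CanonSmiles("*CC"), Chem.CanonSmiles("*O")])


@settings(deadline=None, max_examples=40)
@given(st.sampled_from(sorted(FIXTURE_SMILES.values())), st.integers(0, 2**31 - 1))
def test_decomposition_invariant_under_atom_renumbering(smiles, seed):
    """Fragment identities do not depend on the input atom order."""
    import numpy as np

    m = Chem.MolFromSmiles(smiles)
    order = list(np.random.default_rng(seed).permutation(m.GetNumAtoms()))
    shuffled = Chem.RenumberAtoms(m, [int(i) for i in order])
    a, b = decompose(m), decompose(shuffled)
    assert a.murcko == b.murcko
    assert sorted(a.rings) == sorted(b.rings)
    assert sorted(a.ring_assemblies) == sorted(b.ring_assemblies)
    assert sorted(a.linkers) == sorted(b.linkers)
    assert sorted(a.side_chains) == sorted(b.side_chains)
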