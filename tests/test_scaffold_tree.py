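"""Scaffold-chain construction, level access and the level census."""

from __future__ import annotations

import pandas as pd
import pytest
from rdkit import Chem

from scaffoldscope._mols import canonical_smiles, circuit_rank, element_topology
from scaffoldscope.scaffold_tree import build_chain, get_level, level_census


def chain_of(smiles: str):
    return build_chain(Chem.MolFromSmiles(smiles), smiles)


class TestBuildChain:
    def test_biphenyl(self):
        ch = chain_of("c1ccc(-c2ccccc2)cc1")
        assert ch.levels == ["c1ccccc1", "c1ccc(-c2ccccc2)cc1"]

    def test_anthracene(self):
        ch = chain_of("c1ccc2cc3ccccc3cc2c1")
        assert ch.levels == ["c1ccccc1", "c1ccc2ccccc2c1", "c1ccc2cc3ccccc3cc2c1"]

    def test_acyclic_is_none(self):
        assert chain_of("CCCC") is None

    def test_side_chains_do_not_affect_chain(self):
        bare = chain_of("c1ccc(-c2ccccc2)cc1")
        decorated = chain_of("CCc1ccc(-c2ccccc2)cc1O")
        assert decorated.levels == bare.levels

    @pytest.mark.parametrize(
        "smiles,level0",
        [
            ("c1ccc2ncccc2c1", "c1ccncc1"),      # quinoline keeps pyridine
            ("c1ccc2[nH]ccc2c1", "c1cc[nH]c1"),  # indole keeps pyrrole
            ("c1ccc(-c2ccncc2)cc1", "c1ccncc1"), # phenylpyridine keeps pyridine
        ],
    )
    def test_heteroring_retained_at_level0(self, smiles, level0):
        assert chain_of(smiles).levels[0] == Chem.CanonSmiles(level0)

    def test_determinism_under_atom_renumbering(self):
        import numpy as np

        smiles = "O=C(Nc1ccc(F)cc1)c1ccc(-c2ccncc2)cc1"
        m = Chem.MolFromSmiles(smiles)
        base = build_chain(m).levels
        for seed in range(5):
            order = [int(i) for i in np.random.default_rng(seed).permutation(m.GetNumAtoms())]
            assert build_chain(Chem.RenumberAtoms(m, order)).levels == base


class TestChainAgainstEnumerationOracle:
    """Enumerate every peripheral-removal order by brute force and check the
    implementation's chain is reachable and rule-minimal at each step."""

    def _peripheral_children(self, scaffold: Chem.Mol) -> list[Chem.Mol]:
        """All one-ring-removed parents, via independent submol surgery."""
        from scaffoldscope._mols import sssr_rings, submol
        from scaffoldscope.decompose import classify_atoms

        children = []
        rings = sssr_rings(scaffold)
        for ring in rings:
            others = {a for r in rings if r is not ring for a in r}
            exclusive = set(ring) - others
            if not exclusive:
                continue
            exo = {
                a.GetIdx() for a in scaffold.GetAtoms()
                if a.GetDegree() == 1 and any(
                    n.GetIdx() in exclusive and
                    scaffold.GetBondBetweenAtoms(a.GetIdx(), n.GetIdx()).GetBondTypeAsDouble() >= 2
                    for n in a.GetNeighbors())
            }
            keep = {a.GetIdx() for a in scaffold.GetAtoms()} - exclusive - exo
            cand = submol(scaffold, keep)
            if cand is None or len(Chem.GetMolFrags(cand)) != 1:
                continue
            part = classify_atoms(cand)
            if not part.ring_atoms:
                continue
            cand = submol(cand, part.framework_atoms)
            if cand is not None and circuit_rank(cand) == circuit_rank(scaffold) - 1:
                children.append(cand)
        return children

    def _all_chains(self, scaffold: Chem.Mol) -> set[tuple[str, ...]]:
        if circuit_rank(scaffold) == 1:
            return {(canonical_smiles(scaffold),)}
        out = set()
        for child in self._peripheral_children(scaffold):
            for tail in self._all_chains(child):
                out.add(tail + (canonical_smiles(scaffold),))
        return out

    @pytest.mark.parametrize(
        "smiles",
        [
            "c1ccc(-c2ccc(Cc3ccncc3)cc2)cc1",             # 3-ring chain, mixed
            "O=C(Nc1ccccc1)c1ccc(-c2ccc(N3CCOCC3)cc2)cc1",  # 4 rings, amide linker
            "C1CC2CCC1CC2",                                # bridged bicyclic
            "c1ccc2cc3ccccc3cc2c1",                        # linear fused
            "C1CCC(C2CCC(C3CCNCC3)CC2)CC1",                # saturated 3-ring chain
        ],
    )
    def test_chain_is_a_valid_removal_order(self, smiles):
        m = Chem.MolFromSmiles(smiles)
        from scaffoldscope.decompose import murcko_framework

        scaffold = murcko_framework(m)
        possible = self._all_chains(scaffold)
        got = tuple(build_chain(m).levels)
        assert got in possible

    def test_rule_minimal_first_removal(self):
        """For phenyl–pyridine–piperidine the cascade must drop the plain
        phenyl first (fewest ring heteroatoms among the two terminal rings)."""
        ch = chain_of("c1ccc(-c2ccc(C3CCNCC3)nc2)cc1")
        assert ch.levels[-2] == Chem.CanonSmiles("c1ccc(C2CCNCC2)nc1")
        assert ch.levels[0] == Chem.CanonSmiles("C1CCNCC1")


class TestGetLevel:
    def test_levels_and_out_of_range(self):
        ch = chain_of("c1ccc(-c2ccccc2)cc1")
        assert get_level(ch, 0) == "c1ccccc1"
        assert get_level(ch, 1) == "c1ccc(-c2ccccc2)cc1"
        assert get_level(ch, 2) is None

    def test_negative_level_fatal(self):
        ch = chain_of("c1ccccc1")
        with pytest.raises(ValueError):
            get_level(ch, -1)


class TestLevelCensus:
    def test_hand_counted_example(self):
        chains = [chain_of("c1ccc(-c2ccccc2)cc1"), chain_of("c1ccc(-c2ccccc2)cc1"),
                  chain_of("Cc1ccccc1"), None]
        df = level_census(chains)
        expected = pd.DataFrame(
            {"level": [0, 1], "total": [3, 2], "unique": [1, 1]}
        )
        pd.testing.assert_frame_equal(df, expected)

    def test_empty_input(self):
        assert level_census([]).empty

    def test_level_structure_nests(self):
        ch = chain_of("O=C(Nc1ccccc1)c1ccc(-c2ccncc2)cc1")
        for lo, hi in zip(ch.level_mols, ch.level_mols[1:]):
            assert element_topology(hi).HasSubstructMatch(element_topology(lo))
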