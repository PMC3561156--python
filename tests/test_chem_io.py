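"""Library reading, standardization, filtering, dedup and sampling."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from scaffoldscope.chem_io import (
    LibrarySpec,
    MoleculeRecord,
    deduplicate,
    filter_by_mw,
    match_mw_distribution,
    prepare_library,
    read_library,
    standardize_library,
    standardize_record,
    subsample_random,
    write_library,
)


def _rec(smiles: str, rec_id: str = "m", mw: float | None = None) -> MoleculeRecord:
    mol = Chem.MolFromSmiles(smiles)
    from rdkit.Chem import Descriptors

    return MoleculeRecord(
        id=rec_id,
        smiles=Chem.MolToSmiles(mol),
        mol=mol,
        mw=mw if mw is not None else Descriptors.MolWt(mol),
        n_rings=0,
        source="test",
    )


class TestReadLibrary:
    def test_three_line_smiles_file(self, tmp_path):
        path = tmp_path / "lib.smi"
        path.write_text("c1ccccc1 benzene\nCCO ethanol\nCC(=O)O acetic\n")
        lib = read_library(path)
        assert len(lib) == 3
        assert lib.ids() == ["benzene", "ethanol", "acetic"]

    def test_malformed_line_skipped_when_not_strict(self, tmp_path, caplog):
        path = tmp_path / "lib.smi"
        path.write_text("c1ccccc1 a\nCCO b\nnot_a_smiles((( c\nCC d\nO e\n")
        with caplog.at_level("WARNING"):
            lib = read_library(path, strict=False)
        assert len(lib) == 4
        assert any("skipped 1" in rec.message for rec in caplog.records)

    def test_malformed_line_fatal_when_strict(self, tmp_path):
        path = tmp_path / "lib.smi"
        path.write_text("c1ccccc1 a\nnot_a_smiles((( c\n")
        with pytest.raises(ValueError, match="line 2"):
            read_library(path, strict=True)

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_library(tmp_path / "nope.smi")

    def test_empty_library_fatal(self, tmp_path):
        path = tmp_path / "empty.smi"
        path.write_text("\n")
        with pytest.raises(ValueError, match="empty"):
            read_library(path)

    def test_sdf_roundtrip(self, tmp_path):
        sdf = tmp_path / "lib.sdf"
        writer = Chem.SDWriter(str(sdf))
        for smi, name in [("c1ccccc1", "benzene"), ("CCO", "ethanol")]:
            mol = Chem.MolFromSmiles(smi)
            mol.SetProp("_Name", name)
            writer.write(mol)
        writer.close()
        lib = read_library(sdf, format="sdf")
        assert lib.ids() == ["benzene", "ethanol"]


class TestStandardize:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("CC(=O)[O-].[Na+]", "CC(=O)[O-]"),   # counter-ion stripped
            ("c1ccccc1", "c1ccccc1"),             # identity on clean organics
            ("[13CH4]", "C"),                     # isotope label cleared
        ],
    )
    def test_kept_records(self, smiles, expected):
        out = standardize_record(_rec(smiles))
        assert out is not None
        assert out.smiles == Chem.CanonSmiles(expected)

    def test_water_dropped_as_inorganic(self):
        assert standardize_record(_rec("O")) is None

    def test_largest_fragment_wins(self):
        out = standardize_record(_rec("CCO.c1ccccc1"))
        assert out.smiles == "c1ccccc1"


class TestFilterDedup:
    def test_mw_cutoff_is_strict(self):
        lib = LibrarySpec("t", [_rec("C", "a", 599.9), _rec("C", "b", 600.0), _rec("C", "c", 600.1)])
        assert filter_by_mw(lib, 600.0).ids() == ["a"]

    def test_filter_empty_and_identity(self):
        assert len(filter_by_mw(LibrarySpec("t", []))) == 0
        lib = LibrarySpec("t", [_rec("C", "a"), _rec("CC", "b")])
        assert filter_by_mw(lib).ids() == ["a", "b"]

    def test_dedup_first_occurrence_wins(self):
        lib = LibrarySpec("t", [_rec("c1ccccc1", "a"), _rec("C1=CC=CC=C1", "b"), _rec("Cc1ccccc1", "c")])
        assert deduplicate(lib).ids() == ["a", "c"]

    def test_dedup_keeps_stereoisomers(self):
        lib = LibrarySpec("t", [_rec("C/C=C/C", "trans"), _rec(r"C/C=C\C", "cis")])
        assert deduplicate(lib).ids() == ["trans", "cis"]

    def test_prepare_is_idempotent(self):
        lib = LibrarySpec("t", [_rec(s, f"m{i}") for i, s in enumerate(
            ["c1ccccc1", "c1ccccc1", "CC(=O)[O-].[Na+]", "Cc1ccccc1", "O"])])
        once = prepare_library(lib)
        twice = prepare_library(once)
        assert [r.smiles for r in twice.records] == [r.smiles for r in once.records]


class TestSampling:
    @pytest.fixture
    def lib1000(self):
        rng = np.random.default_rng(0)
        recs = [_rec("C" * int(rng.integers(1, 9)), f"m{i}", mw=float(rng.uniform(50, 550)))
                for i in range(1000)]
        return LibrarySpec("big", recs)

    def test_same_seed_same_sample(self, lib1000):
        a = subsample_random(lib1000, 100, seed=7)
        b = subsample_random(lib1000, 100, seed=7)
        assert a.ids() == b.ids()

    def test_full_and_empty_samples(self, lib1000):
        assert sorted(subsample_random(lib1000, 1000, seed=1).ids()) == sorted(lib1000.ids())
        assert len(subsample_random(lib1000, 0, seed=1)) == 0

    def test_oversampling_fatal(self, lib1000):
        with pytest.raises(ValueError):
            subsample_random(lib1000, 1001, seed=1)

    def test_mw_matching_single_bin_target(self, lib1000):
        target = LibrarySpec("t", [_rec("C", f"t{i}", mw=312.0) for i in range(50)])
        sample, _ = match_mw_distribution(lib1000, target, n=30, bin_width=25.0, seed=3)
        assert len(sample) == 30
        assert all(300.0 <= r.mw < 325.0 for r in sample.records)

    def test_mw_matching_identity(self, lib1000):
        sample, ks = match_mw_distribution(lib1000, lib1000, n=len(lib1000), seed=3)
        assert sorted(sample.ids()) == sorted(lib1000.ids())
        assert ks == pytest.approx(0.0, abs=1e-12)

    def test_triangular_target_ks_below_0_05(self):
        """Uniform source matched to a triangular MW target: KS < 0.05 at n=2000."""
        rng = np.random.default_rng(11)
        source = LibrarySpec("src", [
            _rec("C", f"s{i}", mw=float(rng.uniform(100, 500))) for i in range(8000)
        ])
        target = LibrarySpec("tgt", [
            _rec("C", f"t{i}", mw=float(rng.triangular(100, 300, 500))) for i in range(4000)
        ])
        sample, ks = match_mw_distribution(source, target, n=2000, bin_width=25.0, seed=5)
        assert len(sample) == 2000
        # brute-force KS on the sampled set confirms the reported statistic
        xs = np.sort([r.mw for r in sample.records])
        ys = np.sort([r.mw for r in target.records])
        grid = np.concatenate([xs, ys])
        fx = np.searchsorted(xs, grid, side="right") / len(xs)
        fy = np.searchsorted(ys, grid, side="right") / len(ys)
        brute = float(np.max(np.abs(fx - fy)))
        assert ks == pytest.approx(brute, abs=1e-12)
        assert ks < 0.05

    def test_deterministic_matching(self, lib1000):
        target = LibrarySpec("t", [_rec("C", f"t{i}", mw=float(m)) for i, m in
                                   enumerate(np.linspace(100, 500, 200))])
        a, _ = match_mw_distribution(lib1000, target, n=300, seed=9)
        b, _ = match_mw_distribution(lib1000, target, n=300, seed=9)
        assert a.ids() == b.ids()


def test_write_library_roundtrip(tmp_path):
    lib = LibrarySpec("t", [_rec("c1ccccc1", "a"), _rec("CCO", "b")])
    write_library(lib, tmp_path / "out.smi", tmp_path / "out.tsv")
    back = read_library(tmp_path / "out.smi")
    assert back.ids() == ["a", "b"]
    header = (tmp_path / "out.tsv").read_text().splitlines()[0]
    assert header == "id\tcanonical_smiles\tmw\tn_rings\tsource"
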