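"""Parsing, conformer generation, dataset cleaning and stratified splitting."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

import odorgraph as og
from odorgraph.chem import (
    CleaningError,
    ParseError,
    canonical_key,
    load_dataset,
    read_sdf,
    read_table,
    save_dataset,
)


def dummy_molecule(mol_id, n_labels_row=None):
    return og.Molecule(mol_id, "", [6], None, [])


class TestParsing:
    def test_water_gains_explicit_hydrogens(self):
        mol = og.parse_structure("O")
        assert sorted(mol.atomic_numbers) == [1, 1, 8]
        assert mol.coordinates is None

    def test_ethane_atoms_and_cc_bond(self):
        mol = og.parse_structure("CC")
        assert sorted(mol.atomic_numbers) == [1] * 6 + [6, 6]
        cc = [(i, j) for i, j, _ in mol.bonds
              if mol.atomic_numbers[i] == 6 and mol.atomic_numbers[j] == 6]
        assert len(cc) == 1
        assert len(mol.bonds) == 7

    def test_hydrogens_can_be_excluded(self):
        mol = og.parse_structure("CC", add_hs=False)
        assert mol.atomic_numbers == [6, 6]

    def test_malformed_smiles_raises_with_record_id(self):
        with pytest.raises(ParseError, match="bad-rec"):
            og.parse_structure("C(", record_id="bad-rec")

    def test_sdf_record_keeps_coordinates(self, tmp_path):
        rd = Chem.AddHs(Chem.MolFromSmiles("CO"))
        AllChem.EmbedMolecule(rd, randomSeed=5)
        path = tmp_path / "one.sdf"
        writer = Chem.SDWriter(str(path))
        writer.write(rd)
        writer.close()
        mols = read_sdf(path)
        assert len(mols) == 1
        assert mols[0].coordinates is not None
        assert mols[0].coordinates.shape == (mols[0].n_atoms, 3)


class TestCoordinates:
    def test_same_seed_is_bitwise_identical(self):
        mol = og.parse_structure("CCO")
        a = og.generate_coordinates(mol, seed=3)
        b = og.generate_coordinates(mol, seed=3)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_cc_bond_length_is_chemically_plausible(self):
        mol = og.generate_coordinates(og.parse_structure("CC"), seed=1)
        c_idx = [i for i, z in enumerate(mol.atomic_numbers) if z == 6]
        d = np.linalg.norm(mol.coordinates[c_idx[0]] - mol.coordinates[c_idx[1]])
        assert 1.3 <= d <= 1.7

    def test_existing_coordinates_are_untouched(self):
        coords = np.arange(6.0).reshape(2, 3)
        mol = og.Molecule("x", "[H][H]", [1, 1], coords, [(0, 1, 1.0)])
        assert og.generate_coordinates(mol, seed=9) is mol


class TestCleaning:
    def test_duplicate_structures_merge_descriptor_union(self):
        records = [("a", "OCC", ["fruity"]), ("b", "CCO", ["sweet"])]
        ds = og.clean_dataset(records, min_count=1)
        assert ds.n_tot == 1
        assert ds.vocabulary.names == ["fruity", "sweet"]
        assert ds.labels.tolist() == [[1, 1]]

    def test_desalted_largest_fragment_is_merge_key(self):
        assert canonical_key("CCO.[Na+]") == canonical_key("CCO")

    def test_rare_descriptor_dropped_at_threshold(self):
        records = [
            ("m1", "C", ["minty", "sweet"]),
            ("m2", "CC", ["minty", "sweet"]),
            ("m3", "CCC", ["sweet"]),
        ]
        ds = og.clean_dataset(records, min_count=3)
        assert ds.vocabulary.names == ["sweet"]

    def test_molecules_without_descriptors_are_dropped(self):
        records = [("m1", "C", ["rare"]), ("m2", "CC", ["common"]), ("m3", "CCC", ["common"])]
        ds = og.clean_dataset(records, min_count=2)
        assert ds.n_tot == 2

    def test_odorless_conflict_resolved_in_favor_of_odorants(self):
        records = [
            ("m1", "C", ["odorless", "fruity"]),
            ("m2", "CC", ["odorless"]),
            ("m3", "CCC", ["fruity"]),
        ]
        ds = og.clean_dataset(records, min_count=1)
        fruity = ds.vocabulary.names.index("fruity")
        odorless = ds.vocabulary.names.index("odorless")
        row = {m.id: ds.labels[i] for i, m in enumerate(ds.molecules)}
        assert row["m1"][fruity] == 1 and row["m1"][odorless] == 0
        assert row["m2"][odorless] == 1

    def test_weight_formula(self):
        smiles = ["C" * (i + 1) for i in range(100)]
        records = [
            (f"m{i}", s, ["common", "rare"] if i < 10 else ["common"])
            for i, s in enumerate(smiles)
        ]
        ds = og.clean_dataset(records, min_count=5)
        rare = ds.vocabulary.names.index("rare")
        assert ds.weights[rare] == pytest.approx(0.9, abs=0)
        np.testing.assert_allclose(ds.weights + ds.n_pos / ds.n_tot, 1.0, atol=0)

    def test_cleaning_is_idempotent(self):
        records = [
            ("m1", "CCO", ["fruity", "odorless"]),
            ("m2", "OCC", ["sweet"]),
            ("m3", "CCC", ["sweet", "minty"]),
            ("m4", "CCCC", ["sweet"]),
        ]
        once = og.clean_dataset(records, min_count=2)
        twice = og.clean_dataset(once.to_records(), min_count=2)
        assert once.vocabulary.names == twice.vocabulary.names
        np.testing.assert_array_equal(once.labels, twice.labels)
        np.testing.assert_array_equal(once.weights, twice.weights)

    def test_empty_result_raises(self):
        with pytest.raises(CleaningError):
            og.clean_dataset([("m1", "C", ["only-once"])], min_count=2)


def _label_dataset(rows, names):
    labels = np.asarray(rows)
    mols = [dummy_molecule(f"m{i}") for i in range(len(rows))]
    return og.OdorDataset(mols, labels, og.DescriptorVocabulary(names, labels.sum(0)))


class TestStratifiedSplit:
    def test_single_label_sizes(self):
        ds = _label_dataset([[1]] * 10, ["a"])
        split = og.stratified_split(ds, seed=0)
        sizes = [len(split.indices(s)) for s in ("train", "validation", "test")]
        assert sizes == [8, 1, 1]

    def test_counts_divisible_by_ten_split_exactly(self):
        rows = [[1, 0]] * 20 + [[0, 1]] * 30
        ds = _label_dataset(rows, ["a", "b"])
        split = og.stratified_split(ds, seed=4)
        val = split.indices("validation")
        val_pos = ds.labels[val].sum(axis=0)
        assert val_pos.tolist() == [2, 3]

    def test_same_seed_reproduces_partition(self, default_fixture):
        _, dataset, _, _ = default_fixture
        a = og.stratified_split(dataset, seed=7)
        b = og.stratified_split(dataset, seed=7)
        assert np.array_equal(a.partition, b.partition)

    def test_partition_covers_each_index_once(self, default_fixture):
        _, dataset, _, split = default_fixture
        all_idx = np.concatenate([split.indices(s) for s in ("train", "validation", "test")])
        assert sorted(all_idx) == list(range(dataset.n_tot))

    def test_per_label_positive_counts_near_targets(self, default_fixture):
        _, dataset, _, split = default_fixture
        assert (dataset.n_pos >= 20).all()
        for name, ratio in zip(("train", "validation", "test"), (0.8, 0.1, 0.1)):
            pos = dataset.labels[split.indices(name)].sum(axis=0)
            target = ratio * dataset.n_pos
            assert np.abs(pos - target).max() <= 2

    def test_bad_ratios_rejected(self):
        ds = _label_dataset([[1]] * 10, ["a"])
        with pytest.raises(ValueError, match="sum to 1"):
            og.stratified_split(ds, ratios=(0.5, 0.2, 0.2))

    def test_unlabeled_molecules_rejected_if_label_empty(self):
        labels = np.array([[1], [0], [0], [1]])
        mols = [dummy_molecule(f"m{i}") for i in range(4)]
        ds = og.OdorDataset(mols, np.zeros((4, 1), int), og.DescriptorVocabulary(["a"], [0]))
        with pytest.raises(ValueError, match="without positives"):
            og.stratified_split(ds)


class TestArchive:
    def test_save_load_round_trip(self, tmp_path, small_synthetic):
        _, dataset, _ = small_synthetic
        split = og.stratified_split(dataset, seed=2)
        save_dataset(dataset, tmp_path / "arch", split)
        loaded, loaded_split = load_dataset(tmp_path / "arch")
        assert [m.id for m in loaded.molecules] == [m.id for m in dataset.molecules]
        np.testing.assert_array_equal(loaded.labels, dataset.labels)
        assert loaded.vocabulary.names == dataset.vocabulary.names
        np.testing.assert_allclose(
            loaded.molecules[0].coordinates, dataset.molecules[0].coordinates
        )
        assert np.array_equal(loaded_split.partition, split.partition)

    def test_read_table_parses_semicolon_descriptors(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("id,smiles,descriptors\nm1,CCO,fruity;sweet\nm2,CC,\n")
        records = read_table(path)
        assert records == [("m1", "CCO", ["fruity", "sweet"]), ("m2", "CC", [])]
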