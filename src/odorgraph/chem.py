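"""Molecule parsing, 3D conformers, multilabel odor datasets and splits.

The dataset model is a list of molecules with a binary molecule-by-descriptor
label matrix.  Cleaning merges records that share a canonical structure,
resolves "odorless"-vs-odorant conflicts, and drops descriptors carried by
fewer than ``min_count`` molecules.  Per-descriptor loss weights are
``w_i = 1 - n_pos_i / n_tot``, so rare descriptors weigh close to 1.

Splitting uses second-order iterative stratification: train/validation/test
partitions are grown label-combination by label-combination, rarest first, so
that label and label-pair frequencies track the requested ratios.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

SPLIT_NAMES = ("train", "validation", "test")


class ParseError(ValueError):
    """Raised when a structure record cannot be parsed."""


class EmbeddingError(RuntimeError):
    """Raised when 3D coordinate generation fails for a molecule."""


class CleaningError(ValueError):
    """Raised when cleaning leaves an empty dataset."""


# ---------------------------------------------------------------------------
# Molecule
# ---------------------------------------------------------------------------


@dataclass
class Molecule:
    """Nuclei, coordinates and bonds of one molecule.

    `atomic_numbers` are nuclear charges Z_i; `coordinates` (when present) are
    an n x 3 array in angstroms; `bonds` are (i, j, order) with i < j.
    """

    id: str
    smiles: str
    atomic_numbers: list[int]
    coordinates: np.ndarray | None
    bonds: list[tuple[int, int, float]]

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    def __post_init__(self):
        n = len(self.atomic_numbers)
        if any(z < 1 for z in self.atomic_numbers):
            raise ValueError(f"{self.id}: atomic numbers must be >= 1")
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
            if self.coordinates.shape != (n, 3):
                raise ValueError(f"{self.id}: coordinates must be {n}x3")
            if not np.all(np.isfinite(self.coordinates)):
                raise ValueError(f"{self.id}: non-finite coordinates")
        for i, j, _ in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"{self.id}: invalid bond ({i}, {j})")


def _mol_from_rdkit(rdmol: Chem.Mol, record_id: str, add_hs: bool) -> Molecule:
    has_conf = rdmol.GetNumConformers() > 0
    if add_hs:
        rdmol = Chem.AddHs(rdmol, addCoords=has_conf)
    zs = [atom.GetAtomicNum() for atom in rdmol.GetAtoms()]
    if sum(z > 1 for z in zs) == 0:
        raise ParseError(f"record {record_id!r} has zero heavy atoms")
    bonds = sorted(
        (
            min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
            max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
            b.GetBondTypeAsDouble(),
        )
        for b in rdmol.GetBonds()
    )
    coords = None
    if has_conf:
        coords = np.asarray(rdmol.GetConformer().GetPositions(), dtype=np.float64)
    smiles = Chem.MolToSmiles(Chem.RemoveHs(rdmol))
    return Molecule(record_id, smiles, zs, coords, bonds)


def parse_structure(record, record_id: str | None = None, add_hs: bool = True) -> Molecule:
    """Parse a SMILES string or an RDKit Mol (e.g. one SDF record).

    Explicit hydrogens are added by default; coordinates are kept only when the
    record carries a conformer (SDF with 3D coordinates).
    """
    if isinstance(record, Chem.Mol):
        rid = record_id or (record.GetProp("_Name") if record.HasProp("_Name") else "sdf-record")
        return _mol_from_rdkit(record, rid, add_hs)
    if not isinstance(record, str):
        raise ParseError(f"unsupported record type {type(record).__name__}")
    rid = record_id or record
    rdmol = Chem.MolFromSmiles(record)
    if rdmol is None:
        raise ParseError(f"could not parse SMILES record {rid!r}")
    return _mol_from_rdkit(rdmol, rid, add_hs)


def generate_coordinates(mol: Molecule, seed: int = 0) -> Molecule:
    """Populate 3D coordinates by ETKDG embedding plus MMFF94 relaxation.

    Deterministic for a fixed (molecule, seed); molecules that already carry
    coordinates (e.g. from an SDF) are returned unchanged.
    """
    if mol.coordinates is not None:
        return mol
    rdmol = Chem.MolFromSmiles(mol.smiles)
    if rdmol is None:
        raise EmbeddingError(f"{mol.id}: cannot rebuild structure for embedding")
    rdmol = Chem.AddHs(rdmol)
    zs = [a.GetAtomicNum() for a in rdmol.GetAtoms()]
    if zs != list(mol.atomic_numbers):
        raise EmbeddingError(f"{mol.id}: atom order changed during embedding")
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1) + 1
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(rdmol, params) != 0:
            raise EmbeddingError(f"{mol.id}: 3D embedding failed")
    try:
        AllChem.MMFFOptimizeMolecule(rdmol, maxIters=500)
    except Exception:  # pragma: no cover - MMFF lacks parameters for some species
        logger.warning("%s: MMFF relaxation failed; keeping ETKDG geometry", mol.id)
    coords = np.asarray(rdmol.GetConformer().GetPositions(), dtype=np.float64)
    return replace(mol, coordinates=coords)


# ---------------------------------------------------------------------------
# Dataset containers
# ---------------------------------------------------------------------------


@dataclass
class DescriptorVocabulary:
    names: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if sorted(self.names) != list(self.names):
            raise ValueError("descriptor names must be lexicographically sorted")
        if len(set(self.names)) != len(self.names):
            raise ValueError("descriptor names must be unique")


@dataclass
class OdorDataset:
    molecules: list[Molecule]
    labels: np.ndarray  # m x o binary
    vocabulary: DescriptorVocabulary
    weights: np.ndarray = field(init=False)
    n_pos: np.ndarray = field(init=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (len(self.molecules), len(self.vocabulary.names)):
            raise ValueError("label matrix shape mismatch")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        self.n_pos = self.labels.sum(axis=0)
        self.weights = 1.0 - self.n_pos / self.n_tot

    @property
    def n_tot(self) -> int:
        return len(self.molecules)

    @property
    def n_descriptors(self) -> int:
        return len(self.vocabulary.names)

    def to_records(self) -> list[tuple[str, str, list[str]]]:
        names = np.asarray(self.vocabulary.names)
        return [
            (m.id, m.smiles, list(names[self.labels[i] == 1]))
            for i, m in enumerate(self.molecules)
        ]

    def subset(self, indices) -> "OdorDataset":
        indices = np.asarray(indices)
        sub = OdorDataset(
            [self.molecules[i] for i in indices], self.labels[indices], self.vocabulary
        )
        # Loss weights stay those of the full dataset: they encode global class balance.
        sub.weights = self.weights.copy()
        return sub


@dataclass
class SplitAssignment:
    partition: np.ndarray  # array of split names, one per molecule index
    ratios: tuple[float, float, float]
    seed: int

    def indices(self, split: str) -> np.ndarray:
        if split not in SPLIT_NAMES:
            raise ValueError(f"unknown split {split!r}")
        return np.flatnonzero(self.partition == split)


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def canonical_key(smiles: str) -> str:
    """Canonical SMILES of the largest (de-salted) fragment; the merge key."""
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ParseError(f"could not parse SMILES {smiles!r}")
    frags = Chem.GetMolFrags(rdmol, asMols=True)
    largest = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    return Chem.MolToSmiles(largest)


def clean_dataset(
    records,
    min_count: int = 30,
    odorless_label: str = "odorless",
    add_hs: bool = True,
) -> OdorDataset:
    """Merge duplicate structures, resolve conflicts, drop rare descriptors.

    ``records`` is an iterable of ``(smiles, descriptors)`` or
    ``(id, smiles, descriptors)`` tuples.  A molecule labeled both odorless and
    odorant keeps the odorant descriptors; descriptors on fewer than
    ``min_count`` molecules are removed, and molecules left label-free are
    dropped.
    """
    records = list(records)
    if not records:
        raise CleaningError("no input records")

    merged: dict[str, tuple[str, set[str]]] = {}
    for rec in records:
        rid, smiles, descs = rec if len(rec) == 3 else (rec[0], rec[0], rec[1])
        key = canonical_key(smiles)
        if key in merged:
            merged[key][1].update(descs)
        else:
            merged[key] = (rid, set(descs))

    for key, (rid, descs) in merged.items():
        if odorless_label in descs and len(descs) > 1:
            logger.info("%s: removing conflicting %r label", rid, odorless_label)
            descs.discard(odorless_label)

    counts: dict[str, int] = {}
    for _, descs in merged.values():
        for d in descs:
            counts[d] = counts.get(d, 0) + 1
    kept_names = sorted(d for d, c in counts.items() if c >= min_count)
    if not kept_names:
        raise CleaningError(f"no descriptor reaches min_count={min_count}")
    kept_set = set(kept_names)

    molecules, rows = [], []
    for key in sorted(merged):
        rid, descs = merged[key]
        kept = descs & kept_set
        if not kept:
            continue
        molecules.append(parse_structure(key, record_id=rid, add_hs=add_hs))
        rows.append([1 if d in kept else 0 for d in kept_names])
    if not molecules:
        raise CleaningError("all molecules dropped during cleaning")

    labels = np.asarray(rows, dtype=np.int64)
    vocab = DescriptorVocabulary(kept_names, labels.sum(axis=0))
    return OdorDataset(molecules, labels, vocab)


# ---------------------------------------------------------------------------
# Second-order iterative stratification
# ---------------------------------------------------------------------------


def _label_combinations(row: np.ndarray, order: int) -> list[tuple[int, ...]]:
    on = tuple(np.flatnonzero(row))
    if not on:
        return []
    combos: list[tuple[int, ...]] = [(i,) for i in on]
    if order >= 2:
        combos.extend((i, j) for a, i in enumerate(on) for j in on[a + 1 :])
    return combos


def stratified_split(
    dataset: OdorDataset,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    order: int = 2,
    seed: int = 0,
) -> SplitAssignment:
    """Iterative stratification over label combinations of size <= ``order``.

    Samples are assigned rarest-combination first; each goes to the split with
    the greatest remaining demand for that combination, ties broken by overall
    remaining capacity and then by split index.  Deterministic for fixed seed.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    if (dataset.n_pos == 0).any():
        bad = [dataset.vocabulary.names[i] for i in np.flatnonzero(dataset.n_pos == 0)]
        raise ValueError(f"labels without positives: {bad}")

    m = dataset.n_tot
    rng = np.random.default_rng(seed)
    ratios_arr = np.asarray(ratios, dtype=np.float64)

    sample_combos = [_label_combinations(dataset.labels[i], order) for i in range(m)]
    combo_members: dict[tuple[int, ...], set[int]] = {}
    for i, combos in enumerate(sample_combos):
        for c in combos:
            combo_members.setdefault(c, set()).add(i)

    desired = {c: len(members) * ratios_arr for c, members in combo_members.items()}
    capacity = m * ratios_arr.copy()
    assigned = np.full(m, -1, dtype=np.int64)

    def place(i: int, split: int) -> None:
        assigned[i] = split
        capacity[split] -= 1
        for c in sample_combos[i]:
            desired[c][split] -= 1
            combo_members[c].discard(i)

    while True:
        pending = {c: mem for c, mem in combo_members.items() if mem}
        if not pending:
            break
        # rarest combination first; lexicographic tie-break for determinism
        combo = min(pending, key=lambda c: (len(pending[c]), c))
        members = np.array(sorted(pending[combo]))
        rng.shuffle(members)
        for i in members:
            if assigned[i] >= 0:
                continue
            d = desired[combo]
            best = np.flatnonzero(d == d.max())
            if len(best) > 1:
                cap = capacity[best]
                best = best[cap == cap.max()]
            place(int(i), int(best[0]))

    # label-free samples go wherever capacity remains
    for i in np.flatnonzero(assigned < 0):
        place(int(i), int(np.argmax(capacity)))

    partition = np.array([SPLIT_NAMES[s] for s in assigned])
    return SplitAssignment(partition, tuple(ratios), seed)


# ---------------------------------------------------------------------------
# Dataset archive (plain-text, stable column names)
# ---------------------------------------------------------------------------


def save_dataset(dataset: OdorDataset, outdir, split: SplitAssignment | None = None) -> None:
    """Write molecules.jsonl, labels.csv, vocabulary.json (and split.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "molecules.jsonl", "w") as fh:
        for mol in dataset.molecules:
            fh.write(
                json.dumps(
                    {
                        "id": mol.id,
                        "smiles": mol.smiles,
                        "atomic_numbers": mol.atomic_numbers,
                        "coordinates": None
                        if mol.coordinates is None
                        else mol.coordinates.tolist(),
                        "bonds": [[i, j, o] for i, j, o in mol.bonds],
                    }
                )
                + "\n"
            )
    header = "id," + ",".join(dataset.vocabulary.names)
    lines = [header] + [
        mol.id + "," + ",".join(map(str, row))
        for mol, row in zip(dataset.molecules, dataset.labels)
    ]
    (outdir / "labels.csv").write_text("\n".join(lines) + "\n")
    (outdir / "vocabulary.json").write_text(
        json.dumps(
            {
                "names": dataset.vocabulary.names,
                "counts": dataset.vocabulary.counts.tolist(),
                "weights": dataset.weights.tolist(),
            },
            indent=2,
        )
    )
    if split is not None:
        (outdir / "split.json").write_text(
            json.dumps(
                {
                    "partition": split.partition.tolist(),
                    "ratios": list(split.ratios),
                    "seed": split.seed,
                },
                indent=2,
            )
        )


def load_dataset(indir) -> tuple[OdorDataset, SplitAssignment | None]:
    indir = Path(indir)
    molecules = []
    with open(indir / "molecules.jsonl") as fh:
        for line in fh:
            rec = json.loads(line)
            molecules.append(
                Molecule(
                    rec["id"],
                    rec["smiles"],
                    rec["atomic_numbers"],
                    None if rec["coordinates"] is None else np.asarray(rec["coordinates"]),
                    [tuple(b) for b in rec["bonds"]],
                )
            )
    vocab_info = json.loads((indir / "vocabulary.json").read_text())
    lines = (indir / "labels.csv").read_text().strip().split("\n")
    labels = np.asarray(
        [[int(v) for v in line.split(",")[1:]] for line in lines[1:]], dtype=np.int64
    )
    vocab = DescriptorVocabulary(vocab_info["names"], vocab_info["counts"])
    dataset = OdorDataset(molecules, labels, vocab)
    split = None
    split_path = indir / "split.json"
    if split_path.exists():
        info = json.loads(split_path.read_text())
        split = SplitAssignment(np.array(info["partition"]), tuple(info["ratios"]), info["seed"])
    return dataset, split


def read_table(path, delimiter: str | None = None) -> list[tuple[str, str, list[str]]]:
    """Read id/smiles/descriptors records from CSV or TSV (';'-separated labels)."""
    path = Path(path)
    delimiter = delimiter or ("\t" if path.suffix.lower() in (".tsv", ".tab") else ",")
    records = []
    with open(path) as fh:
        header = fh.readline().strip().split(delimiter)
        cols = {name.strip().lower(): k for k, name in enumerate(header)}
        for need in ("id", "smiles", "descriptors"):
            if need not in cols:
                raise ParseError(f"{path}: missing column {need!r}")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(delimiter)
            descs = [d.strip() for d in fields[cols["descriptors"]].split(";") if d.strip()]
            records.append((fields[cols["id"]].strip(), fields[cols["smiles"]].strip(), descs))
    return records


def read_sdf(path) -> list[Molecule]:
    """Parse all records of a V2000 SDF file, keeping supplied coordinates."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    molecules = []
    for k, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ParseError(f"{path}: unparsable SDF record #{k}")
        molecules.append(parse_structure(rdmol, record_id=None))
    return molecules
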