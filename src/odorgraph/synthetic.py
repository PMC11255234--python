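"""Procedural fixture datasets with structure-determined odor-like labels.

Molecules are random acyclic-or-monocyclic skeletons over {C, N, O, S, Cl}
with chemically valid valences, explicit hydrogens and ETKDG/MMFF 3D
coordinates.  Labels follow structural predicates plus independent flip
noise, emulating the skew and annotator inconsistency of real odor data while
keeping the ground truth known:

* ``sulfurous``   — contains at least one sulfur atom;
* ``halogenated`` — contains at least one chlorine atom;
* ``compact``     — maximum heavy-atom pairwise distance below a cutoff
  (deliberately conformer-dependent, so Coulomb-matrix models can use 3D
  information that bond adjacency alone cannot see).

Because labels are predicates of structure, held-out performance measures
representation learning rather than memorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from rdkit import Chem

from .chem import DescriptorVocabulary, Molecule, OdorDataset, generate_coordinates, parse_structure

VALENCE = {6: 4, 7: 3, 8: 2, 16: 2, 17: 1}


def has_sulfur(mol: Molecule) -> bool:
    return 16 in mol.atomic_numbers


def has_chlorine(mol: Molecule) -> bool:
    return 17 in mol.atomic_numbers


def _compact_predicate(cutoff: float) -> Callable[[Molecule], bool]:
    def compact(mol: Molecule) -> bool:
        heavy = np.asarray(mol.atomic_numbers) > 1
        coords = mol.coordinates[heavy]
        diff = coords[:, None, :] - coords[None, :, :]
        return float(np.sqrt((diff**2).sum(-1)).max()) < cutoff

    return compact


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults are the package's standard fixture."""

    n_molecules: int = 200
    atom_range: tuple[int, int] = (4, 18)  # heavy atoms
    noise: float = 0.05  # independent label flip probability
    seed: int = 0
    p_sulfur: float = 0.4
    p_chlorine: float = 0.35
    ring_prob: float = 0.3
    compact_cutoff: float = 7.0  # angstroms, heavy-atom diameter
    rules: list[tuple[str, Callable[[Molecule], bool]]] = field(default=None)

    def __post_init__(self):
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise must be in [0, 0.5)")
        if self.rules is None:
            self.rules = [
                ("compact", _compact_predicate(self.compact_cutoff)),
                ("halogenated", has_chlorine),
                ("sulfurous", has_sulfur),
            ]
        if [name for name, _ in self.rules] != sorted(name for name, _ in self.rules):
            raise ValueError("rule names must be lexicographically sorted")


def _graph_distance(bonds: list[tuple[int, int]], n: int, start: int) -> np.ndarray:
    adj = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    dist = np.full(n, -1)
    dist[start] = 0
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _random_smiles(rng: np.random.Generator, spec: SyntheticSpec) -> str | None:
    lo, hi = spec.atom_range
    n_heavy = int(rng.integers(lo, hi + 1))
    elements: list[int] = []
    if rng.random() < spec.p_sulfur:
        elements.append(16)
    if rng.random() < spec.p_chlorine:
        elements.append(17)
    while len(elements) < n_heavy:
        r = rng.random()
        elements.append(6 if r < 0.75 else 8 if r < 0.9 else 7)
    order = rng.permutation(len(elements))
    elements = [elements[i] for i in order]

    rw = Chem.RWMol()
    for z in elements:
        rw.AddAtom(Chem.Atom(int(z)))
    free = [VALENCE[z] for z in elements]
    bonds: list[tuple[int, int]] = []
    for i in range(1, len(elements)):
        candidates = [j for j in range(i) if free[j] > 0]
        if not candidates:
            return None
        j = int(candidates[rng.integers(len(candidates))])
        rw.AddBond(i, j, Chem.BondType.SINGLE)
        bonds.append((i, j))
        free[i] -= 1
        free[j] -= 1
    if rng.random() < spec.ring_prob:
        open_atoms = [i for i in range(len(elements)) if free[i] > 0]
        rng.shuffle(open_atoms)
        done = False
        for a in open_atoms:
            if done:
                break
            dist = _graph_distance(bonds, len(elements), a)
            for b in open_atoms:
                if b != a and 2 <= dist[b] <= 6:
                    rw.AddBond(int(a), int(b), Chem.BondType.SINGLE)
                    done = True
                    break
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def generate_molecules(spec: SyntheticSpec) -> list[Molecule]:
    """Deterministically generate unique molecules with 3D coordinates."""
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    molecules: list[Molecule] = []
    attempts = 0
    while len(molecules) < spec.n_molecules:
        attempts += 1
        if attempts > 50 * spec.n_molecules:
            raise RuntimeError("synthetic generation stalled; widen atom_range")
        smiles = _random_smiles(rng, spec)
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        k = len(molecules)
        mol = parse_structure(smiles, record_id=f"syn-{k:04d}")
        coord_seed = (spec.seed * 100003 + k) % (2**31 - 1)
        molecules.append(generate_coordinates(mol, seed=coord_seed))
    return molecules


def predicate_labels(molecules: list[Molecule], spec: SyntheticSpec) -> np.ndarray:
    """Noise-free rule outcomes, one column per rule (lexicographic order)."""
    return np.array(
        [[int(pred(mol)) for _, pred in spec.rules] for mol in molecules], dtype=np.int64
    )


def assign_labels(molecules: list[Molecule], spec: SyntheticSpec) -> OdorDataset:
    """Predicate labels with independent flip noise, packed as a dataset."""
    clean = predicate_labels(molecules, spec)
    zero = np.flatnonzero(clean.sum(axis=0) == 0)
    if len(zero):
        bad = [spec.rules[i][0] for i in zero]
        raise ValueError(f"rules with zero positives: {bad}; increase n_molecules")
    rng = np.random.default_rng(spec.seed + 1)
    flips = rng.random(clean.shape) < spec.noise
    labels = np.where(flips, 1 - clean, clean)
    names = [name for name, _ in spec.rules]
    return OdorDataset(molecules, labels, DescriptorVocabulary(names, labels.sum(axis=0)))


def generate_dataset(spec: SyntheticSpec | None = None) -> tuple[OdorDataset, np.ndarray]:
    """Full fixture: (noisy dataset, noise-free label matrix)."""
    spec = spec or SyntheticSpec()
    molecules = generate_molecules(spec)
    dataset = assign_labels(molecules, spec)
    return dataset, predicate_labels(molecules, spec)
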