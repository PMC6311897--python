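"""Synthetic labeled molecule sets with planted substructures.

The generator assembles random acyclic scaffolds (with optional rings) over
a small element alphabet, then plants a chosen fragment — a carboxy-like
group by default — into the actives.  Because ground truth is known by
construction, these sets make training, fingerprinting and motif recovery
testable without any external screening data.  Planted-atom indices are
re-derived on the canonical molecule by substructure matching, since atom
order changes under canonicalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .tokenizer import canonicalize, mol_from_smiles

logger = logging.getLogger(__name__)

# free valence budget per element (single bonds, neutral atoms)
_MAX_DEGREE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1}


class GenerationError(RuntimeError):
    pass


@dataclass
class GenParams:
    """Knobs of the synthetic benchmark.

    Defaults emulate a small-molecule screening set: scaffolds of 8-30 heavy
    atoms drawn mostly from carbon with N/O/S/halogen decoration, branched
    trees with occasional rings, and a carboxy-like planted motif C(=O)O.
    """

    n_active: int = 200
    n_inactive: int = 200
    min_atoms: int = 8
    max_atoms: int = 30
    branch_prob: float = 0.3
    ring_prob: float = 0.3
    alphabet: tuple[str, ...] = ("C", "C", "C", "C", "C", "N", "O", "S", "F", "Cl")
    planted_motif: str = "C(=O)O"
    seed: int = 0
    max_retries: int = 200

    def __post_init__(self):
        if self.n_active < 0 or self.n_inactive < 0:
            raise ValueError("compound counts must be >= 0")
        if not 1 <= self.min_atoms <= self.max_atoms:
            raise ValueError("need 1 <= min_atoms <= max_atoms")
        if Chem.MolFromSmiles(self.planted_motif) is None:
            raise ValueError(f"planted_motif {self.planted_motif!r} does not parse")
        for el in self.alphabet:
            if el not in _MAX_DEGREE:
                raise ValueError(f"unsupported element {el!r}")


@dataclass
class SyntheticDataset:
    ids: list[str]
    smiles: list[str]
    labels: np.ndarray
    motif_atoms: list[tuple[int, ...]]  # canonical-mol atom indices of planted copies
    params: GenParams = field(repr=False, default=None)

    def __len__(self):
        return len(self.ids)

    def records(self):
        return list(zip(self.ids, self.smiles, self.labels.astype(int).tolist()))


def _random_scaffold(rng: np.random.Generator, params: GenParams) -> Chem.RWMol:
    """Random valence-respecting tree with optional ring closures."""
    n = int(rng.integers(params.min_atoms, params.max_atoms + 1))
    mol = Chem.RWMol()
    symbols = []
    first = str(rng.choice([e for e in params.alphabet if _MAX_DEGREE[e] >= 2] or ["C"]))
    mol.AddAtom(Chem.Atom(first))
    symbols.append(first)
    backbone = 0  # current chain head
    for _ in range(n - 1):
        el = str(rng.choice(params.alphabet))
        # pick an attachment point with spare valence
        if rng.random() < params.branch_prob:
            candidates = [a for a in range(mol.GetNumAtoms())
                          if mol.GetAtomWithIdx(a).GetDegree() < _MAX_DEGREE[symbols[a]]]
        else:
            candidates = [backbone] if mol.GetAtomWithIdx(backbone).GetDegree() < _MAX_DEGREE[symbols[backbone]] else []
            if not candidates:
                candidates = [a for a in range(mol.GetNumAtoms())
                              if mol.GetAtomWithIdx(a).GetDegree() < _MAX_DEGREE[symbols[a]]]
        if not candidates:
            break
        parent = int(rng.choice(candidates))
        idx = mol.AddAtom(Chem.Atom(el))
        symbols.append(el)
        mol.AddBond(parent, idx, Chem.BondType.SINGLE)
        if _MAX_DEGREE[el] >= 2:
            backbone = idx
    # optional ring closure between atoms 3-6 bonds apart
    if rng.random() < params.ring_prob and mol.GetNumAtoms() >= 5:
        dmat = Chem.GetDistanceMatrix(mol.GetMol())
        pairs = [
            (i, j)
            for i in range(mol.GetNumAtoms())
            for j in range(i + 1, mol.GetNumAtoms())
            if 3 <= dmat[i, j] <= 6
            and mol.GetAtomWithIdx(i).GetDegree() < _MAX_DEGREE[symbols[i]]
            and mol.GetAtomWithIdx(j).GetDegree() < _MAX_DEGREE[symbols[j]]
        ]
        if pairs:
            i, j = pairs[int(rng.integers(len(pairs)))]
            mol.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    return mol


def generate_molecule(rng: np.random.Generator, params: GenParams) -> str:
    """One random valid canonical SMILES within the configured size range."""
    for _ in range(params.max_retries):
        mol = _random_scaffold(rng, params)
        try:
            Chem.SanitizeMol(mol)
            return canonicalize(Chem.MolToSmiles(mol))
        except Exception:  # rejection sampling on rare valence clashes
            continue
    raise GenerationError(f"no valid molecule after {params.max_retries} attempts")


def _attach_fragment(rng: np.random.Generator, scaffold_smiles: str, fragment_smiles: str,
                     params: GenParams) -> str | None:
    scaffold = mol_from_smiles(scaffold_smiles)
    frag = mol_from_smiles(fragment_smiles)
    combo = Chem.RWMol(Chem.CombineMols(scaffold, frag))
    n_sc = scaffold.GetNumAtoms()
    anchors = [a.GetIdx() for a in scaffold.GetAtoms() if a.GetTotalNumHs() > 0]
    if not anchors:
        return None
    anchor = int(rng.choice(anchors))
    combo.AddBond(anchor, n_sc, Chem.BondType.SINGLE)
    try:
        Chem.SanitizeMol(combo)
    except Exception:
        return None
    return canonicalize(Chem.MolToSmiles(combo))


def generate_planted_dataset(params: GenParams | None = None) -> SyntheticDataset:
    """Labeled set: actives carry >= 1 planted copy of the motif fragment,
    inactives are verified motif-free by substructure search.

    ``motif_atoms`` records, for each compound, the union of canonical-mol
    atom indices matched by the fragment (empty for inactives).
    """
    params = params or GenParams()
    rng = np.random.default_rng(params.seed)
    pattern = Chem.MolFromSmiles(params.planted_motif)

    ids, smiles, labels, motif_atoms = [], [], [], []

    for i in range(params.n_active):
        for _ in range(params.max_retries):
            scaffold = generate_molecule(rng, params)
            planted = _attach_fragment(rng, scaffold, params.planted_motif, params)
            if planted is None:
                continue
            matches = mol_from_smiles(planted).GetSubstructMatches(pattern)
            if matches:
                break
        else:
            raise GenerationError(
                f"could not plant fragment {params.planted_motif!r} after {params.max_retries} attempts"
            )
        ids.append(f"active_{i:04d}")
        smiles.append(planted)
        labels.append(1)
        motif_atoms.append(tuple(sorted({a for m in matches for a in m})))

    for i in range(params.n_inactive):
        for _ in range(params.max_retries):
            cand = generate_molecule(rng, params)
            if not mol_from_smiles(cand).GetSubstructMatches(pattern):
                break
        else:
            raise GenerationError(
                f"could not generate a motif-free inactive for fragment {params.planted_motif!r}; "
                "fragment may be degenerate"
            )
        ids.append(f"inactive_{i:04d}")
        smiles.append(cand)
        labels.append(0)
        motif_atoms.append(())

    logger.info("generated %d actives + %d inactives", params.n_active, params.n_inactive)
    return SyntheticDataset(ids, smiles, np.asarray(labels, dtype=float), motif_atoms, params)
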