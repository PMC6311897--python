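"""SMILES feature matrices.

Each token of a canonical SMILES string becomes one 42-dimensional row:
columns 0-20 describe an atom (type one-hot, H count, degree, formal charge,
total valence, ring membership, aromaticity, CIP chirality, hybridization),
columns 21-41 one-hot encode the 21 structural SMILES symbols.  The rows are
stacked in token order and zero-padded to a fixed length (400 by default),
giving the ``(max_len, 42)`` input of the convolutional network.  Atom
properties are perceived with RDKit on the canonical molecule; the i-th ATOM
token is aligned to the i-th atom emitted by the canonical SMILES writer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem.rdchem import HybridizationType
from sklearn.base import BaseEstimator, TransformerMixin

from .tokenizer import (
    GrammarClass,
    SmilesParseError,
    Token,
    TokenKind,
    TokenSequence,
    _kekule_canonical,
    mol_from_smiles,
    tokenize,
)

logger = logging.getLogger(__name__)

N_FEATURES = 42
N_ATOM_FEATURES = 21
N_GRAMMAR_FEATURES = 21

_ATOM_TYPES = ("H", "C", "O", "N")  # + "other"
_HYBRIDIZATIONS = (
    HybridizationType.S,
    HybridizationType.SP,
    HybridizationType.SP2,
    HybridizationType.SP3,
    HybridizationType.SP3D,
    HybridizationType.SP3D2,
)  # + other

#: Human-readable column names, atom block then grammar block.
FEATURE_NAMES: tuple[str, ...] = (
    "atom_H", "atom_C", "atom_O", "atom_N", "atom_other",
    "num_hs", "degree", "charge", "valence", "in_ring", "aromatic",
    "chirality_R", "chirality_S", "chirality_other",
    "hyb_s", "hyb_sp", "hyb_sp2", "hyb_sp3", "hyb_sp3d", "hyb_sp3d2", "hyb_other",
    "branch_start", "branch_end", "bracket_open", "bracket_close",
    "ionic_bond", "aromatic_bond", "double_bond", "triple_bond",
    "cis", "trans", "chirality", "cation", "anion",
    "ion_charge_2", "ion_charge_3", "ion_charge_4", "ion_charge_5",
    "ion_charge_6", "ion_charge_7", "ring_start", "ring_end",
)
assert len(FEATURE_NAMES) == N_FEATURES


class FeaturizationError(ValueError):
    pass


class OverflowError_(FeaturizationError):
    """Token sequence longer than the configured matrix length."""


@dataclass(frozen=True)
class AtomFeatures:
    """The 21 per-atom descriptors of the atom block."""

    atom_type: str          # one of H, C, O, N, other
    num_hs: int
    degree: int             # connectivity degree (bonded heavy neighbours)
    charge: int
    valence: int
    in_ring: bool
    aromatic: bool
    chirality: str          # R, S, or other
    hybridization: str      # s, sp, sp2, sp3, sp3d, sp3d2, other

    def to_vector(self) -> np.ndarray:
        v = np.zeros(N_ATOM_FEATURES, dtype=np.float32)
        v[_ATOM_TYPES.index(self.atom_type) if self.atom_type in _ATOM_TYPES else 4] = 1.0
        v[5] = self.num_hs
        v[6] = self.degree
        v[7] = self.charge
        v[8] = self.valence
        v[9] = float(self.in_ring)
        v[10] = float(self.aromatic)
        v[11 + {"R": 0, "S": 1}.get(self.chirality, 2)] = 1.0
        hyb_names = ("s", "sp", "sp2", "sp3", "sp3d", "sp3d2")
        v[14 + (hyb_names.index(self.hybridization) if self.hybridization in hyb_names else 6)] = 1.0
        return v


@dataclass
class FeaturizerConfig:
    max_len: int = 400
    on_overflow: str = "error"  # or "truncate"

    def __post_init__(self):
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if self.on_overflow not in ("error", "truncate"):
            raise ValueError(f"unknown overflow policy {self.on_overflow!r}")


@dataclass
class FeatureMatrix:
    values: np.ndarray          # (max_len, 42)
    valid_len: int
    compound_id: str = ""
    tokens: TokenSequence | None = None

    def __post_init__(self):
        assert self.values.ndim == 2 and self.values.shape[1] == N_FEATURES


def compute_atom_features(mol: Chem.Mol, atom_index: int) -> AtomFeatures:
    """Perceive the atom-block descriptors for one atom of a molecule.

    ``atom_index`` is the RDKit atom index (use :func:`featurize` for the
    token-ordinal to atom-index alignment).  CIP codes are assigned on the
    molecule once, lazily.
    """
    if not 0 <= atom_index < mol.GetNumAtoms():
        raise IndexError(f"atom index {atom_index} out of range (molecule has {mol.GetNumAtoms()})")
    if not mol.HasProp("_scfpCIPDone"):
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        mol.SetProp("_scfpCIPDone", "1")
    atom = mol.GetAtomWithIdx(atom_index)
    hyb_map = {h: n for h, n in zip(_HYBRIDIZATIONS, ("s", "sp", "sp2", "sp3", "sp3d", "sp3d2"))}
    return AtomFeatures(
        atom_type=atom.GetSymbol() if atom.GetSymbol() in _ATOM_TYPES else "other",
        num_hs=atom.GetTotalNumHs(),
        degree=atom.GetDegree(),
        charge=atom.GetFormalCharge(),
        valence=atom.GetTotalValence(),
        in_ring=atom.IsInRing(),
        aromatic=atom.GetIsAromatic(),
        chirality=atom.GetProp("_CIPCode") if atom.HasProp("_CIPCode") else "other",
        hybridization=hyb_map.get(atom.GetHybridization(), "other"),
    )


def encode_token(token: Token, atom_features: AtomFeatures | None = None) -> np.ndarray:
    """One 42-vector: atom block filled for ATOM tokens, a single grammar
    one-hot bit for GRAMMAR tokens."""
    v = np.zeros(N_FEATURES, dtype=np.float32)
    if token.kind is TokenKind.ATOM:
        if atom_features is None:
            raise FeaturizationError("ATOM token requires atom features")
        v[:N_ATOM_FEATURES] = atom_features.to_vector()
    else:
        if atom_features is not None:
            raise FeaturizationError("GRAMMAR token takes no atom features")
        if token.grammar_class is GrammarClass.NONE:
            raise FeaturizationError(f"grammar token {token.text!r} has no class")
        v[N_ATOM_FEATURES + token.grammar_class.value] = 1.0
    return v


def featurize(
    smiles: str,
    config: FeaturizerConfig | None = None,
    compound_id: str = "",
) -> FeatureMatrix:
    """Canonicalize, tokenize and encode a SMILES string into a padded
    ``(max_len, 42)`` feature matrix.

    Deterministic: the same input always yields a bit-identical matrix.
    """
    config = config or FeaturizerConfig()
    mol = mol_from_smiles(smiles)
    canonical, order = _kekule_canonical(mol)
    seq = tokenize(canonical)
    if len(seq) > config.max_len:
        if config.on_overflow == "error":
            raise OverflowError_(
                f"compound {compound_id or smiles!r}: {len(seq)} tokens exceed max_len={config.max_len}"
            )
        seq = TokenSequence(canonical, list(seq.tokens[: config.max_len]))
    mat = np.zeros((config.max_len, N_FEATURES), dtype=np.float32)
    for row, token in enumerate(seq):
        if token.kind is TokenKind.ATOM:
            feats = compute_atom_features(mol, order[token.atom_ordinal])
            mat[row] = encode_token(token, feats)
        else:
            mat[row] = encode_token(token)
    return FeatureMatrix(mat, valid_len=len(seq), compound_id=compound_id, tokens=seq)


def featurize_dataset(
    compounds,
    config: FeaturizerConfig | None = None,
    on_invalid: str = "skip",
):
    """Featurize ``(id, smiles[, label])`` records into stacked arrays.

    Returns ``(X, y, ids, valid_lens)`` where X is ``(n, max_len, 42)`` and y
    is a float array with NaN for missing labels.  Invalid entries are
    skipped with a warning (``on_invalid='skip'``) or abort (``'error'``).
    """
    compounds = list(compounds)
    if not compounds:
        raise FeaturizationError("empty compound list")
    config = config or FeaturizerConfig()
    mats, labels, ids = [], [], []
    n_skipped = 0
    for rec in compounds:
        cid, smiles, label = (*rec, None)[:3] if len(rec) >= 2 else (None, None, None)
        try:
            fm = featurize(smiles, config, compound_id=str(cid))
        except (SmilesParseError, FeaturizationError) as exc:
            if on_invalid == "error":
                raise
            n_skipped += 1
            warnings.warn(f"skipping compound {cid!r}: {exc}", stacklevel=2)
            continue
        mats.append(fm)
        labels.append(np.nan if label is None else float(label))
        ids.append(str(cid))
    if not mats:
        raise FeaturizationError("no valid compounds in dataset")
    logger.info("featurized %d compounds (%d skipped)", len(mats), n_skipped)
    X = np.stack([m.values for m in mats])
    valid_lens = np.array([m.valid_len for m in mats], dtype=np.int64)
    return X, np.asarray(labels), ids, valid_lens


def matrix_to_table(fm: FeatureMatrix):
    """Flat tabular view (one row per token, named columns) for inspection."""
    import pandas as pd

    df = pd.DataFrame(fm.values[: fm.valid_len], columns=list(FEATURE_NAMES))
    if fm.tokens is not None:
        df.insert(0, "token", [t.text for t in fm.tokens][: fm.valid_len])
    return df


class SmilesFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer from SMILES strings to feature matrices.

    Parameters
    ----------
    max_len : int
        Fixed number of rows of each matrix (sequences are zero-padded).
    on_overflow : {'error', 'truncate'}
        What to do when a SMILES has more tokens than ``max_len``.

    ``transform`` returns an ``(n, max_len, 42)`` float array.  Use
    :meth:`valid_lengths` for the unpadded lengths when masking matters.
    """

    def __init__(self, max_len: int = 400, on_overflow: str = "error"):
        self.max_len = max_len
        self.on_overflow = on_overflow

    def _config(self) -> FeaturizerConfig:
        return FeaturizerConfig(max_len=self.max_len, on_overflow=self.on_overflow)

    def fit(self, X, y=None):
        self._config()  # validates params
        self.n_features_in_ = N_FEATURES
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        return np.stack([featurize(s, cfg).values for s in X])

    def valid_lengths(self, X) -> np.ndarray:
        cfg = self._config()
        return np.array([featurize(s, cfg).valid_len for s in X], dtype=np.int64)
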