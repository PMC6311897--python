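"""Chemical-motif detection and chemical-space utilities.

Each SCFP dimension is the global-max activation of one second-stage filter,
so a large value points at one position of one compound.  To compare filters
on a common scale, per-filter means and variances of the global-max values
are estimated over a reference dataset and fingerprints are Z-scored; a
filter firing above the two-sided 99% normal critical value (2.58) on a
compound is called a motif, and its activation argmax is traced back through
the network to a SMILES token span and the atoms inside it.  Z-scoring is
used only for motif calling, never for training or prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .featurizer import FeatureMatrix, FeaturizerConfig, featurize
from .model import SCFPNetwork, receptive_field_bound, traceback_span
from .tokenizer import TokenKind, canonicalize
from .training import compute_scfp_batch

logger = logging.getLogger(__name__)

#: Two-sided 99% standard-normal critical value (0.995 quantile, 2 d.p.).
MOTIF_Z_THRESHOLD = 2.58


@dataclass
class FilterStats:
    """Per-filter mean/variance of pre-normalized global-max values."""

    mean: np.ndarray
    var: np.ndarray
    n_compounds: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if self.mean.shape != self.var.shape:
            raise ValueError("mean/var shape mismatch")
        if np.any(self.var < 0):
            raise ValueError("negative variance")

    @property
    def zero_variance_filters(self) -> np.ndarray:
        """Indices of degenerate (dead/constant) filters, excluded from calling."""
        return np.flatnonzero(self.var <= 0)


@dataclass
class MotifHit:
    filter_index: int
    z_score: float
    input_span: tuple[int, int]  # [start, end) token rows
    smiles_substring: str
    atom_indices: tuple[int, ...]  # canonical-molecule atom indices
    compound_id: str = ""


def fit_filter_stats(model: SCFPNetwork, X, valid_lens=None) -> FilterStats:
    """Mean and variance of each filter's global-max value over a dataset."""
    X = np.asarray(X)
    if len(X) == 0:
        raise ValueError("empty reference dataset")
    scfp = compute_scfp_batch(model, X, valid_lens)
    stats = FilterStats(scfp.mean(axis=0), scfp.var(axis=0), n_compounds=len(X))
    if stats.zero_variance_filters.size:
        logger.warning("%d zero-variance filters flagged", stats.zero_variance_filters.size)
    return stats


def normalize_scfp(scfp: np.ndarray, stats: FilterStats) -> np.ndarray:
    """Z-score a fingerprint (or a stack of them) with reference statistics.

    Zero-variance dimensions get Z = 0 rather than infinities.
    """
    scfp = np.asarray(scfp, dtype=float)
    if scfp.shape[-1] != stats.mean.shape[0]:
        raise ValueError(f"dimension mismatch: scfp {scfp.shape[-1]} vs stats {stats.mean.shape[0]}")
    sd = np.sqrt(stats.var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (scfp - stats.mean) / sd
    return np.where(sd > 0, z, 0.0)


def detect_motifs(
    model: SCFPNetwork,
    compound: str | FeatureMatrix,
    stats: FilterStats,
    threshold: float = MOTIF_Z_THRESHOLD,
    max_len: int | None = None,
    compound_id: str = "",
) -> list[MotifHit]:
    """Call motifs on one compound: filters with Z above ``threshold``,
    traced back to the argmax position's input span.

    Ties at the argmax resolve to the lowest sequence position.  Hits are
    sorted by Z descending.  Spans are clipped to the unpadded token rows;
    reported atom indices refer to the canonical molecule.
    """
    if isinstance(compound, FeatureMatrix):
        fm = compound
    else:
        cfg = FeaturizerConfig(max_len=max_len) if max_len else FeaturizerConfig()
        fm = featurize(canonicalize(compound), cfg, compound_id=compound_id)
    if fm.tokens is None:
        raise ValueError("feature matrix lacks token annotations; featurize from SMILES")
    if not model.trained:
        logger.warning("detecting motifs with an untrained model; hits are not meaningful")

    out = model.forward(fm.values[None], valid_lens=np.array([fm.valid_len]))
    scfp = out["scfp"][0]
    if scfp.shape[0] != stats.mean.shape[0]:
        raise ValueError("model/stats dimension mismatch")
    z = normalize_scfp(scfp, stats)
    argmax = out["gmax_idx"][0]  # lowest position on ties

    # atom ordinal -> canonical molecule atom index
    from .tokenizer import _kekule_canonical, mol_from_smiles

    order = _kekule_canonical(mol_from_smiles(fm.tokens.canonical_smiles))[1]

    hits = []
    for f in np.flatnonzero(z > threshold):
        pos = int(argmax[f])
        start, end = traceback_span(model.config, pos, input_len=fm.values.shape[0])
        end = min(end, fm.valid_len)
        toks = fm.tokens.tokens[start:end]
        hits.append(
            MotifHit(
                filter_index=int(f),
                z_score=float(z[f]),
                input_span=(start, end),
                smiles_substring="".join(t.text for t in toks),
                atom_indices=tuple(order[t.atom_ordinal] for t in toks if t.kind is TokenKind.ATOM),
                compound_id=compound_id or fm.compound_id,
            )
        )
    hits.sort(key=lambda h: -h.z_score)
    return hits


def write_motif_report(path, hits: list[MotifHit]):
    """Tab-separated motif report; one row per hit."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("compound_id\tfilter\tz\tspan_start\tspan_end\tsubstring\tatom_indices\n")
        for h in hits:
            fh.write(
                f"{h.compound_id}\t{h.filter_index}\t{h.z_score!r}\t{h.input_span[0]}\t"
                f"{h.input_span[1]}\t{h.smiles_substring}\t"
                f"{';'.join(map(str, h.atom_indices))}\n"
            )


# ---------------------------------------------------------------- space


def ecfp_fingerprints(smiles_list, n_bits: int = 1024, radius: int = 2) -> np.ndarray:
    """Circular (Morgan/ECFP-style) bit fingerprints for comparison plots."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = np.zeros((len(smiles_list), n_bits), dtype=np.float64)
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        out[i] = np.frombuffer(gen.GetFingerprint(mol).ToBitString().encode(), "u1") - ord("0")
    return out


def embed_chemical_space(fingerprints: np.ndarray, method: str = "mds", seed: int = 0) -> np.ndarray:
    """2-D embedding of a fingerprint matrix by metric MDS."""
    fingerprints = np.asarray(fingerprints, dtype=float)
    if fingerprints.ndim != 2 or fingerprints.shape[0] < 3:
        raise ValueError("need a 2-D fingerprint matrix with at least 3 rows")
    if method != "mds":
        raise ValueError(f"unknown embedding method {method!r}")
    from sklearn.manifold import MDS

    mds = MDS(n_components=2, random_state=seed, n_init=2, normalized_stress="auto")
    return mds.fit_transform(fingerprints)
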