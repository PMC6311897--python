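"""Filter statistics, Z-normalization, motif calling and traceback."""

import numpy as np
import pytest

from scfp import (
    FilterStats,
    MOTIF_Z_THRESHOLD,
    build_model,
    detect_motifs,
    ecfp_fingerprints,
    embed_chemical_space,
    fit_filter_stats,
    normalize_scfp,
    receptive_field_bound,
)
from scfp.estimator import _as_matrices
from scfp.model import ModelConfig
from scfp.motif import write_motif_report
from scfp.training import compute_scfp_batch

TINY = ModelConfig(conv1_filters=8, conv1_window=5, pool1_window=5,
                   conv2_filters=6, conv2_window=5, hidden_units=6)


@pytest.fixture(scope="module")
def tiny_net():
    return build_model(TINY, seed=11)


@pytest.fixture(scope="module")
def reference_matrices(small_dataset):
    return _as_matrices(small_dataset.smiles, 80)


class TestFilterStats:
    def test_matches_two_pass_oracle(self, tiny_net, reference_matrices):
        X, lens = reference_matrices
        stats = fit_filter_stats(tiny_net, X, lens)
        scfp = compute_scfp_batch(tiny_net, X, lens)
        # independent two-pass mean/variance
        mu = scfp.sum(axis=0) / len(scfp)
        var = ((scfp - mu) ** 2).sum(axis=0) / len(scfp)
        assert np.allclose(stats.mean, mu)
        assert np.allclose(stats.var, var)
        assert stats.n_compounds == len(X)

    def test_single_compound_zero_variance_flagged(self, tiny_net, reference_matrices):
        X, lens = reference_matrices
        stats = fit_filter_stats(tiny_net, X[:1], lens[:1])
        assert np.all(stats.var == 0)
        assert stats.zero_variance_filters.size == stats.mean.size

    def test_duplicated_dataset_same_mean(self, tiny_net, reference_matrices):
        X, lens = reference_matrices
        once = fit_filter_stats(tiny_net, X, lens)
        twice = fit_filter_stats(tiny_net, np.concatenate([X, X]), np.concatenate([lens, lens]))
        assert np.allclose(once.mean, twice.mean)

    def test_empty_dataset_raises(self, tiny_net):
        with pytest.raises(ValueError, match="empty"):
            fit_filter_stats(tiny_net, np.zeros((0, 40, 42)))


class TestNormalize:
    def test_mean_fingerprint_maps_to_zero(self):
        stats = FilterStats(np.array([1.0, 2.0]), np.array([4.0, 9.0]), 10)
        assert np.allclose(normalize_scfp(np.array([1.0, 2.0]), stats), 0.0)

    def test_one_sd_above_mean_is_z_one(self):
        stats = FilterStats(np.array([1.0, 2.0]), np.array([4.0, 9.0]), 10)
        z = normalize_scfp(np.array([3.0, 5.0]), stats)
        assert np.allclose(z, 1.0)

    def test_zero_variance_dimension_gets_zero(self):
        stats = FilterStats(np.array([1.0, 2.0]), np.array([0.0, 1.0]), 10)
        z = normalize_scfp(np.array([99.0, 3.0]), stats)
        assert z[0] == 0.0 and z[1] == 1.0

    def test_dimension_mismatch_raises(self):
        stats = FilterStats(np.zeros(3), np.ones(3), 5)
        with pytest.raises(ValueError, match="mismatch"):
            normalize_scfp(np.zeros(4), stats)

    def test_dataset_zscores_standardized(self, tiny_net, reference_matrices):
        X, lens = reference_matrices
        stats = fit_filter_stats(tiny_net, X, lens)
        z = normalize_scfp(compute_scfp_batch(tiny_net, X, lens), stats)
        live = stats.var > 0
        assert np.all(np.abs(z[:, live].mean(axis=0)) < 1e-10)
        assert np.all(np.abs(z[:, live].std(axis=0) - 1) < 1e-10)


class TestDetect:
    def test_fingerprint_at_mean_gives_no_hits(self, tiny_net, reference_matrices, small_dataset):
        X, lens = reference_matrices
        scfp = compute_scfp_batch(tiny_net, X[:1], lens[:1])[0]
        stats = FilterStats(scfp, np.ones_like(scfp), 1)  # mean == this compound
        hits = detect_motifs(tiny_net, small_dataset.smiles[0], stats, max_len=80)
        assert hits == []

    def test_threshold_monotonicity(self, tiny_net, reference_matrices, small_dataset):
        X, lens = reference_matrices
        stats = fit_filter_stats(tiny_net, X, lens)
        counts = [
            sum(
                len(detect_motifs(tiny_net, s, stats, threshold=t, max_len=80))
                for s in small_dataset.smiles[:10]
            )
            for t in (0.5, 1.5, 2.58)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_hits_sorted_and_spans_inside_valid_rows(self, tiny_net, reference_matrices, small_dataset):
        X, lens = reference_matrices
        stats = fit_filter_stats(tiny_net, X, lens)
        bound = receptive_field_bound(tiny_net.config)
        seen = 0
        for i, smi in enumerate(small_dataset.smiles):
            hits = detect_motifs(tiny_net, smi, stats, threshold=1.0, max_len=80)
            zs = [h.z_score for h in hits]
            assert zs == sorted(zs, reverse=True)
            for h in hits:
                s, e = h.input_span
                assert 0 <= s < e <= lens[i]
                assert e - s <= bound
                assert h.smiles_substring  # non-empty
                seen += 1
        assert seen > 0

    def test_deterministic_output(self, tiny_net, reference_matrices, small_dataset):
        X, lens = reference_matrices
        stats = fit_filter_stats(tiny_net, X, lens)
        a = detect_motifs(tiny_net, small_dataset.smiles[0], stats, threshold=0.5, max_len=80)
        b = detect_motifs(tiny_net, small_dataset.smiles[0], stats, threshold=0.5, max_len=80)
        assert a == b

    def test_stats_model_mismatch_raises(self, tiny_net, small_dataset):
        stats = FilterStats(np.zeros(99), np.ones(99), 5)
        with pytest.raises(ValueError, match="mismatch"):
            detect_motifs(tiny_net, small_dataset.smiles[0], stats, max_len=80)

    def test_atom_indices_refer_to_canonical_molecule(self, fitted_detector, planted_dataset):
        from rdkit import Chem

        i = int(np.flatnonzero(planted_dataset.labels == 1)[0])
        mol = Chem.MolFromSmiles(planted_dataset.smiles[i])
        for h in fitted_detector.detect(planted_dataset.smiles[i]):
            assert all(0 <= a < mol.GetNumAtoms() for a in h.atom_indices)

    def test_report_round_trip_columns(self, tmp_path, tiny_net, reference_matrices, small_dataset):
        X, lens = reference_matrices
        stats = fit_filter_stats(tiny_net, X, lens)
        hits = detect_motifs(tiny_net, small_dataset.smiles[0], stats, threshold=0.5,
                             max_len=80, compound_id="c0")
        path = tmp_path / "motifs.tsv"
        write_motif_report(path, hits)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == [
            "compound_id", "filter", "z", "span_start", "span_end", "substring", "atom_indices"
        ]
        assert len(lines) == 1 + len(hits)


class TestChemicalSpace:
    def test_three_equidistant_points(self):
        fp = np.eye(3)
        xy = embed_chemical_space(fp, seed=0)
        d = [np.linalg.norm(xy[i] - xy[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
        assert max(d) - min(d) < 0.05 * max(d)

    def test_duplicated_rows_coincide(self):
        fp = np.vstack([np.eye(3), np.eye(3)[0]])
        xy = embed_chemical_space(fp, seed=0)
        assert np.linalg.norm(xy[0] - xy[3]) < 1e-3 * np.abs(xy).max()

    def test_fewer_than_three_rows_raises(self):
        with pytest.raises(ValueError):
            embed_chemical_space(np.eye(2))

    def test_ecfp_shape_and_binary(self, small_dataset):
        fp = ecfp_fingerprints(small_dataset.smiles[:5])
        assert fp.shape == (5, 1024)
        assert set(np.unique(fp)) <= {0.0, 1.0}

    def test_trained_scfp_separates_labels_better_than_untrained(
        self, trained_classifier, planted_dataset
    ):
        from sklearn.metrics import silhouette_score

        smiles = planted_dataset.smiles[:60] + planted_dataset.smiles[-60:]
        labels = np.r_[planted_dataset.labels[:60], planted_dataset.labels[-60:]]
        trained_fp = trained_classifier.transform(smiles)
        untrained = build_model(trained_classifier.model_config(), seed=99)
        X, lens = _as_matrices(smiles, trained_classifier.max_len)
        untrained_fp = compute_scfp_batch(untrained, X, lens)
        s_trained = silhouette_score(embed_chemical_space(trained_fp, seed=0), labels)
        s_untrained = silhouette_score(embed_chemical_space(untrained_fp, seed=0), labels)
        assert s_trained > s_untrained
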