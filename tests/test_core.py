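"""Distances, confidences, precision conversion and the score pipeline."""

import numpy as np
import pytest

from ndamda.core import (
    AdjustedDistanceMatrix,
    ConfidenceVector,
    compute_distances,
    confidence_diseases,
    confidence_mirnas,
    precision_convert,
    predict_new_disease,
    score_all,
)
from ndamda.io import AssociationMatrix
from ndamda.similarity import SimilarityMatrix


def sim(values, prefix="n"):
    values = np.asarray(values, dtype=float)
    return SimilarityMatrix(values, [f"{prefix}{i}" for i in range(len(values))])


def adjacency(values):
    values = np.asarray(values)
    return AssociationMatrix(
        values,
        [f"m{i}" for i in range(values.shape[0])],
        [f"d{j}" for j in range(values.shape[1])],
    )


def dist_from_adjusted(adjusted, prefix="m"):
    adjusted = np.asarray(adjusted, dtype=float)
    n = len(adjusted)
    return AdjustedDistanceMatrix(
        raw=adjusted.copy(),
        sigma=np.ones(n),
        adjusted=adjusted,
        index=[f"{prefix}{i}" for i in range(n)],
    )


# ------------------------------------------------------------------ #
# independent brute-force re-implementation used as the oracle


def brute_force_scores(dm_adj, dd_adj, yv):
    """Pair-by-pair scoring with explicit loops and a naive sort."""
    n_m, n_d = yv.shape
    prm = np.full((n_m, n_d), np.nan)
    prd = np.full((n_m, n_d), np.nan)
    for j in range(n_d):
        known = [i for i in range(n_m) if yv[i, j]]
        if not known:
            continue
        conf = []
        for i in range(n_m):
            all_mean = sum(dm_adj[i, t] for t in range(n_m)) / n_m
            known_mean = sum(dm_adj[i, t] for t in known) / len(known)
            conf.append(all_mean - known_mean)
        for i in range(n_m):
            h = sum(1 for c in conf if c >= conf[i])
            prm[i, j] = len(known) / h
    for i in range(n_m):
        known = [j for j in range(n_d) if yv[i, j]]
        if not known:
            continue
        conf = []
        for j in range(n_d):
            all_mean = sum(dd_adj[j, t] for t in range(n_d)) / n_d
            known_mean = sum(dd_adj[j, t] for t in known) / len(known)
            conf.append(all_mean - known_mean)
        for j in range(n_d):
            h = sum(1 for c in conf if c >= conf[j])
            prd[i, j] = len(known) / h
    final = np.zeros((n_m, n_d))
    for i in range(n_m):
        for j in range(n_d):
            vals = [v for v in (prm[i, j], prd[i, j]) if not np.isnan(v)]
            final[i, j] = float(np.mean(vals)) if vals else 0.0
    return prm, prd, final


class TestComputeDistances:
    def test_two_by_two_hand_values(self):
        d = compute_distances(sim([[1, 0.5], [0.5, 1]]))
        np.testing.assert_allclose(d.raw, [[1, 2], [2, 1]])
        np.testing.assert_allclose(d.sigma, [1.5, 1.5])
        assert d.adjusted[0, 1] == pytest.approx(2 / 2.25, abs=1e-15)

    def test_identity_network(self):
        d = compute_distances(sim(np.ones((4, 4))))
        np.testing.assert_allclose(d.adjusted, 1.0)

    def test_scale_equivariance_and_score_invariance(self, rng):
        """Rescaling S by c rescales D_adj by exactly c (the sigma product
        contributes c^2 against the raw distance's 1/c), so every scale-free
        downstream quantity -- confidences up to a factor, hence ranks,
        precisions and final scores -- is unchanged."""
        s = rng.uniform(0.1, 1.0, size=(5, 5))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        yv = (rng.random((5, 4)) < 0.5).astype(int)
        yv[0, :] = 1  # keep every disease trainable
        yv[:, 0] = 1
        sd = rng.uniform(0.1, 1.0, size=(4, 4))
        sd = (sd + sd.T) / 2
        np.fill_diagonal(sd, 1.0)
        dd = compute_distances(sim(sd, "d"))
        base = compute_distances(sim(s, "m"))
        base_scores = score_all(base, dd, adjacency(yv)).final
        for c in (0.3, 0.9):
            scaled = compute_distances(sim(c * s, "m"))
            np.testing.assert_allclose(scaled.adjusted, c * base.adjusted, atol=1e-12)
            scaled_scores = score_all(scaled, dd, adjacency(yv)).final
            np.testing.assert_allclose(scaled_scores, base_scores, atol=1e-12)

    def test_epsilon_floors_zero_similarity(self):
        d = compute_distances(sim([[1, 0], [0, 1]]), epsilon=1e-6)
        assert np.isfinite(d.adjusted).all()
        assert d.raw[0, 1] == pytest.approx(1e6)

    def test_exclude_self_option(self):
        d = compute_distances(sim([[1, 0.5], [0.5, 1]]), include_self=False)
        np.testing.assert_allclose(d.sigma, [2.0, 2.0])


class TestConfidence:
    def test_hand_value(self):
        adj = np.array([[0.5, 1.0, 2.0], [1.0, 0.5, 1.5], [2.0, 1.5, 0.5]])
        Y = adjacency([[0], [0], [1]])  # known set {m2}
        c = confidence_mirnas(dist_from_adjusted(adj), Y, "d0")
        assert c.values[0] == pytest.approx(3.5 / 3 - 2.0, abs=1e-12)
        assert c.richness == 1

    def test_known_set_everything_gives_zero(self):
        adj = np.array([[0.5, 1.0], [1.0, 0.5]])
        Y = adjacency([[1], [1]])
        c = confidence_mirnas(dist_from_adjusted(adj), Y, "d0")
        np.testing.assert_allclose(c.values, 0.0, atol=1e-15)

    def test_disease_side_hand_value(self):
        adj = np.array([[0.5, 1.0, 3.0], [1.0, 0.5, 2.0], [3.0, 2.0, 0.5]])
        Y = adjacency([[0, 0, 1]])  # miRNA m0's known diseases: {d2}
        c = confidence_diseases(dist_from_adjusted(adj, "d"), Y, "m0")
        assert c.values[0] == pytest.approx(4.5 / 3 - 3.0, abs=1e-12)

    def test_richness_zero_is_an_error(self):
        adj = np.eye(2)
        Y = adjacency([[0], [0]])
        with pytest.raises(ValueError, match="richness"):
            confidence_mirnas(dist_from_adjusted(adj), Y, "d0")

    def test_shrinking_known_distance_raises_confidence(self, rng):
        adj = rng.uniform(0.5, 2.0, size=(4, 4))
        adj = (adj + adj.T) / 2
        Y = adjacency([[0], [0], [0], [1]])
        base = confidence_mirnas(dist_from_adjusted(adj.copy()), Y, "d0").values[0]
        closer = adj.copy()
        closer[0, 3] -= 0.2
        closer[3, 0] -= 0.2
        bumped = confidence_mirnas(dist_from_adjusted(closer), Y, "d0").values[0]
        assert bumped > base

    def test_mirna_disease_symmetry_under_transposition(self, rng):
        adj = rng.uniform(0.5, 2.0, size=(3, 3))
        adj = (adj + adj.T) / 2
        yv = (rng.random((3, 3)) < 0.5).astype(int)
        yv[:, 0] = [1, 0, 1]
        Y = adjacency(yv)
        Yt = AssociationMatrix(yv.T, [f"m{i}" for i in range(3)], [f"d{j}" for j in range(3)])
        a = confidence_mirnas(dist_from_adjusted(adj), Y, "d0").values
        b = confidence_diseases(dist_from_adjusted(adj, "d"), Yt, "m0").values
        np.testing.assert_allclose(a, b, atol=1e-14)

    def test_invariant_under_rowwise_constant_shift(self, rng):
        adj = rng.uniform(0.5, 2.0, size=(5, 5))
        Y = adjacency((rng.random((5, 2)) < 0.5).astype(int))
        Y.values[0, 0] = 1  # ensure richness >= 1
        base = confidence_mirnas(dist_from_adjusted(adj.copy()), Y, "d0").values
        shifted = adj.copy()
        shifted[2, :] += 3.7  # both means of row 2 shift equally
        out = confidence_mirnas(dist_from_adjusted(shifted), Y, "d0").values
        np.testing.assert_allclose(base, out, atol=1e-12)


class TestPrecisionConvert:
    def _vec(self, values, richness):
        return ConfidenceVector(
            context="d", values=np.asarray(values, dtype=float),
            richness=richness, index=[f"m{i}" for i in range(len(values))],
        )

    def test_distinct_confidences(self):
        prec = precision_convert(self._vec([4.0, 3.0, 2.0, 1.0], richness=2))
        np.testing.assert_allclose(prec, [2 / 1, 2 / 2, 2 / 3, 2 / 4])

    def test_alignment_to_original_order(self):
        prec = precision_convert(self._vec([1.0, 4.0, 2.0], richness=1))
        np.testing.assert_allclose(prec, [1 / 3, 1 / 1, 1 / 2])

    def test_full_tie_shares_worst_rank(self):
        prec = precision_convert(self._vec([0.5] * 5, richness=2))
        np.testing.assert_allclose(prec, 2 / 5)

    def test_nonincreasing_in_rank(self, rng):
        values = rng.normal(size=20).round(1)  # rounding forces some ties
        conf = self._vec(values, richness=3)
        prec = precision_convert(conf)
        order = np.argsort(-values, kind="stable")
        assert (np.diff(prec[order]) <= 1e-15).all()

    def test_standard_precision_variant(self):
        conf = self._vec([4.0, 3.0, 2.0, 1.0], richness=2)
        known = np.array([1, 0, 1, 0], dtype=bool)
        prec = precision_convert(conf, standard=True, known=known)
        np.testing.assert_allclose(prec, [1 / 1, 1 / 2, 2 / 3, 2 / 4])


class TestScoreAll:
    @pytest.mark.parametrize("shape, density, seed", [
        ((5, 4), 0.4, 0),
        ((10, 10), 0.25, 1),
        ((7, 3), 0.5, 2),
    ])
    def test_matches_brute_force(self, shape, density, seed):
        rng = np.random.default_rng(seed)
        yv = (rng.random(shape) < density).astype(int)
        dm = rng.uniform(0.2, 3.0, size=(shape[0], shape[0]))
        dm = (dm + dm.T) / 2
        dd = rng.uniform(0.2, 3.0, size=(shape[1], shape[1]))
        dd = (dd + dd.T) / 2
        Y = adjacency(yv)
        out = score_all(dist_from_adjusted(dm), dist_from_adjusted(dd, "d"), Y)
        prm, prd, final = brute_force_scores(dm, dd, yv)
        np.testing.assert_allclose(out.precision_m, prm, atol=1e-12)
        np.testing.assert_allclose(out.precision_d, prd, atol=1e-12)
        np.testing.assert_allclose(out.final, final, atol=1e-12)

    def test_final_is_mean_of_sides(self):
        yv = np.array([[1, 0], [0, 1]])
        rng = np.random.default_rng(5)
        dm = np.eye(2) + rng.random((2, 2)); dm = (dm + dm.T) / 2
        dd = np.eye(2) + rng.random((2, 2)); dd = (dd + dd.T) / 2
        out = score_all(dist_from_adjusted(dm), dist_from_adjusted(dd, "d"), adjacency(yv))
        np.testing.assert_allclose(
            out.final, (out.precision_m + out.precision_d) / 2, atol=1e-15
        )

    def test_column_order_follows_confidence_given_equal_other_side(self, rng):
        yv = (rng.random((8, 5)) < 0.4).astype(int)
        yv[:, 0] = [1, 1, 0, 0, 0, 0, 0, 0]
        dm = rng.uniform(0.2, 2.0, size=(8, 8)); dm = (dm + dm.T) / 2
        dd = rng.uniform(0.2, 2.0, size=(5, 5)); dd = (dd + dd.T) / 2
        Y = adjacency(yv)
        out = score_all(dist_from_adjusted(dm), dist_from_adjusted(dd, "d"), Y)
        conf = confidence_mirnas(dist_from_adjusted(dm), Y, "d0").values
        col = out.precision_m[:, 0]
        # precision within a disease column is a monotone transform of confidence
        for i in range(8):
            for k in range(8):
                if conf[i] > conf[k]:
                    assert col[i] >= col[k]


class TestPredictNewDisease:
    def test_output_contract(self, small_bundle):
        from ndamda import NDAMDA

        Y = small_bundle["adjacency"]
        model = NDAMDA(Y, small_bundle["functional_similarity"], small_bundle["descriptors"])
        res = model.fit()
        disease = Y.disease_index[0]
        ranking = res.predict_new_disease(disease)
        assert len(ranking) == Y.n_mirnas
        assert (ranking.to_numpy()[:-1] >= ranking.to_numpy()[1:]).all()

    def test_requires_masked_column(self):
        yv = np.array([[1, 1], [0, 1]])
        dm = np.ones((2, 2)); dd = np.ones((2, 2))
        with pytest.raises(ValueError, match="known associations"):
            predict_new_disease(
                dist_from_adjusted(dm), dist_from_adjusted(dd, "d"),
                adjacency(yv), "d0",
            )

    def test_masking_leaves_other_columns_unchanged_with_frozen_kernels(self, small_bundle):
        Y = small_bundle["adjacency"]
        from ndamda import NDAMDA

        model = NDAMDA(Y, small_bundle["functional_similarity"], small_bundle["descriptors"])
        dist_m, dist_d = model._distances_for(Y)
        full = score_all(dist_m, dist_d, Y)
        j = 0
        pairs = [(int(i), j) for i in np.nonzero(Y.values[:, j])[0]]
        masked = model._masked(pairs)
        out = score_all(dist_m, dist_d, masked)
        keep = [c for c in range(Y.n_diseases) if c != j]
        np.testing.assert_allclose(
            out.precision_m[:, keep], full.precision_m[:, keep], atol=1e-14
        )

    def test_planted_truth_ranks_above_decoys(self, small_bundle):
        from ndamda import NDAMDA

        Y = small_bundle["adjacency"]
        clusters_m = small_bundle["mirna_clusters"]
        clusters_d = small_bundle["disease_clusters"]
        model = NDAMDA(Y, small_bundle["functional_similarity"], small_bundle["descriptors"])
        res = model.fit()
        j = 0
        disease = Y.disease_index[j]
        truth = set(np.nonzero(Y.values[:, j])[0])
        ranking = res.predict_new_disease(disease)
        pos = {m: r for r, m in enumerate(ranking.index, start=1)}
        truth_ranks = [pos[Y.mirna_index[i]] for i in truth]
        decoy_ranks = [pos[m] for k, m in enumerate(Y.mirna_index) if k not in truth]
        assert np.median(truth_ranks) < np.median(decoy_ranks)
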