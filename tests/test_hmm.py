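import itertools

import numpy as np
import pytest

from sigcontext.hmm import (
    MREModel,
    StateAnnotation,
    decode_states,
    enrichment_scores,
    posterior_marginals,
    sequence_loglik,
    state_correspondence,
    train_mre,
)
from sigcontext.intervals import BinnedTrack
from sigcontext.simulate import SimulationConfig, planted_hmm, simulate_tracks, tracks_to_binned


def brute_force_loglik(model: MREModel, obs: np.ndarray) -> float:
    """Marginal likelihood by explicit enumeration over all state paths."""
    T = obs.shape[0]
    K = model.n_states
    p = np.clip(model.emission, 1e-6, 1 - 1e-6)
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        prob = model.initial[path[0]]
        for t in range(1, T):
            prob *= model.transition[path[t - 1], path[t]]
        for t, s in enumerate(path):
            prob *= np.prod(np.where(obs[t] == 1, p[s], 1 - p[s]))
        total += prob
    return float(np.log(total))


def match_labels(decoded: np.ndarray, true: np.ndarray, K: int) -> float:
    """Best label-permutation agreement between two 1-based labelings."""
    best = 0.0
    for perm in itertools.permutations(range(1, K + 1)):
        mapped = np.array([perm[t - 1] for t in true])
        best = max(best, float((mapped == decoded).mean()))
    return best


class TestTrain:
    def test_k1_closed_form(self, rng):
        obs = (rng.random((500, 3)) < np.array([0.2, 0.5, 0.8])).astype(float)
        model = train_mre(obs, K=1)
        assert model.transition.tolist() == [[1.0]]
        assert np.allclose(model.emission[0], obs.mean(axis=0), atol=1e-9)

    def test_planted_two_state_emission_recovery(self):
        cfg = SimulationConfig(
            seed=7, n_chroms=1, chrom_length=200_000_00 // 100, bin_size=1000,
            n_states=2, n_features=2, emission_contrast=0.9, self_transition=0.9,
        )
        obs, paths, truth = simulate_tracks(cfg)  # 20k bins
        model = train_mre(obs, K=2, seed=0, restarts=2)
        # match states by emission distance, then compare parameters
        perms = list(itertools.permutations(range(2)))
        errs = [
            np.abs(model.emission[list(p)] - truth.emission).max() for p in perms
        ]
        assert min(errs) < 0.05

    def test_loglik_nondecreasing(self):
        cfg = SimulationConfig(seed=8, n_chroms=1, chrom_length=100_000,
                               n_states=3, n_features=4)
        obs, _, _ = simulate_tracks(cfg)
        model = train_mre(obs, K=3, seed=1, restarts=1)
        diffs = np.diff(model.train_log)
        assert (diffs >= -1e-8).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            train_mre(np.zeros((10, 2)), K=0)
        with pytest.raises(ValueError):
            train_mre([], K=2)
        with pytest.raises(ValueError):
            train_mre(np.full((10, 2), 0.5), K=2)  # non-binary

    def test_sequence_order_invariance(self):
        cfg = SimulationConfig(seed=9, n_chroms=2, chrom_length=50_000,
                               n_states=2, n_features=3)
        obs, _, _ = simulate_tracks(cfg)
        seqs = [obs["chr1"], obs["chr2"]]
        a = train_mre(seqs, K=2, seed=3, restarts=1)
        b = train_mre(seqs[::-1], K=2, seed=3, restarts=1)
        assert np.allclose(sorted(a.emission.ravel()), sorted(b.emission.ravel()), atol=1e-6)


class TestForwardBackward:
    @pytest.mark.parametrize("T,K,F", [(4, 2, 2), (6, 3, 2), (8, 2, 3)])
    def test_matches_brute_force_enumeration(self, T, K, F, rng):
        initial = rng.dirichlet(np.ones(K))
        transition = rng.dirichlet(np.ones(K), size=K)
        emission = rng.uniform(0.1, 0.9, size=(K, F))
        model = MREModel(initial, transition, emission)
        obs = rng.integers(0, 2, size=(T, F)).astype(float)
        assert sequence_loglik(model, obs) == pytest.approx(
            brute_force_loglik(model, obs), abs=1e-10
        )

    def test_posterior_rows_sum_to_one(self, rng):
        model = MREModel(
            np.array([0.5, 0.5]),
            np.array([[0.9, 0.1], [0.2, 0.8]]),
            np.array([[0.8, 0.1], [0.3, 0.7]]),
        )
        obs = rng.integers(0, 2, size=(50, 2)).astype(float)
        gamma = posterior_marginals(model, obs)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)


class TestDecode:
    def test_near_deterministic_emissions_recover_path(self, rng):
        K, F, T = 3, 3, 200
        emission = np.full((K, F), 0.001)
        for s in range(K):
            emission[s, s] = 0.999
        model = MREModel(np.full(K, 1 / K), np.full((K, K), 1 / K), emission)
        path = rng.integers(0, K, size=T)
        obs = np.zeros((T, F))
        obs[np.arange(T), path] = 1
        ann = decode_states(model, obs)
        assert (ann.labels["chr1"] == path + 1).all()

    def test_exact_tie_breaks_to_lower_state(self):
        # two indistinguishable states: posterior exactly 0.5/0.5 everywhere
        model = MREModel(
            np.array([0.5, 0.5]),
            np.array([[0.5, 0.5], [0.5, 0.5]]),
            np.array([[0.5], [0.5]]),
        )
        obs = np.ones((10, 1))
        ann = decode_states(model, obs)
        assert (ann.labels["chr1"] == 1).all()

    def test_feature_mismatch_rejected(self):
        model = MREModel(np.ones(1), np.ones((1, 1)), np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError, match="features"):
            decode_states(model, np.ones((5, 3)))


class TestEnrichment:
    def _annotation(self, labels: np.ndarray, K: int) -> StateAnnotation:
        return StateAnnotation("cell", 100, {"chr1": labels}, K)

    def test_everywhere_present_feature_is_one(self):
        ann = self._annotation(np.array([1, 1, 2, 2, 1]), 2)
        track = BinnedTrack("f", 100, {"chr1": np.ones(5, dtype=np.int8)})
        enr = enrichment_scores(ann, [track])
        assert np.allclose(enr, 1.0)

    def test_exclusive_feature_enrichment_is_reciprocal_share(self):
        # feature present exactly in state-1 bins, which occupy q = 1/4 of bins
        labels = np.array([1, 2, 2, 2] * 10)
        feat = (labels == 1).astype(np.int8)
        ann = self._annotation(labels, 2)
        enr = enrichment_scores(ann, [BinnedTrack("f", 100, {"chr1": feat})])
        assert enr[0, 0] == pytest.approx(4.0)
        assert enr[1, 0] == 0.0

    def test_random_annotation_enrichment_near_one(self, rng):
        n = 50_000
        labels = rng.integers(1, 4, size=n)
        feat = (rng.random(n) < 0.3).astype(np.int8)
        ann = self._annotation(labels, 3)
        enr = enrichment_scores(ann, [BinnedTrack("f", 100, {"chr1": feat})])
        # binomial sampling: se of a state mean ~ sqrt(p(1-p)/(n/3)) / p
        se = np.sqrt(0.3 * 0.7 / (n / 3)) / 0.3
        assert np.abs(enr - 1.0).max() < 3 * se

    def test_absent_feature_is_nan(self):
        ann = self._annotation(np.array([1, 2]), 2)
        enr = enrichment_scores(ann, [BinnedTrack("f", 100, {"chr1": np.zeros(2, dtype=np.int8)})])
        assert np.isnan(enr).all()


class TestCorrespondence:
    def test_self_comparison_is_identity(self, rng):
        labels = rng.integers(1, 5, size=1000)
        ann = StateAnnotation("c", 100, {"chr1": labels}, 4)
        M = state_correspondence(ann, ann)
        assert np.allclose(M, np.eye(4))

    def test_pairwise_merge_gives_one_hot_rows(self, rng):
        labels = rng.integers(1, 5, size=1000)  # states 1..4
        merged = (labels + 1) // 2  # {1,2}->1, {3,4}->2
        a = StateAnnotation("c", 100, {"chr1": labels}, 4)
        b = StateAnnotation("c", 100, {"chr1": merged}, 2)
        M = state_correspondence(a, b)
        expect = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        assert np.allclose(M, expect)

    def test_rows_sum_to_one(self, rng):
        a = StateAnnotation("c", 100, {"chr1": rng.integers(1, 4, 500)}, 3)
        b = StateAnnotation("c", 100, {"chr1": rng.integers(1, 6, 500)}, 5)
        M = state_correspondence(a, b)
        assert np.allclose(M.sum(axis=1), 1.0)

    def test_bin_size_mismatch_rejected(self, rng):
        a = StateAnnotation("c", 100, {"chr1": np.ones(10, dtype=int)}, 1)
        b = StateAnnotation("c", 200, {"chr1": np.ones(10, dtype=int)}, 1)
        with pytest.raises(ValueError):
            state_correspondence(a, b)


class TestPlantedRecovery:
    def test_five_state_six_feature_ari(self):
        """Planted 5-state, 6-feature segmentation recovered with ARI >= 0.8."""
        from sklearn.metrics import adjusted_rand_score

        cfg = SimulationConfig(
            seed=21, n_chroms=5, chrom_length=10_000_000, bin_size=10_000,
            n_states=5, n_features=6,
        )
        obs, paths, truth = simulate_tracks(cfg)  # 5 chromosomes x 1000 bins
        model = train_mre(obs, K=5, seed=2, restarts=2, max_iter=200)
        decoded = np.concatenate([
            decode_states(model, {c: obs[c]}, bin_size=cfg.bin_size).labels[c]
            for c in obs
        ])
        true = np.concatenate([paths[c] for c in obs])
        assert adjusted_rand_score(true, decoded) >= 0.8
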