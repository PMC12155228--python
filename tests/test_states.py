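"""Embedding/clustering, attending labeling, HMM, and state metrics."""

import numpy as np
import pandas as pd
import pytest

from ethophys import states


def _two_blob_features(rng, n=300, d=6, sep=10.0):
    X = rng.standard_normal((n, d))
    X[n // 2:] += sep
    truth = np.repeat([0, 1], n // 2)
    return X, truth


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(4)
    X, truth = _two_blob_features(rng)
    model = states.embed_and_cluster(X, eps=1.0, min_samples=8, seed=0)
    return X, truth, model


class TestEmbedCluster:
    def test_two_blobs_two_clusters(self, blobs):
        X, truth, model = blobs
        ids = model.cluster_ids
        assert len(set(ids[ids >= 0])) == 2
        # clusters align with the planted blobs
        for b in (0, 1):
            vals = ids[(truth == b) & (ids >= 0)]
            assert len(np.unique(vals)) == 1

    def test_same_seed_same_clusters(self, blobs):
        X, _, model = blobs
        model2 = states.embed_and_cluster(X, eps=1.0, min_samples=8, seed=0)
        np.testing.assert_array_equal(model.cluster_ids, model2.cluster_ids)

    def test_transform_maps_near_duplicates_to_same_cluster(self, blobs):
        X, truth, model = blobs
        assigned = model.assign(X[:10])
        assert (assigned == model.cluster_ids[:10]).mean() >= 0.9

    def test_overlay_export_round_trips(self, blobs, tmp_path):
        X, truth, model = blobs
        df = states.export_overlay(model, tmp_path / "overlay.csv",
                                   overlay=truth)
        back = pd.read_csv(tmp_path / "overlay.csv")
        assert len(back) == len(X)
        assert (back["cluster"] == model.cluster_ids).all()

    def test_too_few_rows_raises(self, rng):
        with pytest.raises(ValueError, match="n_neighbors"):
            states.embed_and_cluster(rng.standard_normal((10, 3)),
                                     n_neighbors=15)


class TestAttendingLabels:
    def test_rule_mode_threshold(self):
        ids = np.array([0] * 10 + [1] * 10)
        ev = np.array([1.0] * 10 + [0.0] * 10)
        lab = states.label_attending_clusters(ids, ev, theta=0.5)
        assert lab == {0: "Attending", 1: "NotAttending"}

    def test_theta_one_boundary_strict(self):
        ids = np.zeros(10, int)
        ev = np.ones(10)
        ev[3] = 0.0
        lab = states.label_attending_clusters(ids, ev, theta=1.0)
        assert lab[0] == "NotAttending"

    def test_manual_mode_requires_full_cover(self):
        ids = np.array([0, 1, -1])
        with pytest.raises(ValueError, match="1"):
            states.label_attending_clusters(ids, manual={0: "Attending"})


class TestFrameEnrichment:
    def test_identical_compositions_zero_enrichment(self):
        ids = np.tile([0, 1, -1], 10)
        groups = np.repeat(["A", "B"], 15)
        df = states.cluster_frame_enrichment(
            np.concatenate([ids[:15], ids[:15]]), groups
        )
        np.testing.assert_allclose(df["enrichment"], 0.0)

    def test_percentages_sum_to_100_and_enrichment_to_zero(self, rng):
        ids = rng.integers(-1, 3, 200)
        groups = np.where(rng.random(200) < 0.4, "Drug", "Vehicle")
        df = states.cluster_frame_enrichment(ids, groups)
        assert df["pct_Drug"].sum() == pytest.approx(100.0)
        assert df["pct_Vehicle"].sum() == pytest.approx(100.0)
        assert df["enrichment"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            states.cluster_frame_enrichment([0, 1], ["A", "A"])


def _plant_chain(rng, K, T, self_p=0.95):
    A = np.full((K, K), (1 - self_p) / (K - 1))
    np.fill_diagonal(A, self_p)
    cum = np.cumsum(A, axis=1)
    seq = np.empty(T, dtype=np.int64)
    seq[0] = 0
    u = rng.random(T)
    for t in range(1, T):
        seq[t] = np.searchsorted(cum[seq[t - 1]], u[t])
    return seq, A


class TestHMM:
    def test_two_state_parameter_recovery(self, rng):
        seq, A = _plant_chain(rng, 2, 20_000)
        means = np.array([[-2.0], [2.0]])
        cont = means[seq] + rng.standard_normal((len(seq), 1))
        model, _ = states.fit_state_hmm(cont=cont, fixed_k=2, seed=1)
        order = np.argsort(model.means[:, 0])
        P = model.transition[order][:, order]
        assert np.abs(P - A).sum(axis=1).max() < 0.1

    def test_loglik_monotone_over_em(self, rng):
        seq, _ = _plant_chain(rng, 3, 5_000)
        cont = np.eye(3)[seq] * 2 + rng.standard_normal((len(seq), 3))
        model, _ = states.fit_state_hmm(cont=cont, fixed_k=3, seed=0)
        diffs = np.diff(model.loglik_trace)
        assert (diffs >= -1e-6 * np.abs(model.loglik_trace[:-1])).all()

    def test_k1_equals_iid_fit(self, rng):
        """With one state the HMM log-likelihood is the iid bound."""
        x = rng.standard_normal((2_000, 2))
        model, _ = states.fit_state_hmm(cont=x, fixed_k=1, seed=0)
        from scipy.stats import norm

        mu, sd = x.mean(axis=0), x.std(axis=0)
        iid_ll = norm.logpdf(x, mu, sd).sum()
        assert model.loglik_trace[-1] == pytest.approx(iid_ll, rel=1e-3)

    def test_noiseless_emissions_decode_exactly(self, rng):
        seq, _ = _plant_chain(rng, 2, 3_000)
        cont = seq[:, None] * 10.0 + 0.01 * rng.standard_normal(
            (len(seq), 1)
        )
        model, _ = states.fit_state_hmm(cont=cont, fixed_k=2, seed=0)
        dec = states.match_states(model.decode(cont=cont), seq, 2)
        assert (dec == seq).mean() == 1.0

    def test_posterior_rows_sum_to_one(self, rng):
        seq, _ = _plant_chain(rng, 2, 1_000)
        cont = seq[:, None] + rng.standard_normal((len(seq), 1))
        model, _ = states.fit_state_hmm(cont=cont, fixed_k=2, seed=0)
        gamma, _ = model.posterior(cont=cont)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_unseen_syllable_maps_to_floor(self, rng):
        seq, _ = _plant_chain(rng, 2, 2_000)
        syl = seq.copy()  # alphabet {0, 1}
        model, _ = states.fit_state_hmm(syllables=syl, fixed_k=2, seed=0)
        dec = model.decode(syllables=np.array([0, 1, 7, 7]))
        assert len(dec) == 4  # no crash; unseen symbol handled

    def test_viterbi_and_posterior_agree_when_clean(self, rng):
        seq, _ = _plant_chain(rng, 2, 2_000)
        cont = seq[:, None] * 8.0 + 0.1 * rng.standard_normal((len(seq), 1))
        model, _ = states.fit_state_hmm(cont=cont, fixed_k=2, seed=0)
        a = model.decode(cont=cont, method="posterior")
        b = model.decode(cont=cont, method="viterbi")
        assert (a == b).mean() > 0.999

    def test_matches_hmmlearn_loglik_gaussian_case(self, rng):
        """Independent oracle: our scorer equals hmmlearn's on the same
        Gaussian-emission parameters."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        seq, A = _plant_chain(rng, 2, 1_000)
        cont = seq[:, None] * 3.0 + rng.standard_normal((len(seq), 1))
        model, _ = states.fit_state_hmm(cont=cont, fixed_k=2, seed=0)
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag",
                                   init_params="")
        ref.startprob_ = model.pi
        ref.transmat_ = model.transition
        ref.means_ = model.means
        ref.covars_ = model.vars
        assert model.score(cont=cont) == pytest.approx(ref.score(cont),
                                                       rel=1e-6)


class TestStateMetrics:
    def test_constant_sequence(self):
        m = states.state_metrics(np.zeros(100, int), K=1, fps=10.0)
        assert m.loc[0, "stickiness"] == 1.0
        assert m.loc[0, "time_fraction"] == 1.0
        assert m.loc[0, "mean_dwell_s"] == pytest.approx(10.0)

    def test_strict_alternation_zero_stickiness(self):
        seq = np.tile([0, 1], 50)
        m = states.state_metrics(seq, K=2)
        np.testing.assert_allclose(m["stickiness"], 0.0)

    def test_unvisited_state_flagged_nan(self):
        m = states.state_metrics(np.zeros(10, int), K=2)
        assert not m.loc[1, "visited"]
        assert np.isnan(m.loc[1, "stickiness"])

    def test_planted_self_transition_recovered(self, rng):
        seq, _ = _plant_chain(rng, 2, 100_000, self_p=0.9)
        m = states.state_metrics(seq, K=2)
        np.testing.assert_allclose(m["stickiness"], 0.9, atol=0.01)
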