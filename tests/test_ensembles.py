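"""PSTHs, responsiveness calls, profile clustering, overlap tables."""

import numpy as np
import pandas as pd
import pytest

from ethophys import ensembles, synth
from ethophys.core import CalciumSession, TrialTable


def _session_from_trials(dff, fs=10.0, onsets=(30.0, 60.0, 90.0)):
    return CalciumSession(
        dff=dff, fs=fs,
        event_tables={"ev": TrialTable(onsets=np.array(onsets),
                                       allowed_conditions=())},
    )


class TestComputePsth:
    def test_step_response_psth_value(self):
        """Flat baseline + deterministic step ⇒ PSTH equals step size in SD
        units."""
        fs = 10.0
        n = int(200 * fs)
        base = np.tile([0.0, 1.0], n // 2)  # sd 0.5, mean 0.5 everywhere
        dff = base.copy()
        onsets = [50.0, 100.0, 150.0]
        for onset in onsets:
            i0 = int(onset * fs)
            dff[i0:i0 + 150] += 1.0  # +2 baseline SDs
        sess = _session_from_trials(dff[None, :], onsets=onsets)
        psth, _, ts = ensembles.compute_psth(sess, "ev")
        post = (ts >= 0) & (ts < 15)
        assert psth[0, post].mean() == pytest.approx(2.0, abs=1e-9)

    def test_window_bin_count(self, calcium_population):
        _, sessions, _ = calcium_population
        psth, trial_z, ts = ensembles.compute_psth(sessions[0], "Attending")
        assert psth.shape[1] == 200  # 5 s pre + 15 s post at 10 Hz
        assert trial_z.shape[1] == sessions[0].n_neurons

    def test_pure_noise_psth_near_zero(self, rng):
        n_tr = 12
        onsets = 20.0 + 25.0 * np.arange(n_tr)
        dff = rng.standard_normal((1, int((onsets[-1] + 30) * 10)))
        sess = _session_from_trials(dff, onsets=onsets)
        # a 5 s z baseline keeps the per-trial baseline-mean error small,
        # so the PSTH grand mean is noise-limited
        psth, _, ts = ensembles.compute_psth(sess, "ev",
                                             z_baseline_s=(-5.0, 0.0))
        n_base = 50
        sd_trial = np.sqrt(1.0 / psth.shape[1] + 1.0 / n_base) * 1.2
        assert abs(psth.mean()) < 3.0 * sd_trial / np.sqrt(n_tr)

    def test_affine_invariance(self, calcium_population):
        """Scaling a neuron's raw trace leaves its PSTH unchanged."""
        _, sessions, _ = calcium_population
        s = sessions[0]
        psth1, _, _ = ensembles.compute_psth(s, "Attending")
        scaled = CalciumSession(dff=s.dff * 3.7, fs=s.fs,
                                animal_id=s.animal_id,
                                event_tables=s.event_tables)
        psth2, _, _ = ensembles.compute_psth(scaled, "Attending")
        np.testing.assert_allclose(psth1, psth2, atol=1e-9)

    def test_matched_trial_subsampling_deterministic(self, calcium_population):
        _, sessions, _ = calcium_population
        a = ensembles.compute_psth(sessions[0], "Attending", n_trials=8,
                                   seed=4)[0]
        b = ensembles.compute_psth(sessions[0], "Attending", n_trials=8,
                                   seed=4)[0]
        np.testing.assert_array_equal(a, b)


class TestResponsiveness:
    def test_planted_two_sd_response_excited(self, rng):
        n_tr, bins = 15, 200
        ts = (np.arange(bins) - 50) / 10.0
        z = rng.standard_normal((n_tr, 1, bins))
        z[:, 0, ts >= 0] += 2.0
        calls = ensembles.classify_responsiveness(z, ts)
        assert calls.loc[0, "call"] == "excited"
        assert calls.loc[0, "p"] < 0.001

    def test_response_equal_baseline_none(self):
        ts = (np.arange(200) - 50) / 10.0
        z = np.zeros((10, 1, 200))
        calls = ensembles.classify_responsiveness(z, ts)
        assert calls.loc[0, "call"] == "none"

    def test_too_few_trials_flagged(self, rng):
        ts = (np.arange(200) - 50) / 10.0
        z = rng.standard_normal((4, 1, 200))
        calls = ensembles.classify_responsiveness(z, ts)
        assert calls.loc[0, "call"] == "none" and calls.loc[0, "flagged"]

    def test_null_type1_rate_near_alpha(self, rng):
        ts = (np.arange(200) - 50) / 10.0
        z = rng.standard_normal((15, 400, 200))
        calls = ensembles.classify_responsiveness(z, ts)
        rate = (calls["call"] != "none").mean()
        assert 0.02 <= rate <= 0.09

    def test_inhibited_sign_from_response_window(self, rng):
        ts = (np.arange(200) - 50) / 10.0
        z = rng.standard_normal((15, 1, 200))
        z[:, 0, ts >= 0] -= 2.0
        calls = ensembles.classify_responsiveness(z, ts)
        assert calls.loc[0, "call"] == "inhibited"


class TestClusterProfiles:
    def test_two_archetypes_recovered(self, calcium_population):
        from sklearn.metrics import adjusted_rand_score

        cfg, sessions, truth = calcium_population
        profiles, arch = [], []
        for s in sessions:
            profiles.append(np.hstack([
                ensembles.compute_psth(s, ev)[0] for ev in cfg.event_types
            ]))
            arch.extend(truth["archetype_idx"][s.animal_id])
        assign = ensembles.cluster_profiles(np.vstack(profiles), 0.30)
        assert assign.n_clusters == 2
        assert adjusted_rand_score(arch, assign.labels) >= 0.9

    def test_cutoff_one_single_cluster(self, rng):
        X = rng.standard_normal((20, 50))
        assign = ensembles.cluster_profiles(X, cutoff_frac=1.0)
        assert assign.n_clusters == 1

    def test_duplicating_neurons_keeps_cluster_count(self, rng):
        X = np.vstack([rng.standard_normal((10, 30)),
                       rng.standard_normal((10, 30)) + 5 * np.sin(
                           np.linspace(0, 6, 30))])
        a1 = ensembles.cluster_profiles(X, 0.30)
        a2 = ensembles.cluster_profiles(np.vstack([X, X]), 0.30)
        assert a1.n_clusters == a2.n_clusters

    def test_permutation_equivariance(self, rng):
        X = rng.standard_normal((30, 40))
        X[15:] += 4.0 * np.cos(np.linspace(0, 3, 40))
        perm = rng.permutation(30)
        a = ensembles.cluster_profiles(X, 0.30)
        b = ensembles.cluster_profiles(X[perm], 0.30)
        # relabel-invariant comparison
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0

    def test_constant_profile_excluded(self, rng):
        X = rng.standard_normal((10, 30))
        X[3] = 2.0
        assign = ensembles.cluster_profiles(X, 0.30)
        assert assign.labels[3] == -1
        assert not assign.valid[3]


class TestEnrichmentOverlap:
    def test_single_cluster_full_enrichment(self):
        df = ensembles.cluster_enrichment(
            np.zeros(30, int), np.repeat(["SE", "OM", "TO"], 10)
        )
        for c in ("SE", "OM", "TO"):
            assert df[f"pct_{c}"].iloc[0] == 100.0

    def test_percentages_sum_to_100(self, rng):
        labels = rng.integers(0, 3, 90)
        conds = np.repeat(["SE", "OM", "TO"], 30)
        df = ensembles.cluster_enrichment(labels, conds)
        for c in ("SE", "OM", "TO"):
            assert df[f"pct_{c}"].sum() == pytest.approx(100.0)

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            ensembles.cluster_enrichment(np.zeros(0, int), np.array([]))

    def test_overlap_codes_and_chi2(self):
        def calls(seq):
            return pd.DataFrame({"call": seq})

        by_event = {
            "A": calls(["excited", "none", "inhibited"]),
            "P": calls(["excited", "none", "none"]),
        }
        codes = ensembles.overlap_classes(by_event)
        assert codes["code"].tolist() == ["A+P+", "A0P0", "A-P0"]
        res = ensembles.overlap_chi2({"SE": codes, "OM": codes})
        assert res["p"] == pytest.approx(1.0)

    def test_planted_overlap_fraction_recovered(self):
        """20% of neurons planted A+P+: estimate within binomial CI."""
        cfg = synth.CalciumSimConfig(
            n_animals=2, neurons_per_animal=100,
            archetypes={"AP": {"Attending": 2.0, "pinprick": 2.0},
                        "null": {}},
            proportions=(0.2, 0.8),
            event_types=("Attending", "pinprick"), seed=13,
        )
        sessions, truth = synth.gen_calcium_population(cfg)
        frac_hits = []
        for s in sessions:
            by_event = {}
            for ev in cfg.event_types:
                _, tz, ts = ensembles.compute_psth(s, ev)
                by_event[ev[0].upper()] = ensembles.classify_responsiveness(
                    tz, ts
                )
            codes = ensembles.overlap_classes(by_event)
            frac_hits.append((codes["code"] == "A+P+").mean())
        est = np.mean(frac_hits)
        ci = 1.96 * np.sqrt(0.2 * 0.8 / 200)
        assert abs(est - 0.2) < ci + 0.03

    def test_flow_table_counts(self):
        src = np.array([0, 0, 1, 1])
        tgt = np.array([0, 1, 1, 1])
        df = ensembles.flow_table(src, tgt)
        d = {(r.source, r.target): r.count for r in df.itertuples()}
        assert d == {(0, 0): 1, (0, 1): 1, (1, 1): 2}
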