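"""End-to-end property benchmarks on synthetic data with planted truth.

Each function runs one pipeline stage under its study conditions and
returns the measured quantities (agreement percentages, F1, recovery
errors, calibration rates, ...).  They double as the recomputation backend
for ``scripts/acceptance.py`` and as the substance of the acceptance-level
tests.  Problem sizes are the stated study conditions where those exist
(e.g. 50 000-frame state sequences, 100 000-frame stickiness runs, 1000
null neurons); session-length parameters that only set runtime (ITIs,
trials per session in calibration loops) use desk-scale values documented
in the methods note.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from . import alphaclass, decoding, ensembles, photometry, states, synth
from .core import ArenaGeometry, KeypointTrack, TrialTable


def _sub(seed, k):
    """Derive a stable 31-bit subseed."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# 1. NMS vs brute force
# ---------------------------------------------------------------------------

def brute_force_peaks(hm, kernel, threshold):
    """Exhaustive neighborhood-maximum scan (the independent NMS oracle)."""
    h, w = hm.shape
    r = kernel // 2
    cand = np.zeros((h, w), bool)
    for i in range(h):
        for j in range(w):
            nb = hm[max(0, i - r):i + r + 1, max(0, j - r):j + r + 1]
            if hm[i, j] >= threshold and hm[i, j] == nb.max():
                cand[i, j] = True
    lab, n = ndimage.label(cand, structure=np.ones((3, 3)))
    peaks = []
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(lab == comp)
        order = np.lexsort((cols, rows))
        i, j = int(rows[order[0]]), int(cols[order[0]])
        peaks.append((i, j, float(hm[i, j])))
    peaks.sort(key=lambda p: (-p[2], p[0], p[1]))
    return peaks


def nms_oracle_agreement(seed=0, n_maps=100, size=64, kernel=5,
                         threshold=0.5):
    """% of random heatmaps on which NMS equals the brute-force oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n_maps):
        hm = rng.random((size, size))
        if i % 3 == 0:
            hm = np.round(hm, 1)       # plateaus exercise the tie rule
        if alphaclass.nms_peaks(hm, kernel, threshold) == brute_force_peaks(
            hm, kernel, threshold
        ):
            agree += 1
    return {"agreement_pct": 100.0 * agree / n_maps, "n": n_maps}


# ---------------------------------------------------------------------------
# 2. detector fixture
# ---------------------------------------------------------------------------

def _detector_frames(rng, n, arena):
    """Random-pose frames: attending near the barrier, rest anywhere."""
    attend = rng.random(n) < 0.4
    torso = np.column_stack([
        rng.uniform(arena.barrier[0][0] + 10, arena.width - 10, n),
        rng.uniform(20, arena.height - 20, n),
    ])
    torso[attend, 0] = rng.uniform(arena.barrier[0][0] + 2,
                                   arena.barrier[0][0] + 20, attend.sum())
    heading = np.where(attend[:, None], [-1.0, 0.0], [0.7, 0.5])
    coords = np.repeat(torso[:, None, :], 9, axis=1)
    coords[:, 0] = torso + 14 * heading        # nose
    track = KeypointTrack(coords=coords)
    return track, attend


def detector_fixture(seed=0, n_train=200, n_test=100, epochs=30):
    """Train the desk-scale detector on synthetic frames; held-out F1."""
    rng = np.random.default_rng(seed)
    arena = ArenaGeometry()
    track, attend = _detector_frames(rng, n_train + n_test, arena)
    frames, labels = synth.gen_frames(track, attend, (64, 64), arena,
                                      seed=_sub(seed, 1))
    targets = alphaclass.make_heatmap_targets(labels, (64, 64), ["attending"],
                                              stride=4)
    full = np.zeros((len(frames), 1, 16, 16), np.float32)
    full[: targets.shape[0]] = targets
    model = alphaclass.train_detector(frames[:n_train], full[:n_train],
                                      epochs=epochs, seed=_sub(seed, 2))
    calls, etho = alphaclass.detect(frames[n_train:], model, threshold=0.5)
    ev = alphaclass.evaluate_detector(etho[:, 0], attend[n_train:])
    ev["n"] = n_test
    ev["final_loss"] = model.loss_curve[-1]
    return ev


# ---------------------------------------------------------------------------
# 3. ΔAttending group ordering
# ---------------------------------------------------------------------------

def attending_ordering(seed=0, n_reps=20, n_animals=10, n_trials=20,
                       iti_range_s=(24.0, 30.0), fps=30.0):
    """Group-mean total ΔAttending ordering under planted probabilities.

    Sessions are generated per animal with per-trial attending
    probabilities 0.6 / 0.4 / 0.2 for the three surrogate groups; the
    attending-state occupancy of the true state sequence is the ethogram,
    and the ordering of group-mean total ΔAttending is tallied over
    replicates.
    """
    probs = {"SE": 0.6, "OM": 0.4, "TO": 0.2}
    successes = 0
    for rep in range(n_reps):
        means = {}
        for gi, (g, p) in enumerate(probs.items()):
            totals = []
            for a in range(n_animals):
                cfg = synth.BehaviorSimConfig(
                    n_trials=n_trials, iti_range_s=iti_range_s, fps=fps,
                    trial_attend_p=p, condition=g,
                    seed=_sub(seed, rep * 1000 + gi * 100 + a),
                )
                _, trials, st, _ = synth.gen_behavior_session(cfg)
                etho = st == cfg.attending_state
                tc, kept = alphaclass.attending_timecourse(etho, trials, fps)
                totals.append(tc["total"].mean())
            means[g] = float(np.mean(totals))
        if means["SE"] > means["OM"] > means["TO"]:
            successes += 1
    return {"ordering_successes": successes, "n": n_reps, "last_means": means}


# ---------------------------------------------------------------------------
# 4./5. HMM recovery and stickiness
# ---------------------------------------------------------------------------

def _gen_hmm_data(rng, K=4, T=50_000, n_feat=7, alphabet=20, self_p=0.98):
    A = np.full((K, K), (1 - self_p) / (K - 1))
    np.fill_diagonal(A, self_p)
    seq = np.empty(T, dtype=np.int64)
    seq[0] = rng.integers(K)
    cum = np.cumsum(A, axis=1)
    u = rng.random(T)
    for t in range(1, T):
        seq[t] = np.searchsorted(cum[seq[t - 1]], u[t])
    means = rng.normal(0, 1.5, (K, n_feat))
    cont = means[seq] + rng.standard_normal((T, n_feat))
    sylp = rng.dirichlet(np.ones(alphabet) * 0.3, size=K)
    cums = np.cumsum(sylp, axis=1)[seq]
    syl = (rng.random(T)[:, None] > cums).sum(axis=1)
    flagp = rng.uniform(0.1, 0.9, (K, 2))
    flags = (rng.random((T, 2)) < flagp[seq]).astype(float)
    return seq, A, syl, flags, cont


def hmm_recovery(seed=0, n_reps=20, T=50_000, n_init=2):
    """K selection, transition recovery and decode accuracy on planted
    4-state chains."""
    from scipy.optimize import linear_sum_assignment

    k4, l1s, accs = 0, [], []
    for rep in range(n_reps):
        rng = np.random.default_rng(_sub(seed, 100 + rep))
        seq, A, syl, flags, cont = _gen_hmm_data(rng, T=T)
        _, table = states.fit_state_hmm(
            syllables=syl, flags=flags, cont=cont, k_range=range(2, 13),
            n_init=n_init, seed=_sub(seed, 200 + rep),
        )
        k_sel = int(table.loc[table["selected"], "K"].iloc[0])
        if k_sel == 4:
            k4 += 1
        model, _ = states.fit_state_hmm(
            syllables=syl, flags=flags, cont=cont, fixed_k=4,
            seed=_sub(seed, 300 + rep),
        )
        dec = model.decode(syl, flags, cont)
        accs.append(float((states.match_states(dec, seq, 4) == seq).mean()))
        conf = np.zeros((4, 4))
        np.add.at(conf, (dec, seq), 1)
        r, c = linear_sum_assignment(-conf)
        P = np.zeros((4, 4))
        for i, j in zip(r, c):
            for i2, j2 in zip(r, c):
                P[j, j2] = model.transition[i, i2]
        l1s.append(float(np.abs(P - A).sum(axis=1).max()))
    return {"k4_successes": k4, "n": n_reps,
            "max_row_l1": float(np.max(l1s)),
            "min_accuracy": float(np.min(accs))}


def stickiness_recovery(seed=0, T=100_000, self_p=0.9, K=3):
    """Stickiness estimate on a planted chain with known self-transition."""
    rng = np.random.default_rng(seed)
    A = np.full((K, K), (1 - self_p) / (K - 1))
    np.fill_diagonal(A, self_p)
    cum = np.cumsum(A, axis=1)
    seq = np.empty(T, dtype=np.int64)
    seq[0] = 0
    u = rng.random(T)
    for t in range(1, T):
        seq[t] = np.searchsorted(cum[seq[t - 1]], u[t])
    m = states.state_metrics(seq, K)
    est = float(m["stickiness"].mean())
    return {"stickiness": est, "planted": self_p, "n": T,
            "max_abs_err": float((m["stickiness"] - self_p).abs().max())}


# ---------------------------------------------------------------------------
# 6./7. photometry
# ---------------------------------------------------------------------------

def photometry_separation(seed=0, n_trials=24):
    """Artifact removal / transient retention / z-baseline exactness."""
    rng = np.random.default_rng(seed)
    trials = synth.make_trial_table(rng, n_trials, (40.0, 60.0))
    labels = rng.random(n_trials) < 0.5
    cfg = synth.PhotometrySimConfig(seed=_sub(seed, 1), base_amp_z=6.0,
                                    delta_z=3.0, bleach_amp=0.0)
    sess, truth = synth.gen_photometry(cfg, trials, labels)
    zm, coeffs, resid = photometry.preprocess_session(sess)
    art, tr = truth["artifact"], truth["transients"]
    c_art = np.dot(resid, art) / np.dot(art, art)
    removal = 1.0 - (c_art / cfg.artifact_gain) ** 2
    trc = tr - tr.mean()
    retention = np.dot(resid - resid.mean(), trc) / np.dot(trc, trc)
    b = (zm.time_s >= -1.0) & (zm.time_s < 0.0)
    base = zm.z[:, b]
    return {
        "artifact_removal_pct": float(100 * removal),
        "transient_retention_pct": float(100 * min(retention, 1.0)),
        "baseline_mean_abs_max": float(np.abs(base.mean(axis=1)).max()),
        "baseline_sd_dev_max": float(
            np.abs(base.std(axis=1, ddof=0) - 1).max()
        ),
        "slope": coeffs["slope"],
        "n": n_trials,
    }


def _rf_session_auc(seed, delta_z, n_trials=20, n_trees=100,
                    decode_window=(0.0, 5.0), iti_range=(26.0, 30.0)):
    rng = np.random.default_rng(seed)
    trials = synth.make_trial_table(rng, n_trials, iti_range)
    labels = np.zeros(n_trials, bool)
    labels[rng.permutation(n_trials)[: n_trials // 2]] = True
    table = TrialTable(onsets=trials.onsets, condition="SE",
                       labels=np.where(labels, "Attending", "NotAttending"))
    cfg = synth.PhotometrySimConfig(seed=_sub(seed, 7), delta_z=delta_z)
    sess, _ = synth.gen_photometry(cfg, table, labels)
    zm, _, _ = photometry.preprocess_session(sess)
    out = photometry.summarize_and_decode(
        zm, decode_window_s=decode_window, n_trees=n_trees,
        seed=_sub(seed, 8),
    )
    return out["roc_auc"], out["roc_auc_shuffle"]


def photometry_decoding_calibration(seed=0, n_null_seeds=50, n_trials=20,
                                    n_trees=100, n_effect_reps=5):
    """RF decoding: chance at Δ=0, high AUC at |Δ|=3 of either sign.

    All reported AUCs are means over replicate sessions — the null over
    ``n_null_seeds`` 20-trial sessions, each effect sign over
    ``n_effect_reps`` full 60-trial sessions (a single session's ROC has
    several points of sampling spread on its own).
    """
    null_aucs, null_shufs = [], []
    for i in range(n_null_seeds):
        a, s = _rf_session_auc(_sub(seed, 1000 + i), 0.0, n_trials, n_trees)
        null_aucs.append(a)
        null_shufs.append(s)
    effect = {}
    for sign, delta in (("pos3", +3.0), ("neg3", -3.0)):
        aucs, shufs = [], []
        for i in range(n_effect_reps):
            a, s = _rf_session_auc(_sub(seed, 2000 + 100 * (delta < 0) + i),
                                   delta, 60, n_trees)
            aucs.append(a)
            shufs.append(s)
        effect[f"auc_delta_{sign}"] = float(np.mean(aucs))
        effect[f"shuffle_delta_{sign}"] = float(np.mean(shufs))
    return {
        "null_auc_mean": float(np.mean(null_aucs)),
        "null_shuffle_mean": float(np.mean(null_shufs)),
        **effect,
        "n": n_null_seeds,
    }


# ---------------------------------------------------------------------------
# 8./9. calcium calibration and clustering
# ---------------------------------------------------------------------------

def responsiveness_calibration(seed=0, n_null=1000, n_power=200,
                               n_trials=15):
    """Type-I rate under the null and power at a 2-SD planted response."""
    null_cfg = synth.CalciumSimConfig(
        n_animals=1, neurons_per_animal=n_null,
        archetypes={"null": {}}, proportions=(1.0,),
        event_types=("Attending",), trials_per_event=n_trials,
        seed=_sub(seed, 1),
    )
    sessions, _ = synth.gen_calcium_population(null_cfg)
    _, trial_z, ts = ensembles.compute_psth(sessions[0], "Attending")
    calls = ensembles.classify_responsiveness(trial_z, ts)
    type1 = float((calls["call"] != "none").mean())
    pow_cfg = synth.CalciumSimConfig(
        n_animals=1, neurons_per_animal=n_power,
        archetypes={"resp": {"Attending": 2.0}}, proportions=(1.0,),
        event_types=("Attending",), trials_per_event=n_trials,
        seed=_sub(seed, 2),
    )
    sessions, _ = synth.gen_calcium_population(pow_cfg)
    _, trial_z, ts = ensembles.compute_psth(sessions[0], "Attending")
    calls = ensembles.classify_responsiveness(trial_z, ts)
    power = float((calls["call"] == "excited").mean())
    return {"type1_rate": type1, "power_2sd": power, "n_null": n_null,
            "n_power": n_power}


def clustering_recovery(seed=0, noise_sd=0.2):
    """ARI of the 30 %-cutoff clustering vs two planted archetypes."""
    from sklearn.metrics import adjusted_rand_score

    cfg = synth.CalciumSimConfig(
        n_animals=4, neurons_per_animal=30, noise_sd=noise_sd,
        archetypes={"exc": {"Attending": 2.0, "pinprick": 2.0},
                    "inh": {"Attending": -2.0}},
        proportions=(0.5, 0.5), seed=_sub(seed, 3),
    )
    sessions, truth = synth.gen_calcium_population(cfg)
    profiles, arch, conds = [], [], []
    for s in sessions:
        profiles.append(np.hstack([
            ensembles.compute_psth(s, ev)[0] for ev in cfg.event_types
        ]))
        arch.extend(truth["archetype_idx"][s.animal_id])
        conds.extend([s.animal_id] * s.n_neurons)
    assign = ensembles.cluster_profiles(np.vstack(profiles), 0.30)
    ari = adjusted_rand_score(arch, assign.labels)
    enr = ensembles.cluster_enrichment(assign.labels, np.asarray(conds))
    sums = [enr[c].sum() for c in enr.columns if c.startswith("pct_")]
    return {"ari": float(ari), "n_clusters": assign.n_clusters,
            "enrichment_colsum_dev": float(np.abs(np.array(sums) - 100).max()),
            "n": len(arch)}


# ---------------------------------------------------------------------------
# 10./11. decoding guard and trajectory geometry
# ---------------------------------------------------------------------------

def leakage_guard(seed=0, n_shuffle_seeds=50, n_trials=40, n_neurons=20,
                  n_bins=20):
    """Checksum invariance to test-trial corruption + shuffled-label AUC."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n_trials // 2)
    templ = rng.normal(0, 1.0, (2, n_neurons, n_bins))
    tensor = templ[y] + 0.5 * rng.standard_normal(
        (n_trials, n_neurons, n_bins)
    )
    train = np.zeros(n_trials, bool)
    train[rng.permutation(n_trials)[: n_trials // 2]] = True
    split = decoding.fit_split(tensor[train], y[train], seed=_sub(seed, 1))
    corrupted = tensor.copy()
    corrupted[~train] = rng.standard_normal(corrupted[~train].shape) * 100
    split2 = decoding.fit_split(corrupted[train], y[train],
                                seed=_sub(seed, 1))
    checksum_equal = split.checksum == split2.checksum

    shuffle_aucs = []
    for i in range(n_shuffle_seeds):
        r2 = np.random.default_rng(_sub(seed, 5000 + i))
        null = r2.standard_normal((n_trials, n_neurons, n_bins))
        res = decoding.decode_labels(null, y, shuffle=True,
                                     with_shuffle_control=False,
                                     seed=_sub(seed, 6000 + i))
        shuffle_aucs.append(list(res.window_auc.values())[0])
    return {"checksum_invariant": float(checksum_equal),
            "shuffled_auc_mean": float(np.mean(shuffle_aucs)),
            "n": n_shuffle_seeds}


def trajectory_geometry(seed=0, n_bins=10, k=3):
    """Closed-form trajectory checks + LOO count conservation."""
    rng = np.random.default_rng(seed)
    p = rng.normal(0, 5.0, k)
    line = np.linspace(0, 1, n_bins + 1)[:, None] * p[None, :]
    length = decoding.geodesic_length(line)
    ident_dist = float(decoding.trajectory_distance(line, line).max())
    # LOO on a homogeneous synthetic population
    n_neurons, n_animals = 30, 5
    psth = rng.normal(0, 1.0, (n_neurons, 100))
    animal_of = np.repeat(np.arange(n_animals), n_neurons // n_animals)
    pca = decoding.fit_global_pca(psth.T)
    loo = decoding.loo_trajectory_metrics(psth, pca, animal_of)
    return {
        "straight_line_error": float(abs(length - np.linalg.norm(p))),
        "identical_distance_max": ident_dist,
        "loo_rows": int(len(loo)),
        "n_animals": n_animals,
        "full_length": decoding.geodesic_length(
            decoding.build_trajectory(psth, pca)
        ),
        "loo_min": float(loo["geodesic_length"].min()),
        "loo_max": float(loo["geodesic_length"].max()),
    }
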