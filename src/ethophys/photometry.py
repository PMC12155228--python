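"""Fiber-photometry biosensor preprocessing, trial summaries, and decoding.

Preprocessing follows the standard two-channel pipeline: a causal
(forward-only) median filter on both channels, least-squares regression of
the calcium-independent reference channel out of the signal channel — with
coefficients fit only on trial-averaged data in the −1..0 s pre-cue window,
so stimulus-evoked transients cannot leak into the fit — and per-trial
z-scoring against each trial's own −1..0 s baseline.  Trial summaries are
trapezoidal AUCs over a sensor-specific window; trial-type decoding pools
individual timepoints within a window into a random-forest classifier with
trial-grouped cross-validation and a trial-level label-shuffle control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .core import PhotometrySession, TrialTable, align_windows


def causal_median_filter(trace, span_s=0.2, fs=20.0):
    """Forward-only (trailing-window) median filter.

    ``output[t]`` is the median of the samples in ``(t − span, t]``; the
    first samples use the available partial window, and no future sample is
    ever used.
    """
    trace = np.asarray(trace, float)
    w = max(int(round(span_s * fs)), 1)
    if w == 1 or len(trace) == 0:
        return trace.copy()
    out = np.empty_like(trace)
    n_partial = min(w - 1, len(trace))
    for i in range(n_partial):
        out[i] = np.median(trace[: i + 1])
    if len(trace) >= w:
        from numpy.lib.stride_tricks import sliding_window_view

        out[w - 1:] = np.median(sliding_window_view(trace, w), axis=1)
    return out


def regress_out_reference(signal, reference, trials: TrialTable, fs=20.0,
                          fit_window_s=(-1.0, 0.0)):
    """Regress the reference channel out of the signal channel.

    Slope and intercept are fit by least squares on the **trial-averaged**
    (reference, signal) sample pairs restricted to the pre-cue fit window,
    then applied to the full continuous traces:
    ``residual = signal − (a·reference + b)``.

    Returns (residual, coeffs) with coeffs = {"slope", "intercept"}.  A
    zero-variance reference in the fit window yields slope 0 with a warning.
    """
    signal = np.asarray(signal, float)
    reference = np.asarray(reference, float)
    if trials.n_trials < 2:
        raise ValueError("need >= 2 trials to fit the reference regression")
    t = np.arange(len(signal)) / fs
    pre, post = -fit_window_s[0], fit_window_s[1]
    idx, kept = align_windows(t, trials.onsets, pre, max(post, 0.0))
    sig_avg = signal[idx].mean(axis=0)
    ref_avg = reference[idx].mean(axis=0)
    var = ref_avg.var()
    if var == 0:
        warnings.warn("reference has zero variance in the fit window; slope 0")
        slope = 0.0
    else:
        slope = np.cov(ref_avg, sig_avg, ddof=0)[0, 1] / var
    intercept = sig_avg.mean() - slope * ref_avg.mean()
    residual = signal - (slope * reference + intercept)
    return residual, {"slope": float(slope), "intercept": float(intercept)}


@dataclass
class TrialZMatrix:
    """Per-trial z-scored traces on a common peri-cue time axis."""

    z: np.ndarray              # kept trials × time
    time_s: np.ndarray         # relative to cue onset
    labels: np.ndarray | None
    kept: np.ndarray
    fs: float


def zscore_trials(residual, trials: TrialTable, fs=20.0,
                  baseline_s=(-1.0, 0.0), pre_s=5.0, post_s=20.0,
                  max_flagged_frac=0.5) -> TrialZMatrix:
    """Per-trial z-scoring against each trial's own pre-cue baseline.

    z = (x − mean_baseline) / sd_baseline, with the baseline window
    ``baseline_s`` relative to the cue.  Trials with zero baseline SD are
    flagged and excluded; if more than half the trials are flagged the
    session is rejected.
    """
    residual = np.asarray(residual, float)
    t = np.arange(len(residual)) / fs
    idx, kept = align_windows(t, trials.onsets, pre_s, post_s)
    time_s = (np.arange(idx.shape[1]) - int(round(pre_s * fs))) / fs
    b0 = int(round((baseline_s[0] + pre_s) * fs))
    b1 = int(round((baseline_s[1] + pre_s) * fs))
    windows = residual[idx]
    mu = windows[:, b0:b1].mean(axis=1, keepdims=True)
    sd = windows[:, b0:b1].std(axis=1, ddof=0, keepdims=True)
    good = sd[:, 0] > 0
    flagged = (~good).sum()
    if flagged > max_flagged_frac * len(good):
        raise ValueError(f"{flagged}/{len(good)} trials have zero baseline SD")
    z = (windows[good] - mu[good]) / sd[good]
    kept_full = kept.copy()
    kept_full[np.flatnonzero(kept)[~good]] = False
    labels = trials.labels[kept_full] if trials.labels is not None else None
    return TrialZMatrix(z=z, time_s=time_s, labels=labels, kept=kept_full,
                        fs=fs)


def trial_auc(zm: TrialZMatrix, window_s=(0.0, 20.0)) -> np.ndarray:
    """Trapezoidal integral of z over the sensor window, per trial."""
    m = (zm.time_s >= window_s[0]) & (zm.time_s < window_s[1])
    return np.trapezoid(zm.z[:, m], dx=1.0 / zm.fs, axis=1)


def summarize_and_decode(zm: TrialZMatrix, auc_window_s=(0.0, 20.0),
                         decode_window_s=(0.0, 20.0), folds=5,
                         n_trees=500, max_depth=None, seed=0,
                         shuffle_control=True):
    """Trial summaries plus random-forest decoding of trial labels.

    Decoding samples are the individual timepoints in the decode window
    pooled across trials; features are the z value and the time-bin index;
    labels are the trial's class.  Cross-validation is stratified at the
    **trial** level so all timepoints of a trial stay in one fold (guards
    against within-trial leakage).  Reports the pooled ROC-AUC and, when
    requested, a control with labels shuffled at the trial level.
    """
    if zm.labels is None:
        raise ValueError("trial labels required for decoding")
    labels = np.asarray(zm.labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need 2 classes, got {list(classes)}")
    y_trial = (labels == classes[-1]).astype(int)
    out = {
        "mean_traces": {
            str(c): zm.z[labels == c].mean(axis=0) for c in classes
        },
        "auc": trial_auc(zm, auc_window_s),
        "classes": classes,
    }
    min_class = min((y_trial == v).sum() for v in (0, 1))
    if min_class < 2:
        raise ValueError("need >= 2 trials per class")
    if min_class < folds:
        warnings.warn(f"reducing folds {folds} -> {min_class}")
        folds = min_class
    rng = np.random.default_rng(seed)
    out["roc_auc"] = _pooled_timepoint_auc(zm, y_trial, decode_window_s,
                                           folds, n_trees, max_depth, rng)
    if shuffle_control:
        y_shuf = rng.permutation(y_trial)
        out["roc_auc_shuffle"] = _pooled_timepoint_auc(
            zm, y_shuf, decode_window_s, folds, n_trees, max_depth, rng
        )
    return out


def _pooled_timepoint_auc(zm, y_trial, window_s, folds, n_trees, max_depth,
                          rng):
    m = (zm.time_s >= window_s[0]) & (zm.time_s < window_s[1])
    X_trial = zm.z[:, m]                       # trials × timepoints
    tbin = np.arange(m.sum())
    n_trials = len(y_trial)
    # stratified trial-level folds
    fold_of = np.empty(n_trials, dtype=int)
    for v in (0, 1):
        idx = np.flatnonzero(y_trial == v)
        idx = rng.permutation(idx)
        fold_of[idx] = np.arange(len(idx)) % folds
    scores = np.empty(0)
    truths = np.empty(0, dtype=int)
    for f in range(folds):
        tr, te = fold_of != f, fold_of == f
        Xtr = np.column_stack([
            X_trial[tr].ravel(),
            np.tile(tbin, tr.sum()),
        ])
        ytr = np.repeat(y_trial[tr], m.sum())
        Xte = np.column_stack([
            X_trial[te].ravel(),
            np.tile(tbin, te.sum()),
        ])
        yte = np.repeat(y_trial[te], m.sum())
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_depth=max_depth,
            random_state=int(rng.integers(2**31 - 1)), n_jobs=1,
        )
        clf.fit(Xtr, ytr)
        scores = np.concatenate([scores, clf.predict_proba(Xte)[:, 1]])
        truths = np.concatenate([truths, yte])
    return float(roc_auc_score(truths, scores))


def preprocess_session(session: PhotometrySession, median_span_s=0.2,
                       fit_window_s=(-1.0, 0.0), baseline_s=(-1.0, 0.0),
                       pre_s=5.0, post_s=20.0):
    """Full preprocessing: median filter → reference regression → trial z.

    Returns (TrialZMatrix, coeffs, residual).
    """
    sig = causal_median_filter(session.signal, median_span_s, session.fs)
    ref = causal_median_filter(session.reference, median_span_s, session.fs)
    residual, coeffs = regress_out_reference(
        sig, ref, session.trial_table, session.fs, fit_window_s
    )
    zm = zscore_trials(residual, session.trial_table, session.fs,
                       baseline_s, pre_s, post_s)
    return zm, coeffs, residual
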