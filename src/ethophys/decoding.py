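"""Population decoding and neural-trajectory geometry.

The decoding design is leakage-free by construction: a global PCA is fitted
only on trial averages built from the training fold's trials, single test
trials are then projected with those fixed per-neuron coefficients, and a
classifier (logistic GLM, linear SVM, or random forest) is trained per time
bin on the training trials' PC features.  Multiclass problems use
one-vs-all binaries; unbalanced classes are handled by repeated majority
subsampling with score averaging; controls shuffle training labels only.
Performance is the ROC-AUC per time bin, summarized as the mean over an
evaluation window.

Trajectory geometry operates in the same fixed PC basis: geodesic length is
the summed Euclidean distance between adjacent time bins, trajectory
separation is the bin-by-bin Euclidean distance, and leave-one-animal-out
(dropping all of one animal's neurons while keeping the fitted per-neuron
coefficients) yields one metric value per animal for group statistics.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC


@dataclass
class PCAModel:
    """Global PCA with the 90%-variance component count.

    ``components`` is (k_full × n_neurons); ``k90`` is the smallest count
    reaching the requested cumulative variance, capped at the matrix rank.
    """

    components: np.ndarray
    mean: np.ndarray
    explained_variance_ratio: np.ndarray
    k90: int
    variance_target: float = 0.90

    def project(self, X, neuron_idx=None, k=None):
        """Project observations × neurons (fixed per-neuron coefficients).

        With ``neuron_idx``, only those neurons contribute (leave-one-out
        trajectories); coefficients and means are subset, never refit.
        """
        k = self.k90 if k is None else k
        X = np.asarray(X, float)
        if neuron_idx is None:
            if X.shape[-1] != len(self.mean):
                raise ValueError(
                    f"{X.shape[-1]} neurons != model's {len(self.mean)}"
                )
            return (X - self.mean) @ self.components[:k].T
        neuron_idx = np.asarray(neuron_idx)
        return (X - self.mean[neuron_idx]) @ self.components[:k, neuron_idx].T


def fit_global_pca(train_avg, variance=0.90) -> PCAModel:
    """PCA on training-set trial averages (observations × neurons).

    The component count is the smallest K with cumulative explained
    variance ≥ ``variance``; rank-deficient input caps K at the rank with a
    warning.
    """
    X = np.asarray(train_avg, float)
    pca = PCA(svd_solver="full")
    pca.fit(X)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    rank = int((pca.singular_values_ > 1e-10 * pca.singular_values_[0]).sum())
    reach = np.flatnonzero(cum >= variance - 1e-12)
    if len(reach):
        k = int(reach[0]) + 1
    else:
        k = len(evr)
    if k > rank:
        warnings.warn(f"rank-deficient input: K capped at rank {rank}")
        k = rank
    return PCAModel(components=pca.components_, mean=pca.mean_,
                    explained_variance_ratio=evr, k90=k,
                    variance_target=variance)


def project_trials(model: PCAModel, trials):
    """Single-trial neural trajectories: trials × K × time.

    ``trials`` is trials × neurons × time; projection is linear with the
    model's stored means, no re-centering.
    """
    trials = np.asarray(trials, float)
    if trials.shape[1] != len(model.mean):
        raise ValueError(
            f"trial tensor has {trials.shape[1]} neurons, model expects "
            f"{len(model.mean)}"
        )
    # (trials, time, K) -> (trials, K, time)
    proj = model.project(np.transpose(trials, (0, 2, 1)))
    return np.transpose(proj, (0, 2, 1))


def _make_classifier(model, seed, l2_c=1.0, n_trees=200):
    if model == "glm":
        return LogisticRegression(C=l2_c, max_iter=1000)
    if model == "svm":
        return SVC(kernel="linear", C=l2_c)
    if model == "rf":
        return RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                      n_jobs=1)
    raise ValueError(f"unknown model {model!r}")


def _score(clf, X):
    if hasattr(clf, "decision_function"):
        return clf.decision_function(X)
    return clf.predict_proba(X)[:, 1]


def _fold_assign(rng, y, folds):
    fold_of = np.empty(len(y), dtype=int)
    for v in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == v))
        fold_of[idx] = np.arange(len(idx)) % folds
    return fold_of


@dataclass
class DecodeResult:
    """ROC-over-time per class plus window summaries and fit checksums."""

    roc_over_time: dict          # class -> (n_bins,) AUC
    window_auc: dict             # class -> float
    shuffle_roc_over_time: dict | None
    shuffle_window_auc: dict | None
    time_s: np.ndarray | None
    k_per_fold: list = field(default_factory=list)
    fit_checksum: str = ""


def _checksum(arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(np.asarray(a, float)).tobytes())
    return h.hexdigest()


def decode_labels(tensor, labels, model="glm", folds=5, variance=0.90,
                  balance=True, shuffle=False, eval_window_s=None,
                  time_s=None, l2_c=1.0, seed=0,
                  with_shuffle_control=True) -> DecodeResult:
    """Cross-validated population decoding of trial labels.

    ``tensor`` is trials × neurons × time.  Per CV fold the PCA is refit on
    training-trial class averages only; per time bin a classifier is
    trained on the training trials' PC features at that bin.  Multiclass
    labels become one-vs-all binaries.  With ``balance``, the majority side
    is repeatedly subsampled to the minority size (enough repeats to cover
    all trials) and the test scores averaged.  ``shuffle`` permutes
    *training* labels only (the control path); ``with_shuffle_control``
    also reports that control alongside the real decoding.
    """
    tensor = np.asarray(tensor, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    rng = np.random.default_rng(seed)
    binaries = (
        [(str(c), labels == c) for c in classes]
        if len(classes) > 2
        else [(f"{classes[-1]}_vs_{classes[0]}", labels == classes[-1])]
    )
    n_bins = tensor.shape[2]
    result = DecodeResult(roc_over_time={}, window_auc={},
                          shuffle_roc_over_time={} if with_shuffle_control
                          else None,
                          shuffle_window_auc={} if with_shuffle_control
                          else None,
                          time_s=time_s)
    win = (
        np.ones(n_bins, bool) if eval_window_s is None
        else (time_s >= eval_window_s[0]) & (time_s < eval_window_s[1])
    )
    fit_params = []
    for name, y in binaries:
        y = y.astype(int)
        if min((y == 0).sum(), (y == 1).sum()) < folds:
            f_use = min((y == 0).sum(), (y == 1).sum())
            if f_use < 2:
                warnings.warn(f"class {name}: too few trials; skipped")
                continue
            warnings.warn(f"class {name}: reducing folds {folds} -> {f_use}")
        else:
            f_use = folds
        variants = [(False, rng.integers(2**31 - 1))]
        if with_shuffle_control:
            variants.append((True, rng.integers(2**31 - 1)))
        if shuffle:
            variants = [(True, rng.integers(2**31 - 1))]
        for do_shuffle, sub_seed in variants:
            auc = _decode_binary(tensor, y, model, f_use, variance, balance,
                                 do_shuffle, l2_c, int(sub_seed), fit_params)
            target_rot = (result.shuffle_roc_over_time
                          if do_shuffle and not shuffle
                          else result.roc_over_time)
            target_win = (result.shuffle_window_auc
                          if do_shuffle and not shuffle
                          else result.window_auc)
            target_rot[name] = auc
            target_win[name] = float(np.nanmean(auc[win]))
    result.fit_checksum = _checksum(fit_params) if fit_params else ""
    return result


@dataclass
class FittedSplit:
    """Everything fitted on one training split — and nothing else.

    The PCA and the per-time-bin classifiers are functions of the training
    trials only; ``checksum`` hashes every fitted parameter, so corrupting
    held-out trials provably leaves it unchanged.
    """

    pca: PCAModel
    classifiers: list               # per time bin: list of draw classifiers
    draws: list
    checksum: str

    def predict(self, test_tensor):
        """Average classifier score per test trial per time bin."""
        pte = project_trials(self.pca, test_tensor)
        n_te, _, n_bins = pte.shape
        scores = np.zeros((n_te, n_bins))
        for t in range(n_bins):
            for clf in self.classifiers[t]:
                scores[:, t] += _score(clf, pte[:, :, t])
            scores[:, t] /= len(self.classifiers[t])
        return scores


def fit_split(train_tensor, y_train, model="glm", variance=0.90,
              balance=True, l2_c=1.0, seed=0) -> FittedSplit:
    """Fit the PCA + per-bin classifiers on a training split only.

    The PCA is fit on the training trials' class averages; with
    ``balance``, the majority class is repeatedly subsampled to the
    minority size (covering all majority trials) and one classifier per
    draw is kept, their test scores averaged at predict time.
    """
    rng = np.random.default_rng(seed)
    y_train = np.asarray(y_train, int)
    avgs = [train_tensor[y_train == v].mean(axis=0).T for v in (0, 1)
            if (y_train == v).any()]
    pca = fit_global_pca(np.vstack(avgs), variance)
    ptr = project_trials(pca, train_tensor)      # n_tr × K × time
    idx0 = np.flatnonzero(y_train == 0)
    idx1 = np.flatnonzero(y_train == 1)
    n_min = min(len(idx0), len(idx1))
    if balance and len(idx0) != len(idx1):
        maj, mino = (idx0, idx1) if len(idx0) > len(idx1) else (idx1, idx0)
        n_rep = int(np.ceil(len(maj) / n_min))
        draws = [
            np.concatenate([mino, rng.choice(maj, n_min, replace=False)])
            for _ in range(n_rep)
        ]
    else:
        draws = [np.arange(len(y_train))]
    n_bins = train_tensor.shape[2]
    classifiers = []
    params = [pca.components[: pca.k90]]
    for t in range(n_bins):
        per_draw = []
        for d in draws:
            clf = _make_classifier(model, seed, l2_c)
            clf.fit(ptr[d][:, :, t], y_train[d])
            per_draw.append(clf)
            coef = getattr(clf, "coef_", None)
            if coef is not None:
                params.append(coef)
        classifiers.append(per_draw)
    return FittedSplit(pca=pca, classifiers=classifiers, draws=draws,
                       checksum=_checksum(params))


def _decode_binary(tensor, y, model, folds, variance, balance, shuffle,
                   l2_c, seed, fit_params):
    rng = np.random.default_rng(seed)
    n_trials, _, n_bins = tensor.shape
    fold_of = _fold_assign(rng, y, folds)
    scores = np.full((n_trials, n_bins), np.nan)
    for f in range(folds):
        tr = fold_of != f
        te = ~tr
        ytr = y[tr].copy()
        if shuffle:
            ytr = rng.permutation(ytr)
        split = fit_split(tensor[tr], ytr, model=model, variance=variance,
                          balance=balance, l2_c=l2_c,
                          seed=int(rng.integers(2**31 - 1)))
        fit_params.append(np.frombuffer(bytes.fromhex(split.checksum),
                                        dtype=np.uint8))
        scores[te] = split.predict(tensor[te])
    auc = np.empty(n_bins)
    for t in range(n_bins):
        auc[t] = roc_auc_score(y, scores[:, t])
    return auc


def decode_rank(tensor, rank_labels, model="glm", folds=10, **kw
                ) -> DecodeResult:
    """One-vs-all decoding of tube-test social rank (10-fold default).

    ``rank_labels`` ∈ {dominant, intermediate, subordinate} per trial;
    missing classes are skipped with a warning, small classes reduce the
    fold count automatically.
    """
    return decode_labels(tensor, rank_labels, model=model, folds=folds, **kw)


# ---------------------------------------------------------------------------
# trajectory geometry
# ---------------------------------------------------------------------------

def rebin_trajectory(traj, n_bins=100):
    """Average a (time × K) trajectory into ~n_bins equal time bins."""
    traj = np.asarray(traj, float)
    T = traj.shape[0]
    if T <= n_bins:
        return traj
    edges = np.linspace(0, T, n_bins + 1).astype(int)
    return np.array([traj[a:b].mean(axis=0) for a, b in
                     zip(edges[:-1], edges[1:])])


def geodesic_length(traj) -> float:
    """Sum of Euclidean distances between adjacent trajectory bins."""
    traj = np.asarray(traj, float)
    if traj.shape[0] < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(traj, axis=0), axis=1).sum())


def trajectory_distance(a, b) -> np.ndarray:
    """Euclidean distance between two trajectories, bin by bin."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("trajectories must share time axis and basis")
    return np.linalg.norm(a - b, axis=1)


def build_trajectory(psth, pca: PCAModel, neuron_idx=None, n_bins=100,
                     k=None):
    """Mean-activity trajectory (bins × K) in the fixed PC basis.

    ``psth`` is neurons × time (trial-averaged); ``neuron_idx`` restricts to
    a neuron subset with the same fitted coefficients (LOO variants).
    """
    X = np.asarray(psth, float).T              # time × neurons
    if neuron_idx is not None:
        X = X[:, neuron_idx]
    scores = pca.project(X, neuron_idx=neuron_idx, k=k)
    return rebin_trajectory(scores, n_bins)


def loo_trajectory_metrics(psth, pca: PCAModel, animal_of, n_bins=100,
                           other_psth=None) -> pd.DataFrame:
    """Leave-one-animal-out trajectory metrics.

    For each animal, all its neurons are dropped, the trajectory rebuilt
    with the fixed PC coefficients, and the geodesic length (and, when
    ``other_psth`` is given, the mean bin-by-bin distance to the equally
    re-built second trajectory) recomputed — exactly one row per animal.
    A single-animal group is degenerate and flagged.
    """
    animal_of = np.asarray(animal_of)
    animals = np.unique(animal_of)
    if len(animals) < 2:
        warnings.warn("LOO degenerate: only one animal in group")
    rows = []
    for a in animals:
        keep = np.flatnonzero(animal_of != a)
        traj = build_trajectory(psth, pca, neuron_idx=keep, n_bins=n_bins)
        row = {"animal": a, "geodesic_length": geodesic_length(traj)}
        if other_psth is not None:
            other = build_trajectory(other_psth, pca, neuron_idx=keep,
                                     n_bins=n_bins)
            row["mean_distance"] = float(trajectory_distance(traj, other).mean())
        rows.append(row)
    return pd.DataFrame(rows)
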