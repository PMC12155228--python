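"""Unsupervised behavioral structure.

Two complementary views of the same frames:

* a low-dimensional embedding (UMAP) with density clustering (DBSCAN) and an
  attending/not-attending labeling of clusters, either rule-based (barrier
  contact + port orientation fraction) or from a manual list;
* a hidden Markov model over categorical behavior syllables, discrete flags
  and continuous kinematic features (conditionally independent given the
  state), with EM fitting, a 2–12 state log-likelihood scan and elbow
  selection, posterior/Viterbi decoding, and per-state occupancy metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import DBSCAN, KMeans

_PROB_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# embedding + density clustering
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingModel:
    """Frozen 2-D embedding with its clustering; supports transform mode."""

    reducer: object
    embedding: np.ndarray
    cluster_ids: np.ndarray
    eps: float
    min_samples: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map new frame-rows onto the frozen embedding."""
        return self.reducer.transform(np.asarray(X, float))

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Nearest-cluster assignment of new rows in embedding space.

        Points farther than ``eps`` from every clustered training point are
        labeled noise (−1), matching the DBSCAN semantics of the fit.
        """
        emb = self.transform(X)
        core = self.cluster_ids >= 0
        if not core.any():
            return np.full(len(emb), -1)
        from scipy.spatial import cKDTree

        tree = cKDTree(self.embedding[core])
        dist, idx = tree.query(emb)
        out = self.cluster_ids[core][idx]
        out[dist > self.eps] = -1
        return out


def embed_and_cluster(
    X: np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    n_components: int = 2,
    eps: float = 0.5,
    min_samples: int = 10,
    seed: int = 0,
) -> EmbeddingModel:
    """UMAP the frame × feature matrix, then DBSCAN the embedding.

    Deterministic for a fixed seed; DBSCAN noise points get id −1.  The
    returned model can map held-out frames onto the frozen embedding to
    overlay e.g. detector calls or HMM states on the behavioral map.
    """
    X = np.asarray(X, float)
    if X.ndim == 3:  # trial tensor → frame rows
        X = X.reshape(-1, X.shape[-1])
    if len(X) <= n_neighbors:
        raise ValueError(
            f"{len(X)} rows <= n_neighbors={n_neighbors}; need more frames"
        )
    import umap

    reducer = umap.UMAP(
        n_neighbors=n_neighbors, min_dist=min_dist,
        n_components=n_components, random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", module="sklearn")
        emb = reducer.fit_transform(X)
    ids = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(emb)
    return EmbeddingModel(reducer=reducer, embedding=emb, cluster_ids=ids,
                          eps=eps, min_samples=min_samples)


def label_attending_clusters(
    cluster_ids: np.ndarray,
    attending_evidence: np.ndarray | None = None,
    theta: float = 0.5,
    manual: dict | None = None,
) -> dict:
    """Label each non-noise cluster Attending/NotAttending.

    Rule mode: a cluster is Attending iff the mean of
    ``attending_evidence`` (per-frame 0/1, e.g. ``oriented_and_touching`` OR
    ``touching_barrier``) over its frames exceeds ``theta`` (strict).
    Manual mode: labels come from ``manual`` {cluster_id: label}; every
    non-noise cluster must be covered.
    """
    cluster_ids = np.asarray(cluster_ids)
    clusters = sorted(c for c in np.unique(cluster_ids) if c >= 0)
    if manual is not None:
        missing = [c for c in clusters if c not in manual]
        if missing:
            raise ValueError(f"manual labels missing for clusters {missing}")
        return {c: manual[c] for c in clusters}
    if attending_evidence is None:
        raise ValueError("rule mode needs per-frame attending evidence")
    ev = np.asarray(attending_evidence, float)
    out = {}
    for c in clusters:
        frac = ev[cluster_ids == c].mean()
        out[c] = "Attending" if frac > theta else "NotAttending"
    return out


def export_overlay(model: EmbeddingModel, path, overlay=None) -> pd.DataFrame:
    """Write the embedding with cluster ids (and an optional per-frame
    overlay label, e.g. detector calls or HMM states) to CSV for plotting."""
    df = pd.DataFrame({
        "frame": np.arange(len(model.embedding)),
        "x": model.embedding[:, 0],
        "y": model.embedding[:, 1],
        "cluster": model.cluster_ids,
    })
    if overlay is not None:
        df["overlay"] = np.asarray(overlay)
    df.to_csv(path, index=False)
    return df


def cluster_frame_enrichment(cluster_ids, group_labels) -> pd.DataFrame:
    """Per-cluster enrichment: % of group-A frames − % of group-B frames.

    ``group_labels`` holds exactly two distinct values (e.g. Drug/Vehicle).
    Percentages are per group over clusters-plus-noise, so each group's
    column sums to 100 and the signed enrichments sum to 0.
    """
    cluster_ids = np.asarray(cluster_ids)
    group_labels = np.asarray(group_labels)
    groups = np.unique(group_labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    for g in groups:
        if (group_labels == g).sum() == 0:
            raise ValueError(f"group {g} is empty")
    rows = []
    for c in np.unique(cluster_ids):
        pct = {}
        for g in groups:
            in_g = group_labels == g
            pct[g] = 100.0 * np.mean(cluster_ids[in_g] == c)
        rows.append({"cluster": c, f"pct_{groups[0]}": pct[groups[0]],
                     f"pct_{groups[1]}": pct[groups[1]],
                     "enrichment": pct[groups[0]] - pct[groups[1]]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed-emission HMM
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fwd_bwd(pi, A, B):  # pragma: no cover - numba
    """Scaled forward-backward.  B is the T×K per-frame likelihood matrix
    (any positive rescaling per frame is absorbed by the scaling constants).
    Returns (gamma, xi_sum, log-likelihood-up-to-per-frame-offsets)."""
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a0 = pi * B[0]
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    for t in range(1, T):
        pred = alpha[t - 1] @ A
        at = pred * B[t]
        c[t] = at.sum()
        alpha[t] = at / c[t]
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    for t in range(T):
        gamma[t] /= gamma[t].sum()
    xi = np.zeros((K, K))
    for t in range(T - 1):
        w = B[t + 1] * beta[t + 1]
        for i in range(K):
            xi[i] += alpha[t, i] * A[i] * w / c[t + 1]
    return gamma, xi, np.log(c).sum()


@njit(cache=True)
def _viterbi(log_pi, log_A, log_B):  # pragma: no cover - numba
    T, K = log_B.shape
    delta = log_pi + log_B[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        nd = np.empty(K)
        for j in range(K):
            best, arg = -1e300, 0
            for i in range(K):
                v = delta[i] + log_A[i, j]
                if v > best:
                    best, arg = v, i
            nd[j] = best + log_B[t, j]
            back[t, j] = arg
        delta = nd
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta)
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


@dataclass
class StateHMM:
    """Fitted behavioral-state HMM (results object).

    Emissions per state: a categorical distribution over the syllable
    alphabet × independent Bernoullis over discrete flags × a diagonal
    Gaussian over continuous features.
    """

    pi: np.ndarray
    transition: np.ndarray
    syl_probs: np.ndarray | None     # K × alphabet
    flag_probs: np.ndarray | None    # K × n_flags
    means: np.ndarray | None         # K × n_cont
    vars: np.ndarray | None
    loglik_trace: list = field(default_factory=list)
    selection_table: pd.DataFrame | None = None

    @property
    def n_states(self) -> int:
        return len(self.pi)

    # per-frame log-likelihood matrix
    def _log_b(self, syllables=None, flags=None, cont=None) -> np.ndarray:
        K = self.n_states
        parts = []
        if syllables is not None:
            syl = np.asarray(syllables, int)
            probs = self.syl_probs
            # unseen symbols map to the smoothing floor
            safe = np.clip(syl, 0, probs.shape[1] - 1)
            lb = np.log(probs[:, safe].T)
            lb[(syl < 0) | (syl >= probs.shape[1])] = np.log(_PROB_FLOOR)
            parts.append(lb)
        if flags is not None:
            f = np.asarray(flags, float)
            p = np.clip(self.flag_probs, _PROB_FLOOR, 1 - _PROB_FLOOR)
            parts.append(f @ np.log(p).T + (1 - f) @ np.log(1 - p).T)
        if cont is not None:
            x = np.asarray(cont, float)
            v = self.vars
            lb = -0.5 * (
                ((x[:, None, :] - self.means[None]) ** 2 / v[None]).sum(-1)
                + np.log(2 * np.pi * v).sum(-1)[None]
            )
            parts.append(lb)
        if not parts:
            raise ValueError("no observation streams provided")
        out = parts[0]
        for p in parts[1:]:
            out = out + p
        return out

    def posterior(self, syllables=None, flags=None, cont=None):
        log_b = self._log_b(syllables, flags, cont)
        off = log_b.max(axis=1, keepdims=True)
        B = np.exp(log_b - off)
        gamma, _, ll = _fwd_bwd(self.pi, self.transition, B)
        return gamma, ll + off.sum()

    def score(self, syllables=None, flags=None, cont=None) -> float:
        return self.posterior(syllables, flags, cont)[1]

    def decode(self, syllables=None, flags=None, cont=None,
               method: str = "posterior") -> np.ndarray:
        """Per-frame state ids; posterior argmax by default, Viterbi by flag."""
        if method == "viterbi":
            log_b = self._log_b(syllables, flags, cont)
            return _viterbi(np.log(self.pi + 1e-300),
                            np.log(self.transition + 1e-300), log_b)
        gamma, _ = self.posterior(syllables, flags, cont)
        return gamma.argmax(axis=1)


def _m_step(gamma, xi, syllables, flags, cont, alphabet):
    K = gamma.shape[1]
    pi = gamma[0] / gamma[0].sum()
    A = xi + _PROB_FLOOR
    A /= A.sum(axis=1, keepdims=True)
    occ = gamma.sum(axis=0)
    syl_probs = flag_probs = means = variances = None
    if syllables is not None:
        counts = np.zeros((K, alphabet))
        np.add.at(counts.T, syllables, gamma)
        counts += _PROB_FLOOR
        syl_probs = counts / counts.sum(axis=1, keepdims=True)
    if flags is not None:
        flag_probs = (gamma.T @ flags) / occ[:, None]
        flag_probs = np.clip(flag_probs, _PROB_FLOOR, 1 - _PROB_FLOOR)
    if cont is not None:
        means = (gamma.T @ cont) / occ[:, None]
        sq = gamma.T @ (cont**2) / occ[:, None]
        variances = np.maximum(sq - means**2, 1e-4)
    return StateHMM(pi=pi, transition=A, syl_probs=syl_probs,
                    flag_probs=flag_probs, means=means, vars=variances)


def _init_model(rng, K, syllables, flags, cont, alphabet):
    pi = np.full(K, 1.0 / K)
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9)
    syl_probs = flag_probs = means = variances = None
    if syllables is not None:
        syl_probs = rng.dirichlet(np.ones(alphabet) * 2.0, size=K)
    if flags is not None:
        flag_probs = rng.uniform(0.2, 0.8, size=(K, flags.shape[1]))
    if cont is not None:
        km = KMeans(n_clusters=K, n_init=3,
                    random_state=int(rng.integers(2**31 - 1)))
        sub = cont[rng.choice(len(cont), size=min(len(cont), 5000),
                              replace=False)]
        km.fit(sub)
        means = km.cluster_centers_ + 0.1 * rng.standard_normal((K, cont.shape[1]))
        variances = np.full((K, cont.shape[1]), cont.var(axis=0) + 1e-3)
    return StateHMM(pi=pi, transition=A, syl_probs=syl_probs,
                    flag_probs=flag_probs, means=means, vars=variances)


def _em(model, syllables, flags, cont, alphabet, max_iter, tol):
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        log_b = model._log_b(syllables, flags, cont)
        off = log_b.max(axis=1, keepdims=True)
        B = np.exp(log_b - off)
        gamma, xi, ll = _fwd_bwd(model.pi, model.transition, B)
        ll = ll + off.sum()
        trace.append(ll)
        if gamma.sum(axis=0).min() < 1e-8:
            return None, trace  # degenerate state; caller restarts
        new = _m_step(gamma, xi, syllables, flags, cont, alphabet)
        new.loglik_trace = trace
        model = new
        if ll - prev < tol * abs(ll):
            break
        prev = ll
    return model, trace


def fit_state_hmm(
    syllables=None,
    flags=None,
    cont=None,
    k_range=range(2, 13),
    n_init: int = 2,
    max_iter: int = 50,
    tol: float = 1e-4,
    max_restarts: int = 3,
    fixed_k: int | None = None,
    seed: int = 0,
):
    """EM fit over a range of state counts with elbow model selection.

    For each K the best of ``n_init`` random EM runs is kept; the selection
    table reports the best log-likelihood per K and the selected K is the
    elbow of the LL-vs-K curve (maximum drop in marginal gain, i.e. most
    negative second difference) unless ``fixed_k`` overrides it.

    Returns (StateHMM, selection_table).
    """
    if syllables is not None:
        syllables = np.asarray(syllables, int)
    if flags is not None:
        flags = np.atleast_2d(np.asarray(flags, float))
        if flags.shape[0] != max(
            len(x) for x in (syllables, cont, flags) if x is not None
        ):
            flags = flags.T
    if cont is not None:
        cont = np.asarray(cont, float)
        if cont.ndim == 1:
            cont = cont[:, None]
    alphabet = int(syllables.max()) + 1 if syllables is not None else 0
    rng = np.random.default_rng(seed)
    ks = [fixed_k] if fixed_k is not None else list(k_range)
    best_by_k = {}
    for K in ks:
        best = None
        for _ in range(n_init):
            model = None
            for _r in range(max_restarts + 1):
                init = _init_model(rng, K, syllables, flags, cont, alphabet)
                model, trace = _em(init, syllables, flags, cont, alphabet,
                                   max_iter, tol)
                if model is not None:
                    break
            if model is None:
                raise RuntimeError(
                    f"EM degenerate for K={K} after {max_restarts} restarts"
                )
            if best is None or model.loglik_trace[-1] > best.loglik_trace[-1]:
                best = model
        best_by_k[K] = best
    lls = np.array([best_by_k[K].loglik_trace[-1] for K in ks], float)
    table = pd.DataFrame({"K": ks, "loglik": lls})
    if fixed_k is not None or len(ks) < 3:
        k_sel = ks[int(np.argmax(lls))] if fixed_k is None else fixed_k
    else:
        # elbow: interior K whose marginal LL gain most dominates the next
        # gain (scale-free; a raw second difference can peak one K early
        # when successive gains span orders of magnitude)
        gains = np.diff(lls)
        floor = 1e-6 * np.abs(lls).max() + 1e-8
        ratio = np.maximum(gains[:-1], 0.0) / np.maximum(gains[1:], floor)
        k_sel = ks[1 + int(np.argmax(ratio))]
    table["selected"] = table["K"] == k_sel
    model = best_by_k[k_sel]
    model.selection_table = table
    return model, table


# ---------------------------------------------------------------------------
# state metrics
# ---------------------------------------------------------------------------

def state_metrics(states: np.ndarray, K: int | None = None,
                  fps: float = 30.0) -> pd.DataFrame:
    """Per-state occupancy metrics.

    * time_fraction — frames in the state / total frames;
    * stickiness — MLE of the self-transition probability,
      #(s→s) / #(transitions out of frames in s);
    * mean_dwell_s — mean run length in seconds.

    States never visited get NaN metrics (flagged by the ``visited`` column).
    """
    states = np.asarray(states, int)
    if len(states) == 0:
        raise ValueError("empty state sequence")
    K = K if K is not None else int(states.max()) + 1
    rows = []
    trans_from = states[:-1]
    trans_to = states[1:]
    for s in range(K):
        n_s = (states == s).sum()
        if n_s == 0:
            rows.append({"state": s, "visited": False,
                         "time_fraction": np.nan, "stickiness": np.nan,
                         "mean_dwell_s": np.nan})
            continue
        out_of_s = trans_from == s
        stick = (
            (trans_to[out_of_s] == s).mean() if out_of_s.any() else np.nan
        )
        starts = np.flatnonzero(
            (states == s) & np.r_[True, states[:-1] != s]
        )
        ends = np.flatnonzero(
            (states == s) & np.r_[states[1:] != s, True]
        )
        dwell = (ends - starts + 1).mean() / fps
        rows.append({"state": s, "visited": True,
                     "time_fraction": n_s / len(states),
                     "stickiness": stick, "mean_dwell_s": dwell})
    return pd.DataFrame(rows)


def match_states(decoded: np.ndarray, truth: np.ndarray, K: int) -> np.ndarray:
    """Optimal label alignment: relabel decoded states to best match truth."""
    conf = np.zeros((K, K))
    np.add.at(conf, (decoded, truth), 1)
    row, col = linear_sum_assignment(-conf)
    mapping = dict(zip(row, col))
    return np.array([mapping.get(s, s) for s in decoded])
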