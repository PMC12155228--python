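"""Single-neuron event analysis for calcium populations.

PSTHs are built per neuron by z-scoring every trial against its own pre-cue
baseline — z = (F(t) − Fm)/SD with Fm, SD from the baseline window — then
averaging a matched number of trials per event type.  Responsiveness is a
paired Wilcoxon signed-rank test of per-trial baseline vs post-event means,
signed by the mean z over the 15 s response window.  Response profiles
concatenated across event types are clustered by Ward linkage on
correlation distances, cut at a fraction of the maximum linkage height, and
summarized as per-condition cluster enrichment, excitation/inhibition
overlap classes, and cross-condition flow tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2_contingency, wilcoxon

from .core import CalciumSession, TrialTable, align_windows

logger = logging.getLogger("ethophys")


def compute_psth(session: CalciumSession, event_type: str,
                 window_s=(-5.0, 15.0), z_baseline_s=(-1.0, 0.0),
                 n_trials: int | None = None, seed: int = 0):
    """Trial z-score tensor and PSTH for one event type.

    Each trial of each neuron is z-scored against that trial's own baseline
    (``z_baseline_s`` relative to onset); the PSTH averages across trials.
    With ``n_trials`` set, a fixed-seed subsample matches trial counts
    across event types.  Trials with zero baseline SD are excluded for that
    neuron (logged).

    Returns (psth, trial_z, time_s): psth is neurons × bins, trial_z is
    trials × neurons × bins with NaN for excluded trials.
    """
    table = session.event_tables[event_type]
    if table.n_trials < 1:
        raise ValueError(f"no trials for event {event_type!r}")
    pre, post = -window_s[0], window_s[1]
    idx, kept = align_windows(session.t, table.onsets, pre, post)
    if n_trials is not None and idx.shape[0] > n_trials:
        rng = np.random.default_rng(seed)
        sel = np.sort(rng.choice(idx.shape[0], size=n_trials, replace=False))
        idx = idx[sel]
    b0 = int(round((z_baseline_s[0] + pre) * session.fs))
    b1 = int(round((z_baseline_s[1] + pre) * session.fs))
    windows = session.dff[:, idx]              # neurons × trials × bins
    mu = windows[:, :, b0:b1].mean(axis=2, keepdims=True)
    sd = windows[:, :, b0:b1].std(axis=2, ddof=0, keepdims=True)
    bad = sd[:, :, 0] == 0
    if bad.any():
        logger.info("excluded %d neuron-trials with zero baseline SD",
                    int(bad.sum()))
    sd[sd == 0] = np.nan
    z = (windows - mu) / sd                    # NaN where excluded
    psth = np.nanmean(z, axis=1)
    time_s = (np.arange(idx.shape[1]) - int(round(pre * session.fs))) / session.fs
    return psth, np.transpose(z, (1, 0, 2)), time_s


def classify_responsiveness(trial_z, time_s, baseline_s=5.0, response_s=5.0,
                            sign_window_s=15.0, alpha=0.05,
                            min_trials=6, fdr=False) -> pd.DataFrame:
    """Excited / inhibited / none call per neuron for one event type.

    Per-trial means over the pre-event baseline window (length
    ``baseline_s``) and the first ``response_s`` post-event are compared by
    a paired Wilcoxon signed-rank test; significant neurons are signed by
    their mean z over the ``sign_window_s`` response window.  Neurons with
    fewer than ``min_trials`` usable trials are called "none" and flagged.
    Tests are per-neuron and uncorrected by default; ``fdr=True`` applies
    Benjamini–Hochberg across neurons.
    """
    trial_z = np.asarray(trial_z, float)       # trials × neurons × bins
    mb = (time_s >= -baseline_s) & (time_s < 0)
    mr = (time_s >= 0) & (time_s < response_s)
    ms = (time_s >= 0) & (time_s < sign_window_s)
    rows = []
    n_neurons = trial_z.shape[1]
    for n in range(n_neurons):
        zt = trial_z[:, n, :]
        ok = ~np.isnan(zt).any(axis=1)
        base = zt[ok][:, mb].mean(axis=1)
        resp = zt[ok][:, mr].mean(axis=1)
        if ok.sum() < min_trials:
            rows.append({"neuron": n, "call": "none", "p": np.nan,
                         "stat": np.nan, "mean_z": np.nan,
                         "flagged": True})
            continue
        diff = resp - base
        if np.allclose(diff, 0):
            p, stat = 1.0, 0.0
        else:
            res = wilcoxon(resp, base, zero_method="wilcox")
            p, stat = float(res.pvalue), float(res.statistic)
        mean_z = float(np.nanmean(zt[ok][:, ms]))
        rows.append({"neuron": n, "call": None, "p": p, "stat": stat,
                     "mean_z": mean_z, "flagged": False})
    df = pd.DataFrame(rows)
    pvals = df["p"].to_numpy()
    if fdr:
        from statsmodels.stats.multitest import multipletests

        ok = np.isfinite(pvals)
        rej = np.zeros(len(df), bool)
        rej[ok] = multipletests(pvals[ok], alpha=alpha, method="fdr_bh")[0]
        sig = rej
    else:
        sig = pvals < alpha
    call = np.where(~sig | df["flagged"], "none",
                    np.where(df["mean_z"] > 0, "excited", "inhibited"))
    df["call"] = call
    return df


@dataclass
class ClusterAssignment:
    labels: np.ndarray           # −1 for excluded neurons
    linkage: np.ndarray
    cutoff: float
    valid: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels >= 0]))


def cluster_profiles(profiles, cutoff_frac=0.30, metric="correlation"
                     ) -> ClusterAssignment:
    """Ward-linkage hierarchical clustering of concatenated PSTH profiles.

    ``profiles`` is neurons × features (PSTHs of all event types
    concatenated per neuron).  Pairwise distance is 1 − Pearson correlation;
    Ward linkage is computed on that precomputed distance matrix — the
    common statistical-toolbox behavior, kept for fidelity even though Ward
    formally presumes squared Euclidean distances (``metric="euclidean"``
    switches to Euclidean on the profiles).  Flat clusters come from
    cutting at ``cutoff_frac`` × the maximum linkage height.  Constant
    (zero-variance) profiles have undefined correlation and are excluded
    with label −1.
    """
    X = np.asarray(profiles, float)
    valid = X.std(axis=1) > 0 if metric == "correlation" else np.ones(
        len(X), bool
    )
    Xv = X[valid]
    if len(Xv) < 2:
        raise ValueError("need >= 2 clusterable profiles")
    d = pdist(Xv, metric=metric)
    Z = linkage(d, method="ward")
    cutoff = cutoff_frac * Z[:, 2].max()
    flat = fcluster(Z, t=cutoff, criterion="distance")
    labels = np.full(len(X), -1, dtype=int)
    labels[valid] = flat - 1
    return ClusterAssignment(labels=labels, linkage=Z, cutoff=float(cutoff),
                             valid=valid)


def cluster_enrichment(labels, conditions) -> pd.DataFrame:
    """% of each condition's neurons falling in each cluster.

    Rows are clusters (excluded = −1 included as its own row); columns per
    condition sum to 100.
    """
    labels = np.asarray(labels)
    conditions = np.asarray(conditions)
    conds = np.unique(conditions)
    if len(labels) == 0 or len(conds) == 0:
        raise ValueError("no neurons/conditions to tabulate")
    for c in conds:
        if (conditions == c).sum() == 0:
            raise ValueError(f"empty condition {c}")
    rows = []
    for cl in np.unique(labels):
        row = {"cluster": cl}
        for c in conds:
            sel = conditions == c
            row[f"pct_{c}"] = 100.0 * np.mean(labels[sel] == cl)
        rows.append(row)
    return pd.DataFrame(rows)


_SIGN = {"excited": "+", "inhibited": "-", "none": "0"}


def overlap_classes(calls_by_event: dict) -> pd.DataFrame:
    """Per-neuron excitation/inhibition code across event types.

    ``calls_by_event`` maps event name → responsiveness DataFrame (from
    :func:`classify_responsiveness`, same neuron order).  The code
    concatenates one of {+, −, 0} per event (e.g. ``A+NA0P+``), and counts
    per code are returned alongside the per-neuron table.
    """
    events = list(calls_by_event)
    n = len(calls_by_event[events[0]])
    codes = []
    for i in range(n):
        code = "".join(
            f"{ev}{_SIGN[calls_by_event[ev]['call'].iloc[i]]}" for ev in events
        )
        codes.append(code)
    return pd.DataFrame({"neuron": np.arange(n), "code": codes})


def overlap_chi2(codes_by_condition: dict):
    """Chi-squared test of overlap-class proportions across conditions."""
    all_codes = sorted({c for v in codes_by_condition.values()
                        for c in v["code"]})
    table = np.array([
        [(v["code"] == c).sum() for c in all_codes]
        for v in codes_by_condition.values()
    ])
    keep = table.sum(axis=0) > 0
    chi2, p, dof, _ = chi2_contingency(table[:, keep])
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof),
            "table": pd.DataFrame(table, columns=all_codes,
                                  index=list(codes_by_condition))}


def flow_table(source_labels, target_labels, coreg: dict | None = None
               ) -> pd.DataFrame:
    """Source class → target class counts for alluvial export.

    ``coreg`` maps source neuron index → target neuron index (identity when
    None).
    """
    source_labels = np.asarray(source_labels)
    target_labels = np.asarray(target_labels)
    if coreg is None:
        coreg = {i: i for i in range(len(source_labels))}
    rows = {}
    for si, ti in coreg.items():
        key = (source_labels[si], target_labels[ti])
        rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [{"source": s, "target": t, "count": c} for (s, t), c in
         sorted(rows.items(), key=lambda kv: str(kv[0]))]
    )
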