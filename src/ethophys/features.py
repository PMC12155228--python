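"""Kinematic features from keypoint tracks, and simple behavioral scores.

The feature set mirrors the standard pose-derived description of a mouse in
a divided arena: port-referenced distance/angle, body velocity and
acceleration (backward differences, causal), head/body/tail orientations,
signed turning angle, path tortuosity over 1 s and 5 s windows, nose–tail
distance and its derivative, arena zone, and barrier-contact /
port-orientation flags.  Continuous features are z-scored over the whole
session; discrete flags pass through untouched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ArenaGeometry, KeypointTrack, TrialTable, align_windows

logger = logging.getLogger("ethophys")

CONTINUOUS = (
    "dist_to_port", "angle_to_port", "velocity", "acceleration",
    "head_body_orient", "head_tail_orient", "turning_angle",
    "tortuosity_1s", "tortuosity_5s", "nose_tail_dist", "d_nose_tail_dist",
)
DISCRETE = ("zone", "touching_barrier", "oriented_to_port",
            "oriented_and_touching")


@dataclass
class FeatureMatrix:
    values: np.ndarray          # frames × features
    names: tuple
    continuous_mask: np.ndarray
    fps: float = 30.0

    def col(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))


def preprocess_track(track: KeypointTrack, smooth_win: int = 5) -> KeypointTrack:
    """Interpolate missing keypoints, then moving-average smooth.

    Interior NaNs are filled by per-node linear interpolation; NaNs at the
    edges extend the nearest value.  Smoothing is a centered moving average
    of ``smooth_win`` frames (1 = no smoothing).  Raises if a node has fewer
    than 2 tracked samples.
    """
    coords = track.coords.copy()
    n = coords.shape[0]
    idx = np.arange(n)
    for j, name in enumerate(track.node_names):
        for d in range(2):
            y = coords[:, j, d]
            ok = np.isfinite(y)
            if ok.sum() < 2:
                raise ValueError(f"node {name!r} has <2 tracked samples")
            if not ok.all():
                coords[:, j, d] = np.interp(idx, idx[ok], y[ok])
    if smooth_win > 1:
        kernel = np.ones(smooth_win) / smooth_win
        pad = smooth_win // 2
        for j in range(coords.shape[1]):
            for d in range(2):
                y = np.pad(coords[:, j, d], pad, mode="edge")
                sm = np.convolve(y, kernel, mode="valid")
                coords[:, j, d] = sm[:n]
    return KeypointTrack(coords=coords, node_names=track.node_names,
                         fps=track.fps, confidence=track.confidence)


def _unit(v, eps=1e-9):
    return v / np.maximum(np.linalg.norm(v, axis=-1, keepdims=True), eps)


def _angle_between(u, v):
    """Unsigned angle in degrees between row vectors of u and v, in [0, 180]."""
    c = np.clip(np.sum(_unit(u) * _unit(v), axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(c))


def _tortuosity(torso, win, eps_d=1.0, cap=50.0):
    """Path length / net displacement over a trailing window of `win` frames.

    Where the net displacement is below ``eps_d`` px the ratio is computed
    against ``eps_d`` and capped at ``cap`` (a stationary mouse has maximal
    tortuosity, not an undefined one).
    """
    n = len(torso)
    steps = np.linalg.norm(np.diff(torso, axis=0), axis=1)
    csum = np.concatenate([[0.0], np.cumsum(steps)])
    out = np.ones(n)
    t = np.arange(n)
    t0 = np.maximum(t - win, 0)
    path = csum[t] - csum[t0]
    net = np.linalg.norm(torso[t] - torso[t0], axis=1)
    small = net < eps_d
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(small, path / eps_d, path / np.maximum(net, eps_d))
    out = np.minimum(np.maximum(ratio, 1.0), cap)
    out[path == 0] = cap  # fully stationary window
    return out


def compute_features(
    track: KeypointTrack,
    arena: ArenaGeometry,
    tortuosity_windows_s=(1.0, 5.0),
    eps_d: float = 1.0,
    cap: float = 50.0,
) -> FeatureMatrix:
    """Per-frame feature matrix from a preprocessed (NaN-free) track."""
    if not np.all(np.isfinite(track.coords)):
        raise ValueError("track must be preprocessed (no NaN)")
    fps = track.fps
    torso = track.node("torso")
    nose = track.node("nose")
    tail = track.node("tail_base")
    port = np.asarray(arena.port_xy, float)

    heading = nose - torso                      # torso→nose
    to_port = port - torso
    dist_to_port = np.linalg.norm(to_port, axis=1)
    angle_to_port = _angle_between(heading, to_port)

    step = np.vstack([[0.0, 0.0], np.diff(torso, axis=0)])
    velocity = np.linalg.norm(step, axis=1) * fps
    acceleration = np.concatenate([[0.0], np.diff(velocity)]) * fps

    body_axis = torso - tail
    head_body = _angle_between(heading, body_axis)
    head_tail = _angle_between(nose - tail, body_axis)

    hang = np.degrees(np.arctan2(heading[:, 1], heading[:, 0]))
    dh = np.concatenate([[0.0], np.diff(hang)])
    turning = (dh + 180.0) % 360.0 - 180.0
    turning[turning == -180.0] = 180.0          # wrap to (−180, 180]

    tort = {
        f"tortuosity_{int(w)}s": _tortuosity(
            torso, max(int(round(w * fps)), 1), eps_d, cap
        )
        for w in tortuosity_windows_s
    }

    nose_tail = np.linalg.norm(nose - tail, axis=1)
    d_nose_tail = np.concatenate([[0.0], np.diff(nose_tail)])

    zone = arena.zone_of(torso).astype(float)
    touching = (arena.dist_to_barrier(nose) <= arena.contact_eps).astype(float)
    oriented = (angle_to_port < arena.orient_thresh).astype(float)
    both = touching * oriented

    cols = {
        "dist_to_port": dist_to_port,
        "angle_to_port": angle_to_port,
        "velocity": velocity,
        "acceleration": acceleration,
        "head_body_orient": head_body,
        "head_tail_orient": head_tail,
        "turning_angle": turning,
        **tort,
        "nose_tail_dist": nose_tail,
        "d_nose_tail_dist": d_nose_tail,
        "zone": zone,
        "touching_barrier": touching,
        "oriented_to_port": oriented,
        "oriented_and_touching": both,
    }
    names = tuple(cols)
    values = np.column_stack([cols[n] for n in names])
    cont = np.array([n in CONTINUOUS or n.startswith("tortuosity")
                     for n in names])
    return FeatureMatrix(values=values, names=names, continuous_mask=cont,
                         fps=fps)


def zscore_and_window(fm: FeatureMatrix, trials: TrialTable):
    """Session-level z-scoring of continuous features, then per-trial windows.

    Continuous features are z-scored over all frames of the session (a
    zero-SD feature maps to 0 with a warning); discrete features pass
    through.  Windows cover ``[onset, onset + window_dur)`` per trial.

    Returns (tensor, kept): tensor is trials × round(window_dur·fps) ×
    features; kept is the kept-trial mask from :func:`align_windows`.
    """
    vals = fm.values.copy()
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0)
    for j in np.flatnonzero(fm.continuous_mask):
        if sd[j] == 0:
            warnings.warn(f"feature {fm.names[j]!r} has zero SD; z set to 0")
            vals[:, j] = 0.0
        else:
            vals[:, j] = (vals[:, j] - mu[j]) / sd[j]
    t = np.arange(vals.shape[0]) / fm.fps
    idx, kept = align_windows(t, trials.onsets, 0.0, trials.window_dur)
    tensor = vals[idx]  # trials × time × features
    return tensor, kept


# ---------------------------------------------------------------------------
# behavioral outcome scores
# ---------------------------------------------------------------------------

def normalized_lick(paradigm_s: float, baseline_s: float) -> float:
    """Hot-plate Normalized Lick Duration = paradigm / baseline.

    Baseline 0 yields NaN (flagged, not raised): the ratio is undefined for
    a mouse that never licked at baseline.
    """
    if paradigm_s < 0 or baseline_s < 0:
        raise ValueError("durations must be >= 0")
    if baseline_s == 0:
        warnings.warn("baseline lick duration is 0; normalized score is NaN")
        return float("nan")
    return paradigm_s / baseline_s


def difference_lick(paradigm_s: float, baseline_s: float) -> float:
    """Hot-plate Difference Lick Score = paradigm − baseline."""
    if paradigm_s < 0 or baseline_s < 0:
        raise ValueError("durations must be >= 0")
    return paradigm_s - baseline_s


def social_rank(wins: int, contests: int) -> float:
    """Tube-test social rank = proportion of wins across all contests."""
    if contests <= 0:
        raise ValueError("contest list must be nonempty")
    return wins / contests


def freeze_mask(fm: FeatureMatrix, v_th: float, a_th: float) -> np.ndarray:
    """Frames scored as freezing: velocity < v_th and |acceleration| < a_th."""
    if v_th <= 0 or a_th <= 0:
        raise ValueError("thresholds must be > 0")
    return (fm.col("velocity") < v_th) & (np.abs(fm.col("acceleration")) < a_th)
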