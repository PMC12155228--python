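"""Shared domain types, file IO, and event-to-window alignment.

Conventions used throughout the package:

* time is in seconds; within a trial the cue onset is t = 0 and windows are
  half-open ``[start, end)`` — the sample containing the onset belongs to the
  post-onset period;
* coordinates follow the image convention (origin top-left, x right, y down,
  units px) with 0-based frame indices;
* missing keypoints are carried as NaN and resolved only in
  :func:`ethophys.features.preprocess_track`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath

logger = logging.getLogger("ethophys")

#: 9-point skeleton of the tracked subject mouse, in canonical order.
DEFAULT_NODE_NAMES = (
    "nose",
    "right_ear",
    "left_ear",
    "torso",
    "left_forepaw",
    "right_forepaw",
    "left_hindpaw",
    "right_hindpaw",
    "tail_base",
)

#: Social-task condition labels: Social Exclusion, One Mouse, Tone Only.
SOCIAL_CONDITIONS = ("SE", "OM", "TO")


class FormatError(ValueError):
    """A file is missing a required dataset/column or has the wrong shape."""


@dataclass
class KeypointTrack:
    """Per-frame 2-D node coordinates of the subject mouse.

    Attributes
    ----------
    coords : ndarray, shape (frames, nodes, 2)
        Pixel coordinates; NaN marks missing tracking.
    node_names : tuple of str
        Ordered node labels, unique.
    fps : float
        Video frame rate (frames/s), > 0.
    confidence : ndarray or None, shape (frames, nodes)
        Optional per-node tracking confidence in [0, 1].
    """

    coords: np.ndarray
    node_names: tuple = DEFAULT_NODE_NAMES
    fps: float = 30.0
    confidence: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise FormatError(
                f"coords must be (frames, nodes, 2), got {self.coords.shape}"
            )
        self.node_names = tuple(self.node_names)
        if len(set(self.node_names)) != len(self.node_names):
            raise ValueError("node_names must be unique")
        if self.coords.shape[1] != len(self.node_names):
            raise FormatError(
                f"{self.coords.shape[1]} nodes in coords vs "
                f"{len(self.node_names)} node names"
            )
        if not self.fps > 0:
            raise ValueError("fps must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def node(self, name: str) -> np.ndarray:
        """Coordinates of one node, shape (frames, 2)."""
        return self.coords[:, self.node_names.index(name), :]


@dataclass
class TrialTable:
    """Cue onsets plus condition and optional per-trial labels.

    ``onsets`` are in seconds, strictly increasing.  ``labels``, when present,
    is a length-``n_trials`` sequence (e.g. Attending/NotAttending or
    reward/shock).
    """

    onsets: np.ndarray
    condition: str = "SE"
    cue_dur: float = 10.0
    window_dur: float = 15.0
    labels: np.ndarray | None = None
    allowed_conditions: tuple = SOCIAL_CONDITIONS

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.ndim != 1:
            raise ValueError("onsets must be 1-D")
        if self.n_trials and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if self.allowed_conditions and self.condition not in self.allowed_conditions:
            raise ValueError(
                f"unknown condition {self.condition!r}; "
                f"expected one of {self.allowed_conditions}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.n_trials:
                raise ValueError(
                    f"labels length {len(self.labels)} != n_trials {self.n_trials}"
                )

    @property
    def n_trials(self) -> int:
        return len(self.onsets)


@dataclass
class ArenaGeometry:
    """Static geometry of the divided test arena.

    The barrier is a line segment in px; ``zones`` are named polygons
    (arrays of (x, y) vertices) partitioning the arena; ``port_xy`` is the
    reward-port location on the far side of the barrier.
    """

    width: float = 400.0
    height: float = 300.0
    port_xy: tuple = (40.0, 150.0)
    barrier: tuple = ((100.0, 0.0), (100.0, 300.0))
    zones: dict = field(default_factory=dict)
    contact_eps: float = 15.0
    orient_thresh: float = 45.0

    def __post_init__(self):
        if not self.contact_eps > 0:
            raise ValueError("contact_eps must be > 0")
        if not self.zones:
            # default: three vertical bands on the subject side of the barrier
            bx = self.barrier[0][0]
            span = self.width - bx
            edges = [bx, bx + span / 3, bx + 2 * span / 3, self.width]
            names = ["near_barrier", "middle", "far"]
            self.zones = {
                name: np.array(
                    [(e0, 0.0), (e1, 0.0), (e1, self.height), (e0, self.height)]
                )
                for name, (e0, e1) in zip(names, zip(edges[:-1], edges[1:]))
            }
        self.zone_names = tuple(self.zones)

    def zone_of(self, xy: np.ndarray) -> np.ndarray:
        """Zone index per point (−1 if outside all zones); xy shape (n, 2)."""
        xy = np.atleast_2d(xy)
        out = np.full(len(xy), -1, dtype=int)
        for i, name in enumerate(self.zone_names):
            path = _MplPath(np.asarray(self.zones[name]))
            # radius of either sign makes boundary points inclusive
            # regardless of polygon orientation
            hit = path.contains_points(xy, radius=1e-9) | path.contains_points(
                xy, radius=-1e-9
            )
            out[(out == -1) & hit] = i
        return out

    def dist_to_barrier(self, xy: np.ndarray) -> np.ndarray:
        """Euclidean point-to-segment distance to the barrier, shape (n,)."""
        p0 = np.asarray(self.barrier[0], float)
        p1 = np.asarray(self.barrier[1], float)
        d = p1 - p0
        xy = np.atleast_2d(xy)
        t = np.clip(((xy - p0) @ d) / (d @ d), 0.0, 1.0)
        proj = p0 + t[:, None] * d
        return np.linalg.norm(xy - proj, axis=1)


@dataclass
class PhotometrySession:
    """Two-channel fiber-photometry recording with trial alignment.

    ``signal`` is the sensor channel (470 nm excitation) and ``reference``
    the calcium-independent channel (405/415 nm), both sampled uniformly at
    ``fs`` Hz on the shared time base ``t``.
    """

    t: np.ndarray
    signal: np.ndarray
    reference: np.ndarray
    fs: float = 20.0
    trial_table: TrialTable | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.signal = np.asarray(self.signal, float)
        self.reference = np.asarray(self.reference, float)
        if not (len(self.t) == len(self.signal) == len(self.reference)):
            raise ValueError("t, signal, reference must have equal length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
                raise ValueError("t must be uniform at 1/fs")


@dataclass
class CalciumSession:
    """Extracted ΔF/F0 traces (neurons × frames) with event alignment.

    ``event_tables`` maps event-type name (e.g. "Attending", "pinprick") to a
    :class:`TrialTable`.  ``coreg``, when present, maps this session's neuron
    indices to another session's (injective).
    """

    dff: np.ndarray
    fs: float = 10.0
    animal_id: str = "m0"
    condition: str = "SE"
    event_tables: dict = field(default_factory=dict)
    coreg: dict | None = None

    def __post_init__(self):
        self.dff = np.asarray(self.dff, float)
        if self.dff.ndim != 2:
            raise ValueError("dff must be neurons × frames")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff must be finite")
        if not self.fs > 0:
            raise ValueError("fps must be > 0")
        if self.coreg is not None:
            vals = list(self.coreg.values())
            if len(set(vals)) != len(vals):
                raise ValueError("coreg must be injective")

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.dff.shape[1]) / self.fs


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_keypoints(path, dialect: str = "auto") -> KeypointTrack:
    """Read a keypoint track from an analysis HDF5 or a wide CSV.

    The HDF5 dialect expects datasets ``tracks`` (frames×nodes×2 or
    nodes×2×frames, auto-detected from the axis of length 2) and
    ``node_names``; the CSV dialect expects columns ``frame`` plus
    ``<node>_x``/``<node>_y`` pairs.  Missing tracking reads as NaN.
    """
    path = str(path)
    if dialect == "auto":
        dialect = "h5" if path.endswith((".h5", ".hdf5", ".slp.h5")) else "csv"
    if dialect == "h5":
        with h5py.File(path, "r") as f:
            for key in ("tracks", "node_names"):
                if key not in f:
                    raise FormatError(f"HDF5 file missing dataset {key!r}")
            tracks = np.asarray(f["tracks"], dtype=float)
            names = [
                n.decode() if isinstance(n, bytes) else str(n)
                for n in f["node_names"][()]
            ]
            fps = float(f.attrs.get("fps", 30.0))
        if tracks.ndim == 4:  # single-track SLEAP layout (1, nodes, 2, frames)
            tracks = tracks[0]
        if tracks.ndim != 3:
            raise FormatError(f"tracks must be 3-D, got shape {tracks.shape}")
        if tracks.shape[2] == 2:  # frames × nodes × 2
            coords = tracks
        elif tracks.shape[1] == 2:  # nodes × 2 × frames
            coords = np.transpose(tracks, (2, 0, 1))
        else:
            raise FormatError(f"cannot orient tracks of shape {tracks.shape}")
        return KeypointTrack(coords=coords, node_names=tuple(names), fps=fps)
    # wide CSV
    df = pd.read_csv(path, float_precision="round_trip")
    if "frame" not in df.columns:
        raise FormatError("CSV missing required column 'frame'")
    names = []
    for col in df.columns:
        if col.endswith("_x"):
            node = col[:-2]
            if f"{node}_y" not in df.columns:
                raise FormatError(f"CSV missing column '{node}_y'")
            names.append(node)
    if not names:
        raise FormatError("CSV has no '<node>_x' coordinate columns")
    df = df.sort_values("frame")
    coords = np.stack(
        [df[[f"{n}_x", f"{n}_y"]].to_numpy(float) for n in names], axis=1
    )
    return KeypointTrack(coords=coords, node_names=tuple(names))


def write_keypoints(track: KeypointTrack, path, dialect: str = "auto") -> None:
    """Write a track in a format :func:`read_keypoints` round-trips."""
    path = str(path)
    if dialect == "auto":
        dialect = "h5" if path.endswith((".h5", ".hdf5")) else "csv"
    if dialect == "h5":
        with h5py.File(path, "w") as f:
            f.create_dataset("tracks", data=track.coords)
            f.create_dataset(
                "node_names", data=np.array([n.encode() for n in track.node_names])
            )
            f.attrs["fps"] = track.fps
        return
    cols = {"frame": np.arange(track.n_frames)}
    for i, n in enumerate(track.node_names):
        cols[f"{n}_x"] = track.coords[:, i, 0]
        cols[f"{n}_y"] = track.coords[:, i, 1]
    # repr-precision floats so the round trip is value-identical
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_events(path, allowed_conditions: tuple = SOCIAL_CONDITIONS) -> TrialTable:
    """Read a trial event table (CSV/TSV with ``onset`` and ``condition``).

    Onsets are sorted ascending; condition must come from
    ``allowed_conditions``.  An optional ``label`` column is carried through.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if len(df) == 0:
        return TrialTable(onsets=np.array([]), condition=allowed_conditions[0],
                          allowed_conditions=allowed_conditions)
    for col in ("onset", "condition"):
        if col not in df.columns:
            raise FormatError(f"event table missing column {col!r}")
    df = df.sort_values("onset")
    conds = df["condition"].unique()
    if len(conds) != 1:
        raise ValueError(f"event table mixes conditions {sorted(conds)}")
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return TrialTable(
        onsets=df["onset"].to_numpy(float),
        condition=str(conds[0]),
        labels=labels,
        allowed_conditions=allowed_conditions,
    )


def write_events(table: TrialTable, path) -> None:
    df = pd.DataFrame({"onset": table.onsets})
    df["condition"] = table.condition
    if table.labels is not None:
        df["label"] = table.labels
    df.to_csv(path, index=False)


def align_windows(
    series_t: np.ndarray,
    onsets: np.ndarray,
    pre_s: float,
    post_s: float,
):
    """Map each event onset to contiguous sample indices of its trial window.

    The window is the half-open interval ``[onset − pre_s, onset + post_s)``;
    the sample at exactly the onset belongs to the post period.  Trials whose
    window falls outside the recording span are dropped with a warning.

    Returns
    -------
    indices : ndarray, shape (n_kept, L)
        L = round((pre_s + post_s) · fs) sample indices per kept trial.
    kept : ndarray of bool, shape (n_trials,)
        Mask of trials that were kept, so drops never silently change
        ``n_trials``.
    """
    if pre_s < 0 or post_s < 0:
        raise ValueError("pre_s and post_s must be >= 0")
    series_t = np.asarray(series_t, float)
    onsets = np.asarray(onsets, float)
    if len(series_t) < 2:
        raise ValueError("series_t must have at least 2 samples")
    fs = 1.0 / (series_t[1] - series_t[0])
    n = len(series_t)
    length = int(round((pre_s + post_s) * fs))
    kept = np.zeros(len(onsets), dtype=bool)
    rows = []
    for i, onset in enumerate(onsets):
        start = int(round((onset - pre_s - series_t[0]) * fs))
        if start < 0 or start + length > n:
            warnings.warn(
                f"trial {i} at onset {onset:g}s falls outside the recording; dropped"
            )
            logger.warning("dropped trial %d (onset %g s)", i, onset)
            continue
        kept[i] = True
        rows.append(np.arange(start, start + length))
    indices = (
        np.array(rows, dtype=int) if rows else np.empty((0, length), dtype=int)
    )
    return indices, kept
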