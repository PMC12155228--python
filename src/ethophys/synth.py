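"""Synthetic-data generators with planted ground truth.

Every pipeline input can be generated here: state-structured keypoint
kinematics, attending-frame images with point labels, trial-locked
two-channel photometry with a shared motion artifact, and cluster-structured
multi-animal calcium populations.  All generators are pure functions of
(config, seed): the global seed expands into independent substreams (state
sequence, walk noise, artifact, ...) so individual pieces can be regenerated
in isolation.

The defaults encode the study conditions the pipeline targets: 60-trial
sessions with 40–60 s inter-trial intervals and a 10 s cue, 30 fps video,
20 Hz two-channel photometry, 10 Hz ΔF/F0 traces, and four latent behavioral
states of which one is "attending at the barrier, oriented to the port".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter1d

from .core import (
    DEFAULT_NODE_NAMES,
    ArenaGeometry,
    CalciumSession,
    KeypointTrack,
    PhotometrySession,
    TrialTable,
)


# ---------------------------------------------------------------------------
# behavior sessions
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSimConfig:
    """Latent-state keypoint simulation.

    ``states`` is a list of dicts with keys ``anchor`` (px), ``speed``
    (mean-reversion step scale, px/frame), ``noise`` (walk noise sd,
    px/frame) and ``oriented_to_port`` (bool).  ``attending_state`` names the
    state whose anchor sits at the barrier.  When ``trial_attend_p`` is set,
    each trial independently becomes an attending trial with that
    probability, and during the cue window the chain is biased into (or away
    from) the attending state.
    """

    n_trials: int = 60
    iti_range_s: tuple = (40.0, 60.0)
    cue_dur_s: float = 10.0
    window_dur_s: float = 15.0
    fps: float = 30.0
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    states: list | None = None
    transition: np.ndarray | None = None
    start_state: int | None = None
    attending_state: int = 3
    trial_attend_p: float | None = None
    attend_bias: float = 0.97
    theta: float = 0.15          # mean-reversion rate per frame
    head_len: float = 18.0       # torso→nose distance, px
    condition: str = "SE"
    seed: int = 0

    def __post_init__(self):
        a = self.arena
        if self.states is None:
            bx = a.barrier[0][0]
            self.states = [
                {"anchor": (a.width * 0.85, a.height * 0.85), "speed": 1.0,
                 "noise": 1.0, "oriented_to_port": False},          # rest, far corner
                {"anchor": (a.width * 0.6, a.height * 0.4), "speed": 2.0,
                 "noise": 3.0, "oriented_to_port": False},          # explore
                {"anchor": (a.width * 0.75, a.height * 0.2), "speed": 4.0,
                 "noise": 6.0, "oriented_to_port": False},          # locomote
                {"anchor": (bx + 6.0, a.height * 0.5), "speed": 3.0,
                 "noise": 1.0, "oriented_to_port": True},           # attend at barrier
            ]
        k = len(self.states)
        if self.transition is None:
            self.transition = np.full((k, k), 0.02 / (k - 1))
            np.fill_diagonal(self.transition, 0.98)
        self.transition = np.asarray(self.transition, float)
        rows = self.transition.sum(axis=1)
        if not np.allclose(rows, 1.0):
            raise ValueError("transition rows must sum to 1")
        if k < 2:
            raise ValueError("need at least 2 states")

    @property
    def n_states(self) -> int:
        return len(self.states)


@njit(cache=True)
def _ou_walk(anchors, theta, noise_sd, noise):  # pragma: no cover - numba
    n = anchors.shape[0]
    pos = np.empty((n, 2))
    pos[0] = anchors[0]
    for t in range(1, n):
        for d in range(2):
            pos[t, d] = (
                pos[t - 1, d]
                + theta * (anchors[t, d] - pos[t - 1, d])
                + noise_sd[t] * noise[t, d]
            )
    return pos


def _sample_chain(rng, transition, n, start=None):
    k = transition.shape[0]
    cum = np.cumsum(transition, axis=1)
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.integers(k) if start is None else start
    u = rng.random(n)
    for t in range(1, n):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    return states


def make_trial_table(
    rng, n_trials, iti_range_s, cue_dur_s=10.0, window_dur_s=15.0,
    condition="SE", lead_s=20.0,
) -> TrialTable:
    """Onsets with jittered inter-trial intervals after an initial lead-in."""
    itis = rng.uniform(iti_range_s[0], iti_range_s[1], size=n_trials)
    onsets = lead_s + np.cumsum(itis)
    return TrialTable(onsets=onsets, condition=condition, cue_dur=cue_dur_s,
                      window_dur=window_dur_s)


def gen_behavior_session(cfg: BehaviorSimConfig):
    """Simulate one session: keypoints + trials + true per-frame state.

    The torso performs a mean-reverting walk toward the current state's
    anchor; the nose is placed ahead of the torso along the heading, which
    points at the port in the attending state and along the direction of
    motion otherwise.  Remaining skeleton nodes are rigid body-frame offsets
    plus jitter.

    Returns
    -------
    (KeypointTrack, TrialTable, states, trial_attend)
        ``states`` is the true frame-resolution state sequence;
        ``trial_attend`` the per-trial attending truth (None when
        ``trial_attend_p`` is unset).
    """
    ss = np.random.SeedSequence(cfg.seed)
    r_trials, r_states, r_walk, r_body = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    trials = make_trial_table(
        r_trials, cfg.n_trials, cfg.iti_range_s, cfg.cue_dur_s,
        cfg.window_dur_s, cfg.condition,
    )
    dur = (trials.onsets[-1] if trials.n_trials else 0.0) + cfg.window_dur_s + 20.0
    n = int(round(dur * cfg.fps))
    states = _sample_chain(r_states, cfg.transition, n, cfg.start_state)

    trial_attend = None
    if cfg.trial_attend_p is not None:
        # bias the chain into/away from the attending state during cue windows
        trial_attend = r_trials.random(trials.n_trials) < cfg.trial_attend_p
        k = cfg.n_states
        att = cfg.attending_state
        t_in = np.full((k, k), (1 - cfg.attend_bias) / (k - 1))
        t_in[:, att] = cfg.attend_bias
        t_out = cfg.transition.copy()
        t_out[:, att] = 0.0
        t_out /= t_out.sum(axis=1, keepdims=True)
        cums = {True: np.cumsum(t_in, axis=1), False: np.cumsum(t_out, axis=1)}
        u = r_states.random(n)
        frame_flag = np.full(n, -1, dtype=np.int8)  # -1 outside windows
        for onset, a in zip(trials.onsets, trial_attend):
            i0 = int(round(onset * cfg.fps))
            i1 = min(n, int(round((onset + cfg.window_dur_s) * cfg.fps)))
            frame_flag[i0:i1] = int(a)
        for t in range(1, n):
            if frame_flag[t] >= 0:
                cum = cums[bool(frame_flag[t])]
                states[t] = np.searchsorted(cum[states[t - 1]], u[t])

    anchors = np.array([s["anchor"] for s in cfg.states], float)[states]
    noise_sd = np.array([s["noise"] for s in cfg.states], float)[states]
    speed = np.array([s["speed"] for s in cfg.states], float)[states]
    # faster states revert faster, so they actually travel
    theta_eff = cfg.theta
    torso = _ou_walk(anchors, theta_eff, noise_sd * np.sqrt(speed / 2.0),
                     r_walk.standard_normal((n, 2)))
    a = cfg.arena
    torso[:, 0] = np.clip(torso[:, 0], a.barrier[0][0] + 2.0, a.width - 2.0)
    torso[:, 1] = np.clip(torso[:, 1], 2.0, a.height - 2.0)

    # heading: toward port in oriented states, else smoothed motion direction
    vel = np.vstack([[0.0, 0.0], np.diff(torso, axis=0)])
    vel = gaussian_filter1d(vel, sigma=3.0, axis=0)
    heading = vel / np.maximum(np.linalg.norm(vel, axis=1, keepdims=True), 1e-6)
    oriented = np.array([s["oriented_to_port"] for s in cfg.states])[states]
    to_port = np.asarray(a.port_xy, float) - torso
    to_port /= np.maximum(np.linalg.norm(to_port, axis=1, keepdims=True), 1e-6)
    heading[oriented] = to_port[oriented]
    heading += 0.05 * r_body.standard_normal((n, 2))
    heading /= np.maximum(np.linalg.norm(heading, axis=1, keepdims=True), 1e-6)

    nose = torso + cfg.head_len * heading
    perp = np.stack([-heading[:, 1], heading[:, 0]], axis=1)
    jit = lambda s: s * r_body.standard_normal((n, 2))  # noqa: E731
    offsets = {
        "nose": nose,
        "right_ear": torso + 12.0 * heading + 6.0 * perp + jit(0.5),
        "left_ear": torso + 12.0 * heading - 6.0 * perp + jit(0.5),
        "torso": torso,
        "left_forepaw": torso + 8.0 * heading - 7.0 * perp + jit(1.0),
        "right_forepaw": torso + 8.0 * heading + 7.0 * perp + jit(1.0),
        "left_hindpaw": torso - 8.0 * heading - 7.0 * perp + jit(1.0),
        "right_hindpaw": torso - 8.0 * heading + 7.0 * perp + jit(1.0),
        "tail_base": torso - 16.0 * heading + jit(0.5),
    }
    coords = np.stack([offsets[name] for name in DEFAULT_NODE_NAMES], axis=1)
    track = KeypointTrack(coords=coords, fps=cfg.fps)
    return track, trials, states, trial_attend


# ---------------------------------------------------------------------------
# labeled frames for the detector
# ---------------------------------------------------------------------------

def gen_frames(track: KeypointTrack, attending_mask, image_size=(64, 64),
               arena: ArenaGeometry | None = None, seed: int = 0,
               noise_sd: float = 0.03, barrier_amp: float = 0.15):
    """Render desk-scale grayscale frames with point labels.

    Each frame contains a mouse-shaped blob at the (scaled) torso position
    and a faint vertical barrier edge.  On attending frames the blob is
    rendered elongated against the barrier (a rearing posture) and a point
    label of class ``"attending"`` is emitted at the nose — the posture makes
    the class discernible from static image features, which is the operating
    premise of a single-image detector.

    Returns (frames, labels) where frames is (n, H, W) float in [0, 1] and
    labels is a list of (frame_idx, class_name, x, y) point annotations.
    """
    attending_mask = np.asarray(attending_mask, bool)
    if len(attending_mask) != track.n_frames:
        raise ValueError("mask length must equal number of frames")
    arena = arena or ArenaGeometry()
    H, W = image_size
    sx, sy = W / arena.width, H / arena.height
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:H, 0:W]
    bx = arena.barrier[0][0] * sx
    barrier_img = barrier_amp * np.exp(-((xx - bx) ** 2) / (2 * 0.8**2))

    torso = track.node("torso")
    nose = track.node("nose")
    frames = np.empty((track.n_frames, H, W), dtype=np.float32)
    labels = []
    for i in range(track.n_frames):
        cx = np.clip(torso[i, 0] * sx, 4, W - 5)
        cy = np.clip(torso[i, 1] * sy, 6, H - 7)
        if attending_mask[i]:
            blob = np.exp(
                -((xx - cx) ** 2) / (2 * 2.0**2) - ((yy - cy) ** 2) / (2 * 5.5**2)
            )
            lx = float(np.clip(nose[i, 0] * sx, 0, W - 1))
            ly = float(np.clip(nose[i, 1] * sy, 0, H - 1))
            labels.append((i, "attending", lx, ly))
        else:
            blob = np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 3.5**2)
            )
        img = barrier_img + 0.9 * blob + noise_sd * rng.standard_normal((H, W))
        frames[i] = np.clip(img, 0.0, 1.0)
    return frames, labels


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

@dataclass
class PhotometrySimConfig:
    """Two-channel biosensor simulation.

    The shared motion artifact enters the reference channel with unit gain
    and the signal channel with ``artifact_gain``; trial-locked transients
    (fast rise, exponential decay) enter the signal channel only, with mean
    amplitude differing by ``delta_z`` (in baseline-noise z units) between
    attending and not-attending trials.  ``delta_z`` may be negative
    (oxytocin-like direction) or zero (null).
    """

    fs: float = 20.0
    artifact_sd: float = 2.5
    artifact_tau_s: float = 0.15
    artifact_gain: float = 0.8
    bleach_amp: float = 2.0
    bleach_tau_s: float = 600.0
    noise_sd: float = 0.05
    base_amp_z: float = 1.0
    delta_z: float = 1.0
    amp_jitter_z: float = 0.25
    rise_s: float = 0.5
    decay_s: float = 8.0
    seed: int = 0


def transient_kernel(t, rise_s=0.5, decay_s=2.0):
    """Fast-rise / exponential-decay sensor kernel, peak-normalized to 1."""
    t = np.asarray(t, float)
    k = (1.0 - np.exp(-np.maximum(t, 0) / rise_s)) * np.exp(
        -np.maximum(t, 0) / decay_s
    )
    k[t < 0] = 0.0
    peak = k.max() if k.max() > 0 else 1.0
    return k / peak


def gen_photometry(cfg: PhotometrySimConfig, trials: TrialTable, labels):
    """Simulate a photometry session for a given trial table.

    ``labels`` is a length-``n_trials`` boolean (or {"Attending",
    "NotAttending"}) vector.  Returns (PhotometrySession, truth) where truth
    holds the planted artifact, transient trace and per-trial amplitudes.
    """
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        labels = labels == "Attending"
    labels = labels.astype(bool)
    if len(labels) != trials.n_trials:
        raise ValueError("labels length must equal n_trials")
    ss = np.random.SeedSequence(cfg.seed)
    r_art, r_amp, r_noise = [np.random.default_rng(s) for s in ss.spawn(3)]

    dur = trials.onsets[-1] + trials.window_dur + 25.0
    n = int(round(dur * cfg.fs))
    t = np.arange(n) / cfg.fs

    # shared low-frequency motion artifact
    white = r_art.standard_normal(n)
    art = gaussian_filter1d(white, sigma=cfg.artifact_tau_s * cfg.fs)
    sd = art.std()
    art = art / sd * cfg.artifact_sd if sd > 0 else art

    # transient amplitude is expressed in units of the residual baseline
    # noise that survives reference regression (1.0 when noiseless)
    z_unit = cfg.noise_sd * np.sqrt(1.0 + cfg.artifact_gain**2)
    if z_unit == 0:
        z_unit = 1.0
    amps = (
        cfg.base_amp_z
        + cfg.delta_z * labels
        + cfg.amp_jitter_z * r_amp.standard_normal(trials.n_trials)
    ) * z_unit
    transients = np.zeros(n)
    kernel_len = int(round((trials.window_dur + 10.0) * cfg.fs))
    kt = np.arange(kernel_len) / cfg.fs
    kern = transient_kernel(kt, cfg.rise_s, cfg.decay_s)
    for onset, amp in zip(trials.onsets, amps):
        i0 = int(round(onset * cfg.fs))
        i1 = min(n, i0 + kernel_len)
        transients[i0:i1] += amp * kern[: i1 - i0]

    bleach = cfg.bleach_amp * np.exp(-t / cfg.bleach_tau_s)
    reference = art + cfg.noise_sd * r_noise.standard_normal(n)
    signal = (
        cfg.artifact_gain * art
        + bleach
        + transients
        + cfg.noise_sd * r_noise.standard_normal(n)
    )
    session = PhotometrySession(
        t=t, signal=signal, reference=reference, fs=cfg.fs, trial_table=trials
    )
    truth = {
        "artifact": art,
        "transients": transients,
        "amps": amps,
        "labels": labels,
        "z_unit": z_unit,
    }
    return session, truth


# ---------------------------------------------------------------------------
# calcium populations
# ---------------------------------------------------------------------------

@dataclass
class CalciumSimConfig:
    """Cluster-structured multi-animal ΔF/F0 population.

    ``archetypes`` maps archetype name → {event type → amplitude in noise-sd
    units} (positive = excited, negative = inhibited, absent/0 = flat).
    ``proportions`` gives the archetype mixing weights (must sum to 1).
    Responses follow the same fast-rise/exponential-decay kernel as the
    photometry transients, at calcium timescales.
    """

    n_animals: int = 5
    neurons_per_animal: int = 40
    fs: float = 10.0
    archetypes: dict = field(default_factory=lambda: {
        "A+P+": {"Attending": 2.0, "pinprick": 2.0},
        "A-": {"Attending": -2.0},
        "null": {},
    })
    proportions: tuple = (0.4, 0.3, 0.3)
    event_types: tuple = ("Attending", "NotAttending", "pinprick")
    trials_per_event: int = 15
    event_gap_s: tuple = (25.0, 35.0)
    noise_sd: float = 1.0
    rise_s: float = 1.0
    decay_s: float = 4.0
    response_dur_s: float = 15.0
    n_conditions: int = 1
    seed: int = 0

    def __post_init__(self):
        if not np.isclose(sum(self.proportions), 1.0):
            raise ValueError("proportions must sum to 1")
        if len(self.proportions) != len(self.archetypes):
            raise ValueError("one proportion per archetype")


def gen_calcium_population(cfg: CalciumSimConfig):
    """Generate per-animal calcium sessions with planted archetypes.

    Each neuron is an archetype template per event type plus iid Gaussian
    noise; events of all types are interleaved on one timeline per session.
    Co-registration across conditions is the identity within animal.

    Returns (sessions, truth): ``sessions`` is a list of
    :class:`CalciumSession` (n_animals × n_conditions); ``truth`` holds the
    archetype name and index per neuron per animal.
    """
    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(cfg.n_animals + 1)
    r_assign = np.random.default_rng(streams[0])
    names = list(cfg.archetypes)
    sessions = []
    truth = {"archetype": {}, "archetype_idx": {}}
    kern_len = int(round(cfg.response_dur_s * cfg.fs))
    kern = transient_kernel(np.arange(kern_len) / cfg.fs, cfg.rise_s, cfg.decay_s)

    for a in range(cfg.n_animals):
        rng = np.random.default_rng(streams[a + 1])
        animal = f"m{a}"
        arch_idx = r_assign.choice(len(names), size=cfg.neurons_per_animal,
                                   p=cfg.proportions)
        truth["archetype"][animal] = [names[i] for i in arch_idx]
        truth["archetype_idx"][animal] = arch_idx
        for c in range(cfg.n_conditions):
            # interleaved event schedule
            n_events = cfg.trials_per_event * len(cfg.event_types)
            gaps = rng.uniform(*cfg.event_gap_s, size=n_events)
            onsets = 20.0 + np.cumsum(gaps)
            types = np.repeat(np.arange(len(cfg.event_types)),
                              cfg.trials_per_event)
            rng.shuffle(types)
            n_frames = int(round((onsets[-1] + cfg.response_dur_s + 10.0) * cfg.fs))
            dff = cfg.noise_sd * rng.standard_normal(
                (cfg.neurons_per_animal, n_frames)
            )
            amp_mat = np.zeros((cfg.neurons_per_animal, len(cfg.event_types)))
            for ni, ai in enumerate(arch_idx):
                for ei, ev in enumerate(cfg.event_types):
                    amp_mat[ni, ei] = cfg.archetypes[names[ai]].get(ev, 0.0)
            amp_mat *= cfg.noise_sd
            for onset, ei in zip(onsets, types):
                i0 = int(round(onset * cfg.fs))
                i1 = min(n_frames, i0 + kern_len)
                dff[:, i0:i1] += np.outer(amp_mat[:, ei], kern[: i1 - i0])
            event_tables = {
                ev: TrialTable(
                    onsets=onsets[types == ei], condition="SE",
                    allowed_conditions=(),
                )
                for ei, ev in enumerate(cfg.event_types)
            }
            sessions.append(CalciumSession(
                dff=dff, fs=cfg.fs, animal_id=animal,
                condition=f"c{c}", event_tables=event_tables,
                coreg={i: i for i in range(cfg.neurons_per_animal)}
                if cfg.n_conditions > 1 else None,
            ))
    return sessions, truth
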