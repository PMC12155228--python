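"""Pipeline configuration: every numeric constant has a named default here.

A single YAML file can override any subset; :func:`load_config` deep-merges
user values onto :data:`DEFAULTS`.
"""

from __future__ import annotations

import copy

import yaml

DEFAULTS: dict = {
    "task": {
        "n_trials": 60,
        "iti_range_s": [40.0, 60.0],
        "cue_dur_s": 10.0,
        "window_dur_s": 15.0,
        "fps": 30.0,
    },
    "arena": {
        "width": 400.0,
        "height": 300.0,
        "port_xy": [40.0, 150.0],
        "barrier": [[100.0, 0.0], [100.0, 300.0]],
        "contact_eps_px": 15.0,
        "orient_thresh_deg": 45.0,
    },
    "features": {
        "smooth_win": 5,
        "tortuosity_windows_s": [1.0, 5.0],
        "tortuosity_eps_px": 1.0,
        "tortuosity_cap": 50.0,
        "freeze_velocity_px_s": 10.0,
        "freeze_accel_px_s2": 30.0,
    },
    "embedding": {
        "n_neighbors": 15,
        "min_dist": 0.1,
        "n_components": 2,
        "dbscan_eps": 0.5,
        "dbscan_min_samples": 10,
        "attending_theta": 0.5,
    },
    "hmm": {
        "k_range": [2, 12],
        "n_init": 2,
        "max_iter": 50,
        "tol": 1e-4,
        "max_restarts": 3,
    },
    "alphaclass": {
        "sigma_frac": 0.05,       # Gaussian sd as fraction of min(H, W)
        "stride": 4,
        "nms_kernel": 5,
        "nms_threshold": 0.5,
        "baseline_s": 5.0,
        "bins_s": [[0.0, 5.0], [5.0, 10.0], [10.0, 15.0]],
        "select_n": 15,
        "train": {
            "epochs": 60,
            "lr": 3e-3,
            "batch_size": 32,
            "pos_weight": 8.0,
            "loss": "bce",           # or "focal"
            "channels": [8, 16],
            "kernel": 5,
            "seed": 0,
        },
    },
    "photometry": {
        "fs": 20.0,
        "median_span_ms": 200.0,
        "regress_window_s": [-1.0, 0.0],
        "zscore_baseline_s": [-1.0, 0.0],
        "auc_window_s": {"dopamine": [0.0, 20.0], "oxytocin": [0.0, 20.0],
                         "ecb": [0.0, 15.0]},
        "decode": {"n_trees": 500, "max_depth": None, "folds": 5, "seed": 0},
    },
    "calcium": {
        "fs": 10.0,
        "psth_window_s": [-5.0, 15.0],
        "z_baseline_s": [-1.0, 0.0],
        "test_baseline_s": 5.0,
        "test_response_s": 5.0,
        "sign_window_s": 15.0,
        "alpha": 0.05,
        "fdr": False,
        "cutoff_frac": 0.30,
        "min_trials_test": 6,
    },
    "decoding": {
        "model": "glm",            # glm | svm | rf
        "folds": 5,
        "rank_folds": 10,
        "pca_variance": 0.90,
        "l2_c": 1.0,
        "n_bins": 100,
        "eval_windows_s": {"cs": [0.0, 5.0], "us": [10.0, 15.0],
                           "stimuli": [0.0, 10.0]},
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Return the full config: DEFAULTS ← YAML file ← overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)
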