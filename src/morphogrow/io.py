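"""Configuration parsing, the scenario registry, and trajectory archives.

Trajectories are written as plain text: a ``trajectory.json`` carrying the
fully-resolved config, metrics and GeoJSON-style boundary polygons at full
float precision (so read(write(T)) is bit-exact), per-snapshot boundary CSVs
for convenience, and a manifest with SHA-256 checksums to detect truncation.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .simulate import SimConfig, Trajectory


class ConfigError(ValueError):
    """Raised with a field-path message for invalid configuration input."""


class ArchiveError(RuntimeError):
    """Raised for corrupt or incomplete trajectory directories."""


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------

_TOP_FIELDS = {
    "scheme": str, "params": dict, "shape": dict, "h": (int, float),
    "h_mesh": (int, float), "cfl": (int, float), "t_max": (int, float),
    "max_steps": int, "mask": str, "mask_plane": (int, float),
    "snapshot_every": int, "stop_on_gz_vanish": bool,
    "gz_area_tol": (int, float), "prominence": (int, float), "cut": dict,
}


def config_from_dict(raw: dict) -> SimConfig:
    """Validate a plain dict (e.g. parsed YAML) into a SimConfig."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    raw = dict(raw)
    kwargs = {}
    shape = raw.pop("shape", None)
    if shape is not None:
        if not isinstance(shape, dict):
            raise ConfigError("shape: must be a mapping with kind/x0/y0")
        kind = shape.get("kind", "parabolic")
        if kind not in ("parabolic", "elliptical", "custom"):
            raise ConfigError(f"shape.kind: unknown kind {kind!r}")
        kwargs["shape"] = kind
        for key in ("x0", "y0"):
            if key in shape:
                v = shape[key]
                if not isinstance(v, (int, float)) or v <= 0:
                    raise ConfigError(f"shape.{key}: must be a positive number")
                kwargs[key] = float(v)
        if "points" in shape:
            kwargs["custom_points"] = shape["points"]
    for key, val in raw.items():
        if key not in _TOP_FIELDS:
            raise ConfigError(f"{key}: unknown configuration field")
        want = _TOP_FIELDS[key]
        if val is not None and not isinstance(val, want):
            raise ConfigError(f"{key}: expected {want}, got {type(val).__name__}")
        kwargs[key] = val
    params = kwargs.get("params", {}) or {}
    for name, v in params.items():
        if not isinstance(v, (int, float)):
            raise ConfigError(f"params.{name}: must be a number")
        if name.startswith("mu") and v < 0:
            raise ConfigError(f"params.{name}: secretion rates must be >= 0")
    try:
        cfg = SimConfig(**kwargs)
        cfg.build_circuit()  # validates scheme + params early
    except (ValueError, TypeError) as e:
        raise ConfigError(str(e)) from e
    return cfg


def load_config(path) -> SimConfig:
    """Load and validate a YAML simulation config."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw or {})


# ---------------------------------------------------------------------------
# scenario registry
# ---------------------------------------------------------------------------

def _fig3(mu_X: float, t_max: float) -> dict:
    return dict(scheme="single_inhibitor", params={"mu_X": mu_X},
                shape={"kind": "parabolic", "x0": 1.5, "y0": 1.0},
                mask="front_half", t_max=t_max)


def _fig4(Ks: float, mu_Y0: float, t_max: float) -> dict:
    return dict(scheme="two_inhibitors",
                params={"mu_X": 8.0, "mu_Y0": mu_Y0, "Ks": Ks, "gamma_r": 1.0},
                shape={"kind": "parabolic", "x0": 1.5, "y0": 1.0},
                mask="front_half", t_max=t_max)


def _fig5(b: float, mu_Y0: float, t_max: float) -> dict:
    # growth zones in this family are thin slivers: finer spatial resolution
    return dict(scheme="threshold_regulator",
                params={"mu_X": 8.0, "mu_Y0": mu_Y0, "Ks": 0.9,
                        "gamma_r": 0.2, "b": b},
                shape={"kind": "parabolic", "x0": 1.5, "y0": 1.0},
                mask="front_half", t_max=t_max, h=0.04, h_mesh=0.03)


SCENARIOS: dict = {
    # unregulated growth: the cluster circularizes
    "fig2_parabola": dict(scheme="none", shape={"kind": "parabolic", "x0": 1.5, "y0": 1.0},
                          mask="none", t_max=1.2),
    "fig2_ellipse": dict(scheme="none", shape={"kind": "elliptical", "x0": 1.6, "y0": 0.4},
                         mask="none", t_max=1.2),
    # single growth inhibitor: rod (μ̃X = 10 needs a long creep phase before
    # the growth zone opens)
    "fig3_muX6": _fig3(6.0, 12.0),
    "fig3_muX8": _fig3(8.0, 12.0),
    "fig3_muX10": _fig3(10.0, 30.0),
    # two growth inhibitors: side-protrusion pair (+ stalled tip protrusion)
    "fig4_Ks0.9_muY150": _fig4(0.9, 150.0, 40.0),
    "fig4_Ks0.9_muY200": _fig4(0.9, 200.0, 40.0),
    "fig4_Ks1.0_muY56": _fig4(1.0, 56.0, 40.0),
    "fig4_Ks1.0_muY60": _fig4(1.0, 60.0, 40.0),
    "fig4_Ks1.0_muY65": _fig4(1.0, 65.0, 40.0),
    "fig4_Ks1.2_muY20": _fig4(1.2, 20.0, 40.0),
    "fig4_Ks1.2_muY22": _fig4(1.2, 22.0, 40.0),
    # growth-threshold regulator: narrowing, self-terminating cone
    "fig5_b0": _fig5(0.0, 15.0, 60.0),
    "fig5_b-0.5": _fig5(-0.5, 26.5, 50.0),
    "fig5_b-0.8": _fig5(-0.8, 48.0, 20.0),
    # growth-activator variant
    "s2_activator": dict(scheme="activator_s2",
                         params={"mu_X0": 48.0, "mu_Y": 7.0 / 1.2, "gamma_r": 0.5},
                         shape={"kind": "parabolic", "x0": 1.5, "y0": 1.0},
                         mask="front_half", t_max=8.0),
    # small ellipse, unmasked: growth zone self-localizes at both tips
    "s3_small_ellipse": dict(scheme="single_inhibitor", params={"mu_X": 7.0},
                             shape={"kind": "elliptical", "x0": 1.6, "y0": 0.4},
                             mask="none", t_max=6.0),
    # regeneration: grow a rod to t = 12, cut the tip off, then regrow
    "s7_straight_cut": dict(scheme="single_inhibitor", params={"mu_X": 8.0},
                            shape={"kind": "parabolic", "x0": 1.5, "y0": 1.0},
                            mask="front_half", t_max=30.0,
                            cut={"kind": "straight", "back_from_tip": 0.5,
                                 "at_time": 12.0}),
    "s7_elliptical_cut": dict(scheme="single_inhibitor", params={"mu_X": 8.0},
                              shape={"kind": "parabolic", "x0": 1.5, "y0": 1.0},
                              mask="front_half", t_max=30.0,
                              cut={"kind": "elliptical", "back_from_tip": 0.5,
                                   "semi_axes": (0.3, 0.25), "at_time": 12.0}),
}


def scenario_config(name: str, **overrides) -> SimConfig:
    """Build the SimConfig for a registered scenario (optionally overridden)."""
    if name not in SCENARIOS:
        raise ConfigError(f"unknown scenario {name!r}; see SCENARIOS")
    raw = json.loads(json.dumps(SCENARIOS[name]))  # deep copy
    raw.update(overrides)
    return config_from_dict(raw)


# ---------------------------------------------------------------------------
# trajectory archives
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    hsh = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            hsh.update(chunk)
    return hsh.hexdigest()


def write_trajectory(traj: Trajectory, outdir) -> Path:
    """Write a trajectory archive (JSON + CSV + checksum manifest)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {
        "config": traj.config,
        "stop_reason": traj.stop_reason,
        "events": traj.events,
        "times": traj.times,
        "metrics": traj.metrics,
        "boundaries": [
            {"time": t,
             "polygon": {"type": "Polygon",
                         "coordinates": [np.asarray(c).tolist()]}}
            for t, c in zip(traj.times, traj.curves)
        ],
    }
    files = ["trajectory.json"]
    with open(out / "trajectory.json", "w") as fh:
        json.dump(doc, fh)
    for k, (t, c) in enumerate(zip(traj.times, traj.curves)):
        name = f"boundary_{k:04d}.csv"
        with open(out / name, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["step", "time", "point_index", "x", "y"])
            for i, (x, y) in enumerate(np.asarray(c)):
                w.writerow([k, repr(float(t)), i, repr(float(x)), repr(float(y))])
        files.append(name)
    manifest = {"files": {name: _sha256(out / name) for name in files}}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def read_trajectory(indir) -> Trajectory:
    """Read an archive back; checksums guard against truncation/corruption."""
    src = Path(indir)
    man_path = src / "manifest.json"
    if not man_path.exists():
        raise ArchiveError(f"no manifest.json in {src}")
    with open(man_path) as fh:
        manifest = json.load(fh)
    for name, digest in manifest["files"].items():
        p = src / name
        if not p.exists():
            raise ArchiveError(f"missing file {name}")
        if _sha256(p) != digest:
            raise ArchiveError(f"checksum mismatch for {name}")
    with open(src / "trajectory.json") as fh:
        doc = json.load(fh)
    traj = Trajectory(config=doc["config"])
    traj.stop_reason = doc["stop_reason"]
    traj.events = doc["events"]
    traj.times = list(doc["times"])
    traj.curves = [np.asarray(b["polygon"]["coordinates"][0], dtype=float)
                   for b in doc["boundaries"]]
    traj.metrics = {k: list(v) for k, v in doc["metrics"].items()}
    return traj
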