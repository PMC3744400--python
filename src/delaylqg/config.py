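"""Structured YAML configuration for trials.

A config file has four flat sections — model, noise, cost, trial — each
optional; omitted keys fall back to the package defaults::

    model:
      inertia: 0.065        # kg m^2
      viscosity: 0.05       # N m s / rad
      tau: 0.060            # s
      dt: 0.010             # s
      delay_steps: 6
      target_deg: 0.0
    noise:
      sigma_motor: 1.0e-6
      sigma_meas: 1.0e-6
      sigma_pred: 1.0e-6
      feedback_weight_scale: 1.0
    cost:
      w: 1.0
      r: 2.0e-5
      horizon_steps: 1000
      penalty_window: null  # or [start_step, end_step]
    trial:
      condition: delay_aware
      profile: {kind: step, magnitude: 2.0, onset: 0.0, scale: 1.0}
      duration: 1.5
      noise_on: true
      seed: 0
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .control import CostSpec
from .dynamics import ModelParams
from .estimation import NoiseSpec
from .simulate import PerturbationProfile, TrialConfig, make_profile, null_profile


def _model_params(section: dict) -> ModelParams:
    target_deg = section.pop("target_deg", 0.0)
    return ModelParams(target_rad=np.deg2rad(target_deg), **section)


def _noise_spec(section: dict) -> NoiseSpec:
    return NoiseSpec(**section)


def _cost_spec(section: dict) -> CostSpec:
    if "horizon_steps" in section:
        section["horizon"] = section.pop("horizon_steps")
    window = section.pop("penalty_window", None)
    return CostSpec(penalty_window=tuple(window) if window else None, **section)


def _profile(section: dict | None) -> PerturbationProfile:
    if not section:
        return null_profile()
    section = dict(section)
    kind = section.pop("kind")
    if kind == "custom":
        return make_profile("custom", times=np.asarray(section["times"]),
                            values=np.asarray(section["values"]),
                            onset=section.get("onset", 0.0),
                            scale=section.get("scale", 1.0))
    return make_profile(kind, **section)


def trial_config_from_dict(doc: dict) -> TrialConfig:
    """Build a validated :class:`TrialConfig` from a parsed config dict."""
    trial = dict(doc.get("trial", {}))
    profile = _profile(trial.pop("profile", None))
    return TrialConfig(
        params=_model_params(dict(doc.get("model", {}))),
        noise=_noise_spec(dict(doc.get("noise", {}))),
        cost=_cost_spec(dict(doc.get("cost", {}))),
        profile=profile,
        **trial,
    )


def load_config(path) -> TrialConfig:
    """Read a YAML config file into a :class:`TrialConfig`."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} must be a mapping of sections")
    return trial_config_from_dict(doc)


def gains_to_csv(gain: np.ndarray, path, kind: str = "gain") -> None:
    """Export a gain matrix (row-major, headered columns) to CSV."""
    g = np.atleast_2d(np.asarray(gain, dtype=float))
    cols = [f"{kind}_{j:03d}" for j in range(g.shape[1])]
    pd.DataFrame(g, columns=cols).to_csv(path, index=False)
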