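"""Scenario configuration: defaults, validation and flat-YAML (de)serialisation.

A :class:`ScenarioConfig` fully parameterises one simulation: canvas size,
clone seeding, division/death rates, the ecology switches (contact mutualism,
random mutualism, immune predation) with their thresholds and probabilities,
the oncoprotein prior, step count and RNG seed.  Defaults follow the study
conditions: a 1.25× one-time proliferation boost on heterotypic clone
contact, immune activation at a cancer-cell count of 3000, target and kill
probabilities of 0.99, division rates swept over 0.01–0.1 divisions/hour
with 0.0461 /h as the experimentally grounded reference, and one step per
hour so rates act directly as per-step Bernoulli probabilities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import yaml


class ConfigurationError(ValueError):
    """Invalid scenario configuration; the message names the offending key."""


RateSchedule = Union[float, Sequence[float]]


@dataclass
class ScenarioConfig:
    # lattice & seeding
    canvas_radius: int = 50
    n_cancer_per_clone: int = 10
    n_stem_per_clone: int = 2
    clone_separation: int = 28
    # kinetics (per hour; dt hours per step)
    division_rate: float = 0.0461
    death_rate: float = 0.005
    dt: float = 1.0
    max_steps: int = 340
    # ecology switches
    mutualism_enabled: bool = False
    predation_enabled: bool = False
    random_mutualism: bool = False
    random_mutualism_rate: RateSchedule = 0.03
    # ecology parameters
    mutualism_boost: float = 1.25
    activation_threshold: int = 3000
    target_probability: float = 0.99
    kill_probability: float = 0.99
    oncoprotein_advantage_threshold: float = 4.0
    immune_ring_radius: int = 40
    # stem-cell rules
    p_symmetric_division: float = 0.1
    # oncoprotein field
    oncoprotein_mean: float = 3.0
    oncoprotein_sd: float = 1.5
    oncoprotein_sweeps: int = 10
    oncoprotein_noise_sd: float = 0.1
    oncoprotein_boost: float = 1.25
    # replicate scoring
    advantage_metric: str = "final"   # "final" or "auc"
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def bad(key: str, msg: str) -> None:
            raise ConfigurationError(f"{key}: {msg}")

        if self.canvas_radius < 1:
            bad("canvas_radius", "must be >= 1")
        if self.n_cancer_per_clone < 0 or self.n_stem_per_clone < 0:
            bad("n_cancer_per_clone/n_stem_per_clone", "must be >= 0")
        if self.clone_separation < 0:
            bad("clone_separation", "must be >= 0")
        if self.dt <= 0:
            bad("dt", "must be > 0")
        if self.division_rate < 0 or self.division_rate * self.dt > 1:
            bad("division_rate", "must satisfy 0 <= division_rate * dt <= 1")
        if self.death_rate < 0 or self.death_rate * self.dt > 1:
            bad("death_rate", "must satisfy 0 <= death_rate * dt <= 1")
        if self.max_steps < 0:
            bad("max_steps", "must be >= 0")
        for key in ("target_probability", "kill_probability",
                    "p_symmetric_division"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                bad(key, f"probability must be in [0, 1], got {v}")
        rates = self.random_mutualism_rate
        rate_list = [rates] if isinstance(rates, (int, float)) else list(rates)
        if not rate_list:
            bad("random_mutualism_rate", "schedule must be non-empty")
        for v in rate_list:
            if not 0.0 <= float(v) <= 1.0:
                bad("random_mutualism_rate", f"rate must be in [0, 1], got {v}")
        if self.mutualism_boost <= 0:
            bad("mutualism_boost", "must be > 0")
        if self.activation_threshold < 0:
            bad("activation_threshold", "must be >= 0")
        if self.oncoprotein_sd < 0 or self.oncoprotein_noise_sd < 0:
            bad("oncoprotein_sd/oncoprotein_noise_sd", "must be >= 0")
        if self.oncoprotein_mean < 0:
            bad("oncoprotein_mean", "must be >= 0")
        if self.oncoprotein_sweeps < 1:
            bad("oncoprotein_sweeps", "must be >= 1")
        if self.oncoprotein_boost <= 0:
            bad("oncoprotein_boost", "must be > 0")
        if self.immune_ring_radius < 1:
            bad("immune_ring_radius", "must be >= 1")
        if self.predation_enabled and self.immune_ring_radius > self.canvas_radius:
            bad("immune_ring_radius",
                f"must be <= canvas_radius ({self.canvas_radius}) "
                "when predation is enabled")
        if self.advantage_metric not in ("final", "auc"):
            bad("advantage_metric", "must be 'final' or 'auc'")
        if self.mutualism_enabled and self.random_mutualism:
            bad("random_mutualism",
                "contact mutualism and random mutualism are mutually exclusive")

    def random_mutualism_rate_at(self, step: int) -> float:
        """Per-step random-mutualism conversion rate (schedules clamp at end)."""
        r = self.random_mutualism_rate
        if isinstance(r, (int, float)):
            return float(r)
        sched = list(r)
        return float(sched[min(max(step - 1, 0), len(sched) - 1)])

    def replace(self, **kwargs) -> "ScenarioConfig":
        """A validated copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if not isinstance(d["random_mutualism_rate"], (int, float)):
            d["random_mutualism_rate"] = [float(v) for v in d["random_mutualism_rate"]]
        return d


_FIELDS = {f.name for f in dataclasses.fields(ScenarioConfig)}


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a flat YAML/JSON scenario file; unknown keys are rejected.

    An empty file yields all documented defaults.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"unparseable config file {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must be a flat mapping")
    unknown = sorted(set(raw) - _FIELDS)
    if unknown:
        raise ConfigurationError(f"unknown key '{unknown[0]}'")
    return ScenarioConfig(**raw)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False)
    )
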