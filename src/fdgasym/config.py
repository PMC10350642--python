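"""YAML configuration for the synthetic-cohort pipeline.

Every study condition has a code default (the values documented on
:class:`~fdgasym.phantom.CohortConfig`); a YAML file overrides any
subset.  Schema (all keys optional)::

    cohort:
      n: 52
      p_mri_positive: 0.6538      # 34/52
      p_ez_left: 0.5
      sigma_log: 0.1              # per-patient lognormal kinetic spread
    phantom:
      shape: [64, 64, 48]
      voxel_mm: 3.0
      n_regions: 8                # per hemisphere
      ez_region: 1
      noise_sigma: 0.05           # fraction of regional mean
    kinetics: {K1: 0.102, k2: 0.130, k3: 0.062}
    ez: {K1_factor: 0.92, k3_factor: 0.75}
    input:
      feng: {A1: 851.1, A2: 21.9, A3: 20.8, l1: -4.134, l2: -0.1191, l3: -0.0104}
    protocol:
      dose_per_kg: 3.7
      t_early: {mean: 43.44, sd: 18.04, bounds: [20, 90]}
      t_delayed: {mean: 160.46, sd: 28.70, bounds: [120, 200]}
      weight: {mean: 65.0, sd: 12.0, bounds: [30, 110]}
    observers: {noise_sd: 1.5, same_threshold: 1.0}
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import yaml

from .kinetics import KineticParams, PlasmaInput
from .phantom import CohortConfig, PhantomSpec

__all__ = ["ObserverConfig", "PipelineConfig", "load_config", "config_from_dict"]

DEFAULT_OBSERVER_NOISE_SD = 1.5
DEFAULT_OBSERVER_THRESHOLD = 1.0


@dataclass(frozen=True)
class ObserverConfig:
    noise_sd: float = DEFAULT_OBSERVER_NOISE_SD
    same_threshold: float = DEFAULT_OBSERVER_THRESHOLD


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig
    observers: ObserverConfig

    def describe(self) -> dict:
        c = self.cohort
        return {
            "cohort": {"n": c.n, "p_mri_positive": c.p_mri_positive,
                       "p_ez_left": c.p_ez_left, "sigma_log": c.sigma_log},
            "phantom": {"shape": list(c.spec.shape), "voxel_mm": c.spec.voxel_mm,
                        "n_regions": c.spec.n_regions, "ez_region": c.spec.ez_region,
                        "noise_sigma": c.spec.noise_sigma},
            "kinetics": {"K1": c.kinetics.K1, "k2": c.kinetics.k2, "k3": c.kinetics.k3},
            "ez": {"K1_factor": c.ez_K1_factor, "k3_factor": c.ez_k3_factor},
            "input": {"feng": {"A1": c.input.A1, "A2": c.input.A2, "A3": c.input.A3,
                               "l1": c.input.l1, "l2": c.input.l2, "l3": c.input.l3}},
            "protocol": {
                "dose_per_kg": c.dose_per_kg,
                "t_early": {"mean": c.t_early_mean, "sd": c.t_early_sd, "bounds": list(c.t_early_bounds)},
                "t_delayed": {"mean": c.t_delayed_mean, "sd": c.t_delayed_sd, "bounds": list(c.t_delayed_bounds)},
                "weight": {"mean": c.weight_mean, "sd": c.weight_sd, "bounds": list(c.weight_bounds)},
            },
            "observers": {"noise_sd": self.observers.noise_sd,
                          "same_threshold": self.observers.same_threshold},
        }


def config_from_dict(raw: Optional[dict]) -> PipelineConfig:
    """Build the pipeline configuration from a (possibly partial) mapping."""
    raw = raw or {}
    ph = raw.get("phantom", {})
    spec = PhantomSpec(
        shape=tuple(ph.get("shape", (64, 64, 48))),
        voxel_mm=float(ph.get("voxel_mm", 3.0)),
        n_regions=int(ph.get("n_regions", 8)),
        ez_region=int(ph.get("ez_region", 1)),
        noise_sigma=float(ph.get("noise_sigma", 0.05)),
    )
    kin = raw.get("kinetics", {})
    kinetics = KineticParams(
        K1=float(kin.get("K1", 0.102)), k2=float(kin.get("k2", 0.130)), k3=float(kin.get("k3", 0.062))
    )
    feng = raw.get("input", {}).get("feng", {})
    inp = PlasmaInput(
        A1=float(feng.get("A1", PlasmaInput().A1)),
        A2=float(feng.get("A2", PlasmaInput().A2)),
        A3=float(feng.get("A3", PlasmaInput().A3)),
        l1=float(feng.get("l1", PlasmaInput().l1)),
        l2=float(feng.get("l2", PlasmaInput().l2)),
        l3=float(feng.get("l3", PlasmaInput().l3)),
    )
    ez = raw.get("ez", {})
    co = raw.get("cohort", {})
    proto = raw.get("protocol", {})
    te = proto.get("t_early", {})
    td = proto.get("t_delayed", {})
    wt = proto.get("weight", {})
    cohort = CohortConfig(
        n=int(co.get("n", 52)),
        spec=spec,
        kinetics=kinetics,
        ez_K1_factor=float(ez.get("K1_factor", 0.92)),
        ez_k3_factor=float(ez.get("k3_factor", 0.75)),
        input=inp,
        dose_per_kg=float(proto.get("dose_per_kg", 3.7)),
        t_early_mean=float(te.get("mean", 43.44)),
        t_early_sd=float(te.get("sd", 18.04)),
        t_early_bounds=tuple(te.get("bounds", (20.0, 90.0))),
        t_delayed_mean=float(td.get("mean", 160.46)),
        t_delayed_sd=float(td.get("sd", 28.70)),
        t_delayed_bounds=tuple(td.get("bounds", (120.0, 200.0))),
        weight_mean=float(wt.get("mean", 65.0)),
        weight_sd=float(wt.get("sd", 12.0)),
        weight_bounds=tuple(wt.get("bounds", (30.0, 110.0))),
        p_mri_positive=float(co.get("p_mri_positive", 34.0 / 52.0)),
        p_ez_left=float(co.get("p_ez_left", 0.5)),
        sigma_log=float(co.get("sigma_log", 0.1)),
    )
    obs = raw.get("observers", {})
    observers = ObserverConfig(
        noise_sd=float(obs.get("noise_sd", DEFAULT_OBSERVER_NOISE_SD)),
        same_threshold=float(obs.get("same_threshold", DEFAULT_OBSERVER_THRESHOLD)),
    )
    return PipelineConfig(cohort=cohort, observers=observers)


def load_config(path=None) -> PipelineConfig:
    """Load a YAML config file; with no path, return the defaults."""
    if path is None:
        return config_from_dict({})
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return config_from_dict(raw)
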