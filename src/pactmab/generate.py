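"""Synthetic Incucyte-like confluence data with known ground truth.

The raw microscopy time series behind the study design are not publicly
deposited, so this module emulates their statistical structure: fractional
confluence in 8 replicate wells, sampled every 3 hours over 4 days, for the
full experimental layout — controls, six paclitaxel doses (10-500 nM), three
trastuzumab doses (10-50 ug/mL) and six combination regimens (two paclitaxel
doses x three orderings).  Every generated dataset records the exact truth
parameters used, which is what makes parameter-recovery studies possible.

Default truth parameters per condition were fixed once, by matching the
simulated day-4 confluences to the magnitudes reported for the real
dose-response panel (control ~0.61; paclitaxel 0.45 down to 0.25 across
10-500 nM; trastuzumab 0.43/0.38/0.24 across 10/25/50 ug/mL), and the
combination synergy multipliers to the reported calibrated values.  Default
replicate noise is additive Gaussian with scale 0.025, which puts typical
95% CI half-widths of the 8-replicate mean at ~0.02 confluence — the
magnitude printed for the real day-4 data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .dataset import ConfluenceDataset
from .model import ModelParams
from .regimen import Regimen, build_schedule, default_time_grid, simulate

__all__ = [
    "NoiseModel",
    "GeneratorSpec",
    "generate_dataset",
    "generate_panel",
    "default_truth",
    "panel_conditions",
    "PAC_DOSES",
    "TMAB_DOSES",
    "COMBO_S",
]

PAC_DOSES = (10.0, 25.0, 50.0, 100.0, 250.0, 500.0)  # nM
TMAB_DOSES = (10.0, 25.0, 50.0)  # ug/mL
COMBO_TMAB_DOSE = 25.0
COMBO_PAC_DOSES = (25.0, 100.0)

# Per-dose truth values for the drug-effect magnitudes (normalized scale:
# one dose-equivalent per application), fixed by matching simulated day-4
# confluence to the reported dose-response panel.  Dose strength lives in
# these per-dose parameters, mirroring the per-dose-set calibrations.
PAC_DELTA = {10.0: 0.8737, 25.0: 0.8311, 50.0: 1.1818,
             100.0: 1.4165, 250.0: 1.5663, 500.0: 1.8391}
TMAB_ETA = {10.0: 4.3276, 25.0: 4.6559, 50.0: 5.5520}

# Synergy multiplier per combination regimen at trastuzumab 25 ug/mL,
# anchored to the reported calibrated values: S < 1 when paclitaxel leads,
# S > 1 when trastuzumab leads.
COMBO_S = {
    ("paclitaxel_first", 25.0): 0.09,
    ("paclitaxel_first", 100.0): 0.71,
    ("simultaneous", 25.0): 0.13,
    ("simultaneous", 100.0): 1.22,
    ("trastuzumab_first", 25.0): 1.47,
    ("trastuzumab_first", 100.0): 1.24,
}


@dataclass
class NoiseModel:
    """Replicate measurement noise.

    ``additive-gaussian`` adds N(0, scale) to each replicate observation;
    ``proportional-gaussian`` scales the deviation by the truth value.
    Optional wash artifacts add an extra zero-mean transient at media-change
    times (off by default; they exercise robustness, not mechanism).
    Generated values are clipped to [0, 1].
    """

    kind: str = "additive-gaussian"
    scale: float = 0.025
    n_replicates: int = 8
    wash_artifact_amplitude: float = 0.0
    wash_times: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("additive-gaussian", "proportional-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def draw(self, truth: np.ndarray, times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        eps = rng.standard_normal((self.n_replicates, len(truth)))
        if self.kind == "additive-gaussian":
            values = truth[None, :] + self.scale * eps
        else:
            values = truth[None, :] * (1.0 + self.scale * eps)
        if self.wash_artifact_amplitude > 0 and self.wash_times:
            bump = np.isin(times, np.asarray(self.wash_times))
            values[:, bump] += self.wash_artifact_amplitude * rng.standard_normal(
                (self.n_replicates, int(bump.sum()))
            )
        return np.clip(values, 0.0, 1.0)


@dataclass
class GeneratorSpec:
    """Everything needed to generate one dataset reproducibly."""

    truth: ModelParams
    regimen: Regimen
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    t_grid: Optional[np.ndarray] = None
    initial_T: Optional[float] = None
    condition: Optional[str] = None


def default_truth(
    regimen_name: str,
    pac_dose: float = 0.0,
    tmab_dose: float = 0.0,
    base: Optional[ModelParams] = None,
) -> ModelParams:
    """Truth parameters for one panel condition (see module docstring)."""
    p = base if base is not None else ModelParams()
    updates: Dict[str, float] = {}
    if pac_dose > 0:
        if pac_dose not in PAC_DELTA:
            raise KeyError(f"no default truth for paclitaxel dose {pac_dose}")
        updates["delta_P"] = PAC_DELTA[pac_dose]
    if tmab_dose > 0:
        if tmab_dose not in TMAB_ETA:
            raise KeyError(f"no default truth for trastuzumab dose {tmab_dose}")
        updates["eta_A"] = TMAB_ETA[tmab_dose]
    key = (regimen_name, pac_dose)
    if key in COMBO_S and tmab_dose == COMBO_TMAB_DOSE:
        updates["S"] = COMBO_S[key]
    return p.replace(**updates) if updates else p


def generate_dataset(spec: GeneratorSpec) -> Tuple[ConfluenceDataset, ModelParams]:
    """Simulate the truth trajectory and draw noisy replicates around it.

    Returns the dataset together with the truth parameters it was generated
    from.  The same spec (same seed) always yields identical output.
    """
    t_grid = spec.t_grid if spec.t_grid is not None else default_time_grid(
        spec.regimen.total_duration
    )
    traj = simulate(spec.truth, spec.regimen, t_grid=t_grid, initial_T=spec.initial_T)
    truth_curve = traj.at_times(t_grid)
    rng = np.random.default_rng(spec.seed)
    values = spec.noise.draw(truth_curve, np.asarray(t_grid), rng)
    name = spec.condition or spec.regimen.name
    return ConfluenceDataset(condition=name, times=t_grid, replicate_values=values), spec.truth


def panel_conditions() -> Dict[str, Regimen]:
    """The full study layout: 1 control + 6 + 3 monotherapies + 6 combos."""
    out: Dict[str, Regimen] = {"control": build_schedule("control")}
    for d in PAC_DOSES:
        out[f"pac_{d:g}nM"] = build_schedule("paclitaxel_only", pac_dose=d)
    for d in TMAB_DOSES:
        out[f"tmab_{d:g}ugml"] = build_schedule("trastuzumab_only", tmab_dose=d)
    for name in ("paclitaxel_first", "simultaneous", "trastuzumab_first"):
        for d in COMBO_PAC_DOSES:
            out[f"{name}_pac{d:g}"] = build_schedule(
                name, pac_dose=d, tmab_dose=COMBO_TMAB_DOSE
            )
    return out


def _condition_doses(regimen: Regimen) -> Tuple[float, float]:
    pac = max((e.dose for e in regimen.events if e.drug == "paclitaxel"), default=0.0)
    tmab = max((e.dose for e in regimen.events if e.drug == "trastuzumab"), default=0.0)
    return pac, tmab


def generate_panel(
    seed: int = 0,
    noise: Optional[NoiseModel] = None,
    base: Optional[ModelParams] = None,
) -> Dict[str, Tuple[ConfluenceDataset, ModelParams, Regimen]]:
    """Generate the full 16-condition panel with per-condition truth.

    Each condition gets an independent substream of the root seed, so the
    panel is reproducible as a whole and per condition.
    """
    noise = noise if noise is not None else NoiseModel()
    root = np.random.SeedSequence(seed)
    out = {}
    regimens = panel_conditions()
    for child, (name, reg) in zip(root.spawn(len(regimens)), regimens.items()):
        pac, tmab = _condition_doses(reg)
        truth = default_truth(reg.name, pac_dose=pac, tmab_dose=tmab, base=base)
        spec = GeneratorSpec(
            truth=truth,
            regimen=reg,
            noise=noise,
            seed=int(child.generate_state(1)[0] % (2**31)),
            condition=name,
        )
        ds, tr = generate_dataset(spec)
        out[name] = (ds, tr, reg)
    return out
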