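"""Dosing schedules and piecewise ODE simulation of treatment regimens.

The experimental layout this mirrors: cells plated at t = 0, grown freely for
24 h, and treated from day 1 with 24-hour drug exposures.  A media change at
the end of each exposure removes *all* remaining free drug; bound antibody
and internalized paclitaxel are untouched.  Trajectories are integrated
piecewise between events with a stiff-safe adaptive solver (LSODA,
rtol 1e-6 / atol 1e-9) restarted at every event time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import ModelParams, WellGeometry, _rhs_core, TRASTUZUMAB_MW_KDA, AVOGADRO

__all__ = [
    "DoseEvent",
    "Regimen",
    "Trajectory",
    "SEEDING_CELLS",
    "default_time_grid",
    "default_initial_confluence",
    "build_schedule",
    "dose_to_amount",
    "apply_dose",
    "media_change",
    "simulate",
]

#: Seeding density of the experiments, cells per well.
SEEDING_CELLS = 3.5e4

_DRUGS = ("paclitaxel", "trastuzumab")


class RegimenError(ValueError):
    """Invalid regimen/schedule configuration."""


@dataclass(frozen=True)
class DoseEvent:
    """One drug application: dose applied at ``apply_time`` and washed out
    (free pool zeroed) at ``removal_time``.  Default exposure is 24 h."""

    drug: str
    dose: float  # nM (paclitaxel) or ug/mL (trastuzumab)
    apply_time: float  # day
    removal_time: float  # day

    def __post_init__(self) -> None:
        if self.drug not in _DRUGS:
            raise RegimenError(f"unknown drug {self.drug!r}")
        if self.dose < 0:
            raise RegimenError("dose must be >= 0")
        if not self.removal_time > self.apply_time:
            raise RegimenError("removal_time must be > apply_time")


@dataclass
class Regimen:
    """Named, ordered collection of dose events over a fixed study window."""

    name: str
    events: List[DoseEvent] = field(default_factory=list)
    total_duration: float = 4.0  # days

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.apply_time)
        for drug in _DRUGS:
            spans = [(e.apply_time, e.removal_time) for e in self.events if e.drug == drug]
            spans.sort()
            for (a0, r0), (a1, _r1) in zip(spans, spans[1:]):
                if a1 < r0:
                    raise RegimenError(f"overlapping applications of {drug}")

    def first_apply_time(self, drug: str) -> Optional[float]:
        times = [e.apply_time for e in self.events if e.drug == drug and e.dose > 0]
        return min(times) if times else None

    def event_times(self) -> List[float]:
        out = set()
        for e in self.events:
            out.add(e.apply_time)
            out.add(e.removal_time)
        return sorted(out)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "total_duration": self.total_duration,
            "events": [vars(e) | {} for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Regimen":
        events = [DoseEvent(**e) for e in d.get("events", [])]
        return cls(name=d["name"], events=events, total_duration=d.get("total_duration", 4.0))


@dataclass
class Trajectory:
    """Simulated state time series on a time grid (days)."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 5): T, A_b, A_f, P_i, P_f
    regimen: Regimen
    params: ModelParams

    @property
    def T(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def confluence(self) -> np.ndarray:
        """Tumor burden on the fractional-confluence scale (working units)."""
        return np.clip(self.states[:, 0], 0.0, 1.0)

    def at_times(self, times: Sequence[float]) -> np.ndarray:
        """Confluence values at a subset of the trajectory's grid points."""
        idx = np.searchsorted(self.times, np.asarray(times, dtype=float))
        idx = np.clip(idx, 0, len(self.times) - 1)
        if not np.allclose(self.times[idx], times, atol=1e-9):
            raise ValueError("requested times are not on the trajectory grid")
        return self.confluence[idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.states, columns=["T", "A_b", "A_f", "P_i", "P_f"]
        )
        df.insert(0, "time_days", self.times)
        df["confluence"] = self.confluence
        return df


def default_time_grid(duration: float = 4.0, step: float = 0.125) -> np.ndarray:
    """The experimental sampling grid: 3-hour spacing over four days."""
    n = int(round(duration / step))
    return np.linspace(0.0, duration, n + 1)


def default_initial_confluence(geometry: WellGeometry = WellGeometry()) -> float:
    """Seeding density (3.5e4 cells/well) on the confluence scale."""
    return SEEDING_CELLS / geometry.cells_at_full_confluence


_TEMPLATES = {
    "control": [],
    "paclitaxel_only": [("paclitaxel", 1.0, 2.0)],
    "trastuzumab_only": [("trastuzumab", 1.0, 2.0)],
    "paclitaxel_first": [("paclitaxel", 1.0, 2.0), ("trastuzumab", 2.0, 3.0)],
    "trastuzumab_first": [("trastuzumab", 1.0, 2.0), ("paclitaxel", 2.0, 3.0)],
    "simultaneous": [("paclitaxel", 1.0, 2.0), ("trastuzumab", 1.0, 2.0)],
}


def build_schedule(
    name: str,
    pac_dose: float = 0.0,
    tmab_dose: float = 0.0,
    total_duration: float = 4.0,
    events: Optional[Sequence[dict]] = None,
) -> Regimen:
    """Build a :class:`Regimen` from a template name or explicit event list.

    Templates cover the study design: ``control``, the two monotherapies
    (applied day 1 for 24 h), and the three combination timings — each drug
    day 1-2 then the other day 2-3, or both day 1-2 simultaneously.
    """
    if events is not None:
        return Regimen(name=name, events=[DoseEvent(**e) for e in events],
                       total_duration=total_duration)
    if name not in _TEMPLATES:
        raise RegimenError(
            f"unknown regimen {name!r}; expected one of {sorted(_TEMPLATES)} or explicit events"
        )
    doses = {"paclitaxel": pac_dose, "trastuzumab": tmab_dose}
    evts = [
        DoseEvent(drug=d, dose=doses[d], apply_time=a, removal_time=r)
        for d, a, r in _TEMPLATES[name]
        if doses[d] > 0
    ]
    return Regimen(name=name, events=evts, total_duration=total_duration)


def dose_to_amount(
    drug: str,
    dose: float,
    mode: str = "normalized",
    geometry: WellGeometry = WellGeometry(),
) -> float:
    """Convert an administered dose to a free-pool increment.

    normalized mode: one dose-equivalent per application (the free pool is
    set to 1 whenever a non-zero dose is applied; the strength of the dose
    expresses itself through the per-dose effect parameters, mirroring the
    per-dose-set calibrations).  physical mode: paclitaxel nM * media
    volume -> pmol; trastuzumab ug/mL * media volume / MW -> molecules.
    """
    if drug not in _DRUGS:
        raise RegimenError(f"unknown drug {drug!r}")
    if mode == "normalized":
        return 1.0 if dose > 0 else 0.0
    if mode == "physical":
        if drug == "paclitaxel":
            # nM * mL = (1e-9 mol/L)(1e-3 L) = 1e-12 mol = pmol
            return dose * geometry.media_volume
        grams = dose * geometry.media_volume * 1e-6
        return grams / (TRASTUZUMAB_MW_KDA * 1e3) * AVOGADRO
    raise RegimenError(f"unknown unit mode {mode!r}")


def apply_dose(
    state: np.ndarray,
    event: DoseEvent,
    geometry: WellGeometry = WellGeometry(),
    mode: str = "normalized",
) -> np.ndarray:
    """Increment the free-drug pool for ``event`` (dose 0 is a no-op)."""
    y = np.array(state, dtype=float)
    amount = dose_to_amount(event.drug, event.dose, mode=mode, geometry=geometry)
    if event.drug == "paclitaxel":
        y[4] += amount
    else:
        y[2] += amount
    return y


def media_change(state: np.ndarray, drug: str) -> np.ndarray:
    """Zero the free pool of ``drug`` (wash); bound/internalized untouched."""
    y = np.array(state, dtype=float)
    if drug == "paclitaxel":
        y[4] = 0.0
    elif drug == "trastuzumab":
        y[2] = 0.0
    else:
        raise RegimenError(f"unknown drug {drug!r}")
    return y


class SimulationError(RuntimeError):
    def __init__(self, message: str, params: ModelParams, regimen: Regimen):
        super().__init__(f"{message} (regimen={regimen.name}, params={params.to_dict()})")
        self.params = params
        self.regimen = regimen


def simulate(
    params: ModelParams,
    regimen: Regimen,
    t_grid: Optional[np.ndarray] = None,
    initial_T: Optional[float] = None,
    mode: str = "normalized",
    geometry: WellGeometry = WellGeometry(),
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Trajectory:
    """Simulate a regimen by piecewise integration with event restarts.

    The output grid always contains every event time; extra event times not
    on ``t_grid`` are integrated through but not reported.  Same-instant
    removal and application are ordered removal-then-application.
    """
    if t_grid is None:
        t_grid = default_time_grid(regimen.total_duration)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if initial_T is None:
        initial_T = default_initial_confluence(geometry)
    if initial_T <= 0:
        raise ValueError("initial_T must be > 0")

    events = regimen.events
    restart_times = set(regimen.event_times())
    # the anti-proliferative factor f switches on discontinuously at
    # application + t_star_A; restart the integrator there
    tmab_on = regimen.first_apply_time("trastuzumab")
    if tmab_on is not None:
        restart_times.add(tmab_on + params.t_star_A)
    boundaries = sorted({t for t in restart_times if t_grid[0] < t < t_grid[-1]})
    # the output grid always contains the event times
    t_grid = np.unique(np.concatenate([t_grid, np.array(boundaries)]))
    segment_edges = [t_grid[0], *boundaries, t_grid[-1]]

    apply_times = {
        "trastuzumab": regimen.first_apply_time("trastuzumab"),
        "paclitaxel": regimen.first_apply_time("paclitaxel"),
    }

    y = np.array([initial_T, 0.0, 0.0, 0.0, 0.0])
    # events exactly at the grid start fire immediately
    out_t: list[float] = []
    out_y: list[np.ndarray] = []

    def rhs(t: float, yv: np.ndarray) -> np.ndarray:
        return _rhs_core(t, yv, params, apply_times["trastuzumab"], apply_times["paclitaxel"])

    for seg_start, seg_end in zip(segment_edges[:-1], segment_edges[1:]):
        # removal first, then application, at the segment start
        for e in events:
            if e.removal_time == seg_start:
                y = media_change(y, e.drug)
        for e in events:
            if e.apply_time == seg_start:
                y = apply_dose(y, e, geometry=geometry, mode=mode)

        mask = (t_grid > seg_start) & (t_grid < seg_end)
        interior = list(t_grid[mask])
        if seg_start in t_grid:
            out_t.append(seg_start)
            out_y.append(y)  # post-event state at the segment start
        sol = solve_ivp(
            rhs,
            (seg_start, seg_end),
            y,
            method="LSODA",
            t_eval=interior + [seg_end],
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(f"integration failed: {sol.message}", params, regimen)
        for t, yv in zip(interior, sol.y[:, :-1].T):
            out_t.append(t)
            out_y.append(yv)
        y = sol.y[:, -1]

    # wash events at the final instant, then record the endpoint
    for e in events:
        if e.removal_time == t_grid[-1]:
            y = media_change(y, e.drug)
    if t_grid[-1] not in out_t:
        out_t.append(t_grid[-1])
        out_y.append(y)

    states = np.clip(np.array(out_y), 0.0, None)
    return Trajectory(times=np.array(out_t), states=states, regimen=regimen, params=params)
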