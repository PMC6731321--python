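"""Core ODE models of BT474 cell response to trastuzumab and paclitaxel.

Three coupled systems share one logistic backbone for the tumor cell burden
``T``:

* trastuzumab: bound antibody ``A_b`` reduces the proliferation rate through
  the delayed anti-proliferative factor ``f = eta_A * A_b`` (active once the
  time since administration exceeds ``t_star_A``);
* paclitaxel: internalized drug ``P_i`` reduces the carrying capacity through
  ``h = delta_P * (exp(-gamma_P * (tau - t_star_P)) + S) * P_i`` where ``tau``
  is time since administration — a transient toxicity spike that decays at
  rate ``gamma_P`` on top of a persistent loss scaled by the synergy
  multiplier ``S`` (``S = 1`` for monotherapy);
* combined: both mechanisms at once, with ``S`` free.

Working units are *normalized*: ``T`` is fractional well confluence (so the
carrying capacity ``theta`` is on the 0–1 confluence scale) and drug pools
are in dose-equivalents (1.0 = the 25 nM paclitaxel / 25 ug/mL trastuzumab
reference dose).  Conversion to absolute cell numbers or physical drug
amounts is an explicit I/O step (:func:`confluence_to_cells`,
:class:`WellGeometry`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "ModelState",
    "WellGeometry",
    "TRASTUZUMAB_MW_KDA",
    "AVOGADRO",
    "antiproliferative_effect",
    "capacity_reduction",
    "trastuzumab_rhs",
    "paclitaxel_rhs",
    "combined_rhs",
    "logistic_solution",
    "confluence_to_cells",
    "cells_to_confluence",
]

#: Molecular weight of trastuzumab, kDa (IgG1).
TRASTUZUMAB_MW_KDA = 148.0
AVOGADRO = 6.02214076e23

#: Receptor-pool scale for normalized units: number of HER2 receptors that
#: count as one antibody dose-equivalent of binding capacity per unit
#: confluence.  With the Table-scale expression of 1.94e6 receptors/cell this
#: puts the available-receptor term ``T * her2_exp / HER2_NORM`` at O(1).
HER2_NORM = 1.0e6

# relative floor for the effective carrying capacity theta - h
_CAPACITY_FLOOR_FRAC = 1e-6
# cap on the magnitude of the negative capacity factor (1 - T/(theta - h)):
# a death rate of ~k*1e3 per day is already instantaneous on the 4-day
# experimental timescale, and the cap keeps the system integrable when the
# capacity is driven to its floor
_CAPACITY_FACTOR_MIN = -1e3


@dataclass
class WellGeometry:
    """Geometry of one 96-well plate well used for unit conversions."""

    cell_radius: float = 1.25e-3  # cm
    well_area: float = 0.32  # cm^2
    media_volume: float = 0.1  # mL

    def __post_init__(self) -> None:
        if self.cell_radius <= 0 or self.well_area <= 0 or self.media_volume <= 0:
            raise ValueError("well geometry values must be positive")

    @property
    def cells_at_full_confluence(self) -> float:
        return self.well_area / (math.pi * self.cell_radius**2)


@dataclass
class ModelParams:
    """All model parameters, on the normalized working scale.

    ``S`` defaults to exactly 1 (no interaction) and is only calibrated for
    combination regimens.  ``her2_exp`` is assigned from the cell line, never
    calibrated.
    """

    k: float = 0.83            # growth rate, 1/day
    theta: float = 0.67        # carrying capacity, confluence units
    eta_A: float = 2.51        # anti-proliferative effect per bound antibody
    t_star_A: float = 0.6      # delay of trastuzumab effect, days since dosing
    beta_A: float = 2.0        # antibody binding rate, 1/(receptor-units * day)
    her2_exp: float = 1.94e6   # HER2 receptors per cell (assigned)
    delta_P: float = 0.68      # capacity reduction per internalized paclitaxel
    gamma_P: float = 6.35      # decay rate of initial paclitaxel toxicity, 1/day
    t_star_P: float = 0.30     # time to toxic-effect decrease, days since dosing
    alpha_P: float = 0.68      # paclitaxel internalization rate, 1/(confluence * day)
    S: float = 1.0             # synergy multiplier, unitless

    _FIELDS = (
        "k", "theta", "eta_A", "t_star_A", "beta_A", "her2_exp",
        "delta_P", "gamma_P", "t_star_P", "alpha_P", "S",
    )

    def __post_init__(self) -> None:
        for name in self._FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")

    @property
    def receptor_scale(self) -> float:
        """Receptor binding capacity per unit confluence, in antibody units."""
        return self.her2_exp / HER2_NORM

    def replace(self, **updates: float) -> "ModelParams":
        return replace(self, **updates)

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in self._FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass
class ModelState:
    """State of the combined system at one instant.

    All pools are non-negative; the free/bound (and free/internalized) pairs
    are conserved between dosing and media-change events.
    """

    T: float
    A_b: float = 0.0
    A_f: float = 0.0
    P_i: float = 0.0
    P_f: float = 0.0

    def __post_init__(self) -> None:
        for name in ("T", "A_b", "A_f", "P_i", "P_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"state component {name} must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([self.T, self.A_b, self.A_f, self.P_i, self.P_f])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(*(max(float(v), 0.0) for v in y))


def antiproliferative_effect(
    A_b: float, t_since_tmab: float, eta_A: float, t_star_A: float
) -> float:
    """Reduced-proliferation factor f due to bound trastuzumab.

    Returns ``eta_A * A_b`` once the time since administration exceeds the
    intracellular-signaling delay ``t_star_A``, else 0.  If trastuzumab was
    never applied callers pass ``t_since_tmab = 0``, which lands in the
    delay branch.
    """
    if A_b < 0:
        raise ValueError("A_b must be >= 0")
    if t_since_tmab > t_star_A:
        return eta_A * A_b
    return 0.0


def capacity_reduction(
    P_i: float,
    t_since_pac: float,
    delta_P: float,
    gamma_P: float,
    t_star_P: float,
    S: float = 1.0,
) -> float:
    """Carrying-capacity reduction h due to internalized paclitaxel.

    ``delta_P * (exp(-gamma_P * (t_since_pac - t_star_P)) + S) * P_i``: a
    transient early-toxicity term (greater than ``S`` until ``t_star_P``)
    plus the persistent term scaled by the synergy multiplier ``S``.
    """
    if P_i < 0:
        raise ValueError("P_i must be >= 0")
    return delta_P * (math.exp(-gamma_P * (t_since_pac - t_star_P)) + S) * P_i


def _rhs_core(
    t: float,
    y: np.ndarray,
    p: ModelParams,
    tmab_apply_time: Optional[float],
    pac_apply_time: Optional[float],
) -> np.ndarray:
    """Shared right-hand side of the combined system.

    The single-drug systems are this RHS with the other drug's pools at zero,
    so their derivatives agree bitwise in the shared components.
    """
    T, A_b, A_f, P_i, P_f = (float(v) for v in y)

    # trastuzumab anti-proliferative factor
    if tmab_apply_time is not None:
        f = antiproliferative_effect(max(A_b, 0.0), t - tmab_apply_time, p.eta_A, p.t_star_A)
    else:
        f = 0.0

    # paclitaxel capacity reduction
    if pac_apply_time is not None:
        h = capacity_reduction(
            max(P_i, 0.0), t - pac_apply_time, p.delta_P, p.gamma_P, p.t_star_P, p.S
        )
    else:
        h = 0.0

    capacity = p.theta - h
    floor = _CAPACITY_FLOOR_FRAC * p.theta
    if capacity < floor:
        logger.debug(
            "effective carrying capacity %.3g below floor at t=%.3f; clamped", capacity, t
        )
        capacity = floor

    g_drug = 1.0 - f
    g_cap = 1.0 - T / capacity
    if g_cap < _CAPACITY_FACTOR_MIN:
        g_cap = _CAPACITY_FACTOR_MIN
    dT = p.k * g_drug * g_cap * T
    # Each factor turning negative encodes net cell loss (antibody-driven
    # death / capacity deficit).  When both are negative simultaneously the
    # raw product would flip sign and read as growth; both mechanisms being
    # individually lethal, the net effect is loss.
    if g_drug < 0.0 and g_cap < 0.0:
        dT = -abs(dT)

    if A_f > 0.0:
        dAb = p.beta_A * (A_f - A_b) * (T * p.receptor_scale - A_b)
    else:
        dAb = 0.0

    if P_f > 0.0:
        dPi = p.alpha_P * (P_f - P_i) * T
    else:
        dPi = 0.0

    return np.array([dT, dAb, -dAb, dPi, -dPi])


def trastuzumab_rhs(
    state: np.ndarray,
    t: float,
    params: ModelParams,
    tmab_apply_time: Optional[float] = None,
) -> np.ndarray:
    """RHS of the trastuzumab monotherapy system (paclitaxel pools ignored)."""
    return _rhs_core(t, state, params, tmab_apply_time, None)


def paclitaxel_rhs(
    state: np.ndarray,
    t: float,
    params: ModelParams,
    pac_apply_time: Optional[float] = None,
) -> np.ndarray:
    """RHS of the paclitaxel monotherapy system (antibody pools ignored).

    Callers should use ``S = 1`` in ``params`` for monotherapy.
    """
    return _rhs_core(t, state, params, None, pac_apply_time)


def combined_rhs(
    state: np.ndarray,
    t: float,
    params: ModelParams,
    tmab_apply_time: Optional[float] = None,
    pac_apply_time: Optional[float] = None,
) -> np.ndarray:
    """RHS of the combined two-drug system, with the synergy multiplier S."""
    return _rhs_core(t, state, params, tmab_apply_time, pac_apply_time)


def logistic_solution(t, T0: float, k: float, theta: float):
    """Closed-form logistic growth curve (the no-drug limit of every model)."""
    t = np.asarray(t, dtype=float)
    if T0 == 0:
        return np.zeros_like(t)
    return theta * T0 / (T0 + (theta - T0) * np.exp(-k * t))


def confluence_to_cells(confluence, geometry: WellGeometry = WellGeometry()):
    """Convert fractional confluence to an approximate cell number.

    cells = confluence * well_area / (pi * cell_radius^2).
    """
    c = np.asarray(confluence, dtype=float)
    if np.any(c < 0) or np.any(c > 1.0 + 1e-9):
        raise ValueError("confluence must lie in [0, 1]")
    out = c * geometry.cells_at_full_confluence
    return float(out) if np.isscalar(confluence) else out


def cells_to_confluence(cells, geometry: WellGeometry = WellGeometry()):
    """Inverse of :func:`confluence_to_cells` (exact round trip)."""
    c = np.asarray(cells, dtype=float)
    if np.any(c < 0):
        raise ValueError("cell number must be >= 0")
    out = c / geometry.cells_at_full_confluence
    return float(out) if np.isscalar(cells) else out
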