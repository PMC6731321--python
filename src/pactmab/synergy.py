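"""Drug-interaction metrics: Loewe combination index and concordance CC.

The combination index under Loewe additivity is

    CI = [A]/[A*] + [B]/[B*]

where [A] is the dose of drug A in the combination and [A*] the monotherapy
dose of A achieving the same response; CI < 1 reads as synergy, = 1 additive,
> 1 antagonism.  With a small panel of tested monotherapy doses, [A*] rarely
exists exactly, so the reference lookup is *conservative*: the smallest
tested dose whose response is equal to or stronger than (i.e. confluence at
or below) the combination response.  When the response falls strictly
between two tested doses, evaluating CI at both bracket doses yields an
interval; when it is stronger than anything tested, only an upper bound on
CI can be given (largest tested dose as reference).

The concordance correlation coefficient measures agreement between model
simulation and data, penalizing both scatter and systematic offset:

    CCC = 2 Cov(x, y) / (Var(x) + Var(y) + (mean x - mean y)^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ccc",
    "DoseResponseTable",
    "ReferenceDose",
    "CombinationIndexResult",
    "equivalent_monotherapy_dose",
    "combination_index",
    "bundled_monotherapy_tables",
    "bundled_combination_responses",
]


def ccc(x, y) -> float:
    """Concordance correlation coefficient of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 2:
        raise ValueError("need at least two points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    cov = np.cov(x, y, ddof=1)[0, 1]
    denom = vx + vy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise ValueError("both series are constant and equal; CCC undefined")
    return float(2.0 * cov / denom)


@dataclass
class DoseResponseTable:
    """Day-4 mean responses (fractional confluence) of one drug's monotherapy
    doses.  Doses strictly increasing; response is expected to fall
    (strengthen) with dose — departures are isotonically adjusted with a
    warning before any lookup."""

    drug: str
    doses: np.ndarray
    responses: np.ndarray
    ci_halfwidth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if len(self.doses) != len(self.responses):
            raise ValueError("doses and responses must have equal length")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        self._monotone = self._isotonic(self.responses)

    @staticmethod
    def _isotonic(resp: np.ndarray) -> np.ndarray:
        """Non-increasing adjustment via pool-adjacent-violators."""
        if np.all(np.diff(resp) <= 0):
            return resp.copy()
        warnings.warn(
            "dose-response table is not monotone; applying isotonic adjustment",
            stacklevel=3,
        )
        # PAV for a non-increasing fit = PAV non-decreasing on negated values
        vals = list(-resp)
        blocks = [[v, 1.0] for v in vals]
        merged: list[list[float]] = []
        for b in blocks:
            merged.append(b)
            while len(merged) > 1 and merged[-2][0] > merged[-1][0]:
                s1, n1 = merged.pop()
                s0, n0 = merged.pop()
                merged.append([(s0 * n0 + s1 * n1) / (n0 + n1), n0 + n1])
        out = []
        for mean, n in merged:
            out.extend([mean] * int(n))
        return -np.asarray(out)

    @property
    def monotone_responses(self) -> np.ndarray:
        return self._monotone


@dataclass(frozen=True)
class ReferenceDose:
    """Result of an equivalent-monotherapy-dose lookup."""

    kind: str  # exact | bracketed | beyond_range
    dose: float  # conservative reference (smallest dose achieving the response)
    bracket: Optional[Tuple[float, float]] = None  # (weaker, stronger) doses


def equivalent_monotherapy_dose(response: float, table: DoseResponseTable) -> ReferenceDose:
    """Monotherapy dose of ``table.drug`` matching a combination response.

    Lower confluence = stronger effect.  Conservative rule: the smallest
    tested dose whose (isotonically adjusted) response is <= the target; the
    adjacent weaker dose closes the bracket.  If even the largest tested dose
    is weaker than the target, the lookup is ``beyond_range`` and the largest
    dose serves as an upper-bound reference.
    """
    if len(table.doses) < 2:
        raise ValueError("table needs at least two doses")
    resp = table.monotone_responses
    achieving = np.nonzero(resp <= response)[0]
    if len(achieving) == 0:
        return ReferenceDose(kind="beyond_range", dose=float(table.doses[-1]))
    i = int(achieving[0])
    if resp[i] == response:
        return ReferenceDose(kind="exact", dose=float(table.doses[i]))
    if i == 0:
        # stronger than needed even at the lowest dose; conservative at the
        # low end, no weaker tested dose to bracket with
        return ReferenceDose(kind="bracketed", dose=float(table.doses[0]),
                             bracket=(float(table.doses[0]), float(table.doses[0])))
    return ReferenceDose(
        kind="bracketed",
        dose=float(table.doses[i]),
        bracket=(float(table.doses[i - 1]), float(table.doses[i])),
    )


@dataclass
class CombinationIndexResult:
    """Loewe combination index of one combination regimen at day 4.

    ``kind`` is ``point`` (both references resolved), ``interval`` (the
    varied drug's reference is bracketed; ``interval`` holds the CI at the
    two bracket doses) or ``upper_bound`` (a reference is beyond the tested
    range, so the reported value bounds the true CI from above).
    """

    kind: str
    value: float
    interval: Optional[Tuple[float, float]] = None
    reference_A: Optional[ReferenceDose] = None
    reference_B: Optional[ReferenceDose] = None
    classification: str = ""

    def __post_init__(self) -> None:
        if not self.classification:
            v = self.value
            if self.kind == "upper_bound":
                self.classification = (
                    "synergistic" if v <= 1 else "indeterminate (bound > 1)"
                )
            else:
                self.classification = (
                    "synergistic" if v < 1 else ("additive" if v == 1 else "antagonistic")
                )


def combination_index(
    dose_A: float,
    dose_B: float,
    response: float,
    table_A: DoseResponseTable,
    table_B: DoseResponseTable,
) -> CombinationIndexResult:
    """Loewe combination index for a combination day-4 response.

    Drug A is the "varied" axis: its bracketing drives the interval/bound
    reporting, while drug B always contributes its conservative reference
    term.  A dose of zero contributes nothing (the regimen degenerates to the
    other drug's monotherapy ratio).
    """
    ref_A = equivalent_monotherapy_dose(response, table_A) if dose_A > 0 else None
    ref_B = equivalent_monotherapy_dose(response, table_B) if dose_B > 0 else None

    term_B = 0.0
    b_beyond = False
    if ref_B is not None:
        term_B = dose_B / ref_B.dose
        b_beyond = ref_B.kind == "beyond_range"

    if ref_A is None:
        kind = "upper_bound" if b_beyond else "point"
        return CombinationIndexResult(kind=kind, value=term_B,
                                      reference_B=ref_B)

    if ref_A.kind == "beyond_range" or (ref_A.kind == "exact" and b_beyond):
        return CombinationIndexResult(
            kind="upper_bound",
            value=dose_A / ref_A.dose + term_B,
            reference_A=ref_A,
            reference_B=ref_B,
        )
    if ref_A.kind == "exact":
        return CombinationIndexResult(
            kind="point",
            value=dose_A / ref_A.dose + term_B,
            reference_A=ref_A,
            reference_B=ref_B,
        )
    lo_dose, hi_dose = ref_A.bracket  # weaker (smaller), stronger (larger)
    ci_at_hi = dose_A / hi_dose + term_B
    ci_at_lo = dose_A / lo_dose + term_B
    interval = (min(ci_at_hi, ci_at_lo), max(ci_at_hi, ci_at_lo))
    kind = "upper_bound" if b_beyond else "interval"
    return CombinationIndexResult(
        kind=kind,
        value=ci_at_hi,  # conservative endpoint
        interval=interval,
        reference_A=ref_A,
        reference_B=ref_B,
    )


def _data_frame(name: str) -> pd.DataFrame:
    with resources.files("pactmab.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def bundled_monotherapy_tables() -> Dict[str, DoseResponseTable]:
    """The packaged day-4 monotherapy dose-response panel."""
    df = _data_frame("monotherapy_day4.csv")
    out = {}
    for drug, grp in df.groupby("drug"):
        grp = grp.sort_values("dose")
        out[drug] = DoseResponseTable(
            drug=drug,
            doses=grp["dose"].to_numpy(),
            responses=grp["mean_confluence"].to_numpy(),
            ci_halfwidth=((grp["ci_hi"] - grp["ci_lo"]) / 2).to_numpy(),
        )
    return out


def bundled_combination_responses() -> pd.DataFrame:
    """The packaged day-4 combination-regimen responses."""
    return _data_frame("combination_day4.csv")
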