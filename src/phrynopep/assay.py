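"""Closed-form assay readouts: MIC from dilution series, cytotoxicity percent.

The minimum inhibitory concentration (MIC) is the lowest concentration in a
two-fold dilution series at which no microbial growth is detected, with all
higher concentrations also growth-free.  Cytotoxicity is the standard
control-normalised optical-density fraction
``100 * (OD_obs - OD_0) / (OD_100 - OD_0)``; note that in dye-uptake
viability assays OD decreases with cell death, so the 100%-lysis control
can legitimately have the *lower* OD — the formula is applied exactly as
written, sign-agnostically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["DilutionSeries", "MicResult", "mic", "cytotoxicity_percent"]


@dataclass(frozen=True)
class DilutionSeries:
    """Two-fold dilution series, highest concentration first.

    ``growth[i]`` is True when growth was detected at ``concentrations[i]``.
    """

    concentrations: tuple[float, ...]
    growth: tuple[bool, ...]

    def __init__(self, concentrations: Sequence[float], growth: Sequence[bool]):
        conc = tuple(float(c) for c in concentrations)
        grw = tuple(bool(g) for g in growth)
        if not conc:
            raise ValueError("empty dilution series")
        if len(conc) != len(grw):
            raise ValueError("concentrations and growth flags differ in length")
        for a, b in zip(conc, conc[1:]):
            if b >= a:
                raise ValueError("concentrations must be strictly descending")
            if abs(a / b - 2.0) > 0.02:
                raise ValueError(f"not a two-fold step: {a} -> {b}")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "growth", grw)


@dataclass(frozen=True)
class MicResult:
    value_um: float | None  # None when growth persists at the top concentration
    above_range: bool
    max_tested_um: float
    anomalous_wells: tuple[float, ...] = ()  # no-growth wells below a growth well

    def __str__(self) -> str:
        if self.above_range:
            return f">{self.max_tested_um:g} µM"
        return f"{self.value_um:g} µM"


def mic(series: DilutionSeries) -> MicResult:
    """Lowest concentration with no growth at it and every higher concentration.

    Growth at the top concentration yields an above-range marker.  A
    non-monotone pattern (growth above a growth-free well) is flagged and
    the MIC is computed conservatively from the contiguous growth-free run
    anchored at the highest concentration.
    """
    top = series.concentrations[0]
    n_clear = 0
    for g in series.growth:
        if g:
            break
        n_clear += 1
    anomalies = tuple(
        c for c, g in zip(series.concentrations[n_clear:], series.growth[n_clear:]) if not g
    )
    if n_clear == 0:
        return MicResult(None, True, top, anomalies)
    return MicResult(series.concentrations[n_clear - 1], False, top, anomalies)


def cytotoxicity_percent(od_obs, od0: float, od100: float, clamp: bool = False):
    """100 * (OD_obs - OD_0) / (OD_100 - OD_0); may fall outside [0, 100].

    Noisy wells legitimately map outside the control range and are reported
    unclamped by default.  Accepts scalars or arrays.
    """
    if od100 == od0:
        raise ValueError("degenerate controls: OD_100 equals OD_0")
    pct = 100.0 * (np.asarray(od_obs, dtype=float) - od0) / (od100 - od0)
    if clamp:
        pct = np.clip(pct, 0.0, 100.0)
    if np.ndim(od_obs) == 0:
        return float(pct)
    return pct
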