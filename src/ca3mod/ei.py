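"""Excitation-inhibition ratio maps across burst statistics.

Spike trains are summarised by two intervals: the between-burst interval
(background firing) and the within-burst interval (spacing inside a
10-pulse burst). For every grid cell the excitatory (f^2) and inhibitory
(afd) STP models are initialised at their between-interval steady state
and run over the burst, and the per-pulse E/I ratio is formed from
current magnitudes at the recording holding potentials. Everything here
is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .stp import RecordingConfig, burst_response
from .synth import ConditionSpec, driving_force

__all__ = ["BurstGrid", "EIMap", "compute_ei_map"]


@dataclass(frozen=True)
class BurstGrid:
    """Grid of between/within burst intervals (s) and burst length."""

    between_intervals: np.ndarray = field(
        default_factory=lambda: np.logspace(np.log10(0.5), np.log10(60.0), 25))
    within_intervals: np.ndarray = field(
        default_factory=lambda: np.logspace(np.log10(0.01), np.log10(1.0), 25))
    n_pulses: int = 10

    def __post_init__(self):
        b = np.asarray(self.between_intervals, dtype=float)
        w = np.asarray(self.within_intervals, dtype=float)
        if np.any(b <= 0) or np.any(w <= 0):
            raise ValueError("all intervals must be positive")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        object.__setattr__(self, "between_intervals", b)
        object.__setattr__(self, "within_intervals", w)


@dataclass
class EIMap:
    """EPSC/IPSC current magnitudes (pA) and their ratio per grid cell
    and pulse; cells whose IPSC vanishes are flagged unbounded rather
    than carrying infinities."""

    grid: BurstGrid
    epsc: np.ndarray        # (n_between, n_within, n_pulses)
    ipsc: np.ndarray
    ratio: np.ndarray
    unbounded: np.ndarray   # bool mask where the ratio is undefined
    condition: str

    def pulse_ratio(self, pathway: str, pulse: int) -> np.ndarray:
        """nth/1st within-burst amplitude ratio map (pulse is 1-based)."""
        arr = self.epsc if pathway == "excitatory" else self.ipsc
        return arr[:, :, pulse - 1] / arr[:, :, 0]

    def to_dataframe(self) -> pd.DataFrame:
        b, w, p = np.meshgrid(self.grid.between_intervals,
                              self.grid.within_intervals,
                              np.arange(1, self.grid.n_pulses + 1),
                              indexing="ij")
        return pd.DataFrame({
            "between_s": b.ravel(), "within_s": w.ravel(),
            "pulse": p.ravel().astype(int),
            "epsc_pA": self.epsc.ravel(), "ipsc_pA": self.ipsc.ravel(),
            "ei_ratio": self.ratio.ravel(),
            "unbounded": self.unbounded.ravel(),
            "condition": self.condition,
        })


def compute_ei_map(grid: BurstGrid, epsc_condition: ConditionSpec,
                   ipsc_condition: ConditionSpec,
                   rec: Optional[RecordingConfig] = None,
                   condition_label: Optional[str] = None) -> EIMap:
    """Burst-response E and I amplitude maps and their per-pulse ratio.

    The ratio uses current magnitudes |g * amp * (v_hold - reversal)| at
    the pathway-specific holding potentials (conductance-based ratios
    differ only by the fixed driving-force factor).
    """
    if epsc_condition.pathway != "excitatory" or ipsc_condition.pathway != "inhibitory":
        raise ValueError("conditions must be (excitatory, inhibitory)")
    nb = grid.between_intervals.size
    nw = grid.within_intervals.size
    npul = grid.n_pulses
    epsc = np.empty((nb, nw, npul))
    ipsc = np.empty((nb, nw, npul))
    e_par, e_spec = epsc_condition.params, epsc_condition.model
    i_par, i_spec = ipsc_condition.params, ipsc_condition.model
    e_drive = driving_force("excitatory", rec or RecordingConfig())
    i_drive = driving_force("inhibitory", rec or RecordingConfig())
    for i, bi in enumerate(grid.between_intervals):
        for j, wi in enumerate(grid.within_intervals):
            epsc[i, j] = e_par.g_max * burst_response(
                e_par, e_spec, bi, wi, npul).amplitudes * e_drive
            ipsc[i, j] = i_par.g_max * burst_response(
                i_par, i_spec, bi, wi, npul).amplitudes * i_drive
    unbounded = ipsc < 1e-6 * ipsc.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(unbounded, np.nan, epsc / np.where(unbounded, 1.0, ipsc))
    label = condition_label or epsc_condition.condition
    return EIMap(grid=grid, epsc=epsc, ipsc=ipsc, ratio=ratio,
                 unbounded=unbounded, condition=label)
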