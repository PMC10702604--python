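"""Stepwise pressurization protocol, stretch ratios and compliance.

Runs the full measurement chain (constitutive law -> forward simulation
-> sizing) at each pressure step and derives stretch ratios CSA/CSA0,
compliance slopes dCSA/dP and plateau flags per measurement pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .device import ElectrodeLayout, SalineMedium
from .forward import NoiseModel, simulate_voltages
from .mechanics import ConstitutiveParams
from .sizing import CalibrationResult, size_profile

__all__ = [
    "PressureProtocol",
    "ComplianceCurve",
    "run_pressure_protocol",
    "stretch_ratios",
    "delta_csa",
    "compliance_slope",
    "plateau_detect",
]


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class PressureProtocol:
    """Stepwise inflation schedule, cm H2O.  Default: 0 to 40 by 5."""

    start: float = 0.0
    stop: float = 40.0
    step: float = 5.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ProtocolError("pressure step must be > 0")
        if self.stop < self.start:
            raise ProtocolError("stop pressure must be >= start")

    @property
    def pressures(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)


@dataclass(frozen=True)
class ComplianceCurve:
    """Pressure-indexed family of sizing profiles for one limb."""

    pressures: np.ndarray          # cm H2O, (n_steps,)
    csa: np.ndarray                # mm**2, (n_pairs, n_steps)
    center_mm: np.ndarray          # (n_pairs,)
    pair_index: np.ndarray         # (n_pairs,)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("pressures", "csa", "center_mm", "pair_index"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if self.csa.shape != (self.pair_index.size, self.pressures.size):
            raise ProtocolError("CSA matrix shape must be (pairs, steps)")

    @property
    def csa0(self) -> np.ndarray:
        """Baseline CSA per pair: CSA at the first protocol step."""
        return self.csa[:, 0]

    @property
    def stretch(self) -> np.ndarray:
        """Per-pair, per-step stretch ratios CSA/CSA0."""
        if np.any(self.csa0 <= 0):
            raise ProtocolError("zero baseline CSA")
        return self.csa / self.csa0[:, None]

    def step_index(self, pressure: float) -> int:
        hits = np.flatnonzero(np.isclose(self.pressures, pressure,
                                         rtol=0, atol=1e-9))
        if hits.size == 0:
            raise ProtocolError(
                f"pressure {pressure} cm H2O is not a protocol step"
            )
        return int(hits[0])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per pair per pressure step."""
        stretch = self.stretch
        rows = []
        for i, pidx in enumerate(self.pair_index):
            for j, p in enumerate(self.pressures):
                rows.append(
                    {
                        "animal": self.metadata.get("animal", ""),
                        "limb": self.metadata.get("limb", ""),
                        "state": self.metadata.get("state", ""),
                        "pair_index": int(pidx),
                        "pressure_cmH2O": p,
                        "csa_mm2": self.csa[i, j],
                        "stretch_ratio": stretch[i, j],
                    }
                )
        return pd.DataFrame(rows)


def run_pressure_protocol(vein: ConstitutiveParams, layout: ElectrodeLayout,
                          medium: SalineMedium, noise: NoiseModel,
                          protocol: PressureProtocol | None = None,
                          calibration: CalibrationResult | None = None,
                          metadata: dict | None = None) -> ComplianceCurve:
    """Simulate and size the limb at every protocol pressure step.

    The lumen presented to the simulator is capped at the balloon's
    maximum cross-section (the device measures the balloon itself).  The
    catheter is assumed calibrated: unless an explicit calibration is
    given, the medium's true conductivity is used for the inversion.
    Noise draws continue one seeded stream across steps.
    """
    if protocol is None:
        protocol = PressureProtocol()
    if calibration is None:
        calibration = CalibrationResult(sigma=medium.conductivity)
    pressures = protocol.pressures
    balloon_max_csa = np.pi * (layout.balloon_max_diameter / 2.0) ** 2
    rng = noise.rng() if noise.relative_sd > 0 else None
    csa_cols = []
    centers = pair_idx = None
    for p in pressures:
        lumen = vein.lumen_profile(p).capped(balloon_max_csa)
        rec = simulate_voltages(lumen, layout, medium, noise,
                                pressure_cmh2o=p, rng=rng)
        prof = size_profile(rec, layout, calibration)
        csa_cols.append(prof.csa)
        centers, pair_idx = prof.center_mm, prof.pair_index
    meta = dict(metadata or {})
    meta.setdefault("state", vein.state)
    meta.setdefault("seed", noise.seed)
    return ComplianceCurve(
        pressures=pressures,
        csa=np.column_stack(csa_cols),
        center_mm=centers,
        pair_index=pair_idx,
        metadata=meta,
    )


def stretch_ratios(curve: ComplianceCurve) -> np.ndarray:
    """Mean circumferential stretch ratio per pressure step.

    Per pair the ratio is CSA/CSA0; the returned value per step is the
    unweighted mean of the ratios over the balloon length.
    """
    return curve.stretch.mean(axis=0)


def delta_csa(curve: ComplianceCurve, pair: int, p_lo: float,
              p_hi: float) -> float:
    """CSA(P_hi) - CSA(P_lo), mm**2, for one measurement pair."""
    row = np.flatnonzero(curve.pair_index == pair)
    if row.size == 0:
        raise ProtocolError(f"no pair with index {pair}")
    i = int(row[0])
    return float(curve.csa[i, curve.step_index(p_hi)]
                 - curve.csa[i, curve.step_index(p_lo)])


def compliance_slope(curve: ComplianceCurve, pair: int,
                     window: tuple[float, float] | None = None) -> float:
    """Least-squares slope of CSA vs pressure (mm**2 per cm H2O).

    ``window`` restricts to protocol steps with p_lo <= P <= p_hi;
    the fit has a free intercept (not forced through the origin).
    """
    row = np.flatnonzero(curve.pair_index == pair)
    if row.size == 0:
        raise ProtocolError(f"no pair with index {pair}")
    p = curve.pressures
    y = curve.csa[int(row[0])]
    if window is not None:
        sel = (p >= window[0]) & (p <= window[1])
        p, y = p[sel], y[sel]
    if p.size < 2:
        raise ProtocolError("slope window must contain >= 2 steps")
    return float(np.polyfit(p, y, 1)[0])


def _ls_slope(p: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(p, y, 1)[0])


#: Trailing slope below this fraction of the leading slope flags a plateau.
PLATEAU_SLOPE_FRACTION = 0.1
#: Leading reference window and minimum trailing window, in steps.
PLATEAU_LEAD_STEPS = 3
PLATEAU_MIN_TRAIL_STEPS = 3


def plateau_detect(curve: ComplianceCurve,
                   pair: int) -> tuple[bool, float | None]:
    """Detect a compliance plateau in one pair's pressure-CSA curve.

    The leading slope is fit over the first ``PLATEAU_LEAD_STEPS`` steps.
    Scanning candidate onsets from early to late, a plateau is flagged at
    the first step whose trailing window (that step through the end, at
    least ``PLATEAU_MIN_TRAIL_STEPS`` steps) has slope below
    ``PLATEAU_SLOPE_FRACTION`` of the leading slope.  Returns
    ``(False, None)`` when no window qualifies or the curve never rises.
    """
    row = np.flatnonzero(curve.pair_index == pair)
    if row.size == 0:
        raise ProtocolError(f"no pair with index {pair}")
    p = curve.pressures
    y = curve.csa[int(row[0])]
    n = p.size
    if n < PLATEAU_LEAD_STEPS + 1:
        raise ProtocolError("plateau detection needs >= 4 pressure steps")
    lead = _ls_slope(p[:PLATEAU_LEAD_STEPS], y[:PLATEAU_LEAD_STEPS])
    # floor guards against flagging numerically flat (rigid) curves
    if lead <= 1e-9 * np.max(np.abs(y)) / (p[-1] - p[0]):
        return False, None
    for i in range(1, n - PLATEAU_MIN_TRAIL_STEPS + 1):
        if _ls_slope(p[i:], y[i:]) < PLATEAU_SLOPE_FRACTION * lead:
            return True, float(p[i])
    return False, None
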