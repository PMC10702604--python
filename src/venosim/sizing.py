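"""Inverse problem: from measured voltages back to lumen cross-sections.

Implements what the console does: synchronous demodulation of the carrier,
saline-conductivity calibration against a reference phantom, per-pair
Ohm's-law CSA inversion, profile assembly, minimal-lumen detection and
the stent-sizing reference diameter.

For a lumen that varies within one pair span, the series-conductor
physics makes the recovered CSA the harmonic mean of A(z) over the span;
this is documented behaviour, not corrected for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .device import ElectrodeLayout, pairs
from .forward import RawRecording

__all__ = [
    "CalibrationResult",
    "SizingProfile",
    "demodulate",
    "calibrate_conductivity",
    "csa_from_voltage",
    "diameter_from_csa",
    "size_profile",
    "detect_minimal_lumen",
    "reference_diameter",
    "write_profile",
    "read_profile",
]

PROFILE_COLUMNS = ["pair_index", "center_mm", "csa_mm2", "diameter_mm",
                   "pressure_cmH2O"]


class SizingError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationResult:
    """Estimated saline conductivity from a uniform reference phantom."""

    sigma: float                 # S/mm
    reference_csa: float | None = None   # mm**2
    pair_index: int | None = None        # None when averaged over pairs
    residual: float = 0.0        # max relative spread across pairs used

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise SizingError("calibrated conductivity must be > 0")


@dataclass(frozen=True)
class SizingProfile:
    """Per-pair CSA/diameter estimates at one pressure step."""

    pair_index: np.ndarray
    center_mm: np.ndarray
    csa: np.ndarray              # mm**2
    diameter: np.ndarray         # mm
    pressure_cmh2o: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        for name in ("pair_index", "center_mm", "csa", "diameter"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if np.any(self.csa <= 0):
            raise SizingError("all CSA estimates must be positive")
        if not np.allclose(self.csa, np.pi * (self.diameter / 2) ** 2,
                           rtol=1e-9, atol=0):
            raise SizingError("CSA and diameter columns are inconsistent")

    @property
    def n_pairs(self) -> int:
        return int(self.csa.size)


def demodulate(waveform: np.ndarray, carrier_frequency_khz: float,
               internal_rate_khz: float) -> float:
    """Synchronous (lock-in) amplitude of a sine-phase-aligned carrier.

    amplitude = 2 * mean(w * sin(2 pi f t)) over an integer number of
    carrier cycles; the window is truncated to the largest whole cycle
    count.  Exact for a clean sine.
    """
    w = np.asarray(waveform, dtype=float)
    samples_per_cycle = internal_rate_khz / carrier_frequency_khz
    n_cycles = int(math.floor(w.size / samples_per_cycle))
    if n_cycles < 1:
        raise SizingError("waveform shorter than one carrier cycle")
    n = int(round(n_cycles * samples_per_cycle))
    t = np.arange(n) / (internal_rate_khz * 1e3)
    ref = np.sin(2 * np.pi * carrier_frequency_khz * 1e3 * t)
    return float(2.0 * np.mean(w[:n] * ref))


def calibrate_conductivity(recording: RawRecording, layout: ElectrodeLayout,
                           reference_csa: float,
                           reference_pair: int | None = None,
                           current: float | None = None,
                           average_inner: bool = True) -> CalibrationResult:
    """Saline conductivity from a uniform reference phantom recording.

    For a uniform conductor, sigma = I * L / (dV * A_ref) per pair.  By
    default the estimate is averaged over all inner (shortest-span)
    pairs; pass ``reference_pair`` to use a single pair instead.
    """
    if reference_csa <= 0:
        raise SizingError("reference CSA must be > 0")
    if current is None:
        current = layout.current_a
    idx = recording.pair_index
    spans = recording.span_mm
    dv = recording.voltage
    if np.any(dv <= 0):
        raise SizingError("calibration requires positive voltages")
    per_pair_sigma = current * spans / (dv * reference_csa)
    if reference_pair is not None:
        sel = idx == reference_pair
        if not np.any(sel):
            raise SizingError(f"no pair with index {reference_pair}")
        sigma = float(per_pair_sigma[sel][0])
        return CalibrationResult(sigma=sigma, reference_csa=reference_csa,
                                 pair_index=reference_pair)
    if average_inner:
        sel = spans == spans.min()
    else:
        sel = np.ones_like(spans, dtype=bool)
    vals = per_pair_sigma[sel]
    sigma = float(np.mean(vals))
    residual = float(np.max(np.abs(vals - sigma)) / sigma) if vals.size else 0.0
    return CalibrationResult(sigma=sigma, reference_csa=reference_csa,
                             pair_index=None, residual=residual)


def csa_from_voltage(delta_v: float, sigma: float, span_l: float,
                     current: float) -> float:
    """Ohm's-law inversion: CSA = I * L / (sigma * dV), mm**2."""
    if min(delta_v, sigma, span_l, current) <= 0:
        raise SizingError("all sizing inputs must be positive")
    return current * span_l / (sigma * delta_v)


def diameter_from_csa(csa: float | np.ndarray) -> float | np.ndarray:
    """Equivalent circular diameter, mm: D = 2 sqrt(CSA / pi)."""
    return 2.0 * np.sqrt(np.asarray(csa) / np.pi)


def size_profile(recording: RawRecording, layout: ElectrodeLayout,
                 calibration: CalibrationResult,
                 source: str = "") -> SizingProfile:
    """Apply the Ohm's-law inversion per pair, proximal to distal."""
    expected = pairs(layout)
    if recording.n_pairs != len(expected):
        raise SizingError(
            f"recording has {recording.n_pairs} pairs, layout expects "
            f"{len(expected)}"
        )
    order = np.argsort(recording.pair_index)
    dv = recording.voltage[order]
    spans = recording.span_mm[order]
    csa = layout.current_a * spans / (calibration.sigma * dv)
    return SizingProfile(
        pair_index=recording.pair_index[order],
        center_mm=recording.center_mm[order],
        csa=csa,
        diameter=diameter_from_csa(csa),
        pressure_cmh2o=recording.pressure_cmh2o,
        source=source,
    )


def detect_minimal_lumen(profile: SizingProfile) -> tuple[int, float]:
    """Pair index and CSA of the minimal lumen (the lesion site).

    Ties break toward the most proximal pair.
    """
    if profile.n_pairs == 0:
        raise SizingError("empty sizing profile")
    i = int(np.argmin(profile.csa))   # argmin returns first minimum
    return int(profile.pair_index[i]), float(profile.csa[i])


def reference_diameter(profile: SizingProfile, lesion: int) -> float:
    """Mean diameter away from the lesion (stent-sizing reference).

    Excludes the lesion pair and its immediate neighbours.
    """
    keep = np.abs(profile.pair_index - lesion) > 1
    if not np.any(keep):
        raise SizingError("no pairs left outside the lesion exclusion zone")
    return float(np.mean(profile.diameter[keep]))


def write_profile(profile: SizingProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "pair_index": profile.pair_index.astype(int),
            "center_mm": profile.center_mm,
            "csa_mm2": profile.csa,
            "diameter_mm": profile.diameter,
            "pressure_cmH2O": profile.pressure_cmh2o,
        }
    ).to_csv(path, index=False, columns=PROFILE_COLUMNS)


def read_profile(path: str | Path) -> SizingProfile:
    frame = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in frame.columns]
    if missing:
        raise SizingError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    frame = frame.sort_values("pair_index")
    return SizingProfile(
        pair_index=frame["pair_index"].to_numpy(),
        center_mm=frame["center_mm"].to_numpy(),
        csa=frame["csa_mm2"].to_numpy(),
        diameter=frame["diameter_mm"].to_numpy(),
        pressure_cmh2o=float(frame["pressure_cmH2O"].iloc[0]),
        source=str(path),
    )
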