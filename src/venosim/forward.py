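"""Forward physics: conductance of the saline column and simulated voltages.

The balloon membrane insulates the saline column from the surrounding
tissue, so each measurement pair sees a one-dimensional series conductor:

    G = sigma / integral(dz / A(z))  over the pair span,

which reduces to ``sigma * A / L`` for a uniform lumen.  With a constant
excitation current I the demodulated pair voltage is ``dV = I / G``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .device import ElectrodeLayout, SalineMedium, pairs

__all__ = [
    "LumenProfile",
    "NoiseModel",
    "RawRecording",
    "pair_conductance",
    "simulate_voltages",
    "synthesize_carrier",
    "write_recordings",
    "read_recordings",
]

RECORDING_COLUMNS = [
    "pair_index",
    "center_mm",
    "span_mm",
    "voltage_V",
    "pressure_cmH2O",
    "seed",
]

#: Multiplicative noise never pushes an amplitude below this fraction of
#: its clean value, keeping voltages physical (positive).
NOISE_FLOOR_FRACTION = 0.1


class ProfileError(ValueError):
    """Invalid lumen profile or out-of-range measurement span."""


@dataclass(frozen=True)
class LumenProfile:
    """Axial profile of luminal cross-sectional area at one instant."""

    z: np.ndarray        # mm, strictly increasing
    csa: np.ndarray      # mm**2, > 0
    label: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        csa = np.asarray(self.csa, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "csa", csa)
        if z.ndim != 1 or z.size < 2:
            raise ProfileError("profile grid needs at least 2 points")
        if csa.shape != z.shape:
            raise ProfileError("z and csa must have matching shapes")
        if np.any(np.diff(z) <= 0):
            raise ProfileError("profile grid must be strictly increasing")
        if np.any(csa <= 0) or not np.all(np.isfinite(csa)):
            raise ProfileError("all CSA values must be positive and finite")

    def covers(self, z1: float, z2: float) -> bool:
        return self.z[0] <= z1 and z2 <= self.z[-1]

    @staticmethod
    def uniform(csa: float, z_start: float = 0.0, z_stop: float = 60.0,
                label: str = "") -> "LumenProfile":
        z = np.array([z_start, z_stop])
        return LumenProfile(z=z, csa=np.full(2, float(csa)), label=label)

    def capped(self, max_csa: float) -> "LumenProfile":
        """Profile clipped to the balloon envelope."""
        return LumenProfile(z=self.z, csa=np.minimum(self.csa, max_csa),
                            label=self.label)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise on demodulated voltage amplitudes."""

    relative_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class RawRecording:
    """Demodulated per-pair voltages at one pressure step.

    ``waveforms`` (pairs x samples) and ``sample_rate_hz`` are populated
    only after carrier synthesis.
    """

    pair_index: np.ndarray       # 1-based
    center_mm: np.ndarray
    span_mm: np.ndarray
    voltage: np.ndarray          # V, demodulated amplitude per pair
    pressure_cmh2o: float = 0.0
    seed: int | None = None
    waveforms: np.ndarray | None = None
    sample_rate_hz: float | None = None

    def __post_init__(self) -> None:
        for name in ("pair_index", "center_mm", "span_mm", "voltage"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        n = self.voltage.size
        if not (self.pair_index.size == self.center_mm.size
                == self.span_mm.size == n):
            raise ValueError("per-pair arrays must have equal length")
        if np.any(self.voltage <= 0):
            raise ValueError("demodulated voltages must be positive")

    @property
    def n_pairs(self) -> int:
        return int(self.voltage.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_index": self.pair_index.astype(int),
                "center_mm": self.center_mm,
                "span_mm": self.span_mm,
                "voltage_V": self.voltage,
                "pressure_cmH2O": self.pressure_cmh2o,
                "seed": -1 if self.seed is None else self.seed,
            }
        )


def pair_conductance(profile: LumenProfile, z1: float, z2: float,
                     medium: SalineMedium) -> float:
    """Conductance (S) of the saline column between electrodes at z1 < z2.

    Evaluates ``sigma / integral(dz / A)`` by trapezoidal quadrature of
    1/A on the profile grid restricted to [z1, z2], with linearly
    interpolated endpoint areas.
    """
    if not z1 < z2:
        raise ProfileError(f"need z1 < z2, got {z1} >= {z2}")
    if not profile.covers(z1, z2):
        raise ProfileError(
            f"pair span [{z1}, {z2}] outside profile grid "
            f"[{profile.z[0]}, {profile.z[-1]}]"
        )
    inside = (profile.z > z1) & (profile.z < z2)
    z = np.concatenate(([z1], profile.z[inside], [z2]))
    a_ends = np.interp([z1, z2], profile.z, profile.csa)
    a = np.concatenate(([a_ends[0]], profile.csa[inside], [a_ends[1]]))
    if np.any(a <= 0):
        raise ProfileError("nonpositive CSA inside measurement span")
    integral = np.trapezoid(1.0 / a, z)   # mm / mm**2
    return medium.conductivity / integral


def simulate_voltages(profile: LumenProfile, layout: ElectrodeLayout,
                      medium: SalineMedium, noise: NoiseModel,
                      pressure_cmh2o: float = 0.0,
                      rng: np.random.Generator | None = None) -> RawRecording:
    """Clean Ohm's-law voltages per pair, then multiplicative noise.

    dV = I / G for each measurement pair; with ``relative_sd`` s > 0 each
    amplitude is scaled by (1 + eps), eps ~ N(0, s^2), floored at
    ``NOISE_FLOOR_FRACTION`` of the clean value.  Pass ``rng`` to draw
    from an ongoing stream (e.g. across pressure steps); otherwise a
    fresh generator is seeded from the noise model.
    """
    pr = pairs(layout)
    current = layout.current_a
    dv = np.empty(len(pr))
    for i, p in enumerate(pr):
        g = pair_conductance(profile, p.proximal_position, p.distal_position,
                             medium)
        dv[i] = current / g
    if noise.relative_sd > 0:
        if rng is None:
            rng = noise.rng()
        eps = rng.normal(0.0, noise.relative_sd, size=dv.size)
        dv = np.maximum(dv * (1.0 + eps), NOISE_FLOOR_FRACTION * dv)
    return RawRecording(
        pair_index=np.array([p.index for p in pr]),
        center_mm=np.array([p.center for p in pr]),
        span_mm=np.array([p.span_l for p in pr]),
        voltage=dv,
        pressure_cmh2o=float(pressure_cmh2o),
        seed=noise.seed,
    )


def synthesize_carrier(recording: RawRecording, layout: ElectrodeLayout,
                       internal_rate_khz: float = 200.0,
                       duration_ms: float = 1.0) -> RawRecording:
    """Attach sampled carrier waveforms ``dV * sin(2 pi f t)`` per pair.

    Requires at least 8 samples per carrier cycle and a window of at
    least 10 carrier cycles.
    """
    f = layout.carrier_hz
    rate = internal_rate_khz * 1e3
    if rate < 8 * f:
        raise ValueError(
            f"internal rate {internal_rate_khz} kHz undersamples the "
            f"{layout.carrier_frequency} kHz carrier (need >= 8x)"
        )
    duration_s = duration_ms * 1e-3
    if duration_s * f < 10:
        raise ValueError("duration must cover at least 10 carrier cycles")
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    wave = recording.voltage[:, None] * np.sin(2 * np.pi * f * t)[None, :]
    return replace(recording, waveforms=wave, sample_rate_hz=rate)


def write_recordings(recordings: Sequence[RawRecording],
                     path: str | Path) -> None:
    """Write one or more pressure-step recordings to a single CSV."""
    frame = pd.concat([r.to_frame() for r in recordings], ignore_index=True)
    frame.to_csv(path, index=False, columns=RECORDING_COLUMNS)


def read_recordings(path: str | Path) -> list[RawRecording]:
    """Read a recording CSV back into per-pressure-step recordings.

    Raises ``ProfileError`` naming any missing column.
    """
    frame = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in frame.columns]
    if missing:
        raise ProfileError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    out = []
    for pressure, grp in frame.groupby("pressure_cmH2O", sort=True):
        grp = grp.sort_values("pair_index")
        seed = int(grp["seed"].iloc[0])
        out.append(
            RawRecording(
                pair_index=grp["pair_index"].to_numpy(),
                center_mm=grp["center_mm"].to_numpy(),
                span_mm=grp["span_mm"].to_numpy(),
                voltage=grp["voltage_V"].to_numpy(),
                pressure_cmh2o=float(pressure),
                seed=None if seed < 0 else seed,
            )
        )
    return out
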