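"""Balloon electrode geometry and excitation constants.

Single source of truth for the device's physical layout and unit
conventions.  Internal units: lengths in mm, areas in mm**2, conductivity
in S/mm, voltages in V, pressures in cm H2O.  The layout itself carries
the excitation current in uA and the carrier frequency in kHz (the units
every configuration file uses); convert at point of use via
:attr:`ElectrodeLayout.current_a` and :attr:`ElectrodeLayout.carrier_hz`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

__all__ = [
    "ElectrodeLayout",
    "MeasurementPair",
    "SalineMedium",
    "default_layout",
    "pairs",
    "load_layout",
    "save_layout",
]

#: Diameter envelope of the flexible balloon, mm.
BALLOON_DIAMETER_RANGE = (2.0, 18.0)


class LayoutError(ValueError):
    """Raised when an electrode layout violates its invariants."""


@dataclass(frozen=True)
class MeasurementPair:
    """One adjacent detection-electrode pair (a single axial measurement)."""

    index: int                  # 1-based, proximal -> distal
    proximal_position: float    # mm
    distal_position: float      # mm

    def __post_init__(self) -> None:
        if not self.distal_position > self.proximal_position:
            raise LayoutError(
                f"pair {self.index}: span must be positive "
                f"({self.proximal_position} .. {self.distal_position})"
            )

    @property
    def span_l(self) -> float:
        """Electrode separation, mm."""
        return self.distal_position - self.proximal_position

    @property
    def center(self) -> float:
        """Axial midpoint, mm."""
        return 0.5 * (self.proximal_position + self.distal_position)


@dataclass(frozen=True)
class ElectrodeLayout:
    """Axial electrode positions plus excitation parameters.

    Coordinates are measured from the proximal balloon end and increase
    distally.  The two outer marker electrodes double as excitation and
    the outermost detection electrodes.
    """

    detection_positions: tuple[float, ...]   # mm, strictly increasing
    excitation_positions: tuple[float, float]  # mm
    current_amplitude: float = 136.0         # uA
    carrier_frequency: float = 10.0          # kHz
    balloon_length: float = 60.0             # mm
    balloon_max_diameter: float = 18.0       # mm

    def __post_init__(self) -> None:
        pos = tuple(float(p) for p in self.detection_positions)
        object.__setattr__(self, "detection_positions", pos)
        exc = tuple(float(p) for p in self.excitation_positions)
        object.__setattr__(self, "excitation_positions", exc)
        if len(pos) < 2:
            raise LayoutError("need at least 2 detection electrodes")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise LayoutError("detection positions must be strictly increasing")
        if len(exc) != 2:
            raise LayoutError("exactly two excitation electrodes required")
        lo, hi = min(exc), max(exc)
        if not (lo <= pos[0] and pos[-1] <= hi):
            raise LayoutError("excitation electrodes must bracket all detection electrodes")
        if self.current_amplitude <= 0:
            raise LayoutError("current_amplitude must be > 0")
        if self.carrier_frequency <= 0:
            raise LayoutError("carrier_frequency must be > 0")
        if self.balloon_length <= 0:
            raise LayoutError("balloon_length must be > 0")
        dmin, dmax = BALLOON_DIAMETER_RANGE
        if not (dmin <= self.balloon_max_diameter <= dmax):
            raise LayoutError(
                f"balloon_max_diameter must lie in [{dmin}, {dmax}] mm"
            )

    @property
    def current_a(self) -> float:
        """Excitation current in amperes."""
        return self.current_amplitude * 1e-6

    @property
    def carrier_hz(self) -> float:
        """Carrier frequency in Hz."""
        return self.carrier_frequency * 1e3

    @property
    def n_pairs(self) -> int:
        return len(self.detection_positions) - 1

    def pairs(self) -> tuple[MeasurementPair, ...]:
        return pairs(self)


def pairs(layout: ElectrodeLayout) -> tuple[MeasurementPair, ...]:
    """Adjacent detection-electrode pairs, proximal to distal.

    ``n`` detection electrodes tile into ``n - 1`` non-overlapping,
    gap-free pairs.
    """
    pos = layout.detection_positions
    return tuple(
        MeasurementPair(index=i + 1, proximal_position=a, distal_position=b)
        for i, (a, b) in enumerate(zip(pos, pos[1:]))
    )


@dataclass(frozen=True)
class SalineMedium:
    """Conductive filling solution inside the balloon.

    conductivity is in S/mm (0.9% saline at room temperature is about
    1.6 S/m = 0.0016 S/mm); temperature is informational only.
    """

    conductivity: float = 0.0016   # S/mm
    temperature_c: float = 25.0

    def __post_init__(self) -> None:
        if self.conductivity <= 0:
            raise ValueError("conductivity must be > 0")


# Default geometry: 7 central detection electrodes at 5 mm pitch plus the
# two outer marker electrodes 10 mm beyond their neighbours, all inside a
# 60 mm balloon; the detection span of 50 mm is centred in the balloon.
_DEFAULT_DETECTION = (5.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 55.0)


def default_layout() -> ElectrodeLayout:
    """The stock 9-electrode, 8-pair layout.

    Pair spans, proximal to distal, are [10, 5, 5, 5, 5, 5, 5, 10] mm;
    excitation: 136 uA at 10 kHz between the outermost electrodes.
    """
    return ElectrodeLayout(
        detection_positions=_DEFAULT_DETECTION,
        excitation_positions=(_DEFAULT_DETECTION[0], _DEFAULT_DETECTION[-1]),
    )


def layout_to_dict(layout: ElectrodeLayout) -> dict:
    return {
        "detection_positions_mm": list(layout.detection_positions),
        "excitation_positions_mm": list(layout.excitation_positions),
        "current_amplitude_ua": layout.current_amplitude,
        "carrier_frequency_khz": layout.carrier_frequency,
        "balloon_length_mm": layout.balloon_length,
        "balloon_max_diameter_mm": layout.balloon_max_diameter,
    }


def layout_from_dict(d: dict) -> ElectrodeLayout:
    try:
        return ElectrodeLayout(
            detection_positions=tuple(d["detection_positions_mm"]),
            excitation_positions=tuple(d["excitation_positions_mm"]),
            current_amplitude=float(d["current_amplitude_ua"]),
            carrier_frequency=float(d["carrier_frequency_khz"]),
            balloon_length=float(d["balloon_length_mm"]),
            balloon_max_diameter=float(d["balloon_max_diameter_mm"]),
        )
    except KeyError as exc:
        raise LayoutError(f"device config missing key: {exc.args[0]}") from exc


def save_layout(layout: ElectrodeLayout, path: str | Path) -> None:
    """Write a `device.json` configuration file."""
    Path(path).write_text(json.dumps(layout_to_dict(layout), indent=2) + "\n")


def load_layout(path: str | Path) -> ElectrodeLayout:
    """Read a `device.json` configuration file."""
    return layout_from_dict(json.loads(Path(path).read_text()))
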