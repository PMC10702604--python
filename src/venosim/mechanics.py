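"""Synthetic pressure-area mechanics for phantoms and vein states.

Rigid phantoms have pressure-independent CSA.  Veins follow a
linear-with-hard-plateau constitutive law per axial position:

    CSA(z, P) = CSA0(z) + c(z) * min(P, P_sat(z))

Control and VHT (venous-hypertension) limbs are linear over the working
range (P_sat infinite); post-thrombotic stenosis (PTS) saturates at a
finite P_sat, producing the characteristic stretch-ratio plateau.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .forward import LumenProfile

__all__ = [
    "PhantomSpec",
    "ConstitutiveParams",
    "CohortSpec",
    "CohortLimb",
    "csa_at_pressure",
    "make_worked_example_vein",
    "generate_cohort",
    "make_phantom_set",
    "control_template",
    "vht_template",
    "pts_template",
    "WORKED_EXAMPLE_PAIRS",
]

PHANTOM_DIAMETER_RANGE = (2.0, 18.0)

#: Measurement-pair roles in the worked-example vein (default layout):
#: the uniform segments under the end pairs and the lesion-centre pairs.
WORKED_EXAMPLE_PAIRS = {
    "proximal_reference": 1,
    "distal_reference": 8,
    "lesion": (4, 5),
}

_DEFAULT_GRID_STEP = 0.25   # mm


@dataclass(frozen=True)
class PhantomSpec:
    """Rigid calibration phantom of known diameter."""

    diameter: float           # mm
    length: float = 60.0      # mm

    def __post_init__(self) -> None:
        lo, hi = PHANTOM_DIAMETER_RANGE
        if not (lo <= self.diameter <= hi):
            raise ValueError(
                f"phantom diameter {self.diameter} mm outside [{lo}, {hi}]"
            )
        if self.length <= 0:
            raise ValueError("phantom length must be > 0")

    @property
    def csa(self) -> float:
        return np.pi * (self.diameter / 2.0) ** 2

    def profile(self) -> LumenProfile:
        return LumenProfile.uniform(
            self.csa, 0.0, self.length, label=f"phantom_d{self.diameter:g}mm"
        )


def make_phantom_set(diameters: Sequence[float] | None = None,
                     length: float = 60.0) -> list[LumenProfile]:
    """Uniform rigid profiles; default set is 2..18 mm in 1 mm steps."""
    if diameters is None:
        diameters = range(2, 19)
    return [PhantomSpec(float(d), length).profile() for d in diameters]


@dataclass(frozen=True)
class ConstitutiveParams:
    """Axially resolved linear-plateau pressure-area law for one limb."""

    z: np.ndarray          # mm, strictly increasing
    csa0: np.ndarray       # mm**2, baseline CSA at P = 0
    c: np.ndarray          # mm**2 per cm H2O, compliance slope
    psat: np.ndarray       # cm H2O, saturation pressure (inf = no plateau)
    state: str = "Control"

    def __post_init__(self) -> None:
        for name in ("z", "csa0", "c", "psat"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("axial grid must be strictly increasing")
        if np.any(self.csa0 <= 0):
            raise ValueError("baseline CSA must be > 0")
        if np.any(self.c < 0):
            raise ValueError("compliance slope must be >= 0")
        if np.any(self.psat <= 0):
            raise ValueError("saturation pressure must be > 0")

    def lumen_profile(self, pressure: float) -> LumenProfile:
        """Axial CSA profile at one distending pressure (cm H2O)."""
        if pressure < 0:
            raise ValueError("pressure must be >= 0")
        csa = self.csa0 + self.c * np.minimum(pressure, self.psat)
        return LumenProfile(z=self.z, csa=csa,
                            label=f"{self.state}@P={pressure:g}")

    def to_dict(self) -> dict:
        psat = [None if not np.isfinite(p) else p for p in self.psat]
        return {
            "z_mm": self.z.tolist(),
            "csa0_mm2": self.csa0.tolist(),
            "c_mm2_per_cmH2O": self.c.tolist(),
            "psat_cmH2O": psat,
            "state": self.state,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConstitutiveParams":
        psat = np.array([np.inf if p is None else p for p in d["psat_cmH2O"]])
        return cls(z=np.array(d["z_mm"]), csa0=np.array(d["csa0_mm2"]),
                   c=np.array(d["c_mm2_per_cmH2O"]), psat=psat,
                   state=d["state"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ConstitutiveParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def csa_at_pressure(params: ConstitutiveParams, z: float | np.ndarray,
                    pressure: float) -> float | np.ndarray:
    """CSA (mm**2) at axial position(s) z and pressure P, interpolated
    linearly on the parameter grid."""
    profile = params.lumen_profile(pressure)
    out = np.interp(z, profile.z, profile.csa)
    return float(out) if np.isscalar(z) else out


def _raised_cosine_blend(z: np.ndarray, z_lo: float, z_hi: float,
                         v_lo: float, v_hi: float) -> np.ndarray:
    """Smooth C1 transition of a scalar field between two segments."""
    t = np.clip((z - z_lo) / (z_hi - z_lo), 0.0, 1.0)
    w = 0.5 * (1.0 - np.cos(np.pi * t))
    return v_lo + (v_hi - v_lo) * w


def _segmented_params(z: np.ndarray, segments: list[dict],
                      state: str) -> ConstitutiveParams:
    """Piecewise-uniform segments joined by raised-cosine ramps.

    Each segment dict: z_start, z_stop, csa0, c, psat.  Ramps span the
    gap between consecutive segments.  P_sat is blended harmonically
    (in 1/P_sat) so an infinite value degrades smoothly.
    """
    csa0 = np.empty_like(z)
    c = np.empty_like(z)
    inv_psat = np.empty_like(z)
    for i, seg in enumerate(segments):
        if i == 0:
            mask = z <= seg["z_stop"]
        elif i == len(segments) - 1:
            mask = z > segments[i - 1]["z_stop"]
        else:
            mask = (z > segments[i - 1]["z_stop"]) & (z <= seg["z_stop"])
        csa0[mask] = seg["csa0"]
        c[mask] = seg["c"]
        inv_psat[mask] = 0.0 if np.isinf(seg["psat"]) else 1.0 / seg["psat"]
    for prev, nxt in zip(segments, segments[1:]):
        lo, hi = prev["z_stop"], nxt["z_start"]
        mask = (z > lo) & (z <= hi)
        if not np.any(mask):
            continue
        csa0[mask] = _raised_cosine_blend(z[mask], lo, hi,
                                          prev["csa0"], nxt["csa0"])
        c[mask] = _raised_cosine_blend(z[mask], lo, hi, prev["c"], nxt["c"])
        ip_lo = 0.0 if np.isinf(prev["psat"]) else 1.0 / prev["psat"]
        ip_hi = 0.0 if np.isinf(nxt["psat"]) else 1.0 / nxt["psat"]
        inv_psat[mask] = _raised_cosine_blend(z[mask], lo, hi, ip_lo, ip_hi)
    with np.errstate(divide="ignore"):
        psat = np.where(inv_psat > 0, 1.0 / np.where(inv_psat > 0,
                                                     inv_psat, 1.0), np.inf)
    return ConstitutiveParams(z=z, csa0=csa0, c=c, psat=psat, state=state)


def make_worked_example_vein(grid_step: float = _DEFAULT_GRID_STEP
                             ) -> ConstitutiveParams:
    """The published stenotic-vein example as a constitutive fixture.

    Proximal reference segment: 60 mm**2 at rest rising to 70 mm**2 at
    40 cm H2O.  Distal reference: 57 rising to 70.  Central lesion:
    57 mm**2 rising to 61 mm**2 with a hard plateau from 20 cm H2O.
    Segments are joined by 5 mm-half-width raised-cosine ramps; under
    the default electrode layout the end pairs (1 and 8) and the
    lesion-centre pairs (4 and 5) sit on uniform segments.
    """
    z = np.arange(0.0, 60.0 + grid_step / 2, grid_step)
    segments = [
        # proximal reference: covers pairs 1-2 (z <= 20)
        {"z_start": 0.0, "z_stop": 20.0, "csa0": 60.0, "c": 0.25,
         "psat": np.inf},
        # lesion: covers pairs 4-5 (25 <= z <= 35); 57 -> 61 then plateau
        {"z_start": 25.0, "z_stop": 35.0, "csa0": 57.0, "c": 0.2,
         "psat": 20.0},
        # distal reference: covers pairs 7-8 (z >= 40); 57 -> 70 at 40
        {"z_start": 40.0, "z_stop": 60.0, "csa0": 57.0, "c": 0.325,
         "psat": np.inf},
    ]
    return _segmented_params(z, segments, state="PTS")


def control_template(grid_step: float = _DEFAULT_GRID_STEP
                     ) -> ConstitutiveParams:
    """Healthy femoral-vein limb: uniform, linear over the working range."""
    z = np.arange(0.0, 60.0 + grid_step / 2, grid_step)
    n = z.size
    return ConstitutiveParams(z=z, csa0=np.full(n, 60.0), c=np.full(n, 0.25),
                              psat=np.full(n, np.inf), state="Control")


def vht_template(grid_step: float = _DEFAULT_GRID_STEP) -> ConstitutiveParams:
    """Venous-hypertension limb: compliance between Control and PTS."""
    z = np.arange(0.0, 60.0 + grid_step / 2, grid_step)
    n = z.size
    return ConstitutiveParams(z=z, csa0=np.full(n, 60.0), c=np.full(n, 0.17),
                              psat=np.full(n, np.inf), state="VHT")


def pts_template(grid_step: float = _DEFAULT_GRID_STEP) -> ConstitutiveParams:
    """Post-thrombotic limb: reduced compliance with a hard plateau.

    Uniformly fibrotic over the instrumented length (the limb-average
    stretch ratio is what the state comparison uses), saturating in the
    20-25 cm H2O window: 57 mm**2 rising ~4.5 mm**2 then flat.
    """
    z = np.arange(0.0, 60.0 + grid_step / 2, grid_step)
    n = z.size
    return ConstitutiveParams(z=z, csa0=np.full(n, 57.0), c=np.full(n, 0.2),
                              psat=np.full(n, 22.5), state="PTS")


@dataclass(frozen=True)
class CohortSpec:
    """Swine cohort layout: experimental animals carry a PTS right limb
    and a VHT left limb; control animals are Control bilaterally."""

    n_experimental: int = 6
    n_control: int = 3
    csa0_rel_sd: float = 0.05
    c_rel_sd: float = 0.05
    seed: int = 0
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        if self.n_experimental < 1 or self.n_control < 1:
            raise ValueError("cohort counts must be >= 1")
        if self.csa0_rel_sd < 0 or self.c_rel_sd < 0:
            raise ValueError("variability SDs must be >= 0")


@dataclass(frozen=True)
class CohortLimb:
    animal_id: str
    limb: str       # "left" | "right"
    state: str      # "Control" | "VHT" | "PTS"
    params: ConstitutiveParams


#: PTS saturation pressures are constrained to this window (cm H2O).
PTS_PSAT_RANGE = (20.0, 25.0)


def _perturb(template: ConstitutiveParams, rng: np.random.Generator,
             csa0_rel_sd: float, c_rel_sd: float) -> ConstitutiveParams:
    """Log-normal between-animal perturbation around a state template.

    One multiplicative factor per limb for CSA0 and one for c (the
    axial shape is preserved); finite saturation pressures get the c
    factor too, clipped to the PTS window.
    """
    f_csa0 = rng.lognormal(0.0, csa0_rel_sd) if csa0_rel_sd > 0 else 1.0
    f_c = rng.lognormal(0.0, c_rel_sd) if c_rel_sd > 0 else 1.0
    psat = template.psat.copy()
    finite = np.isfinite(psat)
    if np.any(finite):
        psat[finite] = np.clip(psat[finite] * f_c, *PTS_PSAT_RANGE)
    return ConstitutiveParams(z=template.z, csa0=template.csa0 * f_csa0,
                              c=template.c * f_c, psat=psat,
                              state=template.state)


def generate_cohort(spec: CohortSpec) -> list[CohortLimb]:
    """Seeded synthetic cohort; deterministic given the spec."""
    rng = np.random.default_rng(spec.seed)
    templates = {
        "Control": control_template(spec.grid_step),
        "VHT": vht_template(spec.grid_step),
        "PTS": pts_template(spec.grid_step),
    }
    limbs: list[CohortLimb] = []
    for i in range(spec.n_experimental):
        aid = f"exp{i + 1:02d}"
        for limb, state in (("right", "PTS"), ("left", "VHT")):
            params = _perturb(templates[state], rng,
                              spec.csa0_rel_sd, spec.c_rel_sd)
            limbs.append(CohortLimb(aid, limb, state, params))
    for i in range(spec.n_control):
        aid = f"ctl{i + 1:02d}"
        for limb in ("right", "left"):
            params = _perturb(templates["Control"], rng,
                              spec.csa0_rel_sd, spec.c_rel_sd)
            limbs.append(CohortLimb(aid, limb, "Control", params))
    return limbs
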