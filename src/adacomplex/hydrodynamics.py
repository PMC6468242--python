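"""Native-mass estimation from gel filtration and density centrifugation.

A size-exclusion column is calibrated against globular marker proteins
of known Stokes radius; the complex's Stokes radius Rs follows from its
elution volume.  Its sedimentation coefficient s comes from a linear fit
of marker s values against gradient fraction number.  Rs and s combine
into the native molecular mass by the Svedberg relation

    M = 6 pi eta N_A Rs s / (1 - vbar rho)

with eta the solvent viscosity (poise), rho its density (g/cm^3), vbar
the partial specific volume (mL/g), Rs in cm and s in seconds.  Default
solvent constants are water at 20 degC (eta = 0.01002 poise, rho =
0.9982 g/cm^3) and vbar = 0.73 mL/g, typical for globular protein
complexes; all are overridable.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

AVOGADRO = 6.02214e23  # 1/mol
DEFAULT_VISCOSITY = 0.01002  # poise, water at 20 degC
DEFAULT_DENSITY = 0.9982  # g/cm^3, water at 20 degC
DEFAULT_VBAR = 0.73  # mL/g
FRACTION_VOLUME_ML = 0.5  # gel filtration collects 500 uL fractions


class CalibrationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class MarkerPoint:
    """A gel-filtration marker: known Stokes radius and observed elution."""

    name: str
    stokes_radius: float  # nm
    elution_volume: float  # ml

    def __post_init__(self) -> None:
        if self.stokes_radius <= 0:
            raise ValueError(f"{self.name}: Stokes radius must be positive")


@dataclasses.dataclass
class ColumnCalibration:
    """Fitted elution-volume -> Stokes-radius mapping for one column."""

    markers: list[MarkerPoint]
    void_volume: float  # ml
    total_volume: float | None  # ml
    method: str  # "linear" or "porath"
    coefficients: tuple[float, float]  # (slope, intercept) in transform space
    residuals: np.ndarray  # per-marker Rs residuals, nm

    def predict(self, ve: float) -> float:
        slope, intercept = self.coefficients
        if self.method == "linear":
            return slope * ve + intercept
        if self.method == "porath":
            k = kav(ve, self.void_volume, self.total_volume)
            return slope * math.sqrt(-math.log(k)) + intercept
        raise ValueError(f"unknown calibration method {self.method!r}")

    @property
    def elution_range(self) -> tuple[float, float]:
        ves = [m.elution_volume for m in self.markers]
        return min(ves), max(ves)


@dataclasses.dataclass
class SvedbergInput:
    """Hydrodynamic inputs to the Svedberg mass calculation."""

    stokes_radius: float  # nm
    sedimentation: float  # Svedberg units (1 S = 1e-13 s)
    vbar: float = DEFAULT_VBAR  # mL/g
    density: float = DEFAULT_DENSITY  # g/cm^3
    viscosity: float = DEFAULT_VISCOSITY  # poise

    def __post_init__(self) -> None:
        for field in ("stokes_radius", "sedimentation", "vbar", "density", "viscosity"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if self.vbar * self.density >= 1:
            raise ValueError(
                "vbar * rho >= 1: the particle would float (buoyancy factor <= 0)"
            )


@dataclasses.dataclass
class MassEstimate:
    mass: float  # kDa
    uncertainty: float | None = None  # kDa, first-order propagation


def fraction_to_volume(fraction: float, fraction_volume: float = FRACTION_VOLUME_ML) -> float:
    """Elution volume (ml) at the midpoint of a collected fraction."""
    return (fraction - 0.5) * fraction_volume


def kav(ve: float, v0: float, vt: float) -> float:
    """Size-exclusion partition coefficient (Ve - V0)/(Vt - V0)."""
    if vt <= v0:
        raise ValueError("total volume must exceed void volume")
    if ve <= v0:
        raise CalibrationError(
            f"elution volume {ve} ml is at or before the void volume {v0} ml"
        )
    return (ve - v0) / (vt - v0)


def calibrate_stokes(
    markers: Sequence[MarkerPoint],
    void_volume: float,
    total_volume: float | None = None,
    method: str = "linear",
) -> ColumnCalibration:
    """Fit Stokes radius as a function of elution volume.

    ``linear`` fits a least-squares line of Rs against Ve; ``porath``
    (requires the total column volume) fits Rs against sqrt(-ln Kav),
    the classical gel-filtration linearisation.  A non-monotone marker
    table (larger Rs not eluting earlier) triggers a warning.
    """
    if len(markers) < 2:
        raise CalibrationError("need at least two markers")
    ves = np.array([m.elution_volume for m in markers])
    rs = np.array([m.stokes_radius for m in markers])
    if len(np.unique(ves)) < 2:
        raise CalibrationError("markers must have distinct elution volumes")
    order = np.argsort(ves)
    if not np.all(np.diff(rs[order]) <= 0):
        warnings.warn(
            "marker table is not monotone (larger Rs should elute earlier)",
            stacklevel=2,
        )
    if method == "linear":
        x = ves
    elif method == "porath":
        if total_volume is None:
            raise CalibrationError("porath calibration requires the total volume")
        x = np.array(
            [math.sqrt(-math.log(kav(v, void_volume, total_volume))) for v in ves]
        )
    else:
        raise ValueError(f"unknown calibration method {method!r}")
    slope, intercept = np.polyfit(x, rs, 1)
    fitted = slope * x + intercept
    return ColumnCalibration(
        markers=list(markers),
        void_volume=void_volume,
        total_volume=total_volume,
        method=method,
        coefficients=(float(slope), float(intercept)),
        residuals=rs - fitted,
    )


def stokes_radius(ve: float, calibration: ColumnCalibration) -> float:
    """Stokes radius (nm) at an elution volume; warns on extrapolation."""
    lo, hi = calibration.elution_range
    if not lo <= ve <= hi:
        warnings.warn(
            f"elution volume {ve} ml is outside the calibrated range "
            f"[{lo}, {hi}] ml; extrapolating",
            stacklevel=2,
        )
    return calibration.predict(ve)


def sedimentation_from_gradient(
    peak_fraction: float, markers: Sequence[tuple[float, float]]
) -> float:
    """Sedimentation coefficient (S) at a gradient peak fraction.

    Fits a least-squares line of marker s values against fraction number
    and evaluates it at the complex's peak fraction.
    """
    if len(markers) < 2:
        raise CalibrationError("need at least two gradient markers")
    fr = np.array([m[0] for m in markers], dtype=float)
    s = np.array([m[1] for m in markers], dtype=float)
    slope, intercept = np.polyfit(fr, s, 1)
    return float(slope * peak_fraction + intercept)


def svedberg_mass(
    inp: SvedbergInput,
    uncertainties: Mapping[str, float] | None = None,
) -> MassEstimate:
    """Native molecular mass (kDa) from Stokes radius and sedimentation.

    ``uncertainties`` maps SvedbergInput field names to 1-sigma input
    uncertainties (same units as the field); the returned uncertainty is
    their first-order (delta-method) propagation.
    """
    rs_cm = inp.stokes_radius * 1e-7
    s_sec = inp.sedimentation * 1e-13
    buoyancy = 1.0 - inp.vbar * inp.density
    grams_per_mol = 6 * math.pi * inp.viscosity * AVOGADRO * rs_cm * s_sec / buoyancy
    mass_kda = grams_per_mol / 1000.0
    sigma = None
    if uncertainties:
        # relative partial derivatives of M wrt each input
        rel = {
            "stokes_radius": 1.0 / inp.stokes_radius,
            "sedimentation": 1.0 / inp.sedimentation,
            "viscosity": 1.0 / inp.viscosity,
            "vbar": inp.density / buoyancy,
            "density": inp.vbar / buoyancy,
        }
        var = 0.0
        for field, u in uncertainties.items():
            if field not in rel:
                raise KeyError(f"unknown input field {field!r}")
            var += (mass_kda * rel[field] * u) ** 2
        sigma = math.sqrt(var)
    return MassEstimate(mass=mass_kda, uncertainty=sigma)


# ---------------------------------------------------------------------------
# I/O


def read_marker_table(path: str | Path) -> list[MarkerPoint]:
    """Read a marker TSV: name, stokes_radius_nm, elution_ml."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "stokes_radius_nm", "elution_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    return [
        MarkerPoint(r.name, float(r.stokes_radius_nm), float(r.elution_ml))
        for r in df.itertuples(index=False)
    ]


def read_gradient_table(path: str | Path) -> list[tuple[float, float]]:
    """Read a gradient TSV: fraction, s (Svedberg units)."""
    df = pd.read_csv(path, sep="\t")
    required = {"fraction", "s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gradient table missing columns: {sorted(missing)}")
    return [(float(r.fraction), float(r.s)) for r in df.itertuples(index=False)]
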