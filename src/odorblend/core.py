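"""Core domain types and odor-activity-value arithmetic.

The quantities shared by every other module live here: the odorant with its
odor detection threshold, the odor activity value (OAV) — concentration
divided by threshold, numerically the dilution-to-threshold ratio — and its
natural logarithm, the OIRS odor-intensity scale conventions, and the ideal-gas
conversion between mass concentration (mg/m³) and volume mixing ratio (ppb).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "SCALE_MIN",
    "SCALE_MAX",
    "HALF_STEP",
    "GAS_CONSTANT",
    "STANDARD_TEMPERATURE_C",
    "STANDARD_PRESSURE_KPA",
    "AboveDesignRangeWarning",
    "InvalidInputError",
    "UnsupportedConversionError",
    "Odorant",
    "OirsValue",
    "ComponentExposure",
    "compute_oav",
    "compute_ln_oav",
    "molar_volume",
    "mgm3_to_ppb",
    "ppb_to_mgm3",
    "oi_level",
]

#: OIRS scale bounds (1-butanol references, level 1 = 12 ppm … level 8 = 1550 ppm).
SCALE_MIN = 1.0
SCALE_MAX = 8.0
#: Assessors may rate at half-steps between integer scale levels.
HALF_STEP = 0.5

#: Molar gas constant, J mol⁻¹ K⁻¹ (CODATA 2018).
GAS_CONSTANT = 8.314462618
#: Reference state for the mg/m³ ↔ ppb conversion; reproduces the packaged
#: threshold table's paired values (molar volume ≈ 24.055 L/mol).
STANDARD_TEMPERATURE_C = 20.0
STANDARD_PRESSURE_KPA = 101.325

#: Samples are designed below OI 7.0; higher measured values are still
#: classified but flagged.
DESIGN_OI_CEILING = 7.0


class InvalidInputError(ValueError):
    """A numeric input violated a domain precondition; names the field."""


class UnsupportedConversionError(ValueError):
    """A unit conversion was requested without the data it needs."""


class AboveDesignRangeWarning(UserWarning):
    """Measured OI above the 7.0 design ceiling; classified as 'high' anyway."""


@dataclass(frozen=True)
class Odorant:
    """A chemical species with an odor detection threshold.

    Parameters
    ----------
    name:
        Display name or abbreviation (e.g. ``"PA"`` for propionaldehyde).
    threshold:
        Odor detection threshold in mg/m³; the reference all OAVs are
        computed against. Must be strictly positive.
    cas:
        CAS registry number, optional.
    molecular_weight:
        g/mol; only required for the mg/m³ ↔ ppb conversion.
    """

    name: str
    threshold: float
    cas: Optional[str] = None
    molecular_weight: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.threshold > 0):
            raise InvalidInputError(
                f"threshold must be > 0 (odorant {self.name!r}: {self.threshold})"
            )
        if self.molecular_weight is not None and not (self.molecular_weight > 0):
            raise InvalidInputError(
                f"molecular_weight must be > 0 (odorant {self.name!r}: "
                f"{self.molecular_weight})"
            )

    def threshold_ppb(
        self,
        temperature_c: float = STANDARD_TEMPERATURE_C,
        pressure_kpa: float = STANDARD_PRESSURE_KPA,
    ) -> float:
        """Threshold expressed as a volume mixing ratio (ppb)."""
        if self.molecular_weight is None:
            raise UnsupportedConversionError(
                f"odorant {self.name!r} has no molecular weight; cannot convert"
            )
        return mgm3_to_ppb(self.threshold, self.molecular_weight, temperature_c, pressure_kpa)


class OirsValue(float):
    """An odor intensity on the OIRS scale (dimensionless, 1–8).

    Raw assessor ratings (``raw=True``) must sit on the half-step grid
    {1.0, 1.5, …, 8.0}; panel means may be any real number in [1, 8].
    """

    def __new__(cls, value: float, *, raw: bool = False) -> "OirsValue":
        v = float(value)
        if not (SCALE_MIN <= v <= SCALE_MAX):
            raise InvalidInputError(f"OIRS value {v} outside [{SCALE_MIN}, {SCALE_MAX}]")
        if raw:
            steps = (v - SCALE_MIN) / HALF_STEP
            if abs(steps - round(steps)) > 1e-9:
                raise InvalidInputError(f"raw OIRS rating {v} not on the half-step grid")
        return super().__new__(cls, v)


@dataclass(frozen=True)
class ComponentExposure:
    """One odorant at one airborne concentration, with its derived OAV.

    ``ln_oav`` is the "amount" variable of the mixture model, playing the role
    mole number plays in partial-molar-quantity analysis.
    """

    odorant: Odorant
    concentration: float  # mg/m³

    def __post_init__(self) -> None:
        if not (self.concentration > 0):
            raise InvalidInputError(
                f"concentration must be > 0 (odorant {self.odorant.name!r}: "
                f"{self.concentration})"
            )

    @property
    def oav(self) -> float:
        return self.concentration / self.odorant.threshold

    @property
    def ln_oav(self) -> float:
        return math.log(self.oav)

    @property
    def supra_threshold(self) -> bool:
        """True when the exposure exceeds the odor threshold (lnOAV > 0)."""
        return self.ln_oav > 0

    @classmethod
    def from_ln_oav(cls, odorant: Odorant, ln_oav: float) -> "ComponentExposure":
        """Build the exposure whose lnOAV equals ``ln_oav`` (inverse map)."""
        return cls(odorant, odorant.threshold * math.exp(ln_oav))


def compute_oav(concentration: float, odorant: Odorant) -> float:
    """Odor activity value: concentration divided by the odorant's threshold.

    Both quantities in mg/m³; the ratio is dimensionless. OAV = 1 at the
    threshold, above 1 for perceivable exposures.
    """
    if not (concentration > 0):
        raise InvalidInputError(f"concentration must be > 0, got {concentration}")
    return concentration / odorant.threshold


def compute_ln_oav(concentration: float, odorant: Odorant) -> float:
    """Natural logarithm of the odor activity value (0 exactly at threshold)."""
    return math.log(compute_oav(concentration, odorant))


def molar_volume(
    temperature_c: float = STANDARD_TEMPERATURE_C,
    pressure_kpa: float = STANDARD_PRESSURE_KPA,
) -> float:
    """Ideal-gas molar volume in L/mol at the given state (≈24.055 at defaults)."""
    t_k = temperature_c + 273.15
    if not (t_k > 0):
        raise InvalidInputError(f"absolute temperature must be > 0 (got {temperature_c} °C)")
    if not (pressure_kpa > 0):
        raise InvalidInputError(f"pressure must be > 0 (got {pressure_kpa} kPa)")
    # R in J/(mol K), P in kPa -> R*T/P is directly L/mol
    return GAS_CONSTANT * t_k / pressure_kpa

def mgm3_to_ppb(
    concentration: float,
    molecular_weight: float,
    temperature_c: float = STANDARD_TEMPERATURE_C,
    pressure_kpa: float = STANDARD_PRESSURE_KPA,
) -> float:
    """Convert a mass concentration (mg/m³) to a volume mixing ratio (ppb).

    ppb = (µg/m³ ÷ MW) × molar volume; linear, so 0 maps to 0.
    """
    if molecular_weight is None or not (molecular_weight > 0):
        raise UnsupportedConversionError(
            f"molecular_weight must be a positive number, got {molecular_weight}"
        )
    ug_per_m3 = concentration * 1000.0
    return ug_per_m3 / molecular_weight * molar_volume(temperature_c, pressure_kpa)


def ppb_to_mgm3(
    ppb: float,
    molecular_weight: float,
    temperature_c: float = STANDARD_TEMPERATURE_C,
    pressure_kpa: float = STANDARD_PRESSURE_KPA,
) -> float:
    """Inverse of :func:`mgm3_to_ppb` (exact round-trip)."""
    if molecular_weight is None or not (molecular_weight > 0):
        raise UnsupportedConversionError(
            f"molecular_weight must be a positive number, got {molecular_weight}"
        )
    return ppb * molecular_weight / molar_volume(temperature_c, pressure_kpa) / 1000.0


#: OI-level band edges on the OIRS scale: low [1, 2.5), middle [2.5, 4.5),
#: high [4.5, 7]. Half-open lower-inclusive on the shared edges.
LEVEL_EDGES = (2.5, 4.5)


def oi_level(measured_oi: float) -> str:
    """Classify a measured OI into the low / middle / high design band.

    Values above the 7.0 design ceiling are still 'high' but raise an
    :class:`AboveDesignRangeWarning`.
    """
    v = float(measured_oi)
    if not (SCALE_MIN <= v <= SCALE_MAX):
        raise InvalidInputError(f"measured OI {v} outside [{SCALE_MIN}, {SCALE_MAX}]")
    if v > DESIGN_OI_CEILING:
        warnings.warn(
            f"measured OI {v} above the {DESIGN_OI_CEILING} design ceiling",
            AboveDesignRangeWarning,
            stacklevel=2,
        )
    if v < LEVEL_EDGES[0]:
        return "low"
    if v < LEVEL_EDGES[1]:
        return "middle"
    return "high"
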