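"""Enzymology and protein arithmetic for xylanase characterization.

Covers the reducing-sugar (DNS) end-point assay: a linear standard curve
maps absorbance to mM reducing sugar, which converts to volumetric activity
in U mL^-1 (1 U = 1 umol reducing sugar released per minute).  Also provides
the growth-call rule for liquid cultures (OD600 >= 0.2, inclusive) and
protein length / average molecular mass calculators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "AssayConfig",
    "StandardCurve",
    "GrowthRecord",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "fit_standard_curve",
    "reducing_sugar_mM",
    "volumetric_activity",
    "classify_growth",
    "protein_length",
    "protein_average_mass",
]


@dataclass(frozen=True)
class AssayConfig:
    """Geometry and conditions of the microplate xylanase end-point assay.

    Defaults: 175 uL substrate suspension + 25 uL sample in a 200 uL
    reaction, 30 min at 30 C.
    """

    substrate_volume_uL: float = 175.0
    sample_volume_uL: float = 25.0
    incubation_time_min: float = 30.0
    temperature_C: float = 30.0

    def __post_init__(self) -> None:
        if min(self.substrate_volume_uL, self.sample_volume_uL) <= 0:
            raise ValueError("volumes must be positive")
        if self.incubation_time_min <= 0:
            raise ValueError("incubation time must be positive")

    @property
    def total_volume_uL(self) -> float:
        return self.substrate_volume_uL + self.sample_volume_uL

    @property
    def total_volume_L(self) -> float:
        return self.total_volume_uL * 1e-6

    @property
    def sample_volume_L(self) -> float:
        return self.sample_volume_uL * 1e-6


@dataclass(frozen=True)
class StandardCurve:
    """Linear DNS calibration: absorbance = slope * conc_mM + intercept."""

    slope: float
    intercept: float
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be positive")


@dataclass(frozen=True)
class GrowthRecord:
    species_id: str
    od600: float
    growth_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.od600 < 0:
            raise ValueError(f"{self.species_id}: OD600 cannot be negative")
        if self.growth_threshold <= 0:
            raise ValueError("growth threshold must be positive")


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Ordinary least-squares line through (concentration mM, absorbance)."""
    if len(points) < 2:
        raise ValueError("need at least 2 calibration points")
    conc = [p[0] for p in points]
    absb = [p[1] for p in points]
    if len(set(conc)) < 2:
        raise ValueError("calibration needs at least 2 distinct concentrations")
    fit = stats.linregress(conc, absb)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def reducing_sugar_mM(
    absorbance: float, curve: StandardCurve, blank_absorbance: float = 0.0
) -> float:
    """Invert the standard curve; negative concentrations floor to 0."""
    conc = (absorbance - blank_absorbance - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"absorbance {absorbance} below blank/intercept; clamping to 0 mM",
            stacklevel=2,
        )
        return 0.0
    return conc


def volumetric_activity(
    conc_mM: float,
    total_volume_L: float,
    time_min: float,
    sample_volume_L: float,
) -> float:
    """Volumetric activity in U mL^-1 from released reducing sugar.

    conc_mM * total_volume_L * 1000 is the umol of reducing sugar released
    in the reaction; dividing by time (min) gives Units, and dividing by
    sample volume (in mL, i.e. sample_volume_L * 1000) gives U per mL of
    sample.  The two factors of 1000 cancel:

        U/mL = conc_mM * total_volume_L / time_min / sample_volume_L
    """
    if total_volume_L <= 0 or sample_volume_L <= 0:
        raise ValueError("volumes must be positive")
    if time_min <= 0:
        raise ValueError("assay time must be positive")
    if conc_mM < 0:
        raise ValueError("concentration cannot be negative")
    return conc_mM * total_volume_L / time_min / sample_volume_L


def classify_growth(record: GrowthRecord) -> bool:
    """True iff OD600 >= threshold (inclusive at the boundary)."""
    return record.od600 >= record.growth_threshold


# Expasy-style average residue masses (Da): amino-acid monomer minus water.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153  # Da, added once per chain


def protein_length(sequence: str) -> int:
    """Residue count of an amino-acid sequence (canonical + X/B/Z/U)."""
    if not sequence:
        raise ValueError("empty sequence")
    allowed = set(AVERAGE_RESIDUE_MASS) | set("XBZU")
    for i, c in enumerate(sequence):
        if c not in allowed:
            raise ValueError(f"invalid residue {c!r} at position {i + 1}")
    return len(sequence)


def protein_average_mass(sequence: str) -> float:
    """Average molecular mass (Da): sum of residue masses plus one water.

    Requires canonical residues only — the mass of X/B/Z/U is undefined.
    """
    if not sequence:
        raise ValueError("empty sequence")
    mass = WATER_MASS
    for i, c in enumerate(sequence):
        try:
            mass += AVERAGE_RESIDUE_MASS[c]
        except KeyError:
            raise ValueError(
                f"residue {c!r} at position {i + 1} has no defined average mass"
            ) from None
    return mass
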