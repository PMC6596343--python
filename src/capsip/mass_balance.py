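"""Isotope and redox bookkeeping for ¹³C-substrate microcosms.

Covers the arithmetic from raw GC-MS ion currents to recovery percentages:

* mass-45/44 peak-area processing with indoor-air background correction and
  conversion of the 45/44 ratio to a ¹³C atom fraction,
* chitin stoichiometry (the GlcNAc residue C₈H₁₃NO₅: 8 carbons, 1 nitrogen,
  degree of reduction 32),
* carbon recovery (cumulative ¹³CO₂ over supplied ¹³C) and electron
  recovery (electron equivalents in fermentation products and Fe(II) over
  electrons in degraded substrate).

The degree of reduction of a CHON compound is ``4·C + H − 2·O − 3·N``
available electron equivalents per mole — zero for CO₂, 8 for acetate or
methane, 14 for propionate, 20 for (iso)butyrate, 2 for H₂. Fe(III)→Fe(II)
counts one electron per mole. The convention is charge-state independent at
this precision, so neutral acid formulas are used for the fermentation
products.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ChitinStoichiometry",
    "IonRatioMeasurement",
    "ProductInventory",
    "degree_of_reduction",
    "parse_formula",
    "corrected_ion_ratio",
    "atom_fraction_13c",
    "ratio_from_atom_fraction",
    "chitin_carbon_mmol",
    "max_ammonium_mM",
    "carbon_recovery_percent",
    "electron_recovery_percent",
    "mmol_to_mM",
    "PRODUCT_FORMULAS",
    "PRODUCT_ELECTRONS",
    "PRODUCT_CARBONS",
    "DEFAULT_SLURRY_VOLUME_L",
]

_ELEMENT_WEIGHTS = {"C": 4, "H": 1, "O": -2, "N": -3}
_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

#: Slurry volume used for mmol ↔ mM conversions (110 ml slurries).
DEFAULT_SLURRY_VOLUME_L = 0.110


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a simple molecular formula like ``C8H13NO5`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def degree_of_reduction(formula: str | Mapping[str, int]) -> int:
    """Available electron equivalents per mole of a CHON compound.

    ``4·C + 1·H − 2·O − 3·N``. Elements other than C, H, O, N are rejected
    (extension point for S if ever needed).
    """
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    unsupported = sorted(set(counts) - set(_ELEMENT_WEIGHTS))
    if unsupported:
        raise ValueError(f"unsupported element(s) {unsupported} in formula {counts}")
    if any(n < 0 for n in counts.values()):
        raise ValueError(f"negative element count in {counts}")
    return sum(_ELEMENT_WEIGHTS[el] * n for el, n in counts.items())


@dataclass(frozen=True)
class ChitinStoichiometry:
    """Per-residue stoichiometry of the chitin monomer.

    Defaults describe the N-acetylglucosamine (GlcNAc) residue C₈H₁₃NO₅,
    residue mass 203.19 g mol⁻¹: 8 carbons, 1 nitrogen, degree of
    reduction 32 electron equivalents.
    """

    residue_formula: Mapping[str, int] = field(
        default_factory=lambda: {"C": 8, "H": 13, "N": 1, "O": 5}
    )
    residue_mass: float = 203.19

    def __post_init__(self) -> None:
        if self.residue_mass <= 0:
            raise ValueError("residue_mass must be positive")
        # validates CHON-only composition as a side effect
        degree_of_reduction(self.residue_formula)
        if self.carbons_per_residue < 1:
            raise ValueError("residue must contain carbon")

    @property
    def carbons_per_residue(self) -> int:
        return int(dict(self.residue_formula).get("C", 0))

    @property
    def nitrogens_per_residue(self) -> int:
        return int(dict(self.residue_formula).get("N", 0))

    @property
    def electrons_per_residue(self) -> int:
        return degree_of_reduction(self.residue_formula)


@dataclass(frozen=True)
class IonRatioMeasurement:
    """GC-MS peak areas for m/z 44 and 45 with indoor-air backgrounds."""

    area_44: float
    area_45: float
    background_44: float = 0.0
    background_45: float = 0.0
    replicate_count: int = 5

    def __post_init__(self) -> None:
        for name in ("area_44", "area_45", "background_44", "background_45"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


def corrected_ion_ratio(m: IonRatioMeasurement) -> float:
    """Background-corrected 45/44 ion ratio.

    Backgrounds are subtracted before ratioing. A non-positive corrected
    mass-44 area is an error; a negative corrected mass-45 area is clamped
    to 0 with a warning (background slightly exceeding signal).
    """
    c44 = m.area_44 - m.background_44
    c45 = m.area_45 - m.background_45
    if c44 <= 0:
        raise ValueError(
            f"corrected mass-44 area {c44!r} is non-positive "
            f"(area {m.area_44}, background {m.background_44})"
        )
    if c45 < 0:
        warnings.warn(
            f"corrected mass-45 area {c45!r} is negative; clamping to 0",
            stacklevel=2,
        )
        c45 = 0.0
    return c45 / c44


def atom_fraction_13c(ratio_45_44: float) -> float:
    """¹³C atom fraction implied by a 45/44 molar ratio: ``r / (1 + r)``.

    Treats the 45/44 ratio as the ¹³CO₂/¹²CO₂ molar ratio (the ¹⁷O
    isotopologue contribution to m/z 45 is neglected). Monotone increasing,
    0 at r = 0.
    """
    if ratio_45_44 < 0:
        raise ValueError(f"ratio must be non-negative, got {ratio_45_44!r}")
    return ratio_45_44 / (1.0 + ratio_45_44)


def ratio_from_atom_fraction(atom_fraction: float) -> float:
    """Inverse of :func:`atom_fraction_13c` on [0, 1)."""
    if not 0.0 <= atom_fraction < 1.0:
        raise ValueError(f"atom fraction must be in [0, 1), got {atom_fraction!r}")
    return atom_fraction / (1.0 - atom_fraction)


def chitin_carbon_mmol(mass_g: float, stoich: ChitinStoichiometry | None = None) -> float:
    """Carbon supplied by a chitin mass, in mmol (0.125 g → 4.92 mmol)."""
    if mass_g <= 0:
        raise ValueError(f"chitin mass must be positive, got {mass_g!r}")
    stoich = stoich or ChitinStoichiometry()
    return 1000.0 * mass_g / stoich.residue_mass * stoich.carbons_per_residue


def max_ammonium_mM(carbon_mM: float, stoich: ChitinStoichiometry | None = None) -> float:
    """Maximum ammonium release from complete chitin deamination.

    One nitrogen per residue: ``carbon_mM × N / C`` (44 mM carbon → 5.5 mM,
    i.e. "about 6 mM").
    """
    if carbon_mM < 0:
        raise ValueError("carbon concentration must be non-negative")
    stoich = stoich or ChitinStoichiometry()
    return carbon_mM * stoich.nitrogens_per_residue / stoich.carbons_per_residue


def carbon_recovery_percent(co2_13_mmol: float, supplied_13c_mmol: float) -> float:
    """Percent of supplied ¹³C recovered (e.g. as cumulative ¹³CO₂)."""
    if supplied_13c_mmol <= 0:
        raise ValueError(f"supplied carbon must be positive, got {supplied_13c_mmol!r}")
    if co2_13_mmol < 0:
        raise ValueError("recovered carbon must be non-negative")
    return 100.0 * co2_13_mmol / supplied_13c_mmol


def mmol_to_mM(amount_mmol: float, volume_l: float = DEFAULT_SLURRY_VOLUME_L) -> float:
    """Convert an amount (mmol) to a concentration (mM) in the slurry volume."""
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    return amount_mmol / volume_l


#: Neutral formulas of tracked products ("fe2" is the Fe(III)→Fe(II) couple).
PRODUCT_FORMULAS: dict[str, str] = {
    "co2": "CO2",
    "acetate": "C2H4O2",
    "propionate": "C3H6O2",
    "butyrate": "C4H8O2",
    "isobutyrate": "C4H8O2",
    "h2": "H2",
    "ch4": "CH4",
}

PRODUCT_ELECTRONS: dict[str, int] = {
    name: degree_of_reduction(f) for name, f in PRODUCT_FORMULAS.items()
}
PRODUCT_ELECTRONS["fe2"] = 1  # one electron per mole Fe(III) reduced

PRODUCT_CARBONS: dict[str, int] = {
    name: parse_formula(f).get("C", 0) for name, f in PRODUCT_FORMULAS.items()
}
PRODUCT_CARBONS["fe2"] = 0


@dataclass(frozen=True)
class ProductInventory:
    """Cumulative chitin-derived product amounts (mmol) at one sampling day."""

    day: float
    co2: float = 0.0
    acetate: float = 0.0
    propionate: float = 0.0
    butyrate: float = 0.0
    isobutyrate: float = 0.0
    h2: float = 0.0
    ch4: float = 0.0
    fe2: float = 0.0

    def __post_init__(self) -> None:
        for name in PRODUCT_ELECTRONS:
            if getattr(self, name) < 0:
                raise ValueError(f"negative product amount for {name}")

    def carbon_mmol(self) -> float:
        """Total product carbon (mmol C)."""
        return sum(getattr(self, n) * c for n, c in PRODUCT_CARBONS.items())

    def electron_mmol(self) -> float:
        """Total product electron equivalents (mmol e⁻)."""
        return sum(getattr(self, n) * e for n, e in PRODUCT_ELECTRONS.items())


def electron_recovery_percent(
    products: ProductInventory,
    degraded_chitin_residues_mmol: float,
    stoich: ChitinStoichiometry | None = None,
) -> float:
    """Percent of substrate electrons recovered in reduced products.

    The numerator weighs each product by its degree of reduction (acetate 8,
    propionate 14, butyrate/isobutyrate 20, H₂ 2, CH₄ 8; CO₂ contributes 0)
    plus one electron per mmol Fe(II) formed. The denominator is the
    electron content of the degraded residues (32 e⁻ per GlcNAc residue by
    default). Pass the supplied residue amount to assume complete
    degradation; pass a measured degraded amount for a measured basis.
    """
    if degraded_chitin_residues_mmol <= 0:
        raise ValueError("degraded residue amount must be positive")
    stoich = stoich or ChitinStoichiometry()
    denom = degraded_chitin_residues_mmol * stoich.electrons_per_residue
    return 100.0 * products.electron_mmol() / denom
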