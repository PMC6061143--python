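"""Avian metabolic allometry and energy-to-prey-mass conversions.

The estimation chain rests on a small set of ecophysiological constants:
an allometric power law for standard (resting) metabolism, a fixed field
multiplier for free-living energy expenditure, and three constants that
convert an energy demand into fresh mass of arthropod prey (water content
of prey, energy density of dry animal matter, assimilation efficiency).

Units are strict: body masses are carried in kilograms internally
(grams are accepted only at I/O boundaries), standard metabolism is in
kcal day⁻¹ as the allometric equation produces it, and everything
downstream of the field multiplier is in kJ (or J for reported totals).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "EcophysConstants",
    "StandardBird",
    "DEFAULT_CONSTANTS",
    "CACTUS_WREN",
    "SNOW_BUNTING",
    "standard_metabolic_rate",
    "field_metabolic_rate",
    "energy_to_fresh_mass",
    "fresh_mass_to_gross_energy",
    "seasonal_food_requirement",
]

KCAL_TO_KJ = 4.184  # thermochemical calorie


@dataclass(frozen=True)
class EcophysConstants:
    """Conversion and scaling constants of the energetics chain.

    Parameters
    ----------
    allometry_coeff
        Coefficient of the standard-metabolism power law, kcal day⁻¹ kg⁻ᵇ.
    allometry_exp
        Exponent b of the power law (dimensionless).
    field_multiplier
        Ratio of field metabolic rate to standard metabolism.
    water_fraction
        Mass fraction of water in fresh arthropod prey; the dry fraction
        is always derived as ``1 - water_fraction`` so the two cannot
        drift apart.
    energy_density_dry
        Energy density of dry animal matter, kJ g⁻¹ dry mass.
    assimilation_efficiency
        Fraction of ingested food energy actually absorbed.
    kcal_to_kJ
        Unit conversion applied once, immediately after the allometric
        equation (which is calibrated in kcal).
    """

    allometry_coeff: float = 129.0
    allometry_exp: float = 0.724
    field_multiplier: float = 2.5
    water_fraction: float = 0.70
    energy_density_dry: float = 22.5
    assimilation_efficiency: float = 0.75
    kcal_to_kJ: float = KCAL_TO_KJ

    def __post_init__(self) -> None:
        for name in (
            "allometry_coeff",
            "allometry_exp",
            "field_multiplier",
            "energy_density_dry",
            "kcal_to_kJ",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("water_fraction", "assimilation_efficiency"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    @property
    def dry_fraction(self) -> float:
        """Dry-mass fraction of fresh prey, ``1 - water_fraction``."""
        return 1.0 - self.water_fraction

    @property
    def kJ_per_g_fresh(self) -> float:
        """Assimilable energy per g of fresh prey.

        With the defaults: 0.75 × 22.5 × 0.30 = 5.0625 kJ g⁻¹.
        """
        return self.assimilation_efficiency * self.energy_density_dry * self.dry_fraction

    def with_overrides(self, **kwargs: float) -> "EcophysConstants":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **kwargs)


DEFAULT_CONSTANTS = EcophysConstants()


@dataclass(frozen=True)
class StandardBird:
    """A representative bird used to reconstruct community consumption.

    ``body_mass`` is in kg fresh weight and ``season_length`` in days
    of breeding-season residence.
    """

    name: str
    body_mass: float
    season_length: float

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if not 1.0 <= self.season_length <= 366.0:
            raise ValueError("season_length must lie in [1, 366] days")


# Standard birds for the two data-poor biomes: the cactus wren stands in
# for desert communities (breeding season 90-180 d, mean 135), the snow
# bunting for Arctic tundra (≈100 d).
CACTUS_WREN = StandardBird("cactus wren", body_mass=0.0389, season_length=135.0)
SNOW_BUNTING = StandardBird("snow bunting", body_mass=0.0422, season_length=100.0)


def standard_metabolic_rate(
    mass: float, constants: EcophysConstants = DEFAULT_CONSTANTS
) -> float:
    """Standard metabolism M = a·Wᵇ in kcal day⁻¹ for a bird of ``mass`` kg.

    Strictly increasing in mass; raises ``ValueError`` for non-positive mass.
    """
    if mass <= 0:
        raise ValueError("mass must be strictly positive (kg)")
    return constants.allometry_coeff * mass**constants.allometry_exp


def field_metabolic_rate(
    mass: float, constants: EcophysConstants = DEFAULT_CONSTANTS
) -> float:
    """Free-living energy expenditure in kJ day⁻¹.

    Field conditions are modelled as a fixed multiple (default 2.5×) of
    standard metabolism; the kcal→kJ conversion happens here, once.
    """
    return (
        constants.field_multiplier
        * standard_metabolic_rate(mass, constants)
        * constants.kcal_to_kJ
    )


def energy_to_fresh_mass(
    energy: float, constants: EcophysConstants = DEFAULT_CONSTANTS
) -> float:
    """Fresh prey mass (g) a bird must ingest to meet ``energy`` kJ.

    Divides by assimilation efficiency × dry energy density × dry
    fraction (5.0625 kJ g⁻¹ fresh with the defaults): the bird must eat
    more than the assimilable content because a quarter of ingested
    energy is egested.
    """
    if energy < 0:
        raise ValueError("energy must be non-negative (kJ)")
    return energy / constants.kJ_per_g_fresh


def fresh_mass_to_gross_energy(
    mass: float, constants: EcophysConstants = DEFAULT_CONSTANTS
) -> float:
    """Gross energy content (J) of ``mass`` kg of fresh prey.

    This is the energy *contained* in the prey (dry fraction × dry energy
    density), deliberately without the assimilation factor — the global
    energy-consumption figure refers to prey energy removed from the
    ecosystem, not energy assimilated by the birds. Hence the asymmetry
    with :func:`energy_to_fresh_mass`.
    """
    if mass < 0:
        raise ValueError("mass must be non-negative (kg)")
    kJ = mass * 1000.0 * constants.dry_fraction * constants.energy_density_dry
    return kJ * 1000.0


def seasonal_food_requirement(
    bird: StandardBird,
    density: float,
    constants: EcophysConstants = DEFAULT_CONSTANTS,
) -> float:
    """Fresh prey consumed per hectare over one breeding season (kg ha⁻¹).

    density × season_length × daily fresh-mass requirement of the
    standard bird; linear in both density and season length.
    """
    if density < 0:
        raise ValueError("density must be non-negative (birds ha⁻¹)")
    daily_g = energy_to_fresh_mass(field_metabolic_rate(bird.body_mass, constants), constants)
    return density * bird.season_length * daily_g / 1000.0
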