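"""Film geometry and polymer/food contact system.

A migration cell is a thin additive-loaded polymer film in full contact with
a finite, well-stirred volume of food.  The geometry fixes every extensive
quantity the migration model needs: the film volume ``V_P``, the food volume
``V_F``, the initial additive amount ``m_i`` and the surface-to-volume ratio
used to compare against the standardised 6 dm²/L test condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class FilmSpec:
    """Geometry and additive loading of a polymer film specimen.

    Defaults describe an 80 µm polypropylene film cut to 3 cm × 3 cm
    (single-sided contact), density 0.90 g/cm³, loaded with the additive at
    0.1 g/kg (100 µg per g polymer).

    Parameters
    ----------
    thickness_cm:
        Film thickness ``L`` in cm.  For a film exposed on one side with a
        zero-flux back face this is the full diffusion path length.
    contact_area_cm2:
        Single-sided contact area in cm².
    density_g_cm3:
        Polymer density in g/cm³.
    loading_ug_g:
        Additive mass fraction in µg additive per g polymer.
    """

    thickness_cm: float = 8.0e-3
    contact_area_cm2: float = 9.0
    density_g_cm3: float = 0.90
    loading_ug_g: float = 100.0

    def __post_init__(self) -> None:
        _require_positive(
            thickness_cm=self.thickness_cm,
            contact_area_cm2=self.contact_area_cm2,
            density_g_cm3=self.density_g_cm3,
            loading_ug_g=self.loading_ug_g,
        )

    @property
    def volume_cm3(self) -> float:
        """Polymer volume ``V_P`` in cm³."""
        return self.contact_area_cm2 * self.thickness_cm

    @property
    def mass_g(self) -> float:
        """Film mass in g."""
        return self.volume_cm3 * self.density_g_cm3

    @property
    def initial_amount_ng(self) -> float:
        """Initial additive amount ``m_i`` in ng (mass × loading)."""
        return self.mass_g * self.loading_ug_g * 1.0e3


@dataclass(frozen=True)
class ContactSystem:
    """A film in contact with a finite, well-stirred food volume.

    Defaults reproduce the standard migration cell: 15 mL of food per
    9 cm² of single-sided film area, i.e. exactly 6 dm²/L, at 40 °C.
    """

    film: FilmSpec = field(default_factory=FilmSpec)
    food_volume_ml: float = 15.0
    temperature_c: float = 40.0

    def __post_init__(self) -> None:
        _require_positive(food_volume_ml=self.food_volume_ml)

    @property
    def polymer_volume_cm3(self) -> float:
        return self.film.volume_cm3

    @property
    def volume_ratio(self) -> float:
        """``V_F / V_P`` (dimensionless; mL ≡ cm³)."""
        return self.food_volume_ml / self.film.volume_cm3

    @property
    def surface_to_volume_dm2_per_l(self) -> float:
        """Contact area per food volume in dm²/L (standard condition: 6)."""
        return (self.film.contact_area_cm2 / 100.0) / (self.food_volume_ml / 1000.0)


def alpha_from_partition(k_pf: float, system: ContactSystem) -> float:
    """Capacity ratio α of the food phase from the partition coefficient.

    ``α = V_F / (K_P/F · V_P)`` is the equilibrium mass ratio
    ``m_F,∞ / m_P,∞`` for a polymer/food partition coefficient
    ``K_P/F = C_P,∞ / C_F,∞`` and a finite food bath.
    """
    if not k_pf > 0:
        raise ValueError(f"k_pf must be strictly positive, got {k_pf!r}")
    return system.volume_ratio / k_pf


def partition_from_alpha(alpha: float, system: ContactSystem) -> float:
    """Inverse of :func:`alpha_from_partition` (exact round trip)."""
    if not alpha > 0:
        raise ValueError(f"alpha must be strictly positive, got {alpha!r}")
    return system.volume_ratio / alpha


def equilibrium_fraction(alpha: float) -> float:
    """Fraction ``α/(1+α)`` of the total additive in food at equilibrium.

    Follows from the two-compartment mass balance ``m_F/m_P = α`` at
    equilibrium; 0 for an infinitely retentive polymer (α→0) and 1 in the
    infinite-bath limit (α→∞).
    """
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha!r}")
    return alpha / (1.0 + alpha)


@dataclass(frozen=True)
class PartitionEquilibrium:
    """Paired (K_P/F, α) for one contact system.

    The two parameters are redundant given the system volumes:
    ``α · K_P/F = V_F / V_P``.  Constructors enforce the constraint.
    """

    k_pf: float
    alpha: float

    def __post_init__(self) -> None:
        _require_positive(k_pf=self.k_pf, alpha=self.alpha)

    @classmethod
    def from_k_pf(cls, k_pf: float, system: ContactSystem) -> "PartitionEquilibrium":
        return cls(k_pf=k_pf, alpha=alpha_from_partition(k_pf, system))

    @classmethod
    def from_alpha(cls, alpha: float, system: ContactSystem) -> "PartitionEquilibrium":
        return cls(k_pf=partition_from_alpha(alpha, system), alpha=alpha)

    def consistent_with(self, system: ContactSystem, rtol: float = 1e-6) -> bool:
        product = self.alpha * self.k_pf
        return abs(product - system.volume_ratio) <= rtol * system.volume_ratio

    @property
    def food_fraction_at_equilibrium(self) -> float:
        return equilibrium_fraction(self.alpha)
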