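"""Species traits: cell geometry plus growth/stoichiometry parameters.

The default assemblage mirrors a classic five-species freshwater set chosen
for contrasting resource requirements:

====  ==================  ==============  ========================================
code  genus proxy         group           resource character
====  ==================  ==============  ========================================
AN    *Ankistrodesmus*    chlorophyte     fast grower, high nitrogen demand
CL    *Chlamydomonas*     chlorophyte     moderate grower, high nitrogen demand
CY    *Cylindrospermum*   cyanobacterium  nitrogen fixer (never N-limited)
FR    *Fragilaria*        diatom          high phosphorus affinity (low k_p)
GY    *Gymnodinium*       dinoflagellate  slow grower (carbon demand folded
                                          into a low mu_max)
====  ==================  ==============  ========================================

Growth parameters are synthetic: no kinetic constants were measured for the
laboratory experiment this package emulates, so defaults are calibrated
coarsely against its headline outcomes (total yield roughly 56-fold over
inoculum at the lowest phosphorus supply and roughly 1500-fold at the
highest, with the fixer dominating monoculture yield at high phosphorus, the
diatom at the lowest, and the nitrogen-demanding chlorophyte catching up
when N:P supply is 128).  See ``docs/methods.md`` for the calibration
rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .geometry import cell_biovolume

__all__ = [
    "GrowthParams",
    "SpeciesTrait",
    "SPECIES_CODES",
    "default_traits",
    "exchangeable_traits",
]

#: Canonical species order used throughout (alphabetical two-letter codes).
SPECIES_CODES: tuple[str, ...] = ("AN", "CL", "CY", "FR", "GY")


@dataclass(frozen=True)
class GrowthParams:
    """Monod growth and fixed-quota stoichiometry of one species.

    Parameters
    ----------
    mu_max : day⁻¹
        Maximum specific growth rate.
    k_n, k_p : µmol L⁻¹
        Half-saturation constants for dissolved N and P uptake.
    q_n, q_p : µmol per 10⁶ µm³
        Fixed nutrient quotas: dissolved nutrient removed per unit of new
        biovolume.  A fixer's ``q_n`` is nominal — it never draws on the
        dissolved N pool.
    n_fixer
        If True the species fixes dinitrogen: dissolved N neither limits its
        growth nor is consumed by it.
    interaction_bonus
        Multiplier on growth rate applied only in mixture flasks; 1.0 means
        no interspecific facilitation/interference.  Used to inject a known
        "true" complementarity for recovery experiments.
    """

    mu_max: float
    k_n: float
    k_p: float
    q_n: float
    q_p: float
    n_fixer: bool = False
    interaction_bonus: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_max < 0:
            raise ValueError("mu_max must be >= 0")
        if not (self.k_n > 0 and self.k_p > 0):
            raise ValueError("half-saturation constants must be > 0")
        if self.q_n < 0 or self.q_p < 0:
            raise ValueError("quotas must be >= 0")
        if self.interaction_bonus < 0:
            raise ValueError("interaction_bonus must be >= 0")


@dataclass(frozen=True)
class SpeciesTrait:
    """Identity, cell geometry and growth parameters of one alga."""

    name: str
    taxon_group: str
    shape: str
    dimensions: Mapping[str, float]
    growth: GrowthParams
    mean_cell_biovolume: float = field(default=0.0)

    def __post_init__(self) -> None:
        # Default the mean cell volume to the geometric volume of the
        # measured dimensions when not supplied explicitly.
        if self.mean_cell_biovolume == 0.0:
            object.__setattr__(
                self,
                "mean_cell_biovolume",
                cell_biovolume(self.shape, self.dimensions),
            )
        if not self.mean_cell_biovolume > 0:
            raise ValueError("mean_cell_biovolume must be > 0")

    def with_growth(self, **changes) -> "SpeciesTrait":
        """Copy of this trait with some growth parameters replaced."""
        return replace(self, growth=replace(self.growth, **changes))


def default_traits() -> dict[str, SpeciesTrait]:
    """The default five-species assemblage, in canonical code order."""
    traits = {
        "AN": SpeciesTrait(
            name="AN",
            taxon_group="chlorophyte",
            shape="cylinder",
            dimensions={"diameter": 2.5, "height": 25.0},
            growth=GrowthParams(
                mu_max=1.10, k_n=3.0, k_p=0.50, q_n=3.2e-4, q_p=1.55e-5
            ),
        ),
        "CL": SpeciesTrait(
            name="CL",
            taxon_group="chlorophyte",
            shape="sphere",
            dimensions={"diameter": 8.0},
            growth=GrowthParams(
                mu_max=0.95, k_n=2.5, k_p=0.50, q_n=2.8e-4, q_p=1.55e-5
            ),
        ),
        "CY": SpeciesTrait(
            name="CY",
            taxon_group="cyanobacterium",
            shape="cylinder",
            dimensions={"diameter": 3.5, "height": 30.0},
            growth=GrowthParams(
                mu_max=0.80, k_n=2.0, k_p=1.00, q_n=2.2e-4, q_p=1.15e-5,
                n_fixer=True,
            ),
        ),
        "FR": SpeciesTrait(
            name="FR",
            taxon_group="diatom",
            shape="box",
            dimensions={"length": 25.0, "width": 3.0, "height": 4.0},
            growth=GrowthParams(
                mu_max=0.80, k_n=1.5, k_p=0.02, q_n=1.8e-4, q_p=1.00e-5
            ),
        ),
        "GY": SpeciesTrait(
            name="GY",
            taxon_group="dinoflagellate",
            shape="prolate_spheroid",
            dimensions={"diameter": 25.0, "height": 35.0},
            growth=GrowthParams(
                mu_max=0.40, k_n=2.0, k_p=0.35, q_n=2.4e-4, q_p=1.65e-5
            ),
        ),
    }
    assert tuple(traits) == SPECIES_CODES
    return traits


def exchangeable_traits(
    mu_max: float = 0.25,
    k_n: float = 0.5,
    k_p: float = 0.6,
    q_n: float = 1.0e-4,
    q_p: float = 1.45e-5,
    interaction_bonus: float = 1.0,
) -> dict[str, SpeciesTrait]:
    """An assemblage whose five species share identical growth parameters.

    With exchangeable growth (and no interaction bonus) the mixture is, by
    symmetry, exactly the average monoculture, so the true net biodiversity
    effect is zero — the null condition for recovery experiments.  The
    default rates are deliberately slow enough that growth stays below the
    phosphorus ceiling over the 31-day run at every supply level: yields are
    then rate-limited rather than resource-limited, so an
    ``interaction_bonus`` > 1 (a growth-rate advantage expressed only in
    mixture) translates into surplus mixture yield, i.e. a known positive
    complementarity signal of controllable size.

    Cell geometry keeps each species' default values; only growth is
    equalised.
    """
    growth = GrowthParams(
        mu_max=mu_max,
        k_n=k_n,
        k_p=k_p,
        q_n=q_n,
        q_p=q_p,
        n_fixer=False,
        interaction_bonus=interaction_bonus,
    )
    return {code: replace(t, growth=growth) for code, t in default_traits().items()}
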