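"""Cell geometry: converting microscope measurements and counts into biovolume.

Phytoplankton biovolume is estimated by assigning each species a geometric
solid, measuring the linear dimensions of a sample of cells (conventionally
25 per species), averaging the per-cell volumes, and multiplying cell counts
per unit volume by that mean cell volume.  The shape catalogue here covers
the solids needed for a five-species assemblage of chlorophytes, a
cyanobacterium, a diatom and a dinoflagellate:

``sphere``
    V = pi * d**3 / 6, axis ``diameter``.
``prolate_spheroid``
    V = pi * d**2 * h / 6, axes ``diameter`` (equatorial) and ``height``.
``cylinder``
    V = pi * d**2 * h / 4, axes ``diameter`` and ``height``.
``box``
    V = l * w * h, axes ``length``, ``width``, ``height``.
``cone_half_sphere``
    Cone of height h capped by a hemisphere of the same diameter:
    V = pi * d**2 * (h + d) / 12, axes ``diameter`` and ``height``
    (``height`` is the cone height, exclusive of the cap).

All linear dimensions are in micrometres, volumes in cubic micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "SHAPE_AXES",
    "CountRecord",
    "cell_biovolume",
    "mean_cell_biovolume",
    "counts_to_biovolume",
]

#: Required dimension axes, per shape, in the order they are conventionally
#: reported (largest first for elongate shapes).
SHAPE_AXES: dict[str, tuple[str, ...]] = {
    "sphere": ("diameter",),
    "prolate_spheroid": ("diameter", "height"),
    "cylinder": ("diameter", "height"),
    "box": ("length", "width", "height"),
    "cone_half_sphere": ("diameter", "height"),
}


def cell_biovolume(shape: str, dimensions: Mapping[str, float]) -> float:
    """Volume (µm³) of a single cell of the given geometric shape.

    Parameters
    ----------
    shape
        One of the keys of :data:`SHAPE_AXES`.
    dimensions
        Mapping from axis name to its length in µm.  Every axis the shape
        requires must be present and strictly positive; extra axes are
        ignored.

    Raises
    ------
    ValueError
        If the shape is unknown, an axis is missing (the error names it),
        or an axis is not strictly positive.
    """
    try:
        axes = SHAPE_AXES[shape]
    except KeyError:
        raise ValueError(
            f"unknown shape {shape!r}; expected one of {sorted(SHAPE_AXES)}"
        ) from None
    vals: dict[str, float] = {}
    for axis in axes:
        if axis not in dimensions:
            raise ValueError(f"shape {shape!r} requires axis {axis!r}")
        v = float(dimensions[axis])
        if not v > 0:
            raise ValueError(f"axis {axis!r} must be > 0, got {v}")
        vals[axis] = v

    if shape == "sphere":
        d = vals["diameter"]
        return math.pi * d**3 / 6.0
    if shape == "prolate_spheroid":
        return math.pi * vals["diameter"] ** 2 * vals["height"] / 6.0
    if shape == "cylinder":
        return math.pi * vals["diameter"] ** 2 * vals["height"] / 4.0
    if shape == "box":
        return vals["length"] * vals["width"] * vals["height"]
    # cone_half_sphere
    d, h = vals["diameter"], vals["height"]
    return math.pi * d**2 * (h + d) / 12.0


def mean_cell_biovolume(
    measurements: Iterable[Mapping[str, float]], shape: str
) -> float:
    """Arithmetic mean of per-cell volumes over a set of measured cells.

    The mean of volumes (rather than the volume of mean dimensions) is used
    because the quantity summed downstream is total biovolume, for which the
    per-cell mean is the unbiased scale factor.

    Raises ``ValueError`` on an empty measurement list.
    """
    volumes = [cell_biovolume(shape, m) for m in measurements]
    if not volumes:
        raise ValueError("mean_cell_biovolume requires at least one measurement")
    return sum(volumes) / len(volumes)


@dataclass(frozen=True)
class CountRecord:
    """One species' count from a sedimentation-chamber enumeration.

    ``volume_examined_ml`` is the effective chamber volume actually scanned
    (chamber geometry and the number of grids counted are folded into this
    single effective volume).  ``dilution_factor`` >= 1 records any dilution
    applied before settling.
    """

    species: str
    cells_counted: int
    volume_examined_ml: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.cells_counted < 0:
            raise ValueError("cells_counted must be >= 0")
        if not self.volume_examined_ml > 0:
            raise ValueError("volume_examined_ml must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


def counts_to_biovolume(rec: CountRecord, trait) -> float:
    """Biovolume concentration (µm³ mL⁻¹) implied by a count record.

    ``trait`` is anything exposing ``mean_cell_biovolume`` in µm³ (normally a
    :class:`~phytocosm.species.SpeciesTrait`).

    biovolume = cells_counted / volume_examined × dilution × mean cell volume
    """
    return (
        rec.cells_counted
        / rec.volume_examined_ml
        * rec.dilution_factor
        * float(trait.mean_cell_biovolume)
    )
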