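"""Community metrics: evenness, totals, and resource use efficiency.

Metrics operate at two scales.  *Local* metrics treat one flask's species ×
biovolume sample; *metacommunity* metrics first pool the three patches of a
metacommunity (summing per-species biovolume for evenness, averaging patch
totals for resource use efficiency).

Pielou's evenness J' = H'/ln(S) uses Shannon entropy H' = -Σ p_i ln p_i over
the species actually present (p_i > 0), with S the number of present
species.  It is undefined (returned as NaN) when fewer than two species are
present or the total biovolume is zero — monocultures therefore carry no
evenness, and NaN propagates as a missing value downstream.

Resource use efficiency (RUE) is final biovolume per unit of supplied
phosphorus: B / P_sup locally, mean patch biovolume / P_sup regionally.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "as_abundances",
    "shannon_entropy",
    "pielou_evenness",
    "metacommunity_totals",
    "rue_local",
    "rue_metacommunity",
    "ln_transform",
]


def as_abundances(sample: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    """Coerce a species→biovolume mapping or sequence to a float array."""
    if isinstance(sample, Mapping):
        values = np.asarray(list(sample.values()), dtype=float)
    else:
        values = np.asarray(sample, dtype=float)
    if values.ndim != 1:
        raise ValueError("sample must be one-dimensional")
    if (values < 0).any():
        raise ValueError("abundances must be >= 0")
    return values


def shannon_entropy(sample: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon entropy H' (nats) of the relative abundance distribution."""
    values = as_abundances(sample)
    total = values.sum()
    if total <= 0:
        return float("nan")
    p = values[values > 0] / total
    return float(-(p * np.log(p)).sum())


def pielou_evenness(sample: Mapping[str, float] | Sequence[float]) -> float:
    """Pielou's J' = H'/ln(S) over species present; NaN when undefined.

    S counts species with strictly positive abundance.  J' is in [0, 1],
    reaching 1 for a perfectly even community.
    """
    values = as_abundances(sample)
    present = values[values > 0]
    s = present.size
    if s < 2:
        return float("nan")
    return shannon_entropy(values) / math.log(s)


def metacommunity_totals(
    patches: Sequence[Mapping[str, float]],
) -> dict[str, float]:
    """Per-species biovolume summed across the 3 patches of a metacommunity.

    Species sets are unioned (absent species count as zero).
    """
    if len(patches) != 3:
        raise ValueError(f"a metacommunity has exactly 3 patches, got {len(patches)}")
    species: list[str] = []
    for p in patches:
        for s in p:
            if s not in species:
                species.append(s)
    return {s: float(sum(p.get(s, 0.0) for p in patches)) for s in species}


def rue_local(total_biovolume: float, p_sup: float) -> float:
    """Local resource use efficiency: biovolume per unit supplied P."""
    if not p_sup > 0:
        raise ValueError("p_sup must be > 0")
    return total_biovolume / p_sup


def rue_metacommunity(patch_totals: Sequence[float], p_sup: float) -> float:
    """Regional RUE: mean patch biovolume across the 3 patches over P_sup."""
    if len(patch_totals) != 3:
        raise ValueError("rue_metacommunity expects exactly 3 patch totals")
    if not p_sup > 0:
        raise ValueError("p_sup must be > 0")
    return float(np.mean(patch_totals)) / p_sup


def ln_transform(values: Iterable[float] | float) -> np.ndarray | float:
    """Natural log transform; any non-positive value is an explicit error."""
    arr = np.asarray(values, dtype=float)
    if (arr <= 0).any():
        bad = arr[arr <= 0][0] if arr.ndim else float(arr)
        raise ValueError(f"ln_transform requires strictly positive values, got {bad}")
    out = np.log(arr)
    return float(out) if out.ndim == 0 else out
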