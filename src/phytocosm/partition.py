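"""Observed-versus-expected mixture statistics.

The additive partition splits the net biodiversity effect on yield into
complementarity and selection components.  With monoculture yields M_i,
mixture per-species yields Y_O,i and initial (inoculated) shares s_i:

    RY_O,i = Y_O,i / M_i              observed relative yield
    dRY_i  = RY_O,i - s_i             deviation from expected relative yield
    Y_O    = Σ Y_O,i ;  Y_E = Σ s_i M_i
    net    = Y_O - Y_E
    complementarity = N * mean(dRY) * mean(M)
    selection       = N * cov_pop(dRY, M)

where cov_pop divides by N (not N-1) so that the identity
net = complementarity + selection holds exactly.

Two companion deltas compare mixtures to monoculture-based expectations:
delta-RUE (observed mixture RUE minus the share-weighted mean monoculture
RUE, equal to net/P_sup at matching scale) and delta-evenness (Pielou J' of
the observed mixture minus J' of the expected proportions
p_E,i = M_i / Σ M_j).  One-sample t tests assess whether replicate deltas
differ from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .metrics import pielou_evenness

__all__ = [
    "PartitionResult",
    "ExpectedMixture",
    "TTestResult",
    "additive_partition",
    "expected_mixture_yield",
    "delta_rue",
    "delta_evenness",
    "one_sample_t",
    "t_pvalue",
]


@dataclass(frozen=True)
class PartitionResult:
    """Net biodiversity effect and its additive components (µm³ mL⁻¹)."""

    net: float
    complementarity: float
    selection: float
    y_obs: float
    y_exp: float
    n_species: int


@dataclass(frozen=True)
class ExpectedMixture:
    """Expected mixture yield and proportions from monocultures."""

    y_exp: float
    proportions: dict[str, float]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def _aligned(
    mono_yields: Mapping[str, float],
    init_shares: Mapping[str, float] | None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    species = list(mono_yields)
    if not species:
        raise ValueError("empty species set")
    M = np.array([float(mono_yields[s]) for s in species])
    if init_shares is None:
        shares = np.full(len(species), 1.0 / len(species))
    else:
        if set(init_shares) != set(species):
            raise ValueError("init_shares species do not match mono_yields")
        shares = np.array([float(init_shares[s]) for s in species])
    if not math.isclose(shares.sum(), 1.0, rel_tol=1e-9):
        raise ValueError(f"init_shares must sum to 1, got {shares.sum()}")
    return species, M, shares


def additive_partition(
    mix_per_species: Mapping[str, float],
    mono_yields: Mapping[str, float],
    init_shares: Mapping[str, float] | None = None,
) -> PartitionResult:
    """Additive partition of the net biodiversity effect.

    ``init_shares`` defaults to equal shares (the substitutive design).
    Raises ``ValueError`` if any monoculture yield is zero (relative yield
    undefined) or species sets mismatch.
    """
    species, M, shares = _aligned(mono_yields, init_shares)
    if set(mix_per_species) != set(species):
        raise ValueError("mixture species do not match monoculture species")
    if (M <= 0).any():
        raise ValueError("all monoculture yields must be > 0")
    y = np.array([float(mix_per_species[s]) for s in species])
    n = len(species)

    d_ry = y / M - shares
    y_obs = float(y.sum())
    y_exp = float((shares * M).sum())
    complementarity = n * d_ry.mean() * M.mean()
    # Population covariance (divide by N) keeps the identity exact.
    selection = n * float(np.mean((d_ry - d_ry.mean()) * (M - M.mean())))
    return PartitionResult(
        net=y_obs - y_exp,
        complementarity=float(complementarity),
        selection=float(selection),
        y_obs=y_obs,
        y_exp=y_exp,
        n_species=n,
    )


def expected_mixture_yield(
    mono_yields: Mapping[str, float],
    init_shares: Mapping[str, float] | None = None,
) -> ExpectedMixture:
    """Expected mixture yield Y_E = Σ s_i M_i and proportions M_i / Σ M_j."""
    species, M, shares = _aligned(mono_yields, init_shares)
    total = M.sum()
    if total <= 0:
        raise ValueError("total monoculture yield must be > 0")
    return ExpectedMixture(
        y_exp=float((shares * M).sum()),
        proportions={s: float(m / total) for s, m in zip(species, M)},
    )


def delta_rue(
    observed_mix_rue: float,
    mono_rues: Mapping[str, float],
    init_shares: Mapping[str, float] | None = None,
) -> float:
    """Observed mixture RUE minus the share-weighted mean monoculture RUE.

    All inputs must be computed at the same scale and phosphorus supply;
    then delta_rue * P_sup equals the net biodiversity effect on yield.
    """
    _, rues, shares = _aligned(mono_rues, init_shares)
    return float(observed_mix_rue - (shares * rues).sum())


def delta_evenness(
    observed_mix_sample: Mapping[str, float],
    mono_yields: Mapping[str, float],
) -> float:
    """J' of the observed mixture minus J' of the monoculture expectation.

    The expectation assigns each species the proportion of its monoculture
    yield in the summed monoculture yields.  NaN if either evenness is
    undefined.
    """
    expected = expected_mixture_yield(mono_yields)
    j_obs = pielou_evenness(observed_mix_sample)
    j_exp = pielou_evenness(expected.proportions)
    return float(j_obs - j_exp)


def t_pvalue(t: float, df: float) -> float:
    """Two-sided p-value of a t statistic."""
    return float(2.0 * stats.t.sf(abs(t), df))


def one_sample_t(values: Sequence[float]) -> TTestResult:
    """One-sample t test of the mean against zero.

    t = mean / (sd / sqrt(n)) with df = n - 1 and a two-sided p-value.
    Requires n >= 2 and non-zero sample variance.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise ValueError("one_sample_t requires at least 2 non-missing values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("one_sample_t requires non-zero sample variance")
    t = x.mean() / (sd / math.sqrt(n))
    return TTestResult(t=float(t), df=n - 1, p=t_pvalue(t, n - 1))
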