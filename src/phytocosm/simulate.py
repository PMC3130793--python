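"""Synthetic 31-day metacommunity experiment.

Growth follows a discrete daily Monod × Liebig law with fixed nutrient
quotas.  For species *i* with dissolved nitrogen N and phosphorus P
(µmol L⁻¹):

    f_N = N / (k_n + N)          (identically 1 for a nitrogen fixer)
    f_P = P / (k_p + P)
    mu  = mu_max * bonus * min(f_N, f_P)         # bonus only in mixtures
    B   <- B * exp(mu * dt)

New biovolume draws down dissolved nutrients at fixed quotas
(µmol per 10⁶ µm³; biovolume concentrations are µm³ mL⁻¹, so the drawdown
per litre is ``q * dB / 1000``).  If a step's total demand would overdraw a
pool, all species' increments are scaled by the common factor that exactly
exhausts the binding resource (a Liebig bottleneck at community level);
nitrogen fixers place no demand on dissolved N.

Medium exchange removes a volume fraction (diluting every biovolume by
``(V - v)/V``) and replaces it with fresh medium at the patch's supply
concentrations.  Dispersal pools an equal volume from the three patches of
a metacommunity, mixes, and redistributes: every concentration x_i becomes
``((V - v) x_i + v x̄) / V``, conserving totals exactly.

Observation emulates sedimentation-chamber counting: the effective examined
volume is set so the expected total cell count hits a target (400 in
monocultures, 1000 in mixtures), and per-species counts are Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import MIXTURE, ExperimentConfig, ObservationModel
from .design import (
    TABLE_COLUMNS,
    DesignPoint,
    PatchState,
    design_frame,
    enumerate_design,
    initial_patch_state,
)
from .geometry import CountRecord
from .species import SpeciesTrait

__all__ = [
    "SimulationResult",
    "grow_step",
    "media_exchange",
    "dispersal_event",
    "observe_counts",
    "simulate_experiment",
]


# ---------------------------------------------------------------------------
# Vectorised engine (arrays over patches x species)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _TraitArrays:
    species: tuple[str, ...]
    mu_max: np.ndarray
    k_n: np.ndarray
    k_p: np.ndarray
    q_n: np.ndarray
    q_p: np.ndarray
    fixer: np.ndarray  # bool
    bonus: np.ndarray
    cell_volume: np.ndarray

    @classmethod
    def from_traits(cls, traits: Mapping[str, SpeciesTrait]) -> "_TraitArrays":
        sp = tuple(traits)
        g = [traits[s].growth for s in sp]
        return cls(
            species=sp,
            mu_max=np.array([p.mu_max for p in g]),
            k_n=np.array([p.k_n for p in g]),
            k_p=np.array([p.k_p for p in g]),
            q_n=np.array([p.q_n for p in g]),
            q_p=np.array([p.q_p for p in g]),
            fixer=np.array([p.n_fixer for p in g], dtype=bool),
            bonus=np.array([p.interaction_bonus for p in g]),
            cell_volume=np.array([traits[s].mean_cell_biovolume for s in sp]),
        )


def _grow(
    B: np.ndarray,
    N: np.ndarray,
    P: np.ndarray,
    ta: _TraitArrays,
    in_mixture: np.ndarray,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One growth step on (n_patch, n_species) biovolume arrays.

    Returns (B, N, P, consumed_N, consumed_P); consumed_* are per-patch
    drawdowns (µmol L⁻¹) for mass-balance bookkeeping.
    """
    f_n = N[:, None] / (ta.k_n[None, :] + N[:, None])
    f_n = np.where(ta.fixer[None, :], 1.0, f_n)
    f_p = P[:, None] / (ta.k_p[None, :] + P[:, None])
    bonus = np.where(in_mixture[:, None], ta.bonus[None, :], 1.0)
    mu = ta.mu_max[None, :] * bonus * np.minimum(f_n, f_p)
    dB = B * np.expm1(mu * dt)

    demand_n = (dB * np.where(ta.fixer, 0.0, ta.q_n)[None, :]).sum(axis=1) / 1000.0
    demand_p = (dB * ta.q_p[None, :]).sum(axis=1) / 1000.0
    with np.errstate(divide="ignore", invalid="ignore"):
        s_n = np.where(demand_n > N, N / demand_n, 1.0)
        s_p = np.where(demand_p > P, P / demand_p, 1.0)
    scale = np.clip(np.minimum(s_n, s_p), 0.0, 1.0)

    B = B + dB * scale[:, None]
    consumed_n = demand_n * scale
    consumed_p = demand_p * scale
    N = np.maximum(N - consumed_n, 0.0)
    P = np.maximum(P - consumed_p, 0.0)
    return B, N, P, consumed_n, consumed_p


# ---------------------------------------------------------------------------
# PatchState-level operations (thin wrappers over the engine)
# ---------------------------------------------------------------------------

def grow_step(
    patch: PatchState, traits: Mapping[str, SpeciesTrait], dt: float
) -> PatchState:
    """Advance one patch by ``dt`` days of Monod × Liebig growth."""
    if not dt > 0:
        raise ValueError("dt must be > 0")
    ta = _TraitArrays.from_traits(traits)
    B = np.array([[patch.biovolume.get(s, 0.0) for s in ta.species]])
    in_mix = np.array([patch.design.composition == MIXTURE])
    B, N, P, _, _ = _grow(
        B, np.array([patch.n_conc]), np.array([patch.p_conc]), ta, in_mix, dt
    )
    return PatchState(
        design=patch.design,
        volume_ml=patch.volume_ml,
        n_conc=float(N[0]),
        p_conc=float(P[0]),
        biovolume={s: float(b) for s, b in zip(ta.species, B[0])},
    )


def media_exchange(
    patch: PatchState,
    volume_ml: float,
    fresh_n: float | None = None,
    fresh_p: float | None = None,
) -> PatchState:
    """Replace ``volume_ml`` of the patch with fresh medium.

    Defaults for the fresh medium are the patch's supply concentrations
    (``p_sup`` and ``p_sup * np_ratio``).  Biovolume is simply diluted;
    nutrients are mixed: ``((V - v) * current + v * fresh) / V``.
    """
    V = patch.volume_ml
    if not 0 <= volume_ml < V:
        raise ValueError(f"exchange volume must be in [0, {V}) mL, got {volume_ml}")
    if fresh_p is None:
        fresh_p = patch.design.p_sup
    if fresh_n is None:
        fresh_n = patch.design.p_sup * patch.design.np_ratio
    keep = (V - volume_ml) / V
    return PatchState(
        design=patch.design,
        volume_ml=V,
        n_conc=keep * patch.n_conc + (volume_ml / V) * fresh_n,
        p_conc=keep * patch.p_conc + (volume_ml / V) * fresh_p,
        biovolume={s: keep * b for s, b in patch.biovolume.items()},
    )


def dispersal_event(
    patches: Sequence[PatchState], volume_ml: float
) -> list[PatchState]:
    """Pool-and-redistribute dispersal among the 3 patches of a metacommunity.

    Every species concentration and both nutrients follow
    ``x_i <- ((V - v) x_i + v x̄) / V`` with x̄ the mean over patches, which
    conserves the per-species total across the metacommunity exactly.
    """
    if len(patches) != 3:
        raise ValueError(f"a metacommunity has exactly 3 patches, got {len(patches)}")
    volumes = {p.volume_ml for p in patches}
    if len(volumes) != 1:
        raise ValueError("patches must share the same volume")
    V = volumes.pop()
    if not 0 < volume_ml < V:
        raise ValueError(f"dispersal volume must be in (0, {V}) mL")
    w = volume_ml / V
    species = sorted({s for p in patches for s in p.biovolume})
    means = {
        s: sum(p.biovolume.get(s, 0.0) for p in patches) / len(patches)
        for s in species
    }
    mean_n = sum(p.n_conc for p in patches) / len(patches)
    mean_p = sum(p.p_conc for p in patches) / len(patches)
    out = []
    for p in patches:
        out.append(
            PatchState(
                design=p.design,
                volume_ml=V,
                n_conc=(1 - w) * p.n_conc + w * mean_n,
                p_conc=(1 - w) * p.p_conc + w * mean_p,
                biovolume={
                    s: (1 - w) * p.biovolume.get(s, 0.0) + w * means[s]
                    for s in species
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# Observation model
# ---------------------------------------------------------------------------

def observe_counts(
    true_sample: Mapping[str, float],
    traits: Mapping[str, SpeciesTrait],
    model: ObservationModel,
    rng: np.random.Generator,
    mixture: bool = True,
) -> tuple[list[CountRecord], float]:
    """Simulate chamber counting of one sample.

    Returns the per-species count records and the effective examined volume
    (mL).  The volume is chosen so the expected total count equals the
    model's target; counts are independent Poisson draws.  An all-zero
    community yields zero counts at a nominal volume.
    """
    conc = np.array(
        [
            true_sample.get(s, 0.0) / traits[s].mean_cell_biovolume
            for s in traits
        ]
    )  # cells per mL
    total = conc.sum()
    target = model.target_count_mix if mixture else model.target_count_mono
    if total <= 0:
        return (
            [CountRecord(s, 0, 1.0) for s in traits],
            1.0,
        )
    volume = target / total
    if model.enabled:
        counts = rng.poisson(conc * volume)
    else:
        counts = conc * volume  # noise-free expectation (may be fractional)
    records = []
    for s, c in zip(traits, counts):
        records.append(
            CountRecord(
                species=s,
                cells_counted=int(round(c)),
                volume_examined_ml=volume,
            )
        )
    return records, volume


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Outcome of one simulated experiment.

    ``true_table`` holds noise-free final biovolumes; ``observed_table`` the
    biovolumes re-estimated from simulated Poisson counts (identical to the
    true table when the observation model is disabled).  ``nutrients`` holds
    final dissolved N and P per patch.
    """

    design: pd.DataFrame
    true_table: pd.DataFrame
    observed_table: pd.DataFrame
    nutrients: pd.DataFrame
    config: ExperimentConfig
    seed: int

    @property
    def metadata(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config.hash(),
            "n_flasks": int(self.design.shape[0]),
            "n_metacommunities": int(self.design["metacommunity_id"].nunique()),
            "duration_days": self.config.schedule.duration_days,
        }


def simulate_experiment(
    config: ExperimentConfig | None = None,
    traits: Mapping[str, SpeciesTrait] | None = None,
    seed: int | None = None,
) -> SimulationResult:
    """Run the full factorial experiment and return community tables.

    Daily growth steps are punctuated by medium exchange and dispersal on
    their scheduled days (events apply at the end of the day).  Sampling
    happens once, at the end of the final day.  Fully reproducible from the
    seed.
    """
    if config is None:
        config = ExperimentConfig()
    if traits is None:
        traits = dict(config.traits)
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    points = enumerate_design(config)
    ta = _TraitArrays.from_traits(traits)
    n_sp = len(ta.species)
    n_patch = len(points)

    B = np.zeros((n_patch, n_sp))
    N = np.empty(n_patch)
    P = np.empty(n_patch)
    in_mix = np.zeros(n_patch, dtype=bool)
    for i, dp in enumerate(points):
        st = initial_patch_state(
            dp, traits, config.total_inoculum, config.patch_volume_ml
        )
        B[i] = [st.biovolume[s] for s in ta.species]
        N[i], P[i] = st.n_conc, st.p_conc
        in_mix[i] = dp.composition == MIXTURE

    p_sup = np.array([dp.p_sup for dp in points])
    n_sup = np.array([dp.p_sup * dp.np_ratio for dp in points])
    V = config.patch_volume_ml
    exchange = dict(config.schedule.exchange_events)
    dispersal_days = set(config.schedule.dispersal_days)
    # Patches of a metacommunity are consecutive triples by construction.
    assert n_patch % 3 == 0

    for day in range(1, config.schedule.duration_days + 1):
        B, N, P, _, _ = _grow(B, N, P, ta, in_mix, dt=1.0)
        if day in exchange:
            keep = (V - exchange[day]) / V
            frac = exchange[day] / V
            B *= keep
            N = keep * N + frac * n_sup
            P = keep * P + frac * p_sup
        if day in dispersal_days:
            w = config.schedule.dispersal_volume_ml / V
            for arr in (B, N, P):
                grouped = arr.reshape(arr.shape[0] // 3, 3, *arr.shape[1:])
                mean = grouped.mean(axis=1, keepdims=True)
                grouped[:] = (1 - w) * grouped + w * mean

    design = design_frame(points)
    species = list(ta.species)

    def long_table(values: np.ndarray) -> pd.DataFrame:
        rows = design.loc[design.index.repeat(n_sp)].reset_index(drop=True)
        rows["species"] = species * n_patch
        rows["biovolume_um3_per_ml"] = values.ravel()
        return rows[list(TABLE_COLUMNS)]

    true_table = long_table(B)

    # Observation: Poisson counting per flask, converted back to biovolume.
    obs = np.empty_like(B)
    for i, dp in enumerate(points):
        sample = {s: B[i, j] for j, s in enumerate(species)}
        records, volume = observe_counts(
            sample, traits, config.observation, rng, mixture=in_mix[i]
        )
        if config.observation.enabled:
            obs[i] = [
                r.cells_counted / r.volume_examined_ml * traits[r.species].mean_cell_biovolume
                for r in records
            ]
        else:
            obs[i] = B[i]
    observed_table = long_table(obs)

    nutrients = design.copy()
    nutrients["n_conc_umol_per_l"] = N
    nutrients["p_conc_umol_per_l"] = P

    return SimulationResult(
        design=design,
        true_table=true_table,
        observed_table=observed_table,
        nutrients=nutrients,
        config=config,
        seed=seed,
    )
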