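"""Growth, exchange, dispersal and observation mechanics of the simulator."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytocosm import (
    ExperimentConfig,
    ObservationModel,
    dispersal_event,
    enumerate_design,
    grow_step,
    initial_patch_state,
    media_exchange,
    observe_counts,
    simulate_experiment,
)
from phytocosm.design import PatchState
from phytocosm.species import default_traits, exchangeable_traits


def _mix_patch(traits, p_level="V", np_ratio=128.0, total=231_000.0):
    cfg = ExperimentConfig()
    dp = next(
        p
        for p in enumerate_design(cfg)
        if p.composition == "MIX"
        and p.p_sup_level == p_level
        and p.np_ratio == np_ratio
    )
    return initial_patch_state(dp, traits, total)


# ---------------------------------------------------------------------------
# grow_step
# ---------------------------------------------------------------------------

def test_zero_growth_leaves_state_unchanged():
    traits = {
        c: t.with_growth(mu_max=0.0) for c, t in default_traits().items()
    }
    patch = _mix_patch(traits)
    out = grow_step(patch, traits, dt=1.0)
    assert out.biovolume == pytest.approx(patch.biovolume)
    assert out.n_conc == pytest.approx(patch.n_conc)
    assert out.p_conc == pytest.approx(patch.p_conc)


def test_saturated_growth_is_exponential_before_capping():
    """With N, P >> k the one-day increment is exp(mu_max) per species."""
    traits = default_traits()
    cfg = ExperimentConfig()
    dp = next(
        p
        for p in enumerate_design(cfg)
        if p.composition == "AN" and p.p_sup_level == "V" and p.np_ratio == 128
    )
    patch = initial_patch_state(dp, traits, 1000.0)  # small inoculum: no cap
    patch.n_conc = 1e5
    patch.p_conc = 1e5
    out = grow_step(patch, traits, dt=1.0)
    mu = traits["AN"].growth.mu_max * (1e5 / (traits["AN"].growth.k_n + 1e5))
    # at 1e5 µmol/L both Monod factors are ~1 within 1e-5
    assert out.biovolume["AN"] / patch.biovolume["AN"] == pytest.approx(
        math.exp(traits["AN"].growth.mu_max), rel=1e-4
    )


def test_n_fixer_grows_at_zero_nitrogen():
    traits = default_traits()
    patch = _mix_patch(traits)
    patch.n_conc = 0.0
    patch.p_conc = 1e5
    out = grow_step(patch, traits, dt=1.0)
    # fixer at ~mu_max; N-limited non-fixers static
    assert out.biovolume["CY"] / patch.biovolume["CY"] == pytest.approx(
        math.exp(traits["CY"].growth.mu_max), rel=1e-3
    )
    assert out.biovolume["AN"] == pytest.approx(patch.biovolume["AN"])


def test_liebig_cap_exhausts_phosphorus_without_overdraw():
    traits = default_traits()
    patch = _mix_patch(traits, p_level="I", np_ratio=128.0, total=1e8)
    # huge inoculum: the daily demand far exceeds the dissolved P pool
    out = grow_step(patch, traits, dt=1.0)
    assert out.p_conc == pytest.approx(0.0, abs=1e-12)
    # growth happened, but only as much as P allowed
    assert out.total_biovolume() > patch.total_biovolume()
    added = out.total_biovolume() - patch.total_biovolume()
    # implied P use equals the initial pool
    q = np.array([traits[s].growth.q_p for s in traits])
    dB = np.array(
        [out.biovolume[s] - patch.biovolume[s] for s in traits]
    )
    assert (q * dB).sum() / 1000.0 == pytest.approx(patch.p_conc, rel=1e-9)


def test_nutrient_mass_balance_across_steps():
    """Consumed plus remaining nutrients equal the initial pool (no events)."""
    traits = default_traits()
    patch = _mix_patch(traits, p_level="III", np_ratio=16.0)
    n0, p0 = patch.n_conc, patch.p_conc
    state = patch
    consumed_n = consumed_p = 0.0
    for _ in range(10):
        new = grow_step(state, traits, dt=1.0)
        for s in traits:
            db = new.biovolume[s] - state.biovolume[s]
            g = traits[s].growth
            if not g.n_fixer:
                consumed_n += g.q_n * db / 1000.0
            consumed_p += g.q_p * db / 1000.0
        state = new
    assert consumed_n + state.n_conc == pytest.approx(n0, rel=1e-9)
    assert consumed_p + state.p_conc == pytest.approx(p0, rel=1e-9)


# ---------------------------------------------------------------------------
# media_exchange
# ---------------------------------------------------------------------------

def test_media_exchange_dilutes_biovolume():
    patch = _mix_patch(default_traits())
    out = media_exchange(patch, 10.0)
    for s in patch.biovolume:
        assert out.biovolume[s] == pytest.approx(0.8 * patch.biovolume[s])


def test_media_exchange_nutrient_fixed_point_and_identity():
    patch = _mix_patch(default_traits())
    # fresh equals current concentrations -> nutrients unchanged
    out = media_exchange(patch, 10.0, fresh_n=patch.n_conc, fresh_p=patch.p_conc)
    assert out.n_conc == pytest.approx(patch.n_conc)
    assert out.p_conc == pytest.approx(patch.p_conc)
    # zero volume is the identity
    out0 = media_exchange(patch, 0.0)
    assert out0.biovolume == pytest.approx(patch.biovolume)
    with pytest.raises(ValueError):
        media_exchange(patch, 50.0)


# ---------------------------------------------------------------------------
# dispersal_event
# ---------------------------------------------------------------------------

def _three_patches(concs, traits):
    cfg = ExperimentConfig()
    pts = [p for p in enumerate_design(cfg) if p.metacommunity_id == "PV-MIX-r1"]
    patches = []
    for dp, c in zip(pts, concs):
        st_ = initial_patch_state(dp, traits, 231_000.0)
        st_.biovolume = {s: (c if s == "AN" else 0.0) for s in traits}
        patches.append(st_)
    return patches


def test_dispersal_mixes_five_percent():
    traits = default_traits()
    patches = _three_patches([100.0, 0.0, 0.0], traits)
    out = dispersal_event(patches, 2.5)
    got = [p.biovolume["AN"] for p in out]
    assert got == pytest.approx([96.6667, 1.6667, 1.6667], abs=1e-4)


def test_dispersal_identity_on_equal_patches():
    traits = default_traits()
    patches = _three_patches([50.0, 50.0, 50.0], traits)
    out = dispersal_event(patches, 2.5)
    assert [p.biovolume["AN"] for p in out] == pytest.approx([50.0] * 3)


@settings(deadline=None, max_examples=50)
@given(
    concs=st.lists(
        st.floats(min_value=0, max_value=1e9), min_size=3, max_size=3
    ),
    v=st.floats(min_value=0.1, max_value=49.9),
)
def test_dispersal_conserves_totals(concs, v):
    traits = default_traits()
    patches = _three_patches(concs, traits)
    out = dispersal_event(patches, v)
    before = sum(p.biovolume["AN"] for p in patches)
    after = sum(p.biovolume["AN"] for p in out)
    assert after == pytest.approx(before, rel=1e-9, abs=1e-9)


def test_dispersal_requires_exactly_three_patches():
    traits = default_traits()
    patches = _three_patches([1.0, 2.0, 3.0], traits)
    with pytest.raises(ValueError):
        dispersal_event(patches[:2], 2.5)


def test_dispersal_commutes_with_species_relabelling():
    """No hidden dependence on species order."""
    traits = default_traits()
    patches = _three_patches([100.0, 10.0, 1.0], traits)
    # put distinct biovolumes on every species
    for i, p in enumerate(patches):
        p.biovolume = {s: float(j + 1) * (10 ** i) for j, s in enumerate(traits)}
    out = dispersal_event(patches, 2.5)
    relabel = {"AN": "GY", "CL": "FR", "CY": "CY", "FR": "CL", "GY": "AN"}
    swapped = []
    for p in patches:
        q = PatchState(
            design=p.design,
            volume_ml=p.volume_ml,
            n_conc=p.n_conc,
            p_conc=p.p_conc,
            biovolume={relabel[s]: v for s, v in p.biovolume.items()},
        )
        swapped.append(q)
    out_swapped = dispersal_event(swapped, 2.5)
    for a, b in zip(out, out_swapped):
        for s in relabel:
            assert b.biovolume[relabel[s]] == pytest.approx(a.biovolume[s])


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

def test_observe_counts_hits_target_in_expectation():
    traits = default_traits()
    sample = {s: 1e6 for s in traits}
    model = ObservationModel()
    rng = np.random.default_rng(0)
    totals = []
    for _ in range(300):
        recs, vol = observe_counts(sample, traits, model, rng, mixture=True)
        totals.append(sum(r.cells_counted for r in recs))
    mean = np.mean(totals)
    # expected total = 1000; Poisson SE of the mean ~ sqrt(1000/300) ~ 1.8
    assert abs(mean - 1000) < 6


def test_observe_counts_zero_species_and_noise_free():
    traits = default_traits()
    rng = np.random.default_rng(0)
    sample = {s: (0.0 if s == "GY" else 1e6) for s in traits}
    recs, vol = observe_counts(sample, traits, ObservationModel(), rng)
    by = {r.species: r.cells_counted for r in recs}
    assert by["GY"] == 0
    # disabled model returns exact expected proportions
    recs2, vol2 = observe_counts(
        sample, traits, ObservationModel(enabled=False), rng
    )
    est = {
        r.species: r.cells_counted / vol2 * traits[r.species].mean_cell_biovolume
        for r in recs2
    }
    # integer rounding of counts keeps the estimate within half a cell
    for s in traits:
        assert est[s] == pytest.approx(
            sample[s], abs=traits[s].mean_cell_biovolume / vol2
        )


def test_all_zero_community_yields_zero_counts():
    traits = default_traits()
    rng = np.random.default_rng(0)
    recs, _ = observe_counts(
        {s: 0.0 for s in traits}, traits, ObservationModel(), rng
    )
    assert all(r.cells_counted == 0 for r in recs)


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

def test_zero_growth_final_biovolume_is_dilution_product(noisefree_result):
    """All-zero growth: only the four exchanges act, x0.9 x0.9 x0.8 x0.8."""
    traits = {c: t.with_growth(mu_max=0.0) for c, t in default_traits().items()}
    cfg = ExperimentConfig(
        traits=traits, observation=ObservationModel(enabled=False)
    )
    res = simulate_experiment(cfg, seed=0)
    mix = res.true_table[res.true_table["composition"] == "MIX"]
    totals = mix.groupby("patch_id")["biovolume_um3_per_ml"].sum()
    expected = 231_000.0 * 0.9**2 * 0.8**2
    assert np.allclose(totals, expected, rtol=1e-9)


def test_identical_seeds_reproduce_identical_tables():
    a = simulate_experiment(ExperimentConfig(), seed=42)
    b = simulate_experiment(ExperimentConfig(), seed=42)
    pd.testing.assert_frame_equal(a.observed_table, b.observed_table)
    pd.testing.assert_frame_equal(a.true_table, b.true_table)


def test_monoculture_yield_ranking_structure(noisefree_result):
    """Fixer tops high-P monocultures, diatom the lowest-P ones, and the
    N-demanding chlorophyte catches up to the fixer at N:P = 128."""
    t = noisefree_result.true_table
    mono = t[t["composition"] != "MIX"]
    flask = (
        mono.groupby(["p_sup_level", "composition", "np_ratio", "patch_id"])[
            "biovolume_um3_per_ml"
        ]
        .sum()
        .reset_index()
    )
    mc_mean = flask.groupby(["p_sup_level", "composition"])[
        "biovolume_um3_per_ml"
    ].mean()
    # regional yields
    assert mc_mean["V"].idxmax() == "CY"
    assert mc_mean["I"].idxmax() == "FR"
    # chlorophyte catch-up: AN:CY yield ratio rises strongly with N supply
    local = flask[flask["p_sup_level"] == "V"].groupby(
        ["np_ratio", "composition"]
    )["biovolume_um3_per_ml"].mean()
    ratio_low = local[2.0]["AN"] / local[2.0]["CY"]
    ratio_high = local[128.0]["AN"] / local[128.0]["CY"]
    assert ratio_high > 2 * ratio_low
    assert local[128.0]["AN"] > local[128.0]["GY"]


def test_exchangeable_traits_make_mixture_equal_average_monoculture():
    cfg = ExperimentConfig(
        traits=exchangeable_traits(), observation=ObservationModel(enabled=False)
    )
    res = simulate_experiment(cfg, seed=5)
    t = res.true_table
    flask = t.groupby(["p_sup_level", "np_ratio", "composition", "patch_id"])[
        "biovolume_um3_per_ml"
    ].sum().reset_index()
    for (lvl, npr), grp in flask.groupby(["p_sup_level", "np_ratio"]):
        if lvl in ("II", "IV"):
            continue
        mix = grp[grp["composition"] == "MIX"]["biovolume_um3_per_ml"].mean()
        mono = grp[grp["composition"] != "MIX"]["biovolume_um3_per_ml"].mean()
        assert mix == pytest.approx(mono, rel=1e-6)
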