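# Methods

## The experimental system being modelled

The package emulates a factorial microcosm experiment on the
biodiversity–ecosystem-function relationship in freshwater algae.  Five
species with contrasting resource requirements — two nitrogen-demanding
chlorophytes (codes AN, CL), a nitrogen-fixing cyanobacterium (CY), a
diatom with high phosphorus affinity (FR) and a slow-growing dinoflagellate
(GY) — are grown in monoculture and in five-species mixture.  The regional
treatment is total phosphorus supply, P_sup ∈ {0.13, 0.81, 5.02} µmol L⁻¹
(levels I, III, V), with two extra mixture-only levels {0.32, 2.02} (II,
IV).  The local treatment is the molar N:P supply ratio {2, 16, 128}; 16
approximates the Redfield ratio.  A metacommunity is a trio of 50 mL
patches, one per N:P ratio, sharing composition, P level and replicate.
With 3 replicates the design is (6 compositions × 3 P levels + 1 × 2 extra
levels) × 3 N:P × 3 = 180 flasks in 60 metacommunities.

Every flask starts at 231 × 10³ µm³ mL⁻¹ of biovolume (substitutive design;
the mixture splits it evenly, 46 200 µm³ mL⁻¹ per species).  Nitrogen is
always derived as P_sup × N:P, never configured independently.  Over the
31-day run, medium is partially exchanged on days 3 and 6 (5 mL) and days
10 and 17 (10 mL), and on days 13, 20 and 27 a dispersal event removes
2.5 mL from each patch of a metacommunity, pools and mixes the 7.5 mL, and
returns 2.5 mL to each patch (5% of patch volume per event).

## Growth model

No kinetic parameters were measured for the real experiment, so the
simulator uses the simplest mechanism consistent with resource-ratio
competition: discrete daily steps of Monod growth under Liebig's law of the
minimum, with fixed nutrient quotas.

For species *i* with dissolved N, P (µmol L⁻¹):

    f_N = N/(k_n,i + N)   (≡ 1 for the N fixer)
    f_P = P/(k_p,i + P)
    mu_i = mu_max,i · bonus_i · min(f_N, f_P)
    B_i ← B_i · exp(mu_i · dt),   dt = 1 day

New biovolume consumes dissolved nutrients at quotas q_n, q_p (µmol per
10⁶ µm³); with biovolume in µm³ mL⁻¹ the drawdown per litre is
q · ΔB / 1000.  If a step's community-wide demand would overdraw a pool,
all increments are scaled by the common factor that exactly exhausts the
binding resource.  Nitrogen fixers neither experience N limitation nor draw
on the dissolved N pool.  Medium exchange dilutes biovolume by (V−v)/V and
mixes nutrients with fresh medium at the patch's supply concentrations;
dispersal replaces every concentration x_i by ((V−v)x_i + v·x̄)/V, which
conserves metacommunity totals exactly.

The one-day time step matches the integer event days of the schedule;
within-step growth is exponential.  Silicate demand of the diatom and
carbon demand of the dinoflagellate are folded into their mu_max and
half-saturation values rather than adding resource axes, keeping the state
two-dimensional like the analysis.

`interaction_bonus` is a per-species multiplier on growth active only in
mixture flasks (default 1).  It exists to inject a known, controllable
"true" complementarity for parameter-recovery experiments, not to model a
specific biological mechanism.

## Default trait calibration

Defaults were calibrated coarsely, once, against four qualitative/
quantitative targets of the emulated study, and are not meant as literature
values for the named genera:

1. mixture biovolume multiplies the inoculum by roughly 56× at P level I
   and roughly 1500× at level V (the defaults give ≈45× and ≈1600×, within
   the ±30% the calibration aims for);
2. the diatom FR has the highest monoculture yield at the lowest P supply
   (via its low k_p = 0.02 µmol L⁻¹ and slightly low P quota);
3. the N fixer CY has the highest monoculture yield at the highest P
   supply (N never limits it, while the chlorophytes run out of N in the
   N:P = 2 and 16 patches; its high k_p = 1.0 makes it a poor low-P
   competitor);
4. the N-demanding chlorophyte AN catches up to the fixer where N is
   plentiful (N:P = 128).

Phosphorus quotas are of order 1–1.7 × 10⁻⁵ µmol P per 10⁶ µm³ — toward
the P-starved end of empirical algal stoichiometry, as implied by the large
yield-per-P of the emulated experiment — with nitrogen quotas roughly
15–20× higher.  Because final yields are phosphorus-bound at every supply
level, the ratio of yields between levels tracks the supply ratio; the
observed decline of RUE with enrichment is reproduced through the
composition shift from the P-efficient diatom (dominant at low P) to the
higher-quota fixer and chlorophytes (dominant at high P).

What the simulator does *not* reproduce: the real experiment's decline of
mixture evenness with enrichment (the simulated mixtures are most uneven at
low P, where the diatom dominates), interannual/positional variation, and
any allelopathy, light or temperature effects.  Passing tests therefore
show that the analysis machinery recovers known structure from data shaped
like the experiment — not that the simulator is a faithful model of the
real flasks.

## Observation model

Counting emulates sedimentation-chamber enumeration: the effective examined
volume is chosen so the expected total count equals 400 cells for
monocultures and 1000 for mixtures (the counting convention of the emulated
study), and per-species counts are independent Poisson draws.  Counts are
converted back to biovolume with the species' mean cell volume.  Observed
tables therefore carry ~5% (mono) / ~3% (mixture) coefficient-of-variation
noise on totals, more for rare species.  The model can be disabled for
noise-free output.

## Exchangeable traits for recovery experiments

`species.exchangeable_traits()` gives all five species identical growth
parameters.  By symmetry the mixture then equals the average monoculture
exactly, so the true net diversity effect is zero — the null condition.
The shared rates are deliberately slow (mu_max = 0.25 d⁻¹, k_p = 0.6
µmol L⁻¹) so that growth stays below the phosphorus ceiling at every supply
level over 31 days; yields are then rate-limited, which lets an
interaction bonus (a rate advantage) express itself as surplus mixture
yield, i.e. as positive complementarity of controllable size.  With the
default calibrated traits, by contrast, yields are resource-bound and a
rate bonus would be largely invisible in final biovolume.

## Analysis conventions

* **Evenness.**  J′ = H′/ln S with S the number of species *present*
  (p_i > 0), not the number inoculated; J′ is undefined (NaN) for
  monocultures and zero-total samples, and missing values propagate.
  Metacommunity evenness pools per-species biovolume across the three
  patches before computing J′.
* **RUE.**  Local: patch biovolume / P_sup.  Metacommunity: *mean* patch
  biovolume / P_sup (the mean, not the sum, is used; the two differ by a
  constant factor 3 and give identical test statistics).
* **ln transform.**  Biovolume and RUE are ln-transformed before ANOVA;
  non-positive values are an explicit error, never silently offset —
  inocula guarantee positivity in simulated data.
* **Partition.**  Selection uses the population (divide-by-N) covariance so
  net = complementarity + selection holds to machine precision.  Δ_RUE is
  not partitioned into components (species-specific RUE contributions in
  mixture are not quantifiable).  Expected values pair mixture replicate r
  with monoculture replicates r of the same supply cell, giving three
  deltas per cell and df = 2 t tests.  Metacommunity-scale expectations use
  metacommunity-scale monoculture means.
* **ANOVA.**  Only balanced full factorials are accepted; unbalanced input
  raises rather than being reweighted (this also moots the type-I/III
  distinction).  Sums of squares come from marginal/cell means via
  inclusion–exclusion; the implementation is cross-checked against
  statsmodels OLS fits in the test suite.  Local-scale significance divides
  the error df by 3 (three dispersal-linked patches per metacommunity) and
  keeps the quotient continuous — F quantiles accept non-integer df, and
  flooring would add unstated conservatism.  Metacommunity-scale ANOVAs use
  the actual error df, since metacommunities are independent units.
* **Correlations.**  RUE–evenness association is reported for raw values
  and for treatment residuals (cell-mean removal, i.e. residuals of the
  saturated factorial); diverging results indicate the raw association is
  treatment-driven.

## Problem sizes and numerical choices

The test suite and the acceptance script simulate the full 180-flask
experiment; recovery checks use 200 simulated experiments per condition
(a full experiment simulates in well under 0.1 s because the engine is
vectorised across flasks).  The partition identity is verified on 1000
random communities with yields spanning 10³–10⁹ µm³ mL⁻¹; identity error is
measured relative to the largest partition component, since the
complementarity and selection terms can individually dwarf their sum.
Nutrient pools are floored at zero after the Liebig cap to absorb rounding;
mass balance holds to 1e-9 relative.  All randomness flows through one
seeded NumPy generator per simulation; identical seeds give byte-identical
output tables.

## Known limitations

* The growth model has no luxury uptake, storage, light, temperature or
  allelopathy; quotas are fixed, so RUE trends arise only through
  composition shifts.
* The simulator is calibrated to a handful of aggregate outcomes; per-
  species trajectories and the evenness–enrichment slope are not matched.
* Whether the extra (mixture-only) phosphorus levels form metacommunities
  with the same dispersal scheme is structurally assumed (they have three
  N:P patches and disperse like all others).
* Counting is sampled once, at the end of day 31 after all events; the
  alternative (sampling before a final exchange) is not modelled.
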