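"""Enumerate the factorial design and inspect a starting flask.

The experiment crosses six species compositions (five monocultures + the
five-species mixture) with three phosphorus-supply levels and three N:P
ratios in triplicate, plus two extra mixture-only phosphorus levels.
"""

from phytocosm import ExperimentConfig, enumerate_design, initial_patch_state
from phytocosm.species import default_traits

cfg = ExperimentConfig()
points = enumerate_design(cfg)
extra = [p for p in points if p.p_sup_level in cfg.extra_p_levels]

print(f"flasks: {len(points)}")          # 180 in total
print(f"metacommunities: {len({p.metacommunity_id for p in points})}")  # 60
print(f"extra mixture-only flasks: {len(extra)}")  # 18

mix = next(p for p in points if p.composition == "MIX")
state = initial_patch_state(mix, default_traits(), cfg.total_inoculum)
print(f"\nflask {state.design.patch_id}:")
print(f"  initial N = {state.n_conc:.2f} µmol/L (= P_sup x N:P)")
print(f"  initial P = {state.p_conc:.2f} µmol/L")
print(f"  total inoculum = {state.total_biovolume():,.0f} µm³/mL "
      "(substitutive design: same total in every flask)")
for sp, b in state.biovolume.items():
    print(f"    {sp}: {b:,.0f} µm³/mL")
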