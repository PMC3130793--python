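"""Simulate the 31-day experiment and summarise biovolume, RUE and evenness.

Growth is Monod x Liebig with fixed nutrient quotas; the schedule applies
four partial medium exchanges and three dispersal events.  Yield rises with
phosphorus supply while resource use efficiency (biovolume per unit P)
falls.
"""

from phytocosm import ExperimentConfig, analyze, simulate_experiment

result = simulate_experiment(ExperimentConfig(), seed=1)
print(f"simulated {result.metadata['n_flasks']} flasks, "
      f"{result.metadata['n_metacommunities']} metacommunities, seed {result.seed}")

ana = analyze(result.observed_table)
mix = ana.mc_metrics[ana.mc_metrics["composition"] == "MIX"]
summary = mix.groupby("p_sup_level")[["mean_biovolume", "rue", "evenness"]].mean()

print("\nmixture metacommunities, mean over 3 replicates:")
print(f"{'P level':>8} {'biovolume (µm³/mL)':>20} {'RUE':>14} {'evenness':>9}")
for lvl in ["I", "II", "III", "IV", "V"]:
    row = summary.loc[lvl]
    print(f"{lvl:>8} {row['mean_biovolume']:>20,.0f} "
          f"{row['rue']:>14,.0f} {row['evenness']:>9.3f}")

ratio = summary.loc["V", "mean_biovolume"] / summary.loc["I", "mean_biovolume"]
print(f"\nBiovolume increases ~{ratio:.0f}x between the lowest and highest "
      "P supply, while RUE (biovolume per µmol P supplied) is lower at the "
      "highest supply than at the lowest: enriched communities convert "
      "phosphorus less efficiently.")
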