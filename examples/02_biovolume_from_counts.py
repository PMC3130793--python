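"""Convert chamber counts into biovolume concentrations via cell geometry.

Each species is assigned a geometric solid; the mean volume of 25 measured
cells scales counts per examined volume into µm³ per mL.
"""

from phytocosm import CountRecord, cell_biovolume, counts_to_biovolume
from phytocosm.geometry import mean_cell_biovolume
from phytocosm.species import default_traits

traits = default_traits()
for code, t in traits.items():
    print(f"{code} ({t.taxon_group}, {t.shape}): "
          f"mean cell volume {t.mean_cell_biovolume:,.1f} µm³")

# a sphere of diameter 10 µm
print(f"\nsphere d=10 µm -> {cell_biovolume('sphere', {'diameter': 10.0}):.2f} µm³")

# 25 measured cells of slightly varying size average out
cells = [{"diameter": 8.0 + 0.1 * i} for i in range(-12, 13)]
print(f"25-cell mean (spheres d~8 µm): {mean_cell_biovolume(cells, 'sphere'):.1f} µm³")

# 400 Chlamydomonas cells counted in an effective 0.1 mL of chamber volume
rec = CountRecord(species="CL", cells_counted=400, volume_examined_ml=0.1)
b = counts_to_biovolume(rec, traits["CL"])
print(f"\n400 CL cells in 0.1 mL -> {b:,.0f} µm³/mL biovolume")
print("(counts scale linearly: diluting 10x and counting the same cells "
      "would multiply the estimate by 10)")
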