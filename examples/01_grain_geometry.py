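"""Grain-scale bookkeeping: surface-to-volume ratio, cell densities, roughness.

Builds a synthetic sieved-sand sample (median 290 µm), chains areal cell
counts to a colony-scale volumetric respiration rate, and measures the
convex-hull roughness of a synthetic grain outline.
"""

import numpy as np

import sanddbl

# surface-to-volume ratio of a log-normal sand sample at porosity 0.4
spec = sanddbl.SyntheticSpec(seed=0, grain_count=400)
diam = sanddbl.synthetic.sample_grain_diameters(spec)
dist = sanddbl.GrainSizeDistribution(diam)
sv = sanddbl.surface_to_volume(dist, porosity=0.4)
print(f"median grain diameter : {dist.median_diameter_um:7.1f} um")
print(f"surface-to-volume     : {sv:7.1f} cm^2/cm^3 (solids at porosity 0.4)")

# areal cell counts -> cells per cm^3 of sediment -> per-cell -> colony rate
cells = sanddbl.cells_per_volume(8.57e5, sv)
cell_rate = sanddbl.cell_specific_rate(-46.0, cells)
colony_rate = sanddbl.colony_volumetric_rate(cell_rate, biovolume_um3=0.4)
print(f"volumetric cell count : {cells:9.3g} cells/cm^3")
print(f"cell-specific O2 rate : {cell_rate:7.2f} fmol O2/cell/h")
print(f"colony O2 rate        : {colony_rate:7.0f} mmol O2/L/h")

# convex-hull roughness of one synthetic outline (band-limited perturbation)
rough_spec = sanddbl.SyntheticSpec(seed=1, roughness_amplitude_um=20.0)
outline = sanddbl.make_grain_outline(rough_spec, index=0)
profile = sanddbl.roughness(outline)
print(f"surface roughness     : mean {profile.mean_um:5.1f} um, "
      f"max {profile.max_um:5.1f} um (indentation depth vs convex hull)")
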