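"""Central unit-conversion table.

All trait values are stored in their conventional reporting units
(areas in mm^2 or cm^2, vessel diameters in um, masses in g) and are
converted to SI only where a formula demands it.  Every conversion
factor used anywhere in the package lives here.
"""

UM_TO_M = 1e-6
MM_TO_M = 1e-3
MM2_TO_M2 = 1e-6
UM2_TO_MM2 = 1e-6
CM2_TO_M2 = 1e-4
G_TO_KG = 1e-3

#: cm^2/g -> m^2/kg  (specific leaf area)
CM2_PER_G_TO_M2_PER_KG = CM2_TO_M2 / G_TO_KG  # = 0.1
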