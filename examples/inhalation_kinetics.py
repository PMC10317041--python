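"""Three-phase inhalation kinetics of the digital phantom.

Builds the labelled brain phantom and evaluates each tissue's H2-17O
concentration through the protocol phases: room-air baseline (0-5 min),
17O2-enriched gas (5-11 min), room air again (11-30 min).  The slope
during inhalation proxies the tissue's oxygen consumption; CSF rises
more slowly because it only drains metabolised water.
"""

import numpy as np

from o17mri import (
    GridSpec,
    InhalationProtocol,
    Label,
    build_phantom,
    default_tissue_table,
    tissue_timecourse,
)

grid = GridSpec((32, 32, 32), 7.5)
phantom = build_phantom(grid)
protocol = InhalationProtocol()
table = default_tissue_table()

print("phantom voxel counts:",
      {lab.name: int(mask.sum()) for lab, mask in phantom.masks.items()})

times = np.array([0.0, 5.0, 8.0, 11.0, 20.0, 30.0])
print("\nrelative H2-17O concentration at t =", times, "min:")
for lab in (Label.GM, Label.WM, Label.CSF, Label.STROKE):
    c = tissue_timecourse(table[lab], protocol, times)
    print(f"  {lab.name:7s}", np.round(c, 3))
print(
    "\nHealthy tissue plateaus at 1.18 (+18% H2-17O) after six minutes of "
    "enriched gas; CSF at 1.135. The stroke label defaults to healthy "
    "kinetics - pass a reduced uptake rate to model a metabolic deficit."
)
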