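"""Full 3-D scenario run with line-scan, SCH and wavefront analysis.

Runs two flux-distribution scenarios on a desk-scale branched geometry
(tubule radii scaled up so a coarse grid resolves them), extracts a
simulated confocal line scan 200 nm from the tubule wall, and compares the
spatial Ca²⁺ heterogeneity (SCH) statistic.  Takes a couple of minutes.
"""

from dataclasses import replace

import numpy as np

from ttcasim import TTubuleSpec, generate_ttubule_mesh, run_3d
from ttcasim.analysis import (
    LineScanSpec,
    detect_front,
    extract_linescan,
    sch_report,
    standard_epochs,
)
from ttcasim.membrane import LCCParams, lcc_template_peak_time
from ttcasim.presets import PRESETS, calibrated_lcc_amplitude

spec = TTubuleSpec(radius_min=0.15, radius_max=0.35, mouth_radius=0.45,
                   branch_length=0.5)
mesh = generate_ttubule_mesh(spec, 0.15)
print(f"desk-scale mesh: {mesh.n_vertices} nodes, {len(mesh.tetrahedra)} tets")

amp = calibrated_lcc_amplitude()
ls = LineScanSpec(offset=0.2, angle_deg=120.0)

for name in ("fig4_heterogeneous", "fig4_homogeneous", "fig6_nodye"):
    cfg = PRESETS[name].simulation_config(dt=0.5, output_stride=4)
    cfg = replace(cfg, lcc=LCCParams(amplitude=amp))
    sol = run_3d(mesh, cfg)
    img = extract_linescan(sol, ls)
    avg = sol.volume_average("Ca")
    epochs = standard_epochs((sol.time, avg), lcc_template_peak_time(cfg.lcc))
    rep = sch_report(img, ls.spots, epochs)
    front = detect_front(img)
    print(f"{name:20s}: peak {1e3*avg.max():6.1f} nM, "
          f"SCH@Ca-peak {rep.sch['t_Ca_peak']:.3f}, "
          f"front initiated: {front.initiated}")
# Heterogeneous LCC (density graded along the tubule) gives the flattest
# profile; homogeneous distribution concentrates entry at the cell surface
# and is the most heterogeneous.  Without dye the SCH rises several-fold:
# the indicator masks the spatial non-uniformity it is meant to report.
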