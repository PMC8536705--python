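"""Run the synthetic multi-column ensemble and look at its structure.

125 collocation runs x 100 columns x 3 time slices (preindustrial 1850,
contemporary 2000, projected 2100).  Columns belong to three regime
families whose oxygen response to the uncertain parameters differs.
"""

import numpy as np

from oxymap import ParameterSet, WorldConfig, build_design, generate_world, run_ensemble
from oxymap.diagnostics import weighted_moments

design = build_design(ParameterSet.default())
world = generate_world(WorldConfig(), seed=0)
archive = run_ensemble(design, world)
print(f"archive: {archive.n_runs} runs x {archive.n_columns} columns x {len(archive.times)} slices")

w = archive.weights
for regime in ("deep_water_formation", "tropical_omz", "intermediate"):
    sel = archive.regimes == regime
    m2000, s2000 = weighted_moments(archive.slice(2000).values[:, sel], w)
    print(
        f"{regime:22s} contemporary min O2 = {m2000.mean():6.1f} "
        f"+/- {s2000.mean():5.1f} mmol/m^3 across the ensemble"
    )
print("Ventilated deep-water-formation columns sit near saturation with")
print("almost no ensemble spread; tropical OMZ columns are oxygen-poor and")
print("spread widely because their ventilation hinges on the uncertain kappa.")
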