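"""Per-column Sobol maps and the projection-uncertainty diagnostics.

Fits a polynomial chaos expansion to every column, decomposes the
variance, and computes the map-level diagnostics: ensemble-mean
projected change, its noise-to-signal ratio, contemporary spread/CV and
the low-variance mask (columns whose sd is below 6% of the mean are not
interpreted).
"""

import numpy as np

from oxymap import (
    ParameterSet,
    WorldConfig,
    build_design,
    compute_diagnostics,
    fit_pce,
    generate_world,
    run_ensemble,
    sobol_decompose,
)

design = build_design(ParameterSet.default())
archive = run_ensemble(design, generate_world(WorldConfig(), seed=0))
sobol_2000 = sobol_decompose(fit_pce(design, archive.slice(2000).values))
maps = compute_diagnostics(archive, sobol_2000)

for regime in ("deep_water_formation", "tropical_omz", "intermediate"):
    sel = archive.regimes == regime
    print(
        f"{regime:22s} mean change {maps.mean_change[sel].mean():7.2f} mmol/m^3   "
        f"noise/signal {np.nanmean(maps.noise_to_signal[sel]):6.1f} %   "
        f"masked {maps.low_variance_mask[sel].mean() * 100:5.1f} %"
    )
print(f"\nrank correlation (contemporary CV vs projected noise-to-signal): "
      f"{maps.rank_correlation:.3f}")
print("Large change with low noise-to-signal (deep-water formation) means the")
print("projection is insensitive to the parameter choice; small change with")
print("high noise-to-signal (tropics) means parameter uncertainty dominates.")
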