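# oxymap

Variance-based uncertainty mapping for perturbed-parameter ensembles of
oceanic oxygen: who is this for and what does it do?

Biogeochemical ocean models project future deoxygenation, but their
projections hinge on parameters that observations barely constrain —
here the detritus sinking speed *w*, the vertical background
diffusivity *κ* and the maximum phytoplankton growth rate *a*. `oxymap`
maps that parametric uncertainty onto its local manifestations: for
every gridpoint (water column) it decomposes the ensemble variance of
the water-column oxygen minimum into the fractions attributable to each
parameter and their interactions, for the contemporary state and for
the projected change, and identifies *benchmarking regions* — places
where present-day observations would most effectively pin down a
specific parameter and thereby shrink projection uncertainty.

## Method in brief

Parameters carry independent truncated-Gaussian priors (relative sd
50 % for *w* and *κ*, 25 % for *a*). A full tensor Gauss–Hermite rule
with 5 points per dimension places 125 ensemble members at collocation
nodes ξ_q with weights w_q in standardized coordinates. Each output
field Y (per column) is expanded in orthonormal probabilists' Hermite
polynomials up to total order 3,

    Y(ξ) ≈ Σ_α c_α ψ_α(ξ),   c_α = Σ_q w_q Y_q ψ_α(ξ_q),
    ψ_α(ξ) = Π_i He_{α_i}(ξ_i) / √(α_i!),

so the variance is D = Σ_{α≠0} c_α² and the Sobol index of a parameter
subset U is S_U = Σ_{supp(α)=U} c_α² / D (in %): three main effects,
three pairwise interactions and one triple interaction summing to
100 %. On top of this sit the map diagnostics: ensemble-mean projected
change, its noise-to-signal ratio (sd/|mean|, %), contemporary spread
and CV, a low-variance mask (sd < 6 % of the mean), regional Sobol
averages and benchmark scores. A built-in synthetic multi-column ocean
(steady diffusion–remineralization columns in three regime families)
generates ensembles with the statistical structure the analysis
assumes; externally produced NetCDF archives flow through the same
pipeline (see `docs/archive_format.md`).

## Worked example

```python
import numpy as np
from oxymap import (ParameterSet, WorldConfig, build_design, generate_world,
                    run_ensemble, fit_pce, sobol_decompose, compute_diagnostics)

design = build_design(ParameterSet.default())          # 125 runs
archive = run_ensemble(design, generate_world(WorldConfig(), seed=0))
sobol = sobol_decompose(fit_pce(design, archive.slice(2000).values))
maps = compute_diagnostics(archive, sobol)
for regime in ("deep_water_formation", "tropical_omz", "intermediate"):
    sel = archive.regimes == regime
    print(f"{regime:22s} change {maps.mean_change[sel].mean():7.2f} mmol/m^3  "
          f"noise/signal {np.nanmean(maps.noise_to_signal[sel]):5.1f} %")
```

prints

    deep_water_formation   change  -27.18 mmol/m^3  noise/signal   0.4 %
    tropical_omz           change  -16.05 mmol/m^3  noise/signal  34.4 %
    intermediate           change  -19.98 mmol/m^3  noise/signal   6.2 %

Deep-water-formation columns lose the most oxygen, but the loss is
driven by warming and stratification, not by the uncertain parameters
(noise-to-signal 0.4 %): the projection there is robust. Tropical
oxygen-minimum-zone columns change less in absolute terms, yet a third
of the signal's magnitude recurs as parameter-induced spread — exactly
the regions where projections are least trustworthy and where Sobol
fractions tell you *which* parameter to constrain. The scripts in
`examples/` walk through the design, the ensemble, the sensitivity maps
and the benchmarking-region report one capability at a time.

A shell pipeline mirrors the library:

    oxymap --outdir out all          # design → simulate → fit → sobol → maps → report

producing NetCDF stage files, `regional_sobol.tsv` and
`benchmark_regions.tsv` plus a JSON manifest; same config + seed gives
byte-identical outputs.

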