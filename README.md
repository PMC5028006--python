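# neurocascade

Cascade statistics, cortical-state entropies and regional mutual
information for wide-field voltage-imaging movies.

Wide-field imaging with genetically encoded voltage indicators records
population membrane voltage across a large part of cortex at high
spatiotemporal resolution (hundreds of pixels per axis at tens of Hz).
A central question such recordings can address is whether cortical
dynamics are *scale-free* — whether cascades of activity occur at all
sizes, with a power-law size distribution, as expected near criticality
— and how proximity to that regime relates to the information a region
can represent (entropy) and exchange with other regions (mutual
information).  This package implements that analysis chain as a tested,
reusable library for analysts working with fractional-fluorescence
(ΔF/F) movies, together with a lattice branching-process simulator that
generates movies with known dynamical regime for validation.

## What it computes

Starting from a T×H×W movie and a cortex mask, the pipeline:

1. **Preprocesses** the movie: per-pixel ΔF/F, 4-frame temporal and 8×8
   spatial moving averages, 0.5 Hz zero-phase high-pass, 10 s initial
   trim, and signal-to-noise masking.
2. **Converts to a point process**: a pixel is active only at frames
   where its trace crosses +1 per-pixel S.D. from below.
3. **Detects cascades** as spatiotemporally contiguous clusters of
   active pixels (|Δt| ≤ 1, 4-neighbour spatial adjacency; the
   traditional temporal-only avalanche definition is also available)
   and summarises the size distribution with the **κ statistic**:

   κ = 1 + (1/m) Σₖ [F_ref(βₖ) − F_obs(βₖ)],

   where F_obs is the empirical CDF of cascade sizes z, F_ref a
   discrete truncated power law with exponent −1.5 on the observed size
   range, and β₁..βₘ (m = 10) logarithmically spaced sizes.  κ ≈ 1
   indicates scale-free statistics, κ > 1 an excess of large cascades,
   κ < 1 a deficit.
4. **Quantifies the state repertoire**: k-means clustering of
   cortex-wide activity patterns per 50 s window into k states, state
   visitation entropy H_state = −Σᵢ pᵢ log₂ pᵢ, and the first-order
   Markov transition entropy H_trans over ordered state pairs.
5. **Measures regional information**: 8×8-pixel regions with one bit
   per pixel per frame; regional pattern entropy H_reg, pairwise
   shuffle-corrected mutual information, and information transmission
   IT_x = Σ_{y≠x} MI(x, y) over sufficiently distant region pairs.
6. **Summarises** per-window metric time courses with Pearson
   correlations and log-log cascade-size distribution plots.

The synthetic module simulates cascading activity on a pixel lattice
(each active pixel activates each of its 4 neighbours in the next frame
with probability σ/4, so σ is the expected branching ratio), pixel-wise
independent noise with a prescribed power spectrum, and rendered
fluorescence movies (event kernel + noise) for end-to-end testing.

## Worked example

```python
from neurocascade import (SimulationConfig, simulate_branching_cascades,
                          detect_cascades, kappa)
from neurocascade.cascades import sizes_of, fit_powerlaw_mle
from neurocascade.regimes import noise_size_sample

cfg = SimulationConfig(grid_height=64, grid_width=64, n_frames=6000,
                       branching_param=1.0, seed=42)
pp, labels, meta = simulate_branching_cascades(cfg)
sizes = sizes_of(detect_cascades(pp)).sizes
print(f"{len(sizes)} cascades, {meta['n_events']} events "
      f"({meta['active_fraction']:.2%} of pixels active per frame)")
print(f"kappa = {kappa(sizes):.3f}")
print(f"size exponent (truncated MLE, z >= 2) = "
      f"{fit_powerlaw_mle(sizes, z_min=2, z_max=int(sizes.max())):.2f}")
print(f"noise-control kappa = {kappa(noise_size_sample(seed=42)):.3f}")
```

prints

```
15182 cascades, 236967 events (0.96% of pixels active per frame)
kappa = 1.009
size exponent (truncated MLE, z >= 2) = -1.54
noise-control kappa = 0.923
```

At the critical branching ratio σ = 1 the simulated cascade sizes are
close to the z^−1.5 power law (κ ≈ 1, fitted exponent ≈ −1.5).  The
control — pixel-wise independent 1/f noise pushed through the identical
preprocessing and thresholding chain — lacks large cascades (κ < 1),
while supercritical bursts at σ = 1.4 produce an excess of them
(κ ≈ 1.09 via `neurocascade.regimes.supercritical_size_sample`).

A config-driven end-to-end run (simulate → preprocess → point process →
cascades/κ → states → regional → tables) is available as
`neurocascade run-all --config config.yaml`, and each stage as its own
subcommand (`neurocascade simulate cascades ...`,
`neurocascade cascades kappa ...`; see `neurocascade --help`).

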