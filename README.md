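# pelletmetrics

Quantification of **filamentous biopellet morphology and viability** for
submerged cultivations of pellet-forming microorganisms (actinomycetes,
filamentous fungi).  Process scientists link pellet macro-morphology —
size, roundness, compactness, the thickness of the metabolically active
outer shell — to secondary-metabolite productivity; this package provides a
tested, reproducible implementation of the three measurement channels such
studies use, plus the kinetics and statistics that connect them:

1. **Brightfield microscopy** — adaptive local-mean binarization of dark
   pellets on a bright background, distance-transform watershed, per-pellet
   shape descriptors, debris/edge filtering and q0/q3 size distributions.
2. **CLSM of stained pellet slices** — Otsu binarization of green (live) and
   red (dead, PI) channels, morphological cleanup, and the three-region
   decomposition into solely-live, solely-dead and overlap area shares.
3. **Pulse-shape flow cytometry** — per-particle metrics from spatially
   resolved FSC/SSC/FLG/FLR signal profiles: signal length, compactness,
   viable layer (FDA- or PI-based), viability and autofluorescence factors.
4. **Kinetics & statistics** — biomass-specific productivity and per-day
   one-way ANOVA comparisons between cultivation conditions.
5. **Synthetic data** — generators for all of the above with analytic ground
   truth, so every pipeline stage is testable without measurement data.

## The metrics

With projected area *A* and perimeter *P* of a segmented pellet
(pixel size 4.5 μm/px by default):

    d_a         = sqrt(4·A/π)                  area-equivalent diameter [μm]
    circularity = 4π·A / P²                    1 for an ideal circle
    Feret ratio = Feret_min / Feret_max        elongation measure

Size structure is reported as the number-density q0(d_a) and volume-density
q3(d_a) distributions, each normalized to unit integral.

For a stained slice, with G and R the binarized channel masks:

    live  = |G \ R| / |G ∪ R|     dead = |R \ G| / |G ∪ R|
    overlap = |G ∩ R| / |G ∪ R|   live ratio = live  (solely-green convention)

For a pulse profile of a particle of signal length *L* (first to last FSC
sample above the 200 mV trigger):

    compactness     = FWHM(SSC) / L                      sphere: √3/2 ≈ 0.866
    vl_FDA [μm]     = 0.5 · L · area(FLG) / area(FSC)
    vl_PI  [μm]     = 0.5 · (L − length where FLR > 0.3·max(FLR))
    viability factor = 2 · vl / L                        ∈ [0, 1]
    autofluorescence factor = area(FLG) / area(FSC)      unstained runs

and the specific productivity from a cultivation series
q_P = (1/X)·dP/dt in mg g⁻¹ d⁻¹.

## Worked example

```bash
python examples/03_flow_pulse_metrics.py
```

prints (seeded, so exactly this):

```
first particle: class=pellet, signal length 120 um (truth 123 um)
  compactness 0.885  (sphere reference sqrt(3)/2=0.866)
  viable layer FDA 23.7 um, PI 42.4 um, viability factor 0.39
population: 80 pellets, signal length 141 +/- 33 um
            compactness 0.881 +/- 0.010
            viability factor 0.46 +/- 0.10
```

The particle is classified as a pellet because its FSC trace saturates in
the core and its signal length exceeds 80 μm; compactness slightly above the
homogeneous-sphere value reflects the dense scattering core; the viable
layer is the simplified radius of metabolically active material.  The other
examples cover brightfield morphology (`01`), CLSM shares (`02`),
productivity kinetics with per-day ANOVA (`04`) and the full two-condition
demo (`05`).

A thin CLI wraps the same library functions:

```bash
pelletmetrics synth image --seed 1 --out frames/
pelletmetrics microscopy --in frames/ --pixel-size 4.5 --out results/
pelletmetrics demo --seed 1 --out demo_out/
```

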