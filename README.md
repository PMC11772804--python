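# cytoquant

Quantification of epithelial cytokinesis failure from fluorescence
microscopy, built around the *Drosophila* follicular epithelium as the model
tissue.  In a post-mitotic epithelium every extra nucleus records a failed
division, so cytokinesis robustness can be read out at scale from fixed
two-channel image stacks (membrane marker + nuclear stain).  The package
implements the full measurement chain as a tested Python library plus a set
of narrative analysis drivers, and ships a synthetic-data generator with
complete ground truth so every stage is verifiable without microscopy data.

## What it computes

* **Curvature-aware projection.**  Egg chambers are curved, so nuclei drift
  through z across the field.  Each (y, x) pixel is anchored to its nearest
  detected nucleus (a Voronoi partition of the plane) and a 1 µm section
  centered on that nucleus's axial position is projected — the surface is
  followed locally instead of picking one global plane.
* **Multinucleation scoring.**  Within a central ROI, cells are segmented
  from the membrane channel (seeded watershed), nuclei from the nuclear
  channel (Otsu + distance-transform watershed), and each nucleus is
  assigned to the cell under its centroid.  Per chamber:
  ratio = Σnᵢ/N (nuclei per cell, N qualifying cells), and
  frequency = 100·#{nᵢ ≥ 2}/N.
* **Modifier-screen statistic.**  Δ ratio = (nuclei/cell)ₛₐₘₚₗₑ −
  (1/n)Σ(nuclei/cell)ᵢ,𝒸ₒₙₜᵣₒₗ over same-replicate sensitized controls, with
  a two-sided Mann–Whitney U test (exact for small tie-free samples) driving
  enhancer/suppressor calls.
* **Ring constriction rate.**  Diameter traces d(t) are onset-aligned
  (t₀ = frame prior to a sustained decrease), normalized to d(t₀), and the
  rate is the OLS slope β of d = α + βt over four consecutive timepoints in
  the constant phase (80–40 % of the initial diameter), accepted only when
  R² > 0.95.
* **Intensity and failure scoring.**  Background-corrected cortical/ring
  fluorescence from band and disk ROIs on 2-plane z-sum projections, and
  three-category scoring of division-event logs (no failure / failure during
  constriction / post-constriction regression) after small-cell and ≥ 20 min
  observation filters.

## Worked example

Each script under `analysis/` is a self-contained step writing its tables to
`results/`.  Recovering planted multinucleation fractions through the entire
simulate → project → segment → count chain:

```
$ python analysis/02_multinucleation_recovery.py
planted fraction -> recovered ratio (expect 1 + f) and % (expect 100 f):
  f = 0.00:  ratio 1.000  multinucleated  0.00%
  f = 0.05:  ratio 1.040  multinucleated  4.01%
  f = 0.10:  ratio 1.100  multinucleated 10.02%
  f = 0.20:  ratio 1.192  multinucleated 19.19%
```

With 2 nuclei per multinucleated cell the expected ratio is 1 + f, so the
chain recovers the planted fraction to well within ±0.03 across the grid
(the slight shortfall at f = 0.20 comes from excluding border-touching
cells, which disfavors the larger binucleated cells).  Constriction-rate
estimation on two simulated cohorts:

```
$ python analysis/03_constriction_rates.py
control: 49/50 traces fitted, rate 0.601 +/- 0.072 um/min (true 0.6)
slowed: 45/50 traces fitted, rate 0.364 +/- 0.083 um/min (true 0.35)
control vs slowed: U = 2166, two-sided p = 8.58e-16 (normal_approx)
```

The unfitted traces are those rejected by the R² > 0.95 gate — the method's
own exclusion rule, not a crash.  `analysis/05_modifier_screen.py` assembles
a three-replicate screen and calls the planted +0.15 target an enhancer and
the −0.12 target a suppressor.

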