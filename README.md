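# pcpmig — single-cell quantification of PCP-driven lymphocyte migration

`pcpmig` is a tested re-implementation of an imaging-based methodology for
monitoring the mammalian WNT/planar-cell-polarity (PCP) pathway in single
migrating B lymphocytes (MEC1 cells). The original readout correlates
chemotactic migration with the asymmetric subcellular localisation of
fluorescently tagged PCP proteins such as VANGL2, which is enriched at the
trailing edge of a migrating cell and loses its asymmetry under casein
kinase 1 (CK1) inhibition. Because no raw movies are deposited anywhere,
the package pairs every quantification step with a ground-truthed synthetic
data generator, so the whole pipeline — simulation, rendering, detection,
tracking, statistics — is verifiable end to end.

It is aimed at quantitative cell biologists who want a scriptable,
reproducible version of this analysis: migration statistics, chemotaxis
directionality, fluorescence polarity ratios and inhibitor dose–response
fits, plus a simulator to calibrate and sanity-check each of them.

## What it computes

**Four migration parameters** per tracked cell with positions
$(x_k, y_k)$ at times $t_k$:

- track length $L = \sum_k \lVert p_{k+1} - p_k \rVert$,
- displacement length $D = \lVert p_n - p_0 \rVert$,
- maximum speed $\max_k \lVert p_{k+1}-p_k\rVert / (t_{k+1}-t_k)$,
- straightness $S = D/L \in [0, 1]$ (1 = perfectly straight path).

**Directionality** against a chemokine (CCL19) source: each cell
contributes the signed deviation $\theta_i$ of its start-to-end migration
direction from the direction toward the source; the Rayleigh test for
circular uniformity uses the mean resultant length
$\bar R = \lvert \tfrac1n \sum_i (\cos\theta_i, \sin\theta_i)\rvert$,
$z = n \bar R^2$, with the second-order small-sample p-value correction.

**Polarity ratio** $R = I_\text{trailing} / I_\text{leading}$: the cell
mask is split into equal-area halves by the line through the centroid
perpendicular to the heading, and $R$ is the ratio of mean marker
intensities. $R = 1$ means symmetric distribution; trailing-enriched
markers (VANGL2, ROR2) give $R > 1$.

**Dose–response**: the variable-slope (four-parameter) inhibitory
logistic $y = \text{bottom} + (\text{top}-\text{bottom}) /
(1 + (d/\text{EC}_{50})^{h})$ fitted by least squares on log-dose, and the
transwell **migration index** (chemokine-driven migrated-cell count
divided by the control-medium count).

**Simulator**: cells follow a biased persistent random walk — headings are
von Mises draws centred on the resultant of the previous heading (weight
`persistence_kappa`) and the source direction (weight `bias_kappa`), step
lengths are gamma distributed. Condition presets (`control`, `ccl19`,
`ccl19_ck1i`, `cytochalasin`) encode the observed phenomenology, including
motile arrest with retained marker polarity under actin depolymerisation.
Cells are rendered into two-channel 16-bit TIFF stacks (whole-cell tracker
dye + membrane polarity marker with perimeter intensity
$\propto 1 + A\cos(\varphi - \varphi_\text{peak})$).

## Worked example

```python
import numpy as np
from pcpmig import condition_preset, simulate_tracks, summarize
from pcpmig import deviation_angles, rayleigh_test

src = (100.0, -400.0)                       # chemokine source, um
ts, truth = simulate_tracks(condition_preset("ccl19"),
                            n_cells=50, n_frames=60, dt=30.0,
                            source_point=src, seed=1017)
table, medians = summarize(ts, condition="ccl19")
res = rayleigh_test(deviation_angles(ts, src, min_displacement=2.0))
print(medians.round(3).to_dict())
print(f"R_bar={res.mean_resultant_length:.3f} p={res.p_value:.3g}")
```

prints

```
{'track_length_um': 207.406, 'displacement_um': 168.611,
 'max_speed_um_min': 12.564, 'straightness': 0.814}
R_bar=0.993 p=1e-12
```

i.e. cells in the simulated chemokine gradient migrate long, straight
paths tightly coordinated toward the source (the p-value is clipped at
the 1e-12 reporting floor). The analysis scripts' `control` condition
gives median straightness 0.264 and Rayleigh p = 0.42 — random
migration.

The numbered scripts under `analysis/` run the full study: simulate the
four conditions, render and re-track the movies, compute the migration
metrics with Kruskal–Wallis comparisons, the directionality analysis, the
polarity ratios (including the arrest experiment) and the dose–response
fits. Tables land in `results/`, bulky regenerable intermediates in
`scratch/`. A `pcpmig` command-line interface exposes each stage
(`simulate`, `render`, `detect`, `link`, `metrics`, `direction`,
`polarity`, `dose-response`, `migration-index`, `run-all`).

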