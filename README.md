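# astrotopo

Quantitative analysis of gap-junction-coupled astrocyte networks in the
auditory brainstem, for physiologists who characterise tracer coupling in
acute slices.  In the lateral superior olive (LSO) the mediolateral axis is
the tonotopic axis and the dorsoventral axis follows isofrequency bands;
whether an astrocyte network is elongated *orthogonal* or *parallel* to the
tonotopic axis is the biological question this toolbox quantifies.  The
package covers the full chain:

* **Detection** — coupled cells are intensity maxima of the tracer image
  that exceed 1.75 × background.
* **Topography** — the core anisotropy statistic.  Vectors from the patched
  cell to each coupled cell are binned into four 90° sectors (1A/1B
  straddling ±y, 2A/2B straddling ±x) and the count-normalised quotient of
  sum-vector magnitudes is

  $$R = \frac{|\vec v_{1A}|/n_{1A} + |\vec v_{1B}|/n_{1B}}
             {|\vec v_{2A}|/n_{2A} + |\vec v_{2B}|/n_{2B}}$$

  Rotating the frame in 15° steps over a full turn and fitting
  $R(\theta) = A_0 + A\sin(\omega\theta + \varphi + \tfrac{3}{4}\pi)$
  yields the anisotropy $R_\text{max} = A_0 + A$ and the orientation
  $\alpha \in [0°, 180°)$ of maximal tracer extent.  Elliptical networks
  oscillate twice per turn ($\omega \approx 2$).  Networks are classified
  as (1) anisotropic-orthogonal ($R_\text{max} > 1.1$, $45° < \alpha \le
  135°$), (2) isotropic ($R_\text{max} \le 1.1$), or (3)
  anisotropic-parallel (the rest).
* **Electrophysiology** — passive properties from a −5 mV test step:
  $R_\text{In} = \Delta U / (I_2 - I_1)$,
  $R_S = \Delta U / (I_\text{peak} - I_1)$, $R_M = R_\text{In} - R_S$,
  with QC rejection above $R_S = 15\,\mathrm{M\Omega}$; I/V curves and a
  rectification index separate passive (PA) from non-passive (nPA)
  astrocytes.
* **Immunofluorescence** — ROI mean grey values with negative-control
  background subtraction and nucleus areas.
* **Statistics** — Kolmogorov–Smirnov normality gate choosing between
  unpaired t-test and Mann–Whitney U, χ² for class distributions, and
  Šidák-corrected critical values $1 - (1-\alpha)^{1/m}$.
* **Synthetic data** — seeded generators for all three data modalities
  (anisotropic Gaussian point clouds with exponentially decaying tracer
  brightness, RC-circuit voltage-step currents, punctate immuno fields),
  so every stage is testable without any experimental download.

## Worked example

```python
from astrotopo import (SyntheticNetworkSpec, generate_network_points,
                       rotation_scan, fit_sinusoid, classify_network,
                       network_metrics)

spec = SyntheticNetworkSpec(seed=1)          # 64 cells, 2:1 axes, α_true = 90°
points = generate_network_points(spec)
fit = fit_sinusoid(rotation_scan(points))
print(f"R_max = {fit.r_max:.2f}, alpha = {fit.alpha_deg:.1f} deg, "
      f"omega = {fit.omega:.2f}")
print(classify_network(fit).network_class)
m = network_metrics(points)
print(f"{m.n_cells} cells, {m.density_per_mm2:.0f} cells/mm^2")
```

prints

```
R_max = 2.05, alpha = 88.3 deg, omega = 1.97
class1_orthogonal_anisotropic
64 cells, 1478 cells/mm^2
```

— a dorsoventrally elongated network: the ratio oscillates twice per turn
(ω ≈ 2), its peak 2.05 is well above the 1.1 isotropy bound, and the
fitted orientation 88.3° (true 90°) places it orthogonal to the tonotopic
axis at a wild-type-scale cell density.

The same chain is available from the shell (`astrotopo simulate | detect |
topo | ephys | intensity | stats | run`).

## Analysis scripts

The numbered drivers under `analysis/` rebuild the study-style cohorts and
write their tables to `results/`:

1. `01_simulate_networks.py` — three cohorts (normal-hearing plus two
   deafness models) of tracer-coupled networks,
2. `02_detect_cells.py` — detection recall on rendered micrographs,
3. `03_network_topography.py` — per-network anisotropy/orientation/class
   and χ² comparison of class distributions,
4. `04_ephys_properties.py` — passive properties, QC and nPA/PA phenotypes,
5. `05_immuno_intensity.py` — connexin-style mean grey values per nucleus
   with Šidák-corrected group tests.

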