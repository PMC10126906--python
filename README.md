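# mechanostat

Quantitative mechanoregulation analysis of time-lapsed 3D bone images.

Trabecular bone adds and removes material where the local mechanical
environment tells it to: formation where tissue is highly strained,
resorption where it is disused, quiescence in between — Frost's
*mechanostat*.  Given two registered binary micro-CT volumes of the same
bone (baseline and follow-up), a trabecular-compartment mask and a
mechanical-signal field from micro-finite-element analysis, this package
measures that feedback loop voxel by voxel:

* **Surface (re)modeling velocity (RmV).**  Each baseline surface voxel is
  classified as a formation, quiescence or resorption site; a taxicab
  distance transform of the follow-up image (and of its inverse) yields the
  thickness of formed bone and the depth of resorption, projected onto the
  surface by gray dilation and rescaled per cluster so the summed surface
  distances equal the (re)modeled cluster volumes exactly.  Distances
  become signed velocities in µm/day.
* **Mechanostat curves.**  RmV is binned against the local mechanical
  signal *ms* (effective strain, SED, or ‖∇SED‖, each sampled on its
  proper side of the bone/marrow interface) and fitted with

  - the piecewise linear mechanostat with resorption/formation saturation
    levels RSL, FSL (µm/day), thresholds RT ≤ FT (µε) bounding the lazy
    zone, and velocity moduli RVM, FVM (µm/day/µε);
  - the hyperbola RmV(*ms*) = FSL − RmVM/(RmT + *ms*).

* **Conditional probabilities and CCR.**  P(event | signal bin) curves
  over signal normalized by its 99th percentile and binned at 1%, with
  per-event count normalization; the correct classification rate (CCR) is
  the maximal normalized trace of the 3×3 confusion matrix over all
  two-threshold partitions of the signal axis (1/3 = random, 1 = perfect).
* **Frequency dependence.**  Balanced bootstrapping (every animal appears
  equally often across replicates) yields parameter distributions per
  loading group; medians across cyclic-loading frequencies *f* are fitted
  with y = y0 + a·ln *f*.

A small-grid linear-elastic voxel FE solver (8-node hexahedra, matrix-free
conjugate gradients) is included for producing SED fields on desk-scale
problems, and a synthetic-data generator evolves trabecular-like phantoms
under a known mechanostat rule so the whole chain can be validated against
ground truth.

## Worked example

Generate a synthetic image pair with known ground truth (formation
saturating at 2 µm/day above ~450 µε, lazy zone 150–300 µε, resorption
saturating at −3 µm/day) and run the full analysis:

```python
import numpy as np
from mechanostat import (
    BinaryVolume, build_surface_table, sample_surface_signal,
    conditional_probabilities, compute_ccr, compute_rmv_curve,
    fit_piecewise, fit_hyperbola,
)
from mechanostat.synthgen import synthetic_pair

pair = synthetic_pair(3, shape=(32, 32, 32))
table, qc = build_surface_table(pair["baseline"], pair["followup"], pair["mask"])
bone = BinaryVolume(
    (pair["baseline"].bool_data & pair["mask"].bool_data).astype("uint8"), 10.5
)
table = sample_surface_signal(pair["signal"], table, bone)

ccr = compute_ccr(conditional_probabilities(table))
curve = compute_rmv_curve(table, voxel_size=10.5, interval_days=7.0)
pw = fit_piecewise(curve)
print(f"CCR = {ccr.ccr:.3f}  (t_r = {ccr.t_r:.0f}%, t_f = {ccr.t_f:.0f}%)")
print({k: round(v, 3) for k, v in pw.as_dict().items()})
```

Output:

```
CCR = 0.847  (t_r = 24%, t_f = 54%)
{'RSL': -2.367, 'RVM': 0.037, 'RT': 152.936, 'FT': 291.506,
 'FVM': 0.017, 'FSL': 1.909, 'rmse': 0.105}
```

The CCR of 0.847 says the mechanical signal predicts the observed
(re)modeling events far better than chance (0.33); the fitted thresholds
RT ≈ 153 µε and FT ≈ 292 µε recover the generating lazy zone (150–300 µε)
to within a signal bin, and FSL ≈ 1.9 µm/day approaches the generating
saturation velocity of 2 µm/day (the distance-transform measurement mildly
flattens within-cluster gradients; see `docs/methods.md`).

A command-line interface mirrors the library: `mechanostat synth`,
`run-pair`, `run-study` (YAML study manifest), `fit` and `bootstrap`; exit
codes are 0 (success), 2 (configuration error), 3 (data error), 4 (fit
failure).

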