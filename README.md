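# wallmark

Analysis of bacterial cell-wall growth by tracing **wall-anchored protein
landmarks** (e.g. flagellar motors) in time-lapse microscopy of rod-shaped
bacteria, plus a ground-truthed simulator that makes every stage of the
analysis testable without any experimental data.

## The science

Rod-shaped bacteria such as *E. coli* are spherocylinders: a cylindrical
body capped by two poles. New peptidoglycan is inserted only into the
cylindrical **active zone**; the polar caps are **inert**. Protein
complexes rigidly anchored to the wall therefore act as fiducial markers of
wall material, and their motion reveals the insertion pattern:

- **Inert-zone size** `P_yc`. Track each landmark's distance to its nearest
  pole, `P_y(t)`, fit the average axial velocity `V_Py` per landmark, and
  fit the hinge law

  ```
  V_Py = 0                 for P_y < P_yc
  V_Py = k (P_y − P_yc)    for P_y ≥ P_yc
  ```

  The changepoint `P_yc` is the axial size of the inert polar zone
  (≈ 0.27 µm for cells grown in LB).

- **Homogeneous axial expansion ("Hubble law")**. For landmark pairs in the
  active zone, the axial separation grows as `V_Dy = H·D_y`, where `H` is
  the expansion rate per unit length; lateral separations never change
  (no diameter growth, no twist). After normalizing by `H`, all interval
  datasets collapse on the slope-1 line.

- **Normalized coordinate**. `N_y = Y/L` (position from mid-cell over
  active-zone length, in [−0.5, 0.5]) is a constant of the motion during
  elongation. During septation, local mid-cell insertion drives landmarks
  outward by up to one cap size.

- **Bernoulli shift map**. Because division bisects the cell and builds a
  new inert cap of size `P_yc` at the division site, a landmark's
  normalized position maps across generations as

  ```
  N_y(n+1) = 2 N_y(n) − 0.5   if 0 < N_y(n) ≤ 0.5
  N_y(n+1) = 2 N_y(n) + 0.5   if −0.5 ≤ N_y(n) < 0
  ```

  This map preserves the uniform law and exponentially smooths any uneven
  protein distribution on the cell body — a physical mechanism for the even
  spread of surface complexes across generations.

## What is in the package

| module | contents |
| --- | --- |
| `wallmark.simulate` | growing/dividing spherocylinder cells with wall-anchored landmarks; ground-truth tables; observation noise; TIFF rendering |
| `wallmark.imaging` | sub-pixel 2D-Gaussian spot fitting, Otsu segmentation, midline/pole geometry, cell coordinates, convexity-defect division detection |
| `wallmark.kinematics` | trace linking, `V_Py` fits, the `P_yc` changepoint fit (grid-profiled hinge + bootstrap CI), pairwise expansion and `H`, normalized coordinates |
| `wallmark.bernoulli` | the shift map (exact rational orbits), population distribution evolution, observed-pair comparison |
| `wallmark.pipeline` / `wallmark.cli` | reproducible end-to-end runs with manifests; `wallmark` console command |

## Worked example

```
$ printf 'preset: LB\nn_motors: 15\nlocalization_sigma: 0.02\nrng_seed: 5\n' > sim.yaml
$ wallmark run --config sim.yaml --out demo --generations 1
wrote 14 outputs to demo
$ python -c "import json; print(json.load(open('demo/inert_zone.json')))"
{'P_yc_um': 0.25651281450720664, 'k_per_min': 0.021535601571284767, ...
 'ci95_P_yc_um': [0.23651281450720663, 0.27953781450720666], 'n_motors': 15}
$ head -3 demo/hubble.csv
cell_id,time_min,H_per_min,stderr,n_pairs
0,0,0.0101378035,0.000582215311,55
0,10,0.0118639637,0.000488963152,66
```

The fitted inert zone (0.257 µm, 95% CI [0.237, 0.280] from 15 noisy
landmarks) brackets the generator's ground truth of 0.27 µm; the expansion
rate per unit length rises from 0.0101/min at t = 0 to 0.0119/min one frame
later, reflecting the accelerating growth law `H(t) = H0(1 + βt)`. The
shift-map orbit of the worked example:

```
$ wallmark bernoulli --start 0.1 --generations 4
+0.1 -> -0.3 -> -0.1 -> +0.3 -> +0.1
```

a period-4 cycle, computed in exact rational arithmetic.

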