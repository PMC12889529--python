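# gridsep

Are a grid cell's position tuning and velocity tuning separable?

Grid cells in medial entorhinal cortex fire in a hexagonal lattice of
spatial fields.  If running velocity merely rescales that map — a gain —
the joint tuning over position and velocity factorizes,

    r(x, y, vx, vy) = f_pos(x, y) · f_vel(vx, vy),

and position coding is velocity-invariant.  If instead fields shift,
appear or disappear depending on velocity, the code is irreducibly 4D.
Testing this is hard because a freely foraging animal samples the
30 × 30 × 5 × 5 = 22,500 position-by-velocity bins very unevenly.

`gridsep` implements the full analysis for systems neuroscientists:

- **Binning** of trajectory + spike-count sessions into 4D tuning curves
  (5-cm position bins over a 1.5 m × 1.5 m arena, 10-cm/s velocity bins
  over ±25 cm/s, 50-cm/s artifact cutoff, 10-visit occupancy threshold).
- **`GPTuningModel`** — Gaussian-process regression (Matérn ν = 5/2,
  per-dimension lengthscales, occupancy-aware heteroscedastic noise) that
  estimates the tuning curve at *every* bin, visited or not, with
  predictive uncertainty; 5-fold cross-validated fraction of variance
  explained (FVE = 1 − Var(residual)/Var(held-out)).
- **`SeparableTuningModel`** — the nonnegative rank-1 alternative
  f_pos ⊗ f_vel, fitted by curvature-preconditioned projected gradient
  descent on exactly the same train/validation splits.
- **Non-separability statistics** — ΔFVE = FVE_GP − FVE_sep, and SDCS,
  the standard deviation across velocity bins of the cosine similarity
  c(i, j) between each velocity bin's position map and the
  velocity-marginalised map; SDCS = 0 for separable tuning.  Each cell's
  SDCS is calibrated against a null model: spikes regenerated from the
  cell's zero-velocity position map along the same trajectory.
- **Grid properties** — autocorrelogram-based grid score and grid scale.
- **A synthetic generator** — Ornstein–Uhlenbeck foraging trajectories
  and conjunctive grid cells with controllable (non-)separability
  (`none`, `gain`, `shift`, `dropout` modulations), so the whole chain is
  testable without recordings.

Both model classes follow the familiar model/results pattern:
`Model(data, ...).fit()` returns a results object with estimates,
per-fold scores and a `summary()`.

## Worked example

Simulate a 30-minute session with one velocity-lagged ("shift") grid
cell — position fields displaced by lag × velocity, a non-separable
ground truth — and run the per-cell analysis:

```python
import numpy as np
from gridsep import (GridCellSpec, PipelineConfig, simulate_session,
                     analyze_session)

cells = [GridCellSpec(grid_scale=50.0, peak_rate=15.0,
                      modulation="shift", modulation_params={"lag": 0.25})]
session = simulate_session(cells, duration=1800.0, seed=42)
config = PipelineConfig(seed=42, n_null=20,
                        hyper_train_bins=500, gp_maxiter=40)
report, results = analyze_session(session, config)
print(report[["fve_gp", "fve_sep", "delta_fve", "sdcs_single",
              "null_quantile", "grid_score", "grid_scale",
              "data_density"]].round(4).to_string(index=False))
```

```
 fve_gp  fve_sep  delta_fve  sdcs_single  null_quantile  grid_score  grid_scale  data_density
 0.3059   0.1335     0.1725       0.0175            1.0      1.3789     50.9854        0.4249
```

Reading the row: the GP explains 31% of held-out bin-rate variance and
the separable model 13%, so ΔFVE ≈ 0.17 of the variance reflects a
position × velocity interaction — as built in.  (Held-out targets are
noisy 10-ms bin rates, so even the true rate function cannot reach
FVE = 1; the comparison between models is the point.)  The cell's SDCS
exceeds all 20 null replicates (quantile 1.0), so it is flagged
non-separable — the velocity dependence of its position map cannot be
explained by estimation noise on a velocity-invariant map.  Grid score
1.38 and scale 51 cm recover the generator's hexagonal geometry (50 cm).
Detection degrades with coverage: at 42% of the 22,500 bins visited the
effect is already visible, while 5x shorter sessions miss it for some
cells (see the acceptance experiments).

The same pipeline runs from the shell:

```sh
gridsep simulate --duration 1800 --n-cells 3 --modulation shift \
    --seed 42 --out session.h5
gridsep analyze --session session.h5 --seed 42 --out results/
```

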