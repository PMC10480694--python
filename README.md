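# rollcall

Quantifying **handedness (behavioural lateralization)** in plunge-diving
seabirds from body-mounted tri-axial accelerometers.

Plunge-diving birds such as gannets roll to one side in the seconds
before striking the water. Given raw 50 Hz acceleration traces
(x = surge, y = sway, z = heave, in g), `rollcall`

1. **detects plunge dives** where the 2-s running mean of surge drops
   below 0 g while its 2-s running sample SD exceeds 1.4 g;
2. **extracts the pre-dive roll**: roll is estimated from the static
   acceleration vector as `atan2(y, sqrt(x² + z²))·180/π` (negative =
   left), and each dive is scored by the mean roll over the 5 s before
   the detected start;
3. **scores lateralization per bird** with the lateralization index
   `LI = (Rd − Ld)/(Rd + Ld)` over right- and left-roll dive counts,
   classifying `LI > 0.25` as right-biased, `LI < −0.25` as left-biased
   and `|LI| ≤ 0.25` as non-lateralized, plus population summaries,
   Wilcoxon rank-sum group comparisons and Cohen's-h power analysis;
4. **estimates repeatability** (intraclass correlation)
   `R = σ²_group / (σ²_id + σ²_date + σ²_resid)` of dive direction
   (logit GLMM, Laplace approximation, latent-scale residual π²/3) and
   of roll intensity (Gaussian REML) with crossed random intercepts for
   bird and calendar day, an optional handedness-class fixed effect,
   parametric-bootstrap CIs, permutation p-values and
   boundary-corrected likelihood-ratio tests.

A fully ground-truthed synthetic-data generator produces both per-dive
records drawn from the latent model and raw 50 Hz traces with injected
plunges, so every stage is testable end-to-end without field data.

Intended users: movement ecologists and biologgers analysing
accelerometer deployments, and behavioural ecologists estimating
repeatability of lateralized behaviour.

## Worked example

Run the whole pipeline on a simulated 12-bird study (the library API;
the `rollcall` CLI exposes the same stages as subcommands):

```python
from rollcall.config import PipelineConfig
from rollcall.pipeline import run_pipeline

cfg = PipelineConfig.model_validate({
    "input": {"simulate": {"n_birds": 12, "days_per_bird": (2, 3),
                            "dives_per_bird_day": 8.0, "seed": 7}},
    "repeatability": {"n_boot": 100, "n_perm": 199, "seed": 1},
})
report = run_pipeline(cfg)
```

This prints (via the summary fields of `report`):

```
n_dives 254 counts {'left': 4, 'right': 6, 'neither': 2} pct {'left': 33, 'right': 50, 'neither': 17}
direction R_id=0.735 R_date=0.087 se=0.117 ci=(0.438, 0.870) p_perm=0.005
angle R_id=0.709 R_date=0.000 se=0.099 ci=(0.465, 0.843) p_perm=0.005
angle_laterality_state R_id=0.730 R_date=0.000 se=0.113 ci=(0.442, 0.861) p_perm=0.005
```

Reading: 254 dives were detected and side-scored; 4 of 12 birds were
left-biased, 6 right-biased, 2 non-lateralized. Dive direction is
strongly repeatable among individuals (R = 0.74; permutation p = 1/200,
the smallest attainable at 199 permutations), the day effect is weak
(R_date = 0.09), and roll intensity is repeatable (R = 0.71) and stays
so after controlling for each bird's handedness class (R = 0.73) —
individuals differ consistently in *how far* they roll, not just in
which side they favour.

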