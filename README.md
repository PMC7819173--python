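# particokin

Particokinetics of inhaled nanoparticle aerosols: aerosol size-distribution
metrics, lung-burden processing, and pulmonary clearance-kinetics fitting,
with an end-to-end study simulator.

## The problem

Subacute (28-day) rodent inhalation studies of nanomaterials measure lung
burdens at a handful of post-exposure observation days (typically PEO-1,
PEO-7 and PEO-28) to characterise how fast deposited particles leave the
lung.  Biopersistent particles (e.g. gold nanoparticles) clear mechanically,
via alveolar macrophages and the mucociliary escalator, and follow
first-order kinetics; biosoluble particles (e.g. silver nanoparticles)
additionally dissolve, producing a fast clearance phase on top of the slow
mechanical one.  `particokin` implements the complete analysis chain for such
studies:

1. **Aerosol metrics** — from binned mobility-sizer number-size
   distributions: total number concentration `N`, count median diameter
   `CMD`, geometric standard deviation `GSD`, and the Hatch–Choate moment
   conversions

   `S = N π CMD² exp(2 ln²GSD)`   (surface, nm²/cm³)
   `V = N (π/6) CMD³ exp(4.5 ln²GSD)`   (volume, nm³/cm³)

   plus the density-scaled mass concentration `ρV` in µg/m³.
2. **Lung burdens** — spiked-standard calibration (recovery % =
   100·measured/spiked, OLS curve inversion), LOD/LOQ censoring, whole-lung
   burden = tissue concentration (ng/g) × lung weight (g), group mean ± SE
   tables, retention as a percent of the PEO-1 mean, and
   co-exposure/single-exposure burden ratios against the 0.5 null.
3. **Clearance kinetics** — scikit-learn-style estimators for

   `M(t) = P₁ e^(−λ₁t)`   and   `M(t) = P₁ e^(−λ₁t) + P₂ e^(−λ₂t)`,  `P₁+P₂=1`

   with half-times `T½ = ln 2 / λ`.  With only three retention timepoints
   the unconstrained biexponential is underdetermined, so the fast fraction
   `P₁` can be fixed; an independent bracketing solver
   (`exact_constrained_solve`) cross-checks the least-squares path.
4. **Simulation** — intermittent exposure (6 h/day, 5 days/week, 4 weeks),
   two-pool first-order clearance with exact mass balance, multiplicative
   lognormal sampling noise, and parameter-recovery experiments.

## Worked example

Fit the two-phase model to mean silver retention fractions (1.000, 0.694,
0.450 at 0, 6 and 27 days since PEO-1) with the fast fraction fixed at 1/3:

```python
import numpy as np
from particokin import TwoPhaseClearance, OnePhaseClearance

t = np.array([0.0, 6.0, 27.0])
ag = TwoPhaseClearance(fast_fraction=1/3).fit(t, [1.000, 0.694, 0.450])
print(ag.summary())
```

```
{'model': 'two-phase', 'p1': 0.3333333333333333, 'p2': 0.6666666666666667,
 'lambda1': 0.2311409082403979, 'lambda2': 0.014610622458542078,
 'half_time_fast_d': 2.9988078953079054, 'half_time_slow_d': 47.44131761167355,
 'sse': 1.5407439555097887e-32}
```

A third of the silver burden clears with a ~3.0-day half-time (dissolution)
and two thirds with a ~47.4-day half-time (mechanical clearance); the zero
residual shows the constrained model passes exactly through the three mean
points.  The same gold series fit one-phase
(`OnePhaseClearance().fit(t, [1.000, 0.901, 0.785])`) gives a single
half-time of 83.1 days — biopersistent-particle behaviour in the normal
physiological 60–90-day range for rats.

The same is available from the shell:

```bash
particokin fit retention.csv --model two-phase --fix-fast-fraction 0.3333
particokin aerosol summarize --density 19.32 aerosol.csv
particokin run --config src/particokin/data/demo_study.yaml
```

`particokin run` regenerates the full report bundle (aerosol summary,
burden/retention/ratio tables, kinetics table, provenance record) from raw
CSVs or from a seeded synthetic study; reruns are byte-identical.

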