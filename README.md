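# fetalatlas

Spatiotemporal (3D + gestational age) brain atlas construction and
multi-atlas segmentation, with a synthetic growth-phantom cohort generator
that makes the whole pipeline testable end to end without any imaging
data.

## The problem

A developing (fetal) brain changes shape and size week by week, so a
single population template cannot represent it.  Given a cohort of
volumetric images $I_i$ with gestational ages $t_i$ (weeks), this package
estimates an age-continuous, *unbiased* template $\hat I(\cdot, t)$: at a
query age $t$, subjects are weighted by a Gaussian kernel in age,

$$w_i \propto K(t - t_i) = e^{-(t-t_i)^2 / 2\sigma^2},\qquad \sigma = 1\ \text{week},$$

(raw weights at or below 0.01 are dropped, the rest normalized to sum to
one), and the template and the subject-to-template diffeomorphisms $h_i$
jointly minimize the weighted sum of registration energies
$\sum_i w_i\,[E(I(t), I_i, h_i) + \lVert L v_i \rVert^2]$, where each
$h_i$ is the unit-time flow of a stationary velocity field $v_i$ and $E$
is a local cross-correlation cost.  The estimate alternates symmetric
diffeomorphic registration, kernel-weighted velocity averaging, and an
unbiasing template update until the mean transform converges; at the
solution the weighted mean subject-to-template deformation is identity.
Labeled atlas timepoints then segment new subjects by label propagation
and probabilistic STAPLE fusion, including the two-pass bootstrapping
strategy that reuses a cohort's initial segmentations as additional
atlases.

See `docs/methods.md` for the model, the numerical choices, and what the
phantoms do and do not establish.

## Worked example

```python
from fetalatlas.phantom import GrowthPhantomSpec, make_cohort
from fetalatlas.atlas import build_atlas

spec = GrowthPhantomSpec()                       # 48^3 voxels, 1 mm, ages 19-39 wk
cohort = make_cohort(spec, 12, seed=1, age_range=(25.0, 35.0))
tp = build_atlas(cohort, t=30.0, sigma=1.0, cutoff=0.01,
                 max_iters=15, tol=0.05)
print("retained subjects:", len(tp.weights.subject_ids))
print("iterations:", tp.iterations_run)
print("residual history:", [round(r, 3) for r in tp.residual_history])
```

prints

```
retained subjects: 7
iterations: 3
residual history: [0.097, 0.067, 0.007]
```

Seven of the twelve subjects fall inside the kernel support at 30 weeks
(|age difference| below about 3 weeks); the mean-transform update drops
below the 0.05-voxel tolerance after three outer iterations, echoing the
expected fast convergence of the unbiased estimation, and `tp.template`
holds the 30-week template with the per-subject transforms in
`tp.per_subject`.

The same workflow is available from the shell:

```sh
fetalatlas simulate --n 12 --seed 1 --age-min 25 --age-max 35 --out cohort/
fetalatlas build-atlas --manifest cohort/cohort.csv --age 30 --out atlas_t30/
fetalatlas run --seed 7 --out demo_run/     # full simulate/build/segment/evaluate demo
```

`fetalatlas run` writes `report.json` (kernel weights, residual
histories, per-structure Dice scores); reruns with the same seed
reproduce it bit for bit.

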