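# hpatoggle

Simulation and phase-plane analysis of a bistable HPA–CNS toggle-switch
model of major depressive disorder (MDD).

## The scientific problem

Major depression correlates strongly with hyperactivity of the
hypothalamic–pituitary–adrenal (HPA) stress axis: elevated cortisol,
enlarged adrenal glands, a blunted ACTH response in the CRH stimulation
test, and an elevated ACTH response in the DEX/CRH test.  Classic HPA
models operate on the scale of hours and cannot address the weeks-long
dynamics of depressive episodes or of antidepressant onset.

This package implements a model in which the weeks timescale comes from
the slow turnover of the hormone-secreting **functional gland masses** —
pituitary corticotrophs `P` (growth factor: CRH) and adrenal cortex `A`
(growth factor: ACTH) — coupled to a lumped **CNS inhibitory activity**
`h` (hippocampus / prefrontal cortex) that suppresses the hypothalamic
stress drive and is itself suppressed by cortisol acting through the
glucocorticoid receptor (GR).  Mutual inhibition between `A` and `h` forms
a toggle switch with two stable states: *euthymic* (low `A`, high `h`) and
*depressed* (high `A`, low `h`, high cortisol).

## The model

Fast hormone dynamics (CRH `x1`, ACTH `x2`, cortisol `x3`; all normalized
to a baseline of 1; stress input `u`, treatment factor `D ≥ 1`):

    dx1/dt = a1 u / (h MR(x3) GR(x3)) − b1 x1      (full)
    dx1/dt = a1 u / (h x3) − b1 x1                 (simplified: KMR ≪ x3 ≪ KGR)
    dx2/dt = a2 x1 P / GR(x3) − b2 x2              (pituitary: GR only)
    dx3/dt = a3 x2 A − b3 x3

with `MR(x) = 1 + x/KMR` and `GR(x) = 1 + (x/KGR)^3`.  Slow dynamics:

    dP/dt = aP P x1 − bP P
    dA/dt = aA A x2 − bA A
    dh/dt = ah D / (a + b Θ(x3 > T)) − bh h

The step `Θ` models the cooperative (Hill ≈ 3) GR response of the CNS:
below the cortisol threshold `T` the CNS is inhibited by a factor `a`
(MR only), above it by `a + b`.  On the slow timescale the hormones sit at
quasi-steady state, `x3 = sqrt((a1 a2 a3)/(b1 b2 b3) · A P u / h)`, and
with the pituitary at its cortisol-independent steady size the model
reduces to a 2-D `(A, h)` phase plane whose nullclines cross one to three
times.  Integral feedback in the gland equations pins steady-state CRH and
ACTH at `bP/aP` and `bA/aA` regardless of stress — the glands, and hence
cortisol (`x3 ∝ u/h`), absorb the input instead.

The package provides:

* closed-form fixed-point enumeration with stability, basins, and the
  separatrix (`hpatoggle.phase`);
* fold-change-to-bifurcation sensitivity scans and the stress hysteresis
  thresholds `u1 > u2` (euthymic state lost above `u1`, depressed state
  lost only below `u2`);
* stiff event-detecting integration of the 6-D model, the 3-D slow
  quasi-steady-state subsystem, and the 2-D phase plane
  (`hpatoggle.model`, `hpatoggle.qss`);
* scenario runners for brief/prolonged stress, stress relief and
  CNS-enhancing treatment, and in-silico CRH and DEX/CRH endocrine tests
  on control and MDD subjects (`hpatoggle.scenarios`);
* a `hpatoggle` command-line interface with YAML configs, presets, and
  figure regeneration.

## Worked example

```python
>>> import hpatoggle as ht
>>> p = ht.ModelParameters()          # nominal parameter set
>>> for fp in ht.find_fixed_points(u=1.0, D=1.0, params=p): print(fp)
FixedPoint(A=1.0, h=1.0, x3=1.0, branch='euthymic', stability='stable')
FixedPoint(A=1.5, h=0.6666666666666666, x3=1.5, branch='threshold', stability='unstable')
FixedPoint(A=2.0, h=0.5, x3=2.0, branch='depressed', stability='stable')

>>> ht.bifurcation_foldchange("u", "increase", 1.0, p).critical_fold_change
1.498779296875
>>> h = ht.hysteresis_scan((0.4, 2.0), p); (h.u1, h.u2)
(1.5, 0.75)
>>> ht.run_stress_scenario(1.0, 2.0, 5.0, 60.0, 160.0, p)[1]
'depressed'
>>> c, m = ht.make_subject("control", 1.0, p), ht.make_subject("MDD", 1.0, p)
>>> ht.crh_test(c, 5.0, p).peak_acth, ht.crh_test(m, 5.0, p).peak_acth
(3.443..., 3.303...)      # MDD response blunted
>>> ht.dex_crh_test(c, 15.0, 5.0, p).peak_acth, ht.dex_crh_test(m, 15.0, 5.0, p).peak_acth
(0.1044..., 0.1160...)    # MDD response elevated under DEX
```

Reading: at baseline stress the system is bistable — a healthy state with
normalized adrenal mass 1 and a self-sustaining depressed state with a
doubled adrenal and doubled cortisol, separated by a saddle at the CNS
threshold.  Raising stress 1.5-fold destroys the healthy state; a 60-day
stress episode (but not a 3-day one) carries the system across the
separatrix so that depression persists after the stressor is gone, and
recovery requires dropping stress below `u2 = 0.75 < 1`.  The enlarged MDD
glands reproduce the clinical endocrine-test signatures with a fully
normal GR pathway.

Command-line equivalents:

    hpatoggle fixed-points --u 1.0
    hpatoggle bifurcation --param u --direction increase
    hpatoggle hysteresis
    hpatoggle scenario --kind stress --level 2 --duration 60 --out stress.csv
    hpatoggle crh-test --subject mdd --dose 5
    hpatoggle figures --which all --out figs/

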