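# boneadapt

Participant-specific modeling of trabecular bone adaptation from
longitudinal 3D images, built around a curvature-driven level-set model of
the bone surface.

Serial high-resolution peripheral QCT (HR-pQCT) scans show *that* someone's
trabecular bone changed — during disuse, microgravity, aging, or recovery —
but not the rule it changed by. This package implements the full loop for
testing such a rule on an individual: a **forward solver** that evolves a
binary bone volume under the speed law

    φ_t + F|∇φ| = 0,        F = a − b·κ,

where the bone surface is the zero level of a signed-distance embedding φ,
`a` (μm/day) is a uniform advection (formation/resorption) rate, and `b`
(μm²/day) weights the local mean curvature κ — the term that preferentially
erodes thin, highly curved struts; an **inverse solver** that recovers the
participant-specific parameters θ = (a, b) from two scans and the days
between them, by least-squares initialization, a staged band-residual
refinement, and Adam descent on the non-overlap cost
J(θ) = |predict(θ) XOR target| / |target|; **3D bone morphometry** (static:
Tb.BV/TV, Tb.Th, Tb.Sp, Tb.N; dynamic from formation/resorption overlays:
BFR, BRR, MAR, MRR, MS, ES; agreement: Dice, mean symmetric surface
distance); a **synthetic-cohort generator** (Gaussian-random-field
trabecular surrogates, analytic phantoms, forward-generated longitudinal
series with known ground truth); and the **short-/long-term prediction
experiments** with exclusion bookkeeping and summary statistics.

It is aimed at researchers in bone image analysis who want to test
adaptation models against serial scans — or against synthetic cohorts when,
as is common, the clinical images cannot be shared.

## Worked example

Recover the adaptation parameters of a synthetic "participant" whose
six-month change was generated by the model itself:

```python
from boneadapt import ModelParams, adam_fit, grf_structure, simulate

baseline = grf_structure((64, 64, 64), spacing=61.0, target_bvtv=25.0,
                         correlation_length=260.0, seed=3)
truth = ModelParams(a=-0.30, b=200.0)          # net resorption, curvature-driven
followup, _ = simulate(baseline, truth, duration=90.0)

fit = adam_fit(baseline, followup, duration=90.0)
print(f"a = {fit.params.a:.3f} um/day   b = {fit.params.b:.1f} um^2/day")
print(f"converged={fit.converged}  accepted={fit.accepted}  "
      f"symmetric distance = {fit.symmetric_distance_at_fit:.1f} um")
```

Output:

```
a = -0.299 um/day   b = 200.1 um^2/day
converged=True  accepted=True  symmetric distance = 0.1 um
```

The fitted advection rate (−0.299 μm/day ≈ −109 μm/year of uniform surface
resorption) and curvature constant match the generating values to well
under the scanner's voxel size; `accepted` means the fitted prediction lies
within one voxel (61 μm mean symmetric surface distance) of the observed
follow-up — the same rule the study pipeline uses to reject unreliable
fits.

The same loop from the shell:

```sh
boneadapt cohort --outdir cohort/ --reduced --seed 1
boneadapt experiment --cohort cohort/ --mode short --out results/
boneadapt simulate --input vol0.mha --a -0.3 --b 200 --days 90 --out pred.mha
boneadapt fit --baseline vol0.mha --followup vol1.mha --days 90 --out fit.json
boneadapt morph --binary vol1.mha --out morph.csv
boneadapt overlay --baseline vol0.mha --followup vol1.mha --days 90 \
    --out ov.mha --table dyn.csv
```

See `docs/methods.md` for the model, discretization, fit strategy, what
the synthetic cohorts do and do not emulate, and known limitations.

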