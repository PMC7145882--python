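# bonestrain

**bonestrain** computes a vertebral *Bone Strain Index* (BSI) from lumbar
DXA scans and provides the survival-analysis toolkit used to evaluate such
indexes as predictors of vertebral refracture.  It is aimed at researchers
in osteoporosis imaging and bone biomechanics who want an open, testable
implementation of the DXA-based finite-element strain score, and at
biostatisticians analysing refracture cohorts.

## The model

A lumbar DXA scan is an areal bone-mineral-density map, BMD(x, y) in g/cm².
Each vertebral body is segmented as an iso-contour of the BMD field and
filled with a constrained Delaunay triangulation (Ruppert refinement,
minimum interior angle ≥ 20°).  The vertebra is treated as a thin
plane-stress slab of uniform thickness *t*: each 3-node constant-strain
triangle gets an elastic modulus from the local BMD through a power law

    E = max(E_floor, E_ref · (BMD / BMD_ref)^γ),      default E_ref = 8000 MPa
                                                      at BMD_ref = 1 g/cm², γ = 2

and the patient-specific compressive load

    F_level = a_level · W · g · m_level · (h / h_ref)

(trunk-mass fraction a, lever multiplier m, weight W, height h) is applied
as a uniform vertical pressure on the upper endplate while the lower
endplate is fixed.  Solving K u = f gives the element strain tensors
ε = B u; the scalar per element is the von Mises equivalent strain ε_eq.
The scores are

    BSI_vertebra = k_BSI · Σ_e ε_eq,e A_e / Σ_e A_e        (area-weighted mean)
    BSI_lumbar   = area-weighted mean of the vertebral scores

so a higher BSI means more strain under the patient's own load, i.e. a
mechanically weaker spine.

The survival side implements the refracture endpoint (a one-unit increase of
the Spine Deformity Index, the sum of semiquantitative 0–3 deformity grades
over T4–L4), the Kaplan–Meier product-limit estimator with Greenwood errors,
Cox proportional-hazards regression (Newton–Raphson on the partial
likelihood; Breslow or Efron ties), the Grambsch–Therneau proportionality
test, and Schoenfeld's event-count power formula.

Because clinical DXA scans and refracture cohorts are not freely
distributable, the `phantom` module generates vertebra-shaped BMD images and
synthetic longitudinal cohorts calibrated to published descriptive
statistics, so the entire pipeline runs and is tested without any data
download.

## Worked example

```bash
# 1. synthesize a 4-vertebra DXA phantom and a 143-patient cohort
bonestrain phantom --seed 7 --outdir p1

# 2. scan-to-score for a 70 kg, 170 cm patient
bonestrain compute --image p1/image.csv --weight 70 --height 170 --outdir b1
```

which prints

```
{
  "L1": 5.234796178812163,
  "L2": 5.464475736672434,
  "L3": 5.815050942758064,
  "L4": 6.164340988590438
}
lumbar BSI: 5.670
```

Scores rise from L1 to L4 because the supported trunk mass grows caudally;
all four are in the middle of the clinically reported lumbar range (≈ 2.5–9.4
with mean ≈ 5).  `b1/` also contains one strain-map PNG per vertebra
(blue → green → yellow → red with increasing strain) and the meshes in a
plain-text format.

```bash
# 3. survival analysis of the synthetic cohort
bonestrain cohort --cohort p1/cohort.csv --outdir s1
```

reports, per covariate, the per-unit hazard ratio with 95% CI, Wald p value
and proportionality-test p value, e.g. for this seed

```
bsi: HR 1.281 [1.043-1.573] p=0.0184 PH p=0.024
bmd: HR 0.578 [0.082-4.095] p=0.5832 PH p=0.682
tbs: HR 1.473 [0.087-24.839] p=0.7882 PH p=0.275
```

(the default synthetic cohort has *null* covariate effects, so hazard ratios
fluctuate around 1 from seed to seed), plus the Kaplan–Meier table and a
plot with the unreliable tail — fewer than 20% of patients still at risk —
shaded.

The same functionality is available as a library: see
`bonestrain.compute_patient_bsi`, `bonestrain.cox_fit`,
`bonestrain.km_estimate`, `bonestrain.power_schoenfeld`.

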