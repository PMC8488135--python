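# lvfusion

Fusion analysis of left-ventricular (LV) surface models from 3D
echocardiography and cardiac MR (CMR).

3D echo and CMR both produce endocardial and epicardial LV surface
models, but in unrelated scanner coordinate systems and with systematic
shape discrepancies — echo tends to underestimate the cavity, worst at
the anterolateral wall where trabeculae and signal dropout obscure the
boundary. `lvfusion` quantifies those discrepancies on a common footing:

1. **Cardiac coordinate frames** from fiducial landmarks: the long axis
   connects the basal to the apical centroid; the right-ventricular (RV)
   direction orients the model about that axis. CMR supplies both RV
   insertion points; on echo only the inferior insertion is usually
   visible, so the RV centroid is taken 70° clockwise from it (viewed
   from apex to base).
2. **Rigid registration** per cardiac phase (ED and ES independently,
   since the transducer can move between acquisitions): coarse frame
   alignment followed by iterative-closest-point (ICP) refinement with a
   closed-form SVD update, or an explicit manual override transform.
3. **Common-template re-fitting**: each surface is re-fitted by linear
   least squares to a radial field r(u, φ) on a periodic grid with a
   second-difference smoothness penalty, giving node-wise correspondence
   between modalities.
4. **Regional analysis** on the AHA 16-segment endocardial / 17-segment
   epicardial partition, with the per-segment mean surface distance

   MSD_seg = (1/N_p) Σ_p ‖M_p − E_p‖

   over corresponding template nodes M_p (CMR) and E_p (echo).
5. **Global indices**: EDV, ESV, EF = 100·(EDV−ESV)/EDV, LV mass
   (shell volume × 1.05 g/ml), all indexable by body surface area.
6. **Signal-intensity mapping**: per-image normalization between 0 and
   the 95th percentile, then mean relative intensity per AHA segment
   over the myocardial shell — quantifying anterior echo dropout.
7. **Agreement statistics**: paired t-tests with Bonferroni-corrected
   significance (two-tailed P < 0.0167 for three methods), the two-way
   absolute-agreement average-measure intraclass correlation ICC(A,k),
   and Bland-Altman limits of agreement in both the classical two-method
   form and the multi-method (difference-to-subject-mean) form.

Human imaging data cannot ship with the package, so a first-class
synthetic module (`lvfusion.phantom`) generates truncated-ellipsoid
phantom cohorts with analytically known landmarks, misalignments,
regional deformations, volumes and intensity structure; every pipeline
stage is validated against that ground truth.

## Worked example

Simulate a 3-subject cohort with three echo "methods" per subject and
run the full pipeline:

```sh
lvfusion simulate --n-subjects 3 --seed 11 --out-dir cohort/
lvfusion fuse cohort/subj000 --method echoA
```

The `fuse` step prints, per phase, the registration residual and the
recovered pose (here the phantom was misaligned by a known transform):

```
ED: rms=1.9424 mm iters=3 converged=True rot=1.791 deg trans=2.673 mm
ES: rms=1.9086 mm iters=6 converged=True rot=4.726 deg trans=5.412 mm
```

The ED and ES transforms differ because the phantom was misaligned by a
different ground-truth transform per phase; the residual RMS reflects
the regional deformation built into the echo copies.

A full run writes the report tables:

```sh
echo '{"cohort_dir": "cohort", "out_dir": "out", "seed": 11}' > cfg.json
lvfusion run cfg.json
lvfusion stats out/volumetrics.csv --index edv
```

```
edv echoA-cmr: bias -7.97 ± 4.46 (p=0.0903), ICC(A,k)=0.972, LoA [-16.70, 0.77]
edv echoB-cmr: bias -6.45 ± 1.43 (p=0.0159*), ICC(A,k)=0.986, LoA [-9.24, -3.65]
edv echoC-cmr: bias -8.17 ± 2.51 (p=0.0301), ICC(A,k)=0.977, LoA [-13.09, -3.25]
edv multi-method: symmetric LoA ±4.05, biases echoA -0.44, echoB +1.08, echoC -0.64
```

Reading this: each echo method underestimates the CMR end-diastolic
volume (negative bias, as the phantoms carry an inward anterolateral
deformation emulating echo behaviour); the starred comparison is
significant at the Bonferroni-corrected threshold P < 0.0167; ICC(A,k)
measures absolute agreement between the method pair; and the
multi-method line gives each method's bias from the per-subject mean of
all three, with symmetric 95% limits of agreement. Per-segment mean
surface distances land in `out/msd.csv` (16 endocardial + 17 epicardial
rows per subject/phase/method) — on these phantoms the largest MSD sits
in segment 6 (basal anterolateral), where the deformation was placed.

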