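# paareg

Rigid registration of 3-D medical volumes by the principal-axis
algorithm, with a resting-state ALFF pipeline and two-group cohort
statistics — plus synthetic-data generators for every input, so the
whole chain runs and validates without any scanner data.

## The problem

Head images of the same subject acquired at different times differ by a
rigid motion: three translations and three rotations,
`q = (l1, l2, l3, m4, m5, m6)`.  Iterative intensity-based registration
can recover `q` but is local — started far from the truth it converges
to the wrong optimum.  The principal-axis algorithm (PAA) avoids that:
the intensity-weighted centroid

    x_c = Σ x·p(x,y,z) / Σ p(x,y,z)   (and likewise y_c, z_c)

and the eigenvectors of the second-moment (inertia) matrix `H` of each
image give its position and orientation directly, so matching centroids
and principal axes yields the full rigid transform

    T = T(center) · T(l) · Mx(m4) · My(m5) · Mz(m6) · T(−center)

in closed form, in a single step.  The package implements this
estimator, the four-fold eigenvector sign disambiguation it needs, an
optional Powell refinement of an intensity metric (NCC, MSE, or mutual
information) started from the closed-form estimate, and an exhaustive
grid-search oracle to validate against.

Downstream of registration, resting-state fMRI studies compare the
amplitude of low-frequency fluctuation (ALFF) — the mean single-sided
spectral amplitude of each voxel's BOLD signal inside 0.01–0.08 Hz —
across brain regions between a patient and a control group, and
correlate region ALFF with a cognitive scale score (0–30).  The `alff`
and `group_stats` modules implement that analysis (detrend → FFT →
in-band amplitude → ROI means; Welch t / ANOVA F per region; Pearson r
with the score), and `synthetic_data` simulates cohorts with known
effect sizes and correlations to calibrate it.

See `docs/methods.md` for conventions, numerical choices and
limitations.

## Worked example

`examples/register_phantom.py` builds the standard 64³ asymmetric
phantom, moves it by a known motion plus 5% noise, and registers the
pair:

```
known truth: l = (+4.00, -3.00, +2.00) mm, angles = (+8.00, -12.00, +15.00) deg
       PAA: l = (+4.06, -2.89, +1.91) mm, angles = (+1.00, -10.19, +15.36) deg | max err 0.111 mm / 6.998 deg | NCC 0.9650
   refined: l = (+4.01, -3.00, +2.00) mm, angles = (+7.94, -12.00, +14.91) deg | max err 0.008 mm / 0.090 deg | NCC 0.9901
closed-form PAA used 1 iteration; refinement used 501 metric evaluations.
```

The closed-form step lands within a tenth of a millimetre in
translation and a few degrees in rotation despite the noise; one local
refinement pass started there reaches 0.008 mm / 0.09°.  NCC is the
normalized cross-correlation between the reference and the aligned
floating image (1.0 = perfect; 0.99 here is the noise ceiling).

The other examples run the ALFF pipeline on a simulated BOLD series
(`examples/alff_pipeline.py`) and the cohort statistics on a simulated
107-patient / 51-control study (`examples/cohort_statistics.py`), each
printing the quantities it computes and what they mean.

A thin CLI wraps the same library:

```bash
paareg simulate pair --out sim --seed 1
paareg register sim/reference.nii.gz sim/floating.nii.gz --out t.txt
paareg evaluate sim/reference.nii.gz sim/floating.nii.gz --transform t.txt
paareg alff bold.nii.gz --labels roi.nii.gz --table roi.csv
paareg stats cohort.csv --out stats.csv
```

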