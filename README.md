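# briqa

No-reference (blind) quality scoring for structural brain MRI slices, aimed
at post-acquisition quality control in multi-centre neuroimaging studies,
where data from different scanners, sites and protocols must be compared on
one standardized scale.

## The metric

A brain MRI slice is treated as a two-tissue-class image: a bright,
high-edge-density class (cortical gray matter and the boundaries between
anatomical structures) over a dark class (white matter and everything
else), on an air background. An observed slice `I_d` is modelled as a
degraded version of an underlying ideal two-valued image `I_f`:

    I_d = H I_f + n

with `H` a blur/bias operator and `n` random noise. The pipeline:

1. **Foreground extraction** — segment the head from the air background;
   `n_t` is the number of foreground pixels.
2. **Rescaling** — min-max map the slice to [0, 1]; this is the grayscale
   feature image `I_d`.
3. **Contrast feature** — a local range filter (window max − min; width 3,
   5 or 7 chosen from the image size) gives the contrast feature image
   `I_c`. First moments `μ_d`, `μ_c` are means over the foreground.
4. **Binarisation** — four binary feature images by global thresholding:
   FGMG = (I_d > μ_d), FCMG = (I_d > μ_c), FCMC = (I_c > μ_c),
   FGMC = (I_c > μ_d).
5. **Structural matching** — four attribute scores:
   * `q1` luminance contrast: edge-pixel matching of (FGMG, FCMG),
   * `q2` texture: edge-pixel matching of (FGMC, FCMC),
   * `q3` texture contrast: pixel-wise agreement of (FGMC, FCMC) / `n_t`,
   * `q4` lightness: pixel-wise agreement of (FGMG, FCMG) / `n_t`.
6. **Total score** — `Q = 0.1 q1 + 0.1 q2 + 0.7 q3 + 0.1 q4`, in [0, 1].

For an ideal undistorted image `I_d = I_c = I_f` and `μ_d = μ_c`, so the
pixel-wise scores are exactly 1; degradations drive the two moments apart
and the score down. At the volume level the mean `Q` over slices is
compared against a sequence-specific cut-off (0.40 for T1, 0.45 for T2).

The package also ships the three degradation models used to exercise the
metric (pillbox blur, linear motion blur, Rician noise, each with levels
1–15, plus a synthetic multiplicative bias field), a two-tissue-class
phantom generator with ground-truth masks, and a Spearman rank-correlation
utility for validation against observer scores.

## Worked example

```python
from briqa import PhantomSpec, generate, score_slice, circular_blur

slc, fg, labels = generate(PhantomSpec(seed=0))   # 256x256 synthetic slice
print(score_slice(slc))
# QualityReport(q1=0.134, q2=0.608, q3=0.998, q4=0.868, Q=0.859,
#               n_t=34610, mu_d=0.223, mu_c=0.179, window=3)

print(score_slice(circular_blur(slc, 10)))        # pillbox blur, radius 10
# QualityReport(q1=0.0, q2=0.0, q3=0.622, q4=0.426, Q=0.478,
#               n_t=39588, mu_d=0.329, mu_c=0.052, window=3)
```

The clean phantom sits near the ideal regime (`μ_d ≈ μ_c`, `q3 ≈ 1`,
`Q ≈ 0.86`). Blurring erodes the contrast feature: `μ_c` collapses, the
binary pairs diverge, and the total drops below the T2 cut-off of 0.45 —
the slice's volume would be flagged for review.

The same pipeline runs from the shell:

```
briqa phantom --seed 0 --n-slices 14 --out vol.nii.gz
briqa score vol.nii.gz --sequence T2 --csv-out scores.csv --json-out summary.json
briqa degrade vol.nii.gz --kind rician_noise --level 10 --seed 1 --out noisy.nii.gz
```

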