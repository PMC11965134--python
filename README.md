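# maddwi

Multimodal apparent diffusion (MAD) analysis of multi-b-value
diffusion-weighted MRI, built for discriminating low- from high-grade
clear cell renal cell carcinoma (ccRCC) — and for anyone who needs a
tested, reproducible implementation of four-compartment DWI decomposition
with the downstream biomarker statistics.

A single apparent diffusion coefficient cannot capture tumor
heterogeneity. The MAD model decomposes the normalized signal decay across
b-values from 0 to 3000 s/mm² into four water populations:

    S(b)/S(0) = f_r·e^(−D_r·b) + f_h·e^(−D_h·b^α_h) + f_ui·e^(−D_ui·b) + f_f·e^(−D_f·b)

restricted (D_r < 0.2 µm²/ms), hindered (0.2 ≤ D_h ≤ 3 µm²/ms, stretched
by the heterogeneity exponent α_h), unimpeded (D_ui = 3 µm²/ms, fixed) and
flow (D_f > 3 µm²/ms), with volume fractions summing to one. The package
provides:

* `maddwi.model` — the MAD and mono-exponential forward models, unit
  conventions, validated parameter types;
* `maddwi.fitting` — voxel-wise constrained multistart least squares for
  the MAD parameters plus log-linear ADC, over whole NIfTI volumes;
* `maddwi.synthetic` — phantom and cohort generators with Rician noise,
  NEX averaging, published group distributions, and stored ground truth;
* `maddwi.roi` — ROI means, two-reader merging, per-subject records;
* `maddwi.group_stats` — normality-gated t / Mann-Whitney comparison,
  Cohen's d, clinical characteristics tables;
* `maddwi.classification` — ROC with DeLong 95% CIs and Youden operating
  points, and the combined logistic marker D_h + f_r + α_h;
* `maddwi.io` / `maddwi` CLI — NIfTI/b-table/CSV formats and the
  end-to-end pipeline with a reproducibility manifest.

## Worked example

Simulate a cohort at the study's group sizes (30 low-grade, 24 high-grade
subjects), compare groups, and evaluate the markers:

```
maddwi run --out demo --seed 1
```

prints the group-comparison table (abridged):

```
parameter          low_summary         high_summary         test      p_value  cohens_d  significant
      D_h        1.358 ± 0.087        1.231 ± 0.105            t 1.048900e-05  1.336262         True
      f_r        0.060 ± 0.010        0.081 ± 0.010            t 2.577799e-10  2.137873         True
  alpha_h 0.799 (0.679, 1.023) 0.841 (0.636, 1.140) mann-whitney 7.606435e-01  0.087729        False
      ADC        0.928 ± 0.072        0.841 ± 0.054            t 9.226078e-06  1.346365         True
```

Each row summarizes one parameter per group (mean ± SD when the
normality/variance gate selects the t-test, median and quartiles when it
routes to Mann-Whitney), the two-sided p-value and the pooled-SD Cohen's
d. Here the restricted fraction f_r separates the grades most strongly
(d ≈ 2.1): high-grade tumors are more cellular, so more water is
restricted. The diagnostic table follows:

```
           name  sensitivity  specificity  accuracy      auc   ci_low  ci_high
            D_h     0.625000     0.933333  0.796296 0.831944 0.723049  0.94084
            f_r     0.916667     0.900000  0.907407 0.937500 0.872233  1.00000
            ADC     0.875000     0.700000  0.777778 0.838889 0.733128  0.94465
D_h+f_r+alpha_h     1.000000     0.866667  0.925926 0.970833 0.935020  1.00000
```

One row per marker at its Youden-optimal threshold, with the trapezoid AUC
and DeLong 95% interval; the last row is the in-sample combined logistic
model, which dominates every single marker. (These are synthetic-cohort
numbers for seed 1; the generator draws subjects from the published group
distributions, so values vary by seed.)

Fitting real data instead:

```
maddwi fit --dwi dwi.nii.gz --btable bvals.txt --mask tumor.nii.gz --out maps/
maddwi roi-stats --maps-dir maps/ --roi reader1.nii.gz --roi reader2.nii.gz \
       --subject P001 --grade high --out cohort.csv
maddwi run --mode real --labels cohort.csv --out results/
```

`bvals.txt` is one whitespace-separated line of b-values in s/mm²; an
optional `bvals.txt.nex` sibling carries per-b averaging counts.

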