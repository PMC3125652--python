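# basalmorph

Quantitative morphometry of the basal cell layer in oral mucosa.

Histological grading of oral epithelial dysplasia — the gold standard for
predicting malignant transformation of lesions such as leukoplakia — is
notoriously subjective.  Computer-aided morphometry replaces part of that
judgement with numbers: trace the outline of each basal keratinocyte and
its nucleus, measure size in calibrated physical units, and test whether
the measurements separate diagnostic groups.  `basalmorph` implements that
pipeline end to end for pathologists and image-analysis researchers:

* **measurement** — per-object cell/nuclear area (µm²) and perimeter (µm)
  from co-registered integer label masks, via sub-pixel iso-contours and a
  stage-micrometer-style µm/pixel calibration;
* **descriptors** — form perimeter `form PE = 4πA/P²` (1 for a circle),
  contour index `CI = P/√A` (2√π ≈ 3.54 for a circle), and the
  nuclear–cytoplasmic ratio `N:C = NA/(CA − NA)`;
* **group statistics** — descriptive summaries with t-based 95% CIs,
  one-way ANOVA with full sum-of-squares decomposition, pooled two-sample
  Student t, Mann–Whitney U (normal approximation, tie-corrected) and
  Kruskal–Wallis H, computed on per-case records;
* **synthetic histology** — a seeded generator of label-mask fields
  (star-convex cells with nested nuclei, group-specific size and
  boundary-irregularity distributions) with exact polygon ground truth, so
  the whole pipeline is testable without any external data.

A 70-case reference cohort (10 normal buccal mucosa, 30 leukoplakia, 30
well-differentiated squamous cell carcinoma; per-case mean basal-cell
measurements) ships with the package and drives the worked example below.

## Worked example

```python
>>> from basalmorph import load_reference_cohort, derive_descriptors
>>> from basalmorph.stats import run_full_comparison
>>> records = load_reference_cohort()
>>> derive_descriptors(records[0])        # leukoplakia case L01
ShapeDescriptors(cellular_form_pe=0.6215..., nuclear_form_pe=0.6451...,
                 cellular_ci=4.4966..., nuclear_ci=4.4136..., nc_ratio=1.0059...)
>>> report = run_full_comparison(records)
>>> round(report.anova["nuclear_area"].f_ratio, 3)
193.505
>>> [round(t.statistic, 3) for t in report.t_tests["nuclear_area"]]
[13.509, 20.875, 8.402]
```

The nuclear-area ANOVA (F = 193.5 on df 2, 67, P < 0.0001) says the three
groups differ strongly in mean nuclear area; the pairwise pooled t values
(leukoplakia vs normal 13.51, SCC vs normal 20.88, leukoplakia vs SCC
8.40, all at P < 0.0001) say *every* pair differs — size separates not
just lesion from normal but premalignant from malignant.  The shape
descriptors and N:C ratio behave differently: rank tests give
|Z| ≈ 4.5 (P < 0.0001) against normal mucosa but only |Z| ≈ 1.33
(P ≈ 0.18) between leukoplakia and SCC, so boundary irregularity and
nuclear crowding mark the departure from normality without grading the
lesion.

The same analysis from the shell, plus the synthetic route:

```sh
basalmorph analyze --fixture reference --out report/
basalmorph simulate --seed 123 --out masks/      # render label masks
basalmorph measure  --masks masks/ --out meas/   # masks -> per-case CSV
basalmorph analyze  --csv meas/measurements.csv --out report_syn/
```

The numbered scripts under `analysis/` run the same stages as a narrative
pipeline (01 reference-cohort statistics, 02 simulate, 03 measure,
04 synthetic statistics with parameter-recovery checks), writing tables to
`results/`.

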