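# y90agree

Inter-observer reproducibility analysis for post-treatment ⁹⁰Y PET/CT
dosimetry in liver radioembolization (SIRT).

## The problem

After a SIRT procedure, the mean absorbed dose to the tumor (TD, Gy) and to
the non-tumoral liver (THLD, Gy) are estimated from the ⁹⁰Y PET/CT by
manually delineating the tumor(s) and the whole liver — tumor volume TV,
total liver volume TLV, healthy-liver volume THLV = TLV − TV.  Different
readers draw different contours, so the doses that drive clinical decisions
(tumor efficacy target TD > 200 Gy; liver safety targets THLD < 50 Gy or
< 75 Gy) carry inter-observer variability.  This package quantifies that
variability with the standard multi-reader agreement battery, and — because
real multi-reader dosimetry datasets are rarely shareable — ships two
synthetic data sources with known ground truth:

* a **cohort simulator**: per quantity, log readings follow
  `log x_ij = μ + B_i + b_j + E_ij` with between-treatment spread
  `B_i ~ N(0, σ_b²)`, fixed observer bias `b_j`, and inter-observer error
  `E_ij ~ N(0, σ_w²)`;
* a **voxel phantom pipeline**: ellipsoidal liver + tumor activity maps on a
  4 mm grid, local-deposition dosimetry
  (`dose = K · activity / voxel mass`, K = E·T½/ln 2 ≈ 49.4 J/GBq for ⁹⁰Y),
  and morphological perturbation of the masks emulating each observer's
  contouring.

## The statistics

For an `n treatments × k observers` matrix of one quantity:

* **ICC(A,1)** — two-way random-effects, absolute-agreement, single-rater
  intraclass correlation from the mean squares of the treatments × observers
  layout, with the F-based 95% CI; computed pairwise and for all observers.
* **CV** — root-mean-square within-pair coefficient of variation:
  `CV = 100·sqrt(mean_i (s_i/m_i)²)` with `s_i = |x_i − y_i|/√2`,
  `m_i = (x_i + y_i)/2`.
* **Bland–Altman** — bias and limits of agreement at bias ± 2·SD of the
  per-treatment differences.
* **RDC** — reproducibility coefficient: the maximum ratio between any two
  observers' readings of the same treatment in 95% of cases,
  `RDC = exp(q₀.₉₅(k) · σ̂_w)` with `σ̂_w` the one-way variance-component
  estimate of the log-scale observer SD and `q₀.₉₅(k)` the 95th percentile
  of the range of k iid standard normals (3.3145 for k = 3); 95% CI by
  bootstrap over treatments.
* **Location tests** — Shapiro–Wilk gate per observer column; paired t +
  two-way ANOVA when all columns pass, Wilcoxon signed-rank + Friedman
  otherwise.
* **Concordance** — fraction of treatments classified differently by the
  observers under each dose-target rule (strict inequalities).

## Worked example

```python
from y90agree import RunConfig, run_pipeline

report = run_pipeline(RunConfig(mode="table", n_treatments=25, seed=1))
td = report["quantities"]["TD"]
print(td["rdc"]["estimate"], td["icc"]["A|B|C"]["estimate"])
```

With the default calibration (25 treatments, 3 observers, seed 1) the
report contains:

| quantity | 3-way ICC (95% CI) | pairwise CV (%) | RDC (95% CI) |
|----------|--------------------|-----------------|--------------|
| TLV (ml) | 0.994 (0.988–0.997) | 2.1 / 2.0 / 2.1 | 1.07 (1.06–1.08) |
| THLD (Gy)| 0.985 (0.971–0.993) | 5.5 / 4.5 / 4.6 | 1.18 (1.14–1.21) |
| TV (ml)  | 0.888 (0.797–0.944) | 16.1 / 18.7 / 18.7 | 1.83 (1.60–2.07) |
| TD (Gy)  | 0.837 (0.715–0.918) | 12.2 / 12.4 / 15.4 | 1.57 (1.40–1.79) |

and 2/25 treatments discordant at TD > 200 Gy, 2/25 at THLD < 50 Gy, 0/25
at THLD < 75 Gy.  The pattern — whole-liver quantities nearly perfectly
reproducible, tumor quantities markedly less so — is the clinically
important finding the battery is designed to expose: an RDC of 1.57 for TD
means two readers of the same scan can differ by a factor 1.57 in tumor
dose in the worst 5% of cases.

The same pipeline runs from the shell:

```sh
y90agree simulate --out cohort.csv --seed 1
y90agree analyze cohort.csv --out-dir analysis
y90agree all --mode phantom --out-dir phantom_run --seed 1
```

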