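# dipyrone-pd

Pharmacodynamic analysis of single-dose dipyrone (metamizole) effects on
piglet hemorheology: baseline-vs-effect AUEC ratios, a composite
hemorheological index linked to the 4-methylaminoantipyrine (4MAA)
metabolite, leave-one-out (LOO) model validation, and a calibrated
synthetic-cohort generator.

## The problem

Dipyrone is hydrolysed rapidly to the active metabolites 4MAA and 4AA, and
has documented effects on blood cells and coagulation. In a single-dose
study design, eight piglets receive 100 mg/kg I.M. at t = 0; a panel of
hemorheological parameters (WBC, RBC, Hb, Hct, MCV, MCH, Plt, PT, APTT,
APTT ratio, fibrinogen, ...) is sampled over a baseline window
[−36, 0] h and a post-dose window (0, 72] h. This package implements the
analysis of such a study for pharmacology/biostatistics users:

* **Effect size.** Per animal, the area under the effect curve (AUEC) is
  computed by the linear trapezoid over the baseline window
  (B, −36…0 h) and the effect window (A, 0…72 h). The cohort-level change
  ratio normalises time-averaged levels:

  ```
  A/B ratio = (B/36 − A/72) / (B/36)
  ```

  positive when the parameter *fell* after dosing. Significance is the
  paired Student *t* test on the per-animal differences A/72 − B/36;
  between-animal variability is RSD% = 100·SD/mean, pooled per window.

* **Composite index.** `PT + (Hb + Hct)/RBC^APTT_ratio` (and the linear
  variant `MCV + PT`) condenses the red-cell/coagulation state into one
  time series that can be regressed on metabolite concentration.

* **Model validation.** The index↔concentration model y = b₀ + b₁x is
  validated by leave-one-out: PRESS = Σ(yᵢ − ŷᵢ⁽⁻ⁱ⁾)², Q² = 1 − PRESS/SS,
  the asymptotic Q²asym = 1 − (1 − R²)·((n−1)/(n−2))², and the
  four-criterion gate **0 < Q²asym − Q² < 1, Q² ≥ 0.65, R² ≥ 0.85,
  Q² − R² < 0**. Only a model passing all four is called fully predictive.

* **Synthetic cohort.** Because no raw per-animal data are distributed,
  `dipyrone_pd.cohort` generates study-shaped datasets: lognormal
  between-animal baselines, multiplicative effect templates calibrated to
  the published dynamic ranges and effect timings (e.g. Hb 12.35→9.14 g/dL
  sustained; platelets peak at 10 h, recover by 24 h), residual noise
  within the published RSD% ranges, and catenary first-order 4MAA/4AA
  kinetics.

## Worked example

```bash
python analysis/01_simulate_cohort.py     # -> results/cohort.csv
python analysis/02_effect_table.py        # -> results/effect_table.csv
python analysis/04_loo_validation.py      # -> results/validation_4MAA.txt
```

At seed 0 the effect table ends with:

```
significant at p < 0.05: APTT, APTT_ratio, Hb, Hct, MCH, MCV, PT, RBC, WBC
```

— the nine parameters whose templates carry real effects are detected, while
the null MCHC template and the transient platelet/fibrinogen effects (which
average out over 72 h) are not. A typical Hb row shows
`ab_ratio ≈ 0.24, p < 0.0001`: the time-averaged hemoglobin fell by ~24 %
relative to baseline. The LOO step prints, per analyte,

```
4MAA: Q2=0.4042 R2=0.5457 Q2asym-Q2=0.0626 PRESS=417.32 SS=700.48 -> passed=False
```

i.e. each statistic plus the gate verdict (this synthetic run does not pass —
see `docs/methods.md` on what the generator does and does not emulate).

The same stages are available as a CLI
(`dipyrone-pd simulate|auec|index|validate|run`), e.g.
`dipyrone-pd run --seed 0 --out results/run/` for the full pipeline with a
combined JSON report.

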