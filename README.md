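# mammotherm

Analysis pipeline for menstrual-cycle breast thermometry: from per-minute
evening breast-surface recordings to synchronized cycle series, cosinor
rhythm parameters, luteal-phase group comparisons and tumour prognostic
scoring.

## The problem

Deep breast temperature, read non-invasively once a surface sensor has
equilibrated with the underlying tissue, tracks mammary vascularity: blood
flow to the breast ebbs and flows over the menstrual cycle, rising through
the luteal phase to a peak just before menses. Peri-operative luteal
vascularity differs between pre-menopausal breast cancer patients who
survive long-term and those who die of disseminated disease, making it a
candidate prognostic variable. This package reimplements that analysis as a
tested, reusable pipeline for anyone working with daily thermometric series
anchored to a physiological event:

1. **Plateau extraction** — each evening's per-minute recording is smoothed
   and scanned for the maximal run where the slope magnitude stays within
   tolerance for a minimum duration; the warmest such run is the day's
   *peak plateau* deep-breast temperature.
2. **Vascularity index** — breast minus oral temperature (°C) removes each
   woman's hypothalamic set point; more negative = cooler = less vascular.
3. **Backwards synchronization** — cycles of 19–39 d are aligned by
   counting back from menses onset (day +1; preceding days −1 … −28),
   exploiting the comparatively constant 12–14 d luteal phase. There is no
   day 0: −1 and +1 are adjacent.
4. **Cosinor rhythmometry** — a fixed 28 d cosine
   `y(t) = M + A·cos(2π(t − φ)/τ) + e` is fitted by least squares via the
   linearized regressors cos(ωt), sin(ωt), giving MESOR *M*, amplitude *A*,
   acrophase *φ* (days after menses onset) and a zero-amplitude F test.
5. **Group statistics** — the 11 cross-subject daily means of cycle days
   −11 … −1 are compared between groups with two-tailed pooled-variance
   t-tests; tumours are scored with the Nottingham Prognostic Index
   `NPI = 0.2·size(cm) + grade + nodal stage`.

A calibrated synthetic-cohort generator (`mammotherm.simulate`) produces
daily series and per-minute traces with the statistical structure the
analysis assumes, so the entire pipeline is testable without any data
download. Small reference tables from the originating clinical follow-up
study (luteal daily group means; pathology and follow-up for 36 cancer
cases) ship with the package (`mammotherm.datasets`).

## Worked example

```python
from mammotherm import (load_reference_luteal_daily_means, luteal_stats,
                        pooled_t_test, npi, SimConfig, simulate_cohort,
                        sync_backwards, fit_group_rhythms, acrophase_diff)

ref = load_reference_luteal_daily_means()
for g in ("non-survivor", "control", "survivor"):
    ls = luteal_stats(ref[g], g)
    print(f"{g:>13}: luteal mean {ls.overall_mean:+.2f} C (SD {ls.overall_sd:.2f}, {ls.n_days} days)")
for a, b in [("non-survivor", "survivor"), ("control", "survivor"), ("non-survivor", "control")]:
    t = pooled_t_test(ref[a], ref[b], a, b)
    print(f"{a} vs {b}: diff {t.mean_difference:+.3f} C, t={t.t_stat:.2f}, df={t.df:.0f}, p={t.p_two_tailed:.4f}")
print(f"NPI(15 mm, grade 2, 1 node) = {npi(15, 2, 1):.2f}")
```

prints

```
 non-survivor: luteal mean -1.24 C (SD 0.11, 11 days)
      control: luteal mean -1.42 C (SD 0.09, 11 days)
     survivor: luteal mean -1.65 C (SD 0.23, 11 days)
non-survivor vs survivor: diff +0.405 C, t=5.26, df=20, p=0.0000
control vs survivor: diff +0.226 C, t=3.06, df=20, p=0.0062
non-survivor vs control: diff +0.178 C, t=4.05, df=20, p=0.0006
NPI(15 mm, grade 2, 1 node) = 4.30
```

Survivors' breasts are luteally *hypo*-vascular (−1.65 °C below oral) and
non-survivors *hyper*-vascular (−1.24 °C) relative to healthy controls
(−1.42 °C); all pairwise differences are significant. Running a synthetic
cohort end to end recovers the generator's rhythm structure:

```python
cohort = simulate_cohort(SimConfig(seed=1))
synced = [sync_backwards(s) for s in cohort.subjects]
fits, _ = fit_group_rhythms(synced)
for g, f in fits.items():
    print(f"{g:>13}: MESOR {f.mesor:+.2f} C, amplitude {f.amplitude:.2f} C, "
          f"acrophase day {f.acrophase_days_after_onset:.1f}, p_rhythm={f.p_zero_amplitude:.2g}")
```

```
      control: MESOR -1.51 C, amplitude 0.28 C, acrophase day 26.6, p_rhythm=2.2e-39
     survivor: MESOR -1.86 C, amplitude 0.34 C, acrophase day 21.3, p_rhythm=2.6e-73
 non-survivor: MESOR -1.45 C, amplitude 0.31 C, acrophase day 20.0, p_rhythm=1.5e-56
```

The cancer-group rhythms peak about 5–7 days earlier than the control
rhythm (phase advance), as configured in the generator.

A `mammotherm` console script exposes the stages
(`simulate`, `extract`, `sync`, `cosinor`, `compare`, `npi`, `run-all`);
`mammotherm run-all --seed 7 --out-dir out/` writes the full CSV report
bundle plus a run manifest.

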