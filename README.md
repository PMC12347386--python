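# hodvh

DVH-based dosimetric and radiobiological evaluation of single-fraction
heterotopic-ossification (HO) prophylaxis plans.

Prophylactic irradiation of the hip after arthroplasty — a single 7 Gy
fraction — is routinely planned on a water-equivalent density model
("inhomogeneity correction off", IC-off). Recalculating the same monitor
units with the correction enabled (IC-on) reveals how bone, metal and soft
tissue actually redistribute the dose. `hodvh` is a toolkit for quantifying
that difference at the cohort level, for medical physicists and
radiotherapy researchers:

* **DVH handling** — plain-text cumulative DVH tables in and out,
  cumulative ↔ differential conversion, paired-cohort manifests.
* **Dosimetric indices** — D2%, D50%, D90%, D95%, D98% by linear
  interpolation on the cumulative curve; HI = (D2 − D98)/D50 (ICRU 83);
  GI = V50%/V100% (ICRU 91).
* **Radiobiological indices** — gEUD = (Σ vᵢDᵢᵃ)^(1/a) (a = 1 → mean
  dose); the linear–quadratic EUD, the non-negative root E of
  αE + (β/n)E² = −ln Σ vᵢ·exp(−αDᵢ − βDᵢ²/n), at α/β = 3 and 10 Gy; and
  EQD2 = D·(d + α/β)/(2 + α/β) for each EUD with d = EUD/n.
* **Cohort statistics** — mean ± SD with z-based 95% CIs, Shapiro–Wilk
  normality with the classical critical-value table, skewness, and an
  *exact* paired Wilcoxon signed-rank test (full null distribution for up
  to 25 non-zero differences, midrank ties, effect size r = |z|/√m).
* **Monte Carlo resampling** — 10,000 normal draws per index and arm from
  the cohort (mean, SD), histogram exports and below-threshold fractions
  (e.g. mass under the 7 Gy prophylactic dose).
* **Synthetic paired cohort** — a calibrated logistic-DVH generator that
  reproduces the reference 21-patient per-arm index summaries, so the whole
  pipeline runs with no patient data.

## Worked example

Run the full study on the default synthetic cohort (21 paired plans):

```bash
hodvh run-all --seed 2 --out study/
```

which prints the cohort comparison tables, e.g. (abridged):

```
Dosimetric indices
------------------
Index           IC-off mean±SD (95% CI)           IC-on mean±SD (95% CI)                   p
D2              7.26 ± 0.16 (7.19–7.33)           7.26 ± 0.27 (7.15–7.37)             1.0000
D50             7.04 ± 0.15 (6.98–7.10)           6.86 ± 0.24 (6.76–6.96)             0.0000
D98             6.59 ± 0.15 (6.52–6.65)           6.06 ± 0.38 (5.90–6.22)             0.0000
HI              0.10 ± 0.03 (0.08–0.11)           0.17 ± 0.06 (0.15–0.20)             0.0001
GI              1.46 ± 0.35 (1.31–1.61)           2.82 ± 1.05 (2.37–3.27)             0.0000

Radiobiological indices
-----------------------
gEUD            7.02 ± 0.14 (6.96–7.08)           6.83 ± 0.23 (6.73–6.93)             0.0000
EQD2_gEUD_ab3   14.07 ± 0.47 (13.87–14.27)        13.42 ± 0.77 (13.09–13.76)          0.0000
EQD2_gEUD_ab10  9.96 ± 0.28 (9.84–10.07)          9.58 ± 0.46 (9.38–9.77)             0.0000
```

Reading it: the two plan variants deliver the same hot spot (D2, p = 1.0)
but the IC-on recalculation loses coverage everywhere else — the median
dose drops ~0.2 Gy, the cold end (D98) ~0.5 Gy, homogeneity degrades
(HI 0.10 → 0.17) while the dose gradient steepens (GI 1.46 → 2.82), and
the biologically weighted dose falls (gEUD 7.02 → 6.83 Gy; EQD2 at
α/β = 3 Gy from 14.07 to 13.42 Gy), with every coverage difference
significant on the exact paired Wilcoxon test. `study/` receives the
per-plan index panels, comparison tables (CSV + text), Monte Carlo
summaries/histograms for all 28 (index, arm) distributions, the emitted
synthetic cohort (DVH files + manifest), and a machine-readable
`summary.json` with a run log — byte-identical on rerun with the same seed.

The same stages are available individually (`hodvh synth`, `indices`,
`radbio`, `compare`, `mc`) and as library functions
(`hodvh.run_full_study`, `hodvh.compute_radbio_panel`, …). Add
`--calibrate` to re-tune the generator to the reference targets instead of
using the shipped near-calibrated defaults.

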