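# lysetrack

Automated, chromatography-based monitoring of microbial cell disruption by
high-pressure homogenization (HPH).

When an *E. coli* (or other microbial) suspension is forced through a
homogenizer valve, each pass releases a fraction of the intracellular
protein into the supernatant. A fast anion-exchange HPLC run of the
supernatant — UV absorbance at 280 nm, 5 min per sample, sampled at 5 Hz —
shows two peaks: the unbound **flowthrough (FT)** and the salt-eluted
**elution (EL)** material. The summed area under both peaks tracks total
soluble protein, so the per-cycle growth of that area measures disruption
efficiency at-line, without plating, staining or offline protein assays.

`lysetrack` implements the complete data pipeline around that idea:

* **Alignment** — every trace is shifted by an integer number of samples to
  maximize its Pearson correlation with the elementwise mean of all traces
  (whole-trace or per-interval, edge-replicated fill), correcting retention
  jitter before fixed integration windows are applied.
* **Integration** — composite trapezoid rule over half-open FT/EL windows
  `[start_s, end_s)`, with optional per-window linear baseline subtraction.
* **Recovery statistics** — the start-anchored relative recovery

  $$\mathrm{recovery}_i = \frac{AUC_i - AUC_{start}}{AUC_{end} - AUC_{start}} \cdot 100\,\%$$

  (0 % before homogenization, 100 % after the last cycle) and the
  end-anchored form $AUC_i / AUC_{end} \cdot 100\,\%$, which declares the
  final cycle 100 % total protein. Biomass is estimated from optical
  density via the linear correlation $y = 0.451\,x$ (g DCW/L per OD600).
* **Reference analytics** — reductions for four orthogonal assays
  (serial-dilution colony counts, flow-cytometry viable counts
  RH414 − DiBAC4(3), dual-frequency delta-capacitance, Bradford series)
  and a five-method comparison table: protein signals end-anchored,
  viability signals start-anchored.
* **Screening DoE** — a 3 × 3 × 4 full factorial over pressure
  (500–1500 bar), biomass (10–100 g DCW/L) and cycles (0–3), fitted by OLS
  on coded factors (intercept + main effects + two-factor interactions),
  with goodness of fit $R^2 = 1 - SSE/SS_{tot}$, goodness of prediction
  $Q^2 = 1 - PRESS/SS_{tot}$ (leave-one-out, leverage shortcut),
  per-term *t*-test p-values and contour-surface prediction.
* **Synthetic data** — a seeded simulator of two-peak chromatograms
  (Gaussian FT/EL peaks, baseline drift, white noise, integer retention
  jitter) driven by geometric-survival disruption kinetics
  $f(n) = f_0 + (1-f_0)\,(1-(1-e)^n)$, so the whole pipeline is testable
  without instrument data.

The two algorithmic cores are scikit-learn style estimators —
`ChromatogramAligner` (fit/transform) and `FactorialScreeningModel`
(fit/predict) — and compose with sklearn tooling; everything else is plain
functions over small dataclasses.

## Worked example

Simulate a five-cycle disruption experiment at 1500 bar (per-cycle
efficiency 0.85), then align, integrate and normalize it:

```sh
lysetrack simulate --out demo --seed 7
lysetrack recover --in demo --out demo/recovery.csv
```

`demo/recovery.csv` (rounded):

```
sample_id  cycle  auc_ft  auc_el  auc_total  recovery_eq2_pct  recovery_end_anchored_pct
   cycle0      0   29.54  113.62     143.16              0.00                      12.57
   cycle1      1  366.78  620.51     987.28             84.79                      86.70
   cycle2      2  419.01  698.79    1117.81             97.90                      98.17
   cycle3      3  427.36  711.50    1138.86            100.02                     100.01
   cycle4      4  427.31  713.13    1140.44            100.18                     100.15
   cycle5      5  427.77  710.93    1138.70            100.00                     100.00
```

Read: the untreated "0 sample" already carries ~13 % of the final protein
signal (baseline drift plus pre-released protein), the first pass releases
~87 % of the end-anchored total — one high-pressure cycle does almost all
of the work — and cycles 2–5 add only a few percent each, saturating at
100 % by construction of the end anchor. The start-anchored column is
pinned to 0 and 100 at the ends; interior values slightly above 100 %
reflect integration noise, not extra protein.

The same workflow pieces are available as a library:

```python
from lysetrack import (AlignmentConfig, DisruptionKinetics, SimConfig,
                       align_set, simulate_disruption_experiment,
                       RegionOfInterest, tabulate_recovery)

cset, truth = simulate_disruption_experiment(
    DisruptionKinetics(efficiency_per_cycle=0.85), 5, SimConfig(), seed=7)
aligned = align_set(cset, AlignmentConfig(max_shift_samples=10)).aligned
table = tabulate_recovery(aligned,
                          RegionOfInterest("FT", 20, 130),
                          RegionOfInterest("EL", 150, 300))
```

For the screening study, `lysetrack doe --table runs.csv --out-summary
summary.csv --out-contour contour.csv` fits the factorial model to a run
table (columns `pressure_bar`, `biomass_gdcw_per_l`, `cycles`,
`response`), prints `R2` and `Q2`, and writes the coefficient table and a
cycles × biomass contour matrix at a fixed pressure.

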