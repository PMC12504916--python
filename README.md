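# p31quant

Quantification of phosphorus-31 magnetic resonance spectra of skeletal
muscle, for studies that track neuromuscular disease (e.g. Becker muscular
dystrophy) with metabolic biomarkers. The package covers the whole chain
from complex free-induction decays (FIDs) — synthetic, with known ground
truth — to an analysis-ready biomarker table:

* **2D-CSI preprocessing**: Hann k-space filtering, voxel reconstruction
  with half-voxel grid shifts, conservative SNR estimation with strict
  SNR < 10 exclusion, automatic zero-/first-order phasing by entropy
  minimisation (ACME) with a peak-symmetry polish, 20 Hz Lorentzian
  apodisation, two-times zero-filling, PCr referencing, and frequency/phase
  alignment before averaging.
* **Prior-knowledge time-domain fitting** (AMARES-style): bounded nonlinear
  least squares on Σₖ Aₖ·e^{i(2πfₖt+φₖ)}·e^{−π·lwₖ·t} with quarter-sine
  weighting of the first 12 points (16 for the broad-PDE re-fit), shift
  windows, shared linewidth ratios, and a pH-coupled two-pool Pi model.
* **Biomarkers**:
  - intracellular pH from the Pi–PCr shift σ₁ via
    pH = 6.75 + log₁₀((3.27 − σ₁)/(σ₁ − 5.69)), and the amplitude-weighted
    pH of the two Pi pools, pH_wt = pH_a·Pi_a/Pi_tot + pH_b·Pi_b/Pi_tot;
  - free intracellular [Mg²⁺] by Newton inversion of the five-species
    Mg–ATP equilibrium model of the observed α−β ATP shift difference;
  - the T1-saturation-corrected PDE/γ-ATP ratio, a membrane-damage marker.
* **Staging**: Dixon fat fractions (SI_fat/(SI_fat+SI_water)·100 %,
  area-weighted across five slices) and categorisation of dystrophic
  muscles as preserved (≤ 13.5 %), progressing (13.5–81.5 %) or end-stage
  (≥ 81.5 %), with the thresholds re-derivable as the zero crossings of the
  lower uncertainty band of a fat-replacement progression fit.
* **Reporting**: median [IQR] per group and metric, Spearman correlations,
  and a QC exclusion ledger in which retained + excluded = total at every
  stage.

The synthetic-data module is first-class: it generates single FIDs, 8×10
CSI k-space grids, and three-group cohorts (CTRL / BMD_pre / BMD_prog)
whose ground-truth biomarker distributions default to published
control/patient group medians, so the entire pipeline is testable without
any scanner data.

## Worked example

```python
from p31quant.report import run_pipeline

config = {
    "groups": [{"group": "CTRL", "n_participants": 4}],  # 4 x 6 muscles
    "snr_threshold": 10.0,
}
result = run_pipeline(config, seed=11)
print(result.summary.group_stats)
print(result.ledger)
```

prints (one CPU, ~15 s)

```
  category    metric    median       iqr   n
0     CTRL        mg  0.734603  0.080497  24
1     CTRL     ph_wt  7.040089  0.041312  24
2     CTRL  pde_gatp  0.467998  0.231923  24
{'total': 24, 'low_snr': 0, 'artefact': 0, 'alignment_failure': 0,
 'fit_not_converged': 0, 'metric_failure': 0, 'end_stage_excluded': 0,
 'analyzed': 24}
```

Each row is the median [IQR] of a biomarker over the 24 simulated muscle
spectra after preprocessing, fitting and quantification: [Mg²⁺] in mM,
weighted pH (dimensionless), PDE/γ-ATP (dimensionless). With the default
control-group generator settings the medians scatter around the generating
values (0.72 mM, 7.05, 0.37) — at n = 24 the sampling noise of a median is
still visible (the PDE/γ-ATP ratio has generating IQR 0.18); the ledger
confirms that no spectrum was excluded. At the cohort sizes used for
validation (n = 200) the medians land within 0.005–0.02 of the generating
values.
`result.metrics_table` holds the per-muscle rows and
`result.manifest` the ground truth they should reproduce.

A command-line interface wraps the same calls:

```sh
p31quant simulate --config cohort.yaml --seed 7 --out signals/
p31quant run      --config study.yaml  --seed 7 --out results/
```

`run` writes `metrics.csv`, `manifest.csv`, `summary.json` and
`qc_ledger.csv`.

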