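# vwmprecision

Analysis pipeline for **delayed-reproduction visual working memory (VWM)
experiments** with orientation stimuli: circular-statistics precision
measures, a three-component von Mises mixture model of response error, a
synthetic age-structured cohort generator, and the cohort-level
developmental statistics, with a command-line interface.

## The scientific problem

In a delayed-reproduction task, a participant sees one or more oriented
bars, and after a delay rotates a probe bar to reproduce the orientation of
a probed item from memory. The response error — the angular deviation
between the response and the true orientation — carries far more
information than a correct/incorrect score. Two quantities are of central
interest in developmental work with school-aged children:

1. **Precision**: the reciprocal of the circular standard deviation of
   response error (Fisher's definition, `SD = sqrt(-2 ln R̄)`), corrected
   in two ways: a Monte Carlo estimate of the precision expected from
   uniform random responding is subtracted (so that guessing scores ~0),
   and sensorimotor (dial-adjustment) error variance measured in a
   perception-only control condition is removed by variance subtraction
   (`1 / sqrt(SD_vwm² − SD_sm²)`).
2. **Sources of error**: each response is modelled as a draw from a
   three-component mixture — a von Mises distribution centred on the
   **target** (probability α, concentration κ), a von Mises centred on a
   **non-target** item from the same trial (a misbinding/swap error,
   probability β), or a **uniform** guess (probability γ = 1 − α − β). The
   model is fitted per participant by maximum-likelihood
   expectation-maximization.

The package reproduces this analysis end to end for a study design with
three conditions per participant: 25 sensorimotor control trials, 30
one-item memory trials, and 90 three-item sequential memory trials
(coloured bars, probed by colour, equal probe probability over the three
serial positions, ≥0.175 rad minimum pairwise orientation separation).
Because no participant data are deposited for this design, the
`simulate` module generates synthetic cohorts (default: 87 children aged
7.9–13.6 years, IQ covariate weakly correlated with age, memory
concentration κ increasing linearly with age, constant mixture weights, a
×3 κ recency boost at the final serial position) so that every analysis
stage is testable and the developmental result pattern can be studied as a
parameter-recovery problem.

All angles are radians. Orientation is π-periodic; every dispersion
computation doubles angles onto the 2π circle first (the standard device
for axial data), and SDs/precisions are reported on that doubled scale.
See `docs/methods.md` for the model, estimation details, and the rationale
for every default.

## Worked example

```python
from vwmprecision import RunConfig, generate_dataset, run_pipeline
from vwmprecision.io import participants_to_frame

config = RunConfig()  # default synthetic cohort, seed 0
profiles, trials = generate_dataset(config.cohort)
result = run_pipeline(trials, participants_to_frame(profiles), config)

print(result.regressions.round(4).to_string(index=False))
print(result.param_regressions.round(4).to_string(index=False))
print({k: round(v, 4) for k, v in result.sp_anova.items()})
```

Output (exact, deterministic for seed 0):

```
               measure  n   slope  r2_adj      p
          precision_sm 84  1.1249  0.2801 0.0000
        precision_vwm1 85  0.3433  0.3087 0.0000
        precision_vwm3 87  0.0357  0.0885 0.0030
         precision_sp1 85  0.0350  0.0280 0.0679
         precision_sp2 85  0.0401  0.0402 0.0366
         precision_sp3 84  0.0494  0.0329 0.0538
   precision_diff_load 78 -0.0101 -0.0120 0.7708
precision_diff_recency 63  0.0994  0.0007 0.3109

  parameter  n   slope  r2_adj      p  partial_rho  partial_p
      kappa 85  0.9619  0.4802 0.0000       0.6850     0.0000
   p_target 86 -0.0000 -0.0119 0.9950      -0.0121     0.9122
p_nontarget 85 -0.0016 -0.0069 0.5175      -0.1025     0.3535
  p_uniform 87  0.0029 -0.0045 0.4358       0.1297     0.2339

{'F': 16.485, 'ddof1': 1.8981, 'ddof2': 149.9523, 'eps_gg': 0.9491, 'p': 0.0, 'n': 80}
```

This is the qualitative developmental result pattern the pipeline is
designed to measure: precision on both memory tasks improves significantly
with age; the mixture model attributes the improvement to memory
concentration κ (strongly age-dependent) while the target, non-target and
guess probabilities show no age effect; and the serial-position ANOVA
(Greenhouse–Geisser corrected) detects the recency advantage at the final
serial position.

## Command line

```bash
vwmprecision simulate --out data/ --seed 7          # cohort + trial tables
vwmprecision fit      --trials data/trials.csv --out fits.csv
vwmprecision analyze  --trials data/trials.csv \
                      --participants data/participants.csv --out results/
vwmprecision report   --results results/ --out figures/
```

Every run writes `provenance.json` (configuration SHA-256, master seed,
package version); all randomness flows from the single master seed, and
repeated runs are byte-identical. Configuration is YAML with strict
unknown-key rejection (`--config config.yaml`); see `RunConfig`,
`CohortConfig`, `FitConfig` and `AnalysisConfig` for every setting and its
default.

## Package layout

| Module | Contents |
| --- | --- |
| `vwmprecision.circular` | angular error, Fisher circular SD, chance-corrected precision, sensorimotor correction, precision differences |
| `vwmprecision.mixture` | von Mises density, mixture log-likelihood, EM fitter with restarts, grid-search oracle, mixture simulator |
| `vwmprecision.simulate` | cohort generator, trial generator, session truncation |
| `vwmprecision.pipeline` | per-participant measures, outlier rule, age regressions, partial correlations, serial-position ANOVA, histograms |
| `vwmprecision.io` / `cli` / `plots` | canonical table formats, YAML config, CLI, figures |
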