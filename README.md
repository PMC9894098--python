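# cellforge

Computational design of custom therapeutic cells that restore healthy
action-potential (AP) and calcium-transient (CaT) waveforms in failing human
cardiomyocytes through heterocellular electrotonic coupling.

The package couples an endocardial human ventricular cardiomyocyte model
(healthy, heart-failure remodeled, or heart-failure plus five fibroblasts at
1 nS) to a configurable "custom cell": an isopotential 40 pF membrane
carrying an arbitrary roster of ion channels drawn from c-kit+ cardiac
interstitial cells (hCIC), mesenchymal stem cells (hMSC), cardiac
fibroblasts (CF) and healthy cardiomyocytes (hCM), each with a searchable
conductance scaling.  A genetic algorithm searches channel scalings, the
gap-junction conductance and the coupled-cell count (1-5) for candidates
whose treated final-beat waveforms come within 50% normalized RMSE of the
healthy references for both AP and CaT.

## Layout

- `src/cellforge/cardiomyocyte` — ventricular cell right-hand side (ten
  Tusscher fast Na+ kinetics), parameter sets, HF remodeling factors.
- `src/cellforge/support_cells` — fibroblast model, the custom-cell channel
  library and roster presets.
- `src/cellforge/coupling` — coupled-system integrator (compiled fixed-step
  Rush-Larsen with a piecewise step-size schedule), a stiff adaptive (BDF)
  route used for cross-validation, final-beat extraction.
- `src/cellforge/metrics.py` — normalized RMSE objectives, acceptance rule,
  AP/CaT post-hoc metrics.
- `src/cellforge/ga` — selection / crossover / mutation / elitism operators
  and the GA driver.
- `src/cellforge/experiments` — named experiment presets, reference caching,
  the minimum-RMSE search for engineered hMSC/hCIC groups, and the CLI.
- `src/cellforge/data` — plain-text parameter files and 500-beat pre-paced
  steady states (JSON) used as fast-start points; reference runs can always
  be re-paced from scratch.

## CLI

```bash
# reduced-scale reproduction of a named experiment
cellforge run ical-ik1 --population 100 --generations 3 --seed 1 --out runs/ical-ik1

# engineered-cell searches (control groups run a budgeted grid search)
cellforge run hmsc-ik1 --budget 100 --seed 1 --out runs/hmsc-ik1

# reference waveforms (full 500-beat protocol with --from-scratch)
cellforge references hf+fibrosis --from-scratch

# summarize a stored bundle
cellforge report runs/ical-ik1
```

Paper-scale defaults (population 2500, 5 generations, 500 beats per
candidate) are recorded in every preset; `--population/--generations/--beats`
give desk-scale runs.  `--from-rest` paces every candidate the full 500
beats from rest instead of starting from the shipped untreated steady state.

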