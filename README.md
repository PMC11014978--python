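# rbtransit

Analysis pipeline for single-molecule measurements of RNA polymerase
transit through protein roadblocks, plus the six-state kinetic transit
model used to interpret them.

Stages:

1. **synthetic_data** — generates tether-extension traces with known ground
   truth: monotone transcription progress, short ubiquitous pauses, one
   roadblock pause drawn from the kinetic model, Gaussian noise, per-bead
   scale factors, NaN gaps, and observation-window censoring.
2. **kinetics_sim** — discrete-time Monte Carlo of the six-state transit
   model (backtracking `k1`, recovery `k2`, roadblock dissociation `k3`,
   dislodging probability `P1`), its closed-form pathway rates
   `k_passive = k3` and `k_active = k1/(1 + k1/k2)`, the
   passive/hybrid/active regime classifier, and a Michaelis–Menten GreA
   dependence of the recovery rate. A literal pseudocode reference
   implementation is kept alongside the fast kernel as an oracle.
3. **step_detection** — exact piecewise-constant fits minimizing
   `sum (y - yhat)^2 + lambda * sum |yhat_{i+1} - yhat_i|` (1-D fused
   lasso), solved by an O(n) message-clipping dynamic program; robust noise
   estimation and automatic penalty selection; NaN gaps split segments.
4. **trace_alignment** — dwell-time histograms and per-trace linear
   rescaling `S' = a*S + b` onto promoter / roadblock / terminator
   landmarks (`b = 0` by default).
5. **pause_analysis** — roadblock-pause extraction (±60 bp window, 20 s
   threshold, sub-step merging, optional sub-sample boundary refinement),
   Kaplan–Meier CCDFs, censored-exponential MLE with bootstrap CIs,
   two-exponential EM mixtures, AIC model choice, Wilson passage
   fractions.
6. **model_fitting** — condition-to-parameter mapping (assisting force
   disables backtracking; GreA acts only on `k2`; force magnitude has no
   effect), distribution-distance fitting with common random numbers,
   Welch adequacy t-tests, and qualitative regime reports.
7. **pipeline_io** — TSV/JSON formats, seeded run configuration, and the
   end-to-end pipeline.

## CLI

All stages are exposed under one entry point:

```sh
rbtransit simulate-pauses --k1 0.004 --k2 0.002 --k3 0.01 --p1 0.05 \
    --n 1000 --seed 1 --out pauses.tsv
rbtransit synth-traces --out-dir traces/ --n 10 --noise-sd 2 --seed 1
rbtransit detect-steps --in traces/cli_000.tsv --lambda auto --out stepped.tsv
rbtransit align --in stepped.tsv --geometry geometry.json --out aligned.tsv
rbtransit extract-pauses --in aligned.tsv --geometry geometry.json \
    --out records.tsv
rbtransit fit-exp --in records.tsv --model auto --out fit.json
rbtransit fit-model --obs pauses_by_condition.tsv --map conditions.json \
    --out model_fit.json
rbtransit run --out-dir demo_out --n-traces 8 --seed 0   # end to end
```

## Layout

```
src/rbtransit/      package (one module per stage + kernels, CLI)
tests/              pytest suite; test_acceptance.py holds the
                    acceptance criteria at stated tolerances
scripts/acceptance.py
```
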