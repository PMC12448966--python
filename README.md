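# sofnet

Computational phenotyping of long-term forgetting, and its prediction from
resting-state brain connectivity.

`sofnet` is for cognitive-neuroscience researchers who want to (a) estimate
an individual's **speed of forgetting** — the decay intercept φ of a
power-law trace-decay memory model — from adaptive paired-associate learning
data, and (b) relate that phenotype to 17-network resting-state functional
connectivity with a sparse linear model and a full validation battery.
Because datasets of this design are rarely deposited, the package also ships
a synthetic-study generator that reproduces the design end-to-end with known
ground truth, so every stage is testable.

## The model

Each studied item leaves episodic traces; trace *i*, created at time *tᵢ*,
decays as a power law, and the item's activation is

> *A*(*m*, *t*) = log Σᵢ (*t* − *tᵢ*)^(−*dᵢ*),  *dᵢ* = *c*·e^{*A*(*m*, *tᵢ*)} + φ,

with *c* = 0.25 and first-trace decay *d*₁ = φ. Retrieval probability is
logistic in activation, *P* = 1/(1 + e^(−*A*)), and response latency is
*T* = *t*₀ + *F*·e^(−*A*) (*t*₀ = 0.3 s, *F* = 1). A 12-minute adaptive
session re-tests each vocabulary item just before the model predicts it will
be forgotten, re-estimating φ from latencies after every test; a
participant's speed of forgetting (SoF) is the mean final φ over items
presented at least three times. Higher SoF ⇒ faster loss of memory
accessibility (e.g., with φ = 0.3 an unrehearsed item falls below 25%
retrieval probability within 10 minutes).

The connectivity stage computes 17×17 partial-correlation connectomes from
ROI time series, keeps the 45 edges anchored on the default-mode subnetworks
(3 within-DMN pairs + 3×14 edges to the other networks), and fits

> argmin_β (1/2*n*)‖**y** − β₀ − **X**β‖² + λ‖β‖₁,

with λ chosen by leave-one-out cross-validation. Validation includes LOO
prediction with refit weights on the fixed support, feature-removal re-runs,
variance inflation factors, a permutation null, and network-level summaries
(node importance = L1 norm of incident selected weights; a storage- vs.
retrieval-network contrast; sign-adjusted interpretable weights).

## Worked example

Run the numbered analysis scripts in order (they write under `results/`):

```bash
python analysis/01_simulate_cohort.py      # 33 learners + time series
python analysis/02_fit_phenotypes.py       # SoF estimation + fit metrics
python analysis/03_connectomes.py          # partial correlations + features
python analysis/04_predict_sof.py          # LASSO + validation battery
python analysis/05_network_importance.py   # network-level summaries
```

A run with the default seed prints, among other things:

```
trials per session: mean 158.6 (range 140–181)
true SoF: mean 0.306, sd 0.036
estimated SoF: mean 0.307, sd 0.036, range 0.219–0.386
recovery of generating SoF: r = 0.994 (n = 33)
fitted r = 0.998; LOO r = 0.975
removing the selected support and re-running the λ search ...
  -> intercept-only model
permutation null (200 shuffles): 55.5% intercept-only, 3.5% comparable fits,
empirical p = 0.0398
```

Reading: each simulated session produces a trial count inside the range
observed in real adaptive sessions; the grid re-fit recovers the generating
speeds of forgetting almost perfectly at low latency noise (r = 0.994); the
sparse model predicts held-out SoF from connectivity at r = 0.975; deleting
the selected edges leaves no alternative support (the λ search collapses to
the intercept-only model); and shuffling the phenotype destroys the fit in
all but ~4% of re-runs, so the association is not an artifact of the
selection procedure.

The library is importable directly — e.g.

```python
from sofnet import forgetting_curve
curve = forgetting_curve(phi=0.3, horizon=600, step=10)
print(round(float(curve["P"][-1]), 3))   # 0.128 — below 25% at 10 minutes
```

A command-line interface mirrors the scripts
(`sofnet simulate-cohort | fit-sof | connectome | predict | permtest |
importance | run-all`, each with `--seed/--out`).

## Layout

```
src/sofnet/        memory.py      trace-decay model (activation, decay, RT)
                   task.py        adaptive session engine + φ grid re-fit
                   phenotype.py   SoF aggregation, KL/χ² fit diagnostics
                   cohort.py      synthetic learners, cohorts, time series
                   connectome.py  Pearson/partial connectomes, 45 features
                   prediction.py  LASSO, LOO-CV, validation battery
                   netstats.py    importance, contrasts, signed weights
                   io.py/cli.py/pipeline.py   I/O, CLI, orchestration
analysis/          numbered narrative drivers (see worked example)
docs/methods.md    model, assumptions, parameters, design choices, limits
tests/             pytest suite incl. the acceptance battery
```
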