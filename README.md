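# poreptm

Nanopore ionic-current analysis of peptides bearing post-translational
modifications (PTMs): blockade-event detection, recurrent-network
classification with a rejection option, and capture-rate quantification.

## The problem

An aerolysin (K238A) nanopore held in a lipid membrane passes a stable
open-pore current I₀ (≈72 pA at +100 mV in 1 M KCl). When a single
C-terminal α-synuclein peptide is captured, the current drops to a residual
level for the dwell time of the translocation. Different PTMs
(phosphorylation p, nitration n, oxidation o at residues such as Y125, S129,
Y133, Y136) change both the relative current I/I₀ and the dwell time, so the
event shapes carry a per-peptide fingerprint — e.g. the unmodified peptide
produces a characteristic two-level event (I/I₀ of 9.0 % then 17.1 %), while
the triple-nitrated variant blocks deepest (7.2 %).

`poreptm` implements the full signal-analysis chain for such recordings:

1. **Detection** — fit the open-pore Gaussian (I₀, σ₀), extract events below
   the I₀ − 3σ₀ threshold, compute dwell, I/I₀, σ/σ₀ and the local-extrema
   sequence, and apply the standard filters (0.2–100 ms, 0–40 %).
2. **Classification** — an LSTM (state 128, no readout activation) + MLP
   (6×256, ReLU, softmax) reads each event's extrema sequence; a scaled-down
   assessment network (LSTM 32 + 3×64 tanh + sigmoid) predicts whether the
   classification is correct. Both are trained jointly on a 3-part loss
   L = L_cls + L_assess + L_reinforce (cross-entropy, validity cross-entropy,
   and the cross-entropy scaled by the assessment score). A selection
   percentage keeps only the highest-assessment events, trading coverage for
   accuracy.
3. **Evaluation** — column-normalized confusion matrices, accuracy-versus-
   selection curves, and mixture-assignment percentages under the holdout
   protocol (chronological 75/25 train/validation split).
4. **Quantification** — blockade frequency f_sig = k_on·[analyte]₀, fitted
   through the origin and inverted to estimate concentrations.

Because no experimental recordings are distributed, the package includes a
first-class simulator that generates traces with exact ground-truth
annotations from the measured per-peptide statistics (Gaussian baseline,
Poisson arrivals, log-normal dwells, one- or two-level events). Every stage
is tested end-to-end against it. See `docs/methods.md` for the model details
and the design choices.

## Worked example

```python
import numpy as np
from poreptm import (
    default_signatures, simulate_trace, fit_population_gaussians,
    match_events_to_truth,
)
from poreptm.pipeline import detect
from poreptm.simulator import SimulationConfig

sigs = default_signatures()            # wt + 7 PTM variants, measured defaults
cfg = SimulationConfig(capture_rate_hz=5.0, duration_s=60.0, seed=1)
trace, truth = simulate_trace(cfg, sigs, {"wt": 0.5, "nY125nY133nY136": 0.5})

opm, events, summary = detect(trace)   # open-pore fit + 3 sigma extraction + filters
print(f"I0 = {summary['I0_pA']:.1f} pA, sigma0 = {summary['sigma0_pA']:.2f} pA, "
      f"{summary['n_kept']} events kept")

pairs, recall, _ = match_events_to_truth(events, truth)
print(f"recall vs ground truth: {recall:.3f}")

wt_levels = [r for _, t in pairs.items() for r in truth[t].level_rel_currents
             if truth[t].class_name == "wt"]
fit = fit_population_gaussians(wt_levels, K=2, seed=0)
print(f"wt populations: PI = {fit.means[0]:.2f} %, PII = {fit.means[1]:.2f} %")
```

Output:

```
I0 = 72.0 pA, sigma0 = 1.49 pA, 274 events kept
recall vs ground truth: 1.000
wt populations: PI = 8.95 %, PII = 17.45 %
```

The fitted baseline matches the configured 72 ± 1.5 pA, every annotated
blockade is recovered, and the two wt populations land on the 9.0 / 17.1 %
relative-current levels that the two-component Gaussian fit is meant to
resolve.

A command-line interface mirrors the library:

```bash
porePTM simulate --config sim.cfg --out trace.csv --truth truth.tsv --mix wt=0.6,pY125=0.4
porePTM detect   --trace trace.csv --out events.tsv --extrema extrema.tsv
porePTM train    --events events.tsv --extrema extrema.tsv --out model/
porePTM classify --events events.tsv --extrema extrema.tsv --model model/ --selection 50 --out pred.tsv
porePTM evaluate --pred pred.tsv --out report/
porePTM quantify --events events.tsv --duration 600 --calibration cal.tsv
```

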