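# neckernet

Single-trial EEG classification of bistable visual percepts, built as a
tested, reusable pipeline.  When a person views a Necker cube — an
ambiguous wireframe that can be seen as a left- or right-oriented 3-D
cube — each brief presentation ends in one of two perceptual
interpretations.  `neckernet` implements an analysis chain that decides,
from a single one-second 19-channel EEG trial, which interpretation the
observer reported:

- **Ocular artifact removal** by Gram-Schmidt orthogonalization: each
  scalp channel x is sequentially projected against the normalized
  vertical and horizontal EOG references,
  x′ = x − c_v⁰⟨c_v⁰, x⟩, then x̃ = x′ − c_h⁰⟨c_h⁰, x′⟩.
- **A sample-wise multilayer perceptron** (logistic units, topology
  19-19-5-1) applied to every time sample, with the trial decision
  statistic y = (1/N) Σᵢ u(tᵢ)², classified L if y ≥ 0.5 and R
  otherwise, trained by multi-restart **Levenberg-Marquardt** on
  μ = (1/K) Σₖ (dₖ − yₖ)².
- **Cross-subject transfer**: the accuracy matrix ρ_{h,r} of subject
  h's network evaluated on subject r's held-out trials.
- **Morlet wavelet time-frequency contrast**: class-averaged energy
  spectra ⟨A_L⟩, ⟨A_R⟩ over occipital channels and the integrated
  contrast ⟨ΔA⟩ = ∬ (⟨A_L⟩ − ⟨A_R⟩) df dt.
- **ERP difference traces** Δp(t) = x̄p^L(t) − x̄p^R(t) with window
  summaries of the evoked components.

Because recordings of this paradigm are not publicly deposited, the
package includes a first-class **synthetic EEG generator**
(`neckernet.synthgen`): seeded multi-subject sessions with 1/f
background noise, an occipital-dominant alpha rhythm with
stimulus-locked desynchronization, a class-dependent biphasic evoked
component whose early and late lobes carry different scalp
topographies, linearly mixed blink/saccade EOG artifacts, and the
paradigm's trial timing (0.8-1.3 s presentations, randomized
inter-stimulus intervals, seven wireframe-contrast levels).  Every
downstream stage is tested end-to-end against this generator's ground
truth.  See `docs/methods.md` for the full model description and its
limitations.

The package is aimed at researchers studying single-trial EEG
classification and bistable perception who want a reproducible,
inspectable reference implementation of this analysis family.

## Worked example

Train and evaluate a percept classifier on one synthetic subject with a
strongly separable class component (40 µV):

```python
import neckernet as nn
from neckernet import mlp

profile = nn.generate_subject_profile(seed=1, subject_id=1,
                                      overrides={"class_effect_amp": 40.0})
recording, events = nn.generate_session(profile, n_trials=200, design="button")
recording = nn.inject_eog(recording, profile)

trials = nn.preprocess_session(recording, events)      # 19 x 250 scaled trials
train, test = mlp.split_trials(trials, n_per_class=35, seed=1)

config = mlp.TrainConfig(n_restarts=5, max_iter=100, seed=1)
result = mlp.train_lm(train, [t.label for t in train], config)
best = mlp.select_best(result)

report = mlp.accuracy(best, test)
print(f"best training loss  mu  = {result.restarts[result.best_index].mu:.3f}")
print(f"held-out accuracy   rho = {report.rho:.1f}%  "
      f"(rho_L = {report.rho_L:.1f}%, rho_R = {report.rho_R:.1f}%, n = {report.n_total})")
```

Output:

```
best training loss  mu  = 0.159
held-out accuracy   rho = 99.2%  (rho_L = 100.0%, rho_R = 98.1%, n = 130)
```

The held-out accuracy ρ is the percentage of the 130 trials not used in
training whose predicted percept matches the generated label, overall
and per class.  The training loss μ is the mean squared gap between the
decision statistic y and its targets (1 for L, 0 for R); because the
class signature occupies only 40% of each trial, μ has a structural
floor of about 0.09, so 0.159 indicates a well-converged run (see
`docs/methods.md`).

The same pipeline can be driven from the shell:

```bash
neckernet all --config experiment.yaml --outdir results/
```

with subcommands `simulate`, `preprocess`, `train`, `evaluate`,
`cross-subject`, `wavelet`, `erp`, `all`.  Each run writes delimited
result tables (accuracy per subject, the cross-subject matrix, per-
subject ⟨ΔA⟩, ERP window means), EDF recordings plus tab-delimited
event logs for the simulated sessions, and a JSON manifest with SHA-256
checksums of every artifact.  Re-running with the same config and seed
reproduces byte-identical tables.

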