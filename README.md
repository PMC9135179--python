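# swarmeeg

EEG classification with two deep-learning pipelines, built for the
epilepsy (Bonn-style single-channel) and schizophrenia (19-channel)
problem settings and fully exercisable on synthetic EEG — no data
download is required to run, test, or reproduce anything here.

**SASDL** — sparse-autoencoder features + swarm-based feature selection
+ softmax DNN:

1. A sparse autoencoder learns features of z-scored EEG segments by
   minimising reconstruction error + L2 weight decay + a Bernoulli-KL
   sparsity penalty `β·Σⱼ KL(p‖p̂ⱼ)` (defaults λ=0.01, β=4, p=0.08) with
   Adam; the bottleneck activations are the features (9000 units at full
   scale).
2. A swarm optimizer — PSO (w=0.64, c₁=c₂=1.524, 30×30), cuckoo search
   (20 nests, p_a=0.45, α=1.5, Lévy flights) or the bat algorithm (40
   bats, A⁰=1, r⁰=0.5) — maximises a wrapper fitness (validation score
   of a budgeted DNN) over continuous positions decoded to top-m feature
   masks (9000 → 4500 at full scale).
3. A softmax DNN (hidden 2250/500, dropout, cross-entropy + weight
   decay, Adam, 50 epochs, head-only fine-tuning on the last 20)
   classifies the selected features.

**RBATQ** — a reinforcement-learning decision agent: a peephole BiLSTM
with additive attention builds the initial state s₁, a child-sum
Tree-LSTM over contiguous sub-windows builds the transition state s₂,
and a Q-network trained with running-average targets
`(1/t)·r + ((t−1)/t)·Q(s′,a′)` (RMSprop) decides per segment whether to
commit to the BiLSTM head's prediction (a₁), or defer (a₂) and classify
from the tree state (a₃/a₄).

Both pipelines are sklearn-style estimators (`fit`/`predict`) and are
evaluated with stratified 10-fold cross-validation reporting
sensitivity, specificity, accuracy, GDR and error rate.

All networks run on a small in-package reverse-mode autodiff core over
numpy (float64); gradients are verified against finite differences in
the test suite.

## Worked example

```python
import numpy as np
from swarmeeg import (generate_bonn_like, segment_recording,
                      pool_segments, run_cv)
from swarmeeg.profiles import get_profile

# 40 synthetic recordings (20 per class), 23 chunks each -> 920 segments
recs = generate_bonn_like(20, seed=1)
data = pool_segments([segment_recording(r, 23) for r in recs])

profile = get_profile("test")          # reduced widths, minutes not hours
report = run_cv("sasdl_pso", data, k=10, seed=0,
                estimator_params=profile["sasdl"])
print({k: round(v, 2) for k, v in report.aggregate().items()})
```

Output:

```
{'sensitivity': 96.96, 'specificity': 96.96, 'accuracy': 96.96,
 'gdr': 96.96, 'error_rate': 3.04}
```

The two synthetic classes differ by near-continuous 3–5 Hz spike-wave
discharge at 4× the background amplitude; ~97 % accuracy means the
pipeline recovers that spectral contrast from raw z-scored segments
(about 2 % of ictal-like chunks fall in discharge gaps, which bounds
attainable accuracy). The same harness with `"rbatq"` reports ≈ 98 %.

A CLI wraps the same flow:

```bash
swarmeeg generate --preset bonn-like --seed 7 -o data/
swarmeeg run --pipeline sasdl_pso --problem A-E --profile test \
             --seed 0 -o results/
swarmeeg report results/sasdl_pso_A-E.json
```

`--profile paper` switches to the full-scale widths (9000-unit
bottleneck, 4500 selected features, 2250/500 DNN, LSTM state 250);
expect hours of CPU time.

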