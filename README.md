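# lasenet

Trial-by-trial latent variables — reward expectations, attentive
states, internally selected rules — drive the behavioral predictions of
computational cognitive models, and linking them to neural data is a
staple of model-based analysis. The classical recipe (fit parameters θ
by maximum likelihood, then replay the model to read off the latents)
fails for models whose likelihood is intractable, such as hierarchical
RL with unobservable rule choices, noisy-inference Bayesian learners,
or GLM-HMMs. `lasenet` implements the simulation-based alternative: a
bidirectional GRU sequence estimator is trained on simulated pairs of
observables **Y** = (stimuli, actions, rewards) and latents **Z**, so
that for new data the latent trajectory estimate
Ẑ = argmax P(Z | Y) is a single forward pass — no likelihood, no
parameter recovery, amortized over an entire experiment.

The package contains, as first-class tested code:

* five generative cognitive-model simulators (4-parameter RL, Meta RL
  with a 2-state attentive HMM, hierarchical RL, a Weber-imprecision
  noisy Bayesian task-set learner, and a 3-state GLM-HMM), with priors
  and task environments for benchmarking;
* the estimator network (bidirectional GRU → pyramidal MLP → linear
  and/or softmax heads) with its full training loop, implemented on
  numpy + numba and verified by finite-difference gradient checks;
* likelihood-dependent comparators: closed-form/forward-algorithm
  likelihoods with multi-start MLE/MAP, known-parameter particle
  filters, GLM-HMM EM, and exact path-enumeration oracles;
* evaluation metrics (RMSE, negative log loss, balanced accuracy) and
  an end-to-end benchmark harness including a prior-misspecification
  study;
* a CLI (`simulate`, `build-dataset`, `train`, `infer`, `evaluate`,
  `benchmark`) for running the same pipeline on any schema-conformant
  trial table.

See `docs/methods.md` for the models, priors, and numerical choices.

## Worked example

Train an estimator for the hierarchical RL model on simulated agents
and decode the internally chosen arrow of unseen agents:

```python
import numpy as np
from lasenet import (
    HRL, default_task, build_dataset, default_prior,
    NetworkConfig, TrainingConfig, build_network, train_estimator,
    predict_latents, balanced_accuracy, rmse,
)

task = default_task(HRL, n_trials=200)
train = build_dataset(HRL, default_prior(HRL), 300, task,
                      np.random.default_rng(0))
test = build_dataset(HRL, default_prior(HRL), 40, task,
                     np.random.default_rng(1))

net = build_network(NetworkConfig(gru_units=64, head_cont=1, head_disc=3),
                    input_dim=5, seed=2)
est = train_estimator(net, train, TrainingConfig(
    learning_rate=2e-3, batch_size=32, max_epochs=40,
    early_stop_patience=10, seed=3))

out = predict_latents(est, test.inputs)
acc = np.mean([balanced_accuracy(test.targets_disc[i], out.states[i])
               for i in range(40)])
err = np.mean([rmse(test.targets_cont[i, :, 0], out.continuous[i, :, 0])
               for i in range(40)])
print(f"arrow accuracy {acc:.3f}, chosen-Q rmse {err:.3f}")
```

Output from this exact script:

```
arrow accuracy 0.807, chosen-Q rmse 0.172
```

i.e., with only 300 training agents and 40 epochs the network already
identifies the unobservable chosen arrow on 81% of trials (chance is
33%, and a particle filter given the *true* generating parameters is
likelihood-bound to similar accuracy because it cannot see the future),
while the value estimate still improves with longer training — see
`docs/methods.md` for scale effects.

The same pipeline from the shell:

```bash
lasenet simulate --model hrl --n 300 --trials 200 --seed 0 --out sim/
lasenet train --model hrl --sessions sim/sessions.csv \
        --latents sim/latents.csv --epochs 40 --seed 2 --out ckpt/
lasenet infer --checkpoint ckpt/ --sessions sim/sessions.csv \
        --out predictions.csv
lasenet benchmark --model glmhmm --kind intractable --scale desk \
        --seed 7 --out bench/
```

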