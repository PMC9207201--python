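# affectloop

Closed-loop EEG emotion induction with generated music, end to end on
synthetic data: a cohort simulator with programmed ground truth,
band-power grid features, a CNN emotion decoder with meta-learned
subject adaptation, a CNN+generator-input fusion decoder, and an
iso-principle controller that steers a listener's emotion by updating
the music generator's (valence, arousal) inputs during a piece.

See `docs/methods.md` for the scientific choices, model parameters and
problem sizes.

## Worked example (CLI)

The whole loop on a small cohort runs in about a minute on one core:

```sh
$ affectloop simulate --participants 6 --seed 0 --out cohort.h5
wrote 6 participants x 41 trials to cohort.h5

$ affectloop pretrain --cohort cohort.h5 --pretrain 4 --out init.npz
pre-trained (maml, lr=0.1) -> init.npz

$ affectloop finetune --cohort cohort.h5 --task 5 --init init.npz --pieces 13 --out model.npz
fine-tuned on 13 pieces (13 iterations) -> model.npz

$ affectloop evaluate --cohort cohort.h5 --task 5 --model model.npz
cnn     rmse  valence=0.0711  arousal=0.0726
fusion  rmse  valence=0.0808  arousal=0.0605

$ affectloop loop --cohort cohort.h5 --task 5 --model model.npz \
      --policy A_iso --valence 0.875 --arousal 0.875
block 1: input=(0.427, 0.418)  pred=(0.571, 0.224)
block 2: input=(0.467, 0.629)  pred=(0.621, 0.481)
block 3: input=(0.610, 0.672)  pred=(0.793, 0.489)
block 4: input=(0.692, 0.839)  pred=(0.771, 0.644)
block 5: input=(0.871, 0.933)  pred=(0.877, 0.681)
final distance to target: 0.1939
```

The session transcript shows the iso principle at work: the first
input sits near the listener's predicted silent-state emotion and the
inputs walk toward the (0.875, 0.875) target over the five blocks,
corrected by the in-music predictions.

`affectloop replicate --design methods|policies` runs the two study
replications (long-format CSV plus a printed summary); `affectloop
grids` prints the stimulus grids.

## Worked example (Python)

```python
import affectloop as al
from affectloop import metalearn as ml

cohort = al.build_cohort(6, "full41", seed=0)
tasks = [ml.featurize_task(t) for t in cohort]

init, info = ml.maml_pretrain(tasks[:4], tasks[4:5])
cnn = ml.finetune(init, tasks[5], pieces=13)
fusion = ml.train_fusion(cnn, tasks[5], pieces=13)
print(ml.evaluate_rmse((cnn, fusion), tasks[5], al.test_pieces()))

predictor = al.ModelPredictor(cnn, fusion)
res = al.run_session(cohort[5].participant, predictor, "A_iso",
                     al.EmotionPoint(0.875, 0.875), seed=0)
print(res.final_distance)
```

## Layout

| module                  | contents                                            |
| ----------------------- | --------------------------------------------------- |
| `affectloop.cohort`     | synthetic participants, trials, stimulus grids      |
| `affectloop.features`   | band-power log-variance features on a 6x6x5 grid    |
| `affectloop.nets`       | grid CNN, fusion MLP, SGD (numpy autodiff)          |
| `affectloop.metalearn`  | MAML / pooled pre-training, fine-tuning, evaluation |
| `affectloop.controller` | music-update policies and the session runner        |
| `affectloop.harness`    | method- and policy-comparison replications          |
| `affectloop.io`         | HDF5 cohorts, npz model files                       |

## Tests and acceptance run

```sh
pytest -q                                   # unit + acceptance (~20 min)
pytest -q --ignore=tests/test_acceptance.py # unit tests only (~10 s)
python scripts/acceptance.py --seed 0 --out results.json  # ~6 min
```

The acceptance script writes the headline quantities (feature-pipeline
constants, controller identities, meta-gradient finite-difference
error, method/fusion RMSE means, policy distance means) to JSON; all
randomness derives from `--seed`.
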