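# chirsep

Physics-based machine learning for predicting **diastereomeric salt
resolutions** — the workhorse industrial technique for separating the two
enantiomers of a chiral acid or base. An enantiopure resolving agent forms
two diastereomeric salts with the racemate; if one is sufficiently less
soluble, a single enantiomer crystallises out. Screening resolving agents
and solvents is a needle-in-a-haystack problem (historically only a few
percent of conditions succeed), and `chirsep` is a library + CLI for
learning to rank those conditions from 3D structure.

The package is aimed at process/computational chemists who have (or can
simulate) conformer ensembles of acid–base complexes and tables of
resolution outcomes.

## Method in brief

For a racemate–agent pair, both diastereomeric complexes (R and S substrate
against the same agent) are featurised from conformer snapshots with a
weighted atom-density representation: for every non-hydrogen atom *i*,

```
A2(i)^w(r)     = Σ_{j≠i}          w_ij G_ij(r)
A3(i)^{w,φ}(r) = Σ_{j,k≠i, j≠k}   w_ij w_ik w_jk G_ij(r) φ(θ_ijk)
```

with `G_ij` a σ = 0.0825 Å Gaussian at the distance d_ij evaluated on 160
bins over 0.7–8 Å, φ ∈ {cos, sin} of the angle at atom *i*, and seven
electronic weighting channels 𝒲 = {ε^σ, ε^π, ε^δ, q, p^σ, p^π, p^δ}
(orbital overlaps, charge product q_i·q_j, orbital-population products).
Snapshot vectors (3367 per atom) are aggregated over the trajectory as
mean ‖ std (6734 per atom), compressed to 20 dimensions, and combined into
a **mean stream** (z_R + z_S)/2 and an **absolute difference stream**
|z_R − z_S|. The representation is reflection-invariant, so the diff stream
vanishes exactly when the agent is achiral — chirality sensitivity enters
only through the pair.

A dual-stream transformer processes the two streams independently, pools
the tokens by cross-attention with the solvent descriptor as the query, and
is trained in two stages: regression on (m.frac., e.e.) over all data, then
a classification head fine-tuned on the low-noise subset
(m.frac. ≥ 20%) with all other weights frozen and 50/50 class-balanced
sampling. Evaluation uses racemate-grouped 5-fold cross-validation,
enrichment factors EF(n) and average precision. Success thresholds:
m.frac. > 20% and e.e. > 25% (retrospective); full dissolution and
z = m.frac.·e.e. ≥ 0.25 (prospective; z = 0.5 is the ideal resolution).

The network runs on a small numpy autodiff engine included in the package;
everything is deterministic for a fixed seed.

## Worked example

Generate a synthetic screening grid with a planted, recoverable signal and
train/evaluate the two-stage model on held-out racemates:

```python
import numpy as np
from chirsep.synthetic import generate_dataset, PlantedSignalConfig
from chirsep.pair_assembly import train_compressor, stack_atom_vectors, build_pair_lookup
from chirsep.model_core import ModelConfig
from chirsep.train_eval import (TrainConfig, group_kfold, train_two_stage,
                                score_records, enrichment_at_fraction,
                                average_precision, label)

ds = generate_dataset(n_racemates=30, n_agents=20, n_solvents=2,
                      signal=PlantedSignalConfig(base_rate=0.038),
                      seed=101, n_frames=16)

plan = group_kfold(ds.records, k=5, seed=11)
train_recs, test_recs = plan.split(ds.records, fold=0)
train_keys = {(r.racemate_id, r.agent_id) for r in train_recs}
compressor = train_compressor(stack_atom_vectors(ds.reps, train_keys),
                              kind="pca", seed=11)
lookup = build_pair_lookup(ds.reps, compressor)

models = train_two_stage(train_recs, lookup, ds.solvent_table,
                         ModelConfig(solvent_dim=8, seed=11),
                         TrainConfig(seed=11), ensemble_size=3)

test_ln = [r for r in test_recs if label(r).low_noise]
y = np.array([label(r).retrospective_hit for r in test_ln])
scores = score_records(models, test_ln, lookup, ds.solvent_table)
print(f"held-out low-noise records: {len(y)}, hits: {y.sum()}")
print(f"EF@10%: {enrichment_at_fraction(scores, y, 0.1):.2f}")
print(f"AP: {average_precision(scores, y):.3f} (random = {y.mean():.3f})")
```

Typical output (seeds as above):

```
held-out low-noise records: 107, hits: 12
EF@10%: 4.05
AP: 0.471 (random = 0.112)
```

meaning: among the 107 held-out experiments whose labels are trustworthy,
ranking by the model packs hits into the top 10% at ~4× the rate of random
screening, and the average precision is ~4× the base hit rate — the planted
structure–outcome signal has been recovered end-to-end from raw coordinates.

The same pipeline is available from the shell:

```bash
chirsep simulate --racemates 30 --agents 20 --solvents 2 --seed 11 --out fixtures/
chirsep train --table fixtures/experiments.csv --reps fixtures/representations.h5 \
              --solvent-table fixtures/solvents.csv --folds 5 --seed 7 --out run/
chirsep rank  --model run/fold0_member0.h5 --racemate R003 ...
```

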