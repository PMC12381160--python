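"""Figures of merit, success labels, grouped cross-validation, two-stage
training and ranking metrics.

A resolution experiment is summarised by the solid mass fraction
``m_frac = m_solid / m_initial`` and the enantiomeric excess
``ee = |chi_R - chi_S|`` of the solid; their product ``z = m_frac * ee``
combines both (z = 0.5 is the ideal resolution of a racemic feed).
A retrospective hit has m_frac > 20% and ee > 25%; records with
m_frac >= 20% form the low-noise subset whose labels are trusted for
classification.  The prospective criterion additionally requires full
dissolution before crystallisation and z >= 0.25.

Training is two-staged: a regression model on all data (stage 1), then a
classification head fine-tuned on the low-noise subset with every non-head
weight frozen and 50/50 class-balanced weighted sampling (stage 2).
Evaluation is by racemate-grouped k-fold splits, enrichment factors and
average precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor
from .model_core import DualStreamModel, ModelConfig, ensemble_predict, make_batch
from .pair_assembly import PairTensors, solvent_vector
from .structures_io import ExperimentRecord

logger = logging.getLogger(__name__)

#: success thresholds on the retrospective data
M_FRAC_THRESHOLD = 0.20
EE_THRESHOLD = 0.25
#: prospective combined-figure-of-merit threshold
Z_THRESHOLD = 0.25


# ---------------------------------------------------------------------------
# figures of merit and labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiguresOfMerit:
    m_solid: float
    m_initial: float
    chi_R: float
    chi_S: float
    m_frac: float
    ee: float
    z: float


def figures_of_merit(m_solid: float, m_initial: float,
                     chi_R: float, chi_S: float) -> FiguresOfMerit:
    """Compute m_frac, ee and z from masses and solid-phase molar fractions."""
    if m_initial <= 0:
        raise ValueError("initial mass must be positive")
    if m_solid < 0:
        raise ValueError("solid mass must be non-negative")
    if m_solid > m_initial:
        raise ValueError("solid mass cannot exceed the initial mass")
    for name, chi in (("chi_R", chi_R), ("chi_S", chi_S)):
        if not 0.0 <= chi <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    m_frac = m_solid / m_initial
    ee = abs(chi_R - chi_S)
    return FiguresOfMerit(m_solid, m_initial, chi_R, chi_S,
                          m_frac, ee, m_frac * ee)


@dataclass(frozen=True)
class SuccessLabels:
    retrospective_hit: bool
    low_noise: bool
    prospective_hit: bool


def label(record: ExperimentRecord) -> SuccessLabels:
    """Derive all three success labels; threshold strictness exactly as stated."""
    hit = record.m_frac > M_FRAC_THRESHOLD and record.ee > EE_THRESHOLD
    low_noise = record.m_frac >= M_FRAC_THRESHOLD
    z = record.m_frac * record.ee
    prospective = bool(record.full_dissolution) and z >= Z_THRESHOLD
    return SuccessLabels(hit, low_noise, prospective)


# ---------------------------------------------------------------------------
# grouped cross-validation
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """k-fold assignment keyed by racemate id; no racemate spans folds."""

    k: int
    fold_of: dict[str, int]

    def test_racemates(self, fold: int) -> set[str]:
        return {r for r, f in self.fold_of.items() if f == fold}

    def split(self, records: list[ExperimentRecord], fold: int
              ) -> tuple[list[ExperimentRecord], list[ExperimentRecord]]:
        test_r = self.test_racemates(fold)
        train = [r for r in records if r.racemate_id not in test_r]
        test = [r for r in records if r.racemate_id in test_r]
        return train, test


def group_kfold(records: list[ExperimentRecord], k: int = 5,
                seed: int = 0) -> SplitPlan:
    """Assign racemates to k folds, greedily balancing record counts.

    Racemates are shuffled by ``seed``, ordered by record count (largest
    first, stable) and each is assigned to the currently smallest fold.
    """
    counts: dict[str, int] = {}
    for r in records:
        counts[r.racemate_id] = counts.get(r.racemate_id, 0) + 1
    racemates = sorted(counts)
    if len(racemates) < k:
        raise ValueError(f"need at least k={k} distinct racemates, "
                         f"got {len(racemates)}")
    rng = np.random.default_rng(seed)
    order = [racemates[i] for i in rng.permutation(len(racemates))]
    order.sort(key=lambda r: -counts[r])  # stable: keeps shuffled order on ties
    fold_sizes = np.zeros(k, dtype=int)
    fold_of = {}
    for rac in order:
        f = int(np.argmin(fold_sizes))
        fold_of[rac] = f
        fold_sizes[f] += counts[rac]
    return SplitPlan(k=k, fold_of=fold_of)


# ---------------------------------------------------------------------------
# record -> tensor plumbing
# ---------------------------------------------------------------------------

PairLookup = dict[tuple[str, str], PairTensors]


def records_to_pairs(records: list[ExperimentRecord], pair_lookup: PairLookup,
                     solvent_table: pd.DataFrame) -> list[PairTensors]:
    """Attach solvent vectors; raises KeyError naming any record without tensors."""
    out = []
    for r in records:
        key = (r.racemate_id, r.agent_id)
        if key not in pair_lookup:
            raise KeyError(
                f"no pair tensors for record racemate={r.racemate_id!r} "
                f"agent={r.agent_id!r}")
        out.append(pair_lookup[key].with_solvent(
            solvent_vector(r.solvent_components, solvent_table)))
    return out


def stage1_targets(records: list[ExperimentRecord], target: str) -> np.ndarray:
    if target == "both":
        return np.array([[r.m_frac, r.ee] for r in records])
    if target == "z":
        return np.array([[r.m_frac * r.ee] for r in records])
    raise ValueError(f"unknown stage-1 target {target!r}")


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    stage1_target: str = "both"    # 'both' (m_frac, ee) | 'z'
    stage1_steps: int = 400
    stage1_batch: int = 96
    stage1_lr: float = 1e-3
    val_fraction: float = 0.1      # racemate fraction carved out for early stopping
    stage2_steps: int = 400
    stage2_batch: int = 64
    stage2_lr: float = 1e-3
    seed: int = 0


def _minibatches(n: int, batch: int, steps: int, rng) -> list[np.ndarray]:
    return [rng.choice(n, size=min(batch, n), replace=n < batch)
            for _ in range(steps)]


def stage1_train(model: DualStreamModel, records: list[ExperimentRecord],
                 pair_lookup: PairLookup, solvent_table: pd.DataFrame,
                 tcfg: TrainConfig) -> DualStreamModel:
    """Stage 1: regression on all records (including the noisy low-m_frac ones).

    Minimises squared error on the stage-1 targets with Adam; a validation
    split carved from the training racemates tracks the best parameters.
    Fully seeded and deterministic.
    """
    if not records:
        raise ValueError("empty training set")
    if model.config.head_kind != "regression":
        raise ValueError("stage 1 expects a regression-head model")
    rng = np.random.default_rng(tcfg.seed)

    racemates = sorted({r.racemate_id for r in records})
    n_val = max(1, int(round(tcfg.val_fraction * len(racemates)))) \
        if tcfg.val_fraction > 0 and len(racemates) > 2 else 0
    val_rac = set(np.array(racemates)[rng.permutation(len(racemates))[:n_val]])
    train_recs = [r for r in records if r.racemate_id not in val_rac]
    val_recs = [r for r in records if r.racemate_id in val_rac]
    if not train_recs:
        train_recs, val_recs = records, []

    pairs = records_to_pairs(train_recs, pair_lookup, solvent_table)
    targets = stage1_targets(train_recs, tcfg.stage1_target)
    val_pairs = records_to_pairs(val_recs, pair_lookup, solvent_table) if val_recs else []
    val_targets = stage1_targets(val_recs, tcfg.stage1_target) if val_recs else None

    opt = Adam(model.params, lr=tcfg.stage1_lr)
    best_val, best_params = np.inf, None
    check_every = max(1, tcfg.stage1_steps // 10)
    for step, idx in enumerate(_minibatches(len(pairs), tcfg.stage1_batch,
                                            tcfg.stage1_steps, rng)):
        batch = make_batch([pairs[i] for i in idx])
        out, _ = model.forward(batch, train=True, rng=rng)
        loss = ((out - Tensor(targets[idx])) ** 2).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        if val_pairs and (step + 1) % check_every == 0:
            vout, _ = model.forward(make_batch(val_pairs))
            vloss = float(((vout.data - val_targets) ** 2).mean())
            if vloss < best_val:
                best_val = vloss
                best_params = {k: t.data.copy() for k, t in model.params.items()}
    if best_params is not None:
        for k, t in model.params.items():
            t.data = best_params[k]
    return model


def balanced_sample_weights(hits: np.ndarray) -> np.ndarray:
    """Per-record sampling weights giving an expected 50/50 class mix."""
    hits = np.asarray(hits, dtype=bool)
    n_pos, n_neg = int(hits.sum()), int((~hits).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("balanced sampling needs both classes present")
    w = np.where(hits, 0.5 / n_pos, 0.5 / n_neg)
    return w / w.sum()


def stage2_finetune(model: DualStreamModel, records: list[ExperimentRecord],
                    pair_lookup: PairLookup, solvent_table: pd.DataFrame,
                    tcfg: TrainConfig) -> DualStreamModel:
    """Stage 2: swap to a classification head and fine-tune it alone.

    Trains on the low-noise subset (m_frac >= 20%) with binary cross-entropy
    and 50/50 class-balanced weighted sampling; all non-head parameters stay
    bit-identical (asserted via fingerprint).
    """
    subset = [r for r in records if label(r).low_noise]
    hits = np.array([label(r).retrospective_hit for r in subset], dtype=bool)
    if len(subset) == 0 or hits.all() or not hits.any():
        raise ValueError("stage 2 needs a low-noise subset with both classes")

    clf = model.swap_head("classification")
    before = clf.parameter_fingerprint(exclude_head=True)
    pairs = records_to_pairs(subset, pair_lookup, solvent_table)
    # the backbone is frozen, so each record's pooled vector is fixed: compute
    # it once (eval mode) and train the head on the cached features
    pooled = clf.pooled_features(make_batch(pairs))
    weights = balanced_sample_weights(hits)
    rng = np.random.default_rng(tcfg.seed + 1)
    opt = Adam(clf.params, lr=tcfg.stage2_lr, trainable=clf.trainable_names())
    y = hits.astype(float)[:, None]
    eps = 1e-7
    for _ in range(tcfg.stage2_steps):
        idx = rng.choice(len(pairs), size=min(tcfg.stage2_batch, len(pairs)),
                         p=weights)
        prob = clf.head_forward(Tensor(pooled[idx]))
        p_clipped = prob * (1 - 2 * eps) + eps
        yb = Tensor(y[idx])
        loss = -(yb * p_clipped.log() + (1 - yb) * (1 - p_clipped).log()).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert clf.parameter_fingerprint(exclude_head=True) == before, \
        "frozen backbone changed during stage-2 fine-tuning"
    return clf


def train_two_stage(records: list[ExperimentRecord], pair_lookup: PairLookup,
                    solvent_table: pd.DataFrame, mcfg: ModelConfig,
                    tcfg: TrainConfig, ensemble_size: int = 1
                    ) -> list[DualStreamModel]:
    """Train an ensemble of two-stage classifiers (seeds derived per member)."""
    models = []
    for m in range(ensemble_size):
        from dataclasses import replace

        mc = replace(mcfg, head_kind="regression", seed=mcfg.seed + 1000 * m)
        tc = replace(tcfg, seed=tcfg.seed + 1000 * m)
        reg = stage1_train(DualStreamModel(mc), records, pair_lookup,
                           solvent_table, tc)
        models.append(stage2_finetune(reg, records, pair_lookup,
                                      solvent_table, tc))
    return models


def score_records(models: list[DualStreamModel],
                  records: list[ExperimentRecord], pair_lookup: PairLookup,
                  solvent_table: pd.DataFrame) -> np.ndarray:
    """Ensemble success probabilities for a list of records."""
    pairs = records_to_pairs(records, pair_lookup, solvent_table)
    # batched per token count to avoid cross-pair padding effects on attention
    probs = np.empty(len(pairs))
    order = np.argsort([p.n_tokens for p in pairs], kind="stable")
    lo = 0
    while lo < len(order):
        t = pairs[order[lo]].n_tokens
        hi = lo
        while hi < len(order) and pairs[order[hi]].n_tokens == t:
            hi += 1
        chunk = [pairs[i] for i in order[lo:hi]]
        out = ensemble_predict(models, chunk)
        vals = out.probability if out.probability is not None else out.regression[:, 0]
        probs[order[lo:hi]] = vals
        lo = hi
    return probs


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentCurve:
    n: np.ndarray
    ef: np.ndarray

    def at(self, n: int) -> float:
        return float(self.ef[int(n) - 1])


def _ranked_labels(scores, labels) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    order = np.argsort(-scores, kind="stable")  # ties keep record order
    return labels[order]


def enrichment_curve(scores, labels) -> EnrichmentCurve:
    """EF(n) = (hits in the top n) / (n * H / N) for every n; EF(N) = 1."""
    ranked = _ranked_labels(scores, labels)
    n_total = len(ranked)
    n_hits = int(ranked.sum())
    if n_hits == 0:
        raise ValueError("enrichment factor undefined without hits")
    cum = np.cumsum(ranked)
    n = np.arange(1, n_total + 1)
    return EnrichmentCurve(n=n, ef=cum / (n * n_hits / n_total))


def enrichment_at_fraction(scores, labels, fraction: float = 0.1) -> float:
    """EF at the top ``fraction`` of the ranked list (at least one record)."""
    curve = enrichment_curve(scores, labels)
    n = max(1, int(round(fraction * len(curve.n))))
    return curve.at(n)


def average_precision(scores, labels) -> float:
    """Standard AP: sum of precision-at-k over hit positions, divided by H."""
    ranked = _ranked_labels(scores, labels)
    n_hits = int(ranked.sum())
    if n_hits == 0:
        raise ValueError("average precision undefined without hits")
    k = np.arange(1, len(ranked) + 1)
    precision_at_k = np.cumsum(ranked) / k
    return float(precision_at_k[ranked].sum() / n_hits)


def learning_curve(records: list[ExperimentRecord], pair_lookup: PairLookup,
                   solvent_table: pd.DataFrame, mcfg: ModelConfig,
                   tcfg: TrainConfig, fractions=(0.25, 0.5, 1.0),
                   ensemble_size: int = 10, seed: int = 0) -> pd.DataFrame:
    """AP versus training-set size on a fixed held-out racemate fold.

    Fold 0 of a grouped 5-fold plan is the test set; the remaining racemates
    are shuffled once and nested subsets (smaller contained in larger) are
    drawn by walking the shuffled racemate list until each requested record
    fraction is reached.  Per fraction, an ensemble is trained and AP is
    measured on the low-noise test records.
    """
    plan = group_kfold(records, k=5, seed=seed)
    train_all, test = plan.split(records, fold=0)
    test_ln = [r for r in test if label(r).low_noise]
    test_labels = np.array([label(r).retrospective_hit for r in test_ln])
    if not test_labels.any():
        raise ValueError("test fold contains no hits; choose another seed")

    rng = np.random.default_rng(seed + 7)
    racemates = sorted({r.racemate_id for r in train_all})
    order = [racemates[i] for i in rng.permutation(len(racemates))]
    rows = []
    for frac in sorted(fractions):
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        target = frac * len(train_all)
        chosen: set[str] = set()
        count = 0
        for rac in order:
            if count >= target:
                break
            chosen.add(rac)
            count += sum(r.racemate_id == rac for r in train_all)
        subset = [r for r in train_all if r.racemate_id in chosen]
        n_hits = sum(label(r).retrospective_hit for r in subset)
        if n_hits < 1:
            logger.warning("fraction %.2f has no training hits; skipped", frac)
            continue
        from dataclasses import replace

        models = train_two_stage(subset, pair_lookup, solvent_table,
                                 replace(mcfg, seed=seed),
                                 replace(tcfg, seed=seed),
                                 ensemble_size=ensemble_size)
        aps = []
        for m in models:
            probs = score_records([m], test_ln, pair_lookup, solvent_table)
            aps.append(average_precision(probs, test_labels))
        rows.append({"fraction": frac, "n_train": len(subset),
                     "mean_ap": float(np.mean(aps)),
                     "std_ap": float(np.std(aps))})
    return pd.DataFrame(rows)


def rank_agents(models: list[DualStreamModel], racemate_id: str,
                agent_ids: list[str], solvent_ids: list[str],
                pair_lookup: PairLookup,
                solvent_table: pd.DataFrame) -> pd.DataFrame:
    """Rank resolving agents by max ensemble probability over solvent systems."""
    if not agent_ids or not solvent_ids:
        raise ValueError("empty agent x solvent grid")
    rows = []
    for agent in agent_ids:
        probs = {}
        for solv in solvent_ids:
            rec = ExperimentRecord(racemate_id, agent, [(solv, 1.0)], 0.0, 0.0)
            probs[solv] = float(score_records(models, [rec], pair_lookup,
                                              solvent_table)[0])
        best = max(probs, key=lambda s: probs[s])
        rows.append({"agent_id": agent, "score": probs[best],
                     "best_solvent": best})
    df = pd.DataFrame(rows)
    df = df.sort_values(["score", "agent_id"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df.index.name = "rank"
    return df


def dataset_summary(records: list[ExperimentRecord]) -> dict:
    """Bookkeeping counts used in evaluation reports."""
    labels = [label(r) for r in records]
    hits = np.array([l.retrospective_hit for l in labels])
    low_noise = np.array([l.low_noise for l in labels])
    racs = {}
    for r, l in zip(records, labels):
        racs.setdefault(r.racemate_id, []).append(l.retrospective_hit)
    return {
        "n_records": len(records),
        "n_racemates": len(racs),
        "n_agents": len({r.agent_id for r in records}),
        "hit_rate": float(hits.mean()) if len(records) else 0.0,
        "non_hit_rate": float(1.0 - hits.mean()) if len(records) else 0.0,
        "low_noise_fraction": float(low_noise.mean()) if len(records) else 0.0,
        "hit_rate_low_noise": float(hits[low_noise].mean()) if low_noise.any() else 0.0,
        "racemates_without_hits": sum(1 for v in racs.values() if not any(v)),
    }
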