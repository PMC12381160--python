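import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score

from chirsep.model_core import DualStreamModel, ModelConfig
from chirsep.pair_assembly import PairTensors
from chirsep.structures_io import ExperimentRecord
from chirsep.train_eval import (TrainConfig, average_precision,
                                balanced_sample_weights, dataset_summary,
                                enrichment_curve, figures_of_merit,
                                group_kfold, label, rank_agents,
                                score_records, stage1_train,
                                stage2_finetune)


def record(rac="r0", agent="a0", m_frac=0.3, ee=0.5, solvent="S0", full=None):
    return ExperimentRecord(rac, agent, [(solvent, 1.0)], m_frac, ee, full)


SOLVENTS = pd.DataFrame(
    np.random.default_rng(0).normal(size=(2, 8)),
    index=pd.Index(["S0", "S1"], name="solvent_id"),
    columns=[f"d{k}" for k in range(8)])


def toy_lookup(keys, t=6, f=20, seed=0):
    """Random pair tensors for a set of (racemate, agent) keys."""
    r = np.random.default_rng(seed)
    return {key: PairTensors([f"x{i}" for i in range(t)], ["C"] * t,
                             r.normal(size=(t, f)),
                             np.abs(r.normal(size=(t, f))))
            for key in keys}


class TestFiguresOfMerit:
    def test_mass_fraction(self):
        fom = figures_of_merit(20.0, 100.0, 0.5, 0.5)
        assert fom.m_frac == pytest.approx(0.2)

    def test_enantiomeric_excess(self):
        fom = figures_of_merit(10.0, 100.0, 0.75, 0.25)
        assert fom.ee == pytest.approx(0.5)

    def test_ideal_resolution_z(self):
        fom = figures_of_merit(50.0, 100.0, 1.0, 0.0)
        assert fom.z == pytest.approx(0.5)

    def test_solid_exceeding_initial_rejected(self):
        with pytest.raises(ValueError):
            figures_of_merit(101.0, 100.0, 0.5, 0.5)


class TestLabels:
    @pytest.mark.parametrize("m_frac,ee,hit,low_noise", [
        (0.21, 0.26, True, True),
        (0.19, 0.90, False, False),
        (0.20, 0.90, False, True),    # threshold is strict for hits
        (0.50, 0.25, False, True),
    ])
    def test_retrospective_thresholds(self, m_frac, ee, hit, low_noise):
        lab = label(record(m_frac=m_frac, ee=ee))
        assert lab.retrospective_hit is hit
        assert lab.low_noise is low_noise

    def test_hit_implies_low_noise(self):
        for m, e in [(0.25, 0.3), (0.21, 0.9), (0.5, 1.0)]:
            lab = label(record(m_frac=m, ee=e))
            assert not lab.retrospective_hit or lab.low_noise

    def test_prospective_requires_dissolution_and_z(self):
        assert label(record(m_frac=0.5, ee=0.6, full=True)).prospective_hit
        assert not label(record(m_frac=0.5, ee=0.6, full=False)).prospective_hit
        assert not label(record(m_frac=0.5, ee=0.4, full=True)).prospective_hit


class TestGroupKFold:
    def _records(self, n_rac=10, per=4):
        return [record(rac=f"r{i}", agent=f"a{j}")
                for i in range(n_rac) for j in range(per)]

    def test_equal_counts_two_racemates_per_fold(self):
        plan = group_kfold(self._records(), k=5, seed=0)
        sizes = [len(plan.test_racemates(f)) for f in range(5)]
        assert sizes == [2, 2, 2, 2, 2]

    def test_train_test_racemates_disjoint(self):
        recs = self._records()
        plan = group_kfold(recs, k=5, seed=1)
        for f in range(5):
            train, test = plan.split(recs, f)
            assert not ({r.racemate_id for r in train}
                        & {r.racemate_id for r in test})
            assert len(train) + len(test) == len(recs)

    def test_same_seed_same_plan(self):
        recs = self._records()
        assert group_kfold(recs, 5, 7).fold_of == group_kfold(recs, 5, 7).fold_of

    def test_too_few_racemates(self):
        with pytest.raises(ValueError):
            group_kfold(self._records(n_rac=3), k=5)


class TestBalancedSampling:
    def test_expected_proportion_is_half(self):
        hits = np.zeros(200, dtype=bool)
        hits[:20] = True
        w = balanced_sample_weights(hits)
        assert w[hits].sum() == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_sample_weights(np.ones(10, dtype=bool))


class TestEnrichment:
    def test_counting_example(self):
        """100 records, 8 hits, 4 of them in the top 10 -> EF(10) = 5."""
        scores = np.linspace(1.0, 0.0, 100)
        labels = np.zeros(100, dtype=bool)
        labels[[0, 3, 5, 9]] = True     # 4 hits inside the top 10
        labels[[20, 40, 60, 80]] = True  # 4 outside
        curve = enrichment_curve(scores, labels)
        assert curve.at(10) == pytest.approx(5.0)

    def test_ef_at_full_depth_is_one(self):
        r = np.random.default_rng(5)
        scores = r.normal(size=60)
        labels = r.random(60) < 0.2
        labels[0] = True
        assert enrichment_curve(scores, labels).at(60) == pytest.approx(1.0)

    def test_perfect_ranking_reaches_n_over_h(self):
        labels = np.zeros(100, dtype=bool)
        labels[:8] = True
        scores = np.linspace(1.0, 0.0, 100)
        assert enrichment_curve(scores, labels).at(8) == pytest.approx(12.5)

    def test_zero_hits_rejected(self):
        with pytest.raises(ValueError):
            enrichment_curve(np.ones(5), np.zeros(5, dtype=bool))

    def test_random_scores_average_to_ef_one(self):
        """Mean EF(n) over many random rankings converges to 1 at every n."""
        labels = np.zeros(50, dtype=bool)
        labels[:10] = True
        n_rep = 400
        efs = np.zeros((n_rep, 50))
        for k in range(n_rep):
            scores = np.random.default_rng(k).random(50)
            efs[k] = enrichment_curve(scores, labels).ef
        mean_ef = efs.mean(axis=0)
        se = efs.std(axis=0) / np.sqrt(n_rep)
        assert np.all(np.abs(mean_ef - 1.0) <= 3 * np.maximum(se, 1e-3))


class TestAveragePrecision:
    def test_perfect_ranking(self):
        labels = np.array([True, True, False, False])
        assert average_precision([4, 3, 2, 1], labels) == pytest.approx(1.0)

    def test_single_hit_ranked_last(self):
        n = 20
        labels = np.zeros(n, dtype=bool)
        labels[-1] = True
        scores = np.linspace(1.0, 0.0, n)
        assert average_precision(scores, labels) == pytest.approx(1.0 / n)

    def test_matches_sklearn_on_random_fixtures(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            scores = r.normal(size=40)
            labels = r.random(40) < 0.3
            if not labels.any():
                labels[0] = True
            assert average_precision(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_score_transforms(self, seed):
        r = np.random.default_rng(seed)
        scores = r.normal(size=30)
        labels = r.random(30) < 0.25
        if not labels.any():
            labels[0] = True
        transformed = np.exp(2.0 * scores) + 1.0  # strictly increasing
        assert average_precision(scores, labels) == pytest.approx(
            average_precision(transformed, labels))
        assert enrichment_curve(scores, labels).at(5) == pytest.approx(
            enrichment_curve(transformed, labels).at(5))


def small_training_problem(n_rac=6, agents=2, seed=0):
    """A tiny linearly-structured two-class problem the model can memorise."""
    r = np.random.default_rng(seed)
    keys = [(f"r{i}", f"a{j}") for i in range(n_rac) for j in range(agents)]
    lookup = {}
    records = []
    for k, key in enumerate(keys):
        hit = k % 2 == 0
        base = 2.0 if hit else -2.0
        t = 6
        lookup[key] = PairTensors(
            [f"x{i}" for i in range(t)], ["C"] * t,
            r.normal(size=(t, 20)),
            np.abs(base + 0.1 * r.normal(size=(t, 20))))
        records.append(record(rac=key[0], agent=key[1],
                              m_frac=0.4 if hit else 0.25,
                              ee=0.8 if hit else 0.05))
    return records, lookup


class TestTwoStageTraining:
    mcfg = ModelConfig(solvent_dim=8, dropout=0.0, seed=1)

    def test_stage1_overfits_memorisable_fixture(self):
        records, lookup = small_training_problem()
        tcfg = TrainConfig(stage1_steps=500, stage1_batch=12,
                           val_fraction=0.0, seed=0)
        model = DualStreamModel(self.mcfg)
        from chirsep.model_core import make_batch
        from chirsep.train_eval import records_to_pairs, stage1_targets
        pairs = records_to_pairs(records, lookup, SOLVENTS)
        targets = stage1_targets(records, "both")
        out0, _ = model.forward(make_batch(pairs))
        loss0 = float(((out0.data - targets) ** 2).mean())
        stage1_train(model, records, lookup, SOLVENTS, tcfg)
        out1, _ = model.forward(make_batch(pairs))
        loss1 = float(((out1.data - targets) ** 2).mean())
        assert loss1 < 0.1 * loss0

    def test_stage1_same_seed_same_result(self):
        records, lookup = small_training_problem()
        tcfg = TrainConfig(stage1_steps=30, seed=4)

        def run():
            m = stage1_train(DualStreamModel(self.mcfg), records, lookup,
                             SOLVENTS, tcfg)
            return m.parameter_fingerprint()

        assert run() == run()

    def test_missing_pair_tensor_names_record(self):
        records, lookup = small_training_problem()
        del lookup[("r0", "a0")]
        with pytest.raises(KeyError, match="r0"):
            stage1_train(DualStreamModel(self.mcfg), records, lookup,
                         SOLVENTS, TrainConfig(stage1_steps=5))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            stage1_train(DualStreamModel(self.mcfg), [], {}, SOLVENTS,
                         TrainConfig())

    def test_stage2_freezes_backbone_and_separates_classes(self):
        records, lookup = small_training_problem()
        tcfg = TrainConfig(stage1_steps=200, stage2_steps=400,
                           val_fraction=0.0, seed=2)
        reg = stage1_train(DualStreamModel(self.mcfg), records, lookup,
                           SOLVENTS, tcfg)
        clf = stage2_finetune(reg, records, lookup, SOLVENTS, tcfg)
        assert clf.parameter_fingerprint(exclude_head=True) == \
            reg.parameter_fingerprint(exclude_head=True)
        probs = score_records([clf], records, lookup, SOLVENTS)
        hits = np.array([label(r).retrospective_hit for r in records])
        # linearly separable fixture: perfect ranking (AUC 1)
        assert probs[hits].min() > probs[~hits].max()

    def test_stage2_single_class_rejected(self):
        records, lookup = small_training_problem()
        all_miss = [record(rac=r.racemate_id, agent=r.agent_id, m_frac=0.25,
                           ee=0.05) for r in records]
        reg = stage1_train(DualStreamModel(self.mcfg), all_miss, lookup,
                           SOLVENTS, TrainConfig(stage1_steps=5,
                                                 val_fraction=0.0))
        with pytest.raises(ValueError, match="both classes"):
            stage2_finetune(reg, all_miss, lookup, SOLVENTS, TrainConfig())


class TestRankAgents:
    def _models(self):
        return [DualStreamModel(ModelConfig(solvent_dim=8,
                                            head_kind="classification",
                                            seed=s)) for s in (0, 1)]

    def test_score_is_max_over_solvents(self):
        keys = [("rx", f"a{j}") for j in range(3)]
        lookup = toy_lookup(keys, seed=3)
        models = self._models()
        df = rank_agents(models, "rx", [k[1] for k in keys], ["S0", "S1"],
                         lookup, SOLVENTS)
        for _, row in df.iterrows():
            per_solvent = [score_records(models,
                                         [record(rac="rx",
                                                 agent=row["agent_id"],
                                                 solvent=s)],
                                         lookup, SOLVENTS)[0]
                           for s in ("S0", "S1")]
            assert row["score"] == pytest.approx(max(per_solvent))

    def test_solvent_order_irrelevant(self):
        keys = [("rx", f"a{j}") for j in range(3)]
        lookup = toy_lookup(keys, seed=4)
        models = self._models()
        a = rank_agents(models, "rx", [k[1] for k in keys], ["S0", "S1"],
                        lookup, SOLVENTS)
        b = rank_agents(models, "rx", [k[1] for k in keys], ["S1", "S0"],
                        lookup, SOLVENTS)
        assert list(a["agent_id"]) == list(b["agent_id"])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            rank_agents(self._models(), "rx", [], ["S0"], {}, SOLVENTS)


class TestDatasetSummary:
    def test_bookkeeping_consistency(self):
        records = [record(rac=f"r{i % 4}", m_frac=0.4 if i % 5 == 0 else 0.1,
                          ee=0.5) for i in range(20)]
        s = dataset_summary(records)
        hits = [label(r).retrospective_hit for r in records]
        assert s["hit_rate"] == pytest.approx(np.mean(hits))
        assert s["hit_rate"] + s["non_hit_rate"] == pytest.approx(1.0)
        assert s["n_racemates"] == 4
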