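"""Metrics against brute-force oracles, splits, and orchestration."""

import numpy as np
import pytest

from dtifuse.dtp import DTPNode
from dtifuse.experiment import (
    ExperimentConfig,
    SplitSpec,
    SplitError,
    degree_product_baseline,
    make_split,
    run_experiment,
)
from dtifuse.metrics import MetricError, MetricReport, accuracy, aupr, auroc
from dtifuse.synthetic import SyntheticConfig


def auroc_pairwise_oracle(scores, labels):
    """Brute force over all positive x negative pairs; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUROC:
    def test_perfect_and_inverted(self):
        assert auroc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0
        assert auroc([0.1, 0.2, 0.9], [1, 1, 0]) == 0.0

    def test_three_point_example(self):
        assert auroc([0.9, 0.8, 0.3], [1, 0, 1]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(MetricError):
            auroc([0.1, 0.2], [1, 1])

    def test_agrees_with_pairwise_oracle_on_random_vectors(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 200))
            scores = rng.choice(np.round(rng.random(20), 2), size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert auroc(scores, labels) == pytest.approx(
                auroc_pairwise_oracle(scores, labels), abs=1e-12)


class TestAUPR:
    def test_perfect_separation(self):
        assert aupr([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_positive_fraction(self):
        labels = [1, 0, 0, 1, 0]
        assert aupr([0.5] * 5, labels) == pytest.approx(2 / 5)

    def test_three_point_hand_stepped_curve(self):
        # thresholds descending: 0.9 (P, prec 1, rec 1/2) then 0.3 (P, prec 2/3, rec 1)
        expected = 0.5 * 1.0 + 0.5 * (2 / 3)
        assert aupr([0.9, 0.8, 0.3], [1, 0, 1]) == pytest.approx(expected)


class TestAccuracy:
    def test_all_correct(self):
        assert accuracy([0.9, 0.1], [1, 0]) == 1.0

    def test_constant_scores_above_threshold_predict_positive(self):
        assert accuracy([0.6] * 4, [1, 0, 1, 0]) == 0.5

    def test_direct_count(self):
        assert accuracy([0.7, 0.4, 0.8, 0.2], [1, 1, 0, 0], threshold=0.5) == 0.5

    def test_report_bounds_enforced(self):
        with pytest.raises(MetricError):
            MetricReport(auroc=1.2, aupr=0.5, acc=0.5)


def _nodes(rng, n=200, n_drugs=12, n_targets=15):
    return [DTPNode(int(rng.integers(n_drugs)), int(rng.integers(n_targets)),
                    int(rng.integers(2))) for _ in range(n)]


class TestSplits:
    def test_random_split_sizes(self, rng):
        nodes = _nodes(rng, n=1000)
        tr, va, te = make_split(nodes, SplitSpec(fractions=(0.8, 0.1, 0.1), seed=0))
        assert abs(len(tr) - 800) <= 1 and abs(len(va) - 100) <= 1
        assert len(tr) + len(va) + len(te) == 1000
        assert len(np.intersect1d(tr, te)) == 0

    def test_same_seed_identical_split(self, rng):
        nodes = _nodes(rng)
        s1 = make_split(nodes, SplitSpec(seed=4))
        s2 = make_split(nodes, SplitSpec(seed=4))
        for a, b in zip(s1, s2):
            assert np.array_equal(a, b)

    @pytest.mark.parametrize("mode,attr", [("cold_drug", "drug_idx"),
                                           ("cold_target", "target_idx")])
    def test_cold_modes_have_zero_entity_overlap(self, rng, mode, attr):
        nodes = _nodes(rng)
        tr, va, te = make_split(nodes, SplitSpec(mode=mode, seed=1))
        train_entities = {getattr(nodes[i], attr) for i in tr}
        test_entities = {getattr(nodes[i], attr) for i in te}
        val_entities = {getattr(nodes[i], attr) for i in va}
        assert train_entities & test_entities == set()
        assert train_entities & val_entities == set()

    def test_bad_fractions_rejected(self):
        with pytest.raises(SplitError):
            SplitSpec(fractions=(0.5, 0.2, 0.2))

    def test_infeasible_cold_split_raises(self):
        nodes = [DTPNode(0, t, 1) for t in range(10)]  # a single drug
        with pytest.raises(SplitError):
            make_split(nodes, SplitSpec(mode="cold_drug", seed=0))


class TestDegreeBaseline:
    def test_scores_are_train_positive_degree_products(self):
        nodes = [DTPNode(0, 0, 1), DTPNode(0, 1, 1), DTPNode(1, 0, 1),
                 DTPNode(1, 1, 0)]
        tr = np.array([0, 1, 2])
        s = degree_product_baseline(nodes, tr, np.array([3]))
        # eval pair (drug 1, target 1): deg_drug[1] = 1, deg_target[1] = 1
        assert s[0] == 1.0
        s_all = degree_product_baseline(nodes, tr, np.arange(4))
        # pair (drug 0, target 0): deg_drug[0] = 2, deg_target[0] = 2
        assert s_all[0] == 4.0


@pytest.fixture(scope="module")
def tiny_result():
    cfg = ExperimentConfig(seed=11)
    cfg.synthetic = SyntheticConfig(n_drugs=20, n_targets=25, n_diseases=10,
                                    n_side_effects=12, latent_dim=4,
                                    dti_density=0.12, seed=11)
    cfg.train.epochs = 15
    return cfg, run_experiment(cfg)


class TestRunExperiment:
    def test_report_fields_in_unit_interval(self, tiny_result):
        _, out = tiny_result
        r = out["report"]
        assert 0.0 <= r.auroc <= 1.0 and 0.0 <= r.aupr <= 1.0 and 0.0 <= r.acc <= 1.0

    def test_same_seed_reproduces_report(self, tiny_result):
        cfg, out = tiny_result
        out2 = run_experiment(cfg)
        assert out2["report"].auroc == out["report"].auroc
        assert np.array_equal(out2["train_result"].scores, out["train_result"].scores)

    def test_no_causal_ablation_history_logs_unused_lcl(self):
        cfg = ExperimentConfig(seed=11)
        cfg.synthetic = SyntheticConfig(n_drugs=20, n_targets=25, n_diseases=10,
                                        n_side_effects=12, latent_dim=4,
                                        dti_density=0.12, seed=11)
        cfg.train.epochs = 5
        cfg.ablation = "no_causal"
        out = run_experiment(cfg)
        h = out["history"]
        assert np.isfinite(h["L_CL"]).all()
        assert np.array_equal(h["L"].to_numpy(), h["L_CE"].to_numpy())

    def test_stage_name_propagated_on_failure(self):
        cfg = ExperimentConfig(seed=11, dataset_dir="/nonexistent/path")
        with pytest.raises(RuntimeError, match="dataset"):
            run_experiment(cfg)

    def test_artifacts_written(self, tmp_path):
        cfg = ExperimentConfig(seed=11)
        cfg.synthetic = SyntheticConfig(n_drugs=20, n_targets=25, n_diseases=10,
                                        n_side_effects=12, latent_dim=4,
                                        dti_density=0.12, seed=11)
        cfg.train.epochs = 3
        run_experiment(cfg, out_dir=tmp_path)
        for f in ("metrics.json", "history.tsv", "dtp_nodes.tsv", "dtp_edges.tsv"):
            assert (tmp_path / f).exists()
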