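import numpy as np
import pytest

from hetlink.features import EmbeddingMatrix, PairDataset, build_dataset
from hetlink.predict_eval import (
    evaluate_external,
    compute_metrics,
    kfold_cv,
    rank_candidates,
    score_rows,
    train_classifier,
)


def separable_dataset(n_per_class=60, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.normal(loc=2.0, size=(n_per_class, dim))
    neg = rng.normal(loc=-2.0, size=(n_per_class, dim))
    pairs = [(f"s{i}", f"m{i}") for i in range(2 * n_per_class)]
    return PairDataset(
        pairs=pairs,
        features=np.vstack([pos, neg]),
        labels=np.concatenate([np.ones(n_per_class, int), np.zeros(n_per_class, int)]),
    )


class TestTrainClassifier:
    def test_gbdt_fits_separable_data(self):
        ds = separable_dataset()
        clf = train_classifier(ds, kind="gbdt", seed=1)
        pred = (score_rows(clf, ds.features) >= 0.5).astype(int)
        assert (pred == ds.labels).mean() == 1.0

    def test_one_nearest_neighbour_memorises(self):
        ds = separable_dataset(n_per_class=20)
        clf = train_classifier(ds, kind="knn", params={"n_neighbors": 1})
        pred = (score_rows(clf, ds.features) >= 0.5).astype(int)
        np.testing.assert_array_equal(pred, ds.labels)

    def test_gbdt_seed_determinism(self):
        ds = separable_dataset()
        probe = np.random.default_rng(3).normal(size=(10, 4))
        s1 = score_rows(train_classifier(ds, "gbdt", seed=7), probe)
        s2 = score_rows(train_classifier(ds, "gbdt", seed=7), probe)
        np.testing.assert_array_equal(s1, s2)

    @pytest.mark.parametrize("kind", ["naive_bayes", "logistic", "adaboost"])
    def test_baselines_run(self, kind):
        ds = separable_dataset(n_per_class=25)
        clf = train_classifier(ds, kind=kind, seed=0)
        scores = score_rows(clf, ds.features)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_single_class_rejected(self):
        ds = separable_dataset(n_per_class=5)
        bad = PairDataset(pairs=ds.pairs[:5], features=ds.features[:5], labels=np.ones(5, int))
        with pytest.raises(ValueError):
            train_classifier(bad)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(separable_dataset(), kind="svm")


class TestKFoldCV:
    def test_two_fold_separable_perfect_auc(self):
        ds = separable_dataset(n_per_class=30)
        report = kfold_cv(ds, k=2, kind="logistic", seed=1)
        assert all(f["auc"] == 1.0 for f in report.per_fold)

    def test_fold_assignment_keyed_on_pair_ids(self):
        from hetlink.predict_eval import _fold_of_pairs

        ds = separable_dataset(n_per_class=20)
        fold1 = _fold_of_pairs(ds.pairs, ds.labels, k=4, seed=3)
        perm = np.random.default_rng(0).permutation(len(ds.pairs))
        shuffled_pairs = [ds.pairs[i] for i in perm]
        fold2 = _fold_of_pairs(shuffled_pairs, ds.labels[perm], k=4, seed=3)
        by_pair1 = dict(zip(ds.pairs, fold1))
        by_pair2 = dict(zip(shuffled_pairs, fold2))
        assert by_pair1 == by_pair2

    def test_means_are_arithmetic_means(self):
        ds = separable_dataset(n_per_class=25, seed=5)
        report = kfold_cv(ds, k=5, kind="naive_bayes", seed=2)
        for name, value in report.means.items():
            assert value == pytest.approx(
                np.mean([f[name] for f in report.per_fold]), abs=1e-12
            )

    def test_k_larger_than_class_rejected(self):
        ds = separable_dataset(n_per_class=3)
        with pytest.raises(ValueError):
            kfold_cv(ds, k=5)

    def test_report_serialises(self, tmp_path):
        ds = separable_dataset(n_per_class=15)
        report = kfold_cv(ds, k=3, kind="logistic", seed=0)
        out = tmp_path / "report.json"
        report.to_json(out)
        import json

        loaded = json.loads(out.read_text())
        assert set(loaded["means"]) == {"recall", "precision", "accuracy", "f1", "auc", "aupr"}


class TestEvaluateExternal:
    @staticmethod
    def _fixture():
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(6)] + [f"m{i}" for i in range(6)]
        emb = EmbeddingMatrix(ids=ids, vectors=rng.normal(size=(12, 4)), source="merged")
        positives = [(f"s{i}", f"m{i}") for i in range(6)]
        ds = build_dataset(positives, ids[:6], ids[6:], emb, seed=1)
        clf = train_classifier(ds, "logistic", seed=0)
        return emb, ds, clf

    def test_consistency_with_compute_metrics(self):
        emb, ds, clf = self._fixture()
        metrics = evaluate_external(clf, emb, ds.pairs, ds.labels)
        direct = compute_metrics(ds.labels, score_rows(clf, ds.features))
        assert metrics == direct

    def test_empty_pairs_rejected(self):
        emb, _ds, clf = self._fixture()
        with pytest.raises(ValueError):
            evaluate_external(clf, emb, [], [])

    def test_unknown_endpoint_skipped(self, caplog):
        emb, ds, clf = self._fixture()
        pairs = list(ds.pairs) + [("s0", "m-unknown")]
        labels = list(ds.labels) + [1]
        with caplog.at_level("WARNING"):
            metrics = evaluate_external(clf, emb, pairs, labels)
        assert "skipped 1" in caplog.text
        assert metrics == evaluate_external(clf, emb, ds.pairs, ds.labels)

    def test_all_unknown_rejected(self):
        emb, _ds, clf = self._fixture()
        with pytest.raises(ValueError):
            evaluate_external(clf, emb, [("zz", "qq")], [1])


class _ConstantScorer:
    classes_ = [0, 1]

    def predict_proba(self, X):
        return np.tile([0.4, 0.6], (len(X), 1))


class TestRankCandidates:
    @staticmethod
    def _fixture():
        rng = np.random.default_rng(4)
        ids = ["s0"] + [f"m{i}" for i in range(5)]
        emb = EmbeddingMatrix(ids=ids, vectors=rng.normal(size=(6, 3)), source="merged")
        return emb, [f"m{i}" for i in range(5)]

    def test_top_n_capped_at_candidates(self):
        emb, mirnas = self._fixture()
        ranked = rank_candidates(
            _ConstantScorer(), emb, "s0", set(), top_n=100, mirna_ids=mirnas
        )
        assert len(ranked.entries) == 5

    def test_known_positives_excluded(self):
        emb, mirnas = self._fixture()
        ranked = rank_candidates(
            _ConstantScorer(), emb, "s0", {("s0", "m1"), ("s0", "m3")},
            top_n=10, mirna_ids=mirnas,
        )
        names = [m for m, _p in ranked.entries]
        assert "m1" not in names and "m3" not in names

    def test_ties_broken_lexicographically(self):
        emb, mirnas = self._fixture()
        ranked = rank_candidates(
            _ConstantScorer(), emb, "s0", set(), top_n=10, mirna_ids=mirnas
        )
        names = [m for m, _p in ranked.entries]
        assert names == sorted(names)

    def test_unknown_sm_rejected(self):
        emb, mirnas = self._fixture()
        with pytest.raises(KeyError):
            rank_candidates(_ConstantScorer(), emb, "nope", set(), mirna_ids=mirnas)

    def test_descending_probability_order(self):
        rng = np.random.default_rng(1)

        class RandomScorer:
            classes_ = [0, 1]

            def predict_proba(self, X):
                p = rng.random(len(X))
                return np.column_stack([1 - p, p])

        emb, mirnas = self._fixture()
        ranked = rank_candidates(RandomScorer(), emb, "s0", set(), top_n=10, mirna_ids=mirnas)
        probs = [p for _m, p in ranked.entries]
        assert probs == sorted(probs, reverse=True)


class TestPlantedStructureRecovery:
    def test_holdout_partners_rank_above_median(self):
        """Withheld true partners of probe SMs outrank random non-partners.

        Embeddings are trained on a graph without the held-out edges, so a
        high mean percentile of the held-out partners demonstrates genuine
        recovery of the planted latent structure, averaged over 5 seeds.
        """
        from hetlink.pipeline import PipelineConfig, build_graph, combined_embedding, association_entities
        from hetlink.synthgen import SynthConfig, generate

        percentiles = []
        for seed in range(5):
            data = generate(SynthConfig(seed=100 + seed, holdout_frac=0.2))
            cfg = PipelineConfig(
                seed=seed,
                hegan_dim=16,
                hin2vec_dim=16,
                hin2vec_overrides={"walks_per_node": 5, "walk_length": 40, "epochs": 3},
            )
            graph = build_graph(data, cfg)
            embedding = combined_embedding(graph, cfg)
            positives, sms, mirnas = association_entities(data, graph)
            ds = build_dataset(positives, sms, mirnas, embedding, seed=seed)
            clf = train_classifier(ds, "gbdt", seed=seed)
            known = set(positives)
            held = [
                (s, m) for s, m in data.holdout_positive_pairs
                if s in embedding and m in embedding and m in set(mirnas)
            ]
            by_sm: dict[str, list[str]] = {}
            for s, m in held:
                by_sm.setdefault(s, []).append(m)
            probe_sms = [s for s, ms in by_sm.items() if len(ms) >= 2][:5]
            for s in probe_sms:
                ranked = rank_candidates(
                    clf, embedding, s, known, top_n=10**9, mirna_ids=mirnas
                )
                order = [m for m, _p in ranked.entries]
                n = len(order)
                for m in by_sm[s]:
                    if m in order:
                        percentiles.append(1.0 - order.index(m) / n)
        assert np.mean(percentiles) > 0.5
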