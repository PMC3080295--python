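"""Biosignature encoding, LOOCV max-margin evaluation and ROC/AUC."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import signet as sg
from signet.data_io import DataError, ExpressionMatrix
from signet.knn_integration import Neighborhood
from signet.signature_classify import (
    Biosignature,
    build_features,
    compare_models,
    evaluate_signature,
    k_sweep,
    loocv_evaluate,
    roc_auc,
)


def nb(q, genes):
    return Neighborhood(q, len(genes), [(g, 0.9 - 0.01 * i) for i, g in enumerate(genes)])


def labelled_matrix(rows, n_treated=3):
    df = pd.DataFrame(rows).T.astype(float)
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    labels = pd.Series(
        ["treated"] * n_treated + ["untreated"] * (df.shape[1] - n_treated),
        index=df.columns,
    )
    return ExpressionMatrix(df, labels)


class TestBuildFeatures:
    matrix = ExpressionMatrix(
        pd.DataFrame(
            np.arange(20, dtype=float).reshape(5, 4),
            index=["q1", "q2", "a", "b", "c"],
            columns=["s0", "s1", "s2", "s3"],
        )
    )

    def test_neighborhood_representation_one_column_per_query(self):
        sig = Biosignature(
            "six",
            [f"q{i}" for i in range(6)],
            {f"q{i}": nb(f"q{i}", []) for i in range(6)},
            "integrated_neighborhood",
        )
        m = ExpressionMatrix(
            pd.DataFrame(
                np.random.default_rng(0).normal(size=(6, 4)),
                index=[f"q{i}" for i in range(6)],
                columns=list("wxyz"),
            )
        )
        assert build_features(sig, m).shape == (4, 6)

    def test_neighborhood_column_is_group_mean(self):
        sig = Biosignature("s", ["q1"], {"q1": nb("q1", ["a", "b"])})
        feats = build_features(sig, self.matrix)
        expected = self.matrix.values.loc[["q1", "a", "b"]].mean(axis=0)
        assert np.allclose(feats["q1"], expected)

    def test_empty_neighborhood_feature_equals_query_row(self):
        sig = Biosignature("s", ["q1"], {})
        feats = build_features(sig, self.matrix)
        assert np.allclose(feats["q1"], self.matrix.values.loc["q1"])

    def test_member_order_permutation_invariant(self):
        a = Biosignature("s", ["q1"], {"q1": nb("q1", ["a", "b", "c"])})
        b = Biosignature("s", ["q1"], {"q1": nb("q1", ["c", "a", "b"])})
        assert np.allclose(
            build_features(a, self.matrix), build_features(b, self.matrix)
        )

    def test_individual_representation_lists_distinct_genes(self):
        sig = Biosignature(
            "s", ["q1", "q2"], {"q1": nb("q1", ["a", "b"]), "q2": nb("q2", ["b", "c"])},
            "individual_gene",
        )
        feats = build_features(sig, self.matrix)
        assert sorted(feats.columns) == ["a", "b", "c", "q1", "q2"]

    def test_missing_genes_dropped_with_warning(self):
        sig = Biosignature("s", ["q1"], {"q1": nb("q1", ["a", "zz"])})
        with pytest.warns(UserWarning, match="absent"):
            feats = build_features(sig, self.matrix)
        assert np.allclose(feats["q1"], self.matrix.values.loc[["q1", "a"]].mean(axis=0))

    def test_zero_feature_signature_errors(self):
        sig = Biosignature("s", ["nope"], {}, "individual_gene")
        with pytest.warns(UserWarning):
            with pytest.raises(DataError, match="no features"):
                build_features(sig, self.matrix)


class TestRocAuc:
    def test_perfectly_ordered_scores(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_anti_ordered_scores(self):
        _, auc = roc_auc([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1])
        assert auc == 0.0

    def test_ties_counted_half(self):
        scores = [0.5, 0.5, 0.7, 0.3, 0.5, 0.9]
        labels = [1, 0, 1, 0, 0, 1]
        _, auc = roc_auc(scores, labels)
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        brute = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        ) / (len(pos) * len(neg))
        assert auc == pytest.approx(brute, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_pairwise_formula_matches_trapezoid_sweep(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([0.1, 0.2], [1, 1])


class TestLoocv:
    def test_separable_data_reaches_auc_one(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(5, 0.1, (6, 2)), rng.normal(-5, 0.1, (6, 2))])
        y = np.array([1] * 6 + [0] * 6)
        ev = loocv_evaluate(pd.DataFrame(X), y)
        assert ev.auc == 1.0
        assert len(ev.scores) == 12

    def test_permuted_labels_null_centered_at_half(self):
        # six features, mirroring the six-query neighbourhood design; with
        # very few features the pooled-score LOOCV AUC is known to be
        # pessimistically biased under the null
        rng = np.random.default_rng(2)
        aucs = []
        for _ in range(200):
            X = pd.DataFrame(rng.normal(size=(12, 6)))
            y = rng.permutation([1] * 6 + [0] * 6)
            aucs.append(loocv_evaluate(X, y).auc)
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se

    def test_constant_feature_gives_half(self):
        X = pd.DataFrame(np.ones((8, 1)))
        y = np.array([1, 1, 0, 0, 1, 1, 0, 0])
        assert loocv_evaluate(X, y).auc == 0.5

    def test_held_out_score_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(10, 2)))
        y = np.array([1, 0] * 5)
        ev = loocv_evaluate(X, y)
        perm = rng.permutation(10)
        ev2 = loocv_evaluate(X.iloc[perm], y[perm])
        back = ev2.scores.to_numpy()[np.argsort(perm)]
        # tolerance reflects the SMO solver's numerical convergence, not
        # any order dependence of the procedure itself
        assert np.allclose(ev.scores.to_numpy(), back, atol=1e-3)

    def test_auc_equals_mann_whitney_on_scores(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(12, 3)))
        y = np.array([1] * 6 + [0] * 6)
        ev = loocv_evaluate(X, y)
        _, auc = roc_auc(ev.scores, y)
        assert ev.auc == pytest.approx(auc, abs=1e-9)

    def test_fold_without_both_classes_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(DataError):
            loocv_evaluate(X, np.array([1, 0, 0, 0]))


@pytest.fixture(scope="module")
def fitted(small_config, small_cohort):
    g, ann = sg.generate_ontology(small_config)
    model = sg.build_ontology_model(g, ann, "BP")
    profiles = sg.profiles_from_annotations(ann, "BP")
    return sg.IntegratedKNN(ontology_model=model, profiles=profiles).fit(small_cohort)


class TestCompareAndSweep:
    def test_identical_signature_evaluates_identically(self, fitted, small_config):
        queries = [m.query for m in small_config.modules]
        nbh = fitted.kneighbors(queries, k=5)
        sig = Biosignature("s", queries, nbh)
        a = evaluate_signature(sig, fitted.matrix_)
        b = evaluate_signature(sig, fitted.matrix_)
        assert a.auc == b.auc

    def test_planted_neighborhood_beats_shuffled_control(self, fitted, small_config):
        queries = [m.query for m in small_config.modules]
        nbh = fitted.kneighbors(queries, k=5)
        planted = Biosignature("planted", queries, nbh)
        rng = np.random.default_rng(0)
        background = [g for g in fitted.matrix_.gene_ids if g.startswith("GENE")]
        wins = 0
        n_controls = 20
        for _ in range(n_controls):
            shuffled = {
                q: nb(q, list(rng.choice(background, size=5, replace=False)))
                for q in queries
            }
            control = Biosignature("control", queries, shuffled)
            table = compare_models([planted, control], fitted.matrix_)
            aucs = dict(zip(table["name"], table["auc"]))
            wins += aucs["planted"] >= aucs["control"]
        assert wins >= 0.9 * n_controls

    def test_k_sweep_has_twenty_rows(self, fitted, small_config):
        queries = [m.query for m in small_config.modules]
        sweep = k_sweep(fitted, queries, fitted.matrix_, k_range=range(1, 21))
        assert list(sweep["k"]) == list(range(1, 21))
        assert sweep["auc"].between(0, 1).all()

    def test_compare_models_reports_feature_counts(self, fitted, small_config):
        queries = [m.query for m in small_config.modules]
        nbh = fitted.kneighbors(queries, k=5)
        table = compare_models(
            [
                Biosignature("Q", queries, {}, "individual_gene"),
                Biosignature("Q+5NN", queries, nbh, "integrated_neighborhood"),
                Biosignature("Q+5NN-ind", queries, nbh, "individual_gene"),
            ],
            fitted.matrix_,
        )
        counts = dict(zip(table["name"], table["n_features"]))
        assert counts["Q"] == 2
        assert counts["Q+5NN"] == 2
        assert counts["Q+5NN-ind"] == len(
            {g for q in queries for g in [q, *nbh[q].genes]}
        )


class TestSignatureEncoder:
    def test_transformer_matches_build_features(self, small_cohort):
        sig = Biosignature("s", ["QUERY1"], {"QUERY1": nb("QUERY1", ["MOD1_M1"])})
        enc = sg.SignatureEncoder(signature=sig, gene_ids=small_cohort.gene_ids)
        enc.fit(small_cohort.values.T.to_numpy())
        got = enc.transform(small_cohort.values.T.to_numpy())
        expected = build_features(sig, small_cohort).to_numpy()
        assert np.allclose(got, expected)
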