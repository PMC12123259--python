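"""Feature building, boosted-tree fitting, CV discipline and metrics."""

import numpy as np
import pandas as pd
import pytest

from rewirenet import dataio, linkmodel as lm
from rewirenet.linkmodel import SchemaMismatchError


@pytest.fixture(scope="module")
def trained(small_eco):
    pairs = dataio.assemble_training_pairs(small_eco.networks)
    model = lm.fit(pairs, small_eco.resource, small_eco.consumer, seed=0)
    return pairs, model


class TestFeatures:
    def test_all_pairs_row_count(self, small_eco):
        from rewirenet.metaweb import all_pairs_index
        idx = all_pairs_index(["r1", "r2"], ["c1", "c2", "c3"])
        x, _ = lm.build_features(idx, *self._tiny_tables(small_eco, idx))
        assert len(x) == 6

    @staticmethod
    def _tiny_tables(small_eco, idx):
        res = small_eco.resource.data.iloc[:2].copy()
        res.index = pd.Index(["r1", "r2"], name="species_id")
        con = small_eco.consumer.data.iloc[:3].copy()
        con.index = pd.Index(["c1", "c2", "c3"], name="species_id")
        return (
            dataio.TraitTable(res, "resource", small_eco.resource.schema),
            dataio.TraitTable(con, "consumer", small_eco.consumer.schema),
        )

    def test_deterministic(self, small_eco):
        pairs = dataio.assemble_training_pairs(small_eco.networks)
        x1, e1 = lm.build_features(pairs, small_eco.resource, small_eco.consumer)
        x2, e2 = lm.build_features(pairs, small_eco.resource, small_eco.consumer)
        assert x1.equals(x2) and e1 == e2

    def test_rows_carry_the_pairs_own_traits(self, small_eco):
        pairs = dataio.assemble_training_pairs(small_eco.networks)
        x, _ = lm.build_features(pairs, small_eco.resource, small_eco.consumer)
        i = 7
        rid, cid = pairs.resource_id.iloc[i], pairs.consumer_id.iloc[i]
        assert x.loc[i, "res_corolla_length"] == small_eco.resource.data.loc[rid, "corolla_length"]
        assert x.loc[i, "con_bill_length"] == small_eco.consumer.data.loc[cid, "bill_length"]

    def test_schema_drift_rejected(self, trained, small_eco):
        pairs, model = trained
        x, _ = lm.build_features(pairs, small_eco.resource, small_eco.consumer)
        with pytest.raises(SchemaMismatchError):
            model.predict(x.drop(columns=x.columns[0]))


class TestFit:
    def test_single_class_rejected(self, small_eco):
        pairs = pd.DataFrame({"resource_id": ["R000"], "consumer_id": ["C000"], "label": [1]})
        with pytest.raises(lm.FittingError):
            lm.fit(pairs, small_eco.resource, small_eco.consumer)

    def test_matching_traits_lead_importance(self, study):
        top3 = set(study.model.importance.feature[:3])
        assert {"res_corolla_length", "con_bill_length"} <= top3

    def test_refit_reproduces_predictions(self, trained, small_eco):
        pairs, model = trained
        again = lm.fit(pairs, small_eco.resource, small_eco.consumer, seed=0)
        x, _ = lm.build_features(pairs, small_eco.resource, small_eco.consumer)
        assert np.array_equal(model.predict(x), again.predict(x))


class TestCrossValidate:
    def test_leave_one_out_definition(self, small_eco):
        pairs = dataio.assemble_training_pairs(small_eco.networks).head(20)
        cv = lm.cross_validate(pairs, small_eco.resource, small_eco.consumer, k=20, seed=0,
                               params={"n_estimators": 40, "early_stopping_rounds": 10})
        assert np.isfinite(cv.scores).all()
        assert len(set(cv.fold)) == 20  # every row its own held-out fold

    def test_rejects_k_below_two(self, small_eco):
        pairs = dataio.assemble_training_pairs(small_eco.networks)
        with pytest.raises(ValueError):
            lm.cross_validate(pairs, small_eco.resource, small_eco.consumer, k=1)

    def test_perfectly_separable_scores_auc_one(self, small_eco):
        # labels defined by a trait threshold: fully learnable
        pairs = dataio.assemble_training_pairs(small_eco.networks)
        corolla = small_eco.resource.data["corolla_length"]
        pairs = pairs.assign(label=(corolla.loc[pairs.resource_id] > corolla.median()).astype(int).to_numpy())
        cv = lm.cross_validate(pairs, small_eco.resource, small_eco.consumer, k=5, seed=0,
                               params={"n_estimators": 300, "early_stopping_rounds": 30})
        assert cv.metrics.auc == pytest.approx(1.0, abs=5e-3)

    def test_pooled_metrics_recomputable_from_scores(self, small_eco):
        pairs = dataio.assemble_training_pairs(small_eco.networks)
        cv = lm.cross_validate(pairs, small_eco.resource, small_eco.consumer, k=5, seed=0,
                               params={"n_estimators": 100, "early_stopping_rounds": 20})
        redo = lm.evaluate(cv.labels, cv.scores, 0.4)
        assert redo.as_dict() == cv.metrics.as_dict()

    def test_out_of_fold_scores_come_from_models_excluding_the_row(self, small_eco):
        # recomputation oracle: rebuild one fold's model from its training
        # rows only and confirm the held-out scores match exactly
        import lightgbm as lgb
        from sklearn.model_selection import StratifiedKFold

        pairs = dataio.assemble_training_pairs(small_eco.networks)
        p = {"n_estimators": 80, "early_stopping_rounds": 20}
        cv = lm.cross_validate(pairs, small_eco.resource, small_eco.consumer, k=5, seed=0, params=p)
        x, _ = lm.build_features(pairs, small_eco.resource, small_eco.consumer)
        xv, y = x.to_numpy(), pairs.label.to_numpy()
        tr, te = next(iter(StratifiedKFold(5, shuffle=True, random_state=0).split(xv, y)))
        full = {**lm.DEFAULT_PARAMS, **p}
        n_trees = lm._select_n_trees(xv[tr], y[tr], full, seed=0)
        refit = lgb.train(lm._lgb_params(full, 0),
                          lgb.Dataset(xv[tr], y[tr], feature_name=list(x.columns)),
                          num_boost_round=n_trees)
        assert np.array_equal(cv.scores[te], refit.predict(xv[te]))
        assert (cv.fold[te] == 0).all()


class TestEvaluate:
    def test_symmetric_confusion_table(self):
        labels = np.r_[np.ones(50), np.zeros(50)].astype(int)
        scores = np.r_[np.full(40, 0.9), np.full(10, 0.1), np.full(10, 0.9), np.full(40, 0.1)]
        m = lm.evaluate(labels, scores, 0.5)
        assert (m.tp, m.fn, m.fp, m.tn) == (40, 10, 10, 40)
        assert m.accuracy == pytest.approx(0.8)
        assert m.kappa == pytest.approx(0.6)
        assert m.mcc == pytest.approx(0.6)

    def test_auc_equals_pairwise_ordering_statistic(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        scores = np.round(rng.random(200), 1)  # ties exercised
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        brute = wins / (len(pos) * len(neg))
        assert lm.evaluate(labels, scores).auc == pytest.approx(brute, abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 300)
        labels[:2] = [0, 1]
        scores = rng.random(300)
        a1 = lm.evaluate(labels, scores).auc
        a2 = lm.evaluate(labels, np.exp(5 * scores)).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lm.evaluate(np.ones(5, dtype=int), np.random.default_rng(0).random(5))


class TestChooseThreshold:
    def test_fixed_default(self):
        assert lm.choose_threshold(None, None, "fixed") == 0.4

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            lm.choose_threshold(np.array([0, 1]), np.array([0.1, 0.9]), "best_guess")

    def test_separated_scores_smallest_grid_maximizer(self):
        labels = np.r_[np.zeros(5), np.ones(5)].astype(int)
        scores = np.r_[np.full(5, 0.1), np.full(5, 0.9)]
        # with the strict score > tau rule, 0.10 already classifies perfectly
        assert lm.choose_threshold(labels, scores, "max_kappa") == pytest.approx(0.10)

    def test_max_kappa_matches_exhaustive_grid(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        scores = rng.random(100)
        tau = lm.choose_threshold(labels, scores, "max_kappa")
        from sklearn.metrics import cohen_kappa_score
        grid = lm.THRESHOLD_GRID
        kappas = [cohen_kappa_score(labels, (scores > t).astype(int)) for t in grid]
        best = max(kappas)
        oracle = grid[next(i for i, v in enumerate(kappas) if v >= best - 1e-12)]
        assert tau == pytest.approx(oracle)
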