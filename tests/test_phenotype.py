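import numpy as np
import pandas as pd
import pytest

import phenofreeze as pf
from phenofreeze.mixture import MixtureModel


def toy_model(means, feature_names=("sustained_mean", "b", "y0"), weights=(0.5, 0.5)):
    means = np.asarray(means, dtype=float)
    k, d = means.shape
    covs = np.tile(np.eye(d), (k, 1, 1))
    return MixtureModel(k=k, weights=np.asarray(weights, dtype=float), means=means,
                        covariances=covs, log_likelihood=0.0, bic=0.0, n_iter=1,
                        converged=True, covariance_family="full", n_samples=10,
                        feature_names=tuple(feature_names))


def features_frame(rows, ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    ids = ids or [f"A{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, columns=["sustained_mean", "b", "y0"],
                        index=pd.Index(ids, name="animal_id"))


class TestAssignPhenotypes:
    def test_point_at_sustained_centre(self):
        model = toy_model([[70.0, 0.02, 85.0], [10.0, 0.25, 85.0]])
        asg = pf.assign_phenotypes(model, features_frame([[70.0, 0.02, 85.0]]))
        assert asg.loc[0, "label"] == "sustained"
        assert asg.loc[0, "posterior"] > 0.99

    def test_label_invariant_under_component_swap(self):
        m1 = toy_model([[70.0, 0.02, 85.0], [10.0, 0.25, 85.0]])
        m2 = toy_model([[10.0, 0.25, 85.0], [70.0, 0.02, 85.0]])
        X = features_frame([[65.0, 0.03, 80.0], [12.0, 0.2, 90.0]])
        a1 = pf.assign_phenotypes(m1, X)
        a2 = pf.assign_phenotypes(m2, X)
        pd.testing.assert_frame_equal(a1, a2)

    def test_exact_tie_goes_to_sustained_flagged(self):
        # symmetric components, point at the midpoint: responsibility exactly 0.5
        model = toy_model([[20.0, 0.0, 0.0], [40.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="0.5"):
            asg = pf.assign_phenotypes(model, features_frame([[30.0, 0.0, 0.0]]))
        assert asg.loc[0, "label"] == "sustained"
        assert bool(asg.loc[0, "tied"])

    def test_dimension_mismatch_rejected(self):
        model = toy_model([[70.0, 0.02], [10.0, 0.25]],
                          feature_names=("sustained_mean", "b"))
        with pytest.raises(ValueError, match="dimensionality"):
            pf.assign_phenotypes(model, features_frame([[70.0, 0.02, 85.0]]))

    def test_cohort_recovery_on_synthetic_truth(self):
        """Pipeline recovers true MR1 phenotypes with high agreement."""
        from sklearn.metrics import adjusted_rand_score

        cfg = pf.SyntheticConfig(seed=11)
        sessions_df, _, truth = pf.generate_cohort(cfg)
        sessions = pf.frame_to_sessions(sessions_df)
        asg, models = pf.cluster_cohort(sessions, session_label="MR1", seed=11)
        tm = truth[truth.session == "MR1"].set_index("animal_id").loc[asg.animal_id]
        assert adjusted_rand_score(tm.phenotype, asg.label) >= 0.9
        assert set(models) == {"female", "male"}


class TestConsistency:
    def _asg(self, pairs, session):
        return pd.DataFrame({"animal_id": [p[0] for p in pairs], "session": session,
                             "label": [p[1] for p in pairs],
                             "posterior": 0.9, "tied": False})

    def test_all_four_categories_and_missing(self):
        mr1 = self._asg([("A", "sustained"), ("B", "phasic"), ("C", "sustained"),
                         ("D", "phasic"), ("E", "phasic")], "MR1")
        mr2 = self._asg([("A", "phasic"), ("B", "sustained"), ("C", "sustained"),
                         ("D", "phasic"), ("F", "phasic")], "MR2")
        cons = pf.classify_consistency(mr1, mr2).set_index("animal_id")["category"]
        assert cons["A"] == "shifter_sustained_to_phasic"
        assert cons["B"] == "shifter_phasic_to_sustained"
        assert cons["C"] == "consistent_sustained"
        assert cons["D"] == "consistent_phasic"
        assert cons["E"] == "unclassified"   # present only in MR1
        assert cons["F"] == "unclassified"

    def test_shifter_rates_conditioned_on_mr1_group(self):
        cons = pd.DataFrame({
            "animal_id": list("ABCDEFGHIJ"),
            "category": ["consistent_sustained"] * 3 + ["shifter_sustained_to_phasic"] * 2
                        + ["consistent_phasic"] * 4 + ["shifter_phasic_to_sustained"],
        })
        rates = pf.shifter_rates(cons)
        assert rates["sustained_to_phasic"] == pytest.approx(2 / 5)
        assert rates["phasic_to_sustained"] == pytest.approx(1 / 5)


class TestGreedyFeatureSelection:
    def test_bimodal_feature_found_first(self):
        """One separated bimodal column among noise is picked first, and the
        greedy result attains the best evidence over all subsets (enumeration
        oracle on 3 candidates)."""
        from itertools import combinations

        from phenofreeze.phenotype import _clustering_evidence

        rng = np.random.default_rng(0)
        n = 200
        bimodal = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(4, 1, n // 2)])
        X = pd.DataFrame({"signal": bimodal, "noise1": rng.normal(size=n),
                          "noise2": rng.normal(size=n)})
        res = pf.greedy_feature_selection(X, seed=1)
        assert res.trace[0][:2] == ("add", "signal")
        assert res.supported
        # enumeration oracle: no subset beats the greedy evidence
        best = max(
            _clustering_evidence(X, list(sub), seed=1, n_restarts=10,
                                 covariance_family="full")
            for r in (1, 2, 3) for sub in combinations(X.columns, r)
        )
        assert res.evidence == pytest.approx(best, rel=1e-6)

    def test_pure_noise_reports_no_support(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(150, 3)), columns=["a", "b", "c"])
        with pytest.warns(UserWarning, match="no clustering support"):
            res = pf.greedy_feature_selection(X, seed=1)
        assert not res.supported
        assert res.evidence <= 0 or res.selected == []

    def test_single_candidate_never_errors(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"only": np.concatenate([rng.normal(0, 1, 50),
                                                  rng.normal(6, 1, 50)])})
        res = pf.greedy_feature_selection(X, seed=1)
        assert res.selected in ([], ["only"])

    def test_constant_column_excluded(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"flat": np.ones(100),
                          "sig": np.concatenate([rng.normal(0, 1, 50),
                                                 rng.normal(5, 1, 50)])})
        with pytest.warns(UserWarning, match="constant feature"):
            res = pf.greedy_feature_selection(X, seed=1)
        assert "flat" not in res.selected


class TestSelectExtremes:
    def _assignments(self, labels):
        return pd.DataFrame({"animal_id": list(labels), "session": "MR1",
                             "label": list(labels.values()),
                             "posterior": 0.95, "tied": False})

    def _fits(self, rows):
        return pd.DataFrame([{"animal_id": k, "session": "MR1",
                              "sustained_mean": v[0], "b": v[1]}
                             for k, v in rows.items()])

    def test_single_animal_boundary(self):
        asg = self._assignments({"S1": "sustained", "P1": "phasic"})
        fits = self._fits({"S1": (70, 0.02), "P1": (10, 0.3)})
        res = pf.select_extremes(asg, fits, n_per_group=1)
        assert res.sustained == ["S1"] and res.phasic == ["P1"]

    def test_oft_ranking_full_sort_oracle(self):
        cons = pd.DataFrame({"animal_id": ["a", "b", "c", "d", "p1", "p2", "p3"],
                             "category": ["consistent_sustained"] * 4
                                         + ["consistent_phasic"] * 3})
        metrics = pd.DataFrame({"animal_id": ["a", "b", "c", "d", "p1", "p2", "p3"],
                                "oft_periphery_s": [300, 250, 400, 100, 50, 20, 80]})
        res = pf.select_extremes(self._assignments({}), self._fits({}),
                                 n_per_group=2, mode="consistency_oft",
                                 consistency=cons, metrics=metrics)
        assert res.sustained == ["c", "a"]    # longest periphery times: 400, 300
        assert res.phasic == ["p2", "p1"]     # shortest: 20, 50

    def test_profile_tiebreak_by_decay_rate(self):
        asg = self._assignments({"S1": "sustained", "S2": "sustained",
                                 "P1": "phasic", "P2": "phasic"})
        fits = self._fits({"S1": (50, 0.10), "S2": (50, 0.02),
                           "P1": (50, 0.10), "P2": (50, 0.30)})
        res = pf.select_extremes(asg, fits, n_per_group=2)
        assert res.sustained == ["S2", "S1"]  # slower decay ranks higher
        assert res.phasic == ["P2", "P1"]     # faster decay ranks higher

    def test_insufficient_animals_errors_with_count(self):
        asg = self._assignments({"S1": "sustained", "P1": "phasic"})
        fits = self._fits({"S1": (70, 0.02), "P1": (10, 0.3)})
        with pytest.raises(ValueError, match="only 1 available"):
            pf.select_extremes(asg, fits, n_per_group=2)

    def test_missing_oft_metric_excluded_with_warning(self):
        cons = pd.DataFrame({"animal_id": ["a", "b", "p1", "p2"],
                             "category": ["consistent_sustained"] * 2
                                         + ["consistent_phasic"] * 2})
        metrics = pd.DataFrame({"animal_id": ["a", "b", "p1", "p2"],
                                "oft_periphery_s": [300, np.nan, 50, 60]})
        with pytest.warns(UserWarning, match="excluded"):
            res = pf.select_extremes(self._assignments({}), self._fits({}),
                                     n_per_group=1, mode="consistency_oft",
                                     consistency=cons, metrics=metrics)
        assert res.sustained == ["a"]
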