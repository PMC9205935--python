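import warnings

import numpy as np
import pandas as pd
import pytest

from radsig.outcomes import BINARY, SURVIVAL, OutcomeData
from radsig.phantom import generate_feature_cohort
from radsig.signature import (CVRunRecord, Signature, add_clinical,
                              aggregate_occurrence, apply_transform,
                              fit_yeo_johnson, join_signatures,
                              make_cv_scheme, prune_correlated, run_cv,
                              run_selectors, yeo_johnson)

warnings.filterwarnings("ignore", category=FutureWarning)


def _outcome(labels):
    return OutcomeData([f"s{i}" for i in range(len(labels))],
                       labels=np.asarray(labels))


class TestCVScheme:
    def test_default_gives_99_runs(self):
        _, out = generate_feature_cohort(n=60, p=2, seed=0)
        scheme = make_cv_scheme(out, BINARY)
        assert scheme.n_runs == 99

    def test_stratification_arithmetic(self):
        y = np.array([1] * 4 + [0] * 8)
        scheme = make_cv_scheme(_outcome(y), BINARY, reps=5, folds=3, seed=1)
        for _, _, tr, va in scheme.assignments:
            assert len(va) == 4
            assert 1 <= y[va].sum() <= 2

    def test_folds_partition_each_repetition(self):
        y = np.array([0, 1] * 15)
        scheme = make_cv_scheme(_outcome(y), BINARY, reps=3, folds=3, seed=2)
        for rep in range(3):
            vas = [set(va) for r, f, tr, va in scheme.assignments if r == rep]
            assert set().union(*vas) == set(range(30))
            assert sum(len(v) for v in vas) == 30

    def test_same_seed_identical(self):
        y = np.array([0, 1] * 10)
        a = make_cv_scheme(_outcome(y), BINARY, seed=3)
        b = make_cv_scheme(_outcome(y), BINARY, seed=3)
        for (r1, f1, t1, v1), (r2, f2, t2, v2) in zip(a.assignments,
                                                      b.assignments):
            np.testing.assert_array_equal(t1, t2)

    def test_infeasible_stratification_raises(self):
        y = np.array([1, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="infeasible"):
            make_cv_scheme(_outcome(y), BINARY, folds=3)


class TestYeoJohnson:
    def test_lambda_one_is_identity(self):
        x = np.array([-2.0, 0.0, 1.5, 7.0])
        np.testing.assert_allclose(yeo_johnson(x, 1.0), x, atol=1e-12)

    def test_fit_apply_standardises_training_data(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"a": rng.lognormal(size=200),
                          "b": rng.normal(size=200)})
        params = fit_yeo_johnson(t)
        z = apply_transform(params, t)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-8)
        np.testing.assert_allclose(z.std(ddof=0), 1.0, atol=1e-8)

    def test_normal_column_stays_symmetric(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"a": rng.normal(3.0, 1.0, size=500)})
        z = apply_transform(fit_yeo_johnson(t), t)["a"]
        from scipy.stats import skew
        assert abs(skew(z)) < 0.2

    def test_lognormal_skewness_reduced(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(size=500)
        from scipy.stats import skew
        t = pd.DataFrame({"a": x})
        z = apply_transform(fit_yeo_johnson(t), t)["a"]
        assert abs(skew(z)) < abs(skew(x))

    def test_constant_column_flagged_identity(self):
        t = pd.DataFrame({"c": np.full(20, 3.0)})
        params = fit_yeo_johnson(t)
        assert params.flags["c"] == "constant_identity"
        z = apply_transform(params, t)
        np.testing.assert_allclose(z["c"], 0.0)


class TestSelectors:
    def _strong_single(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        y = np.array([0, 1] * (n // 2))
        t = pd.DataFrame({"signal": y * 3.0 + rng.normal(size=n)})
        for j in range(7):
            t[f"noise{j}"] = rng.normal(size=n)
        return t, _outcome(y)

    def test_overwhelming_feature_ranked_first_by_all(self):
        first_place = {m: 0 for m in ("MIM", "MRMR", "elastic-net",
                                      "univariate")}
        reps = 10
        for r in range(reps):
            t, out = self._strong_single(seed=r)
            params = fit_yeo_johnson(t)
            z = apply_transform(params, t)
            sel = run_selectors(z, out, BINARY, k=5, seed=r)
            for m, feats in sel.items():
                if feats and feats[0] == "signal":
                    first_place[m] += 1
        for m, wins in first_place.items():
            assert wins / reps >= 0.95, m

    def test_k_larger_than_available(self):
        rng = np.random.default_rng(5)
        y = np.array([0, 1] * 25)
        t = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        sel = run_selectors(t, _outcome(y), BINARY, k=5)
        assert all(len(v) <= 3 for v in sel.values())

    def test_mrmr_penalises_duplicate(self):
        # toy: y-informative x, its exact copy, and noise; with k=2 MRMR
        # should pick x then the independent column, not the copy
        rng = np.random.default_rng(6)
        y = np.array([0, 1] * 40)
        x = y + rng.normal(scale=0.4, size=80)
        t = pd.DataFrame({"x": x, "x_copy": x.copy(),
                          "z": rng.normal(size=80)})
        sel = run_selectors(t, _outcome(y), BINARY, k=2)
        assert sel["MRMR"][0] in ("x", "x_copy")
        assert sel["MRMR"][1] == "z"

    def test_survival_selectors_run(self):
        t, out = generate_feature_cohort(
            n=120, p=6, planted={"MR_morph_volume": 1.0},
            endpoint_kind=SURVIVAL, seed=7)
        sel = run_selectors(t, out, SURVIVAL, k=3, seed=1)
        assert set(sel) == {"MIM", "MRMR", "elastic-net", "univariate"}
        assert sel["univariate"][0] == "MR_morph_volume"


class TestOccurrenceRule:
    def _records(self, spec):
        # spec: feature -> per-method number of runs containing it (of 4)
        methods = ("MIM", "MRMR", "elastic-net", "univariate")
        records = []
        for i in range(4):
            sel = {m: [] for m in methods}
            for feat, counts in spec.items():
                for m, c in zip(methods, counts):
                    if i < c:
                        sel[m].append(feat)
            records.append(CVRunRecord(0, i, sel))
        return records

    def test_maximal_feature(self):
        occ, cum, cands = aggregate_occurrence(
            self._records({"f": (4, 4, 4, 4)}))
        assert cum["f"] == pytest.approx(4.0)
        assert cands == ["f"]

    def test_boundary_three_methods_at_half(self):
        occ, cum, cands = aggregate_occurrence(
            self._records({"f": (2, 2, 2, 1)}))  # 0.5, 0.5, 0.5, 0.25
        assert "f" in cands
        assert cum["f"] == pytest.approx(1.75)

    def test_boundary_only_two_methods(self):
        occ, cum, cands = aggregate_occurrence(
            self._records({"f": (4, 4, 1, 1)}))
        assert cands == []

    def test_denominator_is_total_runs(self):
        # a selector may return empty lists; the denominator stays fixed
        records = self._records({"f": (4, 4, 4, 0)})
        occ, _, _ = aggregate_occurrence(records)
        assert occ.loc["f", "univariate"] == 0.0
        assert occ.loc["f", "MIM"] == 1.0


class TestPruneJoin:
    def _table(self, rho_ab=0.9, rho_bc=0.0, n=200, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        b = rho_ab * a + np.sqrt(max(1 - rho_ab ** 2, 1e-12)) * rng.normal(size=n)
        c = rho_bc * b + np.sqrt(max(1 - rho_bc ** 2, 1e-12)) * rng.normal(size=n)
        return pd.DataFrame({"A": a, "B": b, "C": c})

    def test_correlated_pair_keeps_higher_occurrence(self):
        t = self._table(rho_ab=0.9)
        sig = prune_correlated(["A", "B"], pd.Series({"A": 3.0, "B": 2.0}), t)
        assert sig.features == ["A"]

    def test_uncorrelated_all_kept(self):
        t = self._table(rho_ab=0.0)
        sig = prune_correlated(["A", "B"], pd.Series({"A": 3.0, "B": 2.0}), t)
        assert sig.features == ["A", "B"]

    def test_chain_greedy_trace(self):
        # A-B rho .6, B-C rho .6, A-C ~ .1; cumulative A>B>C -> keep {A, C}
        rng = np.random.default_rng(1)
        n = 4000
        b = rng.normal(size=n)
        a = 0.6 * b + np.sqrt(1 - 0.36) * rng.normal(size=n)
        c = 0.6 * b - 0.36 * a + np.sqrt(1 - 0.36) * rng.normal(size=n)
        t = pd.DataFrame({"A": a, "B": b, "C": c})
        rho_ac = t[["A", "C"]].corr(method="spearman").iloc[0, 1]
        assert abs(rho_ac) < 0.5
        sig = prune_correlated(["A", "B", "C"],
                               pd.Series({"A": 3.0, "B": 2.0, "C": 1.0}), t)
        assert sig.features == ["A", "C"]

    def test_join_disjoint_and_correlated(self):
        t = self._table(rho_ab=0.85, seed=2)
        sa = Signature(["A"], provenance={"cumulative_occurrence": {"A": 3.0}})
        sb = Signature(["B"], provenance={"cumulative_occurrence": {"B": 2.0}})
        joint = join_signatures(sa, sb, t)
        assert joint.features == ["A"]
        sc = Signature(["C"], provenance={"cumulative_occurrence": {"C": 1.0}})
        joint2 = join_signatures(sa, sc, t)
        assert joint2.features == ["A", "C"]

    def test_join_with_empty_signature(self):
        t = self._table()
        sa = Signature(["A"], provenance={"cumulative_occurrence": {"A": 3.0}})
        joint = join_signatures(sa, Signature([]), t)
        assert joint.features == ["A"]


class TestAddClinical:
    def test_strong_covariate_appended(self):
        hits = 0
        reps = 20
        for r in range(reps):
            rng = np.random.default_rng(300 + r)
            stage = rng.integers(0, 2, size=300)
            eta = -0.5 + np.log(5) * stage
            y = (rng.uniform(size=300) < 1 / (1 + np.exp(-eta))).astype(int)
            clin = pd.DataFrame({"stage": stage.astype(float)})
            sig = add_clinical(Signature([]), clin, _outcome(y), BINARY)
            hits += bool(sig.clinical)
        assert hits / reps >= 0.9

    def test_null_covariate_type_one_rate(self):
        hits = 0
        reps = 100
        for r in range(reps):
            rng = np.random.default_rng(900 + r)
            y = rng.integers(0, 2, size=200)
            clin = pd.DataFrame({"noise": rng.normal(size=200)})
            sig = add_clinical(Signature([]), clin, _outcome(y), BINARY)
            hits += bool(sig.clinical)
        assert hits / reps < 0.12  # ~5% nominal

    def test_no_clinical_table(self):
        sig = Signature(["A"])
        assert add_clinical(sig, None, _outcome(np.array([0, 1])), BINARY) is sig


class TestLeakage:
    def test_validation_outcomes_never_influence_selection(self):
        from radsig.signature import CVScheme
        t, out = generate_feature_cohort(
            n=90, p=8, planted={"MR_morph_volume": 1.0}, seed=9)
        base = make_cv_scheme(out, BINARY, reps=2, folds=3, seed=4)
        rng = np.random.default_rng(10)
        for rep, fold, tr, va in base.assignments[:3]:
            one_run = CVScheme([(rep, fold, tr, va)], 1, 3, base.seed)
            ref = run_cv(t, out, BINARY, one_run, k=3)[0].selected
            y2 = out.labels.copy()
            y2[va] = rng.permutation(y2[va])
            out2 = OutcomeData(out.subject_ids, labels=y2)
            alt = run_cv(t, out2, BINARY, one_run, k=3)[0].selected
            assert ref == alt

    def test_run_cv_deterministic(self):
        t, out = generate_feature_cohort(n=60, p=5, seed=11)
        scheme = make_cv_scheme(out, BINARY, reps=2, folds=3, seed=5)
        r1 = run_cv(t, out, BINARY, scheme, k=3)
        r2 = run_cv(t, out, BINARY, scheme, k=3)
        for a, b in zip(r1, r2):
            assert a.selected == b.selected
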