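"""Candidate enumeration, AIC ranking, two-phase workflow, model averaging."""

import numpy as np
import pytest

import occufp as o
from occufp.fitting import ModelSpec
from occufp.selection import SelectionError


class FakeSpec:
    def __init__(self, label, misclassification):
        self.label = label
        self.model_class = "MM" if misclassification else "OM"


class FakeFit:
    """Minimal stand-in exposing the fitted-model surface ranking needs."""

    def __init__(self, label, aic, k=3, converged=True, psi=None, p=None, p10=None):
        self._label = label
        self.aic_ = aic
        self.loglik_ = (2 * k - aic) / 2.0
        self.n_params_ = k
        self.converged_ = converged
        self._psi = psi
        self._p = p
        self.p10_ = p10
        self.false_positives = p10 is not None

    @property
    def spec_(self):
        return FakeSpec(self._label, self.false_positives)

    def predict_psi(self, X):
        return np.full(len(X), self._psi)

    def predict_p(self, X):
        return np.full(len(X), self._p)


class TestEnumerate:
    def test_two_covariates_no_interactions(self):
        cs = o.enumerate_candidates(["a", "b"], allow_interactions=False)
        assert len(cs) == 16  # 4 psi-subsets x 4 p-subsets
        assert cs.provenance == "enumerated"

    def test_single_covariate(self):
        cs = o.enumerate_candidates(["a"])
        assert len(cs) == 4
        assert all("*" not in s.psi_formula + s.p_formula for s in cs)

    def test_interactions_within_component(self):
        cs = o.enumerate_candidates(["a", "b"], allow_interactions=True)
        # per component: 1, a, b, a+b, a*b -> 5; 25 total
        assert len(cs) == 25
        assert any(s.psi_formula == "a * b" for s in cs)

    def test_cap_refused_with_count(self):
        with pytest.raises(ValueError, match="1600"):
            o.enumerate_candidates(list("abcd"), max_candidates=100)

    def test_user_list_passthrough(self):
        specs = tuple(
            ModelSpec(f, "1") for f in ("pop", "rug", "pop + rug")
        )
        cs = o.CandidateSet(specs)
        assert len(cs) == 3 and cs.provenance == "user-listed"

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            o.CandidateSet((ModelSpec("pop", "1"), ModelSpec("pop", "1")))


class TestRanking:
    def test_delta_two_weights(self):
        table = o.rank_models([FakeFit("m0", 100.0), FakeFit("m1", 102.0)])
        np.testing.assert_allclose(table["weight"], [0.7311, 0.2689], atol=1e-4)
        np.testing.assert_allclose(table["dAIC"], [0.0, 2.0])

    def test_single_model(self):
        table = o.rank_models([FakeFit("only", 50.0)])
        assert table["weight"].iloc[0] == 1.0 and table["dAIC"].iloc[0] == 0.0

    def test_ties_equal_weights_label_order(self):
        table = o.rank_models(
            [FakeFit("zebra", 10.0), FakeFit("apple", 10.0)]
        )
        assert list(table["label"]) == ["apple", "zebra"]
        np.testing.assert_allclose(table["weight"], [0.5, 0.5])

    def test_weights_sum_to_one(self, rng):
        fits = [FakeFit(f"m{i}", 100 + v) for i, v in enumerate(rng.uniform(0, 30, 20))]
        table = o.rank_models(fits)
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(table["dAIC"]) >= 0)

    def test_nonconverged_excluded(self):
        table = o.rank_models(
            [FakeFit("good", 10.0), FakeFit("bad", 5.0, converged=False)]
        )
        assert list(table["label"]) == ["good"]
        assert table.attrs["excluded"] == ["bad"]

    def test_no_converged_fits_raises(self):
        with pytest.raises(SelectionError):
            o.rank_models([FakeFit("bad", 5.0, converged=False)])


class TestModelAverage:
    def grid(self, n=4):
        import pandas as pd

        return pd.DataFrame({"x": np.zeros(n)})

    def test_single_top_model_identity(self):
        fits = {"m0": FakeFit("m0", 100.0, psi=0.3, p=0.6),
                "m1": FakeFit("m1", 110.0, psi=0.9, p=0.9)}
        ranking = o.rank_models(fits.values())
        avg = o.model_average(fits, ranking, self.grid())
        np.testing.assert_allclose(avg["psi_avg"], 0.3)
        np.testing.assert_allclose(avg["p_avg"], 0.6)

    def test_equal_weights_arithmetic_mean(self):
        fits = {"a": FakeFit("a", 100.0, psi=0.2, p=0.5),
                "b": FakeFit("b", 100.0, psi=0.4, p=0.7)}
        ranking = o.rank_models(fits.values())
        avg = o.model_average(fits, ranking, self.grid())
        np.testing.assert_allclose(avg["psi_avg"], 0.3)
        assert sum(avg.attrs["weights"].values()) == pytest.approx(1.0, abs=1e-12)

    def test_convex_combination(self, rng):
        psis = rng.uniform(0.1, 0.9, 3)
        fits = {
            f"m{i}": FakeFit(f"m{i}", 100.0 + rng.uniform(0, 1.5), psi=v, p=0.5)
            for i, v in enumerate(psis)
        }
        ranking = o.rank_models(fits.values())
        avg = o.model_average(fits, ranking, self.grid())
        assert np.all(avg["psi_avg"] >= psis.min() - 1e-12)
        assert np.all(avg["psi_avg"] <= psis.max() + 1e-12)

    def test_dominated_model_never_enters(self):
        base = {"a": FakeFit("a", 100.0, psi=0.2, p=0.5),
                "b": FakeFit("b", 101.0, psi=0.4, p=0.7)}
        with_dom = dict(base)
        with_dom["c"] = FakeFit("c", 115.0, psi=0.99, p=0.99)
        a1 = o.model_average(base, o.rank_models(base.values()), self.grid())
        a2 = o.model_average(with_dom, o.rank_models(with_dom.values()), self.grid())
        np.testing.assert_allclose(a1["psi_avg"], a2["psi_avg"], atol=1e-12)


@pytest.fixture(scope="module")
def fitted(small_dataset):
    ds = small_dataset
    candidates = o.CandidateSet(
        (
            ModelSpec("pop + rug", "elev"),
            ModelSpec("pop", "elev"),
            ModelSpec("1", "1"),
        )
    )
    return o.two_phase_select(
        candidates, ds.site_covariates, ds.detection_matrix(),
        n_restarts=2, random_state=0,
    )


class TestTwoPhase:

    def test_final_table_contains_mm_counterparts(self, fitted):
        ranking, fits = fitted
        labels = set(ranking["label"])
        assert any(", p10" in lab for lab in labels)
        # every MM in the table has its OM twin fitted
        for lab in labels:
            if lab.endswith(", p10"):
                assert lab.removesuffix(", p10") in fits

    def test_weights_sum_to_one(self, fitted):
        ranking, _ = fitted
        assert ranking["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_candidate_gives_two_rows(self, small_dataset):
        ds = small_dataset
        ranking, _ = o.two_phase_select(
            o.CandidateSet((ModelSpec("pop", "elev"),)),
            ds.site_covariates, ds.detection_matrix(),
            n_restarts=2, random_state=0,
        )
        assert len(ranking) == 2
        assert set(ranking["class"]) == {"OM", "MM"}

    def test_order_invariance(self, small_dataset):
        ds = small_dataset
        specs = (ModelSpec("pop", "elev"), ModelSpec("rug", "1"), ModelSpec("1", "1"))
        r1, _ = o.two_phase_select(
            o.CandidateSet(specs), ds.site_covariates, ds.detection_matrix(),
            n_restarts=2, random_state=0,
        )
        r2, _ = o.two_phase_select(
            o.CandidateSet(specs[::-1]), ds.site_covariates, ds.detection_matrix(),
            n_restarts=2, random_state=0,
        )
        import pandas as pd

        pd.testing.assert_frame_equal(r1, r2, check_exact=False, atol=1e-9)

    def test_rejects_misclassification_candidates(self, small_dataset):
        ds = small_dataset
        with pytest.raises(ValueError, match="conventional"):
            o.two_phase_select(
                o.CandidateSet((ModelSpec("pop", "1", misclassification=True),)),
                ds.site_covariates, ds.detection_matrix(),
            )
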