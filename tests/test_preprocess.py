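"""Metabolomics cascade postconditions and PLS-DA VIP behavior."""

import numpy as np
import pandas as pd
import pytest

from camnet.matrix import Stage
from camnet.preprocess import (
    impute_min,
    log10_transform,
    pls_vip,
    presence_filter,
    qc_rsd_filter,
    run_cascade,
    sum_normalize,
)
from camnet.synthetic import NoiseParams, SyntheticTruth, simulate_design, simulate_layer

from conftest import make_design, make_matrix

NA = np.nan


class TestPresenceFilter:
    def test_boundary_inclusive(self):
        # 8/10 detected at min_frac 0.8 -> retained; 7/10 -> dropped
        rows = [
            [1] * 8 + [NA, NA],
            [1] * 7 + [NA, NA, NA],
        ]
        m = make_matrix(rows, layer="metabolite")
        out = presence_filter(m, 0.8)
        assert out.feature_ids == ["f0"]
        assert out.stage == Stage.FILTERED

    def test_zero_counts_as_undetected(self):
        m = make_matrix([[0, 0, 1, 1]], layer="metabolite")
        assert presence_filter(m, 0.8).n_features == 0

    def test_fully_detected_identity(self):
        m = make_matrix([[1, 2], [3, 4]], layer="metabolite")
        out = presence_filter(m, 0.8)
        assert out.values.equals(m.values)

    def test_wrong_stage_rejected(self):
        m = make_matrix([[1, 2]], layer="metabolite", stage=Stage.IMPUTED)
        with pytest.raises(ValueError, match="stage"):
            presence_filter(m)


class TestImputeMin:
    def test_per_feature_definition(self):
        m = make_matrix([[5, NA, 7]], layer="metabolite", stage=Stage.FILTERED)
        out = impute_min(m, "per_feature")
        assert out.values.iloc[0].tolist() == [5, 5, 7]
        assert not out.mask.to_numpy().any()

    def test_global_scope(self):
        m = make_matrix([[5, NA], [0.3, 1]], layer="metabolite", stage=Stage.FILTERED)
        out = impute_min(m, "global")
        assert out.values.iloc[0, 1] == 0.3

    def test_no_missing_identity(self):
        m = make_matrix([[1, 2]], layer="metabolite", stage=Stage.FILTERED)
        assert impute_min(m).values.equals(m.values)

    def test_all_missing_feature_rejected(self):
        m = make_matrix([[NA, NA]], layer="metabolite", stage=Stage.FILTERED)
        with pytest.raises(ValueError, match="per-feature"):
            impute_min(m, "per_feature")


class TestSumNormalize:
    def test_definition(self):
        m = make_matrix([[2], [3], [5]], layer="metabolite", stage=Stage.IMPUTED)
        out = sum_normalize(m)
        assert out.values[out.sample_ids[0]].tolist() == [0.2, 0.3, 0.5]

    def test_unit_sum_invariant_and_idempotence(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.uniform(0.1, 9, (20, 5)), layer="metabolite", stage=Stage.IMPUTED)
        out = sum_normalize(m)
        np.testing.assert_allclose(out.values.sum(axis=0), 1.0, atol=1e-9)
        again = sum_normalize(make_matrix(out.values.to_numpy(), layer="metabolite", stage=Stage.IMPUTED))
        np.testing.assert_allclose(again.values.to_numpy(), out.values.to_numpy())

    def test_zero_total_names_sample(self):
        m = make_matrix([[0, 1]], layer="metabolite", stage=Stage.IMPUTED)
        with pytest.raises(ValueError, match="s0"):
            sum_normalize(m)


class TestQcRsdFilter:
    def _matrix(self, qc_rows, design):
        return make_matrix(qc_rows, design=design, layer="metabolite", stage=Stage.NORMALIZED)

    def test_zero_variance_retained(self):
        d = make_design(["A"], 2, n_qc=3, layer="metabolite")
        m = self._matrix([[1, 1, 10, 10, 10]], d)
        assert qc_rsd_filter(m, d).n_features == 1

    def test_hand_computed_rsd_excluded(self):
        # QC values [1,2,3]: sample sd = 1, mean = 2, RSD = 0.5 > 0.3
        d = make_design(["A"], 2, n_qc=3, layer="metabolite")
        m = self._matrix([[5, 5, 1, 2, 3]], d)
        assert qc_rsd_filter(m, d, 0.30).n_features == 0
        assert qc_rsd_filter(m, d, 0.5).n_features == 1  # boundary retained

    def test_infinite_threshold_vacuous(self):
        d = make_design(["A"], 2, n_qc=2, layer="metabolite")
        m = self._matrix([[1, 1, 4, 9]], d)
        assert qc_rsd_filter(m, d, np.inf).n_features == 1

    def test_too_few_qc_samples(self):
        d = make_design(["A"], 2, n_qc=1, layer="metabolite")
        m = self._matrix([[1, 1, 1]], d)
        with pytest.raises(ValueError, match="QC"):
            qc_rsd_filter(m, d)


class TestLog10:
    def test_identities_and_roundtrip(self):
        m = make_matrix([[1, 100, 5.5]], layer="metabolite", stage=Stage.QC_FILTERED)
        out = log10_transform(m)
        assert out.values.iloc[0, 0] == 0.0
        assert out.values.iloc[0, 1] == 2.0
        back = 10 ** out.values
        np.testing.assert_allclose(back.to_numpy(), m.values.to_numpy(), atol=1e-12)

    def test_nonpositive_rejected(self):
        m = make_matrix([[1, 0]], layer="metabolite", stage=Stage.QC_FILTERED)
        with pytest.raises(ValueError, match="nonpositive"):
            log10_transform(m)


class TestCascade:
    def test_order_enforced_and_feature_count_monotone(self, metabolite_design):
        truth = SyntheticTruth(unstable_features=frozenset({"M00001", "M00002"}))
        m = simulate_layer(
            metabolite_design, truth, 100,
            NoiseParams(missing_rate=0.1, qc_cv=0.05, qc_cv_unstable=0.8),
            seed=3,
        )
        out, prov = run_cascade(m, metabolite_design)
        assert out.stage == Stage.LOGGED
        counts = [p["n_features_in"] for p in prov] + [prov[-1]["n_features_out"]]
        assert counts == sorted(counts, reverse=True)
        # filters are idempotent: re-filtering the survivors removes nothing
        refiltered = presence_filter(
            make_matrix(10 ** out.values.to_numpy(), design=metabolite_design,
                        layer="metabolite", features=out.feature_ids), 0.8
        )
        assert refiltered.n_features == out.n_features


class TestPlsVip:
    def _logged(self, X, design):
        return make_matrix(X, design=design, layer="metabolite", stage=Stage.LOGGED)

    def test_mean_squared_vip_is_one(self, metabolite_design):
        rng = np.random.default_rng(1)
        m = self._logged(rng.normal(size=(40, 16)), metabolite_design)
        res = pls_vip(m, metabolite_design, ("B", "A"), n_components=2)
        assert float((res.vip**2).mean()) == pytest.approx(1.0, abs=1e-8)

    def test_perfect_separator_has_max_vip(self, metabolite_design):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 16))
        y = np.array([1.0] * 6 + [-1.0] * 6 + [0.0] * 4)  # QC columns at the end
        X[0] = 3 * y + rng.normal(scale=0.05, size=16)
        m = self._logged(X, metabolite_design)
        res = pls_vip(m, metabolite_design, ("A", "B"), n_components=1)
        assert res.vip.idxmax() == "f0"
        assert res.vip.max() > 1

    def test_permuted_labels_break_the_planted_feature(self):
        """Under label permutation the planted feature should top the VIP
        ranking only rarely (permutation null)."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 12))
        y = np.array([1.0] * 6 + [-1.0] * 6)
        X[0] = 2 * y + rng.normal(scale=0.1, size=12)
        top = 0
        for i in range(20):
            perm = rng.permutation(12)
            d = make_design(["A", "B"], 6, layer="metabolite")
            m = self._logged(X[:, perm], d)
            res = pls_vip(m, d, ("A", "B"), n_components=1)
            top += res.vip.idxmax() == "f0"
        assert top <= 2

    def test_constant_feature_gets_zero_vip(self, metabolite_design):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 16))
        X[3] = 1.0
        m = self._logged(X, metabolite_design)
        with pytest.warns(UserWarning, match="constant"):
            res = pls_vip(m, metabolite_design, ("A", "B"), n_components=1)
        assert res.vip["f3"] == 0.0

    def test_matches_sklearn_pls_weights(self, metabolite_design):
        """Cross-check: VIP recomputed from scikit-learn's PLS fit agrees."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 16))
        m = self._logged(X, metabolite_design)
        ours = pls_vip(m, metabolite_design, ("A", "B"), n_components=2)

        samples = metabolite_design.samples_in_group("A") + metabolite_design.samples_in_group("B")
        Xs = m.values[samples].T.to_numpy()
        Xs = (Xs - Xs.mean(0)) / Xs.std(0, ddof=1)
        y = np.array([1.0] * 6 + [-1.0] * 6)
        yc = y - y.mean()
        pls = sklearn.PLSRegression(n_components=2, scale=False).fit(Xs, yc)
        W = pls.x_weights_
        T = pls.x_scores_
        Q = pls.y_loadings_
        ssy = (Q.ravel() ** 2) * (T**2).sum(axis=0)
        p = Xs.shape[1]
        vip_ref = np.sqrt(p * ((W / np.linalg.norm(W, axis=0)) ** 2 @ ssy) / ssy.sum())
        np.testing.assert_allclose(ours.vip.to_numpy(), vip_ref, atol=1e-8)

    def test_component_bounds_checked(self, metabolite_design):
        rng = np.random.default_rng(6)
        m = self._logged(rng.normal(size=(5, 16)), metabolite_design)
        with pytest.raises(ValueError, match="n_components"):
            pls_vip(m, metabolite_design, ("A", "B"), n_components=0)
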