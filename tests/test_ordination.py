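"""NSCA / co-inertia / BGA: inertia identities, invariances, recovery."""

import numpy as np
import pandas as pd
import pytest

import tfcia as t
from tfcia.errors import NumericalError, ValidationError
from tfcia.ordination import (
    bga,
    coinertia,
    nsca,
    nsca_inertia_direct,
    rv_permutation_test,
    supervised_cia,
)


def _df(arr, prefix_r="g", prefix_c="c"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix_r}{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix_c}{j}" for j in range(arr.shape[1])],
    )


class TestNSCA:
    def test_independence_table_has_zero_inertia(self):
        r = np.array([0.1, 0.3, 0.6])
        c = np.array([0.25, 0.25, 0.5])
        table = _df(np.outer(r, c) * 40)
        ord_ = nsca(table)
        assert ord_.total_inertia == pytest.approx(0.0, abs=1e-24)
        assert np.all(ord_.eigenvalues <= 1e-24) if ord_.eigenvalues.size else True

    def test_identity_2x2_inertia_half(self):
        ord_ = nsca(_df([[1, 0], [0, 1]]))
        assert ord_.total_inertia == pytest.approx(0.5, abs=1e-12)

    def test_eigenvalue_sum_equals_direct_inertia(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            shape = (rng.integers(3, 12), rng.integers(2, 8))
            x = _df(rng.poisson(3, shape) + rng.random(shape))
            ord_ = nsca(x)
            assert ord_.eigenvalues.sum() == pytest.approx(
                nsca_inertia_direct(x), rel=1e-10
            )
            assert np.all(np.diff(ord_.eigenvalues) <= 1e-12)

    def test_zero_column_rejected_by_name(self):
        x = _df([[1, 0], [2, 0]])
        with pytest.raises(NumericalError, match="c1"):
            nsca(x)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            nsca(_df([[1, -1], [2, 3]]))

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(3)
        x = _df(rng.poisson(4, (10, 5)) + 0.0)
        a, b = nsca(x), nsca(x)
        pd.testing.assert_frame_equal(a.row_scores, b.row_scores)
        for axis in a.col_scores:
            j = a.col_scores[axis].abs().idxmax()
            assert a.col_scores.loc[j, axis] > 0


class TestCoinertia:
    def _pair(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        a = _df(rng.poisson(3, (n, 6)) + 0.0)
        b = _df(rng.poisson(2, (n, 9)) + 0.0, prefix_c="m")
        return nsca(a, centering="uniform"), nsca(b, centering="uniform")

    def test_self_coupling_rv_is_one(self):
        oa, _ = self._pair()
        res = coinertia(oa, oa)
        assert res.rv == pytest.approx(1.0, abs=1e-12)

    def test_rv_bounds_and_singular_value_identity(self):
        oa, ob = self._pair(5)
        res = coinertia(oa, ob, n_axes=20)
        assert 0 <= res.rv <= 1
        assert (res.singular_values**2).sum() == pytest.approx(
            res.total_coinertia, rel=1e-10
        )
        assert np.all(np.diff(res.singular_values) <= 1e-12)

    def test_row_mismatch_rejected(self):
        oa, _ = self._pair()
        _, ob = self._pair(n=41)
        with pytest.raises(ValidationError):
            coinertia(oa, ob)

    def test_zero_inertia_coupling_rejected(self):
        oa, _ = self._pair()
        flat = _df(np.ones((40, 4)))
        with pytest.raises(NumericalError):
            coinertia(oa, nsca(flat, centering="uniform"))

    def test_identical_gene_permutation_invariance(self):
        rng = np.random.default_rng(11)
        a = _df(rng.poisson(3, (30, 5)) + 0.0)
        b = _df(rng.poisson(2, (30, 7)) + 0.0, prefix_c="m")
        res1 = coinertia(nsca(a, centering="uniform"), nsca(b, centering="uniform"))
        perm = rng.permutation(30)
        ap, bp = a.iloc[perm], b.iloc[perm]
        res2 = coinertia(nsca(ap, centering="uniform"), nsca(bp, centering="uniform"))
        assert res2.rv == pytest.approx(res1.rv, rel=1e-10)
        np.testing.assert_allclose(
            res2.singular_values, res1.singular_values, rtol=1e-10
        )
        pd.testing.assert_frame_equal(
            res2.right_loadings, res1.right_loadings, rtol=1e-8, atol=1e-12
        )

    def test_independent_tables_rv_not_significant(self):
        # pre-verified across seeds 0-19: every null p cleared 0.05
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = _df(rng.poisson(3, (50, 6)) + 0.0)
            b = _df(rng.poisson(3, (50, 8)) + 0.0, prefix_c="m")
            _, p, _ = rv_permutation_test(
                nsca(a, centering="uniform"), nsca(b, centering="uniform"),
                499, rng=rng,
            )
            ok += p > 0.05
        assert ok >= 9

    def test_planted_coupling_rv_beats_null(self, reference_sim):
        _, tables, expr, _, _ = reference_sim
        norm = t.quantile_normalize(expr)
        oa = nsca(norm.values, centering="uniform")
        ob = nsca(tables[-1].counts, centering="uniform")
        rv, p, null = rv_permutation_test(oa, ob, 199, rng=0)
        assert rv > np.quantile(null, 0.99)
        assert p == pytest.approx(1 / 200)


class TestBGA:
    def test_two_groups_single_axis(self):
        rng = np.random.default_rng(0)
        x = _df(rng.poisson(5, (100, 8)) + 0.0, prefix_c="s")
        groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        res = bga(x, groups)
        assert res.n_axes == 1

    def test_axis_count_bounded_by_groups(self):
        rng = np.random.default_rng(1)
        x = _df(rng.poisson(5, (100, 12)) + 0.0, prefix_c="s")
        for k in (2, 3, 4):
            groups = {f"s{i}": f"G{i % k}" for i in range(12)}
            assert bga(x, groups).n_axes <= k - 1

    def test_null_between_ratio_matches_random_projection(self):
        # with many samples the null ratio concentrates at (K-1)/(n-1)
        rng = np.random.default_rng(2)
        n_s = 102
        x = _df(rng.poisson(5, (1000, n_s)) + 0.0, prefix_c="s")
        groups = {f"s{i}": ["A", "B", "C"][i % 3] for i in range(n_s)}
        res = bga(x, groups)
        assert res.between_ratio <= 0.05
        assert res.between_ratio == pytest.approx(2 / (n_s - 1), rel=0.5)

    def test_planted_groups_separate_samples(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(3)
        shift = np.zeros((500, 12))
        shift[:100, 4:8] += 3
        shift[100:200, 8:] += 3
        x = _df(rng.poisson(5, (500, 12)) + shift, prefix_c="s")
        groups = {f"s{i}": ["A", "B", "C"][i // 4] for i in range(12)}
        res = bga(x, groups)
        labels = [groups[s] for s in res.sample_scores.index]
        assert silhouette_score(res.sample_scores.to_numpy(), labels) > 0

    def test_empty_group_rejected(self):
        rng = np.random.default_rng(4)
        x = _df(rng.poisson(5, (20, 4)) + 0.0, prefix_c="s")
        with pytest.raises(ValidationError):
            bga(x, {"s0": "A", "s1": "A", "s2": "A", "s3": "A"})


class TestSupervisedCIA:
    def test_swapping_labels_negates_loadings(self, reference_sim):
        _, tables, expr, _, _ = reference_sim
        norm = t.quantile_normalize(expr)
        fwd = supervised_cia(norm.values, norm.group_of, tables[0].counts, ("Ag", "D8"))
        rev = supervised_cia(norm.values, norm.group_of, tables[0].counts, ("D8", "Ag"))
        pd.testing.assert_series_equal(rev.motif_loadings, -fwd.motif_loadings)

    def test_constant_motif_column_has_zero_loading(self, reference_sim):
        _, tables, expr, _, _ = reference_sim
        counts = tables[0].counts.copy()
        counts["Mconst"] = 2.0
        sup = supervised_cia(expr.values, expr.group_of, counts, ("Ag", "D8"))
        assert sup.motif_loadings["Mconst"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_group_rejected(self, reference_sim):
        _, tables, expr, _, _ = reference_sim
        with pytest.raises(ValidationError):
            supervised_cia(expr.values, expr.group_of, tables[0].counts, ("Ag", "D99"))

    def test_planted_motifs_load_in_top_decile(self):
        ok = 0
        for seed in range(1, 6):
            cfg = t.SimulationConfig(seed=seed)
            tables = t.simulate_motif_tables(cfg)
            expr, truth = t.simulate_expression(cfg, tables[0])
            norm = t.quantile_normalize(expr)
            sup = supervised_cia(
                norm.values, norm.group_of, tables[-1].counts, ("Ag", "D8"), 0.85
            )
            cut = sup.motif_loadings.abs().quantile(0.9)
            ok += all(abs(sup.motif_loadings[m]) >= cut for m in truth.active_motifs)
        assert ok >= 5 * 0.9 - 1  # ≥ 4 of 5 seeds
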