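import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methcorr import (
    BetaMatrix,
    ExpressionMatrix,
    ValidationError,
    impute_missing,
    partition_cohort,
    qc_filter_probes,
    select_correlated_cpgs,
    spearman_matrix,
    spearman_scan,
)


def _ids(n, prefix="S"):
    return [f"{prefix}{i}" for i in range(n)]


class TestPartition:
    def test_published_fractions_at_n100(self):
        part = partition_cohort(_ids(100), (0.4, 0.4, 0.2), seed=1)
        sizes = {k: len(part.set(k)) for k in ("set1", "set2", "set3")}
        assert sizes == {"set1": 40, "set2": 40, "set3": 20}

    def test_rounding_remainder_to_set3(self):
        # n=11: round(4.4)=4 twice, remainder 3 to the validation set
        part = partition_cohort(_ids(11), (0.4, 0.4, 0.2), seed=1)
        assert [len(part.set(k)) for k in ("set1", "set2", "set3")] == [4, 4, 3]

    def test_same_seed_same_assignment(self):
        a = partition_cohort(_ids(57), seed=9).assignments
        b = partition_cohort(_ids(57), seed=9).assignments
        assert a == b

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            partition_cohort(_ids(20), (0.4, 0.4, 0.3), seed=0)

    @given(n=st.integers(10, 300), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_disjoint_and_exhaustive(self, n, seed):
        part = partition_cohort(_ids(n), seed=seed)
        all_ids = sum((part.set(k) for k in ("set1", "set2", "set3")), [])
        assert sorted(all_ids) == sorted(_ids(n))


class TestImpute:
    def test_complete_matrix_unchanged(self, small_beta):
        out = impute_missing(small_beta, k=2)
        pd.testing.assert_frame_equal(out.data, small_beta.data)

    def test_knn_mean_matches_brute_force_oracle(self):
        # 5 probes x 4 samples, one missing cell; oracle: Euclidean distance
        # on mutually observed samples, mean of the 2 nearest rows' column
        vals = np.array([
            [0.5, np.nan, 0.3, 0.9],
            [0.5, 0.20, 0.3, 0.9],
            [0.6, 0.30, 0.3, 0.8],
            [0.1, 0.90, 0.9, 0.1],
            [0.9, 0.10, 0.1, 0.9],
        ])
        beta = BetaMatrix(pd.DataFrame(
            vals, index=_ids(5, "cg"), columns=_ids(4)))
        shared = [0, 2, 3]
        dists = [np.linalg.norm(vals[0, shared] - vals[r, shared])
                 for r in range(1, 5)]
        nearest = np.argsort(dists, kind="stable")[:2] + 1
        expected = vals[nearest, 1].mean()
        out = impute_missing(beta, k=2)
        assert out.values[0, 1] == pytest.approx(expected)
        # observed entries untouched
        assert np.array_equal(np.delete(out.values.ravel(), 1),
                              np.delete(vals.ravel(), 1))

    def test_imputed_values_in_unit_interval(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, size=(10, 8))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        beta = BetaMatrix(pd.DataFrame(vals, index=_ids(10, "cg"),
                                       columns=_ids(8)))
        out = impute_missing(beta, k=3)
        assert not out.has_missing()
        assert ((out.values >= 0) & (out.values <= 1)).all()

    def test_all_missing_probe_listed(self):
        vals = np.array([[np.nan, np.nan], [0.5, 0.5], [0.1, 0.9]])
        beta = BetaMatrix(pd.DataFrame(vals, index=["cgbad", "cg1", "cg2"],
                                       columns=_ids(2)))
        with pytest.raises(ValidationError, match="cgbad"):
            impute_missing(beta)


class TestQcFilter:
    def _cohort(self, frac_fail, n_samples=100):
        probes, samples = ["cgA"], _ids(n_samples)
        beta = BetaMatrix(pd.DataFrame(
            np.full((1, n_samples), 0.5), index=probes, columns=samples))
        p = np.full((1, n_samples), 0.001)
        p[0, : int(round(frac_fail * n_samples))] = 0.2
        return beta, pd.DataFrame(p, index=probes, columns=samples)

    @pytest.mark.parametrize("frac,excluded", [
        (0.06, True),   # fails in 6% of one cohort
        (0.04, False),  # 4% everywhere: retained
        (0.05, True),   # exactly 5%: >= is inclusive
    ])
    def test_exclusion_threshold(self, frac, excluded):
        beta_ok, p_ok = self._cohort(0.0)
        beta, p = self._cohort(frac)
        out = qc_filter_probes([beta_ok, beta], [p_ok, p])
        assert (out == ["cgA"]) == excluded


class TestSpearman:
    def _matrices(self, expr_vals, beta_vals):
        n = expr_vals.shape[1]
        e = ExpressionMatrix(pd.DataFrame(
            expr_vals, index=[f"g{i}" for i in range(expr_vals.shape[0])],
            columns=_ids(n)))
        b = BetaMatrix(pd.DataFrame(
            beta_vals, index=[f"cg{i}" for i in range(beta_vals.shape[0])],
            columns=_ids(n)))
        return e, b

    def test_monotone_pairs(self):
        x = np.linspace(0, 1, 20)
        e, b = self._matrices(np.vstack([5 * x]),
                              np.vstack([x ** 2, 1 - x ** 3]))
        rho, p = spearman_matrix(e, b, _ids(20))
        assert rho[0, 0] == pytest.approx(1.0)
        assert rho[0, 1] == pytest.approx(-1.0)
        assert (p[0] > 0).all()

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(10, 31))
            x = rng.normal(size=n)
            y = np.round(rng.uniform(0, 1, size=n), 1)  # ties on purpose
            e, b = self._matrices(np.abs(x)[None, :], y[None, :])
            rho, _ = spearman_matrix(e, b, _ids(n))
            oracle = np.corrcoef(stats.rankdata(np.abs(x)),
                                 stats.rankdata(y))[0, 1]
            assert abs(rho[0, 0] - oracle) < 1e-12

    def test_matches_scipy_spearmanr(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=25) ** 2
        y = rng.uniform(0, 1, size=25)
        e, b = self._matrices(x[None, :], y[None, :])
        rho, p = spearman_matrix(e, b, _ids(25))
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert rho[0, 0] == pytest.approx(ref_rho, abs=1e-12)
        assert p[0, 0] == pytest.approx(ref_p, rel=1e-6)

    def test_zero_variance_flagged(self):
        rng = np.random.default_rng(1)
        e, b = self._matrices(np.zeros((1, 12)),
                              rng.uniform(0, 1, size=(1, 12)))
        rec = spearman_scan(e, b, _ids(12))
        assert rec["rho"].isna().all()


def _records(rows, label):
    return pd.DataFrame(rows, columns=["gene_id", "probe_id", "rho", "p"]
                        ).assign(set_label=label)


class TestSelection:
    def test_significance_required_in_both_sets(self):
        r1 = _records([("g", "cgA", 0.9, 0.005), ("g", "cgB", -0.8, 0.001)], "set1")
        r2 = _records([("g", "cgA", 0.9, 0.2), ("g", "cgB", -0.7, 0.002)], "set2")
        m = select_correlated_cpgs(r1, r2)
        # cgA dropped (p=0.2 in set2); gene then lacks a positive probe
        assert m.gene_ids == []

    def test_sign_flip_discarded(self):
        r1 = _records([("g", "cgA", 0.9, 0.001), ("g", "cgB", -0.8, 0.001)], "set1")
        r2 = _records([("g", "cgA", -0.9, 0.001), ("g", "cgB", -0.7, 0.002)], "set2")
        assert select_correlated_cpgs(r1, r2).gene_ids == []

    def test_truncation_to_top_100_by_rank_sum(self):
        rng = np.random.default_rng(7)
        rhos = rng.uniform(0.3, 0.99, size=150)
        rows1 = [("g", f"cg{i:03d}", r, 0.001) for i, r in enumerate(rhos)]
        rows1 += [("g", "cgneg", -0.9, 0.001)]
        rows2 = [("g", f"cg{i:03d}", r, 0.001) for i, r in enumerate(rhos)]
        rows2 += [("g", "cgneg", -0.9, 0.001)]
        m = select_correlated_cpgs(_records(rows1, "set1"), _records(rows2, "set2"))
        pos = m.genes["g"].pos
        assert len(pos) == 100
        # kept = the 100 largest rhos; order strongest-first
        expected = {f"cg{i:03d}" for i in np.argsort(-rhos)[:100]}
        assert {e.probe_id for e in pos} == expected
        assert [e.probe_id for e in pos[:3]] == [
            f"cg{i:03d}" for i in np.argsort(-rhos)[:3]]

    def test_tie_rule_matches_brute_force_ordering_oracle(self):
        # cgA and cgB tie on rank sum; cgB has larger mean |rho| and must rank
        # first; cgC/cgD tie on rank sum AND mean -> lexicographic probe id
        rows1 = [("g", "cgA", 0.90, 1e-4), ("g", "cgB", 0.80, 1e-4),
                 ("g", "cgC", 0.60, 1e-4), ("g", "cgD", 0.60, 1e-4),
                 ("g", "cgN", -0.9, 1e-4)]
        rows2 = [("g", "cgA", 0.70, 1e-4), ("g", "cgB", 0.85, 1e-4),
                 ("g", "cgC", 0.60, 1e-4), ("g", "cgD", 0.60, 1e-4),
                 ("g", "cgN", -0.9, 1e-4)]

        def oracle(rows1, rows2):
            d1 = {p: r for _, p, r, _ in rows1 if r > 0}
            d2 = {p: r for _, p, r, _ in rows2 if r > 0}
            def rank(d):
                order = sorted(d, key=lambda p: -abs(d[p]))
                vals = sorted({abs(v) for v in d.values()}, reverse=True)
                # average ranks for ties
                out = {}
                i = 0
                for v in vals:
                    group = [p for p in order if abs(d[p]) == v]
                    ranks = range(i + 1, i + len(group) + 1)
                    for p in group:
                        out[p] = sum(ranks) / len(group)
                    i += len(group)
                return out
            rk1, rk2 = rank(d1), rank(d2)
            return sorted(d1, key=lambda p: (
                rk1[p] + rk2[p], -(abs(d1[p]) + abs(d2[p])) / 2, p))

        m = select_correlated_cpgs(_records(rows1, "set1"), _records(rows2, "set2"))
        got = [e.probe_id for e in m.genes["g"].pos]
        assert got == oracle(rows1, rows2)
        assert got.index("cgC") < got.index("cgD")

    def test_invariant_to_record_order(self):
        rng = np.random.default_rng(19)
        rows = []
        for i in range(30):
            rho = rng.uniform(-0.95, 0.95)
            rows.append(("g", f"cg{i:02d}", rho, float(rng.uniform(1e-5, 0.02))))
        r1 = _records(rows, "set1")
        rows2 = [(g, p, r + rng.normal(0, 0.01), q) for g, p, r, q in rows]
        r2 = _records(rows2, "set2")
        m_fwd = select_correlated_cpgs(r1, r2)
        perm = rng.permutation(len(rows))
        m_shuf = select_correlated_cpgs(r1.iloc[perm].reset_index(drop=True),
                                        r2.iloc[perm].reset_index(drop=True))
        assert m_fwd.gene_ids == m_shuf.gene_ids
        for g in m_fwd.gene_ids:
            assert m_fwd.genes[g].pos == m_shuf.genes[g].pos
            assert m_fwd.genes[g].neg == m_shuf.genes[g].neg
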