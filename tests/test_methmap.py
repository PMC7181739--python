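import itertools

import numpy as np
import pandas as pd
import pytest

from methcorr import (
    GeneProbeSets,
    MCSMatrix,
    MethCorrMatrix,
    ProbeEntry,
    ValidationError,
    build_map,
    cmcs,
    combined_similarity,
    delta_cmcs,
    delta_median_zscore,
    mcs_zscores,
    pct_change_median_mcs,
)


def _matrix_from_neg_sets(neg_sets: dict[str, set]) -> MethCorrMatrix:
    return MethCorrMatrix({
        g: GeneProbeSets(pos=[ProbeEntry(f"pos_{g}", 0.5, 0.5)],
                         neg=[ProbeEntry(p, -0.5, -0.5) for p in sorted(s)])
        for g, s in neg_sets.items()})


class TestCombinedSimilarity:
    def test_identical_sets(self):
        assert combined_similarity({"a", "b"}, {"a", "b"}) == pytest.approx(1.0)

    def test_disjoint_sets(self):
        assert combined_similarity({"a"}, {"b"}) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # J = 2/6, O = 2/4 -> 0.5*0.5 + 0.5*(1/3) = 0.41667
        sim = combined_similarity({"a", "b", "c", "d"}, {"c", "d", "e", "f"})
        assert sim == pytest.approx(0.41667, abs=5e-6)

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            combined_similarity(set(), {"a"})


class TestBuildMap:
    def test_full_overlap_edge(self):
        probes = {f"cg{i}" for i in range(100)}
        g = build_map(_matrix_from_neg_sets({"g1": probes, "g2": probes}))
        assert g.edges["g1", "g2"]["similarity"] == pytest.approx(1.0)

    def test_disjoint_no_edge(self):
        g = build_map(_matrix_from_neg_sets({"g1": {"a", "b"}, "g2": {"c", "d"}}))
        assert g.number_of_edges() == 0
        assert g.nodes["g1"]["isolated"]

    def test_cutoff_is_inclusive(self):
        A = set("abcdefgh")
        B = set("ghijklmnop")
        sim = combined_similarity(A, B)
        g = build_map(_matrix_from_neg_sets({"g1": A, "g2": B}), cutoff=sim)
        assert g.has_edge("g1", "g2")
        g2 = build_map(_matrix_from_neg_sets({"g1": A, "g2": B}),
                       cutoff=np.nextafter(sim, 1))
        assert not g2.has_edge("g1", "g2")

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(31)
        universe = [f"cg{i}" for i in range(60)]
        sets = {f"g{i:02d}": set(rng.choice(universe, size=rng.integers(3, 15),
                                            replace=False))
                for i in range(50)}
        g = build_map(_matrix_from_neg_sets(sets), cutoff=0.126)
        expected = {
            tuple(sorted((a, b)))
            for a, b in itertools.combinations(sets, 2)
            if combined_similarity(sets[a], sets[b]) >= 0.126}
        got = {tuple(sorted(e)) for e in g.edges}
        assert got == expected

    def test_gene_order_invariance(self):
        sets = {"g1": {"a", "b", "c"}, "g2": {"b", "c", "d"}, "g3": {"x"}}
        g_fwd = build_map(_matrix_from_neg_sets(sets))
        g_rev = build_map(_matrix_from_neg_sets(
            dict(reversed(list(sets.items())))))
        assert {tuple(sorted(e)) for e in g_fwd.edges} == \
               {tuple(sorted(e)) for e in g_rev.edges}


def _mcs(rows: dict[str, list[float]], samples=None) -> MCSMatrix:
    n = len(next(iter(rows.values())))
    samples = samples or [f"S{i}" for i in range(n)]
    return MCSMatrix(pd.DataFrame.from_dict(rows, orient="index",
                                            columns=samples, dtype=float))


class TestZScores:
    def test_hand_computed_example(self):
        # (0.2, 0.4, 0.6): mean 0.4, sd (n-1) = 0.2 -> z = (-1, 0, 1)
        z, flagged = mcs_zscores(_mcs({"g": [0.2, 0.4, 0.6]}))
        assert z.loc["g"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert flagged == []

    def test_constant_gene_flagged(self):
        z, flagged = mcs_zscores(_mcs({"g": [0.5, 0.5, 0.5]}))
        assert flagged == ["g"]
        assert z.loc["g"].isna().all()

    def test_normalized_mean_and_sd(self):
        rng = np.random.default_rng(3)
        z, _ = mcs_zscores(_mcs({"g": rng.uniform(0, 1, 20).tolist()}))
        assert z.loc["g"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z.loc["g"].std(ddof=1) == pytest.approx(1.0)


class TestDeltaMedianZ:
    def test_identical_groups_zero(self):
        z, _ = mcs_zscores(_mcs({"g": [0.1, 0.5, 0.9, 0.3]}))
        d = delta_median_zscore(z, ["S0", "S1"], ["S2", "S3"])
        d_same = delta_median_zscore(
            pd.concat([z, z.rename(columns={"S0": "T0", "S1": "T1"})[["T0", "T1"]]],
                      axis=1),
            ["S0", "S1"], ["T0", "T1"])
        assert d_same["g"] == pytest.approx(0.0)
        assert d["g"] == pytest.approx(-delta_median_zscore(
            z, ["S2", "S3"], ["S0", "S1"])["g"])

    def test_separated_groups(self):
        z = pd.DataFrame([[1.0, 1.0, 1.0, -1.0, -1.0, -1.0]], index=["g"],
                         columns=[f"S{i}" for i in range(6)])
        d = delta_median_zscore(z, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        assert d["g"] == pytest.approx(2.0)


class TestCmcs:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(5)
        mcs = _mcs({"g": rng.uniform(0.2, 0.8, 10).tolist()})
        out = cmcs([mcs], ["g"])
        assert out["g"] == pytest.approx(1.0)

    def test_anti_affine_gene(self):
        rng = np.random.default_rng(6)
        ref = rng.uniform(0.2, 0.8, 10)
        mcs = _mcs({"ref": ref.tolist(), "anti": (1 - ref).tolist()})
        out = cmcs([mcs], ["ref"])
        assert out["anti"] == pytest.approx(-1.0)

    def test_average_over_cohorts(self):
        def cohort(r, seed):
            rng = np.random.default_rng(seed)
            p = rng.normal(size=12)
            q = rng.normal(size=12)
            p -= p.mean(); q -= q.mean()
            q -= p * (p @ q) / (p @ p)
            p /= np.linalg.norm(p); q /= np.linalg.norm(q)
            x = r * p + np.sqrt(1 - r * r) * q
            scale = lambda v: (v - v.min()) / (v.max() - v.min()) * 0.8 + 0.1
            return _mcs({"ref": scale(p).tolist(), "g": scale(x).tolist()})
        out = cmcs([cohort(0.8, 1), cohort(0.4, 2)], ["ref"])
        assert out["g"] == pytest.approx(0.6, abs=1e-9)

    def test_values_bounded(self):
        rng = np.random.default_rng(7)
        mcs = _mcs({f"g{i}": rng.uniform(0, 1, 15).tolist() for i in range(20)})
        out = cmcs([mcs], ["g0", "g1", "g2"])
        assert ((out.dropna() >= -1) & (out.dropna() <= 1)).all()


class TestDeltaCmcs:
    def test_equal_sets_zero(self):
        rng = np.random.default_rng(8)
        mcs = _mcs({f"g{i}": rng.uniform(0, 1, 10).tolist() for i in range(5)})
        out = delta_cmcs([mcs], ["g0", "g1"], ["g0", "g1"])
        assert np.allclose(out.dropna(), 0.0)

    def test_swapping_sets_negates(self):
        rng = np.random.default_rng(9)
        mcs = _mcs({f"g{i}": rng.uniform(0, 1, 10).tolist() for i in range(6)})
        a = delta_cmcs([mcs], ["g0"], ["g1"])
        b = delta_cmcs([mcs], ["g1"], ["g0"])
        assert np.allclose(a.dropna(), -b.dropna())


class TestPctChange:
    @pytest.mark.parametrize("medA,medB,expected", [
        (0.5, 0.6, 20.0),
        (0.5, 0.5, 0.0),
        (0.5, 0.25, -50.0),
    ])
    def test_examples(self, medA, medB, expected):
        mcs = _mcs({"g": [medA, medA, medB, medB]})
        out = pct_change_median_mcs(mcs, ["S0", "S1"], ["S2", "S3"])
        assert out["g"] == pytest.approx(expected)

    def test_zero_baseline_flagged(self):
        mcs = _mcs({"g": [0.0, 0.0, 0.5, 0.5]})
        out = pct_change_median_mcs(mcs, ["S0", "S1"], ["S2", "S3"])
        assert np.isnan(out["g"])
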