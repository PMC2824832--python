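"""Transcript counting, normalization, rank aggregation, shuffled null."""

import numpy as np
import pandas as pd
import pytest

from oncopair.expression import (
    GeneModel,
    cluster_samples,
    count_transcript_reads,
    min_count_filter,
    normalize_counts,
    profile_correlation,
    rank_order_de,
    shuffled_rank_null,
)

GENES = [
    GeneModel("G1", "chr1", "+", exons=[(100, 200), (300, 400)]),
    GeneModel("G2", "chr1", "-", exons=[(500, 700)]),
]


def starts(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "strand"])


class TestCounting:
    def test_no_reads_in_exons(self):
        df = starts([("chr1", 250, "+"), ("chr2", 150, "+")])
        counts = count_transcript_reads(df, GENES)
        assert counts.sum() == 0

    def test_reads_summed_over_exons(self):
        df = starts([("chr1", 150, "+")] * 10 + [("chr1", 350, "+")] * 5)
        counts = count_transcript_reads(df, GENES)
        assert counts["G1"] == 15

    def test_antisense_excluded_when_stranded(self):
        df = starts([("chr1", 150, "-")] * 3)
        assert count_transcript_reads(df, GENES)["G1"] == 0
        assert count_transcript_reads(df, GENES, stranded=False)["G1"] == 3

    def test_start_position_rule(self):
        # a read starting 1 bp before the exon does not count
        df = starts([("chr1", 99, "+"), ("chr1", 100, "+"), ("chr1", 199, "+")])
        assert count_transcript_reads(df, GENES)["G1"] == 2


class TestNormalization:
    def test_pseudo_count_only(self):
        raw = pd.DataFrame({"s": [0]}, index=["G1"])
        out = normalize_counts(raw, {"s": 1e6})
        assert out.loc["G1", "s"] == pytest.approx(1e-6)

    def test_arithmetic(self):
        raw = pd.DataFrame({"s": [999]}, index=["G1"])
        assert normalize_counts(raw, {"s": 1e6}).loc["G1", "s"] == pytest.approx(1e-3)

    def test_order_conserved(self):
        raw = pd.DataFrame({"s": [5, 50, 500]}, index=list("abc"))
        out = normalize_counts(raw, {"s": 1000})["s"]
        assert out.is_monotonic_increasing

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_counts(pd.DataFrame({"s": [1]}), {"s": 0})


class TestMinCountFilter:
    def make(self, *pairs):
        return {
            f"p{i}": pd.DataFrame(
                {"normal": [a], "tumor": [b]}, index=["G1"]
            )
            for i, (a, b) in enumerate(pairs)
        }

    def test_one_tissue_suffices_per_patient(self):
        kept = min_count_filter(self.make((60, 0), (0, 70), (55, 55)))
        assert list(kept) == ["G1"]

    def test_one_weak_patient_drops_gene(self):
        kept = min_count_filter(self.make((49, 49), (500, 500), (500, 500)))
        assert list(kept) == []

    def test_zero_threshold_keeps_all(self):
        kept = min_count_filter(self.make((0, 0)), min_raw=0)
        assert list(kept) == ["G1"]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        tables = {
            f"p{i}": pd.DataFrame(
                {"normal": rng.integers(0, 200, 100),
                 "tumor": rng.integers(0, 200, 100)},
                index=[f"G{j}" for j in range(100)],
            )
            for i in range(3)
        }
        prev = None
        for thr in (0, 25, 50, 100):
            kept = set(min_count_filter(tables, min_raw=thr))
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestRankOrderDE:
    def test_identical_vectors(self):
        ratios = pd.DataFrame(
            {"p1": [0.1, -2.0, 3.0], "p2": [0.1, -2.0, 3.0]},
            index=["a", "b", "c"],
        )
        res = rank_order_de(ratios, set_size=1)
        assert res.median_rank["b"] == 1 and res.median_rank["c"] == 3
        assert res.down == ["b"] and res.up == ["c"]

    def test_median_by_enumeration(self):
        # 5 genes, 3 patients; median ranks checked by hand
        ranks = {
            "p1": [1, 2, 3, 4, 5],
            "p2": [2, 1, 3, 5, 4],
            "p3": [1, 3, 2, 4, 5],
        }
        # build ratio vectors realizing exactly these ranks
        ratios = pd.DataFrame(
            {p: np.asarray(r, dtype=float) for p, r in ranks.items()},
            index=list("abcde"),
        )
        res = rank_order_de(ratios, set_size=2)
        expected = [np.median(x) for x in zip(*ranks.values())]
        assert list(res.median_rank) == expected

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        ratios = pd.DataFrame(
            rng.normal(size=(50, 3)), columns=list("xyz"),
            index=[f"G{i}" for i in range(50)],
        )
        a = rank_order_de(ratios, set_size=10)
        b = rank_order_de(ratios**3, set_size=10)
        assert a.up == b.up and a.down == b.down

    def test_ranks_are_permutations_with_tie_averaging(self):
        ratios = pd.DataFrame(
            {"p1": [1.0, 1.0, 2.0, 0.0]}, index=list("abcd")
        )
        res = rank_order_de(ratios, set_size=1)
        assert sorted(res.ranks["p1"]) == [1.0, 2.5, 2.5, 4.0]

    def test_oversized_set_truncated_with_warning(self):
        ratios = pd.DataFrame({"p1": [1.0, 2.0]}, index=["a", "b"])
        with pytest.warns(UserWarning):
            res = rank_order_de(ratios, set_size=10)
        assert res.set_size == 2

    def test_planted_recovery(self):
        """Concordant planted effects with |log2| >= 2 are recovered."""
        from oncopair.expression import normalize_counts

        rng = np.random.default_rng(4)
        recovered = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n_genes, n_planted = 400, 40
            base = rng.lognormal(np.log(300), 0.8, n_genes)
            effects = np.zeros(n_genes)
            idx = rng.choice(n_genes, n_planted, replace=False)
            effects[idx] = rng.choice([-1, 1], n_planted) * (
                2.0 + rng.exponential(1.0, n_planted)
            )
            ratios = {}
            for p in range(3):
                normal = rng.poisson(base)
                tumor = rng.poisson(base * 2.0**effects)
                ratios[f"p{p}"] = np.log2((tumor + 1) / (normal + 1))
            df = pd.DataFrame(ratios, index=[f"G{i}" for i in range(n_genes)])
            res = rank_order_de(df, set_size=n_planted // 2)
            planted_up = {f"G{i}" for i in idx if effects[i] > 0}
            planted_down = {f"G{i}" for i in idx if effects[i] < 0}
            got = len(planted_up & set(res.up)) + len(planted_down & set(res.down))
            want = min(len(planted_up), n_planted // 2) + min(
                len(planted_down), n_planted // 2
            )
            recovered.append(got / want)
        assert np.mean(recovered) >= 0.95


class TestShuffledNull:
    def test_single_patient_uniform_null(self):
        """With one patient the null median rank is uniform, so the top
        gene's exceedance is ~1/n_genes."""
        rng = np.random.default_rng(5)
        n = 100
        ratios = pd.DataFrame(
            {"p1": rng.normal(size=n)}, index=[f"G{i}" for i in range(n)]
        )
        out = shuffled_rank_null(ratios, n_shuffles=2000, seed=1)
        top = out["median_rank"].idxmax()
        assert out.loc[top, "exceedance"] == pytest.approx(1.0 / n, rel=0.25)

    def test_planted_genes_more_extreme_than_unplanted(self):
        rng = np.random.default_rng(6)
        n = 200
        base = rng.normal(0, 0.5, size=(n, 3))
        base[:10] += 4.0  # concordant planted up-regulation
        ratios = pd.DataFrame(base, columns=list("abc"),
                              index=[f"G{i}" for i in range(n)])
        out = shuffled_rank_null(ratios, n_shuffles=300, seed=2)
        planted = out.iloc[:10]["exceedance"].mean()
        others = out.iloc[10:]["exceedance"].mean()
        assert planted < others / 5

    def test_deterministic_under_seed(self):
        ratios = pd.DataFrame(
            np.random.default_rng(7).normal(size=(30, 2)), columns=["a", "b"]
        )
        x = shuffled_rank_null(ratios, 50, seed=9)
        y = shuffled_rank_null(ratios, 50, seed=9)
        pd.testing.assert_frame_equal(x, y)


class TestProfileCorrelation:
    def test_identical_and_mirrored(self):
        v = pd.Series([1.0, -2.0, 0.5, 3.0], index=list("abcd"))
        assert profile_correlation(v, v) == pytest.approx(1.0)
        assert profile_correlation(v, -v) == pytest.approx(-1.0)

    def test_hand_computed(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        b = pd.Series([1.0, 3.0, 2.0, 5.0], index=list("abcd"))
        am, bm = a - a.mean(), b - b.mean()
        expected = (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())
        assert profile_correlation(a, b) == pytest.approx(expected)

    def test_cap_restricts_genes(self):
        a = pd.Series([0.5, -0.5, 5.0], index=list("abc"))
        b = pd.Series([0.4, -0.6, -5.0], index=list("abc"))
        with pytest.raises(ValueError):
            profile_correlation(a, b, cap=2.0)  # only 2 genes survive


class TestClustering:
    def test_tissues_separate(self):
        rng = np.random.default_rng(8)
        base = rng.lognormal(3, 1, 200)
        shift = 2.0 ** rng.normal(0, 1.5, 200)
        cols = {}
        for i in range(2):
            cols[f"N{i}"] = (base * rng.lognormal(0, 0.1, 200) + 1) / 1e6
            cols[f"T{i}"] = (base * shift * rng.lognormal(0, 0.1, 200) + 1) / 1e6
        df = pd.DataFrame(cols)
        link, order = cluster_samples(df)
        # the two top clusters are the tissue types
        half = {order[0], order[1]}
        assert half in ({"N0", "N1"}, {"T0", "T1"})

    def test_duplicate_samples_merge_first(self):
        rng = np.random.default_rng(9)
        x = rng.lognormal(0, 1, 50)
        df = pd.DataFrame({"a": x, "b": x, "c": x * 2.0 ** rng.normal(0, 2, 50)})
        link, order = cluster_samples(df)
        first = sorted(link[0, :2].astype(int))
        assert first == [0, 1] and link[0, 2] == pytest.approx(0.0, abs=1e-12)
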