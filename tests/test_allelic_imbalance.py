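"""Chi-square AI test, filter chain, genotype classification, gene rollup."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oncopair.allelic_imbalance import (
    AIThresholds,
    GeneModel,
    KnownVariant,
    aggregate_ai_to_genes,
    ai_magnitude,
    chi2_independence,
    classify_genotypes,
    classify_site_region,
    detect_relative_ai,
    recurrent_ai_genes,
)
from oncopair.tally import make_tally_frame


def brute_force_pearson(table):
    """Textbook Pearson chi-square on a 2 x k table: expected counts from
    the marginal products, statistic summed cell by cell."""
    table = np.asarray(table, dtype=float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    k = table.shape[1]
    if k <= 1:
        return 0.0, 0, 1.0
    grand = table.sum()
    chi2 = 0.0
    for i in range(2):
        for j in range(k):
            e = table[i].sum() * table[:, j].sum() / grand
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2, k - 1, float(stats.chi2.sf(chi2, k - 1))


class TestChi2:
    def test_identical_tables(self):
        chi2, df, p = chi2_independence([10, 0, 10, 0], [10, 0, 10, 0])
        assert chi2 == 0.0 and p == 1.0

    def test_hand_computed_2x2(self):
        # normal all A (30); tumor splits A/C 15/15.  After dropping zero
        # columns the 2x2 has expected counts 22.5/7.5 per row.
        chi2, df, p = chi2_independence([30, 0, 0, 0], [15, 15, 0, 0])
        assert chi2 == pytest.approx(20.0)
        assert df == 1
        assert p == pytest.approx(7.7e-6, rel=0.01)

    def test_label_symmetry(self):
        a, b = [12, 3, 0, 1], [5, 9, 2, 0]
        assert chi2_independence(a, b) == chi2_independence(b, a)

    def test_single_shared_nucleotide_degenerate(self):
        chi2, df, p = chi2_independence([5, 0, 0, 0], [9, 0, 0, 0])
        assert (chi2, df, p) == (0.0, 0, 1.0)

    def test_zero_coverage_not_testable(self):
        with pytest.raises(ValueError):
            chi2_independence([0, 0, 0, 0], [5, 0, 0, 0])

    def test_matches_brute_force_enumeration(self):
        """Exhaustive oracle: agreement with a cell-by-cell Pearson
        computation over small 2x2 and 2x3 tables, plus a seeded random
        sample of 2x4 tables with cells up to 6."""
        tables = []
        for cells in itertools.product(range(5), repeat=4):  # 2x2
            tables.append([[cells[0], cells[1], 0, 0], [cells[2], cells[3], 0, 0]])
        for cells in itertools.product(range(3), repeat=6):  # 2x3
            tables.append(
                [[cells[0], cells[1], cells[2], 0], [cells[3], cells[4], cells[5], 0]]
            )
        rng = np.random.default_rng(0)
        tables += [rng.integers(0, 7, size=(2, 4)).tolist() for _ in range(2000)]
        checked = 0
        for t in tables:
            a, b = t
            if sum(a) == 0 or sum(b) == 0:
                continue
            chi2, df, p = chi2_independence(a, b)
            chi2_o, df_o, p_o = brute_force_pearson(t)
            assert chi2 == pytest.approx(chi2_o, abs=1e-10)
            assert df == df_o
            assert p == pytest.approx(p_o, abs=1e-12)
            checked += 1
        assert checked > 1000


class TestMagnitude:
    def test_identical_profiles(self):
        _, m = ai_magnitude([10, 5, 0, 0], [20, 10, 0, 0])
        assert m == 0.0

    def test_half_shift(self):
        delta, m = ai_magnitude([30, 0, 0, 0], [15, 15, 0, 0])
        assert delta[0] == pytest.approx(-0.5)
        assert delta[1] == pytest.approx(0.5)
        assert m == pytest.approx(0.5)

    def test_swap_negates_deltas(self):
        d1, m1 = ai_magnitude([12, 3, 1, 0], [5, 9, 2, 0])
        d2, m2 = ai_magnitude([5, 9, 2, 0], [12, 3, 1, 0])
        assert np.allclose(d1, -d2)
        assert m1 == m2


def paired_frames(n_counts, t_counts, n_mss=None, t_mss=None):
    normal = make_tally_frame(["chr1"], [100], "normal", np.array([n_counts]),
                              None if n_mss is None else np.array([n_mss]))
    tumor = make_tally_frame(["chr1"], [100], "tumor", np.array([t_counts]),
                             None if t_mss is None else np.array([t_mss]))
    return normal, tumor


class TestFilterChain:
    def test_low_coverage_fails_even_at_huge_imbalance(self):
        n, t = paired_frames([14, 0, 0, 0], [50, 50, 0, 0])
        call = detect_relative_ai(n, t).iloc[0]
        assert not call["coverage_ok"]
        assert not call["ai_positive"]

    def test_exact_ten_percent_delta_fails_strict_filter(self):
        # 0.10 exactly is not "greater than 10%"
        n, t = paired_frames([50, 50, 0, 0], [40, 60, 0, 0])
        call = detect_relative_ai(n, t).iloc[0]
        assert call["max_abs_delta"] == pytest.approx(0.10)
        assert not call["delta_ok"]

    def test_all_reads_one_start_fails_dupstart(self):
        n, t = paired_frames([30, 0, 0, 0], [20, 10, 0, 0],
                             t_mss=[1, 10, 0, 0])
        call = detect_relative_ai(n, t).iloc[0]
        assert not call["dupstart_ok"]

    def test_clean_strong_site_is_positive(self):
        n, t = paired_frames([30, 0, 0, 0], [15, 15, 0, 0])
        call = detect_relative_ai(n, t).iloc[0]
        assert call[["coverage_ok", "p_ok", "delta_ok", "dupstart_ok"]].all()
        assert call["ai_positive"]

    def test_catalog_annotated_but_not_required(self):
        n, t = paired_frames([30, 0, 0, 0], [15, 15, 0, 0])
        calls = detect_relative_ai(
            n, t, variants=[KnownVariant("chr1", 100, "A", "C")]
        )
        assert calls.iloc[0]["in_variant_catalog"]
        assert calls.iloc[0]["ai_positive"]
        calls2 = detect_relative_ai(n, t, variants=[])
        assert not calls2.iloc[0]["in_variant_catalog"]
        assert calls2.iloc[0]["ai_positive"]

    def test_vectorized_stats_match_scalar(self, ai_cohort):
        p = ai_cohort.patients[0]
        calls = detect_relative_ai(p.tallies["normal"], p.tallies["tumor"])
        sub = calls.sample(50, random_state=0)
        n = p.tallies["normal"].set_index("pos")
        t = p.tallies["tumor"].set_index("pos")
        cols = [f"count_{x}" for x in "ACGT"]
        for row in sub.itertuples(index=False):
            chi2, df, pval = chi2_independence(
                n.loc[row.pos, cols].to_numpy(), t.loc[row.pos, cols].to_numpy()
            )
            assert row.chi2 == pytest.approx(chi2, abs=1e-8)
            assert row.p == pytest.approx(pval, abs=1e-12)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            AIThresholds(min_delta=1.5)


class TestGenotypes:
    def frame(self, ref, alt, ratio):
        return pd.DataFrame(
            {"ref_count": [ref], "alt_count": [alt], "allelic_ratio": [ratio]}
        )

    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.0, "het"), (2.0, "hom-ref"), (-2.0, "hom-alt"),
         (1.99, "het"), (-1.99, "het"), (3.5, "hom-ref")],
    )
    def test_boundaries_inclusive_homozygous(self, ratio, expected):
        out = classify_genotypes(self.frame(10, 10, ratio))
        assert out["genotype"].iloc[0] == expected

    def test_single_allele_is_homozygous(self):
        out = classify_genotypes(self.frame(30, 0, np.nan))
        assert out["genotype"].iloc[0] == "hom-ref"
        out = classify_genotypes(self.frame(0, 30, np.nan))
        assert out["genotype"].iloc[0] == "hom-alt"

    def test_trimodal_recovery_on_cohort(self, null_cohort):
        """Genotype classes recovered from allelic ratios match the truth
        at well-covered sites."""
        from oncopair.tally import allelic_ratio

        p = null_cohort.patients[0]
        normal = p.tallies["normal"]
        truth = null_cohort.truth.genotypes["P1"]
        merged = normal.merge(truth, on=["chrom", "pos"])
        rows = []
        for r in merged.itertuples(index=False):
            ref_c = getattr(r, f"count_{r.ref}")
            alt_c = getattr(r, f"count_{r.alt}")
            ar = allelic_ratio(ref_c, alt_c, r.coverage)
            rows.append((ref_c, alt_c, ar.value if ar.value is not None else np.nan,
                         r.coverage, r.genotype))
        df = pd.DataFrame(rows, columns=["ref_count", "alt_count",
                                         "allelic_ratio", "coverage", "truth"])
        df = df[df["coverage"] >= 15]
        out = classify_genotypes(df)
        agree = (out["genotype"] == out["truth"]).mean()
        assert agree > 0.99


class TestGeneAggregation:
    gene = GeneModel("G1", "chr1", "+", exons=[(100, 200), (300, 400)])

    @pytest.mark.parametrize(
        "pos0,expected",
        [
            (150, "exonic"),
            (207, "near-splice-site"),  # 8 bp into the intron
            (250, "intronic"),
            (292, "near-splice-site"),  # 8 bp before the next exon
            (199, "exonic"),
        ],
    )
    def test_region_classes(self, pos0, expected):
        assert classify_site_region(self.gene, pos0) == expected

    def test_zero_exon_model_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("bad", "chr1", "+", exons=[])

    def test_site_assigned_to_overlapping_genes_both_strands(self):
        g2 = GeneModel("G2", "chr1", "-", exons=[(120, 420)])
        calls = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [151], "ai_positive": [True]}
        )
        out = aggregate_ai_to_genes(calls, [self.gene, g2])
        assert (out.set_index("gene_id")["n_ai_positive"] == 1).all()

    def test_counts(self):
        calls = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "pos": [151, 351, 151],
                "ai_positive": [True, False, True],
            }
        )
        out = aggregate_ai_to_genes(calls, [self.gene]).set_index("gene_id")
        assert out.loc["G1", "n_sites_tested"] == 2
        assert out.loc["G1", "n_ai_positive"] == 1
        assert out.loc["G1", "region_classes"] == ["exonic"]


class TestRecurrence:
    def test_set_arithmetic(self):
        rec, pairs = recurrent_ai_genes(
            {"p1": ["A", "B"], "p2": ["B", "C"], "p3": ["B"]}
        )
        assert rec["B"] == 3 and rec["A"] == 1 and rec["C"] == 1
        assert set(pairs.values()) == {1}

    def test_identical_lists(self):
        rec, _ = recurrent_ai_genes({"p1": ["X", "Y"], "p2": ["X", "Y"]})
        assert (rec == 2).all()

    def test_needs_two_patients(self):
        with pytest.raises(ValueError):
            recurrent_ai_genes({"p1": ["A"]})


class TestCohortLevel:
    def test_null_pvalues_not_anticonservative(self, null_cohort):
        """Under the null, p-values at het sites are stochastically no
        smaller than uniform (one-sided KS)."""
        p = null_cohort.patients[0]
        truth = null_cohort.truth.genotypes["P1"]
        calls = detect_relative_ai(p.tallies["normal"], p.tallies["tumor"])
        het_pos = set(truth.loc[truth["genotype"] == "het", "pos"])
        pv = calls.loc[calls["pos"].isin(het_pos), "p"].dropna().to_numpy()
        assert len(pv) > 500
        # alternative='greater': CDF above uniform means p-values too small
        stat, ks_p = stats.kstest(pv, "uniform", alternative="greater")
        assert ks_p > 0.01

    def test_power_monotone_in_shift(self):
        """Detection power grows with the planted allele-frequency shift."""
        from oncopair.simulate import CNSegmentSpec, SimulationConfig, simulate_cohort

        # allele-specific ratios giving shifts |r/(r+1) - 0.5| of ~0.1/0.2/0.4
        ratios = {0.1: 1.5, 0.2: 7 / 3, 0.4: 9.0}
        power = {}
        for shift, r in ratios.items():
            rates = []
            for seed in range(3):
                cfg = SimulationConfig(
                    seed=100 + seed, n_patients=1, n_variant_sites=600,
                    genome=(("chr1", 1_000_000),),
                    cn_segments=[CNSegmentSpec("chr1", 0, 1_000_000, r, "A")],
                )
                c = simulate_cohort(cfg)
                pat = c.patients[0]
                calls = detect_relative_ai(pat.tallies["normal"], pat.tallies["tumor"])
                planted = c.truth.planted_ai_sites["P1"]
                m = calls.merge(planted, on=["chrom", "pos"])
                rates.append(m["ai_positive"].mean())
            power[shift] = np.mean(rates)
        assert power[0.1] < power[0.2] <= power[0.4]
        assert power[0.4] > 0.9
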