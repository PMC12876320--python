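import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hemivox.variant_integration import (
    Pwm,
    VariantError,
    annotate_region,
    compute_r2,
    compute_r2_from_panel,
    correlate_expression,
    enhancer_colocalize,
    intersect_degs,
    intersect_eqtl,
    ld_expand,
    mcnemar_exact_p,
    pwm_allele_score,
    select_sentinels,
)


class TestSentinels:
    def _gwas(self, ps, rsids=None):
        n = len(ps)
        return pd.DataFrame(
            {
                "rsid": rsids or [f"rs{i}" for i in range(n)],
                "chrom": "chr1",
                "pos": range(100, 100 + n),
                "ref": "A",
                "alt": "G",
                "trait": "stuttering",
                "p": ps,
            }
        )

    def test_threshold_is_strict(self):
        out = select_sentinels(self._gwas([1e-4, 9e-6, 1e-5]))
        assert out["rsid"].tolist() == ["rs1"]

    def test_all_above_threshold_empty(self):
        assert len(select_sentinels(self._gwas([1e-4, 5e-3]))) == 0

    def test_duplicate_rsid_keeps_min_p(self):
        out = select_sentinels(self._gwas([1e-6, 1e-8], ["rsX", "rsX"]))
        assert len(out) == 1
        assert out["p"].iloc[0] == 1e-8

    def test_malformed_p_rejected(self):
        with pytest.raises(VariantError, match="malformed"):
            select_sentinels(self._gwas([1e-6, "oops"]))


class TestComputeR2:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((50, 0, 0, 50), 1.0),
            ((25, 25, 25, 25), 0.0),
            ((40, 10, 10, 40), 0.36),
        ],
    )
    def test_tabulated_values(self, counts, expected):
        assert compute_r2(*counts) == pytest.approx(expected)

    def test_monomorphic_missing(self):
        assert np.isnan(compute_r2(50, 0, 50, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(VariantError):
            compute_r2(-1, 1, 1, 1)

    @given(st.tuples(*[st.integers(0, 30)] * 4))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_range_and_symmetries(self, counts):
        n_ab, n_aB, n_Ab, n_AB = counts
        if sum(counts) == 0:
            return
        r2 = compute_r2(n_AB, n_Ab, n_aB, n_ab)
        if np.isnan(r2):
            return
        assert 0.0 <= r2 <= 1.0 + 1e-12
        # locus exchange: swap the discordant haplotype counts
        assert compute_r2(n_AB, n_aB, n_Ab, n_ab) == pytest.approx(r2)
        # allele relabeling at locus 1
        assert compute_r2(n_aB, n_ab, n_AB, n_Ab) == pytest.approx(r2)

    def test_panel_wrapper(self):
        a = np.array([1, 1, 0, 0])
        b = np.array([1, 1, 0, 0])
        assert compute_r2_from_panel(a, b) == 1.0
        assert compute_r2_from_panel(a, 1 - b) == 1.0


class TestLdExpand:
    def _fixture(self):
        positions = pd.DataFrame(
            {
                "rsid": ["s1", "p1", "p2", "p3", "far"],
                "chrom": ["chr1"] * 5,
                "pos": [1_000_000, 1_000_100, 1_000_200, 1_000_300, 1_600_001],
            }
        )
        sentinels = pd.DataFrame({"rsid": ["s1"]})
        ld = pd.DataFrame(
            {
                "rsid_a": ["s1", "s1", "s1", "s1"],
                "rsid_b": ["p1", "p2", "p3", "far"],
                "r2": [0.9, 0.8, 0.81, 0.95],
            }
        )
        return sentinels, ld, positions

    def test_strict_r2_and_window_boundaries(self):
        sentinels, ld, positions = self._fixture()
        out = ld_expand(sentinels, ld, positions, r2_min=0.8, window_bp=500_000)
        # p2 at exactly r2=0.8 excluded (strict >); far beyond window excluded
        assert sorted(out["rsid"]) == ["p1", "p3"]
        assert (out["source"] == "proxy").all()
        assert (out["parent_rsid"] == "s1").all()

    def test_window_edge_plus_one_excluded(self):
        sentinels, ld, positions = self._fixture()
        out = ld_expand(sentinels, ld, positions, r2_min=0.8, window_bp=600_000)
        assert "far" not in out["rsid"].tolist()  # 600001 > 600000
        out2 = ld_expand(sentinels, ld, positions, r2_min=0.8, window_bp=600_001)
        assert "far" in out2["rsid"].tolist()

    def test_missing_sentinel_warned_and_skipped(self):
        sentinels = pd.DataFrame({"rsid": ["ghost"]})
        _, ld, positions = self._fixture()
        with pytest.warns(UserWarning, match="ghost"):
            out = ld_expand(sentinels, ld, positions)
        assert out.empty


class TestEqtl:
    def test_join_and_collapse(self):
        variants = pd.DataFrame({"rsid": ["r1", "r2"], "chrom": "chr1",
                                 "pos": [1, 2]})
        eqtl = pd.DataFrame(
            {
                "rsid": ["r1", "r1", "r1", "r9"],
                "gene_id": ["G1", "G1", "G1", "G2"],
                "tissue": ["Cortex", "Putamen", "Amygdala", "Cortex"],
                "slope": 0.5,
                "p": 1e-6,
            }
        )
        hits, egenes, tissues = intersect_eqtl(variants, eqtl)
        assert len(hits) == 3
        assert egenes == ["G1"]
        assert tissues["Cortex"] == 1

    def test_disjoint_empty_and_duplicates_deduplicated(self):
        variants = pd.DataFrame({"rsid": ["rX"], "chrom": "chr1", "pos": [5]})
        eqtl = pd.DataFrame(
            {"rsid": ["rX", "rX"], "gene_id": ["G1", "G1"],
             "tissue": ["Cortex", "Cortex"], "slope": 0.1, "p": 1e-4}
        )
        hits, egenes, _ = intersect_eqtl(variants, eqtl)
        assert len(hits) == 1
        hits2, egenes2, _ = intersect_eqtl(
            pd.DataFrame({"rsid": ["zz"], "chrom": "chr1", "pos": [9]}), eqtl
        )
        assert hits2.empty and egenes2 == []


class TestAnnotateRegion:
    def _model(self):
        # gene A: + strand 1000-2000 (0-based half-open), exon 1000-1200,
        # UTR 1180-1200; gene B: - strand 5000-6000
        return pd.DataFrame(
            [
                {"chrom": "chr1", "start": 1000, "end": 2000, "strand": "+",
                 "type": "gene", "gene_id": "A"},
                {"chrom": "chr1", "start": 1000, "end": 1200, "strand": "+",
                 "type": "exon", "gene_id": "A"},
                {"chrom": "chr1", "start": 1180, "end": 1200, "strand": "+",
                 "type": "UTR", "gene_id": "A"},
                {"chrom": "chr1", "start": 5000, "end": 6000, "strand": "-",
                 "type": "gene", "gene_id": "B"},
            ]
        )

    def _variants(self, positions):
        return pd.DataFrame({"rsid": [f"v{i}" for i in range(len(positions))],
                             "chrom": "chr1", "pos": positions})

    def test_precedence_and_classes(self):
        # 1-based positions: 1100 exon; 1190 exon+UTR -> exonic; 1500 intron;
        # 900 upstream of A (+); 6500 upstream of B (-); 9000 intergenic
        labels = annotate_region(
            self._variants([1101, 1191, 1501, 901, 6500, 9000]), self._model()
        )
        assert labels.tolist() == [
            "exonic", "exonic", "intronic", "upstream", "upstream", "intergenic"
        ]

    def test_utr_without_exon_cover(self):
        model = self._model()
        model.loc[model["type"] == "exon", "end"] = 1100  # UTR no longer in exon
        labels = annotate_region(self._variants([1191]), model)
        assert labels.tolist() == ["UTR"]

    def test_intron_beats_neighbor_upstream(self):
        # variant in intron of A and 1 kb upstream of a gene C
        model = pd.concat(
            [self._model(), pd.DataFrame([
                {"chrom": "chr1", "start": 2500, "end": 3000, "strand": "+",
                 "type": "gene", "gene_id": "C"}])],
            ignore_index=True,
        )
        labels = annotate_region(self._variants([1900]), model)
        assert labels.tolist() == ["intronic"]

    def test_classes_partition_variant_set(self):
        rng = np.random.default_rng(0)
        labels = annotate_region(
            self._variants(rng.integers(1, 10_000, size=50)), self._model()
        )
        assert labels.notna().all()

    def test_gff3_reader_round_trip(self, tmp_path):
        from hemivox.variant_integration import read_gff3_model

        gff = tmp_path / "toy.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\ttest\tgene\t1001\t2000\t.\t+\t.\tID=geneA\n"
            "chr1\ttest\texon\t1001\t1200\t.\t+\t.\tID=exonA1;Parent=geneA\n"
            "chr1\ttest\tfive_prime_UTR\t1001\t1050\t.\t+\t.\tID=utrA;Parent=geneA\n"
        )
        model = read_gff3_model(gff)
        # 1-based closed GFF3 converted to 0-based half-open
        gene = model.loc[model["type"] == "gene"].iloc[0]
        assert (gene["start"], gene["end"]) == (1000, 2000)
        assert set(model["type"]) == {"gene", "exon", "UTR"}
        assert (model["gene_id"] == "geneA").all()
        labels = annotate_region(self._variants([1075, 1150, 1500]), model)
        assert labels.tolist() == ["exonic", "exonic", "intronic"]

    def test_malformed_feature_rejected(self):
        model = self._model()
        model.loc[0, "end"] = model.loc[0, "start"]
        with pytest.raises(VariantError, match="malformed"):
            annotate_region(self._variants([1101]), model)


class TestEnhancerColocalize:
    def test_mcnemar_examples(self):
        assert mcnemar_exact_p(5, 0) == pytest.approx(0.0625)
        assert mcnemar_exact_p(1, 1) == 1.0

    def test_mcnemar_matches_enumeration_all_small_counts(self):
        for b in range(21):
            for c in range(21 - b):
                n, k = b + c, min(b, c)
                if n == 0:
                    expected = 1.0
                else:
                    # brute-force binomial tail enumeration
                    from math import comb

                    pmf = [comb(n, i) / 2.0**n for i in range(n + 1)]
                    expected = min(1.0, 2.0 * sum(pmf[: k + 1]))
                assert mcnemar_exact_p(b, c) == pytest.approx(expected, rel=1e-12)

    def test_flags_totals_and_percentages(self):
        variants = pd.DataFrame(
            {"rsid": [f"v{i}" for i in range(5)], "chrom": "chr1",
             "pos": [100, 200, 300, 400, 500]}
        )
        enhancers = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 90, "end": 110, "kind": "SE"},
                {"chrom": "chr1", "start": 190, "end": 210, "kind": "SE"},
                {"chrom": "chr1", "start": 290, "end": 310, "kind": "TE"},
                {"chrom": "chr1", "start": 390, "end": 410, "kind": "SE"},
                {"chrom": "chr1", "start": 390, "end": 410, "kind": "TE"},
            ]
        )
        flags, summary = enhancer_colocalize(variants, enhancers)
        assert summary["n_SE_only"] == 2
        assert summary["n_TE_only"] == 1
        assert summary["n_both"] == 1
        assert summary["n_neither"] == 1
        total = (summary["n_SE_only"] + summary["n_TE_only"] + summary["n_both"]
                 + summary["n_neither"])
        assert total == summary["n_total"] == 5
        assert summary["pct_SE_only"] == 40.0

    def test_half_open_interval_convention(self):
        variants = pd.DataFrame({"rsid": ["a", "b"], "chrom": "chr1",
                                 "pos": [101, 111]})
        enhancers = pd.DataFrame(
            [{"chrom": "chr1", "start": 100, "end": 110, "kind": "SE"}]
        )
        flags, _ = enhancer_colocalize(variants, enhancers)
        # 1-based pos 101 -> 0-based 100 in [100,110); pos 111 -> 110 not in
        assert flags["in_SE"].tolist() == [True, False]

    def test_empty_variant_set_rejected(self):
        with pytest.raises(VariantError, match="empty"):
            enhancer_colocalize(pd.DataFrame(columns=["rsid", "chrom", "pos"]),
                                pd.DataFrame(columns=["chrom", "start", "end", "kind"]))


class TestPwm:
    def test_uniform_pwm_zero_delta(self):
        pwm = Pwm("u", np.full((4, 3), 0.25), pseudocount=0.0)
        ref, alt, delta = pwm_allele_score(pwm, "ACGTA", 2, "G", "T")
        assert delta == pytest.approx(0.0)

    def test_single_position_log_odds(self):
        pwm = Pwm("g", np.array([[0.01], [0.01], [0.97], [0.01]]), pseudocount=0.0)
        _, _, delta = pwm_allele_score(pwm, "AAGAA", 2, "G", "A")
        assert delta == pytest.approx(np.log2(0.01 / 0.97), abs=1e-9)

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0.5, 10, size=(4, 5))
        pwm = Pwm("m", m)
        window = "ACGTGCAT"
        off, ref, alt = 3, "T", "C"
        s1 = pwm_allele_score(pwm, window, off, ref, alt)
        rc = window[::-1].translate(str.maketrans("ACGT", "TGCA"))
        comp = str.maketrans("ACGT", "TGCA")
        s2 = pwm_allele_score(pwm, rc, len(window) - 1 - off,
                              ref.translate(comp), alt.translate(comp))
        assert s1[0] == pytest.approx(s2[0])
        assert s1[2] == pytest.approx(s2[2])

    def test_allele_mismatch_rejected(self):
        pwm = Pwm("u", np.full((4, 2), 0.25))
        with pytest.raises(VariantError, match="disagrees"):
            pwm_allele_score(pwm, "ACGT", 1, "G", "A")

    def test_jaspar_round_trip(self, tmp_path):
        path = tmp_path / "motif.jaspar"
        path.write_text(
            ">MA0000.1 TESTMOTIF\n"
            "A [ 10  2  0 ]\n"
            "C [  2  1  0 ]\n"
            "G [  3 15 20 ]\n"
            "T [  5  2  0 ]\n"
        )
        pwm = Pwm.from_jaspar(path, pseudocount=0.0)
        assert pwm.length == 3
        # column frequencies sum to 1 after normalization
        np.testing.assert_allclose(pwm.freq.sum(axis=0), 1.0)
        assert pwm.score("AGG") == pytest.approx(
            np.log2(0.5 / 0.25) + np.log2(0.75 / 0.25) + np.log2(1.0 / 0.25)
        )


class TestSpearman:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert correlate_expression(x, x)[0] == pytest.approx(1.0)
        assert correlate_expression(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_rank_arithmetic_example(self):
        rho, p = correlate_expression([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        # sum d^2 = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        assert rho == pytest.approx(0.8)
        # exact permutation p: fraction of |rho| >= 0.8 among 120 permutations
        count = 0
        rx = np.arange(1, 6)
        for perm in itertools.permutations(rx):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= 0.8 - 1e-12
        assert p == pytest.approx(count / 120)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = correlate_expression([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho)


class TestIntersectDegs:
    def _results(self):
        mk = lambda fcs, ps: pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(fcs))],
             "log2fc": fcs, "statistic": 0.0, "p": ps}
        )
        return {
            ("LR", "BA44", "BA44"): mk([2.0, 0.1], [0.01, 0.01]),
            ("WH_L", "BA44", "BA22"): mk([np.log2(1.5), -1.0], [0.049, 0.2]),
            ("WH_L", "BA44", "BA4"): mk([0.9, 0.0], [0.01, 0.9]),
        }

    def test_event_and_gene_counting(self):
        genes, events, counts = intersect_degs({"g0", "g1"}, self._results())
        # LR: g0 (fc 2, p .01); WH_L BA44/BA22: g0 at |fc|=log2(1.5) inclusive;
        # WH_L BA44/BA4: g0 fc .9 >= log2 1.5 (.585), p .01
        assert genes == ["g0"]
        assert counts == {"LR": 1, "WH_L": 2, "WH_R": 0}
        assert len(events) == 3

    def test_no_degs_empty(self):
        genes, events, counts = intersect_degs({"zz"}, self._results())
        assert genes == [] and events.empty

    def test_fold_change_boundary_inclusive(self):
        res = {("LR", "BA44", "BA44"): pd.DataFrame(
            {"gene_id": ["g"], "log2fc": [np.log2(1.5)], "statistic": [0.0],
             "p": [0.04]}
        )}
        genes, _, _ = intersect_degs({"g"}, res)
        assert genes == ["g"]
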