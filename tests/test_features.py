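"""Exon/intron selection, splice PWMs, expression groups, interval tests."""

import numpy as np
import pandas as pd
import pytest

from nucleoform import (
    GeneModel,
    GenomeAssembly,
    expression_groups,
    exon_number_profile,
    feature_mean_occupancy,
    gc_tertile_profiles,
    interval_group_compare,
    score_splice_sites,
    select_exons_introns,
    train_splice_pwm,
)
from nucleoform.features import SpliceSitePWM


def make_gene(gid="g1", chrom="c", strand="+", exon_lens=(100, 200, 150),
              intron_lens=(200, 300), start=1000):
    exons = []
    pos = start
    for k, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if k < len(intron_lens):
            pos += intron_lens[k]
    return GeneModel(gid, chrom, strand, exons)


class TestSelectExonsIntrons:
    def test_short_internal_exon_excluded(self):
        g = make_gene(exon_lens=(100, 49, 150), intron_lens=(200, 300))
        exons, _ = select_exons_introns([g])
        assert len(exons) == 0

    def test_flanked_internal_exon_included(self):
        g = make_gene(exon_lens=(100, 200, 150), intron_lens=(125, 300))
        exons, introns = select_exons_introns([g])
        assert len(exons) == 1
        assert exons.iloc[0]["end"] - exons.iloc[0]["start"] == 200
        assert len(introns) == 2

    def test_short_flanking_intron_disqualifies_exon(self):
        g = make_gene(exon_lens=(100, 200, 150), intron_lens=(124, 300))
        exons, introns = select_exons_introns([g])
        assert len(exons) == 0
        assert len(introns) == 1  # only the 300-bp intron qualifies

    def test_two_exon_gene_has_no_qualifying_exons(self):
        g = make_gene(exon_lens=(100, 150), intron_lens=(400,))
        exons, _ = select_exons_introns([g])
        assert len(exons) == 0

    def test_exon_length_bounds_inclusive(self):
        for length, expect in ((50, 1), (500, 1), (501, 0)):
            g = make_gene(exon_lens=(100, length, 150),
                          intron_lens=(200, 300))
            exons, _ = select_exons_introns([g])
            assert len(exons) == expect

    def test_minus_strand_ordinals(self):
        g = make_gene(strand="-", exon_lens=(100, 200, 150),
                      intron_lens=(200, 300))
        exons, _ = select_exons_introns([g])
        # middle exon is exon #2 from either end
        assert exons.iloc[0]["ordinal"] == 2


class TestFeatureMeanOccupancy:
    def test_zero_occupancy(self):
        feats = pd.DataFrame({"chrom": ["c"], "start": [10], "end": [20],
                              "strand": ["+"], "gene_id": ["g"],
                              "ordinal": [2]})
        Nz = {"c": np.zeros(100)}
        mean, se, _ = feature_mean_occupancy(feats, Nz)
        assert (mean, se) == (0.0, 0.0)

    def test_two_features_plus_minus_one(self):
        feats = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 50],
                              "end": [10, 60], "strand": ["+", "+"],
                              "gene_id": ["a", "b"], "ordinal": [2, 2]})
        Nz = {"c": np.concatenate([np.full(25, -1.0), np.full(75, 1.0)])}
        mean, se, per = feature_mean_occupancy(feats, Nz)
        assert mean == pytest.approx(0.0)
        assert se == pytest.approx(1.0)

    def test_matches_naive_loop_with_mask(self, rng):
        from nucleoform.profiles import FilterMask
        Nz = {"c": rng.normal(0, 1, 1000)}
        mask = FilterMask({"c": rng.random(1000) < 0.3})
        feats = pd.DataFrame({"chrom": "c", "start": [100, 400, 700],
                              "end": [200, 500, 800], "strand": "+",
                              "gene_id": list("abc"), "ordinal": 2})
        mean, se, per = feature_mean_occupancy(feats, Nz, mask)
        expect = [Nz["c"][s:e][~mask["c"][s:e]].mean()
                  for s, e in ((100, 200), (400, 500), (700, 800))]
        np.testing.assert_allclose(per, expect, atol=1e-12)


class TestGcTertiles:
    def test_equal_gc_splits_by_stable_order(self, uniform_genome):
        n = 9
        feats = pd.DataFrame({"chrom": "uA", "start": np.arange(n) * 1000,
                              "end": np.arange(n) * 1000 + 200, "strand": "+",
                              "gene_id": [f"g{i}" for i in range(n)],
                              "ordinal": 2})
        Nz = {"uA": np.zeros(30_000)}
        out = gc_tertile_profiles(feats, uniform_genome, Nz, "3end",
                                  max_offset=50)
        # 9 features split 3/3/3 by stable order; all are 200 bp long, so
        # each tertile contributes 3 features at offset 1
        sizes = [int(out[k]["n"].iloc[1]) for k in ("low", "mid", "high")]
        assert sizes == [3, 3, 3]

    def test_planted_gc_occupancy_coupling(self):
        r = np.random.default_rng(8)
        seqs, nz, rows = [], [], []
        pos = 0
        for i in range(30):
            gc = 0.2 + 0.6 * (i / 29)
            block = "".join(r.choice(list("ACGT"),
                                     p=[(1 - gc) / 2, gc / 2, gc / 2,
                                        (1 - gc) / 2], size=300))
            seqs.append(block)
            nz.append(np.full(300, gc * 10))  # occupancy rises with GC
            rows.append(("c", pos, pos + 300, "+", f"g{i}", 2))
            pos += 300
        g = GenomeAssembly({"c": "".join(seqs)})
        Nz = {"c": np.concatenate(nz)}
        feats = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                            "gene_id", "ordinal"])
        out = gc_tertile_profiles(feats, g, Nz, "3end", max_offset=100)
        assert np.nanmean(out["high"]["mean"]) > np.nanmean(out["low"]["mean"])

    def test_contributing_count_equals_length_condition(self):
        lengths = [80, 120, 160, 200, 240, 280]
        rows = []
        pos = 0
        for i, L in enumerate(lengths):
            rows.append(("c", pos, pos + L, "+", f"g{i}", 2))
            pos += L + 50
        g = GenomeAssembly({"c": "ACGT" * (pos // 4 + 100)})
        Nz = {"c": np.zeros(pos + 400)}
        feats = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                            "gene_id", "ordinal"])
        out = gc_tertile_profiles(feats, g, Nz, "3end", max_offset=250)
        total_n = sum(out[k]["n"] for k in out)
        for k, x in enumerate(out["low"]["offset"]):
            expect = sum(1 for L in lengths if L >= max(x, 1))
            assert total_n.iloc[k] == expect


DONOR = "CAGGTAAGTT"


def gene_with_consensus_sites(chrom_len=6000, strand="+"):
    """Three-exon gene whose donor windows carry the canonical consensus."""
    r = np.random.default_rng(77)
    seq = list("".join(r.choice(list("ACGT"), size=chrom_len)))
    g = make_gene(strand=strand, exon_lens=(150, 200, 150),
                  intron_lens=(300, 300), start=1000)
    from nucleoform.genome import reverse_complement
    for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
        if strand == "+":
            seq[e1 - 3:e1 + 7] = list(DONOR)
        else:
            seq[s2 - 7:s2 + 3] = list(reverse_complement(DONOR))
    return g, GenomeAssembly({"c": "".join(seq)})


class TestSplicePWM:
    def test_identical_sites_give_degenerate_pwm(self):
        g, genome = gene_with_consensus_sites()
        pwm = train_splice_pwm([g], genome, "donor", pseudocount=0.0)
        for i, base in enumerate(DONOR):
            assert pwm.probs[i, "ACGT".index(base)] == pytest.approx(1.0)

    def test_probabilities_sum_to_one_per_position(self):
        g, genome = gene_with_consensus_sites()
        pwm = train_splice_pwm([g], genome, "donor")
        np.testing.assert_allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_minus_strand_windows_reverse_complemented(self):
        gp, genome_p = gene_with_consensus_sites(strand="+")
        gm, genome_m = gene_with_consensus_sites(strand="-")
        pwm_p = train_splice_pwm([gp], genome_p, "donor", pseudocount=0.5)
        pwm_m = train_splice_pwm([gm], genome_m, "donor", pseudocount=0.5)
        # counts differ only through background composition, not alignment
        np.testing.assert_allclose(pwm_p.probs, pwm_m.probs, atol=1e-12)

    def test_uniform_background_gives_near_zero_scores(self, uniform_genome):
        pwm = SpliceSitePWM("donor", np.full((10, 4), 0.25),
                            np.full(4, 0.25))
        assert pwm.score("ACGTACGTAC") == pytest.approx(0.0, abs=1e-12)

    def test_consensus_maximizes_score(self):
        g, genome = gene_with_consensus_sites()
        pwm = train_splice_pwm([g], genome, "donor")
        s_consensus = pwm.score(DONOR)
        r = np.random.default_rng(4)
        for _ in range(20):
            other = "".join(r.choice(list("ACGT"), size=10))
            assert pwm.score(other) <= s_consensus + 1e-12

    def test_hand_computed_toy_score(self):
        probs = np.array([[0.7, 0.1, 0.1, 0.1],
                          [0.1, 0.6, 0.2, 0.1],
                          [0.25, 0.25, 0.25, 0.25]])
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        pwm = SpliceSitePWM("donor", probs, bg, exon_bases=1, intron_bases=2)
        expect = np.log(0.7 / 0.3) + np.log(0.2 / 0.2) + np.log(0.25 / 0.3)
        assert pwm.score("AGA") == pytest.approx(expect, abs=1e-12)

    def test_score_splice_sites_quantiles(self):
        r = np.random.default_rng(6)
        genes = []
        seq = list("".join(r.choice(list("ACGT"), size=120_000)))
        pos = 200
        for i in range(30):
            g = make_gene(gid=f"g{i}", exon_lens=(100, 200, 100),
                          intron_lens=(200, 200), start=pos)
            genes.append(g)
            pos = g.end + 300
        genome = GenomeAssembly({"c": "".join(seq)})
        pwm = train_splice_pwm(genes, genome, "donor")
        scores, strong, weak = score_splice_sites(pwm, genes, genome, 0.10)
        assert len(scores) == 60  # two donor junctions per 3-exon gene
        assert len(strong) == 6 and len(weak) == 6
        assert strong["score"].min() >= weak["score"].max()


class TestExpressionGroups:
    def test_zero_tag_genes_omitted(self):
        counts = {f"g{i}": float(i) for i in range(21)}  # g0 has zero tags
        strong, weak = expression_groups(counts, 0.10)
        assert "g0" not in strong + weak
        assert strong == ["g20", "g19"]
        assert weak == ["g1", "g2"]

    def test_group_sizes(self):
        counts = {f"g{i}": float(i + 1) for i in range(20)}
        strong, weak = expression_groups(counts, 0.10)
        assert len(strong) == 2 and len(weak) == 2

    def test_permutation_invariance_without_ties(self):
        counts = {f"g{i}": float(i + 1) for i in range(30)}
        items = list(counts.items())[::-1]
        s1, w1 = expression_groups(counts, 0.10)
        s2, w2 = expression_groups(dict(items), 0.10)
        assert set(s1) == set(s2) and set(w1) == set(w2)

    def test_too_few_genes_raises(self):
        with pytest.raises(ValueError):
            expression_groups({"a": 1.0, "b": 2.0}, 0.10)


class TestExonNumberProfile:
    def _exons(self, n_per_ordinal=25):
        rows = []
        pos = 0
        for ordinal in (2, 3, 4):
            for i in range(n_per_ordinal):
                rows.append(("c", pos, pos + 100, "+",
                             f"g{ordinal}_{i}", ordinal))
                pos += 150
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                           "gene_id", "ordinal"]), pos

    def test_constant_occupancy(self):
        exons, L = self._exons()
        Nz = {"c": np.full(L + 100, 1.5)}
        df = exon_number_profile(exons, Nz, min_exons=20)
        np.testing.assert_allclose(df["mean"], 1.5)
        assert list(df["ordinal"]) == [2, 3, 4]

    def test_ordinals_below_min_count_dropped(self):
        exons, L = self._exons(n_per_ordinal=10)
        Nz = {"c": np.zeros(L + 100)}
        df = exon_number_profile(exons, Nz, min_exons=20)
        assert len(df) == 0

    def test_counts_match_census(self):
        exons, L = self._exons(n_per_ordinal=30)
        Nz = {"c": np.zeros(L + 100)}
        df = exon_number_profile(exons, Nz, min_exons=20)
        assert (df["n"] == 30).all()


class TestIntervalGroupCompare:
    def _groups(self, shift=0.0, rng=None):
        rng = rng or np.random.default_rng(2)
        Nz = {"c": rng.normal(0, 1, 40_000)}
        rows_a, rows_b = [], []
        pos = 0
        for i in range(50):
            rows_a.append(("c", pos, pos + 100))
            pos += 150
            rows_b.append(("c", pos, pos + 100))
            pos += 150
        a = pd.DataFrame(rows_a, columns=["chrom", "start", "end"])
        b = pd.DataFrame(rows_b, columns=["chrom", "start", "end"])
        for s, e in zip(b["start"], b["end"]):
            Nz["c"][s:e] += shift
        return {"ga": a, "gb": b}, Nz

    def test_identical_groups_give_p_near_one(self):
        rng = np.random.default_rng(2)
        Nz = {"c": rng.normal(0, 1, 20_000)}
        rows = [("c", i * 200, i * 200 + 100) for i in range(50)]
        a = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        summary, pvals = interval_group_compare({"ga": a, "gb": a.copy()}, Nz)
        assert pvals[("ga", "gb")] == pytest.approx(1.0)

    def test_shifted_groups_highly_significant(self):
        groups, Nz = self._groups(shift=0.4)  # ~3 SD of the per-feature mean
        summary, pvals = interval_group_compare(groups, Nz)
        assert pvals[("ga", "gb")] < 1e-6

    def test_means_match_feature_mean_occupancy(self):
        groups, Nz = self._groups(shift=0.2)
        summary, _ = interval_group_compare(groups, Nz)
        for name, feats in groups.items():
            f = feats.copy()
            mean, se, _ = feature_mean_occupancy(f, Nz)
            row = summary[summary["group"] == name].iloc[0]
            assert row["mean"] == pytest.approx(mean)
            assert row["se"] == pytest.approx(se)

    def test_single_group_raises(self):
        groups, Nz = self._groups()
        with pytest.raises(ValueError):
            interval_group_compare({"ga": groups["ga"]}, Nz)
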