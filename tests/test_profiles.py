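"""Metagene binning, expression tertiles, group tests, repeat summaries."""

import numpy as np
import pandas as pd
import pytest

from oxbsdm.io import SiteCalls, ValidationError, genome_level
from oxbsdm.profiles import (
    compare_region_averages,
    emseq_region_tests,
    expression_classes,
    metagene_profile,
    region_averages,
    repeat_summary,
    sidak,
)


def _expr(counts: dict):
    genes = list(counts)
    if not genes:
        return pd.DataFrame({"gene_id": [], "r0": []})
    arr = np.array([counts[g] for g in genes])
    df = pd.DataFrame(arr, columns=[f"r{i}" for i in range(arr.shape[1])])
    df.insert(0, "gene_id", genes)
    return df


class TestExpressionClasses:
    def test_all_zero_is_unexpressed(self):
        ec = expression_classes(_expr({"g1": [0, 0, 0, 0], "g2": [5, 5, 5, 5],
                                       "g3": [1, 1, 1, 1], "g4": [9, 9, 9, 9]}))
        assert ec.unexpressed == ("g1",)

    def test_nine_genes_split_evenly(self):
        ec = expression_classes(_expr({f"g{i}": [i + 1] for i in range(9)}))
        assert (len(ec.high), len(ec.mid), len(ec.low)) == (3, 3, 3)

    def test_ten_genes_extra_goes_to_high(self):
        ec = expression_classes(_expr({f"g{i}": [i + 1] for i in range(10)}))
        assert (len(ec.high), len(ec.mid), len(ec.low)) == (4, 3, 3)
        assert "g9" in ec.high and "g0" in ec.low

    def test_ties_break_by_stable_gene_order(self):
        ec = expression_classes(_expr({"a": [5], "b": [5], "c": [5]}))
        assert ec.high == ("a",) and ec.mid == ("b",) and ec.low == ("c",)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            expression_classes(_expr({}))


def _uniform_calls(n=4000, span=200_000, level=0.5, cov=10, seed=0):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, span), size=n, replace=False))
    mod = np.full(n, int(cov * level))
    return SiteCalls.from_arrays(["chr1"] * n, pos, ["+"] * n, np.full(n, cov), mod, "CG")


class TestMetageneProfile:
    def test_constant_landscape_gives_flat_profile(self, simple_genes):
        calls = {"s": _uniform_calls(level=0.5)}
        prof = metagene_profile(calls, simple_genes)
        assert len(prof.df) == 67
        got = prof.df["s"].dropna()
        np.testing.assert_allclose(got, 0.5, atol=1e-12)
        assert list(prof.df["segment"]).count("body") == 27

    def test_strand_flip_oracle(self):
        """A minus-strand gene reads as the mirror image of its plus-strand twin."""
        span = 60_000
        plus = pd.DataFrame([dict(gene_id="p", chrom="chr1", strand="+", start=20_000, end=30_000)])
        minus = pd.DataFrame([dict(gene_id="m", chrom="chr1", strand="-", start=20_000, end=30_000)])
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(1, span), 3000, replace=False))
        cov = np.full(len(pos), 20)
        # modification gradient along the chromosome
        mod = np.round(cov * (pos / span)).astype(int)
        calls = {"s": SiteCalls.from_arrays(["chr1"] * len(pos), pos, ["+"] * len(pos), cov, mod, "CG")}
        # mirrored layout: sites reflected around the gene midpoint, so the
        # minus-strand gene sees the plus-strand landscape in 5'->3' order
        mirrored_pos = (20_000 + 30_000 + 1) - pos
        keep = (mirrored_pos >= 1) & (mirrored_pos <= span)
        order = np.argsort(mirrored_pos[keep])
        mp, mc, mm = mirrored_pos[keep][order], cov[keep][order], mod[keep][order]
        calls_mirror = {"s": SiteCalls.from_arrays(
            ["chr1"] * len(mp), mp, ["+"] * len(mp), mc, mm, "CG")}
        prof_plus = metagene_profile(calls, plus)
        prof_minus = metagene_profile(calls_mirror, minus)
        np.testing.assert_allclose(prof_plus.df["s"], prof_minus.df["s"], atol=1e-9)

    def test_planted_tss_dip_recovered(self, rng):
        genes = pd.DataFrame([dict(gene_id="g", chrom="chr1", strand="+", start=10_000, end=20_000)])
        pos = np.arange(1, 30_000, 7)
        cov = np.full(len(pos), 30)
        level = np.where((pos - 1 >= 9_500) & (pos - 1 < 10_500), 0.10, 0.80)
        mod = rng.binomial(cov, level)
        calls = {"s": SiteCalls.from_arrays(["chr1"] * len(pos), pos, ["+"] * len(pos), cov, mod, "CG")}
        prof = metagene_profile(calls, genes).df
        dip_bins = prof[(prof["bin"] >= 19) & (prof["bin"] <= 22)]["s"]
        flat_bins = prof[prof["bin"] <= 10]["s"]
        assert dip_bins.min() < 0.45 < flat_bins.min()

    def test_short_genes_dropped_with_count(self, simple_genes):
        tiny = pd.concat([simple_genes, pd.DataFrame([dict(
            gene_id="tiny", chrom="chr1", strand="+", start=500, end=510,
            exon_starts=[500], exon_ends=[510], cds_start=500, cds_end=510)])])
        prof = metagene_profile({"s": _uniform_calls()}, tiny)
        assert prof.n_dropped == 1 and prof.n_genes == 2

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValidationError):
            metagene_profile({"s": _uniform_calls()}, pd.DataFrame(columns=["start", "end"]))


class TestRegionAverages:
    def test_constant_landscape_equal_regions(self, simple_genes):
        ra = region_averages({"s": _uniform_calls(level=0.4)}, simple_genes)
        np.testing.assert_allclose(ra["level"], 0.4, atol=1e-12)

    def test_body_elevation_detected(self, rng):
        genes = pd.DataFrame([dict(gene_id="g", chrom="chr1", strand="+", start=10_000, end=20_000)])
        pos = np.arange(1, 30_000, 5)
        cov = np.full(len(pos), 20)
        level = np.where((pos - 1 >= 10_000) & (pos - 1 < 20_000), 0.8, 0.3)
        calls = {"s": SiteCalls.from_arrays(["chr1"] * len(pos), pos, ["+"] * len(pos),
                                            cov, rng.binomial(cov, level), "CG")}
        ra = region_averages(calls, genes).set_index("region")["level"]
        assert ra["body"] > ra["upstream"] and ra["body"] > ra["downstream"]

    def test_conservation_against_genome_level(self):
        """Coverage-weighted combination of region means equals the pooled level."""
        genes = pd.DataFrame([dict(gene_id="g", chrom="chr1", strand="+", start=4_000, end=8_000)])
        calls = _uniform_calls(n=1000, span=12_000, level=0.5, seed=2)
        ra = region_averages({"s": calls}, genes)
        union_cov = ra["coverage"].sum()
        weighted = (ra["level"] * ra["coverage"]).sum() / union_cov
        # region intervals [0,4k),[4k,8k),[8k,12k) cover every site exactly once
        assert weighted == pytest.approx(genome_level(calls))


class TestCompareRegionAverages:
    def _df(self, shift=0.0, sd=0.0, n=4, rng=None):
        rows = []
        for region in ("upstream", "body", "downstream"):
            for i in range(n):
                base = 0.5 if rng is None else 0.5 + rng.normal(0, sd)
                rows.append(dict(group="input", pair=i, region=region, level=base))
                noise = 0.0 if rng is None else rng.normal(0, sd)
                rows.append(dict(group="positive", pair=i, region=region, level=base + shift + noise))
        return pd.DataFrame(rows)

    def test_identical_groups_paired_p_is_one(self):
        res = compare_region_averages(self._df(), design="paired")
        assert (res["p"] == 1.0).all()

    def test_unbalanced_pairing_rejected(self):
        df = self._df().drop(index=[0])
        with pytest.raises(ValidationError):
            compare_region_averages(df, design="paired")

    def test_power_with_known_shift(self):
        rng = np.random.default_rng(42)
        rejected = 0
        for _ in range(200):
            df = self._df(shift=0.05, sd=0.01, rng=rng)
            res = compare_region_averages(df, design="paired")
            rejected += int((res["p"] < 0.05).all())
        assert rejected / 200 >= 0.99

    def test_multi_group_sidak_matches_closed_form(self):
        rng = np.random.default_rng(3)
        rows = []
        for g, mu in (("neuron", 0.4), ("astro", 0.5), ("micro", 0.6)):
            for region in ("upstream", "body"):
                for i in range(4):
                    rows.append(dict(group=g, pair=i, region=region,
                                     level=mu + rng.normal(0, 0.02)))
        res = compare_region_averages(pd.DataFrame(rows), design="multi")
        m = len(res)
        np.testing.assert_allclose(res["p_sidak"], 1 - (1 - res["p"]) ** m)

    def test_sidak_closed_form(self):
        assert sidak(0.01, 5) == pytest.approx(1 - 0.99**5)


class TestRepeatSummary:
    def _calls(self, level_in, level_out, frac=0.5, n=10_000, seed=0):
        rng = np.random.default_rng(seed)
        span = 1_000_000
        cut = int(span * frac)
        pos = np.sort(rng.choice(np.arange(1, span), n, replace=False))
        cov = np.full(n, 20)
        level = np.where(pos - 1 < cut, level_in, level_out)
        calls = SiteCalls.from_arrays(["chr1"] * n, pos, ["+"] * n, cov,
                                      rng.binomial(cov, level), "CG")
        repeats = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [cut],
                                "repeat_class": ["LINE"]})
        return calls, repeats

    def test_no_repeats(self, make_calls):
        calls = make_calls([(10, 10, 5)])
        res = repeat_summary({"s": calls}, pd.DataFrame(columns=["chrom", "start", "end", "repeat_class"]))
        res = res.set_index("category")["level"]
        assert np.isnan(res["repeat"])
        assert res["non_repeat"] == res["whole_genome"]

    def test_repeats_cover_everything(self, make_calls):
        calls = make_calls([(10, 10, 5), (20, 10, 7)])
        repeats = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100],
                                "repeat_class": ["SINE"]})
        res = repeat_summary({"s": calls}, repeats).set_index("category")["level"]
        assert res["repeat"] == res["whole_genome"]

    def test_mixture_arithmetic(self):
        calls, repeats = self._calls(0.85, 0.70)
        res = repeat_summary({"s": calls}, repeats).set_index("category")["level"]
        assert res["whole_genome"] == pytest.approx(0.775, abs=0.01)
        assert res["repeat"] == pytest.approx(0.85, abs=0.01)
        assert res["non_repeat"] == pytest.approx(0.70, abs=0.01)
        assert res["LINE"] == pytest.approx(res["repeat"])

    def test_unknown_class_warns_and_groups(self, make_calls):
        calls = make_calls([(10, 10, 5)])
        repeats = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100],
                                "repeat_class": ["Satellite"]})
        with pytest.warns(UserWarning, match="Satellite"):
            res = repeat_summary({"s": calls}, repeats)
        assert "Other" in set(res["category"])


class TestEmseqRegionTests:
    def _levels(self, diff_positions=(), diff=0.0, sd=0.0, n_rep=3, n_pos=20, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for ct in ("neuron", "microglia"):
            for rep in range(n_rep):
                for pos in range(n_pos):
                    base = 0.4 + (diff if ct == "neuron" and pos in diff_positions else 0.0)
                    rows.append(dict(cell_type=ct, replicate=rep, pos=pos,
                                     level=base + rng.normal(0, sd)))
        return pd.DataFrame(rows)

    def test_identical_profiles_nothing_significant(self):
        res = emseq_region_tests(self._levels(sd=0.0), ("neuron", "microglia"))
        assert res.region_p == 1.0
        assert (res.per_cpg["p_sidak"] > 0.05).all()

    def test_planted_positions_flagged(self):
        hits, total, fps = 0, 0, 0
        for seed in range(30):
            res = emseq_region_tests(
                self._levels(diff_positions=(3, 9, 15), diff=0.30, sd=0.05, seed=seed),
                ("neuron", "microglia"))
            sig = set(res.per_cpg[res.per_cpg["p_sidak"] < 0.05]["pos"])
            hits += len(sig & {3, 9, 15})
            total += 3
            fps += len(sig - {3, 9, 15})
        assert hits / total >= 0.9
        assert fps <= 4  # Sidak keeps the family-wise error near 5% per region

    def test_too_few_common_positions_skips_per_cpg(self):
        df = self._levels(n_pos=1, sd=0.01, seed=1)
        res = emseq_region_tests(df, ("neuron", "microglia"))
        assert res.per_cpg is None and "common positions" in res.note

    def test_replicate_requirement(self):
        df = self._levels(n_rep=1)
        with pytest.raises(ValidationError):
            emseq_region_tests(df, ("neuron", "microglia"))
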