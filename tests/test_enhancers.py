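import numpy as np
import pandas as pd
import pytest

from groseqtools.enhancers import (
    SiteRecord,
    categorize_sites,
    consensus_sites,
    erna_quantify,
    stranded_sites,
    tss_distance_histogram,
)
from groseqtools.genome_io import GeneModel, ReadSet, StrandedInterval

I = StrandedInterval


def brute_force_consensus(peak_sets, min_support):
    """Independent O(n^2) union-merge + support scan."""
    pooled = sorted(
        [(p.chrom, p.start, p.end) for peaks in peak_sets for p in peaks]
    )
    merged = []
    for c, s, e in pooled:
        if merged and merged[-1][0] == c and s <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([c, s, e])
    out = []
    for c, s, e in merged:
        support = sum(
            any(p.chrom == c and p.start < e and s < p.end for p in peaks)
            for peaks in peak_sets
        )
        if support >= min_support:
            out.append((c, s, e, support))
    return out


class TestConsensus:
    def test_support_threshold(self):
        site = I("chr1", 100, 200)
        other = I("chr2", 500, 600)
        sets5 = [[site]] * 5 + [[other]] * 2
        kept = consensus_sites(sets5, min_support=5)
        assert [(s.site.start, s.support) for s in kept] == [(100, 5)]
        sets4 = [[site]] * 4 + [[other]] * 3
        assert all(s.site.chrom != "chr1"
                   for s in consensus_sites(sets4, min_support=5))

    def test_identical_sets_full_support(self):
        out = consensus_sites([[I("chr1", 10, 20)]] * 7, min_support=5)
        assert len(out) == 1 and out[0].support == 7

    def test_overlap_bookkeeping(self):
        out = consensus_sites(
            [[I("chr1", 100, 200)], [I("chr1", 150, 250)]], min_support=2
        )
        assert [(s.site.start, s.site.end, s.support) for s in out] == [(100, 250, 2)]

    def test_min_support_one_is_union_merge(self):
        rng = np.random.default_rng(0)
        sets = [
            [I("chr1", int(s), int(s) + 80) for s in rng.integers(0, 5000, 30)]
            for _ in range(4)
        ]
        from groseqtools.genome_io import merge_intervals

        out = consensus_sites(sets, min_support=1)
        assert [s.site for s in out] == merge_intervals(
            [p for ps in sets for p in ps]
        )

    def test_monotone_in_support(self):
        rng = np.random.default_rng(1)
        sets = [
            [I("chr1", int(s), int(s) + 100) for s in rng.integers(0, 20_000, 40)]
            for _ in range(7)
        ]
        sizes = [len(consensus_sites(sets, min_support=m)) for m in range(1, 8)]
        assert sizes == sorted(sizes, reverse=True)

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(2)
        sets = [
            [
                I("chr1", int(s), int(s) + int(w))
                for s, w in zip(
                    rng.integers(0, 100_000, 140), rng.integers(50, 400, 140)
                )
            ]
            for _ in range(7)
        ]
        got = consensus_sites(sets, min_support=4)
        expected = brute_force_consensus(sets, 4)
        assert [
            (s.site.chrom, s.site.start, s.site.end, s.support) for s in got
        ] == expected


class TestStrandedSites:
    def test_two_copies_per_site_before_filtering(self):
        sites = [SiteRecord(I("chr1", i * 1000, i * 1000 + 200), 5)
                 for i in range(10)]
        records, n_before = stranded_sites(sites, [])
        assert n_before == 20 and len(records) == 20

    def test_genic_same_strand_copy_dropped(self):
        sites = [SiteRecord(I("chr1", 5_000, 5_500), 5)]
        genes = [GeneModel("g", I("chr1", 1_000, 9_000, "+"))]
        records, n_before = stranded_sites(sites, genes)
        assert n_before == 2
        assert [r.interval.strand for r in records] == ["-"]

    def test_empty_input(self):
        records, n_before = stranded_sites([], [])
        assert records == [] and n_before == 0


class TestCategorize:
    def _genes(self):
        return [
            GeneModel("target", I("chr1", 100_000, 120_000, "+")),
            GeneModel("other", I("chr1", 300_000, 320_000, "+")),
        ]

    def test_distal_beyond_radius(self):
        sites = [SiteRecord(I("chr1", 150_000, 150_600), 5)]
        categorize_sites(sites, self._genes(), {"target"})
        assert sites[0].category == "distal"
        assert sites[0].distance_to_nearest_gene == 30_000

    def test_target_precedence(self):
        # non-target 5 kb away, target 10 kb away: target wins
        genes = [
            GeneModel("target", I("chr1", 100_000, 120_000, "+")),
            GeneModel("other", I("chr1", 135_000, 140_000, "+")),
        ]
        sites = [SiteRecord(I("chr1", 129_500, 130_000), 5)]
        categorize_sites(sites, genes, {"target"})
        assert sites[0].category == "proximal_target"

    def test_site_inside_target(self):
        sites = [SiteRecord(I("chr1", 110_000, 110_600), 5)]
        categorize_sites(sites, self._genes(), {"target"})
        assert sites[0].category == "proximal_target"
        assert sites[0].distance_to_nearest_target == 0

    def test_proximal_non_target(self):
        sites = [SiteRecord(I("chr1", 290_000, 290_600), 5)]
        categorize_sites(sites, self._genes(), {"target"})
        assert sites[0].category == "proximal_non_target"

    def test_empty_annotation_warns_all_distal(self):
        sites = [SiteRecord(I("chr1", 0, 600), 5)]
        with pytest.warns(UserWarning):
            categorize_sites(sites, [], set())
        assert sites[0].category == "distal"

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        genes = [
            GeneModel(
                f"g{i}", I("chr1", int(s), int(s) + 5_000, "+")
            )
            for i, s in enumerate(np.cumsum(rng.integers(10_000, 80_000, 400)))
        ]
        targets = {g.name for g in genes[::5]}
        sites = [
            SiteRecord(I("chr1", int(s), int(s) + 500), 5)
            for s in rng.integers(0, genes[-1].interval.end + 100_000, 400)
        ]
        categorize_sites(sites, genes, targets, radius=25_000)
        gs = np.array([g.interval.start for g in genes])
        ge = np.array([g.interval.end for g in genes])
        is_t = np.array([g.name in targets for g in genes])
        for rec in sites:
            d = np.maximum(
                0, np.maximum(gs - rec.site.end, rec.site.start - ge)
            )
            assert rec.distance_to_nearest_gene == d.min()
            if d.min() > 25_000:
                expect = "distal"
            elif d[is_t].min() <= 25_000:
                expect = "proximal_target"
            else:
                expect = "proximal_non_target"
            assert rec.category == expect


class TestErnaQuantify:
    def _fixture(self):
        site = SiteRecord(I("chr1", 10_000, 10_600), 5)
        records, _ = stranded_sites([site], [])
        plus = [I("chr1", 10_100, 10_150, "+")] * 20
        minus = [I("chr1", 10_200, 10_250, "-")] * 5
        treated = ReadSet(plus + minus, total_mapped=1_000_000,
                          genome_length=50_000_000)
        control = ReadSet(minus, total_mapped=1_000_000,
                          genome_length=50_000_000)
        return records, {"control": control, "treated": treated}

    def test_counts_fpkm_and_activity(self):
        records, samples = self._fixture()
        rec_t, site_t, _ = erna_quantify(records, samples)
        treated_plus = rec_t[(rec_t["sample"] == "treated")
                             & (rec_t["strand"] == "+")]
        assert treated_plus["count"].item() == 20
        # lambda = 0.03 * 1e6 * 600 / 5e7 = 0.36; 20 reads is far beyond
        assert treated_plus["active"].item()
        site_treated = site_t[(site_t["site"] == 0)
                              & (site_t["sample"] == "treated")]
        assert site_treated["active"].item()

    def test_site_inactive_when_both_strands_inactive(self):
        records, samples = self._fixture()
        empty = ReadSet([], total_mapped=1_000_000, genome_length=50_000_000)
        rec_t, site_t, _ = erna_quantify(records, {"null": empty})
        assert not site_t["active"].any()

    def test_zero_read_records_excluded_from_fold_changes(self):
        records, samples = self._fixture()
        _, _, fc = erna_quantify(
            records, samples, comparisons={"t_vs_c": ("control", "treated")}
        )
        # plus-strand record has 0 reads in control: excluded; minus strand
        # has 5 vs 5 at equal depth/length -> fold 1
        table = fc["t_vs_c"]
        assert len(table) == 1
        assert table["fold_change"].item() == pytest.approx(1.0)

    def test_fold_change_ratio_arithmetic(self):
        site = SiteRecord(I("chr1", 0, 600), 5)
        records, _ = stranded_sites([site], [])
        mk = lambda n: ReadSet(
            [I("chr1", 100, 150, "+")] * n + [I("chr1", 100, 150, "-")],
            total_mapped=1_000_000, genome_length=50_000_000,
        )
        _, _, fc = erna_quantify(
            records, {"a": mk(5), "b": mk(20)},
            comparisons={"b_vs_a": ("a", "b")},
        )
        plus = fc["b_vs_a"]["fold_change"].iloc[0]
        assert plus == pytest.approx(4.0)

    def test_preactivated_contrast_on_synthetic_data(self, standard_dataset):
        ds = standard_dataset
        sites = consensus_sites(ds.peaks, min_support=5)
        truth = ds.truth.gene_truth
        targets = set(truth.index[truth["induced"]])
        categorize_sites(sites, ds.annotation, targets)
        records, _ = stranded_sites(sites, ds.annotation)
        rec_t, _, _ = erna_quantify(records, ds.samples)
        cat = pd.Series({i: s.category for i, s in enumerate(sites)})
        active_by_rec = rec_t.groupby("record")["active"].any()
        site_of_rec = pd.Series({i: r.site_index for i, r in enumerate(records)})
        df = pd.DataFrame(
            {"active": active_by_rec, "cat": site_of_rec.map(cat)}
        )
        frac = df.groupby("cat")["active"].mean()
        assert frac["proximal_target"] > frac["distal"]


class TestTssHistogram:
    def _sites(self, positions):
        return [SiteRecord(I("chr1", p - 50, p + 50), 5) for p in positions]

    def test_signed_distance_binning_plus(self):
        genes = [GeneModel("g", I("chr1", 10_000, 20_000, "+"))]
        hist = tss_distance_histogram(genes, self._sites([9_500]))
        row = hist[(hist["bin_left"] == -1000) & (hist["bin_right"] == 0)]
        assert row["count"].item() == 1
        assert hist["count"].sum() == 1

    def test_strand_reflection(self):
        genes = [GeneModel("g", I("chr1", 2_000, 10_001, "-"))]
        # TSS at 10,000; site midpoint 9,500 is downstream for a minus gene
        hist = tss_distance_histogram(genes, self._sites([9_500]))
        row = hist[(hist["bin_left"] == 0) & (hist["bin_right"] == 1000)]
        assert row["count"].item() == 1

    def test_bin_layout(self):
        genes = [GeneModel("g", I("chr1", 100_000, 110_000, "+"))]
        hist = tss_distance_histogram(genes, self._sites([50_000]))
        assert len(hist) == 70  # 10 outer + 50 inner + 10 outer
        outer = hist.iloc[0]
        assert outer["bin_right"] - outer["bin_left"] == 5_000
        inner = hist.iloc[35]
        assert inner["bin_right"] - inner["bin_left"] == 1_000
        # -50 kb falls in a left outer bin
        row = hist[(hist["bin_left"] == -50_000)]
        assert row["count"].item() == 1

    def test_mass_conservation_within_span(self):
        rng = np.random.default_rng(4)
        genes = [
            GeneModel(f"g{i}", I("chr1", int(p), int(p) + 5_000, "+"))
            for i, p in enumerate(rng.integers(100_000, 5_000_000, 50))
        ]
        sites = self._sites(rng.integers(1_000, 5_200_000, 80))
        hist = tss_distance_histogram(genes, sites)
        n_within = 0
        for g in genes:
            best = min(
                abs((s.site.start + s.site.end) / 2 - g.tss) for s in sites
            )
            if best <= 75_000:
                n_within += 1
        # histogram mass equals genes whose nearest site is within +/- 75 kb
        # (up to boundary-exact ties, absent in this random fixture)
        assert hist["count"].sum() == n_within

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError):
            tss_distance_histogram([], [])
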