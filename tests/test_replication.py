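"""Replication-timing profiles, early/late segmentation and boundary
geometry."""

import numpy as np
import pandas as pd
import pytest

from readthru import (
    CoverageTrack,
    SimulationConfig,
    distance_to_boundary,
    exclude_chromosomes,
    peaks_in_late,
    readthrough_direction,
    region_coverage,
    replication_domains,
    rt_profile,
    segment_rt,
    simulate_genome,
    simulate_repliseq,
)
from readthru.replication import ReplicationSegments

from conftest import make_gene


def track(bins, bin_size=10_000, lib=1_000_000):
    return CoverageTrack(bin_size, {"chr1": np.asarray(bins, dtype=float)}, lib)


def segments(*segs, min_len=100_000):
    return ReplicationSegments({"chr1": list(segs)}, min_len)


class TestRtProfile:
    def test_equal_tracks_give_zero_rt(self):
        e = track(np.full(100, 8.0))
        l = track(np.full(100, 8.0))
        rt = rt_profile(e, l)
        assert np.allclose(rt.rt["chr1"], 0.0)

    def test_fourfold_enrichment_approaches_log2_four(self):
        e = track(np.full(100, 400.0))
        l = track(np.full(100, 100.0))
        rt = rt_profile(e, l, epsilon=1e-9)
        assert np.allclose(rt.rt["chr1"], 2.0, atol=1e-6)

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(0)
        e = track(rng.poisson(20, 200))
        l = track(rng.poisson(10, 200))
        a = rt_profile(e, l).rt["chr1"]
        b = rt_profile(l, e).rt["chr1"]
        assert np.allclose(a, -b)

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ValueError, match="binning"):
            rt_profile(track(np.ones(10), bin_size=10_000),
                       track(np.ones(10), bin_size=5_000))

    def test_synthetic_domains_separate_in_rt(self):
        for seed in (1, 2, 3):
            cfg = SimulationConfig(n_genes=20, n_chroms=1, chrom_length=20_000_000,
                                   seed=seed)
            _, _, truth = simulate_genome(cfg)
            E, L = simulate_repliseq(truth, cfg, "DMSO")
            rt = rt_profile(E, L)
            domains = replication_domains(cfg)
            bs = cfg.repli_bin_size
            early = np.zeros(len(rt.rt["chr1"]), dtype=bool)
            for s, e, lab in domains["chr1"]:
                if lab == "early":
                    early[s // bs: e // bs] = True
            assert rt.rt["chr1"][early].mean() > 0 > rt.rt["chr1"][~early].mean()


class TestSegmentation:
    def test_single_sign_change_single_boundary(self):
        rt = rt_profile(track(np.r_[np.full(50, 40.0), np.full(50, 10.0)]),
                        track(np.r_[np.full(50, 10.0), np.full(50, 40.0)]),
                        smoothing_bp=10_000)
        segs = segment_rt(rt, min_segment_length=100_000)
        assert segs.segments["chr1"] == [(0, 500_000, "early"), (500_000, 1_000_000, "late")]

    def test_short_flip_absorbed(self):
        e = np.full(100, 40.0)
        e[60] = 1.0  # one-bin dip inside a long early run
        rt = rt_profile(track(e), track(np.full(100, 10.0)), smoothing_bp=10_000)
        segs = segment_rt(rt, min_segment_length=50_000)
        assert segs.segments["chr1"] == [(0, 1_000_000, "early")]

    def test_alternating_labels_tile_territory(self):
        cfg = SimulationConfig(n_genes=20, n_chroms=1, chrom_length=20_000_000, seed=4)
        _, _, truth = simulate_genome(cfg)
        E, L = simulate_repliseq(truth, cfg, "DMSO")
        segs = segment_rt(rt_profile(E, L))
        s = segs.segments["chr1"]
        assert s[0][0] == 0
        for (s1, e1, l1), (s2, e2, l2) in zip(s, s[1:]):
            assert e1 == s2 and l1 != l2

    def test_boundary_recovery_within_two_bins(self):
        tot = found = 0
        for seed in (1, 2, 3):
            cfg = SimulationConfig(n_genes=20, n_chroms=1, chrom_length=20_000_000,
                                   seed=seed)
            _, _, truth = simulate_genome(cfg)
            E, L = simulate_repliseq(truth, cfg, "DMSO")
            segs = segment_rt(rt_profile(E, L))
            domains = replication_domains(cfg)
            called = segs.boundaries("chr1")
            for b in [e for _, e, _ in domains["chr1"][:-1]]:
                tot += 1
                if any(abs(c - b) <= 2 * cfg.repli_bin_size for c in called):
                    found += 1
        assert tot >= 20
        assert found / tot >= 0.9


class TestRegionCoverage:
    SEGS = segments((0, 500_000, "early"), (500_000, 1_000_000, "late"))

    def test_cpm_invariant_to_depth_doubling(self):
        bins = np.r_[np.full(50, 30.0), np.full(50, 5.0)]
        a = region_coverage(track(bins, lib=1_000_000), self.SEGS, "early")
        b = region_coverage(track(2 * bins, lib=2_000_000), self.SEGS, "early")
        assert np.allclose(a["cpm"], b["cpm"])

    def test_empty_region_list(self):
        segs = segments((0, 1_000_000, "early"))
        out = region_coverage(track(np.ones(100)), segs, "late")
        assert out.empty

    def test_late_rescue_ratio_recovered(self):
        cfg = SimulationConfig(n_genes=20, n_chroms=1, chrom_length=20_000_000, seed=5)
        _, _, truth = simulate_genome(cfg)
        E0, L0 = simulate_repliseq(truth, cfg, "DMSO")
        segs = segment_rt(rt_profile(E0, L0))
        _, L_sn = simulate_repliseq(truth, cfg, "SN38")      # factor 0.5, rescue 1.0
        _, L_cmb = simulate_repliseq(truth, cfg, "SN38+JQ1")  # factor 0.5, rescue 1.5
        a = region_coverage(L_sn, segs, "late")["cpm"].sum()
        b = region_coverage(L_cmb, segs, "late")["cpm"].sum()
        # CPM renormalizes totals, so compare raw late-region count ratios
        raw_a = sum(L_sn.region_sum_cpm(c, s, e) * L_sn.library_size / 1e6
                    for c, segs_ in segs.segments.items() for s, e, lab in segs_
                    if lab == "late")
        raw_b = sum(L_cmb.region_sum_cpm(c, s, e) * L_cmb.library_size / 1e6
                    for c, segs_ in segs.segments.items() for s, e, lab in segs_
                    if lab == "late")
        assert raw_b / raw_a == pytest.approx(1.5, rel=0.05)


class TestBoundaryDistance:
    SEGS = segments((0, 250_000, "early"), (250_000, 600_000, "late"),
                    (600_000, 900_000, "early"), (900_000, 1_000_000, "late"))

    def test_plus_strand(self):
        g = make_gene("A", start=50_000, end=100_001)  # TES 100,000 in early
        assert distance_to_boundary(g, self.SEGS) == 150_000

    def test_minus_strand_measures_leftward(self):
        g = make_gene("A", start=700_000, end=800_000, strand="-")  # TES 700,000
        # traveling left, the early segment (600k,900k) ends at 600k into late
        assert distance_to_boundary(g, self.SEGS) == 100_000

    def test_tes_not_in_early_excluded(self):
        g = make_gene("A", start=300_000, end=400_000)
        assert distance_to_boundary(g, self.SEGS) is None

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(9)
        labs = ["early", "late"] * 5
        edges = np.sort(rng.choice(np.arange(1, 100), 9, replace=False)) * 10_000
        segs_list = []
        prev = 0
        for i, e in enumerate(list(edges) + [1_000_000]):
            segs_list.append((prev, int(e), labs[i]))
            prev = int(e)
        segs = segments(*segs_list)
        for _ in range(50):
            start = int(rng.integers(0, 900_000))
            strand = "+" if rng.random() < 0.5 else "-"
            g = make_gene("A", start=start, end=start + 50_000, strand=strand)
            got = distance_to_boundary(g, segs)
            # oracle: walk bp-wise-ish over segment edges
            tes = g.tes
            lab = segs.label_at("chr1", tes)
            if lab != "early":
                assert got is None
                continue
            expect = None
            if strand == "+":
                for (s1, e1, l1), (s2, e2, l2) in zip(segs_list, segs_list[1:]):
                    if e1 > tes and l1 == "early" and l2 == "late":
                        expect = e1 - tes
                        break
            else:
                for (s1, e1, l1), (s2, e2, l2) in zip(segs_list, segs_list[1:]):
                    if s2 <= tes and l2 == "early" and l1 == "late":
                        expect = tes - s2
            assert got == (float(expect) if expect is not None else None) or \
                (got is None and expect is None)

    def test_planted_near_boundary_dogs_are_closer(self):
        """DoGs planted just upstream of early-to-late borders sit closer to
        the called boundary than other early-region genes."""
        cfg = SimulationConfig(n_genes=200, n_chroms=2, chrom_length=25_000_000,
                               dog_near_boundary=True, seed=21)
        genes, _, truth = simulate_genome(cfg)
        E, L = simulate_repliseq(truth, cfg, "DMSO")
        segs = segment_rt(rt_profile(E, L))
        by_id = {g.gene_id: g for g in genes}
        d_dog, d_ctrl = [], []
        for row in truth.itertuples():
            d = distance_to_boundary(by_id[row.gene_id], segs)
            if d is None:
                continue
            (d_dog if row.is_dog else d_ctrl).append(d)
        assert len(d_dog) >= 20 and len(d_ctrl) >= 20
        assert np.median(d_dog) < np.median(d_ctrl)


class TestDirectionAndPeaks:
    SEGS = segments((0, 500_000, "early"), (500_000, 1_000_000, "late"))

    def test_early_to_late(self):
        g = make_gene("A", start=300_000, end=450_001)
        assert readthrough_direction(g, 100_000, self.SEGS) == "early→late"

    def test_within_early(self):
        g = make_gene("A", start=100_000, end=200_001)
        assert readthrough_direction(g, 50_000, self.SEGS) == "within-early"

    def test_matches_label_lookup(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            start = int(rng.integers(0, 800_000))
            g = make_gene("A", start=start, end=start + 20_000,
                          strand="+" if rng.random() < 0.5 else "-")
            dog_len = int(rng.integers(10_000, 300_000))
            got = readthrough_direction(g, dog_len, self.SEGS)
            a = self.SEGS.label_at("chr1", g.tes)
            end_pos = g.tes + dog_len if g.strand == "+" else g.tes - dog_len
            end_pos = min(max(end_pos, 0), 999_999)
            b = self.SEGS.label_at("chr1", end_pos)
            assert got == (f"within-{a}" if a == b else f"{a}→{b}")

    def test_peaks_in_late_rules(self):
        segs = self.SEGS
        inside = ("chr1", 600_000, 610_000)
        early_only = ("chr1", 100_000, 110_000)
        one_bp = ("chr1", 499_999, 500_001)
        count, bp = peaks_in_late([inside, early_only, one_bp], segs)
        assert count == 2
        assert bp == 10_000 + 1


class TestExcludeChromosomes:
    def test_gene_list(self):
        genes = [make_gene("A", chrom="chr1"), make_gene("B", chrom="chr3")]
        out = exclude_chromosomes(genes, ["chr3"])
        assert [g.gene_id for g in out] == ["A"]

    def test_dataframe_and_identity_and_idempotence(self):
        df = pd.DataFrame({"chrom": ["chr1", "chr3", "chr1"], "x": [1, 2, 3]})
        assert exclude_chromosomes(df, []).equals(df)
        once = exclude_chromosomes(df, ["chr3"])
        twice = exclude_chromosomes(once, ["chr3"])
        assert once.equals(twice)
        assert set(once["chrom"]) == {"chr1"}

    def test_missing_name_warns(self):
        with pytest.warns(UserWarning, match="not present"):
            exclude_chromosomes([make_gene("A")], ["chrX"])
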