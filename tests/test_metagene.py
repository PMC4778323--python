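"""Metagene binning: geometry, brute-force oracle, aggregation, summaries."""

import numpy as np
import pytest

from crypticscan import (
    BinningConfig,
    ClassQuery,
    GeneModel,
    GeneProfile,
    GeneSet,
    MetageneProfile,
    RatioTrack,
    aggregate_metagene,
    aggregate_ratio_of_means,
    bin_gene,
    metagene_by_class,
    summarize_profile,
)

from conftest import constant_ratio


def _track(chrom_sizes, arrays):
    data = {}
    for c, n in chrom_sizes.items():
        plus, minus = arrays.get(c, (np.ones(n), np.ones(n)))
        data[c] = {"+": np.asarray(plus, float), "-": np.asarray(minus, float)}
    return RatioTrack(data=data, pseudocount=0.01)


def brute_force_bins(gene, track, cfg):
    """Independent per-base reference: loop over bases, average per bin.

    Walks the gene frame base by base: flank windows of ``unit_bp`` bases
    outward from the anchors, body bin of base k (of L) = k*body_units//L.
    """
    L = gene.length
    tss, pa = gene.anchors
    step = 1 if gene.strand == "+" else -1
    chrom_len = len(track.values(gene.chrom, "+"))
    out = {}
    for orientation in ("sense", "antisense"):
        if orientation == "sense":
            strand = gene.strand
        else:
            strand = "-" if gene.strand == "+" else "+"
        arr = track.values(gene.chrom, strand)
        bins = []
        for b in range(cfg.n_bins):
            vals = []
            if b < cfg.flank_units:
                # upstream flank, most upstream first
                offset = -(cfg.flank_units - b) * cfg.unit_bp
                for k in range(cfg.unit_bp):
                    pos = tss + step * (offset + k) - (0 if gene.strand == "+" else 1)
                    if 0 <= pos < chrom_len:
                        vals.append(arr[pos])
            elif b < cfg.flank_units + cfg.body_units:
                bb = b - cfg.flank_units
                for k in range(L):
                    if k * cfg.body_units // L == bb:
                        pos = tss + step * k - (0 if gene.strand == "+" else 1)
                        vals.append(arr[pos])
            else:
                offset = (b - cfg.flank_units - cfg.body_units) * cfg.unit_bp
                for k in range(cfg.unit_bp):
                    pos = pa + step * (offset + k) - (0 if gene.strand == "+" else 1)
                    if 0 <= pos < chrom_len:
                        vals.append(arr[pos])
            bins.append(sum(vals) / len(vals) if vals else np.nan)
        out[orientation] = np.array(bins)
    return out


class TestBinGeometry:
    def test_constant_field_gives_constant_bins(self, chrom_sizes):
        track = constant_ratio(chrom_sizes, 1.0)
        g = GeneModel("g", "chrI", 2000, 3000, "+")
        prof = bin_gene(g, track, BinningConfig())
        assert np.allclose(prof.sense, 1.0)
        assert np.allclose(prof.antisense, 1.0)

    def test_default_window_coordinates(self, chrom_sizes):
        """Bin 0 = [1600,1620), body bin 20 = [2000,2050), bin 59 = [3380,3400)
        for a 1-kb plus-strand gene at [2000,3000) under 20 bp/unit geometry."""
        n = chrom_sizes["chrI"]
        for lo, hi, bin_idx in [(1600, 1620, 0), (2000, 2050, 20), (3380, 3400, 59)]:
            plus = np.ones(n)
            plus[lo:hi] = 9.0
            track = _track(chrom_sizes, {"chrI": (plus, np.ones(n))})
            prof = bin_gene(GeneModel("g", "chrI", 2000, 3000, "+"), track, BinningConfig())
            assert prof.sense[bin_idx] == pytest.approx(9.0)
            others = np.delete(prof.sense, bin_idx)
            assert np.allclose(others, 1.0)

    def test_minus_strand_signal_on_plus_is_antisense(self, chrom_sizes):
        n = chrom_sizes["chrI"]
        plus = np.full(n, 5.0)
        minus = np.ones(n)
        track = _track(chrom_sizes, {"chrI": (plus, minus)})
        prof = bin_gene(GeneModel("g", "chrI", 3000, 4000, "-"), track, BinningConfig())
        assert np.allclose(prof.antisense, 5.0)
        assert np.allclose(prof.sense, 1.0)

    def test_short_body_excluded_with_reason(self, chrom_sizes):
        track = constant_ratio(chrom_sizes)
        prof = bin_gene(GeneModel("g", "chrI", 2000, 2050, "+"), track, BinningConfig())
        assert not prof.included
        assert "min_body_bp" in prof.reason

    def test_clipped_flank_bins_are_nan_not_zero(self, chrom_sizes):
        track = constant_ratio(chrom_sizes, 2.0)
        prof = bin_gene(GeneModel("g", "chrI", 100, 400, "+"), track, BinningConfig())
        # upstream flank needs 400 bp but only 100 exist: 15 bins fully missing
        assert np.isnan(prof.sense[:15]).all()
        assert np.allclose(prof.sense[15:], 2.0)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_brute_force_oracle(self, strand):
        rng = np.random.default_rng(11)
        sizes = {"chrI": 6000}
        track = _track(sizes, {"chrI": (rng.uniform(0.1, 3, 6000), rng.uniform(0.1, 3, 6000))})
        cfg = BinningConfig()
        for length in (60, 61, 137, 999, 1000, 2717):
            g = GeneModel("g", "chrI", 2000, 2000 + length, strand)
            prof = bin_gene(g, track, cfg)
            expect = brute_force_bins(g, track, cfg)
            np.testing.assert_allclose(prof.sense, expect["sense"], atol=1e-9)
            np.testing.assert_allclose(prof.antisense, expect["antisense"], atol=1e-9)

    def test_mirror_symmetry_bitwise(self):
        rng = np.random.default_rng(5)
        sizes = {"chrI": 5000}
        track = _track(sizes, {"chrI": (rng.uniform(0.1, 3, 5000), rng.uniform(0.1, 3, 5000))})
        cfg = BinningConfig()
        for strand in ("+", "-"):
            g = GeneModel("g", "chrI", 1500, 2750, strand)
            gs = GeneSet(genes=[g], chrom_sizes=sizes)
            (gm,) = gs.mirrored().genes
            prof = bin_gene(g, track, cfg)
            prof_m = bin_gene(gm, track.mirrored(), cfg)
            np.testing.assert_array_equal(prof.sense, prof_m.sense)
            np.testing.assert_array_equal(prof.antisense, prof_m.antisense)


class TestAggregate:
    def _profile(self, gene_id, sense):
        arr = np.asarray(sense, float)
        return GeneProfile(gene_id, arr, arr.copy())

    def test_identical_profiles_zero_stderr(self):
        p = np.linspace(1, 2, 60)
        sense, anti = aggregate_metagene([self._profile("a", p), self._profile("b", p)], "c")
        np.testing.assert_allclose(sense.bins, p)
        assert np.all(sense.stderr == 0)
        assert sense.n_genes == 2

    def test_all_unit_profiles_stay_unit_for_both_methods(self, chrom_sizes):
        track = constant_ratio(chrom_sizes, 1.0)
        sig_profiles = [self._profile(g, np.ones(60)) for g in "abc"]
        sense, _ = aggregate_metagene(sig_profiles, "c")
        assert np.allclose(sense.bins, 1.0)
        sense2, _ = aggregate_ratio_of_means(sig_profiles, sig_profiles, "c", pseudocount=0.01)
        assert np.allclose(sense2.bins, 1.0)

    def test_mean_of_ratios_hand_arithmetic(self):
        """Bin-0 values {1,2,3}: mean 2.0, stderr = SD/sqrt(3) = 0.577."""
        profiles = [self._profile(g, [v] + [1.0] * 59) for g, v in zip("abc", (1.0, 2.0, 3.0))]
        sense, _ = aggregate_metagene(profiles, "c")
        assert sense.bins[0] == pytest.approx(2.0)
        assert sense.stderr[0] == pytest.approx(1.0 / np.sqrt(3), abs=1e-3)

    def test_missing_flank_bins_excluded_from_mean(self):
        a = self._profile("a", [np.nan] + [2.0] * 59)
        b = self._profile("b", [4.0] + [2.0] * 59)
        sense, _ = aggregate_metagene([a, b], "c")
        assert sense.bins[0] == pytest.approx(4.0)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError, match="nothing"):
            aggregate_metagene([], "nothing")


class TestMetageneByClass:
    def test_class_partition_conserved(self, chrom_sizes, small_genes):
        track = constant_ratio(chrom_sizes)
        classes = [
            ClassQuery("coding", biotype="coding"),
            ClassQuery("TATA", biotype="coding", promoter_class="TATA"),
            ClassQuery("TATA-like", biotype="coding", promoter_class="TATA-like"),
        ]
        res = metagene_by_class(small_genes, track, BinningConfig(), classes)
        n = {p.class_label: p.n_genes for p in res.profiles}
        assert n["TATA"] + n["TATA-like"] == n["coding"]

    def test_empty_query_errors(self, chrom_sizes, small_genes):
        track = constant_ratio(chrom_sizes)
        with pytest.raises(ValueError, match="empty"):
            metagene_by_class(
                small_genes, track, BinningConfig(),
                [ClassQuery("empty", biotype="CUT", promoter_class="TATA")],
            )

    def test_exclusions_itemized(self, chrom_sizes):
        genes = GeneSet(
            genes=[
                GeneModel("ok", "chrI", 1000, 2000, "+"),
                GeneModel("tiny", "chrI", 3000, 3030, "+"),
            ],
            chrom_sizes=chrom_sizes,
        )
        track = constant_ratio(chrom_sizes)
        res = metagene_by_class(genes, track, BinningConfig(), [ClassQuery("coding", biotype="coding")])
        assert res.get("coding", "sense").n_genes == 1
        assert [gid for gid, _ in res.exclusions["coding"]] == ["tiny"]


class TestSummarize:
    def _metagene(self, bins, label="c", orientation="sense"):
        arr = np.asarray(bins, float)
        return MetageneProfile(label, orientation, arr, np.zeros_like(arr), 10)

    def test_flat_profile(self):
        s = summarize_profile(self._metagene(np.ones(60)), self._metagene(np.ones(60), orientation="antisense"))
        assert s.peak5_height == pytest.approx(1.0)
        assert s.peak3_height == pytest.approx(1.0)
        assert s.body_sense_mean == pytest.approx(1.0)
        assert s.antisense_body_mean == pytest.approx(1.0)

    def test_single_bin_peak_is_argmax(self):
        bins = np.ones(60)
        bins[15] = 3.0
        s = summarize_profile(self._metagene(bins))
        assert s.peak5_bin == 15
        assert s.peak5_height == pytest.approx(3.0)

    def test_plateau_peak_reports_centre(self):
        bins = np.ones(60)
        bins[12:18] = 4.0  # flat-topped boxcar
        bins[50] = 2.0
        s = summarize_profile(self._metagene(bins))
        assert s.peak5_bin == 14  # centre of 12..17
        assert s.peak3_bin == 50
        assert s.peak3_height == pytest.approx(2.0)

    def test_body_means_use_body_bins_only(self):
        bins = np.ones(60)
        bins[20:40] = 1.5
        s = summarize_profile(self._metagene(bins), self._metagene(2.5 * np.ones(60), orientation="antisense"))
        assert s.body_sense_mean == pytest.approx(1.5)
        assert s.antisense_body_mean == pytest.approx(2.5)
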