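"""Synthetic genome and track generator: determinism, construction, noise."""

import numpy as np
import pytest
from scipy import stats

from crypticscan import (
    BinningConfig,
    ClassQuery,
    EffectConfig,
    SimConfig,
    generate_annotation,
    metagene_by_class,
    noise_free_tracks,
    ratio_track,
    read_strand_signal,
    simulate_macroarray,
    simulate_tracks,
    write_fixture_bundle,
)
from crypticscan.annotation import read_chrom_sizes, read_gene_annotations


SMALL = SimConfig(n_genes=120, n_chroms=2, seed=7)


class TestGenerateAnnotation:
    def test_seed_determinism(self):
        a = generate_annotation(SMALL)
        b = generate_annotation(SMALL)
        assert a.genes == b.genes
        assert a.chrom_sizes == b.chrom_sizes

    def test_no_tata_when_fraction_zero(self):
        cfg = SimConfig(n_genes=100, n_chroms=1, frac_TATA=0.0, seed=1)
        genes = generate_annotation(cfg)
        assert not genes.select(promoter_class="TATA")

    def test_tata_count_within_binomial_band(self):
        cfg = SimConfig(n_genes=2000, frac_TATA=0.18, seed=42)
        genes = generate_annotation(cfg)
        n_tata = len(genes.select(biotype="coding", promoter_class="TATA"))
        lo, hi = stats.binom.ppf([0.005, 0.995], 2000, 0.18)
        assert lo <= n_tata <= hi

    def test_canonical_genes_do_not_overlap(self):
        genes = generate_annotation(SMALL)
        coding = genes.select(biotype="coding")
        by_chrom = {}
        for g in coding:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_strands_alternate(self):
        genes = generate_annotation(SMALL)
        strands = [g.strand for g in genes.select(biotype="coding")]
        assert strands[:4] == ["+", "-", "+", "-"]

    def test_dubious_orfs_overlap_three_prime_flanks(self):
        genes = generate_annotation(SimConfig(n_genes=300, n_chroms=1, seed=3))
        coding = genes.select(biotype="coding")
        for dub in genes.select(biotype="dubious_orf"):
            # each dubious ORF starts just downstream of some host pA
            hosts = [
                g for g in coding
                if g.chrom == dub.chrom and g.strand == dub.strand
                and (
                    (g.strand == "+" and dub.start == g.end + 10)
                    or (g.strand == "-" and dub.end == g.start - 10)
                )
            ]
            assert len(hosts) == 1

    def test_fixed_chrom_len_too_small_errors(self):
        with pytest.raises(ValueError, match="chrom_len"):
            generate_annotation(SimConfig(n_genes=500, n_chroms=1, chrom_len=10_000, seed=0))


class TestSimulateTracks:
    def test_null_noiseless_mutant_equals_wildtype(self):
        cfg = SimConfig(n_genes=60, n_chroms=1, noise_cv=0.0, n_reps=2, seed=2)
        genes = generate_annotation(cfg)
        wt, mut = simulate_tracks(genes, cfg, EffectConfig.preset("null"))
        for w, m in zip(wt, mut):
            for c in w.data:
                np.testing.assert_array_equal(w.values(c, "+"), m.values(c, "+"))
                np.testing.assert_array_equal(w.values(c, "-"), m.values(c, "-"))

    def test_boxcar_ratio_exact_inside_window(self):
        """amp=3 boxcar upstream of the TSS: mutant/WT ratio exactly 4 inside,
        1 elsewhere on the sense strand of an isolated flank."""
        cfg = SimConfig(n_genes=40, n_chroms=1, noise_cv=0.0, n_reps=1, seed=9,
                        frac_SUT=0.0, frac_CUT=0.0, frac_dubious=0.0,
                        intergenic_len_median=2000.0, intergenic_len_sigma=0.0)
        genes = generate_annotation(cfg)
        eff = EffectConfig(sense5_amp=3.0, sense5_center_bp=100, sense5_width_bp=150)
        (wt,), (mut,) = simulate_tracks(genes, cfg, eff)
        g = genes.select(biotype="coding")[2]
        assert g.strand == "+"
        tss = g.start
        ratio = mut.values(g.chrom, "+") / wt.values(g.chrom, "+")
        np.testing.assert_allclose(ratio[tss - 175 : tss - 25], 4.0, rtol=1e-12)
        np.testing.assert_allclose(ratio[tss - 24 : tss], 1.0, rtol=1e-12)
        np.testing.assert_allclose(ratio[tss : g.end], 1.0, rtol=1e-12)

    def test_antisense_body_elevation_through_profiler(self):
        """bur6-like antisense amplitude 1.5 over a 0.2 background: noise-free
        metagene antisense body bins = 2.5, sense body = 1."""
        cfg = SimConfig(n_genes=60, n_chroms=1, noise_cv=0.0, n_reps=1, seed=4,
                        frac_SUT=0.0, frac_CUT=0.0, frac_dubious=0.0,
                        intergenic_len_median=2000.0, intergenic_len_sigma=0.0)
        genes = generate_annotation(cfg)
        eff = EffectConfig(antisense_body_amp=1.5)
        (wt,), (mut,) = simulate_tracks(genes, cfg, eff)
        ratios = ratio_track(mut, wt, pseudocount=1e-9)
        res = metagene_by_class(genes, ratios, BinningConfig(), [ClassQuery("coding", biotype="coding")])
        body = BinningConfig().body_slice
        np.testing.assert_allclose(res.get("coding", "antisense").bins[body], 2.5, rtol=1e-6)
        np.testing.assert_allclose(res.get("coding", "sense").bins[body], 1.0, rtol=1e-9)

    def test_replicate_noise_mean_converges_to_truth(self):
        """Log-normal noise has E=1, so averaging many replicates recovers the
        noise-free track."""
        cfg = SimConfig(n_genes=10, n_chroms=1, noise_cv=0.3, n_reps=200, seed=11)
        genes = generate_annotation(cfg)
        eff = EffectConfig.preset("ydr1-like")
        wt_reps, _ = simulate_tracks(genes, cfg, eff)
        wt0, _ = noise_free_tracks(genes, cfg, eff)
        c = next(iter(wt0.data))
        avg = np.mean([r.values(c, "+") for r in wt_reps], axis=0)
        rel = avg / wt0.values(c, "+") - 1.0
        assert abs(rel.mean()) < 0.01
        assert np.percentile(np.abs(rel), 99) < 0.1

    def test_tata_body_upregulation(self):
        cfg = SimConfig(n_genes=200, n_chroms=1, noise_cv=0.0, n_reps=1, seed=5)
        genes = generate_annotation(cfg)
        eff = EffectConfig(tata_body_sense_amp=0.5)
        (wt,), (mut,) = simulate_tracks(genes, cfg, eff)
        g = genes.select(promoter_class="TATA")[0]
        ratio = mut.values(g.chrom, g.strand)[g.start : g.end] / wt.values(g.chrom, g.strand)[g.start : g.end]
        np.testing.assert_allclose(ratio, 1.5, rtol=1e-12)


class TestMacroarray:
    def test_deterministic_and_unbiased_under_null(self):
        cfg = SimConfig(n_genes=300, n_chroms=1, seed=6, orf_noise_cv=0.15)
        genes = generate_annotation(cfg)
        a = simulate_macroarray(genes, cfg, EffectConfig.preset("null"))
        b = simulate_macroarray(genes, cfg, EffectConfig.preset("null"))
        assert a.equals(b)
        # E[noise]=1: replicate-averaged means hover around the truth
        assert np.median(a["mut_mean"] / a["wt_mean"]) == pytest.approx(1.0, abs=0.05)

    def test_flank_peaks_raise_dubious_orf_signal(self):
        cfg = SimConfig(n_genes=300, n_chroms=1, seed=8, orf_noise_cv=0.0)
        genes = generate_annotation(cfg)
        df = simulate_macroarray(genes, cfg, EffectConfig.preset("bur6-like"))
        df = df.set_index("gene_id")
        dub = [g.gene_id for g in genes.select(biotype="dubious_orf")]
        coding = [g.gene_id for g in genes.select(biotype="coding")]
        dub_ratio = (df.loc[dub, "mut_mean"] / df.loc[dub, "wt_mean"]).median()
        coding_ratio = (df.loc[coding, "mut_mean"] / df.loc[coding, "wt_mean"]).median()
        assert dub_ratio > 2.0 > coding_ratio


class TestFixtureBundle:
    def test_file_census_and_round_trip(self, tmp_path):
        cfg = SimConfig(n_genes=30, n_chroms=1, n_reps=3, seed=12)
        genes = generate_annotation(cfg)
        wt, mut = simulate_tracks(genes, cfg, EffectConfig.preset("null"))
        manifest = write_fixture_bundle(genes, wt, mut, tmp_path / "fx", cfg=cfg)
        bedgraphs = [f for f in manifest["files"] if f.endswith(".bedgraph")]
        assert len(bedgraphs) == 12  # 2 strands x 3 reps x 2 strains
        sizes = read_chrom_sizes(tmp_path / "fx" / "chrom.sizes")
        back = read_gene_annotations(tmp_path / "fx" / "annotations.bed", "BED6", sizes)
        assert len(back) == len(genes)
        sig = read_strand_signal(
            tmp_path / "fx" / "wt_rep2.plus.bedgraph",
            tmp_path / "fx" / "wt_rep2.minus.bedgraph",
            sizes,
        )
        c = next(iter(sizes))
        np.testing.assert_allclose(sig.values(c, "+"), wt[1].values(c, "+"), atol=1e-9)

    def test_same_seed_same_manifest(self, tmp_path):
        cfg = SimConfig(n_genes=25, n_chroms=1, n_reps=1, seed=13)
        genes = generate_annotation(cfg)
        wt, mut = simulate_tracks(genes, cfg, EffectConfig.preset("null"))
        m1 = write_fixture_bundle(genes, wt, mut, tmp_path / "a", cfg=cfg)
        m2 = write_fixture_bundle(genes, wt, mut, tmp_path / "b", cfg=cfg)
        assert m1["files"] == m2["files"]
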