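#!/usr/bin/env python
"""Write a demonstration fixture bundle of the synthetic study design.

Generates a small noise-free genome (300 coding genes plus SUTs, CUTs and
3'-flank dubious ORFs) under the bur6-like phenotype and writes the full
file bundle the pipeline readers consume — BED6 annotation, class-label
TSV, chromosome sizes, per-strand bedGraphs for 3 replicates of each
strain, and a checksummed manifest — plus a ready-to-run run_config.yaml.

Noise-free tracks run-length-encode to small bedGraphs and have exactly
the model's expected ratios, which makes the bundle convenient for genome-
browser inspection; the quantitative analyses (02, 03) simulate the full
noisy study conditions in memory instead.
"""

from pathlib import Path

from crypticscan import EffectConfig, SimConfig, generate_annotation, simulate_tracks, write_fixture_bundle
from crypticscan.cli import RunConfig, SignalPair

OUT = Path(__file__).resolve().parent.parent / "results" / "fixture_bur6"


def main() -> None:
    cfg = SimConfig(n_genes=300, n_chroms=2, noise_cv=0.0, n_reps=3, seed=42)
    effects = EffectConfig.preset("bur6-like")
    genes = generate_annotation(cfg)
    wt, mut = simulate_tracks(genes, cfg, effects)
    manifest = write_fixture_bundle(genes, wt, mut, OUT, cfg=cfg, effects=effects)
    config = RunConfig(
        annotations=str(OUT / "annotations.bed"),
        labels=str(OUT / "labels.tsv"),
        chrom_sizes=str(OUT / "chrom.sizes"),
        wildtype=[SignalPair(plus=str(OUT / s["plus"]), minus=str(OUT / s["minus"]))
                  for s in manifest["samples"]["wt"]],
        mutant=[SignalPair(plus=str(OUT / s["plus"]), minus=str(OUT / s["minus"]))
                for s in manifest["samples"]["mut"]],
    )
    config.to_yaml(OUT / "run_config.yaml")

    census = genes.class_census()
    print(f"wrote fixture bundle to {OUT}")
    print(f"{len(genes)} features on {len(genes.chrom_sizes)} chromosomes:")
    print(census.to_string(index=False))
    print(f"\nanalyse it with:  crypticscan run-all --config {OUT / 'run_config.yaml'} "
          f"--outdir {OUT.parent / 'fixture_bur6_out'}")


if __name__ == "__main__":
    main()
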