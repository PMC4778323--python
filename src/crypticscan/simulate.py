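"""Synthetic yeast-like genomes and stranded WT/mutant signal tracks.

The generator emulates the statistical structure a tiling/macroarray study
of cryptic transcription rests on, so the whole pipeline runs with no
downloads:

* non-overlapping canonical genes on alternating strands, log-normal gene
  and intergenic lengths; SUTs/CUTs tucked into intergenic gaps; dubious
  ORFs overlapping the 3' flank of canonical genes (where run-through
  cryptic transcripts land on their probes);
* ~18% of coding promoters carry a TATA box, the rest are TATA-like;
* wild-type sense signal = per-gene log-normal expression over [TSS, pA)
  on top of a uniform background; ncRNAs are expressed at a reduced scale;
* the mutant adds cryptic-transcription effects: sense boxcar peaks in the
  5' and 3' nucleosome-free flank regions, a uniform antisense elevation
  over the body, and an optional sense up-regulation of TATA genes;
* three replicates per strain with multiplicative log-normal noise
  (E[noise] = 1): per base for the tiling-track model, per ORF feature for
  the spotted-macroarray model.

Boxcar peaks (not Gaussians) keep every expected bin value analytically
exact, so recovery tests have closed-form truth. One integer seed drives
separate, fixed-order substreams for annotation, expression and noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GeneSet, write_bed6, write_chrom_sizes, write_class_labels
from .signal import STRANDS, StrandSignal, write_strand_signal

PRESETS = ("null", "ydr1-like", "bur6-like")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the synthetic genome and arrays.

    Lengths are log-normal, parameterized by median (bp) and sigma (log
    scale). Fractions of the ncRNA/dubious classes are relative to
    ``n_genes`` canonical genes and follow the census of the yeast
    annotation (847 SUTs and 925 CUTs per 5423 mapped genes; 431 dubious
    per 5803 array ORFs). ``noise_cv`` is the per-base multiplicative
    coefficient of variation of a tiling replicate; ``orf_noise_cv`` the
    per-feature CV of a spotted macroarray replicate.
    """

    n_genes: int = 2000
    n_chroms: int = 4
    gene_len_median: float = 1200.0
    gene_len_sigma: float = 0.65
    intergenic_len_median: float = 400.0
    intergenic_len_sigma: float = 0.6
    nc_len_median: float = 450.0
    nc_len_sigma: float = 0.5
    dubious_len_median: float = 200.0
    dubious_len_sigma: float = 0.3
    frac_TATA: float = 0.18
    frac_SUT: float = 0.156
    frac_CUT: float = 0.171
    frac_dubious: float = 0.074
    base_expr_median: float = 1.0
    base_expr_sigma: float = 0.8
    nc_expr_scale: float = 0.3
    background: float = 0.2
    noise_cv: float = 0.2
    orf_noise_cv: float = 0.2
    n_reps: int = 3
    seed: int = 0
    chrom_len: int | None = None

    def __post_init__(self) -> None:
        for name in ("frac_TATA", "frac_SUT", "frac_CUT", "frac_dubious"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_SUT + self.frac_CUT + self.frac_dubious > 1.0:
            raise ValueError("biotype fractions sum to more than 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_genes < 1 or self.n_chroms < 1:
            raise ValueError("n_genes and n_chroms must be positive")


@dataclass(frozen=True)
class EffectConfig:
    """Injectable cryptic-transcription effects of the mutant.

    Amplitudes are in background units: a 5' boxcar of amplitude a adds
    ``a * background`` to the sense strand over a window of
    ``sense5_width_bp`` centred ``sense5_center_bp`` upstream of the TSS,
    giving a noise-free mutant/WT flank ratio of exactly ``1 + a``; the 3'
    boxcar is symmetric around the pA site. ``antisense_body_amp`` raises
    the opposite strand uniformly over [TSS, pA); ``tata_body_sense_amp``
    multiplies the mutant sense body of TATA genes by ``1 + amp``.
    ``flank_biotypes`` / ``antisense_biotypes`` restrict which gene classes
    receive each effect.
    """

    sense5_amp: float = 0.0
    sense5_center_bp: int = 100
    sense5_width_bp: int = 150
    sense3_amp: float = 0.0
    sense3_center_bp: int = 100
    sense3_width_bp: int = 150
    antisense_body_amp: float = 0.0
    tata_body_sense_amp: float = 0.0
    flank_biotypes: tuple[str, ...] = ("coding", "SUT", "CUT")
    antisense_biotypes: tuple[str, ...] = ("coding", "SUT")

    def __post_init__(self) -> None:
        for name in ("sense5_amp", "sense3_amp", "antisense_body_amp", "tata_body_sense_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sense5_width_bp", "sense3_width_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def preset(cls, name: str) -> "EffectConfig":
        """Named phenotypes.

        ``null`` — no effect. ``ydr1-like`` — flank peaks (3' > 5'), modest
        antisense, and sense up-regulation of TATA-gene bodies.
        ``bur6-like`` — stronger flank peaks and a strong intragenic
        antisense elevation, no TATA-specific body effect.
        """
        if name == "null":
            return cls()
        if name == "ydr1-like":
            return cls(sense5_amp=3.0, sense3_amp=4.0, antisense_body_amp=0.5,
                       tata_body_sense_amp=0.5)
        if name == "bur6-like":
            return cls(sense5_amp=4.0, sense3_amp=6.0, antisense_body_amp=1.5,
                       tata_body_sense_amp=0.0)
        raise ValueError(f"unknown preset {name!r} (expected one of {PRESETS})")


def _lognormal(rng: np.random.Generator, median: float, sigma: float, n: int) -> np.ndarray:
    return median * np.exp(sigma * rng.standard_normal(n))


# ---------------------------------------------------------------------------
# annotation generation

_EDGE_MARGIN = 500  # room for flank windows and 3'-flank dubious ORFs


def generate_annotation(cfg: SimConfig) -> GeneSet:
    """Sample a synthetic annotated genome; deterministic given cfg.seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    lens = np.maximum(90, _lognormal(rng, cfg.gene_len_median, cfg.gene_len_sigma, cfg.n_genes)).astype(int)
    gaps = np.maximum(60, _lognormal(rng, cfg.intergenic_len_median, cfg.intergenic_len_sigma, cfg.n_genes)).astype(int)

    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1

    genes: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    gap_records: list[tuple[str, int, int]] = []  # (chrom, gap_start, gap_end)
    gi = 0
    for ci, n_here in enumerate(per_chrom):
        chrom = f"chr{ci + 1:02d}"
        cursor = _EDGE_MARGIN
        for _ in range(n_here):
            gap_start = cursor
            cursor += gaps[gi]
            gap_records.append((chrom, gap_start, cursor))
            strand = "+" if gi % 2 == 0 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi + 1:05d}",
                    chrom=chrom,
                    start=cursor,
                    end=cursor + int(lens[gi]),
                    strand=strand,
                    biotype="coding",
                )
            )
            cursor += int(lens[gi])
            gi += 1
        size = cursor + _EDGE_MARGIN
        if cfg.chrom_len is not None:
            if size > cfg.chrom_len:
                raise ValueError(
                    f"{chrom}: placed genes need {size} bp but chrom_len={cfg.chrom_len}; "
                    "increase chrom_len or reduce n_genes per chromosome"
                )
            size = cfg.chrom_len
        chrom_sizes[chrom] = size

    # promoter classes for coding genes
    tata = rng.random(cfg.n_genes) < cfg.frac_TATA
    genes = [
        replace(g, promoter_class="TATA" if tata[i] else "TATA-like")
        for i, g in enumerate(genes)
    ]

    # ncRNAs in intergenic gaps (20 bp margins from neighbouring genes)
    nc_genes: list[GeneModel] = []
    order = rng.permutation(len(gap_records))
    targets = [("sut", "SUT", round(cfg.frac_SUT * cfg.n_genes)),
               ("cut", "CUT", round(cfg.frac_CUT * cfg.n_genes))]
    cursor_i = 0
    for prefix, biotype, n_target in targets:
        placed = 0
        while placed < n_target and cursor_i < len(order):
            chrom, gs, ge = gap_records[order[cursor_i]]
            cursor_i += 1
            room = ge - gs - 40
            if room < 80:
                continue
            length = int(min(max(80, _lognormal(rng, cfg.nc_len_median, cfg.nc_len_sigma, 1)[0]), room))
            offset = int(rng.integers(0, room - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            placed += 1
            nc_genes.append(
                GeneModel(
                    gene_id=f"{prefix}{placed:05d}",
                    chrom=chrom,
                    start=gs + 20 + offset,
                    end=gs + 20 + offset + length,
                    strand=strand,
                    biotype=biotype,
                )
            )

    # dubious ORFs overlapping 3' flanks of randomly chosen canonical genes
    n_dub = round(cfg.frac_dubious * cfg.n_genes)
    hosts = rng.choice(cfg.n_genes, size=min(n_dub, cfg.n_genes), replace=False)
    dub_genes: list[GeneModel] = []
    for k, hi in enumerate(sorted(hosts)):
        host = genes[hi]
        length = int(max(90, _lognormal(rng, cfg.dubious_len_median, cfg.dubious_len_sigma, 1)[0]))
        _tss, pa = host.anchors
        if host.strand == "+":
            start, end = pa + 10, pa + 10 + length
        else:
            start, end = pa - 10 - length, pa - 10
        start = max(0, start)
        end = min(chrom_sizes[host.chrom], end)
        dub_genes.append(
            GeneModel(
                gene_id=f"dub{k + 1:05d}",
                chrom=host.chrom,
                start=start,
                end=end,
                strand=host.strand,
                biotype="dubious_orf",
            )
        )

    return GeneSet(genes=genes + nc_genes + dub_genes, chrom_sizes=chrom_sizes)


# ---------------------------------------------------------------------------
# signal synthesis


def _sample_expression(genes: GeneSet, cfg: SimConfig) -> dict[str, float]:
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    expr: dict[str, float] = {}
    for g in genes:
        level = float(_lognormal(rng, cfg.base_expr_median, cfg.base_expr_sigma, 1)[0])
        if g.biotype in ("SUT", "CUT"):
            level *= cfg.nc_expr_scale
        elif g.biotype == "dubious_orf":
            level = 0.0  # dubious ORFs are array features, not transcripts
        expr[g.gene_id] = level
    return expr


def _add_boxcar(arr: np.ndarray, center: int, width: int, value: float) -> None:
    start = max(0, center - width // 2)
    end = min(len(arr), center + (width - width // 2))
    if start < end:
        arr[start:end] += value


def noise_free_tracks(
    genes: GeneSet, cfg: SimConfig, effects: EffectConfig
) -> tuple[StrandSignal, StrandSignal]:
    """Expected (noise-free) WT and mutant tracks under the effect model."""
    expr = _sample_expression(genes, cfg)
    wt = {
        c: {s: np.full(size, cfg.background) for s in STRANDS}
        for c, size in genes.chrom_sizes.items()
    }
    for g in genes:
        if expr[g.gene_id] > 0:
            wt[g.chrom][g.strand][g.start : g.end] += expr[g.gene_id]
    mut = {c: {s: arr.copy() for s, arr in strands.items()} for c, strands in wt.items()}

    bg = cfg.background
    for g in genes:
        tss, pa = g.anchors
        sense = mut[g.chrom][g.strand]
        anti = mut[g.chrom]["-" if g.strand == "+" else "+"]
        direction = 1 if g.strand == "+" else -1
        if g.biotype in effects.flank_biotypes:
            if effects.sense5_amp > 0:
                _add_boxcar(sense, tss - direction * effects.sense5_center_bp,
                            effects.sense5_width_bp, effects.sense5_amp * bg)
            if effects.sense3_amp > 0:
                _add_boxcar(sense, pa + direction * effects.sense3_center_bp,
                            effects.sense3_width_bp, effects.sense3_amp * bg)
        if g.biotype in effects.antisense_biotypes and effects.antisense_body_amp > 0:
            anti[g.start : g.end] += effects.antisense_body_amp * bg
        if (
            g.biotype == "coding"
            and g.promoter_class == "TATA"
            and effects.tata_body_sense_amp > 0
        ):
            sense[g.start : g.end] *= 1.0 + effects.tata_body_sense_amp

    return (
        StrandSignal(data=wt, sample_id="wt"),
        StrandSignal(data=mut, sample_id="mut"),
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with E = 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(sigma * rng.standard_normal(shape) - 0.5 * sigma * sigma)


def simulate_tracks(
    genes: GeneSet, cfg: SimConfig, effects: EffectConfig
) -> tuple[list[StrandSignal], list[StrandSignal]]:
    """Tiling-style replicate tracks: per-base multiplicative noise.

    Returns ``(wt_replicates, mut_replicates)``, ``cfg.n_reps`` each,
    deterministic given ``cfg.seed``.
    """
    wt0, mut0 = noise_free_tracks(genes, cfg, effects)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2]))
    wt_reps, mut_reps = [], []
    for sample_id, base, sink in (("wt", wt0, wt_reps), ("mut", mut0, mut_reps)):
        for rep in range(1, cfg.n_reps + 1):
            data = {
                c: {
                    s: base.values(c, s) * _lognormal_noise(rng, cfg.noise_cv, len(base.values(c, s)))
                    for s in STRANDS
                }
                for c in sorted(base.data)
            }
            sink.append(StrandSignal(data=data, sample_id=sample_id, replicate=rep))
    return wt_reps, mut_reps


def simulate_macroarray(
    genes: GeneSet,
    cfg: SimConfig,
    effects: EffectConfig,
    biotypes: Sequence[str] = ("coding", "dubious_orf"),
) -> pd.DataFrame:
    """Spotted ORF-array emulation: one feature per ORF, per-feature noise.

    Each ORF's true abundance is the mean of the noise-free track over its
    span on its own strand; each replicate multiplies it by log-normal noise
    with CV ``cfg.orf_noise_cv`` (E = 1), replicates are then averaged.
    Returns a frame with ``gene_id``, ``wt_mean``, ``mut_mean``.
    """
    wt0, mut0 = noise_free_tracks(genes, cfg, effects)
    selected = [g for g in genes if g.biotype in biotypes]
    truth = np.empty((2, len(selected)))
    for j, g in enumerate(selected):
        truth[0, j] = np.mean(wt0.values(g.chrom, g.strand)[g.start : g.end])
        truth[1, j] = np.mean(mut0.values(g.chrom, g.strand)[g.start : g.end])
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 3]))
    noise = _lognormal_noise(rng, cfg.orf_noise_cv, (2, cfg.n_reps, len(selected)))
    means = (truth[:, None, :] * noise).mean(axis=1)
    return pd.DataFrame(
        {"gene_id": [g.gene_id for g in selected], "wt_mean": means[0], "mut_mean": means[1]}
    )


# ---------------------------------------------------------------------------
# fixture bundles


def write_fixture_bundle(
    genes: GeneSet,
    wt_reps: Sequence[StrandSignal],
    mut_reps: Sequence[StrandSignal],
    outdir: str | Path,
    cfg: SimConfig | None = None,
    effects: EffectConfig | None = None,
) -> dict:
    """Write the full file bundle the pipeline readers consume.

    BED6 annotation + label TSV + chrom sizes + per-strand bedGraphs per
    strain/replicate + a manifest JSON with configs and SHA-256 checksums.
    Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed6(genes, outdir / "annotations.bed")
    write_class_labels(genes, outdir / "labels.tsv")
    write_chrom_sizes(genes.chrom_sizes, outdir / "chrom.sizes")
    files = ["annotations.bed", "labels.tsv", "chrom.sizes"]
    samples: dict[str, list[dict]] = {"wt": [], "mut": []}
    for strain, reps in (("wt", wt_reps), ("mut", mut_reps)):
        for sig in reps:
            stem = f"{strain}_rep{sig.replicate}"
            plus, minus = f"{stem}.plus.bedgraph", f"{stem}.minus.bedgraph"
            write_strand_signal(sig, outdir / plus, outdir / minus)
            files.extend([plus, minus])
            samples[strain].append({"replicate": sig.replicate, "plus": plus, "minus": minus})
    checksums = {
        name: hashlib.sha256((outdir / name).read_bytes()).hexdigest() for name in files
    }
    manifest = {
        "sim_config": asdict(cfg) if cfg is not None else None,
        "effect_config": asdict(effects) if effects is not None else None,
        "seed": cfg.seed if cfg is not None else None,
        "samples": samples,
        "files": checksums,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
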