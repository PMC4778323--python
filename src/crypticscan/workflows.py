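"""In-memory study workflows over the simulator and the analysis stages.

These helpers wire the full chain — simulate replicate tracks, median
normalize, average replicates, form the ratio track, profile by class, and
run the macroarray-style ranked enrichment — without touching disk. They
define the standard study conditions (2000 coding genes, 3 replicates per
strain, 20% multiplicative noise) used by the analysis drivers and the
calibration/recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .enrichment import (
    FoldChangeTable,
    count_fold_changed,
    fold_change_from_means,
    ranked_window_counts,
    window_enrichment_test,
)
from .metagene import (
    BinningConfig,
    ClassQuery,
    DEFAULT_CLASSES,
    MetageneResult,
    metagene_by_class,
    summarize_profile,
)
from .signal import average_replicates, median_normalize, ratio_track
from .simulate import EffectConfig, SimConfig, generate_annotation, simulate_macroarray, simulate_tracks

STUDY_CONDITIONS = SimConfig(n_genes=2000, n_chroms=4, noise_cv=0.2, n_reps=3)


@dataclass
class TracksRun:
    """Everything the tiling-track arm of a run produces."""

    genes: object
    metagene: MetageneResult
    cfg: SimConfig
    effects: EffectConfig
    binning: BinningConfig

    def summary(self, class_label: str):
        return summarize_profile(
            self.metagene.get(class_label, "sense"),
            self.metagene.get(class_label, "antisense"),
            self.binning,
        )


def run_tracks_scenario(
    effects: EffectConfig,
    seed: int,
    cfg: SimConfig = STUDY_CONDITIONS,
    binning: BinningConfig | None = None,
    classes=DEFAULT_CLASSES,
) -> TracksRun:
    """Simulate tracks under ``effects`` and profile them by gene class."""
    cfg = replace(cfg, seed=int(seed))
    binning = binning or BinningConfig()
    genes = generate_annotation(cfg)
    wt_reps, mut_reps = simulate_tracks(genes, cfg, effects)
    normalized = median_normalize(wt_reps + mut_reps)
    wt = average_replicates(normalized[: cfg.n_reps])
    mut = average_replicates(normalized[cfg.n_reps :])
    ratios = ratio_track(mut, wt)
    result = metagene_by_class(genes, ratios, binning, classes=classes)
    return TracksRun(genes=genes, metagene=result, cfg=cfg, effects=effects, binning=binning)


def null_calibration(seed: int, cfg: SimConfig = STUDY_CONDITIONS) -> dict:
    """Largest |bin - 1| over every class and orientation under the null."""
    run = run_tracks_scenario(EffectConfig.preset("null"), seed, cfg)
    worst = 0.0
    worst_at = None
    for p in run.metagene.profiles:
        dev = np.nanmax(np.abs(p.bins - 1.0))
        if dev > worst:
            worst, worst_at = float(dev), (p.class_label, p.orientation)
    return {"max_abs_deviation": worst, "worst_profile": worst_at, "run": run}


@dataclass
class EnrichmentRun:
    genes: object
    table: FoldChangeTable
    n_up: int
    n_down: int
    observed: int
    expected: float
    p: float
    n_total: int
    n_flagged: int


def run_enrichment_scenario(
    effects: EffectConfig,
    seed: int,
    cfg: SimConfig = STUDY_CONDITIONS,
    window: int = 500,
    threshold: float = 2.0,
) -> EnrichmentRun:
    """Macroarray-style ranked dubious-ORF enrichment under ``effects``.

    Simulates one ORF feature per coding/dubious gene with per-feature
    replicate noise, ranks detected features by mutant/WT ratio and tests
    the top window for dubious-ORF excess. Pseudocount and detection floor
    are both 10% of the median feature intensity.
    """
    cfg = replace(cfg, seed=int(seed))
    genes = generate_annotation(cfg)
    df = simulate_macroarray(genes, cfg, effects)
    floor = 0.1 * float(np.median(np.concatenate([df["wt_mean"], df["mut_mean"]])))
    table = fold_change_from_means(
        df["gene_id"].tolist(),
        df["wt_mean"].to_numpy(),
        df["mut_mean"].to_numpy(),
        pseudocount=floor,
        detection_floor=floor,
    )
    n_up, n_down = count_fold_changed(table, threshold)
    flags = {g.gene_id for g in genes if g.biotype == "dubious_orf"}
    hist = ranked_window_counts(table, flags, window=window)
    top_size = min(window, hist.n_total)
    observed = int(hist.counts[0])
    expected = top_size * hist.n_flagged_total / hist.n_total
    p = window_enrichment_test(observed, top_size, hist.n_total, hist.n_flagged_total)
    return EnrichmentRun(
        genes=genes,
        table=table,
        n_up=n_up,
        n_down=n_down,
        observed=observed,
        expected=expected,
        p=p,
        n_total=hist.n_total,
        n_flagged=hist.n_flagged_total,
    )


def recovery_metrics(run: TracksRun, class_label: str = "canonical") -> dict:
    """Scale-invariant effect amplitudes recovered from a class profile.

    Between-array scaling is only defined up to the choice of an invariant
    base set, so a mutant with widespread injected signal shifts the
    genome-wide median and with it the absolute ratio scale. Amplitudes are
    therefore quoted relative to the same profile's sense-body mean (which
    carries no injected effect for non-TATA scenarios): the 5' flank peak
    ratio as ``peak5_height / body_sense_mean`` and the antisense body
    elevation as ``antisense_body_mean / body_sense_mean``. Both reduce to
    the plain profile values when the scale factor is 1.
    """
    s = run.summary(class_label)
    return {
        "peak5_bin": s.peak5_bin,
        "peak3_bin": s.peak3_bin,
        "sense5_peak_ratio": s.peak5_height / s.body_sense_mean,
        "sense3_peak_ratio": s.peak3_height / s.body_sense_mean,
        "antisense_body_elevation": s.antisense_body_mean / s.body_sense_mean,
    }


def derive_seeds(base_seed: int, n: int, stream: int = 0) -> list[int]:
    """n reproducible 31-bit sub-seeds from one base seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(base_seed), 997, stream]))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
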