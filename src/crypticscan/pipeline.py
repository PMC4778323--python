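"""Pipeline orchestration: config, staged execution, reproducible outputs.

A :class:`RunConfig` (YAML on disk, validated by pydantic) names the input
files — annotation, class labels, chromosome sizes, and per-strain
replicate bedGraph pairs — plus every analysis parameter with its default
materialized. :func:`run_pipeline` executes ingestion -> normalization ->
replicate averaging -> ratio track -> class metagenes/summaries ->
fold-change table -> ranked-window histogram -> enrichment test, writing
TSV/JSON outputs atomically (temp-then-rename) together with a JSON-lines
event log and an echo of the fully-resolved config.
"""

from __future__ import annotations

import json
import os
import sys
from dataclasses import asdict
from pathlib import Path
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .annotation import (
    BIOTYPES,
    GeneSet,
    assign_class_labels,
    read_chrom_sizes,
    read_class_labels,
    read_gene_annotations,
)
from .enrichment import (
    FoldChangeTable,
    count_fold_changed,
    default_detection_floor,
    histogram_enrichment,
    orf_expression_table,
    ranked_window_counts,
    read_orf_table,
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
from .signal import average_replicates, default_pseudocount, median_normalize, ratio_track, read_strand_signal


class SignalPair(BaseModel):
    plus: str
    minus: str


class ClassSpec(BaseModel):
    label: str
    biotype: Optional[str] = None
    promoter_class: Optional[str] = None

    @field_validator("biotype")
    @classmethod
    def _known_biotype(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in BIOTYPES:
            raise ValueError(f"unknown biotype {v!r} in class query (expected one of {BIOTYPES})")
        return v


class RunConfig(BaseModel):
    """Fully-resolved run configuration; round-trips to YAML losslessly."""

    annotations: str
    annotation_format: Literal["BED6", "GFF3"] = "BED6"
    labels: Optional[str] = None
    chrom_sizes: str
    wildtype: list[SignalPair]
    mutant: list[SignalPair]

    unit_bp: int = 20
    flank_units: int = 20
    body_units: int = 20
    min_body_bp: int = 60
    aggregation: Literal["mean_of_ratios", "ratio_of_means"] = "mean_of_ratios"
    pseudocount: Optional[float] = None  # None -> 1% of WT genome-wide median
    classes: list[ClassSpec] = Field(
        default_factory=lambda: [ClassSpec(**asdict(q)) for q in DEFAULT_CLASSES]
    )

    orf_table: Optional[str] = None  # per-ORF TSV; overrides the track-derived table
    orf_biotypes: list[str] = Field(default_factory=lambda: ["coding", "dubious_orf"])
    flag_biotype: str = "dubious_orf"
    detection_floor: Optional[float] = None  # None -> 10% of pooled median intensity
    window: int = 500
    threshold: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def binning(self) -> BinningConfig:
        return BinningConfig(
            unit_bp=self.unit_bp,
            flank_units=self.flank_units,
            body_units=self.body_units,
            min_body_bp=self.min_body_bp,
        )

    def class_queries(self) -> list[ClassQuery]:
        return [ClassQuery(c.label, c.biotype, c.promoter_class) for c in self.classes]

    def input_paths(self) -> list[str]:
        paths = [self.annotations, self.chrom_sizes]
        if self.labels:
            paths.append(self.labels)
        if self.orf_table:
            paths.append(self.orf_table)
        for pair in self.wildtype + self.mutant:
            paths.extend([pair.plus, pair.minus])
        return paths


class _RunLog:
    def __init__(self, path: Path):
        self._events: list[dict] = []
        self._path = path

    def event(self, kind: str, **payload: Any) -> None:
        self._events.append({"event": kind, **payload})

    def flush(self) -> None:
        with open(self._path, "w") as fh:
            for ev in self._events:
                fh.write(json.dumps(ev, sort_keys=True) + "\n")


def _atomic_write(path: Path, writer) -> None:
    tmp = path.with_name(path.name + ".tmp")
    writer(tmp)
    os.replace(tmp, path)


def _load_inputs(config: RunConfig) -> GeneSet:
    sizes = read_chrom_sizes(config.chrom_sizes)
    genes = read_gene_annotations(config.annotations, config.annotation_format, sizes)
    if config.labels:
        genes = assign_class_labels(genes, read_class_labels(config.labels))
    return genes


def _averaged_strain_tracks(config: RunConfig, log: _RunLog):
    sizes = read_chrom_sizes(config.chrom_sizes)
    wt_reps = [
        read_strand_signal(p.plus, p.minus, sizes, sample_id="wt", replicate=i + 1)
        for i, p in enumerate(config.wildtype)
    ]
    mut_reps = [
        read_strand_signal(p.plus, p.minus, sizes, sample_id="mut", replicate=i + 1)
        for i, p in enumerate(config.mutant)
    ]
    normalized = median_normalize(wt_reps + mut_reps)
    wt = average_replicates(normalized[: len(wt_reps)])
    mut = average_replicates(normalized[len(wt_reps) :])
    log.event("replicates_averaged", n_wt=len(wt_reps), n_mut=len(mut_reps))
    return wt, mut


def run_pipeline(config: RunConfig, outdir: str | Path, plots: bool = False) -> dict[str, Path]:
    """Execute every stage; returns a name -> path map of outputs."""
    missing = [p for p in config.input_paths() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "run_log.jsonl")
    log.event("start", version=__version__, python=sys.version.split()[0])
    log.event("config", config=config.model_dump())

    genes = _load_inputs(config)
    # fail on an empty class query before any signal is read
    queries = config.class_queries()
    for q in queries:
        if not genes.select(biotype=q.biotype, promoter_class=q.promoter_class):
            raise ValueError(f"class query {q.label!r} selects no genes")

    wt, mut = _averaged_strain_tracks(config, log)
    eps = config.pseudocount if config.pseudocount is not None else default_pseudocount(wt)
    ratios = ratio_track(mut, wt, eps)
    log.event("ratio_track", pseudocount=eps)

    result: MetageneResult = metagene_by_class(
        genes,
        ratios,
        config.binning(),
        classes=queries,
        method=config.aggregation,
        mutant=mut,
        wildtype=wt,
        pseudocount=eps,
    )
    for label, excluded in result.exclusions.items():
        log.event("exclusions", class_label=label, n_excluded=len(excluded), gene_ids=[g for g, _ in excluded])

    outputs: dict[str, Path] = {}

    rows = []
    for p in result.profiles:
        for b in range(len(p.bins)):
            rows.append((p.class_label, p.orientation, b, p.bins[b], p.stderr[b], p.n_genes, p.method))
    import pandas as pd  # local import keeps module import light

    metagene_df = pd.DataFrame(
        rows, columns=["class", "orientation", "bin", "mean", "stderr", "n_genes", "method"]
    )
    path = outdir / "metagene.tsv"
    _atomic_write(path, lambda t: metagene_df.to_csv(t, sep="\t", index=False, float_format="%.10g"))
    outputs["metagene"] = path

    summaries = {}
    for q in queries:
        summaries[q.label] = summarize_profile(
            result.get(q.label, "sense"), result.get(q.label, "antisense"), config.binning()
        ).to_dict()
    path = outdir / "profile_summaries.json"
    _atomic_write(path, lambda t: Path(t).write_text(json.dumps(summaries, indent=2, sort_keys=True)))
    outputs["profile_summaries"] = path

    floor = (
        config.detection_floor
        if config.detection_floor is not None
        else default_detection_floor(wt, mut)
    )
    if config.orf_table:
        table = read_orf_table(config.orf_table, pseudocount=floor, detection_floor=floor)
    else:
        table = orf_expression_table(
            genes, wt, mut, pseudocount=floor, detection_floor=floor, biotypes=config.orf_biotypes
        )
    log.event("fold_change_table", detection_floor=floor, n_rows=len(table), n_detected=len(table.detected))
    path = outdir / "fold_change.tsv"
    _atomic_write(path, table.to_tsv)
    outputs["fold_change"] = path

    n_up, n_down = count_fold_changed(table, config.threshold)
    flags = {g.gene_id for g in genes if g.biotype == config.flag_biotype}
    hist = ranked_window_counts(table, flags, window=config.window)
    path = outdir / "ranked_histogram.tsv"
    _atomic_write(path, lambda t: hist.to_frame().to_csv(t, sep="\t", index=False))
    outputs["ranked_histogram"] = path

    enr = histogram_enrichment(hist)
    top_size = min(config.window, hist.n_total)
    top_obs = int(hist.counts[0])
    top_expected = top_size * hist.n_flagged_total / hist.n_total if hist.n_total else 0.0
    top_p = window_enrichment_test(top_obs, top_size, hist.n_total, hist.n_flagged_total) if hist.n_total else 1.0
    report = {
        "threshold": config.threshold,
        "n_up": n_up,
        "n_down": n_down,
        "n_detected": int(hist.n_total),
        "n_flagged_detected": int(hist.n_flagged_total),
        "window": config.window,
        "top_window": {
            "observed": top_obs,
            "expected": top_expected,
            "p": top_p,
        },
        "per_window": enr.to_dict(orient="records"),
    }
    path = outdir / "enrichment.json"
    _atomic_write(path, lambda t: Path(t).write_text(json.dumps(report, indent=2, sort_keys=True)))
    outputs["enrichment"] = path

    if plots:
        from .plotting import plot_metagene_panels

        path = outdir / "metagene_panels.pdf"
        _atomic_write(path, lambda t: plot_metagene_panels(result, config.binning(), t))
        outputs["plots"] = path

    path = outdir / "config_echo.yaml"
    _atomic_write(path, config.to_yaml)
    outputs["config_echo"] = path
    log.event("done", outputs={k: str(v) for k, v in outputs.items()})
    log.flush()
    outputs["run_log"] = outdir / "run_log.jsonl"
    return outputs
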