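"""Per-ORF fold-change tables and ranked-window dubious-ORF enrichment.

Reconstructs the macroarray-style view of a depletion experiment: one
expression value per ORF per strain, a mutant/wild-type ratio with a
pseudocount, counts of at-least-two-fold changed genes, and the
ranked-window histogram asking whether ORFs flagged as "dubious" crowd the
top of the ranking — the signature of cryptic transcripts spilling over ORF
boundaries onto probes that cover neighbouring dubious ORFs. An upper-tail
hypergeometric test formalizes the enrichment; Benjamini–Hochberg controls
the FDR when every window is tested.

Detection semantics: a feature is ``detected`` when either strain's mean
intensity reaches ``detection_floor`` (default 10% of the genome-wide
median intensity). The table's default pseudocount equals that floor, so
ratios of features near the detection limit are regularised at the same
scale — near-background ratios shrink toward 1 instead of exploding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneSet
from .signal import StrandSignal, _all_values

TABLE_COLUMNS = ["gene_id", "wt_mean", "mut_mean", "ratio", "detected"]


@dataclass
class FoldChangeTable:
    """Per-ORF WT/mutant means and pseudocounted ratios (one row per gene)."""

    frame: pd.DataFrame
    pseudocount: float
    detection_floor: float

    def __post_init__(self) -> None:
        missing = set(TABLE_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"fold-change table missing columns {sorted(missing)}")
        if self.frame["gene_id"].duplicated().any():
            raise ValueError("fold-change table has duplicate gene_ids")
        det = self.frame.loc[self.frame["detected"], "ratio"]
        if (det <= 0).any():
            raise ValueError("detected rows must have positive ratios")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def detected(self) -> pd.DataFrame:
        return self.frame[self.frame["detected"]]

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def fold_change_from_means(
    gene_ids: Sequence[str],
    wt_means: np.ndarray,
    mut_means: np.ndarray,
    pseudocount: float,
    detection_floor: float,
) -> FoldChangeTable:
    """Assemble a fold-change table from per-ORF mean intensities."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    wt = np.asarray(wt_means, dtype=float)
    mut = np.asarray(mut_means, dtype=float)
    frame = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "wt_mean": wt,
            "mut_mean": mut,
            "ratio": (mut + pseudocount) / (wt + pseudocount),
            "detected": np.maximum(wt, mut) >= detection_floor,
        }
    )
    return FoldChangeTable(frame=frame, pseudocount=pseudocount, detection_floor=detection_floor)


def default_detection_floor(wt: StrandSignal, mut: StrandSignal, fraction: float = 0.1) -> float:
    """``fraction`` x the genome-wide median intensity of both strains pooled."""
    vals = np.concatenate([_all_values(wt), _all_values(mut)])
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("no positive signal in either strain")
    return fraction * float(np.median(pos))


def orf_expression_table(
    genes: GeneSet,
    wt: StrandSignal,
    mut: StrandSignal,
    pseudocount: float | None = None,
    detection_floor: float | None = None,
    biotypes: Sequence[str] | None = None,
) -> FoldChangeTable:
    """Per-gene mean sense-strand intensity over the ORF, for both strains.

    ``wt``/``mut`` should be normalized, replicate-averaged tracks.
    ``biotypes`` restricts the table (e.g. ``("coding", "dubious_orf")`` for
    an ORF-array emulation); default is every gene. ``detection_floor=None``
    uses 10% of the pooled genome-wide median; ``pseudocount=None`` defaults
    to the detection floor.
    """
    if detection_floor is None:
        detection_floor = default_detection_floor(wt, mut)
    if pseudocount is None:
        pseudocount = detection_floor
    selected = [g for g in genes if biotypes is None or g.biotype in biotypes]
    ids, wt_means, mut_means = [], [], []
    for g in selected:
        ids.append(g.gene_id)
        wt_means.append(float(np.mean(wt.values(g.chrom, g.strand)[g.start : g.end])))
        mut_means.append(float(np.mean(mut.values(g.chrom, g.strand)[g.start : g.end])))
    return fold_change_from_means(
        ids, np.array(wt_means), np.array(mut_means), pseudocount, detection_floor
    )


def read_orf_table(
    path: str | Path, pseudocount: float, detection_floor: float
) -> FoldChangeTable:
    """Load a per-ORF expression TSV (``gene_id  wt_mean  mut_mean``)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "wt_mean", "mut_mean"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: ORF table missing columns {sorted(missing)}")
    return fold_change_from_means(
        df["gene_id"].astype(str).tolist(),
        df["wt_mean"].to_numpy(float),
        df["mut_mean"].to_numpy(float),
        pseudocount,
        detection_floor,
    )


def count_fold_changed(table: FoldChangeTable, threshold: float = 2.0) -> tuple[int, int]:
    """(n_up, n_down) among detected genes; boundaries inclusive."""
    if threshold <= 1:
        raise ValueError(f"fold-change threshold must exceed 1, got {threshold}")
    ratios = table.detected["ratio"]
    n_up = int((ratios >= threshold).sum())
    n_down = int((ratios <= 1.0 / threshold).sum())
    return n_up, n_down


@dataclass
class RankedWindowHistogram:
    """Flagged-gene counts in successive windows of the ratio ranking."""

    window_size: int
    counts: np.ndarray  # per window, descending-ratio order
    n_total: int
    n_flagged_total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if int(self.counts.sum()) != self.n_flagged_total:
            raise ValueError("window counts do not sum to the flagged total")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window": np.arange(len(self.counts)),
                "rank_start": np.arange(len(self.counts)) * self.window_size,
                "n_flagged": self.counts,
            }
        )


def ranked_window_counts(
    table: FoldChangeTable,
    flags: Mapping[str, bool] | Iterable[str],
    window: int = 500,
) -> RankedWindowHistogram:
    """Histogram of flagged genes per window of the descending-ratio ranking.

    Only detected genes are ranked. Ties in the ratio break
    lexicographically by gene_id, so the ranking is deterministic. ``flags``
    is a set of flagged gene_ids or a gene_id -> bool mapping.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if isinstance(flags, Mapping):
        flagged_ids = {gid for gid, v in flags.items() if v}
    else:
        flagged_ids = set(flags)
    ranked = table.detected.sort_values(
        ["ratio", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    is_flagged = ranked["gene_id"].isin(flagged_ids).to_numpy()
    n_total = len(ranked)
    n_windows = max(1, -(-n_total // window))
    counts = np.zeros(n_windows, dtype=int)
    for w in range(n_windows):
        counts[w] = int(is_flagged[w * window : (w + 1) * window].sum())
    return RankedWindowHistogram(
        window_size=window,
        counts=counts,
        n_total=n_total,
        n_flagged_total=int(is_flagged.sum()),
    )


def window_enrichment_test(
    observed: int, window: int, n_total: int, n_flagged_total: int
) -> float:
    """Upper-tail hypergeometric P(X >= observed).

    X counts flagged members when ``window`` genes are drawn without
    replacement from ``n_total`` genes of which ``n_flagged_total`` are
    flagged.
    """
    if not (0 <= n_flagged_total <= n_total):
        raise ValueError("need 0 <= n_flagged_total <= n_total")
    if not (0 < window <= n_total):
        raise ValueError("need 0 < window <= n_total")
    if not (0 <= observed <= min(window, n_flagged_total)):
        raise ValueError(
            f"observed={observed} inconsistent with window={window}, "
            f"n_flagged_total={n_flagged_total}"
        )
    return float(stats.hypergeom.sf(observed - 1, n_total, n_flagged_total, window))


def histogram_enrichment(hist: RankedWindowHistogram) -> pd.DataFrame:
    """Per-window observed vs expected counts with BH-adjusted p-values.

    The headline question concerns the top window; the full per-window
    table applies Benjamini–Hochberg across windows. The last window may be
    smaller than ``window_size``.
    """
    n_windows = len(hist.counts)
    rows = []
    for w in range(n_windows):
        size = min(hist.window_size, hist.n_total - w * hist.window_size)
        obs = int(hist.counts[w])
        expected = size * hist.n_flagged_total / hist.n_total if hist.n_total else 0.0
        p = window_enrichment_test(obs, size, hist.n_total, hist.n_flagged_total)
        rows.append((w, size, obs, expected, p))
    df = pd.DataFrame(rows, columns=["window", "size", "observed", "expected", "p"])
    df["q"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    return df
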