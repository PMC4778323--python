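"""Anchored-scaling metagene profiles of mutant/wild-type signal ratios.

Every gene is mapped onto a common abscissa of ``2*flank_units +
body_units`` bins (default 60). With the default geometry one abscissa unit
is 20 bp, so each 20-unit flank spans 400 bp of fixed-width windows walking
outward from the TSS (upstream) and from the pA site (downstream), while
the gene body — whatever its length — is rescaled onto 20 equal-length
segments occupying units 20–40. Bin 0 is always the most upstream bin in
the gene's own direction of transcription; minus-strand genes are handled
by reading reversed slices of the genome vectors, which makes every
downstream computation exactly mirror-symmetric.

``sense`` means signal on the gene's own strand, ``antisense`` the opposite
strand, both in the gene's frame. Class-averaged profiles put the cryptic
transcription phenotype on one picture: sense peaks over the 5'/3'
nucleosome-free regions, and elevated antisense signal across the body.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .annotation import GeneModel, GeneSet


class _Track(Protocol):
    def values(self, chrom: str, strand: str) -> np.ndarray: ...


@dataclass(frozen=True)
class BinningConfig:
    """Geometry of the metagene abscissa.

    unit_bp
        Base pairs per abscissa unit in the flanks (one bin per unit).
    flank_units
        Bins per flank; flank span = ``unit_bp * flank_units`` bp.
    body_units
        Bins the gene body is rescaled onto.
    min_body_bp
        Genes with a shorter body are excluded (scaled bins degenerate
        below a few bases per bin).
    """

    unit_bp: int = 20
    flank_units: int = 20
    body_units: int = 20
    min_body_bp: int = 60

    def __post_init__(self) -> None:
        for name in ("unit_bp", "flank_units", "body_units", "min_body_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def flank_bp(self) -> int:
        return self.unit_bp * self.flank_units

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_units + self.body_units

    @property
    def body_slice(self) -> slice:
        return slice(self.flank_units, self.flank_units + self.body_units)


@dataclass
class GeneProfile:
    """Per-gene binned sense/antisense values (NaN marks clipped flank bins)."""

    gene_id: str
    sense: np.ndarray
    antisense: np.ndarray
    included: bool = True
    reason: str | None = None


@dataclass
class MetageneProfile:
    """Class-averaged profile for one orientation."""

    class_label: str
    orientation: str  # "sense" | "antisense"
    bins: np.ndarray
    stderr: np.ndarray
    n_genes: int
    method: str = "mean_of_ratios"


@dataclass
class ProfileSummary:
    """Headline features of a class profile pair.

    Peak positions are centres of the near-maximal plateau (bins within
    ``peak_frac`` of the regional maximum), so a flat-topped peak reports
    its middle rather than an arbitrary edge; heights are the regional
    maxima. Body means average the scaled-body bins.
    """

    peak5_bin: int
    peak5_height: float
    peak3_bin: int
    peak3_height: float
    body_sense_mean: float
    antisense_body_mean: float

    def to_dict(self) -> dict:
        return {
            "peak5_bin": int(self.peak5_bin),
            "peak5_height": float(self.peak5_height),
            "peak3_bin": int(self.peak3_bin),
            "peak3_height": float(self.peak3_height),
            "body_sense_mean": float(self.body_sense_mean),
            "antisense_body_mean": float(self.antisense_body_mean),
        }


# ---------------------------------------------------------------------------
# per-gene binning


def _frame_slice(arr: np.ndarray, start: int, end: int, reverse: bool) -> np.ndarray:
    """``arr[start:end)`` as float with NaN outside the array bounds.

    ``reverse=True`` returns the window in descending genomic order (the
    reading direction of a minus-strand gene).
    """
    n = end - start
    out = np.full(n, np.nan)
    lo, hi = max(start, 0), min(end, len(arr))
    if lo < hi:
        out[lo - start : hi - start] = arr[lo:hi]
    return out[::-1] if reverse else out


def _fixed_bins(vals: np.ndarray, n_bins: int, width: int) -> np.ndarray:
    """Mean per fixed-width window, NaN-aware (all-NaN window -> NaN)."""
    m = vals.reshape(n_bins, width)
    valid = ~np.isnan(m)
    cnt = valid.sum(axis=1)
    sums = np.where(valid, m, 0.0).sum(axis=1)
    out = np.full(n_bins, np.nan)
    nz = cnt > 0
    out[nz] = sums[nz] / cnt[nz]
    return out


def _scaled_bins(vals: np.ndarray, n_bins: int) -> np.ndarray:
    """Partition ``vals`` into ``n_bins`` equal-length segments; mean each.

    Base k of an L-base body belongs to bin ``k * n_bins // L``.
    """
    length = len(vals)
    idx = (np.arange(length) * n_bins) // length
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    cnts = np.bincount(idx, minlength=n_bins)
    return sums / cnts


def bin_gene(gene: GeneModel, track: _Track, cfg: BinningConfig) -> GeneProfile:
    """Bin one gene's sense and antisense signal onto the metagene abscissa.

    ``track`` is anything exposing per-base vectors via
    ``values(chrom, strand)`` — a :class:`~crypticscan.signal.RatioTrack`
    for ratio profiles or a :class:`~crypticscan.signal.StrandSignal` when
    per-condition bin means are needed (ratio-of-means aggregation).

    Flank windows clipped at chromosome boundaries are padded with NaN, not
    zeros, and drop out of downstream averages.
    """
    n = cfg.n_bins
    if gene.length < cfg.min_body_bp:
        empty = np.full(n, np.nan)
        return GeneProfile(
            gene.gene_id, empty, empty.copy(), included=False,
            reason=f"body {gene.length} bp < min_body_bp {cfg.min_body_bp}",
        )
    sense_arr = track.values(gene.chrom, gene.strand)
    anti_arr = track.values(gene.chrom, "-" if gene.strand == "+" else "+")
    F = cfg.flank_bp
    if gene.strand == "+":
        regions = [(gene.start - F, gene.start), (gene.start, gene.end), (gene.end, gene.end + F)]
        reverse = False
    else:
        # frame order upstream->downstream corresponds to descending coords
        regions = [(gene.end, gene.end + F), (gene.start, gene.end), (gene.start - F, gene.start)]
        reverse = True

    def profile(arr: np.ndarray) -> np.ndarray:
        up = _frame_slice(arr, *regions[0], reverse)
        body = _frame_slice(arr, *regions[1], reverse)
        down = _frame_slice(arr, *regions[2], reverse)
        return np.concatenate(
            [
                _fixed_bins(up, cfg.flank_units, cfg.unit_bp),
                _scaled_bins(body, cfg.body_units),
                _fixed_bins(down, cfg.flank_units, cfg.unit_bp),
            ]
        )

    return GeneProfile(gene.gene_id, profile(sense_arr), profile(anti_arr))


# ---------------------------------------------------------------------------
# aggregation


def _nan_mean_stderr(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    valid = ~np.isnan(matrix)
    cnt = valid.sum(axis=0)
    sums = np.where(valid, matrix, 0.0).sum(axis=0)
    mean = np.full(matrix.shape[1], np.nan)
    nz = cnt > 0
    mean[nz] = sums[nz] / cnt[nz]
    devs = np.where(valid, matrix - np.where(nz, mean, 0.0), 0.0)
    ss = (devs**2).sum(axis=0)
    stderr = np.zeros(matrix.shape[1])
    multi = cnt > 1
    stderr[multi] = np.sqrt(ss[multi] / (cnt[multi] - 1)) / np.sqrt(cnt[multi])
    return mean, stderr


def aggregate_metagene(
    profiles: Sequence[GeneProfile],
    class_label: str,
) -> tuple[MetageneProfile, MetageneProfile]:
    """Across-gene mean of per-gene ratio profiles (mean-of-ratios).

    Missing (clipped) flank bins are excluded from that bin's mean; stderr
    is the across-gene sample SD / sqrt(n).
    """
    included = [p for p in profiles if p.included]
    if not included:
        raise ValueError(f"class {class_label!r}: no included gene profiles")
    out = []
    for orientation in ("sense", "antisense"):
        matrix = np.stack([getattr(p, orientation) for p in included])
        mean, stderr = _nan_mean_stderr(matrix)
        out.append(
            MetageneProfile(class_label, orientation, mean, stderr, len(included), "mean_of_ratios")
        )
    return out[0], out[1]


def aggregate_ratio_of_means(
    mut_profiles: Sequence[GeneProfile],
    wt_profiles: Sequence[GeneProfile],
    class_label: str,
    pseudocount: float,
) -> tuple[MetageneProfile, MetageneProfile]:
    """Ratio of across-gene mean mutant bin signal to mean WT bin signal.

    Requires per-condition bin profiles (genes binned on the mutant and
    wild-type signal tracks separately). Stderr is a first-order
    delta-method propagation of the two per-bin standard errors.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    mut_inc = [p for p in mut_profiles if p.included]
    wt_inc = [p for p in wt_profiles if p.included]
    if not mut_inc or not wt_inc:
        raise ValueError(f"class {class_label!r}: no included gene profiles")
    out = []
    for orientation in ("sense", "antisense"):
        m_mean, m_se = _nan_mean_stderr(np.stack([getattr(p, orientation) for p in mut_inc]))
        w_mean, w_se = _nan_mean_stderr(np.stack([getattr(p, orientation) for p in wt_inc]))
        ratio = (m_mean + pseudocount) / (w_mean + pseudocount)
        stderr = np.sqrt(m_se**2 + ratio**2 * w_se**2) / (w_mean + pseudocount)
        out.append(
            MetageneProfile(class_label, orientation, ratio, stderr, len(mut_inc), "ratio_of_means")
        )
    return out[0], out[1]


@dataclass(frozen=True)
class ClassQuery:
    """Selects the genes a metagene is averaged over."""

    label: str
    biotype: str | None = None
    promoter_class: str | None = None


DEFAULT_CLASSES = (
    ClassQuery("canonical", biotype="coding"),
    ClassQuery("TATA", biotype="coding", promoter_class="TATA"),
    ClassQuery("TATA-like", biotype="coding", promoter_class="TATA-like"),
    ClassQuery("SUT", biotype="SUT"),
    ClassQuery("CUT", biotype="CUT"),
)


@dataclass
class MetageneResult:
    profiles: list[MetageneProfile]
    exclusions: dict[str, list[tuple[str, str]]]  # class label -> (gene_id, reason)

    def get(self, class_label: str, orientation: str) -> MetageneProfile:
        for p in self.profiles:
            if p.class_label == class_label and p.orientation == orientation:
                return p
        raise KeyError((class_label, orientation))


def metagene_by_class(
    genes: GeneSet,
    track: _Track,
    cfg: BinningConfig,
    classes: Sequence[ClassQuery] = DEFAULT_CLASSES,
    method: str = "mean_of_ratios",
    mutant: _Track | None = None,
    wildtype: _Track | None = None,
    pseudocount: float | None = None,
) -> MetageneResult:
    """One sense + one antisense metagene per gene class.

    ``method="mean_of_ratios"`` (default) bins the ratio track per gene and
    averages genes with equal weight. ``method="ratio_of_means"`` bins the
    ``mutant`` and ``wildtype`` averaged signal tracks per gene and takes
    the ratio of the across-gene bin means (requires both tracks plus a
    pseudocount).
    """
    if method not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError(f"unknown aggregation method {method!r}")
    if method == "ratio_of_means" and (mutant is None or wildtype is None or pseudocount is None):
        raise ValueError("ratio_of_means needs mutant and wildtype tracks and a pseudocount")
    profiles: list[MetageneProfile] = []
    exclusions: dict[str, list[tuple[str, str]]] = {}
    for query in classes:
        selected = genes.select(biotype=query.biotype, promoter_class=query.promoter_class)
        if not selected:
            raise ValueError(f"class query {query.label!r} selects no genes")
        if method == "mean_of_ratios":
            gps = [bin_gene(g, track, cfg) for g in selected]
            sense, anti = aggregate_metagene(gps, query.label)
        else:
            mut_gps = [bin_gene(g, mutant, cfg) for g in selected]
            wt_gps = [bin_gene(g, wildtype, cfg) for g in selected]
            gps = mut_gps
            sense, anti = aggregate_ratio_of_means(mut_gps, wt_gps, query.label, pseudocount)
        exclusions[query.label] = [(p.gene_id, p.reason or "") for p in gps if not p.included]
        profiles.extend([sense, anti])
    return MetageneResult(profiles=profiles, exclusions=exclusions)


# ---------------------------------------------------------------------------
# summaries


def _plateau_peak(bins: np.ndarray, lo: int, hi: int, peak_frac: float) -> tuple[int, float]:
    seg = bins[lo:hi]
    finite = np.isfinite(seg)
    if not finite.any():
        raise ValueError("peak search region contains no finite bins")
    height = float(np.max(seg[finite]))
    near = finite & (seg >= height - peak_frac * abs(height))
    j0 = int(np.flatnonzero(finite & (seg == height))[0])
    a = j0
    while a > 0 and near[a - 1]:
        a -= 1
    b = j0
    while b < len(seg) - 1 and near[b + 1]:
        b += 1
    return lo + a + (b - a) // 2, height


def summarize_profile(
    sense: MetageneProfile,
    antisense: MetageneProfile | None = None,
    cfg: BinningConfig | None = None,
    peak_frac: float = 0.02,
) -> ProfileSummary:
    """Flank peak positions/heights and body means of a class profile pair.

    The 5' peak is searched over the upstream flank plus the first quarter
    of the body, the 3' peak over the last quarter of the body plus the
    downstream flank. A peak's position is the centre of the contiguous run
    of bins within ``peak_frac`` (relative) of the regional maximum — for a
    single-bin peak this is the argmax; for a flat-topped peak it is the
    plateau middle.
    """
    cfg = cfg or BinningConfig()
    bins = sense.bins
    if len(bins) < cfg.n_bins:
        raise ValueError("profile shorter than the configured bin count")
    f, b = cfg.flank_units, cfg.body_units
    peak5_bin, peak5_height = _plateau_peak(bins, 0, f + b // 4, peak_frac)
    peak3_bin, peak3_height = _plateau_peak(bins, f + 3 * b // 4, cfg.n_bins, peak_frac)
    body = bins[cfg.body_slice]
    body_sense_mean = float(np.nanmean(body))
    if antisense is not None:
        anti_body_mean = float(np.nanmean(antisense.bins[cfg.body_slice]))
    else:
        anti_body_mean = float("nan")
    return ProfileSummary(
        peak5_bin=peak5_bin,
        peak5_height=peak5_height,
        peak3_bin=peak3_bin,
        peak3_height=peak3_height,
        body_sense_mean=body_sense_mean,
        antisense_body_mean=anti_body_mean,
    )
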