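"""Strand-specific signal tracks: bedGraph IO, normalization, ratio tracks.

Signals are dense per-base, per-strand, non-negative float vectors keyed by
chromosome — the limiting case of a tiling array whose probes shrink to
single bases. Between-sample scaling uses a single genome-wide median factor
(computed over bases covered in any input sample), which preserves all
within-sample structure. Mutant/wild-type comparison is a per-base linear
ratio with a small pseudocount so that nucleosome-free regions, where
hybridization signal is lowest, cannot divide by zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-")


@dataclass
class StrandSignal:
    """Per-chromosome, per-strand non-negative intensity vectors.

    ``data[chrom][strand]`` is a float64 vector of per-base intensities with
    length equal to the chromosome size.
    """

    data: dict[str, dict[str, np.ndarray]]
    sample_id: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        for chrom, strands in self.data.items():
            for strand in STRANDS:
                if strand not in strands:
                    raise ValueError(f"{chrom}: missing strand {strand!r}")
                arr = np.asarray(strands[strand], dtype=float)
                if not np.all(np.isfinite(arr)):
                    raise ValueError(f"{chrom}{strand}: non-finite intensity")
                if np.any(arr < 0):
                    raise ValueError(f"{chrom}{strand}: negative intensity")
                strands[strand] = arr

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s["+"]) for c, s in self.data.items()}

    def values(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[chrom][strand]

    def copy(self) -> "StrandSignal":
        return StrandSignal(
            data={c: {s: arr.copy() for s, arr in strands.items()} for c, strands in self.data.items()},
            sample_id=self.sample_id,
            replicate=self.replicate,
        )

    def mirrored(self) -> "StrandSignal":
        """Coordinate-reflected, strand-swapped signal (x -> L - 1 - x)."""
        return StrandSignal(
            data={
                c: {"+": strands["-"][::-1].copy(), "-": strands["+"][::-1].copy()}
                for c, strands in self.data.items()
            },
            sample_id=self.sample_id,
            replicate=self.replicate,
        )


@dataclass
class RatioTrack:
    """Per-base mutant/wild-type ratio per strand (strictly positive)."""

    data: dict[str, dict[str, np.ndarray]]
    pseudocount: float

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError(f"pseudocount must be > 0, got {self.pseudocount}")
        for chrom, strands in self.data.items():
            for strand, arr in strands.items():
                if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                    raise ValueError(f"{chrom}{strand}: ratios must be finite and > 0")

    def values(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[chrom][strand]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s["+"]) for c, s in self.data.items()}

    def mirrored(self) -> "RatioTrack":
        return RatioTrack(
            data={
                c: {"+": strands["-"][::-1].copy(), "-": strands["+"][::-1].copy()}
                for c, strands in self.data.items()
            },
            pseudocount=self.pseudocount,
        )


# ---------------------------------------------------------------------------
# bedGraph IO (0-based half-open intervals, one file per strand)


def _read_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    tracks = {c: np.zeros(size, dtype=float) for c, size in chrom_sizes.items()}
    covered = {c: np.zeros(size, dtype=bool) for c, size in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
            chrom, start, end, value = parts
            if chrom not in tracks:
                raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            s, e, v = int(start), int(end), float(value)
            if not (0 <= s < e <= chrom_sizes[chrom]):
                raise ValueError(
                    f"{path}: line {lineno}: interval [{s},{e}) out of bounds for {chrom}"
                )
            if v < 0:
                raise ValueError(f"{path}: line {lineno}: negative value {v}")
            if covered[chrom][s:e].any():
                raise ValueError(f"{path}: line {lineno}: overlapping interval [{s},{e}) on {chrom}")
            covered[chrom][s:e] = True
            tracks[chrom][s:e] = v
    return tracks


def read_strand_signal(
    path_plus: str | Path,
    path_minus: str | Path,
    chrom_sizes: Mapping[str, int],
    sample_id: str = "",
    replicate: int = 0,
) -> StrandSignal:
    """Load a per-strand bedGraph pair into dense per-base vectors.

    Uncovered bases are zero; overlapping intervals within one strand are an
    error.
    """
    plus = _read_bedgraph(path_plus, chrom_sizes)
    minus = _read_bedgraph(path_minus, chrom_sizes)
    data = {c: {"+": plus[c], "-": minus[c]} for c in chrom_sizes}
    return StrandSignal(data=data, sample_id=sample_id, replicate=replicate)


def _write_bedgraph(track: Mapping[str, np.ndarray], path: str | Path) -> None:
    # Run-length encode constant stretches to keep files small.
    with open(path, "w") as fh:
        for chrom in track:
            arr = np.asarray(track[chrom], dtype=float)
            if arr.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr) != 0)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks + 1, [arr.size]))
            for s, e in zip(starts, ends):
                v = float(arr[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")


def write_strand_signal(signal: StrandSignal, path_plus: str | Path, path_minus: str | Path) -> None:
    _write_bedgraph({c: signal.values(c, "+") for c in signal.data}, path_plus)
    _write_bedgraph({c: signal.values(c, "-") for c in signal.data}, path_minus)


# ---------------------------------------------------------------------------
# normalization / averaging / ratio


def _all_values(signal: StrandSignal, mask: Mapping[str, dict[str, np.ndarray]] | None = None) -> np.ndarray:
    chunks = []
    for chrom in sorted(signal.data):
        for strand in STRANDS:
            arr = signal.values(chrom, strand)
            chunks.append(arr[mask[chrom][strand]] if mask is not None else arr)
    return np.concatenate(chunks) if chunks else np.array([])


def median_normalize(signals: Sequence[StrandSignal], target: float = 1.0) -> list[StrandSignal]:
    """Rescale each sample so its median over jointly covered bases is ``target``.

    Covered = bases with nonzero intensity in *any* input sample (per
    chromosome and strand). A pure per-sample rescale: within-sample
    structure is untouched, so the operation is idempotent.
    """
    if not signals:
        return []
    sizes = signals[0].chrom_sizes
    for sig in signals[1:]:
        if sig.chrom_sizes != sizes:
            raise ValueError("samples have mismatched chromosome sets or sizes")
    mask = {
        c: {s: np.zeros(size, dtype=bool) for s in STRANDS} for c, size in sizes.items()
    }
    for sig in signals:
        for c in sizes:
            for s in STRANDS:
                mask[c][s] |= sig.values(c, s) > 0
    out = []
    for sig in signals:
        vals = _all_values(sig, mask)
        if vals.size == 0:
            raise ValueError(f"sample {sig.sample_id!r}: no covered bases in any input")
        med = float(np.median(vals))
        if med <= 0:
            raise ValueError(f"sample {sig.sample_id!r}: all-zero over covered bases")
        scale = target / med
        scaled = sig.copy()
        for c in sizes:
            for s in STRANDS:
                scaled.data[c][s] *= scale
        out.append(scaled)
    return out


def average_replicates(signals: Sequence[StrandSignal]) -> StrandSignal:
    """Per-base arithmetic mean across replicates, per strand."""
    if not signals:
        raise ValueError("need at least one replicate")
    sizes = signals[0].chrom_sizes
    for sig in signals[1:]:
        if sig.chrom_sizes != sizes:
            raise ValueError("replicates have mismatched chromosome sets or sizes")
    data = {
        c: {
            s: np.mean([sig.values(c, s) for sig in signals], axis=0)
            for s in STRANDS
        }
        for c in sizes
    }
    return StrandSignal(data=data, sample_id=signals[0].sample_id, replicate=0)


def default_pseudocount(wildtype: StrandSignal, fraction: float = 0.01) -> float:
    """``fraction`` x genome-wide median of the (averaged) WT track.

    The median is taken over strictly positive bases so sparse tracks still
    yield a usable scale.
    """
    vals = _all_values(wildtype)
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("wild-type track has no positive signal")
    return fraction * float(np.median(pos))


def ratio_track(
    mutant: StrandSignal,
    wildtype: StrandSignal,
    pseudocount: float | None = None,
) -> RatioTrack:
    """Per-base, per-strand linear ratio ``(mut + eps) / (wt + eps)``.

    Inputs should be normalized and replicate-averaged. ``pseudocount=None``
    uses :func:`default_pseudocount` (1% of the WT genome-wide median).
    """
    if mutant.chrom_sizes != wildtype.chrom_sizes:
        raise ValueError("mutant and wild-type have mismatched chromosomes")
    eps = default_pseudocount(wildtype) if pseudocount is None else float(pseudocount)
    if eps <= 0:
        raise ValueError(f"pseudocount must be > 0, got {eps}")
    data = {
        c: {
            s: (mutant.values(c, s) + eps) / (wildtype.values(c, s) + eps)
            for s in STRANDS
        }
        for c in mutant.data
    }
    return RatioTrack(data=data, pseudocount=eps)
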