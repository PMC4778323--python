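"""Gene annotation model: transcription units, anchors, and class labels.

Internal coordinates are 0-based half-open (BED convention) on a named
chromosome. A transcription unit carries two kinds of class information:

* ``biotype`` — what the feature is: a ``coding`` ORF, a stable untranslated
  transcript (``SUT``), a cryptic unstable transcript (``CUT``), or a
  ``dubious_orf`` (small ORFs unlikely to encode protein, frequently
  overlapping the flanks of canonical genes).
* ``promoter_class`` — ``TATA`` for promoters with a consensus TATA box,
  ``TATA-like`` for degenerate TBP-binding elements, ``unknown`` where no
  classification exists (the ncRNA classes have none).

Anchors are strand-aware: the transcription start site (TSS) of a ``-``
strand gene is its right-hand coordinate and its polyadenylation site (pA)
the left-hand one. Everything downstream (metagene binning, effect
injection) works in the gene's own frame of transcription, so these two
anchors are the only orientation logic annotation consumers need.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

BIOTYPES = ("coding", "SUT", "CUT", "dubious_orf")
PROMOTER_CLASSES = ("TATA", "TATA-like", "unknown")


@dataclass(frozen=True)
class GeneModel:
    """One annotated transcription unit.

    ``start``/``end`` are 0-based half-open genomic coordinates with
    ``end > start`` regardless of strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "coding"
    promoter_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.start < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"gene {self.gene_id!r}: unknown biotype {self.biotype!r}")
        if self.promoter_class not in PROMOTER_CLASSES:
            raise ValueError(
                f"gene {self.gene_id!r}: unknown promoter class {self.promoter_class!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def anchors(self) -> tuple[int, int]:
        """(TSS, pA) in genomic coordinates, strand-aware."""
        if self.strand == "+":
            return self.start, self.end
        return self.end, self.start


def gene_anchors(gene: GeneModel) -> tuple[int, int]:
    """Strand-aware (TSS, pA) anchor positions of ``gene``."""
    return gene.anchors


@dataclass
class GeneSet:
    """An ordered collection of genes plus the chromosome sizes they live on."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"gene {g.gene_id!r}: unknown chromosome {g.chrom!r}")
            if g.end > self.chrom_sizes[g.chrom]:
                raise ValueError(
                    f"gene {g.gene_id!r} extends to {g.end}, beyond {g.chrom} "
                    f"length {self.chrom_sizes[g.chrom]}"
                )
        self._index = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def by_id(self, gene_id: str) -> GeneModel:
        return self._index[gene_id]

    def select(
        self,
        biotype: str | None = None,
        promoter_class: str | None = None,
    ) -> list[GeneModel]:
        """Genes matching every given class constraint (None = no constraint)."""
        out = []
        for g in self.genes:
            if biotype is not None and g.biotype != biotype:
                continue
            if promoter_class is not None and g.promoter_class != promoter_class:
                continue
            out.append(g)
        return out

    def class_census(self) -> pd.DataFrame:
        """Counts of genes per (biotype, promoter_class)."""
        rows = [(g.biotype, g.promoter_class) for g in self.genes]
        df = pd.DataFrame(rows, columns=["biotype", "promoter_class"])
        return (
            df.value_counts(["biotype", "promoter_class"])
            .rename("n_genes")
            .reset_index()
            .sort_values(["biotype", "promoter_class"], ignore_index=True)
        )

    def mirrored(self) -> "GeneSet":
        """The coordinate-reflected, strand-flipped genome (x -> L - x).

        Anchor identity is preserved: a gene's TSS maps onto the mirrored
        gene's TSS. Used for strand-symmetry checks.
        """
        flip = {"+": "-", "-": "+"}
        genes = [
            replace(
                g,
                start=self.chrom_sizes[g.chrom] - g.end,
                end=self.chrom_sizes[g.chrom] - g.start,
                strand=flip[g.strand],
            )
            for g in self.genes
        ]
        return GeneSet(genes=genes, chrom_sizes=dict(self.chrom_sizes))


# ---------------------------------------------------------------------------
# readers / writers


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV ``chrom<TAB>length``."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def _parse_bed6(path: str | Path) -> Iterator[GeneModel]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"line {lineno}: BED6 needs 6 columns, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate: {exc}") from exc
            try:
                yield GeneModel(gene_id=name, chrom=chrom, start=s, end=e, strand=strand)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc


def _parse_gff3(path: str | Path) -> Iterator[GeneModel]:
    # GFF3 is 1-based inclusive; converted here to 0-based half-open.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"line {lineno}: GFF3 needs 9 columns, got {len(parts)}")
            chrom, _src, _type, start, end, _score, strand, _phase, attrs = parts
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate: {exc}") from exc
            gene_id = None
            for kv in attrs.split(";"):
                kv = kv.strip()
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if not gene_id:
                raise ValueError(f"line {lineno}: GFF3 attributes lack an ID= tag")
            try:
                yield GeneModel(gene_id=gene_id, chrom=chrom, start=s, end=e, strand=strand)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc


def read_gene_annotations(
    path: str | Path,
    format: str,
    chrom_sizes: Mapping[str, int],
) -> GeneSet:
    """Read gene annotations from BED6 or GFF3 into a :class:`GeneSet`.

    Biotype and promoter class default to ``coding``/``unknown``; attach the
    sidecar label table with :func:`assign_class_labels`.
    """
    fmt = format.upper()
    if fmt == "BED6":
        parser = _parse_bed6(path)
    elif fmt == "GFF3":
        parser = _parse_gff3(path)
    else:
        raise ValueError(f"unknown annotation format {format!r} (expected BED6 or GFF3)")
    try:
        genes = list(parser)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return GeneSet(genes=genes, chrom_sizes=dict(chrom_sizes))


def write_bed6(genes: GeneSet | Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_class_labels(path: str | Path) -> pd.DataFrame:
    """Sidecar TSV with header ``gene_id  biotype  promoter_class``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "biotype", "promoter_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: label table missing columns {sorted(missing)}")
    return df


def write_class_labels(genes: GeneSet | Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "biotype", "promoter_class"])
        for g in genes:
            w.writerow([g.gene_id, g.biotype, g.promoter_class])


def assign_class_labels(genes: GeneSet, labels: pd.DataFrame) -> GeneSet:
    """Apply a (gene_id, biotype, promoter_class) label table to a GeneSet.

    Unlabeled genes are untouched; every labeled gene_id must exist.
    """
    unknown = [gid for gid in labels["gene_id"] if gid not in genes]
    if unknown:
        raise ValueError(f"label table names unknown gene_ids: {unknown[:10]}")
    by_id = dict(zip(labels["gene_id"], zip(labels["biotype"], labels["promoter_class"])))
    updated = []
    for g in genes:
        if g.gene_id in by_id:
            biotype, pclass = by_id[g.gene_id]
            g = replace(g, biotype=biotype, promoter_class=pclass)
        updated.append(g)
    return GeneSet(genes=updated, chrom_sizes=dict(genes.chrom_sizes))
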